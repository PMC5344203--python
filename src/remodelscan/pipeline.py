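"""Config-driven orchestration of the full two-state chromatin analysis.

Stages: simulate (optional; otherwise tag/annotation paths are read from
the config), nucleosome calling per state, dynamics classification, NDR
analysis, promoter histone-mark states, enhancer identification and
classification, and the promoter-enhancer synergy table.  Every derived
threshold, fraction and seed lands in a versioned JSON run report; a
stage whose inputs and parameters are unchanged (content hash) is
skipped on re-runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dynamics, enhancers as enh_mod, io as gio, ndr as ndr_mod
from . import nucmap, promoter_hm, synthetic

log = logging.getLogger("remodelscan")

REPORT_SCHEMA_VERSION = 1


@dataclass
class StageParams:
    sigma: float = 20.0
    exclusion_bp: int = 147
    min_reads: int = 3
    scan_window_bp: int = 500
    tss_bin_bp: int = 5
    k_tss_clusters: int = 5
    k_fc_clusters: int = 4
    fc_min: float = 2.0
    pseudocount: float = 1.0
    synergy_fc_min: float = 1.5
    peak_window_bp: int = 1000
    peak_step_bp: int = 100
    peak_fdr: float = 0.001
    ndr_min_length: int = 150
    k_ndr_modes: int = 3


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    synthetic: synthetic.SyntheticConfig | None = None
    mnase_tags: dict[str, str] = field(default_factory=dict)   # state -> BED
    chip_tags: dict[str, dict[str, str]] = field(default_factory=dict)  # mark -> state -> BED
    annotation: str | None = None
    expression: str | None = None
    chrom_sizes: str | None = None
    params: StageParams = field(default_factory=StageParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        params = raw.pop("params", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if syn is not None:
            syn.setdefault("seed", cfg.seed)
            if "shift_range" in syn:
                syn["shift_range"] = tuple(syn["shift_range"])
            if "mark_bimodal_params" in syn:
                syn["mark_bimodal_params"] = {
                    m: synthetic.MarkMixture(**p)
                    for m, p in syn["mark_bimodal_params"].items()
                }
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        cfg.params = StageParams(**params)
        return cfg

    def validate(self) -> None:
        if self.synthetic is None:
            for state in ("A", "B"):
                if state not in self.mnase_tags:
                    raise ValueError(f"missing MNase tags for state {state}")
                if not Path(self.mnase_tags[state]).exists():
                    raise FileNotFoundError(self.mnase_tags[state])
            for need in ("annotation", "chrom_sizes"):
                if getattr(self, need) is None:
                    raise ValueError(f"missing {need}")
            for mark, paths in self.chip_tags.items():
                for state, p in paths.items():
                    if not Path(p).exists():
                        raise FileNotFoundError(p)


def _hash_inputs(*parts) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(repr(p).encode())
        if isinstance(p, (str, Path)) and Path(str(p)).exists():
            h.update(Path(str(p)).read_bytes())
    return h.hexdigest()[:16]


class _StageCache:
    """Skip a stage when its recorded input hash matches and its outputs
    are still present on disk."""

    def __init__(self, outdir: Path):
        self.path = outdir / ".stage_hashes.json"
        self.hashes = json.loads(self.path.read_text()) if self.path.exists() else {}

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        return self.hashes.get(stage) == digest and all(p.exists() for p in outputs)

    def record(self, stage: str, digest: str) -> None:
        self.hashes[stage] = digest
        self.path.write_text(json.dumps(self.hashes, indent=0, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in dependency order; returns the run report dict."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION, "seed": config.seed,
                    "stages": {}}

    def stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    def done(name, t0, **extra):
        # wall time goes to the log, not the report, so re-runs stay
        # byte-identical
        report["stages"][name] = dict(extra)
        log.info("stage %s done (%.2fs)", name, time.time() - t0)

    # ----- inputs ---------------------------------------------------------
    if config.synthetic is not None:
        t0 = stage("simulate")
        syn = config.synthetic
        data = synthetic.generate_dataset(syn)
        data.truth.write(outdir / "truth")
        syn.to_yaml(outdir / "synthetic_config.yaml")
        gio.write_annotation(data.truth.genes[["gene_id", "chrom", "strand", "tss", "tes"]]
                             if "tes" in data.truth.genes.columns else
                             data.truth.genes[["gene_id", "chrom", "strand", "tss"]],
                             outdir / "annotation.tsv")
        data.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        for state, tags in data.mnase.items():
            gio.write_tags(tags, outdir / f"mnase_{state}.bed")
        for (mark, state), tags in data.chip.items():
            gio.write_tags(tags, outdir / f"chip_{mark}_{state}.bed", read_length=50)
        chrom_sizes = data.truth.chrom_sizes
        genes = data.truth.genes
        expression = data.expression
        mnase = data.mnase
        chip = data.chip
        done("simulate", t0, n_genes=len(genes), n_enhancers=len(data.truth.enhancers))
    else:
        genes = gio.read_annotation(config.annotation)
        chrom_sizes = gio.read_chrom_sizes(config.chrom_sizes)
        expression = gio.read_expression(config.expression) if config.expression else None
        mnase = {s: gio.read_tags(path)[0] for s, path in config.mnase_tags.items()}
        chip = {(m, s): gio.read_tags(path)[0]
                for m, paths in config.chip_tags.items() for s, path in paths.items()}

    totals = {s: len(t) for s, t in mnase.items()}

    # ----- nucleosome maps ------------------------------------------------
    t0 = stage("nucmap")
    cache = _StageCache(outdir)
    digest = _hash_inputs(
        p.sigma, p.exclusion_bp, p.min_reads, p.scan_window_bp, totals, config.seed,
        config.synthetic, sorted(config.mnase_tags.items()),
    )
    call_paths = {s: outdir / f"calls_{s}.tsv" for s in ("A", "B")}
    calls = {}
    if cache.fresh("nucmap", digest, list(call_paths.values())):
        for state, path in call_paths.items():
            calls[state] = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        log.info("stage nucmap skipped (inputs unchanged)")
    else:
        for state in ("A", "B"):
            dyads, _dropped = nucmap.reads_to_dyads(mnase[state], chrom_sizes)
            calls[state] = nucmap.call_nucleosomes(
                dyads, totals[state], sigma=p.sigma,
                exclusion_bp=p.exclusion_bp, min_reads=p.min_reads,
            )
            calls[state].to_csv(call_paths[state], sep="\t", index=False)
            nucmap.write_calls(calls[state], outdir / f"calls_{state}.bed")
            track = nucmap.window_occupancy(dyads, chrom_sizes, totals[state], p.scan_window_bp)
            gio.write_bedgraph(
                track[["chrom", "start", "end", "occupancy"]].itertuples(index=False),
                outdir / f"occupancy_{state}.bedgraph",
            )
        cache.record("nucmap", digest)
    done("nucmap", t0, n_calls_a=len(calls["A"]), n_calls_b=len(calls["B"]))

    # ----- dynamics -------------------------------------------------------
    t0 = stage("dynamics")
    matches, match_summary = dynamics.match_nucleosomes(calls["A"], calls["B"])
    matches.to_csv(outdir / "matches.tsv", sep="\t", index=False)
    enrichment = (dynamics.feature_enrichment(calls["A"], genes, chrom_sizes)
                  if "tes" in genes.columns else None)
    if enrichment is not None:
        enrichment.to_csv(outdir / "feature_enrichment_A.tsv", sep="\t", index=False)
    mat_a = dynamics.tss_matrix(mnase["A"], genes, chrom_sizes, totals["A"], p.tss_bin_bp)
    mat_b = dynamics.tss_matrix(mnase["B"], genes, chrom_sizes, totals["B"], p.tss_bin_bp)
    clusters = dynamics.tss_difference_clusters(mat_a, mat_b, k=p.k_tss_clusters,
                                               seed=config.seed)
    clusters.labels.rename("cluster").to_csv(outdir / "tss_clusters.tsv", sep="\t")
    done("dynamics", t0, fractions=match_summary["fractions_union"],
         counts=match_summary["counts"], tss_degenerate=clusters.degenerate)
    report["dynamics_summary"] = {
        k: v for k, v in match_summary.items() if k != "counts"
    } | {"counts": match_summary["counts"]}

    # ----- promoter NDRs --------------------------------------------------
    t0 = stage("ndr_promoter")
    ndr_table = ndr_mod.promoter_ndr_occupancy(
        mnase["A"], mnase["B"], genes, chrom_sizes, totals["A"], totals["B"]
    )
    ndr_table.to_csv(outdir / "promoter_ndr.tsv", sep="\t", index=False)
    assoc = {}
    if expression is not None:
        for state in ("A", "B"):
            assoc[state] = ndr_mod.ndr_expression_association(ndr_table, expression, state)
    done("ndr_promoter", t0, association=assoc)
    report["ndr_expression"] = assoc

    # ----- promoter histone marks ----------------------------------------
    marks = sorted({m for (m, _s) in chip})
    thresholds: dict[str, promoter_hm.HMThreshold] = {}
    levels = {}
    if marks:
        t0 = stage("hmstates")
        chip_totals = {key: len(t) for key, t in chip.items()}
        for state in ("A", "B"):
            levels[state] = pd.DataFrame({
                mark: promoter_hm.promoter_mark_levels(
                    chip[(mark, state)], genes, chip_totals[(mark, state)])
                for mark in marks
            })
            levels[state].to_csv(outdir / f"promoter_levels_{state}.tsv", sep="\t")
        for mark in marks:
            pooled = np.concatenate([levels["A"][mark], levels["B"][mark]])
            thresholds[mark] = promoter_hm.auto_threshold(pooled, mark=mark,
                                                          seed=config.seed)
        states = {s: promoter_hm.assign_promoter_states(levels[s], thresholds)
                  for s in ("A", "B")}
        for s, df in states.items():
            df.to_csv(outdir / f"promoter_states_{s}.tsv", sep="\t")
        transitions = promoter_hm.state_transitions(states["A"]["state"], states["B"]["state"])
        transitions.to_csv(outdir / "promoter_state_transitions.tsv", sep="\t")
        fc_clusters = promoter_hm.cluster_mark_fold_changes(
            levels["A"], levels["B"], fc_min=p.fc_min, k=p.k_fc_clusters,
            pseudocount=p.pseudocount, seed=config.seed,
        )
        if not fc_clusters.empty:
            fc_clusters.labels.rename("cluster").to_csv(
                outdir / "promoter_fc_clusters.tsv", sep="\t")
        gain_modes = {}
        for mark in ("H3K4me3", "H3K9ac"):
            if mark in marks:
                gm = promoter_hm.classify_gain_mode(
                    levels["A"][mark], levels["B"][mark], thresholds[mark],
                    fc_min=p.fc_min, pseudocount=p.pseudocount)
                gm.to_csv(outdir / f"gain_mode_{mark}.tsv", sep="\t")
                gain_modes[mark] = gm.value_counts().to_dict()
        done("hmstates", t0,
             thresholds={m: {"method": t.method, "value": round(t.value, 4)}
                         for m, t in thresholds.items()},
             gain_modes=gain_modes)
        report["hm_thresholds"] = {m: {"method": t.method, "value": t.value}
                                   for m, t in thresholds.items()}

    # ----- enhancers ------------------------------------------------------
    have_enh_marks = all((m, s) in chip for m in ("H3K4me1", "H3K27ac", "H3K4me3")
                         for s in ("A", "B"))
    if have_enh_marks:
        t0 = stage("enhancers")
        peak_sets = {
            s: enh_mod.call_mark_peaks(chip[("H3K4me1", s)], chrom_sizes,
                                       p.peak_window_bp, p.peak_step_bp, p.peak_fdr)
            for s in ("A", "B")
        }
        merged = enh_mod.merge_peak_sets(peak_sets["A"], peak_sets["B"])
        enh_set, mix_fit = enh_mod.filter_peaks_to_enhancers(
            merged, {s: chip[("H3K4me3", s)] for s in ("A", "B")}, seed=config.seed)
        bg = {}
        enh_levels = {}
        for mark in ("H3K4me1", "H3K27ac"):
            for s in ("A", "B"):
                enh_levels[(mark, s)] = enh_mod.interval_rpkm(chip[(mark, s)], enh_set)
            bg[mark] = {
                s: enh_mod.background_false_positive_threshold(
                    chip[(mark, s)], chrom_sizes, max(10, len(enh_set)),
                    seed=config.seed)
                for s in ("A", "B")
            }
        t_k4me1 = {s: bg["H3K4me1"][s]["threshold"] for s in ("A", "B")}
        t_k27ac = {s: bg["H3K27ac"][s]["threshold"] for s in ("A", "B")}
        enh_states = {
            s: enh_mod.classify_enhancer_states(
                enh_levels[("H3K4me1", s)], enh_levels[("H3K27ac", s)],
                t_k4me1[s], t_k27ac[s])
            for s in ("A", "B")
        }
        for s in ("A", "B"):
            enh_set[f"state_{s}"] = enh_states[s]
            enh_set[f"k4me1_{s}"] = enh_levels[("H3K4me1", s)]
            enh_set[f"k27ac_{s}"] = enh_levels[("H3K27ac", s)]
        transitions = enh_mod.enhancer_state_transitions(enh_states["A"], enh_states["B"])
        transitions.to_csv(outdir / "enhancer_state_transitions.tsv", sep="\t")
        nearest = enh_mod.assign_nearest_gene(enh_set, genes)
        enh_set = enh_set.merge(nearest, on="enhancer_id", how="left")
        enh_set.to_csv(outdir / "enhancers.tsv", sep="\t", index=False)
        done("enhancers", t0, n_peaks_merged=len(merged), n_enhancers=len(enh_set),
             k4me3_mixture_threshold=(mix_fit.threshold if mix_fit else None),
             background_thresholds={"H3K4me1": t_k4me1, "H3K27ac": t_k27ac})
        report["enhancer_thresholds"] = {
            "k4me3_mixture": mix_fit.threshold if mix_fit else None,
            "H3K4me1": t_k4me1, "H3K27ac": t_k27ac,
        }

        # enhancer NDRs in state-B active enhancers
        t0 = stage("ndr_enhancer")
        active_b = enh_set[enh_set["state_B"] == "active"]
        endrs = ndr_mod.scan_enhancer_ndrs(active_b, calls["B"], p.ndr_min_length)
        if len(endrs):
            modes = ndr_mod.cluster_ndr_modes(endrs, mnase["A"], mnase["B"],
                                              chrom_sizes, seed=config.seed)
            modes.to_csv(outdir / "enhancer_ndrs.tsv", sep="\t", index=False)
            mode_counts = modes["mode"].value_counts().to_dict()
        else:
            endrs.to_csv(outdir / "enhancer_ndrs.tsv", sep="\t", index=False)
            mode_counts = {}
        length_summary = ndr_mod.ndr_length_summary(endrs)
        done("ndr_enhancer", t0, **length_summary, mode_counts=mode_counts)
        report["enhancer_ndrs"] = {**length_summary, "mode_counts": mode_counts}

        # synergy
        if expression is not None:
            t0 = stage("synergy")
            c = p.pseudocount
            expr_fc = pd.Series(
                np.log2((expression["fpkm_b"] + c) / (expression["fpkm_a"] + c)).to_numpy(),
                index=expression["gene_id"].to_numpy(),
            )
            assigned = enh_set[enh_set["assigned"] == True]  # noqa: E712
            enh_fc = pd.Series(
                np.log2((assigned["k27ac_B"] + c) / (assigned["k27ac_A"] + c)).to_numpy(),
                index=assigned["gene_id"].to_numpy(),
            )
            enh_fc = enh_fc.groupby(level=0).max()
            prom_fc = None
            if levels:
                prom_fc = promoter_hm.mark_fold_changes(levels["A"], levels["B"], c)
                keep_cols = [m for m in ("H3K27ac", "H3K9ac") if m in prom_fc.columns]
                prom_fc = prom_fc[keep_cols] if keep_cols else None
            synergy = enh_mod.promoter_enhancer_synergy(
                expr_fc, enh_fc, prom_fc, fc_min=p.synergy_fc_min)
            synergy["table"].to_csv(outdir / "synergy.tsv", sep="\t")
            done("synergy", t0, n_up=len(synergy["up"]), n_down=len(synergy["down"]))
            report["synergy"] = {"n_up": len(synergy["up"]), "n_down": len(synergy["down"])}

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    return report
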