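"""Synthetic two-state chromatin data with planted, recorded ground truth.

The generator emulates the statistical structure of an MNase-seq /
ChIP-seq / RNA-seq comparison of two cell states (here called ``A`` for
the progenitor, e.g. neural stem cells, and ``B`` for the differentiated
state, e.g. neurons):

* per-gene nucleosome arrays with a canonical -1 / NDR / +1 arrangement
  around each TSS, plus intergenic filler arrays;
* per-nucleosome dynamics labels (fixed / shift / loss / gain) realised
  as a second dyad map for state B;
* a gene subset whose promoter NDR window is occupied in A and free in B,
  with a continuous occupancy weight driving expression;
* enhancers carrying nucleosome arrays whose state-B rearrangement follows
  one of three NDR-formation modes (eviction, shift toward 5', shift
  toward 3');
* bimodal promoter histone-mark levels and active/poised/off enhancer
  states, rendered as uniformly placed ChIP tags over a uniform genomic
  background;
* expression tables where log2 FPKM is negatively coupled to promoter-NDR
  occupancy, with enhancer-synergy genes whose expression fold change
  matches the sign of their enhancer's H3K27ac fold change.

Everything planted is recorded in a :class:`TruthRecord` so downstream
recovery can be scored exactly.  All randomness flows from one master
seed through named, independent streams: adding a mark or a state never
perturbs the draws of another output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio

MARKS = ["H3K4me1", "H3K4me3", "H3K9ac", "H3K27ac", "H3K27me3"]
STATES = ["A", "B"]
DYNAMICS_LABELS = ["fixed", "shift", "loss", "gain"]
NDR_MODES = ["eviction", "shift5", "shift3"]

#: half-width of the 147-bp nucleosome footprint
HALF_FOOTPRINT = 73

_UNIT_BP = 6000          # genome layout unit: one gene OR one enhancer
_TSS_OFFSET = 2500       # TSS position within a gene unit
_ENH_OFFSET = 2500       # enhancer start within an enhancer unit
_ENH_LENGTH = 1000


class ConfigError(ValueError):
    pass


class CapacityError(ConfigError):
    """The requested genome cannot host the requested elements."""


@dataclass
class MarkMixture:
    """Two-component promoter-level mixture for one histone mark (RPKM-like
    arbitrary level units; read counts are proportional to the level)."""

    low_mean: float
    high_mean: float
    low_sd: float
    high_sd: float
    weight_high: float  # mixing weight of the high (marked) component

    def validate(self) -> None:
        if not 0.0 <= self.weight_high <= 1.0:
            raise ConfigError("weight_high must lie in [0, 1]")
        if min(self.low_mean, self.high_mean, self.low_sd, self.high_sd) < 0:
            raise ConfigError("mixture parameters must be non-negative")


def _default_mixtures() -> dict[str, MarkMixture]:
    mix = {
        "H3K4me1": MarkMixture(2.0, 20.0, 1.0, 4.0, 0.5),
        "H3K4me3": MarkMixture(2.0, 20.0, 1.0, 4.0, 0.5),
        "H3K9ac": MarkMixture(2.0, 20.0, 1.0, 4.0, 0.5),
        "H3K27ac": MarkMixture(2.0, 20.0, 1.0, 4.0, 0.5),
        # K27me3 promoter levels are near-unimodal: two overlapping modes,
        # so the valley detector must defer to the K-means fallback.
        "H3K27me3": MarkMixture(5.0, 10.0, 2.5, 3.0, 0.5),
    }
    return mix


@dataclass
class SyntheticConfig:
    """Parameters of the planted genome; defaults define the study
    conditions the pipeline is validated under."""

    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 120
    spacing_mean: int = 180           # nucleosome repeat length, bp
    fuzziness_bp: float = 20.0        # sd of read dyads around a planted dyad
    coverage: float = 20.0            # mean reads per planted nucleosome
    dynamics_fractions: dict[str, float] = field(
        default_factory=lambda: {"fixed": 0.10, "shift": 0.80, "loss": 0.05, "gain": 0.05}
    )
    shift_range: tuple[int, int] = (1, 120)   # planted |shift| interval, bp
    n_enhancers: int = 40
    genic_nucleosomes: int = 13       # +1..+N array length per gene
    upstream_nucleosomes: int = 3     # -1..-M array upstream of the NDR
    mark_bimodal_params: dict[str, MarkMixture] = field(default_factory=_default_mixtures)
    mark_persistence: float = 0.7     # P(state B mark == state A mark)
    chip_reads_per_level: float = 3.0   # mean tags per level unit per element
    chip_background_per_kb: float = 1.0  # mean background tags per kb
    ndr_mode_fractions: dict[str, float] = field(
        default_factory=lambda: {"eviction": 1 / 3, "shift5": 1 / 3, "shift3": 1 / 3}
    )
    ndr_dynamic_fraction: float = 0.3  # genes NDR-occupied in A, free in B
    ndr_stable_max_weight: float = 1.0  # occupancy ceiling for stable-NDR genes
    expression_coupling: float = 1.0   # slope on log2 FPKM per occupancy unit
    expression_baseline: float = 6.0   # log2(FPKM+1) at zero NDR occupancy
    expression_noise_sd: float = 0.3
    synergy_effect: float = 2.0        # log2 FC applied to enhancer-synergy genes
    seed: int = 0

    def validate(self) -> None:
        if set(self.dynamics_fractions) != set(DYNAMICS_LABELS):
            raise ConfigError("dynamics_fractions must cover fixed/shift/loss/gain")
        if abs(sum(self.dynamics_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("dynamics_fractions must sum to 1")
        if set(self.ndr_mode_fractions) != set(NDR_MODES):
            raise ConfigError("ndr_mode_fractions must cover eviction/shift5/shift3")
        if abs(sum(self.ndr_mode_fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("ndr_mode_fractions must sum to 1")
        for frac in list(self.dynamics_fractions.values()) + list(
            self.ndr_mode_fractions.values()
        ) + [self.ndr_dynamic_fraction, self.mark_persistence]:
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.coverage <= 0:
            raise ConfigError("coverage must be positive")
        lo, hi = self.shift_range
        if not (1 <= lo <= hi <= 127):
            raise ConfigError(
                "shift_range must lie within [1, 127] (larger moves read as loss+gain)"
            )
        if self.expression_coupling < 0:
            raise ConfigError("expression_coupling must be >= 0")
        for mark, mix in self.mark_bimodal_params.items():
            if mark not in MARKS:
                raise ConfigError(f"unknown mark {mark!r}")
            mix.validate()

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["shift_range"] = list(self.shift_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["shift_range"] = tuple(data["shift_range"])
        data["mark_bimodal_params"] = {
            m: MarkMixture(**p) for m, p in data["mark_bimodal_params"].items()
        }
        return cls(**data)


def _stream(config_seed: int, *labels: str) -> np.random.Generator:
    """Independent named RNG stream derived from the master seed."""
    words = [config_seed & 0x7FFFFFFF] + [zlib.crc32(s.encode()) for s in labels]
    return np.random.default_rng(np.random.SeedSequence(words))


@dataclass
class TruthRecord:
    """Everything the generator planted, for exact downstream scoring."""

    genes: pd.DataFrame        # annotation + per-gene truth columns
    enhancers: pd.DataFrame    # loci + per-state states/levels + NDR mode
    nucleosomes: pd.DataFrame  # dyad_a/dyad_b maps + labels + weights
    chrom_sizes: dict[str, int]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.enhancers.to_csv(outdir / "truth_enhancers.tsv", sep="\t", index=False)
        self.nucleosomes.to_csv(outdir / "truth_nucleosomes.tsv", sep="\t", index=False)
        gio.write_chrom_sizes(self.chrom_sizes, outdir / "chrom.sizes")

    @classmethod
    def read(cls, outdir: str | Path) -> "TruthRecord":
        outdir = Path(outdir)
        return cls(
            genes=pd.read_csv(outdir / "truth_genes.tsv", sep="\t",
                              dtype={"gene_id": str, "chrom": str}),
            enhancers=pd.read_csv(outdir / "truth_enhancers.tsv", sep="\t",
                                  dtype={"enhancer_id": str, "chrom": str}),
            nucleosomes=pd.read_csv(
                outdir / "truth_nucleosomes.tsv", sep="\t", dtype={"chrom": str},
            ).fillna({"gene_id": "", "enhancer_id": ""}),
            chrom_sizes=gio.read_chrom_sizes(outdir / "chrom.sizes"),
        )


# ---------------------------------------------------------------------------
# annotation


def build_annotation(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Lay out genes and enhancers on the synthetic genome.

    The genome is a grid of 6-kb units; each hosts one gene (TSS centered
    so +/-1 kb promoters never overlap) or one enhancer.  Occupied units
    are scattered uniformly, which keeps elements well separated: ChIP
    peaks of adjacent elements never come within the 1-kb peak-merging
    distance, and every enhancer sits >= 2 kb from every TSS.  Strand is
    drawn per gene.  Deterministic under the seed.
    """
    config.validate()
    units_per_chrom = config.chrom_length // _UNIT_BP
    capacity = units_per_chrom * config.n_chroms
    n_elements = config.n_genes + config.n_enhancers
    if n_elements > capacity:
        raise CapacityError(
            f"{n_elements} elements need {_UNIT_BP} bp each; genome holds {capacity}"
        )

    rng = _stream(config.seed, "annotation")
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    chrom_names = list(chrom_sizes)

    chosen = np.sort(rng.choice(capacity, size=n_elements, replace=False))
    enh_mask = np.zeros(n_elements, dtype=bool)
    if config.n_enhancers:
        enh_mask[rng.choice(n_elements, size=config.n_enhancers, replace=False)] = True

    rows = []
    enh_rows = []
    g_i = e_i = 0
    for unit_id, is_enh in zip(chosen, enh_mask):
        chrom = chrom_names[int(unit_id) // units_per_chrom]
        base = (int(unit_id) % units_per_chrom) * _UNIT_BP
        if is_enh:
            start = base + _ENH_OFFSET
            enh_rows.append({"enhancer_id": f"e{e_i:04d}", "chrom": chrom,
                             "start": start, "end": start + _ENH_LENGTH})
            e_i += 1
        else:
            tss = base + _TSS_OFFSET
            strand = "+" if rng.random() < 0.5 else "-"
            span = 75 + config.genic_nucleosomes * config.spacing_mean
            tes = tss + span if strand == "+" else tss - span
            rows.append({"gene_id": f"g{g_i:04d}", "chrom": chrom, "strand": strand,
                         "tss": tss, "tes": tes})
            g_i += 1
    genes = pd.DataFrame(rows).sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)
    enhancers = pd.DataFrame(enh_rows, columns=["enhancer_id", "chrom", "start", "end"])
    if len(enhancers):
        enhancers = enhancers.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes, enhancers, chrom_sizes


# ---------------------------------------------------------------------------
# nucleosome truth


def _gene_nucleosome_offsets(config: SyntheticConfig) -> list[tuple[int, str]]:
    """Dyad offsets (gene-direction coordinates relative to TSS) of the
    canonical array: -M..-1 upstream, NDR over [-200, +50], +1..+N genic."""
    s = config.spacing_mean
    offsets: list[tuple[int, str]] = []
    for k in range(1, config.upstream_nucleosomes + 1):
        offsets.append((-275 - (k - 1) * s, f"-{k}"))
    for k in range(1, config.genic_nucleosomes + 1):
        offsets.append((75 + (k - 1) * s, f"+{k}"))
    return offsets


NDR_CENTER_OFFSET = -75  # center of the [-200, +50] promoter NDR window


def plant_nucleosome_truth(
    genes: pd.DataFrame,
    enhancers: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: SyntheticConfig,
) -> TruthRecord:
    """Plant the two dyad maps and all per-object truth labels.

    Ordinary ("array") nucleosomes draw a dynamics label from
    ``dynamics_fractions`` with exact (rounded) counts; shifts move the
    state-B dyad by a uniform draw from ``shift_range`` with random sign.
    Promoter-NDR and enhancer-NDR nucleosomes are planted separately with
    origin tags so their engineered dynamics do not distort the global
    fractions bookkeeping.
    """
    config.validate()
    rng = _stream(config.seed, "truth")
    lo, hi = config.shift_range

    nuc_rows: list[dict] = []

    def add_nuc(chrom, dyad_a, dyad_b, label, origin, gene_id="", enhancer_id="",
                weight_a=1.0, weight_b=1.0):
        nuc_rows.append(
            {
                "chrom": chrom,
                "dyad_a": dyad_a if dyad_a is not None else np.nan,
                "dyad_b": dyad_b if dyad_b is not None else np.nan,
                "label": label,
                "origin": origin,
                "gene_id": gene_id,
                "enhancer_id": enhancer_id,
                "weight_a": weight_a,
                "weight_b": weight_b,
            }
        )

    # --- gene arrays + intergenic fillers --------------------------------
    # when promoter-NDR occupancy is planted, the -1/+1 nucleosomes
    # flanking the NDR are strongly positioned and pinned fixed so the
    # planted occupancy contrast stays clean; otherwise they join the
    # dynamics draw like every other array nucleosome
    pin_flanks = (config.ndr_dynamic_fraction > 0
                  or config.ndr_stable_max_weight > 0)
    offsets = _gene_nucleosome_offsets(config)
    array_sites: list[tuple[str, int, str]] = []  # (chrom, dyad, gene_id)
    for gene in genes.itertuples():
        sign = 1 if gene.strand == "+" else -1
        for off, name in offsets:
            dyad = gene.tss + sign * off
            if not (HALF_FOOTPRINT <= dyad < chrom_sizes[gene.chrom] - HALF_FOOTPRINT):
                continue
            if pin_flanks and name in ("-1", "+1"):
                add_nuc(gene.chrom, dyad, dyad, "fixed", "promoter_flank", gene.gene_id)
            else:
                array_sites.append((gene.chrom, dyad, gene.gene_id))

    # intergenic filler arrays in the back stretch of each occupied unit
    # (MNase-only; they generate no ChIP signal)
    s = config.spacing_mean
    for gene in genes.itertuples():
        base = gene.tss - _TSS_OFFSET
        for k in range(4):
            dyad = base + 5100 + k * s
            if dyad < chrom_sizes[gene.chrom] - HALF_FOOTPRINT:
                array_sites.append((gene.chrom, dyad, ""))
    for enh in enhancers.itertuples():
        base = enh.start - _ENH_OFFSET
        for k in range(5):
            dyad = base + 4300 + k * s
            if dyad < chrom_sizes[enh.chrom] - HALF_FOOTPRINT:
                array_sites.append((enh.chrom, dyad, ""))

    # dynamics labels with exact rounded counts, shuffled deterministically
    n_array = len(array_sites)
    counts = {lab: int(round(config.dynamics_fractions[lab] * n_array))
              for lab in DYNAMICS_LABELS}
    while sum(counts.values()) > n_array:
        counts["shift"] -= 1
    while sum(counts.values()) < n_array:
        counts["shift"] += 1
    labels = np.array(
        [lab for lab in DYNAMICS_LABELS for _ in range(counts[lab])], dtype=object
    )
    rng.shuffle(labels)

    for (chrom, dyad, gene_id), label in zip(array_sites, labels):
        if label == "fixed":
            add_nuc(chrom, dyad, dyad, "fixed", "array", gene_id)
        elif label == "shift":
            # state-B dyad assigned afterwards: consecutive shifted
            # nucleosomes move as a block (see _assign_block_shifts)
            add_nuc(chrom, dyad, None, "shift", "array", gene_id)
        elif label == "loss":
            add_nuc(chrom, dyad, None, "loss", "array", gene_id)
        else:  # gain
            add_nuc(chrom, None, dyad, "gain", "array", gene_id)

    # --- promoter NDR occupancy ------------------------------------------
    gene_truth = genes.copy()
    n_dyn = int(round(config.ndr_dynamic_fraction * len(genes)))
    dyn_idx = rng.choice(len(genes), size=n_dyn, replace=False) if n_dyn else np.array([], int)
    is_dyn = np.zeros(len(genes), dtype=bool)
    is_dyn[dyn_idx] = True
    w_a = np.empty(len(genes))
    w_b = np.empty(len(genes))
    stable_w = rng.uniform(0.0, 1.0, size=len(genes)) * config.ndr_stable_max_weight
    w_a[:] = stable_w
    w_b[:] = stable_w
    w_a[is_dyn] = rng.uniform(0.7, 1.0, size=n_dyn)
    w_b[is_dyn] = 0.0
    gene_truth["ndr_dynamic"] = is_dyn
    gene_truth["ndr_weight_a"] = w_a
    gene_truth["ndr_weight_b"] = w_b

    for i, gene in enumerate(genes.itertuples()):
        sign = 1 if gene.strand == "+" else -1
        dyad = gene.tss + sign * NDR_CENTER_OFFSET
        wa, wb = float(w_a[i]), float(w_b[i])
        if wa == 0.0 and wb == 0.0:
            continue
        label = "loss" if (wa > 0 and wb == 0) else "fixed"
        add_nuc(gene.chrom, dyad if wa > 0 else None, dyad if wb > 0 else None,
                label, "promoter_ndr", gene.gene_id, weight_a=wa, weight_b=wb)

    # --- enhancer nucleosome arrays and NDR modes ------------------------
    enh_truth = enhancers.copy()
    if len(enhancers):
        mode_counts = {m: int(round(config.ndr_mode_fractions[m] * len(enhancers)))
                       for m in NDR_MODES}
        while sum(mode_counts.values()) > len(enhancers):
            mode_counts["eviction"] -= 1
        while sum(mode_counts.values()) < len(enhancers):
            mode_counts["eviction"] += 1
        modes = np.array([m for m in NDR_MODES for _ in range(mode_counts[m])],
                         dtype=object)
        rng.shuffle(modes)
        enh_truth["ndr_mode"] = modes

        s = config.spacing_mean
        for enh in enh_truth.itertuples():
            center = (enh.start + enh.end) // 2
            mode = enh.ndr_mode
            # state A: full array at -2s..+2s around the element center
            offs_a = [-2 * s, -s, 0, s, 2 * s]
            if mode == "eviction":
                moved = {0: None}
            elif mode == "shift5":
                moved = {0: -150, -s: -150, -2 * s: -150}
            else:  # shift3
                moved = {0: +150, s: +150, 2 * s: +150}
            for off in offs_a:
                dyad_a = center + off
                if off in moved:
                    if moved[off] is None:
                        add_nuc(enh.chrom, dyad_a, None, "loss", "enhancer_ndr",
                                enhancer_id=enh.enhancer_id)
                    else:
                        add_nuc(enh.chrom, dyad_a, dyad_a + moved[off], "shift",
                                "enhancer_ndr", enhancer_id=enh.enhancer_id)
                else:
                    add_nuc(enh.chrom, dyad_a, dyad_a, "fixed", "enhancer_ndr",
                            enhancer_id=enh.enhancer_id)
    else:
        enh_truth["ndr_mode"] = pd.Series(dtype=object)

    nucleosomes = pd.DataFrame(
        nuc_rows,
        columns=["chrom", "dyad_a", "dyad_b", "label", "origin", "gene_id",
                 "enhancer_id", "weight_a", "weight_b"],
    )
    _assign_block_shifts(nucleosomes, chrom_sizes, config, rng)
    _enforce_b_separation(nucleosomes, config)

    truth = TruthRecord(genes=gene_truth, enhancers=enh_truth,
                        nucleosomes=nucleosomes, chrom_sizes=dict(chrom_sizes))
    _plant_mark_states(truth, config)
    _plant_expression_truth(truth, config)
    return truth


#: minimum center-to-center distance between planted state-B nucleosomes;
#: slightly above one footprint so neighbouring dyads stay resolvable
_MIN_B_SEPARATION = 175


def _assign_block_shifts(
    nucleosomes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> None:
    """Assign state-B dyads to shift-labeled array nucleosomes.

    Nucleosomes do not reposition independently: neighbours at ~180-bp
    spacing cannot each move up to +/-127 bp without clashing.  Instead,
    maximal runs of consecutive shift-labeled nucleosomes (broken at
    non-shift labels or gaps beyond two repeat lengths) slide together by
    one signed displacement drawn uniformly from ``shift_range``,
    emulating coherent array repositioning.
    """
    lo, hi = config.shift_range
    arrays = nucleosomes["origin"] == "array"
    for chrom in sorted(chrom_sizes):
        sub = nucleosomes[arrays & (nucleosomes["chrom"] == chrom)
                          & nucleosomes["dyad_a"].notna()]
        sub = sub.sort_values("dyad_a")
        run: list[int] = []
        prev_pos = None

        def flush(run: list[int]) -> None:
            if not run:
                return
            u = int(rng.integers(lo, hi + 1)) * (1 if rng.random() < 0.5 else -1)
            pos = nucleosomes.loc[run, "dyad_a"].to_numpy() + u
            pos = np.clip(pos, HALF_FOOTPRINT, chrom_sizes[chrom] - HALF_FOOTPRINT - 1)
            nucleosomes.loc[run, "dyad_b"] = pos

        for row in sub.itertuples():
            pos = row.dyad_a
            if row.label != "shift":
                flush(run)
                run = []
            else:
                if run and prev_pos is not None and pos - prev_pos > 2 * config.spacing_mean:
                    flush(run)
                    run = []
                run.append(row.Index)
            prev_pos = pos
        flush(run)


def _enforce_b_separation(nucleosomes: pd.DataFrame, config: SyntheticConfig) -> None:
    """Compress block shifts at their boundaries so planted state-B dyads
    keep at least ``_MIN_B_SEPARATION`` bp center-to-center.

    A rightward-sliding block is capped against its right-hand stationary
    neighbour (right-to-left pass), a leftward one against its left-hand
    neighbour (left-to-right pass); displacements stay within
    ``shift_range`` and a shift squeezed back onto its own state-A dyad is
    relabeled fixed.
    """
    _lo, hi = config.shift_range
    sep = _MIN_B_SEPARATION
    present = nucleosomes["dyad_b"].notna()
    for _chrom, sub in nucleosomes[present].groupby("chrom"):
        idx = sub.sort_values("dyad_b").index.to_numpy()
        b = nucleosomes.loc[idx, "dyad_b"].to_numpy(dtype=float)
        a = nucleosomes.loc[idx, "dyad_a"].to_numpy(dtype=float)
        movable = ((nucleosomes.loc[idx, "label"] == "shift")
                   & (nucleosomes.loc[idx, "origin"] == "array")).to_numpy()
        for _ in range(2):
            for k in range(len(idx) - 2, -1, -1):  # cap against right neighbour
                if movable[k] and b[k] > b[k + 1] - sep:
                    b[k] = max(b[k + 1] - sep, a[k] - hi)
            for k in range(1, len(idx)):  # raise against left neighbour
                if movable[k] and b[k] < b[k - 1] + sep:
                    b[k] = min(b[k - 1] + sep, a[k] + hi)
        nucleosomes.loc[idx, "dyad_b"] = b
        squeezed = idx[movable & (b == a)]
        nucleosomes.loc[squeezed, "label"] = "fixed"


def _plant_mark_states(truth: TruthRecord, config: SyntheticConfig) -> None:
    """Draw per-gene per-mark boolean promoter states and per-enhancer
    chromatin states for both cell states, with configurable persistence."""
    rng = _stream(config.seed, "mark-states")
    n = len(truth.genes)
    for mark in MARKS:
        p_high = config.mark_bimodal_params[mark].weight_high
        state_a = rng.random(n) < p_high
        keep = rng.random(n) < config.mark_persistence
        redraw = rng.random(n) < p_high
        state_b = np.where(keep, state_a, redraw)
        truth.genes[f"{mark}_marked_a"] = state_a
        truth.genes[f"{mark}_marked_b"] = state_b.astype(bool)

    n_enh = len(truth.enhancers)
    if n_enh:
        state_probs = np.array([0.65, 0.20, 0.15])  # active, poised, off
        states = np.array(["active", "poised", "off"])
        sa = states[rng.choice(3, size=n_enh, p=state_probs)]
        keep = rng.random(n_enh) < config.mark_persistence
        sb = np.where(keep, sa, states[rng.choice(3, size=n_enh, p=state_probs)])
        truth.enhancers["state_a"] = sa
        truth.enhancers["state_b"] = sb
    else:
        truth.enhancers["state_a"] = pd.Series(dtype=object)
        truth.enhancers["state_b"] = pd.Series(dtype=object)


def _nearest_tss_gene(truth: TruthRecord) -> pd.Series:
    """Planted nearest gene per enhancer (by TSS distance to the midpoint)."""
    out = []
    for enh in truth.enhancers.itertuples():
        mid = (enh.start + enh.end) // 2
        sub = truth.genes[truth.genes["chrom"] == enh.chrom]
        d = (sub["tss"] - mid).abs()
        out.append(sub.loc[d.idxmin(), "gene_id"] if len(sub) else "")
    return pd.Series(out, index=truth.enhancers.index, dtype=object)


def _plant_expression_truth(truth: TruthRecord, config: SyntheticConfig) -> None:
    """FPKM per state coupled to promoter-NDR occupancy, plus enhancer-synergy
    genes whose expression fold change tracks the enhancer H3K27ac change."""
    rng = _stream(config.seed, "expression")
    genes = truth.genes
    n = len(genes)
    noise_a = rng.normal(0.0, config.expression_noise_sd, size=n)
    noise_b = rng.normal(0.0, config.expression_noise_sd, size=n)
    log2_a = (config.expression_baseline
              - config.expression_coupling * genes["ndr_weight_a"].to_numpy() + noise_a)
    log2_b = (config.expression_baseline
              - config.expression_coupling * genes["ndr_weight_b"].to_numpy() + noise_b)

    # enhancer-synergy genes: expression FC sign follows enhancer K27ac FC sign
    synergy = np.zeros(n, dtype=bool)
    if len(truth.enhancers):
        nearest = _nearest_tss_gene(truth)
        truth.enhancers["planted_gene_id"] = nearest
        gene_pos = {g: i for i, g in enumerate(genes["gene_id"])}
        for enh in truth.enhancers.itertuples():
            up = enh.state_a != "active" and enh.state_b == "active"
            down = enh.state_a == "active" and enh.state_b != "active"
            if not (up or down) or enh.planted_gene_id not in gene_pos:
                continue
            i = gene_pos[enh.planted_gene_id]
            synergy[i] = True
            delta = config.synergy_effect if up else -config.synergy_effect
            log2_b[i] = log2_a[i] + delta + rng.normal(0.0, config.expression_noise_sd)
    else:
        truth.enhancers["planted_gene_id"] = pd.Series(dtype=object)

    genes["synergy_case"] = synergy
    genes["fpkm_a"] = np.maximum(0.0, 2.0 ** log2_a - 1.0)
    genes["fpkm_b"] = np.maximum(0.0, 2.0 ** log2_b - 1.0)


# ---------------------------------------------------------------------------
# read sampling


def sample_mnase_reads(
    truth: TruthRecord, config: SyntheticConfig, cell_state: str
) -> pd.DataFrame:
    """MNase tags for one cell state.

    Per planted nucleosome, Poisson(coverage x weight) reads with dyads
    Normal(planted dyad, fuzziness) rounded to integers; strand uniform;
    the 5' position is back-computed from the dyad by the 147-bp geometry.
    Reads whose footprint leaves the chromosome are dropped.
    """
    if cell_state not in STATES:
        raise ConfigError(f"cell_state must be one of {STATES}")
    rng = _stream(config.seed, "mnase", cell_state)
    dyad_col = f"dyad_{cell_state.lower()}"
    weight_col = f"weight_{cell_state.lower()}"
    nucs = truth.nucleosomes[truth.nucleosomes[dyad_col].notna()]

    chroms: list[str] = []
    pos5s: list[np.ndarray] = []
    strands: list[np.ndarray] = []
    for nuc in nucs.itertuples():
        dyad = int(getattr(nuc, dyad_col))
        weight = float(getattr(nuc, weight_col))
        n_reads = rng.poisson(config.coverage * weight)
        if n_reads == 0:
            continue
        read_dyads = np.rint(rng.normal(dyad, config.fuzziness_bp, size=n_reads)).astype(np.int64)
        plus = rng.random(n_reads) < 0.5
        pos5 = np.where(plus, read_dyads - HALF_FOOTPRINT, read_dyads + HALF_FOOTPRINT)
        size = truth.chrom_sizes[nuc.chrom]
        start = np.where(plus, pos5, pos5 - gio.TAG_BED_LENGTH + 1)
        end = start + gio.TAG_BED_LENGTH
        ok = (start >= 0) & (end <= size)
        if not ok.any():
            continue
        chroms.extend([nuc.chrom] * int(ok.sum()))
        pos5s.append(pos5[ok])
        strands.append(np.where(plus[ok], "+", "-"))

    if not chroms:
        return pd.DataFrame({"chrom": pd.array([], dtype="str"),
                             "pos5": np.array([], dtype=np.int64),
                             "strand": pd.array([], dtype="str")})
    tags = pd.DataFrame(
        {
            "chrom": pd.array(chroms, dtype="str"),
            "pos5": np.concatenate(pos5s),
            "strand": pd.array(np.concatenate(strands), dtype="str"),
        }
    )
    return tags.sort_values(["chrom", "pos5"], kind="stable").reset_index(drop=True)


def _mark_level(rng: np.random.Generator, mix: MarkMixture, marked: bool) -> float:
    if marked:
        level = rng.normal(mix.high_mean, mix.high_sd)
    else:
        level = rng.normal(mix.low_mean, mix.low_sd)
    return max(0.0, level)


#: enhancer ChIP level parameters (level units; >= 3-fold above background)
ENHANCER_LEVELS = {
    "H3K4me1": {"on": (15.0, 3.0), "off": (1.0, 0.4)},
    "H3K27ac": {"on": (12.0, 3.0), "off": (1.0, 0.4)},
}


def sample_hm_reads(
    truth: TruthRecord, config: SyntheticConfig, mark: str, cell_state: str
) -> pd.DataFrame:
    """ChIP tags for one histone mark in one cell state.

    Each promoter draws a level from the mark's two-component mixture
    according to its planted boolean state; each enhancer draws H3K4me1 /
    H3K27ac levels from its planted chromatin state.  Tags are placed
    uniformly within the element with a Poisson count proportional to the
    level, on top of a uniform genome-wide background.
    """
    if mark not in MARKS:
        raise ConfigError(f"unknown mark {mark!r}")
    if cell_state not in STATES:
        raise ConfigError(f"cell_state must be one of {STATES}")
    rng = _stream(config.seed, "chip", mark, cell_state)
    mix = config.mark_bimodal_params[mark]
    sfx = cell_state.lower()

    chroms: list[str] = []
    positions: list[np.ndarray] = []

    def place(chrom: str, start: int, end: int, n_reads: int) -> None:
        if n_reads <= 0:
            return
        pos = rng.integers(start, end, size=n_reads)
        chroms.extend([chrom] * n_reads)
        positions.append(pos.astype(np.int64))

    levels = []
    for gene in truth.genes.itertuples():
        marked = bool(getattr(gene, f"{mark}_marked_{sfx}"))
        level = _mark_level(rng, mix, marked)
        levels.append(level)
        p_start, p_end = gio.promoter_interval(gene.tss)
        n_reads = rng.poisson(level * config.chip_reads_per_level)
        place(gene.chrom, p_start, p_end, int(n_reads))
    truth.genes[f"{mark}_level_{sfx}"] = levels

    if mark in ENHANCER_LEVELS and len(truth.enhancers):
        enh_levels = []
        for enh in truth.enhancers.itertuples():
            state = getattr(enh, f"state_{sfx}")
            if mark == "H3K4me1":
                key = "on" if state in ("active", "poised") else "off"
            else:  # H3K27ac
                key = "on" if state == "active" else "off"
            mean, sd = ENHANCER_LEVELS[mark][key]
            level = max(0.0, rng.normal(mean, sd))
            enh_levels.append(level)
            n_reads = rng.poisson(level * config.chip_reads_per_level)
            place(enh.chrom, enh.start, enh.end, int(n_reads))
        truth.enhancers[f"{mark}_level_{sfx}"] = enh_levels

    # margin keeps notional read extents inside the chromosome
    for chrom, size in truth.chrom_sizes.items():
        n_bg = rng.poisson(config.chip_background_per_kb * size / 1000.0)
        place(chrom, gio.TAG_BED_LENGTH, size - gio.TAG_BED_LENGTH, int(n_bg))

    if not chroms:
        return pd.DataFrame({"chrom": pd.array([], dtype="str"),
                             "pos5": np.array([], dtype=np.int64),
                             "strand": pd.array([], dtype="str")})
    pos5 = np.concatenate(positions)
    strand = np.where(rng.random(len(pos5)) < 0.5, "+", "-")
    tags = pd.DataFrame(
        {"chrom": pd.array(chroms, dtype="str"), "pos5": pos5,
         "strand": pd.array(strand, dtype="str")}
    )
    return tags.sort_values(["chrom", "pos5"], kind="stable").reset_index(drop=True)


def sample_expression(truth: TruthRecord, config: SyntheticConfig) -> pd.DataFrame:
    """Expression table (gene_id, fpkm_a, fpkm_b) from the planted truth."""
    return truth.genes[["gene_id", "fpkm_a", "fpkm_b"]].copy()


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: TruthRecord
    mnase: dict[str, pd.DataFrame]               # state -> tags
    chip: dict[tuple[str, str], pd.DataFrame]    # (mark, state) -> tags
    expression: pd.DataFrame


def generate_dataset(
    config: SyntheticConfig, marks: list[str] | None = None
) -> SyntheticDataset:
    """Run the whole generator: annotation, truth, reads, expression."""
    genes, enhancers, chrom_sizes = build_annotation(config)
    truth = plant_nucleosome_truth(genes, enhancers, chrom_sizes, config)
    mnase = {state: sample_mnase_reads(truth, config, state) for state in STATES}
    chip = {}
    for mark in (marks if marks is not None else MARKS):
        for state in STATES:
            chip[(mark, state)] = sample_hm_reads(truth, config, mark, state)
    expression = sample_expression(truth, config)
    return SyntheticDataset(config=config, truth=truth, mnase=mnase,
                            chip=chip, expression=expression)
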