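"""Enhancer identification, chromatin-state classification and the
promoter-enhancer synergy analysis.

Enhancers are H3K4me1-enriched regions found by a Poisson sliding-window
scan (1000-bp windows, Benjamini-Hochberg FDR 0.1%), merged across the
two cell states keeping the highest-scoring peak, and cleaned of
promoter-like elements by removing peaks whose H3K4me3 level exceeds a
two-Gaussian mixture threshold.  Chromatin states (active / poised /
off) are called against false-positive thresholds derived from random
background regions: the smallest level among the top 10% of background
signals.  Each enhancer is tied to its nearest TSS, and the synergy
analysis collects the genes whose expression fold change agrees in sign
with their enhancer's H3K27ac fold change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

ENHANCER_STATES = ["active", "poised", "off"]


# ---------------------------------------------------------------------------
# peak calling


def _bh_reject(pvals: np.ndarray, fdr: float) -> np.ndarray:
    """Benjamini-Hochberg: boolean mask of rejected hypotheses."""
    n = len(pvals)
    if n == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order]
    thresh = fdr * (np.arange(1, n + 1) / n)
    passing = np.nonzero(ranked <= thresh)[0]
    out = np.zeros(n, dtype=bool)
    if len(passing):
        out[order[: passing[-1] + 1]] = True
    return out


def call_mark_peaks(
    tags: pd.DataFrame,
    chrom_sizes: dict[str, int],
    window_bp: int = 1000,
    step_bp: int = 100,
    fdr: float = 0.001,
    merge_distance: int = 1000,
) -> pd.DataFrame:
    """Poisson sliding-window peak calling with BH FDR control.

    Window counts are tested against Poisson(genome-wide tag rate x
    window_bp); significant overlapping windows merge into peaks and
    peaks separated by less than ``merge_distance`` merge further.  The
    score is the merged peak's tag density in reads per kb per million.
    """
    total = len(tags)
    if total == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "read_count"])
    genome = sum(chrom_sizes.values())
    lam = total / genome * window_bp
    by_chrom = {c: np.sort(s["pos5"].to_numpy()) for c, s in
                tags.groupby("chrom", observed=True)}

    window_rows = []  # (chrom, start, end, count)
    counts_all = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = by_chrom.get(chrom, np.array([], dtype=np.int64))
        starts = np.arange(0, max(1, size - window_bp + 1), step_bp)
        counts = np.searchsorted(pos, starts + window_bp) - np.searchsorted(pos, starts)
        for s, c in zip(starts, counts):
            window_rows.append((chrom, int(s), int(s) + window_bp))
        counts_all.append(counts)
    counts_all = np.concatenate(counts_all)
    pvals = stats.poisson.sf(counts_all - 1, lam)
    keep = _bh_reject(pvals, fdr)

    # merge overlapping significant windows, then nearby peaks
    peaks: list[list] = []
    for (chrom, s, e), ok in zip(window_rows, keep):
        if not ok:
            continue
        if peaks and peaks[-1][0] == chrom and s - peaks[-1][2] < merge_distance:
            peaks[-1][2] = max(peaks[-1][2], e)
        else:
            peaks.append([chrom, s, e])
    # refine each merged region to its densest window_bp stretch, so the
    # reported peak matches the element scale rather than the window spread
    rows = []
    for chrom, s, e in peaks:
        pos = by_chrom.get(chrom, np.array([], dtype=np.int64))
        if e - s > window_bp:
            sub_starts = np.arange(s, e - window_bp + 1, 50)
            sub_counts = (np.searchsorted(pos, sub_starts + window_bp)
                          - np.searchsorted(pos, sub_starts))
            best = int(sub_starts[np.argmax(sub_counts)])
            s, e = best, best + window_bp
        count = int(np.searchsorted(pos, e) - np.searchsorted(pos, s))
        score = count * 1e9 / ((e - s) * total)
        rows.append((chrom, s, e, score, count))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "read_count"])


def merge_peak_sets(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> pd.DataFrame:
    """Union of two scored peak sets: each overlapping group collapses to
    its single highest-scoring member (ties: earlier start, then first set)."""
    both = pd.concat(
        [peaks_a.assign(set_id=0), peaks_b.assign(set_id=1)], ignore_index=True
    ).sort_values(["chrom", "start", "end"], kind="stable")
    kept_rows = []
    group: list = []
    group_end = None
    group_chrom = None

    def flush():
        if not group:
            return
        best = max(group, key=lambda r: (r.score, -r.start, -r.set_id))
        kept_rows.append(best)

    for row in both.itertuples():
        if group and row.chrom == group_chrom and row.start < group_end:
            group.append(row)
            group_end = max(group_end, row.end)
        else:
            flush()
            group = [row]
            group_chrom = row.chrom
            group_end = row.end
    flush()
    out = pd.DataFrame(
        [(r.chrom, r.start, r.end, r.score, getattr(r, "read_count", np.nan))
         for r in kept_rows],
        columns=["chrom", "start", "end", "score", "read_count"],
    )
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# mixture threshold


@dataclass
class MixtureFit:
    threshold: float | None
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    converged: bool
    degenerate: bool


def fit_two_gaussian_threshold(
    values: np.ndarray | pd.Series, seed: int = 0
) -> MixtureFit:
    """Two-component Gaussian mixture threshold.

    EM fit (quantile-initialized means, tolerance 1e-6, up to 500
    iterations); the threshold is the point between the two fitted means
    where the weighted component densities are equal.  Fits whose means
    sit closer than half the pooled sd are flagged degenerate and return
    no threshold.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(x) < 100:
        raise ValueError("need at least 100 values for a mixture threshold")
    means_init = np.percentile(x, [25, 75]).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, tol=1e-6, max_iter=500, random_state=seed,
        means_init=means_init, reg_covar=1e-9,
    )
    gm.fit(x)
    order = np.argsort(gm.means_.ravel())
    m1, m2 = gm.means_.ravel()[order]
    s1, s2 = np.sqrt(gm.covariances_.ravel()[order])
    w1, w2 = gm.weights_[order]
    pooled = np.sqrt((s1**2 + s2**2) / 2)
    degenerate = m2 - m1 < 0.5 * pooled
    if not degenerate and m2 > m1:
        # a true two-population fit is bimodal: the mixture density must
        # dip between the means (a unimodal sample split into overlapping
        # halves by EM has no interior minimum there)
        grid = np.linspace(m1, m2, 512)
        pdf = (w1 * stats.norm.pdf(grid, m1, max(s1, 1e-12))
               + w2 * stats.norm.pdf(grid, m2, max(s2, 1e-12)))
        imin = int(np.argmin(pdf))
        degenerate = imin in (0, len(grid) - 1)
    if degenerate:
        return MixtureFit(None, (m1, m2), (s1, s2), (w1, w2), bool(gm.converged_), True)

    def log_diff(t: float) -> float:
        return (np.log(w1) + stats.norm.logpdf(t, m1, s1)
                - np.log(w2) - stats.norm.logpdf(t, m2, s2))

    lo, hi = m1, m2
    if log_diff(lo) * log_diff(hi) < 0:
        threshold = float(optimize.brentq(log_diff, lo, hi, xtol=1e-9))
    else:  # no crossing between the means; take the closest-density point
        grid = np.linspace(lo, hi, 1024)
        threshold = float(grid[np.argmin(np.abs([log_diff(t) for t in grid]))])
    return MixtureFit(threshold, (m1, m2), (s1, s2), (w1, w2), bool(gm.converged_), False)


# ---------------------------------------------------------------------------
# levels and filtering


def interval_rpkm(
    tags: pd.DataFrame, intervals: pd.DataFrame, total_mapped: int | None = None
) -> np.ndarray:
    """RPKM of a tag library over arbitrary intervals (by tag pos5)."""
    total = len(tags) if total_mapped is None else total_mapped
    if total == 0:
        raise ValueError("zero mapped tags; RPKM undefined")
    by_chrom = {c: np.sort(s["pos5"].to_numpy()) for c, s in
                tags.groupby("chrom", observed=True)} if len(tags) else {}
    out = np.zeros(len(intervals))
    for i, iv in enumerate(intervals.itertuples()):
        pos = by_chrom.get(iv.chrom)
        if pos is None:
            continue
        count = np.searchsorted(pos, iv.end) - np.searchsorted(pos, iv.start)
        out[i] = count * 1e9 / ((iv.end - iv.start) * total)
    return out


def filter_peaks_to_enhancers(
    peaks: pd.DataFrame,
    k4me3_tags: dict[str, pd.DataFrame],
    seed: int = 0,
    manual_threshold: float | None = None,
) -> tuple[pd.DataFrame, MixtureFit | None]:
    """Drop promoter-like peaks: those whose H3K4me3 RPKM (max over the two
    cell states) exceeds the two-Gaussian mixture threshold.

    ``k4me3_tags`` maps cell state -> tag frame.  A degenerate mixture
    aborts unless ``manual_threshold`` is supplied.
    """
    levels = np.max(
        [interval_rpkm(t, peaks) for t in k4me3_tags.values()], axis=0
    )
    fit = None
    if manual_threshold is None:
        fit = fit_two_gaussian_threshold(levels, seed=seed)
        if fit.degenerate or fit.threshold is None:
            raise RuntimeError(
                "two-Gaussian fit degenerate; supply manual_threshold "
                f"(means={fit.means}, weights={fit.weights})"
            )
        threshold = fit.threshold
    else:
        threshold = manual_threshold
    keep = peaks[levels <= threshold].reset_index(drop=True).copy()
    keep["k4me3_level"] = levels[levels <= threshold]
    if "enhancer_id" not in keep.columns:
        keep.insert(0, "enhancer_id", [f"e{i:04d}" for i in range(len(keep))])
    return keep, fit


def background_false_positive_threshold(
    tags: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n_regions: int,
    region_length: int = 1000,
    seed: int = 0,
) -> dict:
    """False-positive level threshold from random background regions.

    ``n_regions`` non-overlapping windows of ``region_length`` are drawn
    uniformly (grid slots sampled without replacement); the threshold is
    the smallest value among the top 10% of per-region RPKMs
    (nearest-rank ceiling: the minimum of the ceil(n/10) largest values).
    """
    if n_regions < 10:
        raise ValueError("need at least 10 background regions")
    slots = []
    for chrom in sorted(chrom_sizes):
        n_slots = chrom_sizes[chrom] // region_length
        slots.extend((chrom, i * region_length) for i in range(n_slots))
    if len(slots) < n_regions:
        raise ValueError("genome too small for that many non-overlapping regions")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(slots), size=n_regions, replace=False)
    regions = pd.DataFrame(
        [(slots[i][0], slots[i][1], slots[i][1] + region_length) for i in chosen],
        columns=["chrom", "start", "end"],
    )
    levels = (interval_rpkm(tags, regions) if len(tags)
              else np.zeros(n_regions))
    return {
        "threshold": top_decile_minimum(levels),
        "n_regions": n_regions,
        "region_length": region_length,
        "seed": seed,
        "levels": levels,
    }


def top_decile_minimum(levels: np.ndarray) -> float:
    """Smallest value among the ceil(n/10) largest levels."""
    n = len(levels)
    k = int(np.ceil(n / 10))
    return float(np.sort(levels)[n - k])


# ---------------------------------------------------------------------------
# states, nearest genes, synergy


def classify_enhancer_states(
    k4me1_level: np.ndarray, k27ac_level: np.ndarray, t_k4me1: float, t_k27ac: float
) -> np.ndarray:
    """active / poised / off per enhancer from the two mark levels."""
    k4me1_level = np.asarray(k4me1_level, dtype=float)
    k27ac_level = np.asarray(k27ac_level, dtype=float)
    state = np.full(len(k4me1_level), "off", dtype=object)
    on = k4me1_level > t_k4me1
    state[on & (k27ac_level > t_k27ac)] = "active"
    state[on & ~(k27ac_level > t_k27ac)] = "poised"
    return state


def enhancer_state_transitions(states_a, states_b) -> pd.DataFrame:
    """3x3 active/poised/off transition counts; the total equals the
    enhancer count exactly."""
    matrix = pd.DataFrame(0, index=ENHANCER_STATES, columns=ENHANCER_STATES, dtype=int)
    for a, b in zip(states_a, states_b):
        matrix.loc[a, b] += 1
    return matrix


def assign_nearest_gene(enhancers: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest-TSS gene per enhancer with a strand-aware signed distance.

    Distance is |midpoint - TSS| minimized; ties go to the
    lexicographically smaller gene_id.  The signed distance is positive
    when the enhancer lies downstream of the TSS in the gene's direction.
    Enhancers on gene-free chromosomes come back unassigned.
    """
    rows = []
    by_chrom = {c: s.sort_values(["tss", "gene_id"]) for c, s in
                genes.groupby("chrom", observed=True)}
    for enh in enhancers.itertuples():
        mid = (enh.start + enh.end) // 2
        sub = by_chrom.get(enh.chrom)
        if sub is None or len(sub) == 0:
            rows.append((enh.enhancer_id, None, np.nan, False))
            continue
        d = (sub["tss"] - mid).abs()
        best = d.min()
        cands = sub[d == best].sort_values("gene_id")
        gene = cands.iloc[0]
        signed = mid - int(gene["tss"])
        if gene["strand"] == "-":
            signed = -signed
        rows.append((enh.enhancer_id, gene["gene_id"], signed, True))
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "signed_distance", "assigned"])


def promoter_enhancer_synergy(
    expression_fc: pd.Series,
    enhancer_k27ac_fc: pd.Series,
    promoter_fc: pd.DataFrame | None = None,
    fc_min: float = 1.5,
) -> dict:
    """Genes whose expression log2 FC agrees in sign with their enhancer
    H3K27ac log2 FC, both at least log2(fc_min) in magnitude.

    All inputs are indexed by gene_id (enhancer FCs already mapped to
    their nearest gene).  Returns the table ordered by descending
    enhancer K27ac log2 FC, split into up- and downregulated sets.
    """
    joined = pd.DataFrame({"expr_log2fc": expression_fc}).join(
        pd.DataFrame({"enh_k27ac_log2fc": enhancer_k27ac_fc}), how="inner"
    )
    if promoter_fc is not None:
        joined = joined.join(promoter_fc.add_prefix("prom_"), how="left")
    if len(joined) == 0:
        return {"table": joined, "up": [], "down": [], "empty": True}
    min_l2 = np.log2(fc_min)
    same_sign = np.sign(joined["expr_log2fc"]) * np.sign(joined["enh_k27ac_log2fc"]) > 0
    big = (joined["expr_log2fc"].abs() >= min_l2) & (joined["enh_k27ac_log2fc"].abs() >= min_l2)
    table = joined[same_sign & big].sort_values("enh_k27ac_log2fc", ascending=False)
    up = table.index[table["enh_k27ac_log2fc"] > 0].tolist()
    down = table.index[table["enh_k27ac_log2fc"] < 0].tolist()
    return {"table": table, "up": up, "down": down, "empty": len(table) == 0}
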