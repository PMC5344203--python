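"""Nucleosome-depleted regions in promoters and enhancers.

Promoter NDR occupancy is the extended-read coverage over the closed
[-200, +50] window around the TSS (strand-aware, 251 bp), RPKM-normalized
per cell state; its association with expression is summarized with a
Spearman correlation and an optional two-group Wilcoxon rank-sum test.

Enhancer NDRs are maximal stretches inside an enhancer that intersect no
nucleosome-call footprint and are at least 150 bp long (one nucleosome's
worth of free DNA).  Their formation mode is labeled by comparing the
state-A occupancy around the NDR with the state-B gap: a nucleosome
present in A at the gap center with symmetric flanks means eviction; a
lateral displacement of the occupancy center of mass means a shift
toward 5' (negative) or 3' (positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .dynamics import _coverage_arrays
from .nucmap import footprint_interval

#: promoter NDR window relative to the TSS, closed on both ends
NDR_UPSTREAM = 200
NDR_DOWNSTREAM = 50

MIN_NDR_LENGTH = 150


def promoter_ndr_window(tss: int, strand: str) -> tuple[int, int]:
    """Chromosome-coordinate half-open window for the [-200, +50] NDR."""
    if strand == "+":
        return tss - NDR_UPSTREAM, tss + NDR_DOWNSTREAM + 1
    return tss - NDR_DOWNSTREAM, tss + NDR_UPSTREAM + 1


def promoter_ndr_occupancy(
    tags_a: pd.DataFrame,
    tags_b: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    total_a: int | None = None,
    total_b: int | None = None,
) -> pd.DataFrame:
    """Per-gene NDR occupancy in both cell states.

    Occupancy is the mean per-bp extended-read coverage over the window
    scaled to RPKM (reads x 1e9 / (window_bp x library size)).  Windows
    clipped at a chromosome end are flagged.
    """
    total_a = len(tags_a) if total_a is None else total_a
    total_b = len(tags_b) if total_b is None else total_b
    cov_a = _coverage_arrays(tags_a, chrom_sizes)
    cov_b = _coverage_arrays(tags_b, chrom_sizes)
    rows = []
    for gene in genes.itertuples():
        lo, hi = promoter_ndr_window(int(gene.tss), gene.strand)
        size = chrom_sizes[gene.chrom]
        clipped = lo < 0 or hi > size
        c_lo, c_hi = max(0, lo), min(size, hi)
        width = hi - lo
        occ_a = cov_a[gene.chrom][c_lo:c_hi].sum() * 1e9 / (width * total_a)
        occ_b = cov_b[gene.chrom][c_lo:c_hi].sum() * 1e9 / (width * total_b)
        rows.append((gene.gene_id, gene.chrom, c_lo, c_hi, occ_a, occ_b, clipped))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "occupancy_a", "occupancy_b", "clipped"],
    )


def ndr_expression_association(
    ndr_table: pd.DataFrame,
    expression: pd.DataFrame,
    cell_state: str = "A",
    groups: dict[str, list[str]] | None = None,
) -> dict:
    """Spearman correlation of NDR occupancy vs FPKM for one cell state,
    plus an optional two-group Wilcoxon rank-sum comparison of occupancy."""
    sfx = cell_state.lower()
    joined = ndr_table.merge(expression, on="gene_id", how="inner")
    if len(joined) < 3:
        raise ValueError("fewer than 3 genes joined between NDR and expression tables")
    occ = joined[f"occupancy_{sfx}"].to_numpy()
    fpkm = joined[f"fpkm_{sfx}"].to_numpy()
    rho, pval = stats.spearmanr(occ, fpkm)
    out = {"n": int(len(joined)), "spearman_rho": float(rho), "spearman_p": float(pval)}
    if groups is not None:
        (name1, ids1), (name2, ids2) = list(groups.items())
        x1 = joined.loc[joined["gene_id"].isin(ids1), f"occupancy_{sfx}"]
        x2 = joined.loc[joined["gene_id"].isin(ids2), f"occupancy_{sfx}"]
        statv, p = stats.ranksums(x1, x2)
        out["wilcoxon"] = {
            "groups": (name1, name2),
            "n1": int(len(x1)),
            "n2": int(len(x2)),
            "statistic": float(statv),
            "p_value": float(p),
        }
    return out


def scan_enhancer_ndrs(
    enhancers: pd.DataFrame, calls: pd.DataFrame, min_length: int = MIN_NDR_LENGTH
) -> pd.DataFrame:
    """Maximal nucleosome-free stretches >= min_length inside each enhancer.

    A position is blocked when any call footprint [dyad-73, dyad+74)
    covers it; footprints reaching in from outside the enhancer still
    block, but reported NDRs are clipped to the enhancer interval.
    """
    rows = []
    by_chrom = {c: s["dyad"].to_numpy() for c, s in calls.groupby("chrom", observed=True)} \
        if len(calls) else {}
    for enh in enhancers.itertuples():
        dyads = by_chrom.get(enh.chrom, np.array([], dtype=np.int64))
        blocks = []
        for d in dyads:
            s, e = footprint_interval(int(d))
            if e > enh.start and s < enh.end:
                blocks.append((max(s, enh.start), min(e, enh.end)))
        blocks.sort()
        merged = []
        for s, e in blocks:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        cursor = enh.start
        gaps = []
        for s, e in merged:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < enh.end:
            gaps.append((cursor, enh.end))
        for s, e in gaps:
            if e - s >= min_length:
                rows.append((enh.enhancer_id, enh.chrom, s, e, e - s))
    return pd.DataFrame(rows, columns=["enhancer_id", "chrom", "start", "end", "length"])


def ndr_length_summary(ndrs: pd.DataFrame, lo: int = 150, hi: int = 250) -> dict:
    """Count of NDRs and the fraction with length in [lo, hi] (the
    single-nucleosome size class)."""
    n = len(ndrs)
    in_band = int(((ndrs["length"] >= lo) & (ndrs["length"] <= hi)).sum()) if n else 0
    return {"n_ndrs": n, "fraction_single_nucleosome": in_band / n if n else np.nan}


@dataclass
class NdrModeConfig:
    flank_bp: int = 1000
    bin_bp: int = 50
    k: int = 3
    center_halfwidth: int = 75     # bp around the NDR midpoint tested for eviction
    eviction_ratio: float = 2.0    # A-center must exceed this x A-flank trough
    shift_min_bp: float = 25.0     # |center-of-mass displacement| for a shift call


def _ndr_profile_matrix(
    ndrs: pd.DataFrame, cov: dict[str, np.ndarray], flank_bp: int, bin_bp: int
) -> np.ndarray:
    n_bins = 2 * flank_bp // bin_bp
    mat = np.zeros((len(ndrs), n_bins))
    for i, ndr in enumerate(ndrs.itertuples()):
        mid = (ndr.start + ndr.end) // 2
        arr = cov[ndr.chrom]
        lo = mid - flank_bp
        win = np.zeros(2 * flank_bp)
        s, e = max(0, lo), min(len(arr), mid + flank_bp)
        win[s - lo:s - lo + (e - s)] = arr[s:e]
        mat[i] = win.reshape(n_bins, bin_bp).mean(axis=1)
    return mat


def _label_from_profiles(
    mean_a: np.ndarray, mean_b: np.ndarray, cfg: NdrModeConfig
) -> str:
    n_bins = len(mean_a)
    offsets = (np.arange(n_bins) + 0.5) * cfg.bin_bp - cfg.flank_bp
    center = np.abs(offsets) <= cfg.center_halfwidth
    a_center = float(mean_a[center].mean())
    b_center = float(mean_b[center].mean())
    a_flank_trough = float(mean_a[~center].min())

    def com(profile: np.ndarray) -> float:
        total = profile.sum()
        return float((profile * offsets).sum() / total) if total > 0 else 0.0

    displacement = com(mean_b) - com(mean_a)
    if abs(displacement) > cfg.shift_min_bp:
        return "shift5" if displacement < 0 else "shift3"
    # eviction: the gap center was occupied in A and is empty in B
    if (a_center > cfg.eviction_ratio * a_flank_trough
            and a_center > cfg.eviction_ratio * b_center and a_center > 0):
        return "eviction"
    return "ambiguous"


def cluster_ndr_modes(
    ndrs: pd.DataFrame,
    tags_a: pd.DataFrame,
    tags_b: pd.DataFrame,
    chrom_sizes: dict[str, int],
    seed: int = 0,
    config: NdrModeConfig | None = None,
) -> pd.DataFrame:
    """K-means (k=3) over state-B occupancy around each NDR midpoint, then
    a semantic mode per cluster from the A-vs-B mean profiles.

    Returns the NDR table with ``cluster`` and ``mode`` columns.  With
    fewer NDRs than k, every NDR is labeled directly by the rule.
    """
    if len(ndrs) == 0:
        raise ValueError("no NDRs to cluster")
    cfg = config or NdrModeConfig()
    cov_a = _coverage_arrays(tags_a, chrom_sizes)
    cov_b = _coverage_arrays(tags_b, chrom_sizes)
    mat_a = _ndr_profile_matrix(ndrs, cov_a, cfg.flank_bp, cfg.bin_bp)
    mat_b = _ndr_profile_matrix(ndrs, cov_b, cfg.flank_bp, cfg.bin_bp)

    out = ndrs.copy()
    if len(ndrs) < cfg.k:
        out["cluster"] = -1
        out["mode"] = [
            _label_from_profiles(mat_a[i], mat_b[i], cfg) for i in range(len(ndrs))
        ]
        return out
    km = KMeans(n_clusters=cfg.k, n_init=10, random_state=seed)
    labels = km.fit_predict(mat_b)
    modes = {}
    for c in range(cfg.k):
        members = labels == c
        modes[c] = _label_from_profiles(mat_a[members].mean(axis=0),
                                        mat_b[members].mean(axis=0), cfg)
    out["cluster"] = labels
    out["mode"] = [modes[c] for c in labels]
    return out
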