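"""Histone-modification levels and combinatorial states in promoters.

Mark levels are RPKM over the +/-1 kb promoter.  Marks with a bimodal
promoter-level distribution (typically H3K4me1, H3K4me3, H3K9ac) are
thresholded at the KDE valley between the two modes; near-unimodal marks
(typically H3K27me3) fall back to a 1-D K-means (k=2) split.  A promoter
is "marked" when its level is strictly above the threshold; the
combinatorial state string is the sorted set of marked marks.

On top of the per-state calls the module counts state transitions
between the two cell states, clusters per-mark log2 fold changes of the
genes whose marks move at least ``fc_min``-fold, and classifies how an
active mark was gained (de novo vs increase from an existing level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from . import io as gio

GAIN_MODES = ["de_novo", "increase_existing", "unchanged", "lost"]


@dataclass(frozen=True)
class HMThreshold:
    mark: str
    method: str  # "valley" or "kmeans2"
    value: float


class UnimodalError(ValueError):
    """The level distribution has no usable valley; use kmeans2_threshold."""


def promoter_mark_levels(
    tags: pd.DataFrame,
    genes: pd.DataFrame,
    total_mapped: int | None = None,
    promoter_half: int = 1000,
) -> pd.Series:
    """RPKM of one mark over each +/-1 kb promoter.

    level = count x 1e9 / (width x total); tag position (pos5) decides
    membership.  Indexed by gene_id.
    """
    total = len(tags) if total_mapped is None else total_mapped
    if total == 0:
        raise ValueError("zero mapped tags; RPKM undefined")
    width = 2 * promoter_half
    by_chrom = {c: np.sort(s["pos5"].to_numpy()) for c, s in
                tags.groupby("chrom", observed=True)} if len(tags) else {}
    levels = np.zeros(len(genes))
    for i, gene in enumerate(genes.itertuples()):
        pos = by_chrom.get(gene.chrom)
        if pos is None:
            continue
        lo, hi = gio.promoter_interval(int(gene.tss), promoter_half)
        count = np.searchsorted(pos, hi) - np.searchsorted(pos, lo)
        levels[i] = count * 1e9 / (width * total)
    return pd.Series(levels, index=genes["gene_id"].to_numpy(), name="level")


def valley_threshold(
    levels: np.ndarray | pd.Series,
    mark: str = "",
    grid_points: int = 512,
    min_mode_ratio: float = 0.10,
) -> HMThreshold:
    """Threshold at the KDE valley between the two main modes.

    Gaussian KDE (Silverman bandwidth) on a grid from 0 to the 99th
    percentile; the two highest local maxima are located and the
    threshold is the density minimum strictly between them.  If the
    second mode is below ``min_mode_ratio`` of the first's height the
    distribution is treated as unimodal and an :class:`UnimodalError`
    directs the caller to :func:`kmeans2_threshold`.
    """
    x = np.asarray(levels, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 values for a density threshold")
    if np.ptp(x) == 0:
        raise ValueError("all values identical; no threshold exists")
    grid = np.linspace(0.0, np.percentile(x, 99), grid_points)
    density = gaussian_kde(x)(grid)
    interior = np.nonzero(
        (density[1:-1] >= density[:-2]) & (density[1:-1] > density[2:])
    )[0] + 1
    if len(interior) < 2:
        raise UnimodalError(f"{mark or 'sample'}: no two density modes found")
    top2 = interior[np.argsort(density[interior])][-2:]
    major, minor = max(top2, key=lambda i: density[i]), min(top2, key=lambda i: density[i])
    if density[minor] < min_mode_ratio * density[major]:
        raise UnimodalError(
            f"{mark or 'sample'}: second mode below {min_mode_ratio:.0%} of the first"
        )
    lo, hi = sorted((int(major), int(minor)))
    valley = lo + 1 + int(np.argmin(density[lo + 1:hi]))
    return HMThreshold(mark=mark, method="valley", value=float(grid[valley]))


def kmeans2_threshold(
    levels: np.ndarray | pd.Series, mark: str = "", seed: int = 0
) -> HMThreshold:
    """Two-class 1-D K-means split; threshold = midpoint of the centers."""
    x = np.asarray(levels, dtype=float).reshape(-1, 1)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct values for a k-means split")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    km.fit(x)
    c1, c2 = sorted(km.cluster_centers_.ravel())
    return HMThreshold(mark=mark, method="kmeans2", value=float((c1 + c2) / 2))


def auto_threshold(
    levels: np.ndarray | pd.Series, mark: str = "", seed: int = 0
) -> HMThreshold:
    """Valley threshold when the distribution is bimodal, K-means otherwise."""
    try:
        return valley_threshold(levels, mark=mark)
    except UnimodalError:
        return kmeans2_threshold(levels, mark=mark, seed=seed)


def assign_promoter_states(
    levels: pd.DataFrame, thresholds: dict[str, HMThreshold]
) -> pd.DataFrame:
    """Boolean mark calls and the combinatorial state string per gene.

    ``levels`` has one column per mark (RPKM), indexed by gene_id.  A
    level exactly at the threshold is NOT marked (strict inequality).
    Adds a ``bivalent`` flag (H3K4me3+ and H3K27me3+) when both marks
    are present.
    """
    marks = list(levels.columns)
    missing = [m for m in marks if m not in thresholds]
    if missing:
        raise KeyError(f"missing thresholds for {missing}")
    out = pd.DataFrame(index=levels.index)
    for mark in marks:
        out[f"{mark}_marked"] = levels[mark] > thresholds[mark].value
    marked_cols = [f"{m}_marked" for m in marks]
    out["state"] = [
        "+".join(sorted(m for m, flag in zip(marks, row) if flag)) or "none"
        for row in out[marked_cols].to_numpy()
    ]
    if "H3K4me3" in marks and "H3K27me3" in marks:
        out["bivalent"] = out["H3K4me3_marked"] & out["H3K27me3_marked"]
    return out


def state_transitions(states_a: pd.Series, states_b: pd.Series) -> pd.DataFrame:
    """Square transition-count matrix between the two cell states.

    Rows are state-A strings, columns state-B; row sums equal the per-state
    gene counts in A and the grand total equals the shared gene universe.
    """
    if not states_a.index.sort_values().equals(states_b.index.sort_values()):
        raise ValueError("state series must cover the same gene universe")
    states_b = states_b.reindex(states_a.index)
    universe = sorted(set(states_a) | set(states_b))
    matrix = pd.DataFrame(0, index=universe, columns=universe, dtype=int)
    for a, b in zip(states_a, states_b):
        matrix.loc[a, b] += 1
    return matrix


def mark_fold_changes(
    levels_a: pd.DataFrame, levels_b: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene per-mark log2((level_b + c) / (level_a + c))."""
    if not levels_a.index.equals(levels_b.index):
        raise ValueError("level tables must share the gene index")
    return np.log2((levels_b + pseudocount) / (levels_a + pseudocount))


@dataclass
class FoldChangeClusters:
    labels: pd.Series              # gene_id -> cluster (selected genes only)
    fold_changes: pd.DataFrame     # log2 FC matrix of the selected genes
    centroids: np.ndarray
    empty: bool


def cluster_mark_fold_changes(
    levels_a: pd.DataFrame,
    levels_b: pd.DataFrame,
    fc_min: float = 2.0,
    k: int = 4,
    pseudocount: float = 1.0,
    seed: int = 0,
) -> FoldChangeClusters:
    """K-means over the per-mark log2 fold-change vectors of the genes whose
    strongest mark change is at least ``fc_min``-fold."""
    fc = mark_fold_changes(levels_a, levels_b, pseudocount)
    selected = fc[fc.abs().max(axis=1) >= np.log2(fc_min)]
    if len(selected) == 0:
        return FoldChangeClusters(pd.Series(dtype=int), selected, np.empty((0, 0)), True)
    n_clusters = min(k, len(selected))
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    raw = km.fit_predict(selected.to_numpy())
    sizes = np.bincount(raw, minlength=n_clusters)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(n_clusters, dtype=int)
    remap[order] = np.arange(n_clusters)
    labels = pd.Series(remap[raw], index=selected.index)
    return FoldChangeClusters(labels, selected, km.cluster_centers_[order], False)


def classify_gain_mode(
    levels_a: pd.Series,
    levels_b: pd.Series,
    threshold: HMThreshold,
    fc_min: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.Series:
    """How an active mark was acquired (or lost) between the cell states.

    de_novo: below threshold in A, above in B; increase_existing: above in
    both with >= fc_min fold increase; lost: above in A, below in B;
    everything else: unchanged.  The four categories are exclusive and
    exhaustive.
    """
    t = threshold.value
    a = levels_a.to_numpy(dtype=float)
    b = levels_b.reindex(levels_a.index).to_numpy(dtype=float)
    fc = (b + pseudocount) / (a + pseudocount)
    mode = np.full(len(a), "unchanged", dtype=object)
    mode[(a <= t) & (b > t)] = "de_novo"
    mode[(a > t) & (b > t) & (fc >= fc_min)] = "increase_existing"
    mode[(a > t) & (b <= t)] = "lost"
    return pd.Series(mode, index=levels_a.index, name="gain_mode")
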