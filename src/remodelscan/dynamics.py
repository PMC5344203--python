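"""Cross-state nucleosome matching and dynamics classification.

Two nucleosome maps (state A, state B) are matched one-to-one per
chromosome.  A pair is eligible when the 147-bp footprints overlap by at
least 20 bp, i.e. |dyad_a - dyad_b| <= 127.  Among eligible pairings we
take the matching of maximum cardinality and, among those, minimum total
|shift|; because pair costs are point distances on a line, an optimal
matching can always be chosen non-crossing, which a banded dynamic
program finds exactly.  Matched pairs with zero displacement are
``fixed``; displaced pairs are ``shift`` (1..127 bp); unmatched state-A
calls are ``loss`` and unmatched state-B calls are ``gain``.

The module also assigns calls to genomic feature classes (promoter >
genic > intergenic precedence), builds strand-aware TSS-centered
composite profiles and matrices, and clusters per-gene occupancy
difference matrices with K-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .nucmap import HALF_FOOTPRINT

#: maximum |dyad_a - dyad_b| for a footprint overlap of >= 20 bp
MAX_SHIFT = 127

MATCH_COLUMNS = ["chrom", "dyad_a", "dyad_b", "status", "shift_bp"]


class UnsortedInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# matching


def _components(da: np.ndarray, db: np.ndarray, max_shift: int):
    """Split two sorted dyad arrays into independent blocks: no eligible
    pair crosses a block boundary."""
    events = [(int(p), 0, i) for i, p in enumerate(da)] + [
        (int(p), 1, i) for i, p in enumerate(db)
    ]
    events.sort()
    comps: list[tuple[list[int], list[int]]] = []
    cur_a: list[int] = []
    cur_b: list[int] = []
    # Links are cross-side only and positions ascend, so once an event sits
    # more than max_shift beyond the last position of BOTH sides, neither it
    # nor anything after it can pair into the open block.
    last_a = -np.inf
    last_b = -np.inf
    for pos, side, idx in events:
        if (cur_a or cur_b) and pos - last_a > max_shift and pos - last_b > max_shift:
            comps.append((cur_a, cur_b))
            cur_a, cur_b = [], []
        if side == 0:
            cur_a.append(idx)
            last_a = pos
        else:
            cur_b.append(idx)
            last_b = pos
    if cur_a or cur_b:
        comps.append((cur_a, cur_b))
    return comps


def _match_component(a: np.ndarray, b: np.ndarray, max_shift: int):
    """Exact max-cardinality / min-total-|shift| non-crossing matching of
    two small sorted position arrays.  Returns matched (i, j) index pairs."""
    na, nb = len(a), len(b)
    NEG = (-1, 0.0)
    # value[i][j] = (n_matches, -total_distance) best over a[:i], b[:j]
    value = [[(0, 0.0)] * (nb + 1) for _ in range(na + 1)]
    move = [[0] * (nb + 1) for _ in range(na + 1)]  # 1=skip-a, 2=skip-b, 3=match
    for i in range(na + 1):
        for j in range(nb + 1):
            if i == 0 and j == 0:
                continue
            best, arg = NEG, 0
            if i > 0 and j > 0 and abs(int(a[i - 1]) - int(b[j - 1])) <= max_shift:
                prev = value[i - 1][j - 1]
                cand = (prev[0] + 1, prev[1] - abs(int(a[i - 1]) - int(b[j - 1])))
                if cand > best:
                    best, arg = cand, 3
            if i > 0 and value[i - 1][j] > best:
                best, arg = value[i - 1][j], 1
            if j > 0 and value[i][j - 1] > best:
                best, arg = value[i][j - 1], 2
            value[i][j] = best
            move[i][j] = arg
    pairs = []
    i, j = na, nb
    while i > 0 or j > 0:
        m = move[i][j]
        if m == 3:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif m == 1:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def _check_sorted(calls: pd.DataFrame, name: str) -> None:
    for _, sub in calls.groupby("chrom", observed=True):
        if not sub["dyad"].is_monotonic_increasing:
            raise UnsortedInputError(f"{name} calls are not sorted by dyad per chromosome")


def match_nucleosomes(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, max_shift: int = MAX_SHIFT
) -> tuple[pd.DataFrame, dict]:
    """Match two call sets and classify every nucleosome.

    Returns (match table, summary).  The match table has one row per
    nucleosome event: fixed / shift rows carry both dyads and shift_bp =
    dyad_b - dyad_a; loss rows carry only dyad_a; gain rows only dyad_b.
    The summary reports the four fractions under the union denominator
    (matched pairs count once) and, for reference, the per-side totals.
    """
    _check_sorted(calls_a, "state A")
    _check_sorted(calls_b, "state B")
    rows = []
    chroms = sorted(set(calls_a["chrom"]) | set(calls_b["chrom"]))
    for chrom in chroms:
        da = calls_a.loc[calls_a["chrom"] == chrom, "dyad"].to_numpy(dtype=np.int64)
        db = calls_b.loc[calls_b["chrom"] == chrom, "dyad"].to_numpy(dtype=np.int64)
        matched_a = np.zeros(len(da), dtype=bool)
        matched_b = np.zeros(len(db), dtype=bool)
        for ia, ib in _components(da, db, max_shift):
            sub_a = da[ia]
            sub_b = db[ib]
            for pi, pj in _match_component(sub_a, sub_b, max_shift):
                i, j = ia[pi], ib[pj]
                matched_a[i] = True
                matched_b[j] = True
                delta = int(db[j] - da[i])
                status = "fixed" if delta == 0 else "shift"
                rows.append((chrom, int(da[i]), int(db[j]), status, delta))
        for i in np.nonzero(~matched_a)[0]:
            rows.append((chrom, int(da[i]), np.nan, "loss", np.nan))
        for j in np.nonzero(~matched_b)[0]:
            rows.append((chrom, np.nan, int(db[j]), "gain", np.nan))
    matches = pd.DataFrame(rows, columns=MATCH_COLUMNS)
    counts = matches["status"].value_counts().to_dict()
    for status in ("fixed", "shift", "loss", "gain"):
        counts.setdefault(status, 0)
    union = sum(counts.values())
    summary = {
        "counts": counts,
        "n_a": int(len(calls_a)),
        "n_b": int(len(calls_b)),
        "n_union": int(union),
        "fractions_union": {s: counts[s] / union if union else np.nan
                            for s in ("fixed", "shift", "loss", "gain")},
        "fractions_a": {s: counts[s] / len(calls_a) if len(calls_a) else np.nan
                        for s in ("fixed", "shift", "loss")},
        "fractions_b": {s: counts[s] / len(calls_b) if len(calls_b) else np.nan
                        for s in ("fixed", "shift", "gain")},
    }
    return matches, summary


# ---------------------------------------------------------------------------
# feature assignment


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _total_length(iv: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in iv)


def _subtract(iv: list[tuple[int, int]], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s, e in iv:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, min(ms, e)))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def feature_classes(
    genes: pd.DataFrame, chrom_sizes: dict[str, int], promoter_half: int = 1000
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Disjoint promoter / genic / intergenic interval sets per chromosome
    with precedence promoter > genic > intergenic.

    Genic spans TSS to TES; the annotation must carry a ``tes`` column.
    """
    if "tes" not in genes.columns:
        raise ValueError("annotation needs a 'tes' column for genic intervals")
    out: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for chrom, size in chrom_sizes.items():
        sub = genes[genes["chrom"] == chrom]
        promoters = _merge_intervals(
            [(max(0, t - promoter_half), min(size, t + promoter_half))
             for t in sub["tss"]]
        )
        bodies = _merge_intervals(
            [(max(0, min(t, e)), min(size, max(t, e)))
             for t, e in zip(sub["tss"], sub["tes"])]
        )
        genic = _subtract(bodies, promoters)
        intergenic = _subtract([(0, size)], _merge_intervals(promoters + genic))
        out[chrom] = {"promoter": promoters, "genic": genic, "intergenic": intergenic}
    return out


def feature_enrichment(
    calls: pd.DataFrame, genes: pd.DataFrame, chrom_sizes: dict[str, int],
    promoter_half: int = 1000,
) -> pd.DataFrame:
    """Call density (calls per kb) per feature class, assigning each call by
    its dyad with promoter > genic > intergenic precedence."""
    classes = feature_classes(genes, chrom_sizes, promoter_half)
    counts = {"promoter": 0, "genic": 0, "intergenic": 0}
    lengths = {"promoter": 0, "genic": 0, "intergenic": 0}
    for chrom in chrom_sizes:
        for name in counts:
            iv = classes.get(chrom, {}).get(name, [])
            lengths[name] += _total_length(iv)
            if not len(calls):
                continue
            dy = calls.loc[calls["chrom"] == chrom, "dyad"].to_numpy()
            for s, e in iv:
                counts[name] += int(((dy >= s) & (dy < e)).sum())
    rows = []
    for name in ("promoter", "genic", "intergenic"):
        kb = lengths[name] / 1000.0
        rows.append((name, counts[name], lengths[name],
                     counts[name] / kb if kb > 0 else np.nan))
    return pd.DataFrame(rows, columns=["feature", "n_calls", "length_bp", "calls_per_kb"])


# ---------------------------------------------------------------------------
# TSS-centered profiles and matrices


def _coverage_arrays(tags: pd.DataFrame, chrom_sizes: dict[str, int],
                     read_length: int = 147) -> dict[str, np.ndarray]:
    """Per-chromosome per-bp coverage of tags extended 147 bp toward 3'."""
    cov = {c: np.zeros(s + 1) for c, s in chrom_sizes.items()}
    for chrom, sub in tags.groupby("chrom", observed=True):
        if chrom not in cov:
            continue
        pos5 = sub["pos5"].to_numpy(dtype=np.int64)
        plus = (sub["strand"] == "+").to_numpy()
        start = np.where(plus, pos5, pos5 - read_length + 1)
        end = start + read_length
        size = chrom_sizes[chrom]
        start = np.clip(start, 0, size)
        end = np.clip(end, 0, size)
        diff = cov[chrom]
        np.add.at(diff, start, 1.0)
        np.add.at(diff, end, -1.0)
    return {c: np.cumsum(d)[:-1] for c, d in cov.items()}


def _gene_window(values: np.ndarray, tss: int, strand: str, half: int) -> np.ndarray:
    """Strand-aware slice rel = -half..half-1 (downstream = gene direction)."""
    size = len(values)
    out = np.zeros(2 * half)
    if strand == "+":
        lo, hi = tss - half, tss + half
        src = values[max(0, lo):min(size, hi)]
        out[max(0, lo) - lo:max(0, lo) - lo + len(src)] = src
    else:
        lo, hi = tss - half + 1, tss + half + 1
        src = values[max(0, lo):min(size, hi)][::-1]
        offset = hi - min(size, hi)
        out[offset:offset + len(src)] = src
    return out


def tss_matrix(
    tags: pd.DataFrame,
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    total_mapped: int,
    bin_bp: int = 5,
    half: int = 1000,
) -> pd.DataFrame:
    """Per-gene strand-aware occupancy matrix over -half..+half, binned.

    Values are RPKM of extended-read coverage per bin.  Rows are genes,
    columns the bin start offsets.
    """
    if (2 * half) % bin_bp != 0:
        raise ValueError("bin_bp must divide the window size")
    cov = _coverage_arrays(tags, chrom_sizes)
    n_bins = 2 * half // bin_bp
    mat = np.zeros((len(genes), n_bins))
    for g, gene in enumerate(genes.itertuples()):
        win = _gene_window(cov[gene.chrom], int(gene.tss), gene.strand, half)
        mat[g] = win.reshape(n_bins, bin_bp).sum(axis=1)
    mat *= 1e9 / (bin_bp * total_mapped)
    cols = np.arange(-half, half, bin_bp)
    return pd.DataFrame(mat, index=genes["gene_id"].to_numpy(), columns=cols)


def _moving_average(values: np.ndarray, ma_bins: int) -> np.ndarray:
    if ma_bins <= 1:
        return values
    kernel = np.ones(ma_bins) / ma_bins
    pad = ma_bins // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + len(values)]
    return out


def tss_composite_profile(
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    total_mapped: int,
    tags: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    metric: str = "occupancy",
    bin_bp: int | None = None,
    ma_bins: int | None = None,
    half: int = 1000,
) -> pd.DataFrame:
    """Composite (gene-averaged) profile around the TSS.

    occupancy: extended-read RPKM, default 5-bp bins with a 5-bin moving
    average; call_density: call dyads per bin per million mapped, default
    10-bp bins with a 3-bin moving average; fuzziness: mean call
    fuzziness per bin (10-bp bins, 3-bin moving average).
    """
    defaults = {"occupancy": (5, 5), "call_density": (10, 3), "fuzziness": (10, 3)}
    if metric not in defaults:
        raise ValueError(f"unknown metric {metric!r}")
    d_bin, d_ma = defaults[metric]
    bin_bp = d_bin if bin_bp is None else bin_bp
    ma_bins = d_ma if ma_bins is None else ma_bins
    if (2 * half) % bin_bp != 0:
        raise ValueError("bin_bp must divide the window size")
    n_bins = 2 * half // bin_bp
    offsets = np.arange(-half, half, bin_bp)

    if metric == "occupancy":
        if tags is None:
            raise ValueError("occupancy metric needs tags")
        mat = tss_matrix(tags, genes, chrom_sizes, total_mapped, bin_bp, half)
        profile = mat.to_numpy().mean(axis=0)
    else:
        if calls is None:
            raise ValueError(f"{metric} metric needs calls")
        acc = np.zeros(n_bins)
        cnt = np.zeros(n_bins)
        by_chrom = {c: s for c, s in calls.groupby("chrom", observed=True)}
        for gene in genes.itertuples():
            sub = by_chrom.get(gene.chrom)
            if sub is None:
                continue
            rel = (sub["dyad"].to_numpy() - int(gene.tss))
            if gene.strand == "-":
                rel = -rel
            ok = (rel >= -half) & (rel < half)
            idx = ((rel[ok] + half) // bin_bp).astype(int)
            if metric == "call_density":
                np.add.at(cnt, idx, 1.0)
            else:
                np.add.at(acc, idx, sub["fuzziness"].to_numpy()[ok])
                np.add.at(cnt, idx, 1.0)
        if metric == "call_density":
            profile = cnt * 1e6 / total_mapped
        else:
            with np.errstate(invalid="ignore"):
                profile = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    smoothed = _moving_average(np.nan_to_num(profile), ma_bins)
    return pd.DataFrame({"offset": offsets, "value": profile, "smoothed": smoothed})


@dataclass
class ClusterResult:
    labels: pd.Series          # gene_id -> cluster id (0..k-1)
    ordered_gene_ids: list[str]
    centroids: np.ndarray
    degenerate: bool


def tss_difference_clusters(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame, k: int = 5, seed: int = 0
) -> ClusterResult:
    """K-means clustering of the per-gene occupancy difference (B - A).

    Rows of the returned ordering are grouped by cluster and sorted by
    distance to their centroid, the layout used for difference heatmaps.
    An all-zero difference is flagged degenerate (one effective cluster).
    """
    if not matrix_a.index.equals(matrix_b.index) or not matrix_a.columns.equals(matrix_b.columns):
        raise ValueError("matrices must share gene set and binning")
    diff = matrix_b.to_numpy() - matrix_a.to_numpy()
    gene_ids = list(matrix_a.index)
    if np.allclose(diff, 0.0):
        labels = pd.Series(0, index=matrix_a.index)
        return ClusterResult(labels, gene_ids, np.zeros((1, diff.shape[1])), True)
    if k == 1:
        labels = pd.Series(0, index=matrix_a.index)
        centroid = diff.mean(axis=0, keepdims=True)
        return ClusterResult(labels, gene_ids, centroid, False)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(diff)
    # canonical cluster ids: descending cluster size, ties by centroid norm
    sizes = np.bincount(raw, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = np.lexsort((norms, -sizes))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels_arr = remap[raw]
    centroids = km.cluster_centers_[order]
    dist = np.linalg.norm(diff - centroids[labels_arr], axis=1)
    row_order = np.lexsort((dist, labels_arr))
    labels = pd.Series(labels_arr, index=matrix_a.index)
    ordered = [gene_ids[i] for i in row_order]
    return ClusterResult(labels, ordered, centroids, False)
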