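"""Nucleosome positioning from MNase tags.

Each uniquely mapped tag is extended toward its 3' end to the canonical
147-bp nucleosomal length; the midpoint of the extension is the inferred
dyad.  Dyads are accumulated into a per-bp histogram, smoothed with a
Gaussian kernel, and peaks are accepted greedily in descending height
under an exclusion-zone rule — the same construction GeneTrack-style
callers use.  Per call we report the supporting read count, occupancy
(reads per million mapped) and fuzziness (the standard deviation of the
supporting dyad coordinates).
"""

from __future__ import annotations

from bisect import bisect_left, insort

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

HALF_FOOTPRINT = 73
FOOTPRINT = 147

CALL_COLUMNS = ["chrom", "dyad", "read_count", "occupancy", "fuzziness"]


def reads_to_dyads(
    tags: pd.DataFrame, chrom_sizes: dict[str, int] | None = None
) -> tuple[pd.DataFrame, int]:
    """Infer a dyad per tag: pos5 + 73 on the + strand, pos5 - 73 on -.

    Returns (DataFrame with columns chrom/dyad, count of dyads dropped for
    falling outside the chromosome).  Without chrom_sizes only dyads below
    zero are dropped.
    """
    plus = (tags["strand"] == "+").to_numpy()
    dyads = np.where(plus, tags["pos5"].to_numpy() + HALF_FOOTPRINT,
                     tags["pos5"].to_numpy() - HALF_FOOTPRINT)
    out = pd.DataFrame({"chrom": tags["chrom"].to_numpy(), "dyad": dyads})
    ok = out["dyad"] >= 0
    if chrom_sizes is not None:
        sizes = out["chrom"].map(chrom_sizes)
        if sizes.isna().any():
            missing = sorted(out.loc[sizes.isna(), "chrom"].unique())
            raise ValueError(f"chromosomes absent from sizes: {missing}")
        ok &= out["dyad"] < sizes
    n_dropped = int((~ok).sum())
    return out[ok].reset_index(drop=True), n_dropped


def _gaussian_kernel(sigma: float) -> np.ndarray:
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _call_one_chrom(
    positions: np.ndarray,
    sigma: float,
    exclusion_bp: int,
    min_reads: int,
) -> list[tuple[int, int, float]]:
    """Greedy peak calling on one chromosome.

    Returns (dyad, read_count, fuzziness) tuples sorted by dyad.
    """
    # pad by the kernel half-width so "same"-mode convolution stays aligned
    # even when the occupied span is shorter than the kernel
    half = int(np.ceil(4 * sigma))
    lo = int(positions.min()) - half
    hi = int(positions.max()) + half
    hist = np.bincount(positions - lo, minlength=hi - lo + 1).astype(float)
    kernel = _gaussian_kernel(sigma)
    smoothed = np.convolve(hist, kernel, mode="same")

    peaks, props = find_peaks(smoothed, height=0.0)
    if len(peaks) == 0:
        # degenerate: a single occupied bp has no interior local maximum
        peaks = np.array([int(np.argmax(smoothed))])
        props = {"peak_heights": smoothed[peaks]}
    order = np.lexsort((peaks, -props["peak_heights"]))

    accepted: list[int] = []  # kept sorted by position
    for idx in order:
        pos = int(peaks[idx])
        j = bisect_left(accepted, pos)
        if j > 0 and pos - accepted[j - 1] < exclusion_bp:
            continue
        if j < len(accepted) and accepted[j] - pos < exclusion_bp:
            continue
        insort(accepted, pos)
    call_dyads = np.asarray(accepted) + lo

    # assign each dyad to the nearest accepted call within the footprint
    # half-width; a dyad equidistant to two calls joins the leftmost.
    srt = np.sort(positions)
    j = np.searchsorted(call_dyads, srt)
    left = np.clip(j - 1, 0, len(call_dyads) - 1)
    right = np.clip(j, 0, len(call_dyads) - 1)
    d_left = np.abs(srt - call_dyads[left])
    d_right = np.abs(srt - call_dyads[right])
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    member_of = np.where(dist <= HALF_FOOTPRINT, nearest, -1)

    calls = []
    for c in range(len(call_dyads)):
        members = srt[member_of == c]
        if len(members) < min_reads:
            continue
        fuzz = float(np.std(members))  # population sd; single read -> 0
        calls.append((int(call_dyads[c]), int(len(members)), fuzz))
    return calls


def call_nucleosomes(
    dyads: pd.DataFrame,
    total_mapped: int,
    sigma: float = 20.0,
    exclusion_bp: int = FOOTPRINT,
    min_reads: int = 3,
) -> pd.DataFrame:
    """Call nucleosomes from per-tag dyads.

    dyads: DataFrame with columns chrom/dyad (from :func:`reads_to_dyads`).
    total_mapped: library size used for the per-million occupancy scale.
    Returns a DataFrame with columns chrom, dyad, read_count, occupancy,
    fuzziness, sorted by (chrom, dyad).  Empty input gives an empty frame.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if exclusion_bp < 1:
        raise ValueError("exclusion_bp must be >= 1")
    rows = []
    for chrom, sub in dyads.groupby("chrom", sort=True, observed=True):
        if len(sub) == 0:
            continue
        positions = sub["dyad"].to_numpy(dtype=np.int64)
        for dyad, count, fuzz in _call_one_chrom(positions, sigma, exclusion_bp, min_reads):
            rows.append((chrom, dyad, count, count * 1e6 / total_mapped, fuzz))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if len(calls):
        calls = calls.sort_values(["chrom", "dyad"], kind="stable").reset_index(drop=True)
    return calls


def footprint_interval(dyad: int) -> tuple[int, int]:
    """147-bp footprint of a call: [dyad - 73, dyad + 74)."""
    return dyad - HALF_FOOTPRINT, dyad + HALF_FOOTPRINT + 1


def window_occupancy(
    dyads: pd.DataFrame,
    chrom_sizes: dict[str, int],
    total_mapped: int,
    window_bp: int = 500,
) -> pd.DataFrame:
    """Tile each chromosome with fixed windows and count tag dyads per
    window; occupancy is the count normalized per million mapped reads.

    150 / 300 / 500 bp windows correspond to mono-, di- and tri-nucleosome
    scales; the scan is a non-overlapping tiling from position 0.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    rows = []
    grouped = {c: s for c, s in dyads.groupby("chrom", observed=True)} if len(dyads) else {}
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        n_win = (size + window_bp - 1) // window_bp
        counts = np.zeros(n_win, dtype=np.int64)
        if chrom in grouped:
            pos = grouped[chrom]["dyad"].to_numpy(dtype=np.int64)
            pos = pos[(pos >= 0) & (pos < size)]
            np.add.at(counts, pos // window_bp, 1)
        for w in range(n_win):
            rows.append(
                (chrom, w * window_bp, min((w + 1) * window_bp, size),
                 int(counts[w]), counts[w] * 1e6 / total_mapped)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "read_count", "occupancy"])


def window_occupancy_difference(
    track_a: pd.DataFrame, track_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-window occupancy difference (B - A) on identical tilings."""
    if not (track_a[["chrom", "start", "end"]].equals(track_b[["chrom", "start", "end"]])):
        raise ValueError("windows differ between the two tracks")
    out = track_a[["chrom", "start", "end"]].copy()
    out["occupancy_a"] = track_a["occupancy"].to_numpy()
    out["occupancy_b"] = track_b["occupancy"].to_numpy()
    out["difference"] = out["occupancy_b"] - out["occupancy_a"]
    return out


def fuzziness_of(member_dyads: np.ndarray | list[int]) -> float:
    """Fuzziness of one call: population sd of the supporting dyad
    coordinates.  A single-read call has fuzziness 0; no reads is an error."""
    arr = np.asarray(member_dyads, dtype=float)
    if arr.size == 0:
        raise ValueError("fuzziness undefined for a call with no member reads")
    return float(np.std(arr))


def write_calls(calls: pd.DataFrame, path) -> None:
    """Calls as BED6+3: footprint interval, then read_count/occupancy/fuzziness."""
    with open(path, "w") as fh:
        for i, row in enumerate(calls.itertuples()):
            start, end = footprint_interval(int(row.dyad))
            fh.write(
                f"{row.chrom}\t{start}\t{end}\tnuc{i}\t{row.read_count}\t.\t"
                f"{row.read_count}\t{row.occupancy:.6g}\t{row.fuzziness:.6g}\n"
            )
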