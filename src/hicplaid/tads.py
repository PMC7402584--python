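"""TAD boundary calling via per-diagonal z-scores and diamond separation scores.

The contact matrix is standardised per genomic distance, multi-window
diamond means ("separation scores") are computed at every bin edge, local
minima at least ``delta`` below their flanking maxima become boundary
candidates, and each candidate is tested with a one-sided Wilcoxon rank-sum
test (candidate diamond lower than the flanking-maxima diamonds) with
Bonferroni correction over all candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import rank_sum_p
from .hic_core import ContactMatrix

__all__ = [
    "SeparationTrack",
    "TADBoundary",
    "TADSet",
    "zscore_transform",
    "separation_score",
    "find_boundaries",
    "boundaries_to_tads",
    "call_tads",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = (3, 5, 7, 10)


@dataclass
class SeparationTrack:
    """Separation scores at bin edges, one row per interior edge.

    Edge ``i`` of a chromosome sits between bins i-1 and i; its bp position
    is i * resolution. ``window_scores`` has shape (n_edges, n_windows);
    ``aggregate`` is the mean over windows, NaN where any window lacks
    full context.
    """

    chroms: np.ndarray  # per edge
    positions: np.ndarray  # bp, per edge
    edge_index: np.ndarray  # bin index i of the edge within its chromosome
    windows: tuple[int, ...]
    window_scores: np.ndarray
    aggregate: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chroms, "position": self.positions})
        for k, w in enumerate(self.windows):
            df[f"score_w{w}"] = self.window_scores[:, k]
        df["aggregate"] = self.aggregate
        return df


@dataclass(frozen=True)
class TADBoundary:
    chrom: str
    position: int  # bp of the bin edge
    score: float  # aggregate separation score
    p: float
    p_adj: float


@dataclass
class TADSet:
    """Half-open TAD intervals per chromosome, sorted and non-overlapping."""

    intervals: dict[str, list[tuple[int, int]]]

    @property
    def n_tads(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def counts(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.intervals.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(c, s, e) for c, ivs in self.intervals.items() for s, e in ivs]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def zscore_transform(m: ContactMatrix) -> dict[str, np.ndarray]:
    """Per-chromosome z-score matrix over all contacts at the same distance.

    Mean and sd (population) are taken over unmasked entries of each
    diagonal; diagonals with zero sd give NaN.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, sl in m.bins.chrom_slices().items():
        dense = m.values[sl, sl].toarray().astype(float)
        mask = m.mask[sl]
        dense[mask, :] = np.nan
        dense[:, mask] = np.nan
        n = dense.shape[0]
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        z = np.full((n, n), np.nan)
        for d in range(n):
            sel = dist == d
            vals = dense[sel]
            finite = np.isfinite(vals)
            if finite.sum() == 0:
                continue
            fv = vals[finite]
            mu = fv.mean()
            sd = fv.std()
            if sd == 0 or fv.max() == fv.min():
                # degenerate diagonal: all equal -> z = 0 by convention
                vals = np.where(finite, 0.0, np.nan)
            else:
                vals = (vals - mu) / sd
            z[sel] = vals
        out[chrom] = z
    return out


def _diamond(z: np.ndarray, i: int, w: int) -> np.ndarray:
    """Values of the w-diamond straddling edge i: rows [i-w, i), cols [i, i+w)."""
    return z[i - w : i, i : i + w].ravel()


def separation_score(
    z: dict[str, np.ndarray] | np.ndarray,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    resolution: int | None = None,
    chrom_order: list[str] | None = None,
) -> SeparationTrack:
    """Diamond-mean separation score per bin edge for several window sizes.

    For edge i and window w the score is the mean z over the diamond
    {(a, b): i-w <= a < i <= b < i+w}. Edges lacking full context for a
    window get NaN for that window; the aggregate averages the windows that
    do have context and is NaN only when none do. Windows larger than a
    chromosome are skipped with a warning.
    """
    if isinstance(z, np.ndarray):
        z = {"chr1": z}
    windows = tuple(sorted(set(int(w) for w in windows)))
    if any(w < 2 for w in windows):
        raise ValueError("window sizes must be >= 2 bins")
    chroms_out, positions, edge_idx, scores = [], [], [], []
    names = chrom_order if chrom_order is not None else list(z.keys())
    for chrom in names:
        zc = z[chrom]
        n = zc.shape[0]
        usable = [w for w in windows if w <= n - 1]
        skipped = set(windows) - set(usable)
        if skipped:
            warnings.warn(
                f"separation_score: windows {sorted(skipped)} exceed chromosome {chrom} ({n} bins); skipped"
            )
        for i in range(1, n):
            row = np.full(len(windows), np.nan)
            for k, w in enumerate(windows):
                if w in skipped or i - w < 0 or i + w > n:
                    continue
                vals = _diamond(zc, i, w)
                finite = vals[np.isfinite(vals)]
                if finite.size:
                    row[k] = finite.mean()
            chroms_out.append(chrom)
            positions.append(i)
            edge_idx.append(i)
            scores.append(row)
    window_scores = np.array(scores) if scores else np.empty((0, len(windows)))
    if len(window_scores):
        # mean over the windows with full context; NaN when no window fits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            aggregate = np.nanmean(window_scores, axis=1)
    else:
        aggregate = np.array([])
    pos_bp = np.asarray(positions, dtype=np.int64)
    if resolution is not None:
        pos_bp = pos_bp * resolution
    return SeparationTrack(
        chroms=np.asarray(chroms_out, dtype=object),
        positions=pos_bp,
        edge_index=np.asarray(edge_idx, dtype=np.int64),
        windows=windows,
        window_scores=window_scores,
        aggregate=np.asarray(aggregate, dtype=float),
    )


def _local_extrema(s: np.ndarray) -> tuple[list[int], list[int]]:
    minima, maxima = [], []
    for i in range(1, len(s) - 1):
        if not (np.isfinite(s[i]) and np.isfinite(s[i - 1]) and np.isfinite(s[i + 1])):
            continue
        if s[i] < s[i - 1] and s[i] < s[i + 1]:
            minima.append(i)
        if s[i] >= s[i - 1] and s[i] >= s[i + 1]:
            maxima.append(i)
    return minima, maxima


def _flank_reference(s: np.ndarray, maxima: list[int], c: int, direction: int) -> int | None:
    """Nearest flanking local maximum; falls back to the argmax of the flank."""
    if direction < 0:
        cands = [i for i in maxima if i < c]
        if cands:
            return cands[-1]
        flank = s[:c]
        if np.any(np.isfinite(flank)):
            return int(np.nanargmax(flank))
    else:
        cands = [i for i in maxima if i > c]
        if cands:
            return cands[0]
        flank = s[c + 1 :]
        if np.any(np.isfinite(flank)):
            return c + 1 + int(np.nanargmax(flank))
    return None


def _edge_diamond(zc: np.ndarray, i: int, windows: tuple[int, ...]) -> np.ndarray:
    """Finite z-values pooled over every usable diamond window at edge i."""
    n = zc.shape[0]
    pooled = []
    for w in windows:
        if i - w >= 0 and i + w <= n:
            vals = _diamond(zc, i, w)
            pooled.append(vals[np.isfinite(vals)])
    if not pooled:
        return np.array([])
    return np.concatenate(pooled)


def find_boundaries(
    track: SeparationTrack,
    z: dict[str, np.ndarray] | np.ndarray,
    delta: float = 0.01,
    p_threshold: float = 0.01,
) -> list[TADBoundary]:
    """Significant TAD boundaries from the aggregate separation score.

    Candidates are local minima at least ``delta`` below both flanking local
    maxima. Each candidate's diamond z-values are compared (one-sided, lower)
    against the pooled diamonds at the two flanking maxima; Bonferroni
    correction uses the number of candidates tested. Boundaries with adjusted
    p below ``p_threshold`` are reported.
    """
    if isinstance(z, np.ndarray):
        z = {"chr1": z}
    candidates: list[tuple[str, int, float, float]] = []  # chrom, track row, score, p
    for chrom in pd.unique(track.chroms):
        rows = np.flatnonzero(track.chroms == chrom)
        s = track.aggregate[rows]
        zc = z[chrom]
        minima, maxima = _local_extrema(s)
        for c in minima:
            left = _flank_reference(s, maxima, c, -1)
            right = _flank_reference(s, maxima, c, +1)
            if left is None or right is None:
                continue
            if min(s[left], s[right]) - s[c] < delta:
                continue
            edge = int(track.edge_index[rows[c]])
            cand_vals = _edge_diamond(zc, edge, track.windows)
            flank_vals = np.concatenate(
                [
                    _edge_diamond(zc, int(track.edge_index[rows[left]]), track.windows),
                    _edge_diamond(zc, int(track.edge_index[rows[right]]), track.windows),
                ]
            )
            if cand_vals.size == 0 or flank_vals.size == 0:
                continue
            p = rank_sum_p(cand_vals, flank_vals, alternative="less")
            candidates.append((chrom, c, float(s[c]), p))
    m_tests = len(candidates)
    out: list[TADBoundary] = []
    for chrom, c, score, p in candidates:
        p_adj = min(1.0, m_tests * p)
        if p_adj < p_threshold:
            rows = np.flatnonzero(track.chroms == chrom)
            out.append(
                TADBoundary(
                    chrom=chrom,
                    position=int(track.positions[rows[c]]),
                    score=score,
                    p=p,
                    p_adj=p_adj,
                )
            )
    return out


def boundaries_to_tads(bs: list[TADBoundary], chrom_sizes: dict[str, int]) -> TADSet:
    """Intervals between consecutive boundaries, with chromosome-end flanks.

    A chromosome with no significant boundary contributes no TADs; with at
    least one boundary, the flanks to the chromosome ends are included.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    by_chrom: dict[str, list[int]] = {}
    for b in bs:
        by_chrom.setdefault(b.chrom, []).append(b.position)
    for chrom, size in chrom_sizes.items():
        positions = sorted(set(by_chrom.get(chrom, [])))
        positions = [p for p in positions if 0 < p < size]
        if not positions:
            intervals[chrom] = []
            continue
        edges = [0] + positions + [size]
        intervals[chrom] = [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]
    return TADSet(intervals=intervals)


def call_tads(
    m: ContactMatrix,
    windows: tuple[int, ...] = DEFAULT_WINDOWS,
    delta: float = 0.01,
    p_threshold: float = 0.01,
) -> tuple[TADSet, list[TADBoundary], SeparationTrack]:
    """Full chain: z-score -> separation score -> boundaries -> TAD intervals."""
    z = zscore_transform(m)
    sizes = m.bins.chrom_sizes()
    res = int(np.max(m.bins.ends - m.bins.starts))
    track = separation_score(z, windows, resolution=res, chrom_order=m.bins.chrom_names())
    boundaries = find_boundaries(track, z, delta=delta, p_threshold=p_threshold)
    return boundaries_to_tads(boundaries, sizes), boundaries, track
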