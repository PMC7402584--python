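"""A/B compartment calling: observed/expected, correlation PC1, peak-based
sign orientation and run-length segmentation.

PC1 is computed independently per chromosome. The eigenvector sign is
arbitrary until :func:`orient_and_label` flips each chromosome so that bins
with positive PC1 carry the higher activating-mark peak density (compartment
A); positive PC1 then means label A, negative means B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hic_core import BinTable, ContactMatrix

__all__ = [
    "CompartmentTrack",
    "CompartmentSegment",
    "observed_expected",
    "correlation_pc1",
    "orient_and_label",
    "segment_compartments",
    "call_compartments",
    "bin_peak_coverage",
]


@dataclass
class CompartmentTrack:
    """Per-bin PC1 value and A/B/NA label at fixed resolution."""

    bins: BinTable
    pc1: np.ndarray  # float, NaN for NA bins
    labels: np.ndarray  # 'A' | 'B' | 'NA'
    unoriented_chroms: set[str] = field(default_factory=set)

    def __post_init__(self):
        self.pc1 = np.asarray(self.pc1, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.pc1) != self.bins.n_bins or len(self.labels) != self.bins.n_bins:
            raise ValueError("track length must match bin table")

    def to_dataframe(self) -> pd.DataFrame:
        df = self.bins.to_dataframe()
        df["pc1"] = self.pc1
        df["label"] = self.labels
        return df


@dataclass(frozen=True)
class CompartmentSegment:
    """Maximal run of identically labelled bins."""

    chrom: str
    start: int
    end: int
    label: str
    n_bins: int


def observed_expected(m: ContactMatrix) -> dict[str, np.ndarray]:
    """Per-chromosome observed/expected matrix.

    Entry (i, j) is M_ij divided by the mean of unmasked entries at the same
    bin distance; masked bins and distances with zero mean become NaN.
    Invariant to global scaling of the input.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, sl in m.bins.chrom_slices().items():
        dense = m.values[sl, sl].toarray().astype(float)
        mask = m.mask[sl]
        n = dense.shape[0]
        oe = np.full((n, n), np.nan)
        if (~mask).sum() < 4:
            warnings.warn(f"observed_expected: chromosome {chrom} has < 4 unmasked bins")
            out[chrom] = oe
            continue
        dense[mask, :] = np.nan
        dense[:, mask] = np.nan
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        expected = np.full(n, np.nan)
        for d in range(n):
            vals = dense[dist == d]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                mu = vals.mean()
                expected[d] = mu if mu != 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            oe = dense / expected[dist]
        out[chrom] = oe
    return out


def correlation_pc1(oe: np.ndarray, min_periods: int = 3) -> np.ndarray:
    """First principal component of the Pearson correlation of O/E rows.

    Correlations are pairwise-complete; rows with fewer than ``min_periods``
    complete pairs against fewer than two other rows become NaN, as do
    constant rows. The returned vector has unit norm over its finite entries;
    its global sign is arbitrary.
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    pc1 = np.full(n, np.nan)
    corr = pd.DataFrame(oe).corr(min_periods=min_periods).to_numpy()
    finite_offdiag = np.isfinite(corr).sum(axis=1) - np.isfinite(np.diag(corr)).astype(int)
    valid = finite_offdiag >= 2
    if valid.sum() < 2:
        return pc1
    sub = corr[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, 0.0)
    np.fill_diagonal(sub, 1.0)
    w, v = np.linalg.eigh(sub)
    vec = v[:, -1]
    vec = vec / np.linalg.norm(vec)
    pc1[valid] = vec
    return pc1


def bin_peak_coverage(bins: BinTable, peaks: pd.DataFrame) -> np.ndarray:
    """Fraction of each bin covered by (merged) peak intervals."""
    covered = np.zeros(bins.n_bins)
    if len(peaks) == 0:
        return covered
    slices = bins.chrom_slices()
    for chrom, grp in peaks.groupby("chrom"):
        sl = slices.get(chrom)
        if sl is None:
            continue
        ivs = sorted(zip(grp["start"].astype(int), grp["end"].astype(int)))
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = bins.starts[sl]
        ends = bins.ends[sl]
        for s, e in merged:
            lo = int(np.searchsorted(ends, s, side="right"))
            hi = int(np.searchsorted(starts, e, side="left"))
            for k in range(lo, hi):
                covered[sl.start + k] += max(0, min(e, ends[k]) - max(s, starts[k]))
    widths = (bins.ends - bins.starts).astype(float)
    return covered / widths


def orient_and_label(pc1: np.ndarray, peaks: pd.DataFrame, bins: BinTable) -> CompartmentTrack:
    """Flip PC1 per chromosome so positive values coincide with peak-dense bins.

    Orientation compares the mean peak-covered fraction of pc1>0 bins against
    pc1<0 bins; a chromosome with no peaks keeps its sign and is flagged as
    unoriented. Labels: A for pc1>0, B for pc1<0, NA for NaN or exact zero.
    """
    pc1 = np.asarray(pc1, dtype=float).copy()
    density = bin_peak_coverage(bins, peaks)
    unoriented: set[str] = set()
    for chrom, sl in bins.chrom_slices().items():
        v = pc1[sl]
        dens = density[sl]
        if dens.sum() == 0:
            unoriented.add(chrom)
            continue
        pos = np.isfinite(v) & (v > 0)
        neg = np.isfinite(v) & (v < 0)
        dens_pos = dens[pos].mean() if pos.any() else -np.inf
        dens_neg = dens[neg].mean() if neg.any() else -np.inf
        if dens_neg > dens_pos:
            pc1[sl] = -v
    labels = np.where(
        ~np.isfinite(pc1) | (pc1 == 0), "NA", np.where(pc1 > 0, "A", "B")
    ).astype(object)
    return CompartmentTrack(bins=bins, pc1=pc1, labels=labels, unoriented_chroms=unoriented)


def segment_compartments(track: CompartmentTrack) -> list[CompartmentSegment]:
    """Maximal same-label runs; NA bins break runs and produce no segment."""
    segments: list[CompartmentSegment] = []
    bins = track.bins
    for chrom, sl in bins.chrom_slices().items():
        labels = track.labels[sl]
        i = 0
        n = sl.stop - sl.start
        while i < n:
            lab = labels[i]
            j = i
            while j < n and labels[j] == lab:
                j += 1
            if lab in ("A", "B"):
                segments.append(
                    CompartmentSegment(
                        chrom=chrom,
                        start=int(bins.starts[sl.start + i]),
                        end=int(bins.ends[sl.start + j - 1]),
                        label=str(lab),
                        n_bins=j - i,
                    )
                )
            i = j
    return segments


def call_compartments(
    m: ContactMatrix, peaks: pd.DataFrame, min_segments_warn: int = 3
) -> CompartmentTrack:
    """Full chain: O/E -> correlation PC1 per chromosome -> orientation.

    Warns when a chromosome yields fewer than ``min_segments_warn`` segments,
    a symptom of PC1 tracking chromosome arms instead of compartments.
    """
    oe = observed_expected(m)
    pc1 = np.full(m.bins.n_bins, np.nan)
    for chrom, sl in m.bins.chrom_slices().items():
        pc1[sl] = correlation_pc1(oe[chrom])
    track = orient_and_label(pc1, peaks, m.bins)
    for chrom in m.bins.chrom_names():
        sl = m.bins.chrom_slices()[chrom]
        labs = track.labels[sl]
        runs = sum(
            1
            for i in range(len(labs))
            if labs[i] in ("A", "B") and (i == 0 or labs[i] != labs[i - 1])
        )
        if 0 < runs < min_segments_warn:
            warnings.warn(
                f"compartments: chromosome {chrom} produced only {runs} segment(s); "
                "PC1 may reflect chromosome arms rather than compartments"
            )
    return track
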