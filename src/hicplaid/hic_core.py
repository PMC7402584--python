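"""Contact-matrix construction, filtering, merging, rebinning and ICE balancing.

Coordinates are 0-based half-open throughout. Matrices are stored as full
symmetric sparse CSR; masked bins have their rows and columns zeroed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "BinTable",
    "ContactMatrix",
    "PairRecord",
    "restriction_bins",
    "pairs_to_matrix",
    "merge_matrices",
    "remove_chromosomes",
    "filter_bins",
    "ice_normalize",
    "rebin",
]


class PairRecord(NamedTuple):
    """One mapped Hi-C contact (two genomic positions)."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int


@dataclass(frozen=True)
class BinTable:
    """Genome-wide table of bins: per-chromosome sorted, contiguous, 0-based half-open.

    Bin indices are dense 0..n-1 in table order.
    """

    chroms: np.ndarray  # str per bin
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64

    def __post_init__(self):
        object.__setattr__(self, "chroms", np.asarray(self.chroms, dtype=object))
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=np.int64))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=np.int64))
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("bin table columns have unequal lengths")
        if np.any(self.ends <= self.starts):
            raise ValueError("bin table contains empty or inverted bins")
        for _, sl in self.chrom_slices().items():
            s, e = self.starts[sl], self.ends[sl]
            if s[0] != 0 or np.any(s[1:] != e[:-1]):
                raise ValueError("bins must be contiguous from 0 within each chromosome")

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def n_bins(self) -> int:
        return len(self.chroms)

    def chrom_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chroms:
            seen.setdefault(c)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index slice per chromosome, in table order."""
        out: dict[str, slice] = {}
        chroms = self.chroms
        i = 0
        n = len(chroms)
        while i < n:
            c = chroms[i]
            j = i
            while j < n and chroms[j] == c:
                j += 1
            if c in out:
                raise ValueError(f"chromosome {c} appears in two separate blocks")
            out[c] = slice(i, j)
            i = j
        return out

    def chrom_sizes(self) -> dict[str, int]:
        return {c: int(self.ends[sl][-1]) for c, sl in self.chrom_slices().items()}

    def locate(self, chrom: str, pos: int) -> int:
        """Genome-wide index of the bin containing (chrom, pos), or -1."""
        sl = self.chrom_slices().get(chrom)
        if sl is None:
            return -1
        starts = self.starts[sl]
        if pos < 0 or pos >= self.ends[sl][-1]:
            return -1
        return sl.start + int(np.searchsorted(starts, pos, side="right")) - 1

    def locate_many(self, chroms: Sequence[str], positions: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`locate`; -1 for unknown chromosome / out of range."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(len(positions), -1, dtype=np.int64)
        chroms = np.asarray(chroms, dtype=object)
        for c, sl in self.chrom_slices().items():
            m = chroms == c
            if not m.any():
                continue
            pos = positions[m]
            ok = (pos >= 0) & (pos < self.ends[sl][-1])
            idx = np.searchsorted(self.starts[sl], pos, side="right") - 1 + sl.start
            out[m] = np.where(ok, idx, -1)
        return out

    def same_as(self, other: "BinTable") -> bool:
        return (
            len(self) == len(other)
            and np.array_equal(self.chroms, other.chroms)
            and np.array_equal(self.starts, other.starts)
            and np.array_equal(self.ends, other.ends)
        )

    @classmethod
    def fixed(cls, chrom_sizes: Mapping[str, int], bin_size: int) -> "BinTable":
        """Fixed-width bins; the last bin of each chromosome is truncated."""
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        chroms, starts, ends = [], [], []
        for name, size in chrom_sizes.items():
            edges = list(range(0, size, bin_size)) + [size]
            for s, e in zip(edges[:-1], edges[1:]):
                chroms.append(name)
                starts.append(s)
                ends.append(e)
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})


@dataclass
class ContactMatrix:
    """Symmetric contact matrix over a :class:`BinTable`.

    ``mask[i]`` is True for excluded bins (rows/columns zeroed after
    filtering). ``bias`` is set only on ICE-corrected matrices.
    """

    bins: BinTable
    values: sparse.csr_matrix
    mask: np.ndarray = field(default=None)
    bias: np.ndarray | None = None
    raw_coverage: np.ndarray | None = None  # coverage basis recorded by filter_bins

    def __post_init__(self):
        self.values = sparse.csr_matrix(self.values)
        n = self.bins.n_bins
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match bin table")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def marginals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def total(self) -> float:
        """Sum over the upper triangle plus diagonal (contact count)."""
        full = self.values.sum()
        diag = self.values.diagonal().sum()
        return float((full + diag) / 2.0)

    def chrom_dense(self, chrom: str) -> np.ndarray:
        sl = self.bins.chrom_slices()[chrom]
        return self.values[sl, sl].toarray()

    def is_symmetric(self, tol: float = 0.0) -> bool:
        d = self.values - self.values.T
        return abs(d).max() <= tol if d.nnz else True

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            bins=self.bins,
            values=self.values.copy(),
            mask=self.mask.copy(),
            bias=None if self.bias is None else self.bias.copy(),
            raw_coverage=None if self.raw_coverage is None else self.raw_coverage.copy(),
        )


def _as_sequences(genome_fasta) -> Mapping[str, str]:
    if isinstance(genome_fasta, (str,)):
        from pyfaidx import Fasta

        fa = Fasta(genome_fasta)
        return {name: str(fa[name][:]) for name in fa.keys()}
    return genome_fasta


def restriction_bins(genome_fasta, site: str) -> BinTable:
    """Bin table of restriction fragments: intervals between consecutive cut starts.

    ``site`` is searched exactly on the forward strand (the enzymes used here
    recognise reverse-complement palindromes). Zero-length bins (a site at
    position 0) are dropped.
    """
    site = site.upper()
    if not site or any(b not in "ACGT" for b in site):
        raise ValueError(f"restriction site must be a non-empty ACGT string, got {site!r}")
    seqs = _as_sequences(genome_fasta)
    chroms, starts, ends = [], [], []
    for name, seq in seqs.items():
        seq = str(seq).upper()
        cuts = []
        i = seq.find(site)
        while i != -1:
            cuts.append(i)
            i = seq.find(site, i + 1)
        edges = sorted(set([0] + cuts + [len(seq)]))
        for s, e in zip(edges[:-1], edges[1:]):
            chroms.append(name)
            starts.append(s)
            ends.append(e)
    return BinTable(np.array(chroms, dtype=object), np.array(starts), np.array(ends))


def pairs_to_matrix(pairs, bins: BinTable) -> ContactMatrix:
    """Aggregate contact pairs into a symmetric count matrix.

    ``pairs`` is an iterable of :class:`PairRecord`-like tuples or a DataFrame
    with columns chrom1, pos1, chrom2, pos2. Pairs on unknown chromosomes or
    outside chromosome bounds are dropped and the count is logged.
    """
    if isinstance(pairs, pd.DataFrame):
        df = pairs
    else:
        rows = []
        n_malformed = 0
        for rec in pairs:
            try:
                c1, p1, c2, p2 = rec[0], int(rec[1]), rec[2], int(rec[3])
            except (TypeError, ValueError, IndexError):
                n_malformed += 1
                continue
            rows.append((c1, p1, c2, p2))
        if n_malformed:
            logger.warning("pairs_to_matrix: skipped %d malformed records", n_malformed)
        df = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2"])
    n = bins.n_bins
    if len(df) == 0:
        return ContactMatrix(bins=bins, values=sparse.csr_matrix((n, n)))
    i = bins.locate_many(df["chrom1"].to_numpy(), df["pos1"].to_numpy())
    j = bins.locate_many(df["chrom2"].to_numpy(), df["pos2"].to_numpy())
    ok = (i >= 0) & (j >= 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("pairs_to_matrix: dropped %d unmappable pairs", dropped)
    i, j = i[ok], j[ok]
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    upper = sparse.coo_matrix((np.ones(len(lo)), (lo, hi)), shape=(n, n)).tocsr()
    diag = sparse.diags(upper.diagonal())
    full = upper + upper.T - diag
    return ContactMatrix(bins=bins, values=full.tocsr())


def merge_matrices(ms: Sequence[ContactMatrix]) -> ContactMatrix:
    """Element-wise sum of raw replicate matrices over identical bin tables."""
    if not ms:
        raise ValueError("merge_matrices requires at least one matrix")
    ref = ms[0]
    for m in ms[1:]:
        if not ref.bins.same_as(m.bins):
            raise ValueError("cannot merge matrices with mismatched bin tables")
    values = sum((m.values for m in ms[1:]), start=ref.values.copy())
    mask = np.logical_or.reduce([m.mask for m in ms])
    return ContactMatrix(bins=ref.bins, values=values.tocsr(), mask=mask)


def remove_chromosomes(m: ContactMatrix, names: Iterable[str]) -> ContactMatrix:
    """Delete bins of the listed chromosomes and re-densify indices."""
    names = set(names)
    keep = np.array([c not in names for c in m.bins.chroms], dtype=bool)
    if keep.all():
        return m.copy()
    if not keep.any():
        warnings.warn("remove_chromosomes: all chromosomes removed, matrix is empty")
        empty = BinTable(np.array([], dtype=object), np.array([], dtype=np.int64), np.array([], dtype=np.int64))
        return ContactMatrix(bins=empty, values=sparse.csr_matrix((0, 0)))
    idx = np.flatnonzero(keep)
    bins = BinTable(m.bins.chroms[keep], m.bins.starts[keep], m.bins.ends[keep])
    values = m.values[np.ix_(idx, idx)]
    return ContactMatrix(
        bins=bins,
        values=sparse.csr_matrix(values),
        mask=m.mask[keep],
        bias=None if m.bias is None else m.bias[keep],
        raw_coverage=None if m.raw_coverage is None else m.raw_coverage[keep],
    )


def _zero_masked(values: sparse.csr_matrix, mask: np.ndarray) -> sparse.csr_matrix:
    keep = sparse.diags((~mask).astype(float))
    out = keep @ values @ keep
    out.eliminate_zeros()
    return out.tocsr()


def filter_bins(m: ContactMatrix, low_quantile: float = 0.0, mad_factor: float = np.inf) -> ContactMatrix:
    """Mask low-coverage bins and high outliers on the log-coverage scale.

    Thresholds are computed over bins with nonzero coverage: the low cut
    masks bins below the ``low_quantile`` quantile of log10 coverage, the
    high cut masks bins above median + ``mad_factor`` * MAD. Zero-coverage
    bins are always masked. Decisions are based on the pre-filter coverage,
    which is recorded on the result so that re-filtering is a no-op.
    """
    if not 0.0 <= low_quantile < 1.0:
        raise ValueError("low_quantile must be in [0, 1)")
    cov = m.raw_coverage if m.raw_coverage is not None else m.marginals()
    cov = np.asarray(cov, dtype=float)
    nonzero = cov > 0
    mask = ~nonzero
    if nonzero.any():
        logcov = np.full_like(cov, np.nan)
        logcov[nonzero] = np.log10(cov[nonzero])
        vals = logcov[nonzero]
        if low_quantile > 0:
            thr = np.quantile(vals, low_quantile)
            mask |= nonzero & (logcov < thr)
        if np.isfinite(mad_factor):
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            mask |= nonzero & (logcov > med + mad_factor * mad)
    mask |= m.mask
    if mask.all():
        raise ValueError("filter_bins would mask every bin; thresholds too aggressive")
    values = _zero_masked(m.values, mask)
    return ContactMatrix(bins=m.bins, values=values, mask=mask, raw_coverage=cov)


def ice_normalize(m: ContactMatrix, tol: float = 1e-5, max_iter: int = 200) -> ContactMatrix:
    """Iterative correction: rescale until unmasked marginals equalise.

    Returns W with W_ij = M_ij / (b_i * b_j) and the bias vector ``b``
    (NaN for masked bins). Unmasked all-zero rows must be masked first.
    """
    active = ~m.mask
    n_active = int(active.sum())
    if n_active == 0:
        raise ValueError("ice_normalize: no unmasked bins")
    marg = m.marginals()
    if np.any(active & (marg == 0)):
        raise ValueError("ice_normalize: unmasked all-zero bins present; run filter_bins first")
    W = m.values.astype(float).tocsr()
    b = np.ones(m.n_bins)
    converged = False
    for _ in range(max_iter):
        s = np.asarray(W.sum(axis=1)).ravel()
        sa = s[active]
        mean = sa.mean()
        dev = np.max(np.abs(sa / mean - 1.0))
        if dev < tol:
            converged = True
            break
        db = np.ones(m.n_bins)
        db[active] = sa / mean
        dinv = sparse.diags(1.0 / db)
        W = (dinv @ W @ dinv).tocsr()
        b *= db
    if not converged:
        warnings.warn(f"ice_normalize: not converged after {max_iter} iterations (dev={dev:.3g})")
    bias = np.where(active, b, np.nan)
    return ContactMatrix(bins=m.bins, values=W, mask=m.mask.copy(), bias=bias)


def rebin(m: ContactMatrix, resolution: int) -> ContactMatrix:
    """Aggregate to fixed-width bins; fragments assigned by midpoint.

    The last bin of each chromosome is truncated at the chromosome end.
    The matrix total is conserved exactly.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    sizes = m.bins.chrom_sizes()
    new_bins = BinTable.fixed(sizes, resolution)
    new_slices = new_bins.chrom_slices()
    n_old, n_new = m.bins.n_bins, new_bins.n_bins
    assign = np.empty(n_old, dtype=np.int64)
    for chrom, sl in m.bins.chrom_slices().items():
        mid = (m.bins.starts[sl] + m.bins.ends[sl]) // 2
        assign[sl] = new_slices[chrom].start + mid // resolution
    # aggregate the upper triangle so pairs folding onto the new diagonal
    # are counted once, then symmetrise
    old_upper = sparse.triu(m.values).tocoo()
    ni, nj = assign[old_upper.row], assign[old_upper.col]
    lo, hi = np.minimum(ni, nj), np.maximum(ni, nj)
    upper = sparse.coo_matrix((old_upper.data, (lo, hi)), shape=(n_new, n_new)).tocsr()
    values = (upper + upper.T - sparse.diags(upper.diagonal())).tocsr()
    # a new bin stays masked only if it receives no unmasked fragment
    contrib_unmasked = np.bincount(assign, weights=(~m.mask).astype(float), minlength=n_new)
    mask = contrib_unmasked == 0
    return ContactMatrix(bins=new_bins, values=values, mask=mask)
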