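"""Synthetic Hi-C data with planted ground truth.

Generates contact maps with distance decay, a two-state plaid (compartment)
overlay, block-diagonal TAD enrichment, multiplicative per-bin biases and
Poisson counting noise, together with matched gene annotations, expression
tables and activating-mark peak sets. Every generator is deterministic
under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .hic_core import BinTable, ContactMatrix

__all__ = [
    "SyntheticGenome",
    "SimulationParams",
    "generate_genome",
    "simulate_contacts",
    "expected_contacts",
    "simulate_genes_expression",
    "simulate_peaks",
    "simulate_sequences",
    "flip_compartment_blocks",
    "write_truth",
]


@dataclass
class SyntheticGenome:
    """Planted genome: compartment labels, TAD tiling and bin biases.

    ``compartment_truth`` holds one 'A'/'B' label per genome-wide bin;
    ``tad_truth`` maps chromosome name to half-open bp intervals that tile
    the chromosome; ``bias_truth`` is a strictly positive per-bin factor.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int
    compartment_truth: np.ndarray
    tad_truth: dict[str, list[tuple[int, int]]]
    bias_truth: np.ndarray
    seed: int

    def __post_init__(self):
        self.compartment_truth = np.asarray(self.compartment_truth, dtype=object)
        self.bias_truth = np.asarray(self.bias_truth, dtype=float)
        n = self.n_bins
        if len(self.compartment_truth) != n or len(self.bias_truth) != n:
            raise ValueError("truth vectors must have one entry per bin")
        if not set(self.compartment_truth) <= {"A", "B"}:
            raise ValueError("compartment labels must be A or B")
        if np.any(self.bias_truth <= 0):
            raise ValueError("bias factors must be strictly positive")
        for name, length in self.chromosomes:
            tads = self.tad_truth[name]
            pos = 0
            for s, e in tads:
                if s != pos or e <= s:
                    raise ValueError(f"TADs must tile chromosome {name} without gaps")
                pos = e
            if pos != length:
                raise ValueError(f"TADs must end at the {name} chromosome end")

    @property
    def n_bins(self) -> int:
        return sum(length // self.bin_size for _, length in self.chromosomes)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def bins(self) -> BinTable:
        return BinTable.fixed(self.chrom_sizes, self.bin_size)

    def tad_bin_membership(self) -> np.ndarray:
        """Genome-wide TAD id per bin (ids unique across chromosomes)."""
        out = np.empty(self.n_bins, dtype=np.int64)
        bins = self.bins()
        tad_id = 0
        for name, _ in self.chromosomes:
            sl = bins.chrom_slices()[name]
            starts = bins.starts[sl]
            for s, e in self.tad_truth[name]:
                member = (starts >= s) & (starts < e)
                out[sl.start : sl.stop][member] = tad_id
                tad_id += 1
        return out


@dataclass
class SimulationParams:
    """Knobs of the contact / expression / peak simulators."""

    decay_exponent: float = 1.0
    plaid_factor: float = 1.0
    tad_factor: float = 1.0
    depth: float = 1e6
    bias_sd: float = 0.0
    expr_logfc: float = 0.0
    peak_prob_A: float = 0.0
    peak_prob_B: float = 0.0

    def __post_init__(self):
        if self.plaid_factor < 1 or self.tad_factor < 1:
            raise ValueError("plaid_factor and tad_factor must be >= 1")
        if not 0 <= self.peak_prob_B <= self.peak_prob_A <= 1:
            raise ValueError("need 0 <= peak_prob_B <= peak_prob_A <= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.bias_sd < 0:
            raise ValueError("bias_sd must be non-negative")


def generate_genome(
    n_chrom: int,
    chrom_length: int,
    bin_size: int,
    mean_tad_size: int = 400_000,
    compartment_block_bins: int = 10,
    seed: int = 0,
    bias_sd: float = 0.0,
) -> SyntheticGenome:
    """Plant alternating compartment blocks, a TAD tiling and bin biases.

    Compartment blocks have geometric lengths with the given mean (a mean of
    at least the chromosome bin count collapses to a single block). TAD sizes
    are geometric with mean ``mean_tad_size`` and a 2-bin minimum, truncated
    to tile each chromosome exactly. Biases are LogNormal(0, ``bias_sd``).
    """
    if chrom_length % bin_size != 0:
        raise ValueError(
            f"bin_size {bin_size} does not divide chromosome length {chrom_length}"
        )
    mean_tad_bins = mean_tad_size / bin_size
    if mean_tad_bins < 2:
        raise ValueError("mean_tad_size must be at least two bins")
    rng = np.random.default_rng(seed)
    n_per_chrom = chrom_length // bin_size
    labels: list[str] = []
    tads: dict[str, list[tuple[int, int]]] = {}
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    for name in names:
        # compartment blocks
        lab = "A" if rng.random() < 0.5 else "B"
        filled = 0
        while filled < n_per_chrom:
            if compartment_block_bins >= n_per_chrom:
                block = n_per_chrom
            else:
                block = int(rng.geometric(1.0 / compartment_block_bins))
            block = min(block, n_per_chrom - filled)
            labels.extend([lab] * block)
            lab = "B" if lab == "A" else "A"
            filled += block
        # TAD tiling, whole bins, min 2 bins
        ivs: list[tuple[int, int]] = []
        pos = 0
        while pos < n_per_chrom:
            size = 1 + int(rng.geometric(1.0 / (mean_tad_bins - 1)))
            size = min(size, n_per_chrom - pos)
            if n_per_chrom - (pos + size) == 1:  # avoid a dangling 1-bin TAD
                size += 1
            ivs.append((pos * bin_size, (pos + size) * bin_size))
            pos += size
        if len(ivs) > 1 and (ivs[-1][1] - ivs[-1][0]) < 2 * bin_size:
            last = ivs.pop()
            prev = ivs.pop()
            ivs.append((prev[0], last[1]))
        tads[name] = ivs
    n_total = n_per_chrom * n_chrom
    bias = rng.lognormal(0.0, bias_sd, size=n_total) if bias_sd > 0 else np.ones(n_total)
    return SyntheticGenome(
        chromosomes=[(name, chrom_length) for name in names],
        bin_size=bin_size,
        compartment_truth=np.array(labels, dtype=object),
        tad_truth=tads,
        bias_truth=bias,
        seed=seed,
    )


def expected_contacts(genome: SyntheticGenome, params: SimulationParams) -> dict[str, np.ndarray]:
    """Noise-free expected count matrix per chromosome, scaled to ``depth``.

    E_ij ∝ (1+|i-j|)^-alpha · plaid(i,j) · tad(i,j) · bias_i · bias_j, with
    the proportionality constant chosen so the expected upper-triangle +
    diagonal total over the genome equals ``params.depth``. Contacts are
    intra-chromosomal only.
    """
    bins = genome.bins()
    tad_ids = genome.tad_bin_membership()
    blocks: dict[str, np.ndarray] = {}
    total = 0.0
    for name, _ in genome.chromosomes:
        sl = bins.chrom_slices()[name]
        n = sl.stop - sl.start
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        e = (1.0 + d) ** (-params.decay_exponent)
        lab = genome.compartment_truth[sl]
        same_comp = lab[:, None] == lab[None, :]
        e = e * np.where(same_comp, params.plaid_factor, 1.0)
        tid = tad_ids[sl.start : sl.stop]
        same_tad = tid[:, None] == tid[None, :]
        e = e * np.where(same_tad, params.tad_factor, 1.0)
        b = genome.bias_truth[sl]
        e = e * np.outer(b, b)
        blocks[name] = e
        total += np.triu(e).sum()
    scale = params.depth / total
    return {name: e * scale for name, e in blocks.items()}


def simulate_contacts(genome: SyntheticGenome, params: SimulationParams, seed: int = 0) -> ContactMatrix:
    """Poisson-sample a symmetric contact matrix from the expected model."""
    rng = np.random.default_rng(seed)
    bins = genome.bins()
    expected = expected_contacts(genome, params)
    n_total = bins.n_bins
    mats = []
    for name, _ in genome.chromosomes:
        e = expected[name]
        upper = np.triu(rng.poisson(e))
        full = upper + upper.T - np.diag(np.diag(upper))
        mats.append(sparse.csr_matrix(full))
    values = sparse.block_diag(mats, format="csr")
    assert values.shape == (n_total, n_total)
    return ContactMatrix(bins=bins, values=values)


def simulate_genes_expression(
    genome: SyntheticGenome,
    n_genes: int,
    expr_logfc: float,
    seed: int = 0,
    mu_b: float = 1.0,
    sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform TSS placement plus compartment-coupled expression.

    log10(TPM+1) is Normal(mu_b, sd) for B-compartment genes and
    Normal(mu_b + expr_logfc, sd) for A-compartment genes. Returns a BED6-style
    gene table (1-bp genes on the + strand, start = TSS) and an expression
    table (gene_id, tpm).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    names = [name for name, _ in genome.chromosomes]
    lengths = np.array([length for _, length in genome.chromosomes], dtype=float)
    chrom_idx = rng.choice(len(names), size=n_genes, p=lengths / lengths.sum())
    pos = (rng.random(n_genes) * lengths[chrom_idx]).astype(np.int64)
    bins = genome.bins()
    chroms = [names[i] for i in chrom_idx]
    bin_idx = bins.locate_many(chroms, pos)
    labels = genome.compartment_truth[bin_idx]
    mu = mu_b + expr_logfc * (labels == "A")
    log_expr = rng.normal(mu.astype(float), sd)
    tpm = np.maximum(10.0**log_expr - 1.0, 0.0)
    gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": chroms,
            "start": pos,
            "end": pos + 1,
            "strand": "+",
        }
    )
    expr = pd.DataFrame({"gene_id": gene_ids, "tpm": tpm})
    return genes, expr


def simulate_peaks(genome: SyntheticGenome, params: SimulationParams, seed: int = 0) -> pd.DataFrame:
    """Bin-granularity peaks: Bernoulli per bin with label-dependent probability."""
    rng = np.random.default_rng(seed)
    bins = genome.bins()
    p = np.where(genome.compartment_truth == "A", params.peak_prob_A, params.peak_prob_B)
    hit = rng.random(bins.n_bins) < p
    return pd.DataFrame(
        {
            "chrom": bins.chroms[hit],
            "start": bins.starts[hit],
            "end": bins.ends[hit],
        }
    ).reset_index(drop=True)


def simulate_sequences(genome: SyntheticGenome, seed: int = 0, gc: float = 0.4) -> dict[str, str]:
    """Random genome sequence matching the chromosome sizes (for motif tests)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    return {
        name: "".join(alphabet[rng.choice(4, size=length, p=p)])
        for name, length in genome.chromosomes
    }


def flip_compartment_blocks(
    genome: SyntheticGenome, fraction: float, seed: int = 0
) -> tuple[SyntheticGenome, float]:
    """Flip the labels of randomly chosen compartment blocks.

    Blocks (maximal same-label runs per chromosome) are added in random
    order until at least ``fraction`` of all bins are flipped. Returns the
    modified genome and the realised flipped-bin fraction.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = genome.compartment_truth.copy()
    bins = genome.bins()
    blocks: list[tuple[int, int]] = []  # [start, stop) genome-wide bin index
    for _, sl in bins.chrom_slices().items():
        i = sl.start
        while i < sl.stop:
            j = i
            while j < sl.stop and labels[j] == labels[i]:
                j += 1
            blocks.append((i, j))
            i = j
    order = rng.permutation(len(blocks))
    target = fraction * len(labels)
    flipped = 0
    for k in order:
        if flipped >= target:
            break
        s, e = blocks[k]
        labels[s:e] = np.where(labels[s:e] == "A", "B", "A")
        flipped += e - s
    new = SyntheticGenome(
        chromosomes=list(genome.chromosomes),
        bin_size=genome.bin_size,
        compartment_truth=labels,
        tad_truth={k: list(v) for k, v in genome.tad_truth.items()},
        bias_truth=genome.bias_truth.copy(),
        seed=seed,
    )
    return new, flipped / len(labels)


def write_truth(genome: SyntheticGenome, outdir) -> None:
    """Write planted truth: compartments BED4, TADs BED3, biases TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bins = genome.bins()
    comp = bins.to_dataframe()
    comp["label"] = genome.compartment_truth
    comp.to_csv(outdir / "compartments_truth.bed", sep="\t", header=False, index=False)
    rows = [
        (name, s, e) for name, _ in genome.chromosomes for s, e in genome.tad_truth[name]
    ]
    pd.DataFrame(rows).to_csv(outdir / "tads_truth.bed", sep="\t", header=False, index=False)
    pd.DataFrame({"bin": np.arange(genome.n_bins), "bias": genome.bias_truth}).to_csv(
        outdir / "bias_truth.tsv", sep="\t", header=False, index=False
    )
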