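"""Known-motif enrichment around TAD boundaries.

Extracts flanking sequences, scans both strands with log-odds PWM scores,
and tests hit-rate enrichment against a dinucleotide-shuffled background
with a one-sided binomial test. This is a transparent stand-in for a
hypergeometric known-motif pipeline: the scan threshold, background
construction and test are all explicit and seedable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PWM",
    "MotifHit",
    "MotifEnrichment",
    "load_jaspar",
    "extract_boundary_sequences",
    "scan_pwm",
    "dinucleotide_shuffle",
    "motif_enrichment",
    "enrich_against_shuffled",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    """Position probability matrix over {A, C, G, T} with background frequencies."""

    name: str
    probs: np.ndarray  # (L, 4)
    background: np.ndarray = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (L, 4)")
        if self.probs.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1 within 1e-6")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray, pseudocount: float = 0.5,
                    background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(name=name, probs=counts / counts.sum(axis=1, keepdims=True),
                   background=background)

    def log_odds(self, eps: float = 1e-9) -> np.ndarray:
        """(L, 5) log2-odds matrix; column 4 (N / unknown base) is -inf."""
        lo = np.log2((self.probs + eps) / self.background[None, :])
        return np.hstack([lo, np.full((len(self), 1), -np.inf)])

    def max_score(self) -> float:
        return float(self.log_odds()[:, :4].max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(name=self.name, probs=self.probs[::-1, ::-1].copy(),
                   background=self.background[::-1].copy())


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based offset of the match on the forward sequence
    strand: str  # '+' | '-'
    score: float


@dataclass(frozen=True)
class MotifEnrichment:
    motif: str
    fg_hits: int
    bg_hits: int
    fg_bp: int
    bg_bp: int
    ratio: float
    p: float
    significant: bool


def load_jaspar(path) -> list[PWM]:
    """Parse JASPAR-style plain-text matrices.

    Accepts the bracketed 4-row format (``A [ 1 2 3 ]``) and bare 4-row
    numeric blocks after each ``>name`` header. Count matrices are converted
    to probabilities with a 0.5 pseudocount.
    """
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush():
        if name is None or not rows:
            return
        mat = np.array([rows[b] for b in _BASES if b in rows], dtype=float).T
        if mat.shape[1] != 4:
            raise ValueError(f"motif {name}: expected 4 base rows, got {mat.shape[1]}")
        if np.allclose(mat.sum(axis=1), 1.0, atol=1e-3):
            pwms.append(PWM(name=name, probs=mat / mat.sum(axis=1, keepdims=True)))
        else:
            pwms.append(PWM.from_counts(name, mat))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                rows, order = {}, []
                continue
            tokens = line.replace("[", " ").replace("]", " ").split()
            if tokens[0] in _BASE_INDEX:
                base, vals = tokens[0], tokens[1:]
            else:
                base = _BASES[len(order)]
                vals = tokens
            rows[base] = [float(v) for v in vals]
            order.append(base)
    flush()
    return pwms


def extract_boundary_sequences(boundaries, fasta, flank: int = 20_000) -> list[tuple[str, str]]:
    """Uppercase sequences spanning [x - flank, x + flank) around each boundary.

    ``fasta`` is a mapping name -> sequence or a FASTA path. Intervals are
    clipped at chromosome ends; boundaries on unknown chromosomes are skipped
    with a logged warning.
    """
    if isinstance(fasta, str):
        from pyfaidx import Fasta

        fa = Fasta(fasta)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
    else:
        seqs = fasta
    out: list[tuple[str, str]] = []
    for b in boundaries:
        chrom = getattr(b, "chrom", None) or b[0]
        pos = int(getattr(b, "position", None) if hasattr(b, "position") else b[1])
        seq = seqs.get(chrom)
        if seq is None:
            logger.warning("extract_boundary_sequences: unknown chromosome %s, skipped", chrom)
            continue
        lo = max(0, pos - flank)
        hi = min(len(seq), pos + flank)
        out.append((f"{chrom}:{lo}-{hi}", str(seq[lo:hi]).upper()))
    return out


def _seq_to_indices(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in _BASE_INDEX.items():
        out[arr == ord(base)] = i
    return out


def _scan_one_strand(idx: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score at every start offset; windows containing N score -inf."""
    L = lo.shape[0]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for k in range(L):
        scores += lo[k, idx[k : k + n]]
    return scores


def scan_pwm(seqs, pwm: PWM, score_fraction: float = 0.8) -> list[MotifHit]:
    """Scan both strands; a hit needs score >= score_fraction * max score.

    ``seqs`` is a list of (id, sequence). Overlapping hits are kept; reverse
    strand hits are reported at their forward-strand offset.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    threshold = score_fraction * pwm.max_score()
    lo_fwd = pwm.log_odds()
    lo_rev = pwm.reverse_complement().log_odds()
    hits: list[MotifHit] = []
    for seq_id, seq in seqs:
        if len(seq) < len(pwm):
            continue
        idx = _seq_to_indices(seq)
        with np.errstate(invalid="ignore"):
            for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
                scores = _scan_one_strand(idx, lo)
                for off in np.flatnonzero(scores >= threshold):
                    hits.append(MotifHit(seq_id, int(off), strand, float(scores[off])))
    return hits


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle preserving exact dinucleotide counts.

    Builds the dinucleotide transition multigraph and samples a random
    Eulerian path with the original first and last characters fixed.
    """
    if len(seq) < 3:
        return seq
    chars = list(seq)
    vertices = sorted(set(chars))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(chars[:-1], chars[1:]):
        edges[a].append(b)
    last = chars[-1]
    for _ in range(100):
        # pick a random terminal edge per non-final vertex; they must form a
        # tree toward the final vertex for an Eulerian path to exist
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last or not edges[v]:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - pathological inputs
        return seq
    shuffled: dict[str, list[str]] = {}
    for v in vertices:
        pool = list(edges[v])
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        shuffled[v] = pool
    out = [chars[0]]
    cur = chars[0]
    counters = {v: 0 for v in vertices}
    for _ in range(len(chars) - 1):
        nxt = shuffled[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def motif_enrichment(fg_hits: int, fg_bp: int, bg_hits: int, bg_bp: int,
                     motif: str = "", p_cut: float = 0.01) -> MotifEnrichment:
    """Rate-ratio enrichment with a one-sided binomial test.

    Ratio = (fg_hits/fg_bp) / (bg_hits/bg_bp), with a 0.5-hit floor on the
    background rate when it has zero hits. The p-value is the upper binomial
    tail of fg_hits out of fg_hits + bg_hits with p0 = fg_bp/(fg_bp + bg_bp).
    """
    if fg_bp <= 0 or bg_bp <= 0:
        raise ValueError("sequence lengths must be positive")
    if bg_bp < fg_bp:
        raise ValueError("background must be at least as large as the foreground")
    bg_eff = max(bg_hits, 0.5)
    ratio = (fg_hits / fg_bp) / (bg_eff / bg_bp)
    n = fg_hits + bg_hits
    p0 = fg_bp / (fg_bp + bg_bp)
    if n == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(fg_hits, n, p0, alternative="greater").pvalue)
    return MotifEnrichment(
        motif=motif, fg_hits=fg_hits, bg_hits=bg_hits, fg_bp=fg_bp, bg_bp=bg_bp,
        ratio=float(ratio), p=p, significant=p < p_cut,
    )


def enrich_against_shuffled(
    seqs: list[tuple[str, str]],
    pwm: PWM,
    n_shuffles: int = 10,
    seed: int = 0,
    score_fraction: float = 0.8,
    p_cut: float = 0.01,
) -> MotifEnrichment:
    """End-to-end enrichment of one PWM in ``seqs`` vs shuffled copies."""
    rng = np.random.default_rng(seed)
    fg_hits = len(scan_pwm(seqs, pwm, score_fraction))
    fg_bp = sum(len(s) for _, s in seqs)
    bg_seqs = [
        (f"{sid}|shuf{k}", dinucleotide_shuffle(s, rng))
        for k in range(n_shuffles)
        for sid, s in seqs
    ]
    bg_hits = len(scan_pwm(bg_seqs, pwm, score_fraction))
    bg_bp = sum(len(s) for _, s in bg_seqs)
    return motif_enrichment(fg_hits, fg_bp, bg_hits, bg_bp, motif=pwm.name, p_cut=p_cut)
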