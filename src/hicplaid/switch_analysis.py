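"""Two-sample integration: compartment-switch classification, gene
assignment, expression contrasts, normalized per-chromosome scores, TAD
conservation and boundary-proximity expression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import rank_sum_p
from .compartments import CompartmentSegment, CompartmentTrack
from .tads import TADBoundary, TADSet

__all__ = [
    "SwitchTable",
    "classify_switches",
    "assign_genes",
    "gene_switch_table",
    "expression_by_group",
    "random_stable_background",
    "normalized_scores",
    "tad_overlap",
    "tads_in_switch_regions",
    "boundary_proximity_expression",
    "log_tpm",
]

SWITCH_CLASSES = ("stableA", "AtoB", "BtoA", "stableB")


def log_tpm(tpm) -> np.ndarray:
    """Expression transform used throughout: log10(TPM + 1)."""
    return np.log10(np.asarray(tpm, dtype=float) + 1.0)


@dataclass
class SwitchTable:
    """Per-bin four-way switch class comparing two compartment tracks."""

    table: pd.DataFrame  # chrom, start, end, label1, label2, switch_class

    def class_counts(self) -> dict[str, int]:
        vc = self.table["switch_class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in SWITCH_CLASSES + ("NA",)}

    @property
    def n_classified(self) -> int:
        counts = self.class_counts()
        return sum(counts[c] for c in SWITCH_CLASSES)

    @property
    def stable_fraction(self) -> float:
        """Percentage of classified bins that are stableA or stableB."""
        counts = self.class_counts()
        n = self.n_classified
        if n == 0:
            return float("nan")
        return 100.0 * (counts["stableA"] + counts["stableB"]) / n

    @property
    def switch_fraction(self) -> float:
        """Percentage of classified bins that are AtoB or BtoA."""
        n = self.n_classified
        if n == 0:
            return float("nan")
        counts = self.class_counts()
        return 100.0 * (counts["AtoB"] + counts["BtoA"]) / n


def _switch_class(l1: str, l2: str) -> str:
    if l1 == "NA" or l2 == "NA":
        return "NA"
    if l1 == "A":
        return "stableA" if l2 == "A" else "AtoB"
    return "BtoA" if l2 == "A" else "stableB"


def classify_switches(t1: CompartmentTrack, t2: CompartmentTrack) -> SwitchTable:
    """Per-bin four-way classification of two tracks over identical bins.

    A bin is NA whenever either track labels it NA; percentages exclude NA
    bins from both numerator and denominator.
    """
    if not t1.bins.same_as(t2.bins):
        raise ValueError("classify_switches requires identical bin tables")
    classes = [_switch_class(a, b) for a, b in zip(t1.labels, t2.labels)]
    df = t1.bins.to_dataframe()
    df["label1"] = t1.labels
    df["label2"] = t2.labels
    df["switch_class"] = classes
    return SwitchTable(table=df)


def assign_genes(genes: pd.DataFrame, segments: list[CompartmentSegment]) -> pd.DataFrame:
    """Assign each gene to the compartment segment fully containing its TSS.

    The TSS is the start for + strand genes and end-1 for - strand; the 1-bp
    TSS interval must lie inside the segment (half-open convention: a TSS at
    a segment end coordinate belongs to the following segment). Returns the
    gene table with added ``tss`` and ``label`` ('A'/'B'/'NA') columns.
    """
    out = genes.copy()
    strand = out["strand"] if "strand" in out else pd.Series("+", index=out.index)
    out["tss"] = np.where(strand == "+", out["start"], out["end"] - 1).astype(np.int64)
    labels = np.full(len(out), "NA", dtype=object)
    by_chrom: dict[str, list[CompartmentSegment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        m = (out["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        tss = out.loc[m, "tss"].to_numpy()
        idx = np.searchsorted(starts, tss, side="right") - 1
        inside = (idx >= 0) & (tss < ends[np.clip(idx, 0, None)])
        lab = np.full(m.sum(), "NA", dtype=object)
        lab[inside] = [segs[i].label for i in idx[inside]]
        labels[m] = lab
    out["label"] = labels
    return out


def gene_switch_table(
    genes: pd.DataFrame,
    segments1: list[CompartmentSegment],
    segments2: list[CompartmentSegment],
    expr: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join two per-sample gene assignments into switch classes (+ expression)."""
    a1 = assign_genes(genes, segments1)
    a2 = assign_genes(genes, segments2)
    out = a1.rename(columns={"label": "label1"})
    out["label2"] = a2["label"].to_numpy()
    out["switch_class"] = [
        _switch_class(x, y) for x, y in zip(out["label1"], out["label2"])
    ]
    if expr is not None:
        out = out.merge(expr, on="gene_id", how="left")
        out["log_tpm"] = log_tpm(out["tpm"])
    return out


def expression_by_group(assign: pd.DataFrame, expr: pd.DataFrame | None = None) -> dict:
    """Per switch class: n, transformed values, quartiles; rank-sum contrasts.

    Tests BtoA vs stableB and AtoB vs stableA (two-sided); a contrast with an
    empty class is skipped. ``assign`` needs a ``switch_class`` column and
    either a ``log_tpm`` column or a ``tpm`` join via ``expr``.
    """
    df = assign
    if "log_tpm" not in df.columns:
        if expr is None:
            raise ValueError("expression_by_group needs expression values")
        df = df.merge(expr, on="gene_id", how="left")
        df["log_tpm"] = log_tpm(df["tpm"])
    groups: dict[str, dict] = {}
    for cls in SWITCH_CLASSES:
        vals = df.loc[df["switch_class"] == cls, "log_tpm"].dropna().to_numpy()
        summary = {"n": int(vals.size), "values": vals}
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            summary.update(median=float(med), q1=float(q1), q3=float(q3))
        groups[cls] = summary
    tests: dict[str, float] = {}
    for name, (ga, gb) in {
        "BtoA_vs_stableB": ("BtoA", "stableB"),
        "AtoB_vs_stableA": ("AtoB", "stableA"),
    }.items():
        va, vb = groups[ga]["values"], groups[gb]["values"]
        if va.size and vb.size:
            tests[name] = rank_sum_p(va, vb, alternative="two-sided")
    return {"groups": groups, "tests": tests}


def random_stable_background(assign: pd.DataFrame, n: int, seed: int = 0) -> pd.DataFrame:
    """Seeded uniform sample without replacement of stable-region genes."""
    pool = assign[assign["switch_class"].isin(["stableA", "stableB"])]
    if len(pool) == 0:
        raise ValueError("no stable-region genes to sample from")
    if n > len(pool):
        warnings.warn(
            f"random_stable_background: requested {n} > pool {len(pool)}; returning whole pool"
        )
        n = len(pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return pool.iloc[np.sort(idx)].reset_index(drop=True)


def normalized_scores(items, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome normalized scores: count / per-chrom total / chrom size.

    For compartment segments the per-chromosome total is the segment count on
    that chromosome (A-count + B-count); for a :class:`TADSet` the total is
    the genome-wide TAD count and the label is 'TAD'. A chromosome with zero
    total yields NaN.
    """
    rows = []
    if isinstance(items, TADSet):
        total = items.n_tads
        for chrom, size in chrom_sizes.items():
            cnt = len(items.intervals.get(chrom, []))
            score = cnt / total / size if total > 0 else float("nan")
            rows.append((chrom, "TAD", cnt, score))
    else:
        counts: dict[str, dict[str, int]] = {c: {"A": 0, "B": 0} for c in chrom_sizes}
        for seg in items:
            if seg.chrom in counts:
                counts[seg.chrom][seg.label] += 1
        for chrom, size in chrom_sizes.items():
            total = counts[chrom]["A"] + counts[chrom]["B"]
            for label in ("A", "B"):
                cnt = counts[chrom][label]
                score = cnt / total / size if total > 0 else float("nan")
                rows.append((chrom, label, cnt, score))
    return pd.DataFrame(rows, columns=["chrom", "label", "count", "score"])


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def tad_overlap(
    s1: TADSet, s2: TADSet, frac: float = 0.7, reciprocal: bool = True
) -> tuple[list[tuple[str, tuple[int, int], tuple[int, int]]], list, list]:
    """Conserved / unique TADs under a (reciprocal) fractional-overlap criterion.

    A pair (t1, t2) is conserved when the intersection exceeds ``frac`` of
    |t1| and (if ``reciprocal``) of |t2|. Each TAD is matched to at most one
    partner, by greatest overlap with ties broken toward the leftmost
    partner. Returns (conserved pairs, unique-in-s1, unique-in-s2).
    """
    pairs = []
    matched1: set[tuple[str, tuple[int, int]]] = set()
    matched2: set[tuple[str, tuple[int, int]]] = set()
    for chrom in set(s1.intervals) | set(s2.intervals):
        ivs1 = sorted(s1.intervals.get(chrom, []))
        ivs2 = sorted(s2.intervals.get(chrom, []))
        for t1 in ivs1:
            best, best_ov = None, 0
            for t2 in ivs2:
                if (chrom, t2) in matched2:
                    continue
                ov = _overlap(t1, t2)
                if ov <= best_ov:  # ties keep the leftmost (earlier) partner
                    continue
                len1, len2 = t1[1] - t1[0], t2[1] - t2[0]
                if ov > frac * len1 and (not reciprocal or ov > frac * len2):
                    best, best_ov = t2, ov
            if best is not None:
                pairs.append((chrom, t1, best))
                matched1.add((chrom, t1))
                matched2.add((chrom, best))
    unique1 = [
        (c, iv) for c, ivs in s1.intervals.items() for iv in ivs if (c, iv) not in matched1
    ]
    unique2 = [
        (c, iv) for c, ivs in s2.intervals.items() for iv in ivs if (c, iv) not in matched2
    ]
    return pairs, unique1, unique2


def tads_in_switch_regions(
    tads: TADSet, switches: SwitchTable, min_frac: float = 0.5
) -> tuple[int, float]:
    """TADs with at least ``min_frac`` of their length in switching bins.

    Switching bins are those classed AtoB or BtoA. Returns (count, fraction
    of total TADs).
    """
    sw = switches.table
    sw = sw[sw["switch_class"].isin(["AtoB", "BtoA"])]
    by_chrom = {
        c: list(zip(g["start"].astype(int), g["end"].astype(int)))
        for c, g in sw.groupby("chrom")
    }
    count = 0
    for chrom, ivs in tads.intervals.items():
        switch_ivs = by_chrom.get(chrom, [])
        for t in ivs:
            covered = sum(_overlap(t, s) for s in switch_ivs)
            if covered >= min_frac * (t[1] - t[0]):
                count += 1
    total = tads.n_tads
    return count, count / total if total else float("nan")


def boundary_proximity_expression(
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    boundaries: list[TADBoundary],
    dist: int = 40_000,
    tads: TADSet | None = None,
) -> dict:
    """Expression of genes near TAD boundaries vs genes inside TAD bodies.

    NEAR: genes with |TSS - nearest boundary| strictly below ``dist``.
    FAR: the remaining genes, restricted to TAD intervals when ``tads`` is
    given, else to chromosomes carrying at least one boundary. One-sided
    rank-sum test (NEAR higher); the test is skipped with a message when a
    group is empty.
    """
    df = genes.copy()
    strand = df["strand"] if "strand" in df else pd.Series("+", index=df.index)
    df["tss"] = np.where(strand == "+", df["start"], df["end"] - 1).astype(np.int64)
    df = df.merge(expr, on="gene_id", how="inner")
    df["log_tpm"] = log_tpm(df["tpm"])
    by_chrom: dict[str, np.ndarray] = {}
    for b in boundaries:
        by_chrom.setdefault(b.chrom, [])
    for b in boundaries:
        by_chrom[b.chrom].append(b.position)
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    near_mask = np.zeros(len(df), dtype=bool)
    eligible = np.zeros(len(df), dtype=bool)
    for chrom, pos in by_chrom.items():
        m = (df["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        tss = df.loc[m, "tss"].to_numpy()
        k = np.searchsorted(pos, tss)
        left = np.where(k > 0, np.abs(tss - pos[np.clip(k - 1, 0, len(pos) - 1)]), np.inf)
        right = np.where(k < len(pos), np.abs(pos[np.clip(k, 0, len(pos) - 1)] - tss), np.inf)
        near_mask[m] = np.minimum(left, right) < dist
        eligible[m] = True
    far_eligible = eligible.copy()
    if tads is not None:
        in_tad = np.zeros(len(df), dtype=bool)
        for chrom, ivs in tads.intervals.items():
            m = (df["chrom"] == chrom).to_numpy()
            if not m.any():
                continue
            tss = df.loc[m, "tss"].to_numpy()
            hit = np.zeros(len(tss), dtype=bool)
            for s, e in ivs:
                hit |= (tss >= s) & (tss < e)
            in_tad[m] = hit
        far_eligible &= in_tad
    near = df.loc[near_mask & eligible, "log_tpm"].to_numpy()
    far = df.loc[~near_mask & far_eligible, "log_tpm"].to_numpy()
    result = {
        "n_near": int(near.size),
        "n_far": int(far.size),
        "median_near": float(np.median(near)) if near.size else float("nan"),
        "median_far": float(np.median(far)) if far.size else float("nan"),
        "p": None,
    }
    if near.size and far.size:
        result["p"] = rank_sum_p(near, far, alternative="greater")
    else:
        result["message"] = "one group empty; test skipped"
    return result
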