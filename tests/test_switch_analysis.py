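"""Switch classification, gene assignment, expression coupling, normalized
scores, TAD conservation and boundary-proximity expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hicplaid import compartments as comp
from hicplaid import hic_core as hc
from hicplaid import switch_analysis as sw
from hicplaid import synthdata as sd
from hicplaid import tads as td


def make_track(labels, bin_size=100_000, chrom="chr1"):
    labels = np.array(labels, dtype=object)
    bins = hc.BinTable.fixed({chrom: len(labels) * bin_size}, bin_size)
    pc1 = np.where(labels == "A", 1.0, np.where(labels == "B", -1.0, np.nan))
    return comp.CompartmentTrack(bins=bins, pc1=pc1, labels=labels)


class TestClassifySwitches:
    def test_identity_track_fully_stable(self):
        t = make_track(list("AABBA"))
        table = sw.classify_switches(t, t)
        assert table.stable_fraction == 100.0
        assert table.switch_fraction == 0.0

    def test_definition_of_directions(self):
        t1 = make_track(["A", "B"])
        t2 = make_track(["B", "A"])
        table = sw.classify_switches(t1, t2)
        assert list(table.table["switch_class"]) == ["AtoB", "BtoA"]

    def test_na_propagates(self):
        table = sw.classify_switches(make_track(["A", "NA"]), make_track(["A", "A"]))
        assert list(table.table["switch_class"]) == ["stableA", "NA"]
        assert table.n_classified == 1

    def test_counts_match_brute_force_tabulation(self):
        rng = np.random.default_rng(0)
        l1 = rng.choice(["A", "B", "NA"], size=10_000, p=[0.45, 0.45, 0.1])
        l2 = rng.choice(["A", "B", "NA"], size=10_000, p=[0.45, 0.45, 0.1])
        table = sw.classify_switches(make_track(l1), make_track(l2))
        counts = table.class_counts()
        # counting oracle
        oracle = {"stableA": 0, "AtoB": 0, "BtoA": 0, "stableB": 0, "NA": 0}
        for a, b in zip(l1, l2):
            if a == "NA" or b == "NA":
                oracle["NA"] += 1
            elif a == "A":
                oracle["stableA" if b == "A" else "AtoB"] += 1
            else:
                oracle["BtoA" if b == "A" else "stableB"] += 1
        assert counts == oracle
        assert sum(counts.values()) == 10_000

    def test_rejects_mismatched_bins(self):
        with pytest.raises(ValueError):
            sw.classify_switches(make_track(["A"] * 3), make_track(["A"] * 4))


class TestAssignGenes:
    def segs(self):
        return [
            comp.CompartmentSegment("chr1", 100_000, 200_000, "A", 1),
            comp.CompartmentSegment("chr1", 200_000, 500_000, "B", 3),
        ]

    def gene(self, start, strand="+", end=None):
        end = end if end is not None else start + 1000
        return pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"],
                             "start": [start], "end": [end], "strand": [strand]})

    def test_tss_inside_segment(self):
        out = sw.assign_genes(self.gene(150_000), self.segs())
        assert out["label"].iloc[0] == "A"

    def test_tss_at_segment_end_goes_to_next(self):
        out = sw.assign_genes(self.gene(200_000), self.segs())
        assert out["label"].iloc[0] == "B"

    def test_minus_strand_uses_end(self):
        # gene interval [150,000, 250,000) on '-': TSS = 249,999 -> B segment
        out = sw.assign_genes(self.gene(150_000, strand="-", end=250_000), self.segs())
        assert out["tss"].iloc[0] == 249_999
        assert out["label"].iloc[0] == "B"

    def test_outside_segments_unassigned(self):
        out = sw.assign_genes(self.gene(50_000), self.segs())
        assert out["label"].iloc[0] == "NA"

    def test_random_against_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        # random non-overlapping segments
        edges = np.sort(rng.choice(np.arange(1, 100), size=20, replace=False)) * 10_000
        segs = []
        for k in range(0, len(edges) - 1, 2):
            segs.append(comp.CompartmentSegment(
                "chr1", int(edges[k]), int(edges[k + 1]),
                "A" if k % 4 == 0 else "B", 0))
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(1000)],
            "chrom": "chr1",
            "start": rng.integers(0, 1_000_000, size=1000),
            "strand": "+",
        })
        genes["end"] = genes["start"] + 1
        out = sw.assign_genes(genes, segs)
        for _, row in out.iterrows():
            expected = "NA"
            for s in segs:
                if s.start <= row["tss"] < s.end:
                    expected = s.label
            assert row["label"] == expected


class TestExpressionByGroup:
    def test_log_transform_values(self):
        assert sw.log_tpm([0.0])[0] == 0.0
        assert sw.log_tpm([9.0])[0] == pytest.approx(1.0)

    def test_planted_logfc_rejected_strongly(self):
        ps = []
        for seed in range(10):
            g = sd.generate_genome(1, 10_000_000, 100_000, seed=seed)
            genes, expr = sd.simulate_genes_expression(g, 500, 1.0, seed=seed)
            bins = g.bins()
            truth_segments = comp.segment_compartments(
                comp.CompartmentTrack(
                    bins=bins,
                    pc1=np.where(g.compartment_truth == "A", 1.0, -1.0),
                    labels=g.compartment_truth,
                )
            )
            assign = sw.gene_switch_table(genes, truth_segments, truth_segments, expr)
            res = sw.expression_by_group(assign)
            a = res["groups"]["stableA"]["values"]
            b = res["groups"]["stableB"]["values"]
            ps.append(stats.ranksums(a, b).pvalue)
        assert np.median(ps) < 1e-10

    def test_empty_class_skips_test(self):
        df = pd.DataFrame({"switch_class": ["stableA"] * 3, "log_tpm": [1.0, 2.0, 3.0]})
        res = sw.expression_by_group(df)
        assert res["groups"]["BtoA"]["n"] == 0
        assert "BtoA_vs_stableB" not in res["tests"]


class TestRandomStableBackground:
    def assign_frame(self, n_stable=20, n_switch=5):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_stable + n_switch)],
            "switch_class": ["stableA"] * n_stable + ["BtoA"] * n_switch,
        })

    def test_full_pool_when_n_equals_pool(self):
        out = sw.random_stable_background(self.assign_frame(), 20, seed=0)
        assert len(out) == 20

    def test_deterministic_under_seed(self):
        a = sw.random_stable_background(self.assign_frame(), 10, seed=3)
        b = sw.random_stable_background(self.assign_frame(), 10, seed=3)
        assert list(a["gene_id"]) == list(b["gene_id"])

    def test_oversized_request_warns(self):
        with pytest.warns(UserWarning, match="whole pool"):
            out = sw.random_stable_background(self.assign_frame(), 100, seed=0)
        assert len(out) == 20

    def test_inclusion_frequency_uniform(self):
        # frequency oracle: inclusion of each gene within binomial 99% bounds
        counts = np.zeros(20)
        n_rep, k = 2000, 5
        for seed in range(n_rep):
            out = sw.random_stable_background(self.assign_frame(), k, seed=seed)
            for gid in out["gene_id"]:
                counts[int(gid[1:])] += 1
        p = k / 20
        # 99.9% bounds: 20 genes tested simultaneously
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_rep, p)
        assert np.all(counts >= lo) and np.all(counts <= hi)


class TestNormalizedScores:
    def test_formula_application(self):
        segs = [comp.CompartmentSegment("chr1", 0, 10, "A", 1)] * 40 + [
            comp.CompartmentSegment("chr1", 0, 10, "B", 1)] * 10
        out = sw.normalized_scores(segs, {"chr1": 100_000_000})
        a = out[(out["label"] == "A")]["score"].iloc[0]
        assert a == pytest.approx(40 / 50 / 1e8)

    def test_single_label_ratio_one(self):
        segs = [comp.CompartmentSegment("chr1", 0, 10, "A", 1)] * 7
        out = sw.normalized_scores(segs, {"chr1": 1_000_000})
        assert out[out["label"] == "A"]["score"].iloc[0] == pytest.approx(1 / 1e6)
        assert out[out["label"] == "B"]["score"].iloc[0] == 0.0

    def test_zero_total_nan(self):
        out = sw.normalized_scores([], {"chr1": 1_000_000})
        assert np.isnan(out["score"]).all()

    def test_tadset_uses_genome_total(self):
        ts = td.TADSet(intervals={"chr1": [(0, 10), (10, 20)], "chr2": [(0, 10)]})
        out = sw.normalized_scores(ts, {"chr1": 100, "chr2": 200})
        assert out[out["chrom"] == "chr1"]["score"].iloc[0] == pytest.approx(2 / 3 / 100)
        assert out[out["chrom"] == "chr2"]["score"].iloc[0] == pytest.approx(1 / 3 / 200)

    def test_random_segments_match_spreadsheet_oracle(self):
        rng = np.random.default_rng(2)
        sizes = {"chr1": 1_000_000, "chr2": 2_000_000}
        segs = [
            comp.CompartmentSegment(rng.choice(["chr1", "chr2"]), 0, 10,
                                    rng.choice(["A", "B"]), 1)
            for _ in range(200)
        ]
        out = sw.normalized_scores(segs, sizes)
        for chrom in sizes:
            tot = sum(1 for s in segs if s.chrom == chrom)
            for label in "AB":
                cnt = sum(1 for s in segs if s.chrom == chrom and s.label == label)
                got = out[(out["chrom"] == chrom) & (out["label"] == label)]["score"].iloc[0]
                assert got == pytest.approx(cnt / tot / sizes[chrom])


def brute_force_tad_overlap(ivs1, ivs2, frac, reciprocal=True):
    """All-pairs reciprocal-overlap oracle (single chromosome)."""
    conserved = set()
    for t1 in ivs1:
        for t2 in ivs2:
            ov = max(0, min(t1[1], t2[1]) - max(t1[0], t2[0]))
            if ov > frac * (t1[1] - t1[0]) and (not reciprocal or ov > frac * (t2[1] - t2[0])):
                conserved.add(t1)
    return conserved


def random_tiling(rng, size=10_000_000, step=50_000, max_n=40):
    edges = np.sort(rng.choice(np.arange(1, size // step), size=rng.integers(5, max_n),
                               replace=False)) * step
    edges = [0] + list(map(int, edges)) + [size]
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


class TestTadOverlap:
    def test_identical_sets_all_conserved(self):
        ivs = [(0, 100), (100, 250), (250, 400)]
        s = td.TADSet(intervals={"chr1": ivs})
        pairs, u1, u2 = sw.tad_overlap(s, s)
        assert len(pairs) == 3 and not u1 and not u2

    def test_shifted_interval_arithmetic(self):
        s1 = td.TADSet(intervals={"chr1": [(0, 100)]})
        s2 = td.TADSet(intervals={"chr1": [(10, 110)]})
        pairs, u1, u2 = sw.tad_overlap(s1, s2, frac=0.7)
        assert len(pairs) == 1  # 90 > 70 both ways

    def test_non_reciprocal_flag(self):
        s1 = td.TADSet(intervals={"chr1": [(0, 100)]})
        s2 = td.TADSet(intervals={"chr1": [(0, 400)]})
        assert len(sw.tad_overlap(s1, s2, reciprocal=True)[0]) == 0
        assert len(sw.tad_overlap(s1, s2, reciprocal=False)[0]) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_all_pairs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ivs1 = random_tiling(rng)
        ivs2 = random_tiling(rng)
        s1 = td.TADSet(intervals={"chr1": ivs1})
        s2 = td.TADSet(intervals={"chr1": ivs2})
        pairs, u1, u2 = sw.tad_overlap(s1, s2, frac=0.7)
        oracle = brute_force_tad_overlap(ivs1, ivs2, 0.7)
        assert {t1 for _, t1, _ in pairs} == oracle
        assert len(pairs) + len(u1) == len(ivs1)
        assert len(pairs) + len(u2) == len(ivs2)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_symmetric_conserved_count(self, seed):
        rng = np.random.default_rng(seed)
        s1 = td.TADSet(intervals={"chr1": random_tiling(rng)})
        s2 = td.TADSet(intervals={"chr1": random_tiling(rng)})
        assert len(sw.tad_overlap(s1, s2)[0]) == len(sw.tad_overlap(s2, s1)[0])


class TestTadsInSwitchRegions:
    def switch_table(self, classes, bin_size=100_000):
        t1 = make_track(["A"] * len(classes), bin_size)
        labels2 = ["B" if c else "A" for c in classes]
        t2 = make_track(labels2, bin_size)
        return sw.classify_switches(t1, t2)

    def test_no_switching_zero(self):
        tads = td.TADSet(intervals={"chr1": [(0, 200_000)]})
        count, frac = sw.tads_in_switch_regions(tads, self.switch_table([0] * 5))
        assert count == 0 and frac == 0.0

    def test_tad_inside_switch_bin_counted(self):
        tads = td.TADSet(intervals={"chr1": [(110_000, 180_000)]})
        count, _ = sw.tads_in_switch_regions(tads, self.switch_table([0, 1, 0]))
        assert count == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bp_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed)
        classes = rng.random(100) < 0.3
        table = self.switch_table(list(classes.astype(int)))
        ivs = random_tiling(rng, size=10_000_000, step=40_000)
        tads = td.TADSet(intervals={"chr1": ivs})
        count, frac = sw.tads_in_switch_regions(tads, table)
        # brute-force bp intersection against switching bins
        switch_bins = [(i * 100_000, (i + 1) * 100_000) for i, c in enumerate(classes) if c]
        oracle = 0
        for s, e in ivs:
            ov = sum(max(0, min(e, be) - max(s, bs)) for bs, be in switch_bins)
            if ov >= 0.5 * (e - s):
                oracle += 1
        assert count == oracle
        assert frac == pytest.approx(oracle / len(ivs))


class TestBoundaryProximityExpression:
    def setup_data(self, tss_positions, tpms, boundaries_at=(1_000_000,)):
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(tss_positions))],
            "chrom": "chr1", "start": tss_positions,
            "end": np.array(tss_positions) + 1, "strand": "+",
        })
        expr = pd.DataFrame({"gene_id": genes["gene_id"], "tpm": tpms})
        bs = [td.TADBoundary("chr1", p, -1.0, 1e-5, 1e-4) for p in boundaries_at]
        return genes, expr, bs

    def test_tss_at_boundary_is_near(self):
        genes, expr, bs = self.setup_data([1_000_000, 1_500_000], [5.0, 5.0])
        res = sw.boundary_proximity_expression(genes, expr, bs, dist=40_000)
        assert res["n_near"] == 1 and res["n_far"] == 1

    def test_distance_exactly_dist_is_far(self):
        genes, expr, bs = self.setup_data([1_040_000, 1_039_999], [5.0, 5.0])
        res = sw.boundary_proximity_expression(genes, expr, bs, dist=40_000)
        assert res["n_near"] == 1 and res["n_far"] == 1

    def test_planted_near_excess_detected(self):
        ps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            near_pos = rng.integers(980_000, 1_039_000, size=300)
            far_pos = rng.integers(2_000_000, 5_000_000, size=300)
            near_expr = 10 ** rng.normal(1.5, 0.5, 300) - 1
            far_expr = 10 ** rng.normal(1.0, 0.5, 300) - 1
            genes, expr, bs = self.setup_data(
                list(near_pos) + list(far_pos),
                np.clip(list(near_expr) + list(far_expr), 0, None),
            )
            res = sw.boundary_proximity_expression(genes, expr, bs, dist=40_000)
            assert res["n_near"] == 300 and res["n_far"] == 300
            ps.append(res["p"])
        assert np.median(ps) < 1e-6

    def test_empty_group_skips_test(self):
        genes, expr, bs = self.setup_data([1_000_000], [5.0])
        res = sw.boundary_proximity_expression(genes, expr, bs)
        assert res["p"] is None and "message" in res


class TestFullPipelineSwitch:
    def run_pair(self, g1, g2, seed):
        params = sd.SimulationParams(depth=2e6, plaid_factor=1.6,
                                     peak_prob_A=0.6, peak_prob_B=0.1)
        tracks = []
        for k, g in enumerate((g1, g2)):
            m = sd.simulate_contacts(g, params, seed=seed + k)
            m = hc.ice_normalize(hc.filter_bins(m))
            peaks = sd.simulate_peaks(g, params, seed=seed + 10 + k)
            tracks.append(comp.call_compartments(m, peaks))
        return sw.classify_switches(tracks[0], tracks[1])

    def test_identical_truth_highly_stable(self):
        fracs = []
        for seed in range(5):
            g = sd.generate_genome(1, 10_000_000, 100_000, compartment_block_bins=10,
                                   seed=seed)
            fracs.append(self.run_pair(g, g, seed * 100).stable_fraction)
        assert np.median(fracs) >= 95.0

    def test_flipped_blocks_recovered(self):
        errs = []
        for seed in range(5):
            g = sd.generate_genome(1, 10_000_000, 100_000, compartment_block_bins=10,
                                   seed=seed)
            g2, frac = sd.flip_compartment_blocks(g, 0.10, seed=seed)
            table = self.run_pair(g, g2, seed * 100)
            errs.append(abs(table.switch_fraction - 100 * frac))
        assert np.median(errs) <= 3.0
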