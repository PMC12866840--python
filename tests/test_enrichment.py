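import numpy as np
import pandas as pd
import pytest

from geomgenome.enrichment import (Loop, PeakSet, content_distribution_test,
                                   distance_profile, enrichment_test,
                                   loop_composition,
                                   mutation_frequency_grouping,
                                   overlap_fraction, packing_ratio,
                                   random_control, read_bedpe_loops,
                                   read_narrowpeak)
from geomgenome.intervals import ChromosomeLayout, GenomicInterval
from geomgenome.segmentation import segment_layout
from tests.conftest import random_layout


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestOverlap:
    def test_one_bp_boundary_and_half_open(self):
        peaks = PeakSet("m", [iv("chr1", 399, 500)])
        assert overlap_fraction([("chr1", 100, 400)], peaks)["chr1"] == 1.0
        peaks2 = PeakSet("m", [iv("chr1", 400, 500)])
        assert overlap_fraction([("chr1", 100, 400)], peaks2)["chr1"] == 0.0

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_q, n_p = rng.integers(1, 200, 2)
            qs = rng.integers(0, 10_000, n_q)
            qe = qs + rng.integers(1, 500, n_q)
            ps = rng.integers(0, 10_000, n_p)
            pe = ps + rng.integers(1, 500, n_p)
            peaks = PeakSet("m", [iv("chr1", int(s), int(e))
                                  for s, e in zip(ps, pe)])
            queries = [("chr1", int(s), int(e)) for s, e in zip(qs, qe)]
            got = overlap_fraction(queries, peaks)["chr1"]
            expect = np.mean([
                any(p_s < q_e and q_s < p_e for p_s, p_e in zip(ps, pe))
                for q_s, q_e in zip(qs, qe)])
            assert got == pytest.approx(expect)

    def test_random_control_count_size_determinism(self):
        ctrl = random_control({"chr1": 10, "chr2": 5},
                              {"chr1": 100_000, "chr2": 50_000}, seed=4)
        assert len(ctrl) == 15
        assert all(len(c) == 300 for c in ctrl)
        again = random_control({"chr1": 10, "chr2": 5},
                               {"chr1": 100_000, "chr2": 50_000}, seed=4)
        assert [(c.chrom, c.start) for c in ctrl] == \
            [(c.chrom, c.start) for c in again]

    def test_control_overlap_matches_analytic_rate(self):
        # peaks of width w tiled at spacing s cover f=w/s; a 300-bp control
        # overlaps iff a peak start falls within (start-w, start+300)
        w, spacing, length = 200, 10_000, 10_000_000
        starts = np.arange(0, length - w, spacing)
        peaks = PeakSet("m", [iv("chr1", int(s), int(s + w)) for s in starts])
        ctrl = random_control({"chr1": 3000}, {"chr1": length}, seed=9)
        frac = overlap_fraction(ctrl, peaks)["chr1"]
        expect = (300 + w - 1) / spacing
        assert frac == pytest.approx(expect, rel=0.15)

    def test_enrichment_test_labels(self):
        obs = pd.Series({f"chr{i}": 0.3 + 0.01 * i for i in range(6)})
        ctrl = pd.Series({f"chr{i}": 0.1 + 0.01 * i for i in range(6)})
        res = enrichment_test(obs, ctrl)
        swapped = enrichment_test(ctrl, obs)
        assert res.test.pvalue == pytest.approx(swapped.test.pvalue)
        assert res.test.statistic == pytest.approx(-swapped.test.statistic)
        assert res.test.pvalue < 0.01


class TestDistanceProfile:
    def _genes(self, spans):
        from tests.test_annotation import make_gene
        return [make_gene(f"NM_{i}", [(s, e)]) for i, (s, e) in
                enumerate(spans)]

    def test_simple_nearest(self):
        a = PeakSet("a", [iv("chr1", 990, 1010)])          # midpoint 1000
        b = PeakSet("b", [iv("chr1", 890, 910), iv("chr1", 1490, 1510)])
        prof = distance_profile(a, b, self._genes([(0, 2000)]))
        assert prof.loc[0, "a_count"] == 1
        assert prof.loc[0, "median_distance"] == 100

    def test_chromosome_without_b_excluded(self):
        a = PeakSet("a", [iv("chr1", 990, 1010), iv("chr2", 90, 110)])
        b = PeakSet("b", [iv("chr1", 890, 910)])
        genes = self._genes([(0, 2000)])
        from tests.test_annotation import make_gene
        genes.append(make_gene("NM_9", [(0, 2000)], chrom="chr2"))
        prof = distance_profile(a, b, genes)
        assert prof["n_distances"].sum() == 1
        assert prof.attrs["n_excluded"] == 1

    def test_matches_brute_force_nearest(self):
        rng = np.random.default_rng(3)
        a_mid = np.sort(rng.choice(100_000, 300, replace=False))
        b_mid = np.sort(rng.choice(100_000, 200, replace=False))
        a = PeakSet("a", [iv("chr1", int(m - 5), int(m + 5)) for m in a_mid + 5])
        b = PeakSet("b", [iv("chr1", int(m - 5), int(m + 5)) for m in b_mid + 5])
        genes = self._genes([(0, 100_010)])
        prof = distance_profile(a, b, genes, max_count=10**9)
        brute = np.median([np.abs(b_mid + 5 - (m + 5)).min() for m in a_mid])
        assert prof["median_distance"].iloc[0] == pytest.approx(brute)

    def test_monotone_with_planted_density(self):
        # genes with more a-peaks get denser b-peaks: median must decrease
        rng = np.random.default_rng(8)
        a_ivs, b_ivs, spans = [], [], []
        pos = 0
        for count in (1, 4, 8):
            for _ in range(30):
                span = (pos, pos + 50_000)
                spans.append(span)
                for m in rng.integers(pos, pos + 50_000, count):
                    a_ivs.append(iv("chr1", int(m), int(m) + 2))
                for m in rng.integers(pos, pos + 50_000, count * 8):
                    b_ivs.append(iv("chr1", int(m), int(m) + 2))
                pos += 50_000
        prof = distance_profile(PeakSet("a", a_ivs), PeakSet("b", b_ivs),
                                self._genes(spans))
        med = prof.set_index("a_count")["median_distance"]
        assert med.loc[1] > med.loc[4] > med.loc[8]


class TestLoops:
    def test_composition_conserves_span(self, toy_layout):
        loop = Loop(iv("chr1", 50, 150), iv("chr1", 700, 800), 30)
        df = loop_composition([loop], toy_layout)
        row = df.iloc[0]
        assert row["loop_class"] == "strong"
        assert row["exon_bp"] + row["ne_bp"] == 800 - 50
        assert row["exon_bp"] == 200  # both toy exons inside the span

    def test_zero_exon_loop_and_classes(self, toy_layout):
        loops = [Loop(iv("chr1", 200, 210), iv("chr1", 490, 500), 1),
                 Loop(iv("chr1", 0, 10), iv("chr1", 90, 100), 10)]
        df = loop_composition(loops, toy_layout)
        assert df.loc[0, "exon_bp"] == 0
        assert df.loc[0, "loop_class"] == "transient"
        assert df.loc[1, "loop_class"] == "mid"

    def test_cross_chromosome_anchor_rejected_at_parse(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        path.write_text("chr1\t0\t100\tchr1\t500\t600\t25\n"
                        "chr1\t0\t100\tchr2\t500\t600\t25\n")
        loops, n_rej = read_bedpe_loops(path)
        assert len(loops) == 1 and n_rej == 1

    def test_other_chromosome_loops_counted(self, toy_layout):
        loops = [Loop(iv("chr2", 0, 10), iv("chr2", 90, 100), 25)]
        df = loop_composition(loops, toy_layout)
        assert df.empty and df.attrs["n_rejected"] == 1


class TestPackingRatio:
    def test_full_and_empty_coverage(self, toy_layout):
        regions = [("chr1", 0, 1000)]
        full = PeakSet("s", [iv("chr1", 0, 1000)])
        df, _ = packing_ratio(full, regions, toy_layout)
        assert df.loc[0, "ratio"] == pytest.approx(1000 / 800)
        empty = PeakSet("s", [])
        df2, fit = packing_ratio(empty, regions, toy_layout)
        assert df2.loc[0, "ratio"] == 0.0 and fit is None

    def test_constructed_exponent(self):
        # coverage ~ ne^(1-delta) by construction -> ratio exponent -delta
        rng = np.random.default_rng(1)
        length = 10_000_000
        lay = ChromosomeLayout("chr1", "+", length)
        regions, ivs = [], []
        pos = 0
        for _ in range(200):
            ne = int(10 ** rng.uniform(3, 5))
            covered = int(ne ** 0.7)
            regions.append(("chr1", pos, pos + ne))
            ivs.append(iv("chr1", pos, pos + covered))
            pos += ne + 10
        df, fit = packing_ratio(PeakSet("s", ivs), regions, lay)
        assert fit.exponent == pytest.approx(-0.3, abs=0.02)


class TestMutationGrouping:
    def test_equal_frequencies_equal_means(self):
        table = pd.DataFrame({"gene_id": list("abcdef"),
                              "frequency": [0.5] * 6})
        out = mutation_frequency_grouping(table, {}, 3)
        assert (out["mean_frequency"] == 0.5).all()
        assert out["n_genes"].tolist() == [2, 2, 2]

    def test_each_gene_its_own_group(self):
        table = pd.DataFrame({"gene_id": ["a", "b", "c"],
                              "frequency": [0.3, 0.1, 0.2]})
        out = mutation_frequency_grouping(table, {"a": True}, 3)
        assert out["mean_frequency"].tolist() == [0.1, 0.2, 0.3]
        assert out["hinge_fraction"].tolist() == [0.0, 0.0, 1.0]

    def test_hinge_fraction_monotone_when_planted(self):
        rng = np.random.default_rng(2)
        n = 300
        freq = np.sort(rng.random(n))
        flags = {f"g{i}": bool(rng.random() < (i / n) * 0.9)
                 for i in range(n)}
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(n)],
                              "frequency": freq})
        out = mutation_frequency_grouping(table, flags, 5)
        hf = out["hinge_fraction"].to_numpy()
        assert np.all(np.diff(hf) > -0.15)  # rising trend, minor noise ok
        assert hf[-1] > hf[0] + 0.3

    def test_tie_break_is_deterministic(self):
        table = pd.DataFrame({"gene_id": ["b", "a", "d", "c"],
                              "frequency": [0.1, 0.1, 0.1, 0.1]})
        a = mutation_frequency_grouping(table, {"a": True}, 2)
        b = mutation_frequency_grouping(table.iloc[::-1], {"a": True}, 2)
        assert a["hinge_fraction"].tolist() == b["hinge_fraction"].tolist()


class TestIO:
    def test_narrowpeak_pvalue_filter(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        # col 8 is -log10(p): 2.0 -> p=0.01 kept; 0.5 -> p~0.32 dropped
        path.write_text("chr1\t0\t100\tpk1\t0\t.\t5.0\t2.0\t2.0\t50\n"
                        "chr1\t200\t300\tpk2\t0\t.\t5.0\t0.5\t0.5\t50\n")
        ps = read_narrowpeak(path, pvalue_cutoff=0.1)
        assert len(ps.intervals) == 1
        ps_all = read_narrowpeak(path, pvalue_cutoff=None)
        assert len(ps_all.intervals) == 2

    def test_mann_whitney_utility(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200)
        u, p_same = content_distribution_test(a, a)
        assert p_same == pytest.approx(1.0, abs=1e-6)
        _, p_diff = content_distribution_test(a, a + 3)
        assert p_diff < 1e-10
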