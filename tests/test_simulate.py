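import numpy as np
import pytest

from geomgenome.enrichment import overlap_fraction
from geomgenome.scaling import fit_ei_vs_length
from geomgenome.segmentation import detect_hinges, segment_layout
from geomgenome.simulate import (FeatureSpec, GenomeSpec, generate_genome,
                                 generate_loops, generate_peaks,
                                 generate_sequence, write_fasta)


class TestGenomeSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"architecture": "banana"},
        {"architecture": "power_law", "gamma": 3.5},
        {"exonic_fraction": 0.7},
        {"n_genes": 0},
        {"hinge_len_range": (50, 200)},  # 2*200 > 300
    ])
    def test_invalid_specs(self, kwargs):
        with pytest.raises(ValueError):
            GenomeSpec(**kwargs)

    def test_infeasible_fraction_target(self):
        # wide exon totals make the natural fraction far below 9.8%
        spec = GenomeSpec(n_genes=200, exonic_fraction=0.098, seed=0)
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(spec)


class TestGenerateGenome:
    def test_power_law_arithmetic(self):
        spec = GenomeSpec(n_genes=50, gamma=2.3, p=5000,
                          noise_sigma_log10=0.0, seed=5)
        genome = generate_genome(spec)
        m = genome.metrics()
        # each gene's NE budget is E^gamma/p, split introns + trailing gap;
        # gene-level intron bp never exceeds the budget
        for _, row in m.iterrows():
            budget = row["exon_bp"] ** 2.3 / 5000
            assert row["intron_bp"] <= budget + 1

    def test_segment_level_power_law_is_exact_without_noise(self):
        spec = GenomeSpec(n_genes=300, gamma=2.3, p=5000,
                          noise_sigma_log10=0.0, seed=5)
        genome = generate_genome(spec)
        _, _, segs = segment_layout(genome.layouts["chr1"])
        e = np.array([s.exon_bp for s in segs], float)
        n = np.array([s.ne_bp for s in segs], float)
        expect = e ** 2.3 / 5000
        assert np.allclose(n, expect, rtol=0.01)

    def test_linear_architecture(self):
        spec = GenomeSpec(n_genes=40, architecture="linear", linear_slope=9.0,
                          noise_sigma_log10=0.0, seed=2)
        genome = generate_genome(spec)
        _, _, segs = segment_layout(genome.layouts["chr1"])
        for s in segs:
            assert s.ne_bp == pytest.approx(9.0 * s.exon_bp, rel=0.01)

    def test_random_null_has_flat_ei(self):
        # fine exon granularity keeps the small-window Jensen bias of the
        # log-space slope below the tolerance
        spec = GenomeSpec(n_genes=1500, architecture="random_null",
                          exonic_fraction=0.098,
                          exon_total_range=(1000, 6000),
                          exon_count_range="auto", typical_exon_bp=100,
                          seed=6)
        genome = generate_genome(spec)
        res = fit_ei_vs_length(genome.metrics())
        assert abs(res.n_hat) < 0.1

    def test_bit_reproducible(self):
        a = generate_genome(GenomeSpec(n_genes=60, seed=9))
        b = generate_genome(GenomeSpec(n_genes=60, seed=9))
        assert np.array_equal(a.layouts["chr1"].exon_starts,
                              b.layouts["chr1"].exon_starts)
        assert a.hinge_spans == b.hinge_spans
        c = generate_genome(GenomeSpec(n_genes=60, seed=10))
        assert not np.array_equal(a.layouts["chr1"].exon_starts,
                                  c.layouts["chr1"].exon_starts)

    def test_layout_conservation_and_gene_consistency(self, default_genome):
        for lay in default_genome.layouts.values():
            assert lay.exon_bp + lay.ne_bp == lay.length
        m = default_genome.metrics()
        assert (m["exon_bp"] + m["intron_bp"] == m["length"]).all()

    def test_planted_hinges_are_exactly_the_detected_hinges(self,
                                                            default_genome):
        lay = default_genome.layouts["chr1"]
        pairs, hinges, _ = segment_layout(lay)
        planted = default_genome.hinge_spans["chr1"]
        detected = sorted((h.span.start, h.span.end) for h in hinges)
        assert detected == sorted(planted)

    def test_exonic_fraction_target_hit(self, dense_genome):
        for chrom, f in dense_genome.provenance["exonic_fraction"].items():
            assert f == pytest.approx(0.098, abs=0.001)

    def test_multi_chromosome_split(self):
        genome = generate_genome(GenomeSpec(n_genes=50, n_chromosomes=4,
                                            seed=3))
        assert set(genome.layouts) == {"chr1", "chr2", "chr3", "chr4"}
        per = [sum(1 for g in genome.genes if g.chrom == c)
               for c in genome.layouts]
        assert sum(per) == 50 and max(per) - min(per) <= 1

    def test_hinge_rate_controls_pair_fraction(self):
        lo = generate_genome(GenomeSpec(n_genes=200, hinge_rate=0.2, seed=1))
        hi = generate_genome(GenomeSpec(n_genes=200, hinge_rate=0.6, seed=1))
        def frac(g):
            pairs, hinges, _ = segment_layout(g.layouts["chr1"])
            return len(hinges) / len(pairs)
        assert frac(lo) == pytest.approx(0.2, abs=0.05)
        assert frac(hi) == pytest.approx(0.6, abs=0.05)


class TestSequence:
    def test_all_gc(self):
        genome = generate_genome(GenomeSpec(
            n_genes=5, exon_total_range=(500, 1000), seed=1))
        lay = genome.layouts["chr1"]
        fs = FeatureSpec(gc_background=1.0, gc_exon=1.0, gc_hinge=1.0,
                         motif_rate_hinge=0.0, motif_rate_exon=0.0, seed=2)
        seq = generate_sequence(lay, fs, genome.hinge_spans["chr1"])
        assert set(seq) <= {"G", "C"}
        assert len(seq) == lay.length

    def test_motif_planting_rate_one(self):
        genome = generate_genome(GenomeSpec(
            n_genes=20, exon_total_range=(500, 1000), seed=4))
        lay = genome.layouts["chr1"]
        fs = FeatureSpec(motif_rate_hinge=1.0, motif_rate_exon=0.0, seed=5)
        seq = generate_sequence(lay, fs, genome.hinge_spans["chr1"])
        for s, e in genome.hinge_spans["chr1"]:
            assert "CCCTC" in seq[s:e]

    def test_fasta_round_trip(self, tmp_path):
        from pyfaidx import Fasta

        seqs = {"chr1": "ACGT" * 50, "chr2": "GGGG" * 30}
        path = tmp_path / "g.fa"
        write_fasta(seqs, path)
        fa = Fasta(str(path))
        assert str(fa["chr1"][:]) == seqs["chr1"]
        assert str(fa["chr2"][:]) == seqs["chr2"]


class TestPeaksAndLoops:
    def test_zero_intensity_empty(self, default_genome):
        lay = default_genome.layouts["chr1"]
        fs = FeatureSpec(peak_rate={"hinge": 0, "exon": 0, "ne": 0}, seed=1)
        ps = generate_peaks(lay, fs, "mark",
                            default_genome.hinge_spans["chr1"])
        assert ps.intervals == []

    def test_hinge_enriched_peaks_overlap_hinges_more(self):
        genome = generate_genome(GenomeSpec(
            n_genes=400, exon_total_range=(1000, 6000),
            exon_count_range="auto", hinge_rate=0.5, seed=11))
        lay = genome.layouts["chr1"]
        fs = FeatureSpec(peak_rate={"hinge": 3e-4, "exon": 0.0, "ne": 1e-6},
                         seed=12)
        ps = generate_peaks(lay, fs, "ctcf", genome.hinge_spans["chr1"])
        hinges = [("chr1", s, e) for s, e in genome.hinge_spans["chr1"]]
        rng = np.random.default_rng(13)
        ctrl_starts = rng.integers(0, lay.length - 300, len(hinges))
        controls = [("chr1", int(s), int(s) + 300) for s in ctrl_starts]
        f_h = overlap_fraction(hinges, ps)["chr1"]
        f_c = overlap_fraction(controls, ps)["chr1"]
        assert f_h > 3 * max(f_c, 1e-3)

    def test_loops_respect_frequency_cuts_and_spans(self, default_genome):
        lay = default_genome.layouts["chr1"]
        _, _, segs = segment_layout(lay)
        fs = FeatureSpec(n_strong_loops=40, n_transient_loops=40, seed=14)
        loops = generate_loops(segs, fs, lay)
        strong = [l for l in loops if l.frequency > 20]
        transient = [l for l in loops if l.frequency < 5]
        assert len(strong) == 40 and len(transient) == 40
        seg_spans = {(s.span.start, s.span.end) for s in segs}
        for l in strong:
            assert (l.span.start, l.span.end) in seg_spans
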