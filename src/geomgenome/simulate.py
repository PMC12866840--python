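"""Synthetic genomes, sequences, peaks and loops with the statistical
structure the packing-geometry analysis assumes.

The genome generator emits gene annotations whose intron totals follow one
of three architectures:

* ``power_law``  — I = E^gamma / p with lognormal scatter (packing-domain
  geometry; defaults gamma = 2.3, p = 5000 bp, the most frequently observed
  ensemble values).
* ``linear``     — I = c * E (beads-on-a-string chain).
* ``random_null``— exons thrown uniformly onto the chromosome (no coupling).

Genes are laid head-to-tail on each chromosome with a short planted hinge
pair (exon + NE, total <= 300 bp) between consecutive genes, so that hinge
segmentation recovers genes as power-law segments. Intra-gene introns are
floored at 301 bp and exon/gap shares keep every non-planted pair above the
hinge threshold: the planted hinges are provably the only hinges.

Every generator takes an explicit seed and is bit-reproducible; provenance
records all draws needed to recompute expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotation import GeneModel, metrics_frame
from .enrichment import Loop, PeakSet
from .intervals import ChromosomeLayout, GenomicInterval
from .segmentation import PowerLawSegment

__all__ = [
    "GenomeSpec",
    "FeatureSpec",
    "SyntheticGenome",
    "generate_genome",
    "generate_sequence",
    "generate_peaks",
    "generate_loops",
    "write_fasta",
]

MIN_INTRON = 301  # keeps intra-gene pairs above the 300-bp hinge threshold
MIN_EXON = 20


@dataclass
class GenomeSpec:
    """Stated world of a synthetic genome.

    Each gene's NE budget (introns + its trailing intergenic gap, one
    volumetric pool) is set by the architecture. ``exonic_fraction`` is an
    optional global target reached by appending spacer NE to the gaps
    (spacers can only add NE, so the target must lie below the
    architecture's natural fraction). ``chrom_length`` pads the chromosome
    with trailing NE when given; otherwise length is whatever the content
    assembles to.
    """

    n_chromosomes: int = 1
    n_genes: int = 2000
    architecture: str = "power_law"  # power_law | linear | random_null
    gamma: float = 2.3
    p: float = 5000.0
    linear_slope: float = 9.0
    noise_sigma_log10: float = 0.1
    exon_total_range: tuple = (300, 300_000)  # log-uniform draw of E per gene
    #: a (lo, hi) tuple draws exon count k uniformly; "auto" sizes it by gene
    #: content (k = round(E / typical_exon_bp), >= 2, many-small-exons).
    #: Within a gene, exon sizes are near-even, so pair size tracks gene size
    #: (the pair-level exon/NE coupling of the packing hypothesis); "auto"
    #: instead fixes piece size, which is what window-based null analyses of
    #: dense genomes want.
    exon_count_range: tuple | str = (2, 5)
    typical_exon_bp: int = 300
    exonic_fraction: Optional[float] = None
    hinge_len_range: tuple = (50, 150)  # exon and NE of each planted hinge
    #: target fraction of all pairs that are planted hinges; the default puts
    #: a short train of hinge pairs between consecutive genes, the regime the
    #: packing hypothesis describes (hinges frequent enough that domains are
    #: single-gene-scale)
    hinge_rate: Optional[float] = 0.6
    chrom_length: Optional[int] = None
    orientation: str = "+"
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ("power_law", "linear", "random_null"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.architecture == "power_law" and not 2.0 <= self.gamma <= 3.0:
            raise ValueError("gamma must be in [2, 3] for power_law")
        if self.exonic_fraction is not None and not 0 < self.exonic_fraction < 0.5:
            raise ValueError("exonic_fraction must be in (0, 0.5)")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("need >= 1 gene and chromosome")
        lo, hi = self.hinge_len_range
        if 2 * hi > 300:
            raise ValueError("planted hinge exon+NE must stay <= 300 bp")


@dataclass
class FeatureSpec:
    """Stated world of synthetic sequence, peak and loop features.

    GC and motif defaults are the contrasts reported for the human genome:
    hinge GC 0.53 against a 0.41 background, CTCF-core motif planted in 37%
    of hinges against 22% of exons. Peak rates are per-bp intensities of a
    thinned point process by region class.
    """

    gc_background: float = 0.41
    gc_exon: float = 0.41
    gc_hinge: float = 0.53
    motif: str = "CCCTC"
    motif_rate_hinge: float = 0.37
    motif_rate_exon: float = 0.22
    peak_rate: dict = field(default_factory=lambda: {
        "hinge": 1e-4, "exon": 1e-4, "ne": 1e-5})
    peak_width_log_mean: float = np.log(200.0)
    peak_width_log_sigma: float = 0.5
    n_strong_loops: int = 100
    n_transient_loops: int = 100
    strong_freq_range: tuple = (21, 60)
    transient_freq_range: tuple = (1, 4)
    seed: int = 0


@dataclass
class SyntheticGenome:
    """Generated annotation plus provenance of every draw."""

    spec: GenomeSpec
    genes: list[GeneModel]
    layouts: dict[str, ChromosomeLayout]
    hinge_spans: dict[str, list[tuple[int, int]]]  # planted (start, end)
    provenance: dict

    def metrics(self):
        return metrics_frame(self.genes)

    def gene_windows(self, chrom: str):
        return [(g.tx_start, g.tx_end) for g in self.genes if g.chrom == chrom]


def _integer_split(total: int, n: int, floor: int, rng) -> np.ndarray:
    """Split ``total`` into n integers >= floor, Dirichlet(1) shares."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    spare = total - n * floor
    if spare < 0:
        raise ValueError("total too small for floors")
    shares = rng.dirichlet(np.ones(n)) * spare
    parts = np.floor(shares).astype(np.int64) + floor
    parts[-1] += total - parts.sum()
    return parts


def generate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Generate gene models and chromosome layouts for the stated world."""
    rng = np.random.default_rng(spec.seed)
    if spec.architecture == "random_null":
        return _generate_random_null(spec, rng)

    n_per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    n_per_chrom[: spec.n_genes % spec.n_chromosomes] += 1

    genes: list[GeneModel] = []
    layouts: dict[str, ChromosomeLayout] = {}
    hinge_spans: dict[str, list[tuple[int, int]]] = {}
    prov_rows = []
    gene_no = 0
    lo_e, hi_e = spec.exon_total_range
    h_lo, h_hi = spec.hinge_len_range

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = int(n_per_chrom[ci])
        # per-gene draws
        E = np.exp(rng.uniform(np.log(lo_e), np.log(hi_e), size=n))
        E = np.maximum(E.astype(np.int64), 2 * MIN_EXON + 1)
        noise = 10.0 ** rng.normal(0.0, spec.noise_sigma_log10, size=n)
        if spec.architecture == "power_law":
            I = (E.astype(float) ** spec.gamma / spec.p) * noise
        else:  # linear
            I = spec.linear_slope * E.astype(float) * noise
        I = np.maximum(I.astype(np.int64), 0)

        # the NE budget I covers introns plus the gene's trailing intergenic
        # gap (introns and intergenic segments are one volumetric pool);
        # introns need a 301-bp floor and the trailing gap keeps >= 301 bp
        # whenever any intron exists, so planted hinges stay the only hinges
        # among multi-exon genes
        ks = _draw_exon_counts(spec, rng, E, n)
        ks = np.minimum(ks, I // (2 * MIN_INTRON) + 1)
        ks = np.maximum(np.minimum(ks, E // MIN_EXON), 1)
        # planted hinges: one per inter-gene boundary, plus extras to reach
        # a requested hinge fraction of all pairs
        reps = np.ones(max(n - 1, 0), dtype=np.int64)
        if spec.hinge_rate is not None and n > 1:
            target = int(round(spec.hinge_rate / (1 - spec.hinge_rate)
                               * int(ks.sum())))
            extra = max(0, target - (n - 1))
            reps += np.bincount(np.arange(extra) % (n - 1), minlength=n - 1)
        n_hinges = int(reps.sum())
        hinge_exon = rng.integers(h_lo, h_hi + 1, size=n_hinges)
        hinge_ne = rng.integers(h_lo, h_hi + 1, size=n_hinges)

        extra_gap = _spacer_budget(spec, rng, E, I, hinge_exon, hinge_ne, n)

        pos = 0
        spans: list[tuple[int, int]] = []
        ex_starts: list[int] = []
        ex_ends: list[int] = []
        hinge_cursor = 0
        for gi in range(n):
            k = int(ks[gi])
            n_introns = k - 1
            exon_parts = np.full(k, int(E[gi]) // k, dtype=np.int64)
            exon_parts[-1] += int(E[gi]) - int(exon_parts.sum())
            if n_introns:
                ne_parts = _integer_split(int(I[gi]), n_introns + 1,
                                          MIN_INTRON, rng)
                intron_parts, gap = ne_parts[:-1], int(ne_parts[-1])
            else:
                intron_parts, gap = np.empty(0, np.int64), int(I[gi])

            gene_no += 1
            gid = f"NM_{gene_no:06d}"
            tx_start = pos
            exons = []
            for ei in range(k):
                e_len = int(exon_parts[ei])
                exons.append(GenomicInterval(chrom, pos, pos + e_len,
                                             spec.orientation))
                ex_starts.append(pos)
                ex_ends.append(pos + e_len)
                pos += e_len
                if ei < n_introns:
                    pos += int(intron_parts[ei])
            tx_end = pos
            genes.append(GeneModel(gid, chrom, spec.orientation, tx_start,
                                   tx_end, exons))
            prov_rows.append((gid, chrom, int(E[gi]), int(tx_end - tx_start
                                                          - E[gi]), k))
            pos += gap + int(extra_gap[gi])
            if gi < n - 1:  # planted hinge pair(s) between genes
                for _ in range(int(reps[gi])):
                    hs = pos
                    ex_starts.append(pos)
                    ex_ends.append(pos + int(hinge_exon[hinge_cursor]))
                    pos += int(hinge_exon[hinge_cursor]) + int(hinge_ne[hinge_cursor])
                    spans.append((hs, pos))
                    hinge_cursor += 1
        length = pos
        if spec.chrom_length is not None:
            if spec.chrom_length < length:
                raise ValueError(
                    f"chrom_length {spec.chrom_length} < assembled {length}")
            length = spec.chrom_length
        layouts[chrom] = ChromosomeLayout(
            chrom=chrom, orientation=spec.orientation, length=length,
            exon_starts=np.array(ex_starts, np.int64),
            exon_ends=np.array(ex_ends, np.int64),
        )
        hinge_spans[chrom] = spans

    provenance = {
        "spec": spec,
        "genes": prov_rows,
        "chrom_lengths": {c: lay.length for c, lay in layouts.items()},
        "exonic_fraction": {
            c: lay.exon_bp / lay.length for c, lay in layouts.items()
        },
    }
    return SyntheticGenome(spec, genes, layouts, hinge_spans, provenance)


def _draw_exon_counts(spec, rng, E, n):
    if spec.exon_count_range == "auto":
        return np.maximum(np.round(E / spec.typical_exon_bp).astype(np.int64), 2)
    k_lo, k_hi = spec.exon_count_range
    return rng.integers(k_lo, k_hi + 1, size=n)


def _spacer_budget(spec, rng, E, I, hinge_exon, hinge_ne, n):
    """Extra spacer NE per gene needed to hit an exonic-fraction target.

    The architecture already allocates each gene its NE budget I (introns +
    trailing gap); a global exonic-fraction target below the architecture's
    natural fraction is reached by appending spacer NE to the trailing gaps
    (Dirichlet shares). Without a target, no spacer is added. Spacers
    distort segment-level scaling by construction — they are for the
    whole-chromosome null analyses, not for exponent-recovery worlds.
    """
    if spec.exonic_fraction is None:
        return np.zeros(n, dtype=np.int64)
    f = spec.exonic_fraction
    total_exon = int(E.sum()) + int(hinge_exon.sum())
    required = total_exon / f
    budget = required - total_exon - int(I.sum()) - int(hinge_ne.sum())
    if budget < 0:
        raise ValueError(
            "exonic_fraction target infeasible: the architecture's NE "
            "content already puts the exonic fraction below the target")
    return _integer_split(int(budget), n, 0, rng)


def _generate_random_null(spec: GenomeSpec, rng) -> SyntheticGenome:
    """Exons thrown uniformly onto each chromosome; gene windows tile it.

    Windows are contiguous blocks whose lengths mirror the architecture-free
    gene-length scale (E + gap for the drawn exon totals at the target
    exonic fraction), so fit_ei_vs_length over them probes pure randomness.
    """
    from .randomization import randomize_exons

    f = spec.exonic_fraction if spec.exonic_fraction is not None else 0.098
    n_per_chrom = np.full(spec.n_chromosomes, spec.n_genes // spec.n_chromosomes)
    n_per_chrom[: spec.n_genes % spec.n_chromosomes] += 1
    lo_e, hi_e = spec.exon_total_range
    genes: list[GeneModel] = []
    layouts: dict[str, ChromosomeLayout] = {}
    gene_no = 0
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n = int(n_per_chrom[ci])
        E = np.exp(rng.uniform(np.log(lo_e), np.log(hi_e), size=n)).astype(np.int64)
        win_lens = (E / f).astype(np.int64)
        length = int(win_lens.sum())
        # exon length pool: split each E into exon_count pieces
        k = np.maximum(np.minimum(_draw_exon_counts(spec, rng, E, n),
                                  E // MIN_EXON), 1)
        pieces = []
        for gi in range(n):
            pieces.extend(_integer_split(int(E[gi]), int(k[gi]), MIN_EXON, rng))
        base = ChromosomeLayout(chrom=chrom, orientation=spec.orientation,
                                length=length,
                                exon_starts=np.cumsum([0] + [int(x) for x in pieces[:-1]]),
                                exon_ends=np.cumsum([int(x) for x in pieces]))
        layout = randomize_exons(base, seed=int(rng.integers(2**31))).layout
        layouts[chrom] = layout
        # windows tile the chromosome; synthesize gene records holding the
        # exons that landed fully inside each window
        bounds = np.concatenate([[0], np.cumsum(win_lens)])
        for gi in range(n):
            s, e = int(bounds[gi]), int(bounds[gi + 1])
            # clip boundary-straddling exons so window exon bp stays unbiased
            inside = [(max(int(a), s), min(int(b), e)) for a, b in
                      zip(layout.exon_starts, layout.exon_ends)
                      if a < e and b > s]
            if not inside:
                continue
            gene_no += 1
            genes.append(GeneModel(
                f"NM_{gene_no:06d}", chrom, spec.orientation, s, e,
                [GenomicInterval(chrom, a, b, spec.orientation)
                 for a, b in inside]))
    provenance = {
        "spec": spec,
        "chrom_lengths": {c: lay.length for c, lay in layouts.items()},
        "exonic_fraction": {c: lay.exon_bp / lay.length
                            for c, lay in layouts.items()},
    }
    return SyntheticGenome(spec, genes, layouts, {c: [] for c in layouts},
                           provenance)


# ---------------------------------------------------------------------------
# Sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_bases(n, gc, rng):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def generate_sequence(layout: ChromosomeLayout, feature_spec: FeatureSpec,
                      hinge_spans=None, seed: Optional[int] = None) -> str:
    """I.i.d. sequence with class-specific GC and planted CCCTC motifs.

    Background NE, exon and hinge regions get their own GC; each hinge
    (resp. exon) region independently receives one literal motif copy at a
    uniform position with probability ``motif_rate_hinge``
    (``motif_rate_exon``). Hinge class overrides exon class where they
    overlap.
    """
    fs = feature_spec
    rng = np.random.default_rng(fs.seed if seed is None else seed)
    codes = _random_bases(layout.length, fs.gc_background, rng)
    exon_regions = list(zip(layout.exon_starts, layout.exon_ends))
    for s, e in exon_regions:
        codes[s:e] = _random_bases(e - s, fs.gc_exon, rng)
    hinge_spans = hinge_spans or []
    for s, e in hinge_spans:
        codes[s:e] = _random_bases(e - s, fs.gc_hinge, rng)

    motif_codes = np.array(["ACGT".index(b) for b in fs.motif.upper()])
    m = motif_codes.size

    def plant(regions, rate):
        for s, e in regions:
            if e - s >= m and rng.random() < rate:
                pos = int(rng.integers(s, e - m + 1))
                codes[pos:pos + m] = motif_codes

    plant(exon_regions, fs.motif_rate_exon)
    plant(hinge_spans, fs.motif_rate_hinge)
    return _BASES[codes].tobytes().decode("ascii")


def write_fasta(sequences: dict, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Peaks and loops
# ---------------------------------------------------------------------------


def generate_peaks(layout: ChromosomeLayout, feature_spec: FeatureSpec,
                   mark: str, hinge_spans=None,
                   seed: Optional[int] = None) -> PeakSet:
    """Thinned point process of peaks with class-specific per-bp intensity.

    Classes are planted-hinge spans, exons, and the NE remainder; peak
    widths are lognormal around ~200 bp, centred uniformly within the class
    region that fired.
    """
    fs = feature_spec
    rng = np.random.default_rng(fs.seed if seed is None else seed)
    hinge_spans = list(hinge_spans or [])
    regions = {
        "hinge": hinge_spans,
        "exon": list(zip(layout.exon_starts.tolist(), layout.exon_ends.tolist())),
        "ne": list(zip(*[arr.tolist() for arr in layout.ne_intervals()])),
    }
    ivs: list[GenomicInterval] = []
    for cls, regs in regions.items():
        rate = fs.peak_rate.get(cls, 0.0)
        if rate <= 0 or not regs:
            continue
        lens = np.array([e - s for s, e in regs], dtype=np.int64)
        n_peaks = rng.poisson(rate * lens)
        for (s, e), npk in zip(regs, n_peaks):
            for _ in range(int(npk)):
                centre = int(rng.integers(s, e))
                width = max(10, int(rng.lognormal(fs.peak_width_log_mean,
                                                  fs.peak_width_log_sigma)))
                a = max(0, centre - width // 2)
                b = min(layout.length, a + width)
                if b > a:
                    ivs.append(GenomicInterval(layout.chrom, a, b))
    return PeakSet(mark, ivs)


def generate_loops(segments: list[PowerLawSegment], feature_spec: FeatureSpec,
                   layout: ChromosomeLayout,
                   seed: Optional[int] = None) -> list[Loop]:
    """Strong loops coincide with power-law segment spans (frequency above
    the strong cut); transient loops are uniform random spans with low
    frequency."""
    fs = feature_spec
    rng = np.random.default_rng(fs.seed if seed is None else seed)
    loops: list[Loop] = []
    if segments and fs.n_strong_loops:
        idx = rng.integers(0, len(segments), size=fs.n_strong_loops)
        for i in idx:
            span = segments[int(i)].span
            anchor = min(500, max(1, len(span) // 10))
            freq = int(rng.integers(*fs.strong_freq_range))
            loops.append(Loop(
                GenomicInterval(span.chrom, span.start, span.start + anchor),
                GenomicInterval(span.chrom, span.end - anchor, span.end),
                freq))
    for _ in range(fs.n_transient_loops):
        ln = int(rng.lognormal(np.log(2e4), 1.0))
        ln = min(max(ln, 2000), max(layout.length // 2, 2000))
        s = int(rng.integers(0, max(layout.length - ln, 1)))
        anchor = min(500, max(1, ln // 10))
        freq = int(rng.integers(*fs.transient_freq_range))
        loops.append(Loop(
            GenomicInterval(layout.chrom, s, s + anchor),
            GenomicInterval(layout.chrom, s + ln - anchor, s + ln),
            freq))
    return loops
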