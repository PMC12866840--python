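"""Gene annotation models, readers and strand-oriented exon projection.

Supported dialects: genePred-like TSV (UCSC 8- or 10+-column flavours with
trailing-comma exon lists), BED12, and GTF (parsed with :mod:`gffutils`;
1-based closed coordinates converted to 0-based half-open at the boundary).

Gene class is taken from the RefSeq accession prefix: ``NM``/``XM`` are
protein coding, ``NR``/``XR`` non-coding; anything else defaults to protein
coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import ChromosomeLayout, GenomicInterval

log = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneMetrics",
    "ProjectionResult",
    "read_annotation",
    "gene_metrics",
    "project_exons",
    "write_layout_bed",
    "read_layout_bed",
]

PROTEIN_CODING = "protein_coding"
NON_CODING = "non_coding"


@dataclass
class GeneModel:
    """One gene record: transcript bounds plus its ordered exons."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[GenomicInterval] = field(default_factory=list)
    gene_class: str = PROTEIN_CODING

    def __post_init__(self):
        self.exons = sorted(self.exons, key=lambda iv: iv.start)
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have >= 1 exon")
        for iv in self.exons:
            if iv.start < self.tx_start or iv.end > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon outside tx bounds")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons within gene")

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass(frozen=True)
class GeneMetrics:
    """Per-gene exon/intron composition.

    ``ei_ratio`` is E/I, the shell-to-volume proxy of the packing model;
    it is ``nan`` (and ``single_exon`` is set) when the gene has no intronic
    bp, because the ratio is undefined there.
    """

    gene_id: str
    exon_bp: int
    intron_bp: int
    length: int
    ei_ratio: float
    single_exon: bool
    gene_class: str = PROTEIN_CODING


def classify_accession(gene_id: str) -> str:
    acc = gene_id.upper()
    if acc.startswith(("NR_", "XR_", "NR", "XR")) and acc[:2] in ("NR", "XR"):
        return NON_CODING
    return PROTEIN_CODING


def gene_metrics(gene: GeneModel) -> GeneMetrics:
    """E = summed exon bp, I = L - E, E/I (nan for single-exon/intronless genes)."""
    e = sum(len(iv) for iv in gene.exons)
    length = gene.length
    i = length - e
    if i > 0:
        ratio = e / i
        single = False
    else:
        ratio = float("nan")
        single = True
    return GeneMetrics(gene.gene_id, e, i, length, ratio, single, gene.gene_class)


def metrics_frame(genes: list[GeneModel]) -> pd.DataFrame:
    """Tabulate :func:`gene_metrics` over a gene list."""
    rows = [gene_metrics(g) for g in genes]
    return pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in rows],
            "gene_class": [m.gene_class for m in rows],
            "exon_bp": [m.exon_bp for m in rows],
            "intron_bp": [m.intron_bp for m in rows],
            "length": [m.length for m in rows],
            "ei_ratio": [m.ei_ratio for m in rows],
            "single_exon": [m.single_exon for m in rows],
        }
    )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


class AnnotationError(ValueError):
    """Malformed annotation record, reported with its line number."""


def _split_comma_list(text: str) -> list[int]:
    return [int(x) for x in str(text).strip().rstrip(",").split(",") if x != ""]


def _gene_from_exonlist(name, chrom, strand, tx_start, tx_end, starts, ends, lineno):
    if len(starts) != len(ends) or not starts:
        raise AnnotationError(f"line {lineno}: exon start/end count mismatch")
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in zip(starts, ends)]
    return GeneModel(
        gene_id=name,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        exons=exons,
        gene_class=classify_accession(name),
    )


def _read_genepred(path):
    genes, rejected = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if len(f) >= 10 and f[2] in "+-":
                    # UCSC genePred: name chrom strand txStart txEnd cdsStart
                    # cdsEnd exonCount exonStarts exonEnds
                    name, chrom, strand = f[0], f[1], f[2]
                    tx_start, tx_end = int(f[3]), int(f[4])
                    starts, ends = _split_comma_list(f[8]), _split_comma_list(f[9])
                elif len(f) >= 8:
                    # compact flavour: name chrom strand txStart txEnd
                    # exonCount exonStarts exonEnds
                    name, chrom, strand = f[0], f[1], f[2]
                    tx_start, tx_end = int(f[3]), int(f[4])
                    starts, ends = _split_comma_list(f[6]), _split_comma_list(f[7])
                else:
                    raise AnnotationError(f"line {lineno}: too few columns")
                genes.append(
                    _gene_from_exonlist(
                        name, chrom, strand, tx_start, tx_end, starts, ends, lineno
                    )
                )
            except (ValueError, IndexError) as err:
                rejected.append((lineno, str(err)))
    return genes, rejected


def _read_bed12(path):
    genes, rejected = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                if len(f) < 12:
                    raise AnnotationError(f"line {lineno}: BED12 needs 12 columns")
                chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
                strand = f[5] if f[5] in "+-" else "."
                sizes = _split_comma_list(f[10])
                offsets = _split_comma_list(f[11])
                starts = [start + o for o in offsets]
                ends = [s + sz for s, sz in zip(starts, sizes)]
                genes.append(
                    _gene_from_exonlist(name, chrom, strand, start, end, starts, ends, lineno)
                )
            except (ValueError, IndexError) as err:
                rejected.append((lineno, str(err)))
    return genes, rejected


def _read_gtf(path):
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes, rejected = [], []
    for tx in db.features_of_type(("transcript", "mRNA")):
        try:
            exons = [
                # gffutils keeps GTF 1-based closed coords; convert here.
                GenomicInterval(tx.seqid, ex.start - 1, ex.end, tx.strand)
                for ex in db.children(tx, featuretype="exon", order_by="start")
            ]
            name = tx.attributes.get("transcript_id", [tx.id])[0]
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=tx.seqid,
                    strand=tx.strand,
                    tx_start=tx.start - 1,
                    tx_end=tx.end,
                    exons=exons,
                    gene_class=classify_accession(name),
                )
            )
        except ValueError as err:
            rejected.append((tx.id, str(err)))
    return genes, rejected


def read_annotation(path, dialect: str = "genepred", first_isoform: bool = False):
    """Read gene models from an annotation file.

    Parameters
    ----------
    path : str or Path
    dialect : {"genepred", "bed12", "gtf"}
    first_isoform : bool
        Keep only the first record encountered per ``gene_id`` (file order),
        matching the single-isoform analysis mode; default keeps all isoforms
        (the chromosome-level analysis mode).

    Returns
    -------
    genes : list of GeneModel
    rejected : list of (line/id, reason)
        Malformed or out-of-bounds records, reported rather than raised.
    """
    readers = {"genepred": _read_genepred, "bed12": _read_bed12, "gtf": _read_gtf}
    try:
        reader = readers[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}") from None
    genes, rejected = reader(path)
    if rejected:
        log.warning("%d malformed records rejected from %s", len(rejected), path)
    if first_isoform:
        seen, kept = set(), []
        for g in genes:
            if g.gene_id not in seen:
                seen.add(g.gene_id)
                kept.append(g)
        genes = kept
    return genes, rejected


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


@dataclass
class ProjectionResult:
    """Chromosome layout plus the multi-start/multi-stop omission report."""

    layout: ChromosomeLayout
    n_exons_in: int
    n_omitted: int
    n_rejected: int

    @property
    def omitted_fraction(self) -> float:
        return self.n_omitted / self.n_exons_in if self.n_exons_in else 0.0


def project_exons(
    genes: list[GeneModel], orientation: str, chrom_length: int
) -> ProjectionResult:
    """Project exons of one strand of one chromosome onto a layout.

    Exact duplicate exons (shared by isoforms) collapse to one. Exons that
    partially overlap another exon with different boundaries — the
    multi-start / multi-stop events — are omitted entirely, and the omission
    fraction is reported. The NE intervals are the complement of the
    surviving exons within ``[0, chrom_length)``.
    """
    chroms = {g.chrom for g in genes}
    if len(chroms) > 1:
        raise ValueError(f"genes span multiple chromosomes: {sorted(chroms)}")
    ivs = []
    n_rejected = 0
    for g in genes:
        if g.strand != orientation:
            raise ValueError(f"{g.gene_id}: strand {g.strand} != {orientation}")
        for iv in g.exons:
            if iv.end > chrom_length:
                n_rejected += 1
                log.warning("%s: exon beyond chromosome end rejected", g.gene_id)
            else:
                ivs.append((iv.start, iv.end))
    n_in = len(ivs) + n_rejected
    # collapse exact duplicates, then omit every distinct interval that
    # partially overlaps another distinct interval (sorted neighbour scan;
    # overlap is transitive-free so each i only needs to look right)
    uniq = sorted(set(ivs))
    starts = np.array([s for s, _ in uniq], dtype=np.int64)
    ends = np.array([e for _, e in uniq], dtype=np.int64)
    keep = np.ones(len(uniq), dtype=bool)
    for i in range(len(uniq)):
        j = i + 1
        while j < len(uniq) and starts[j] < ends[i]:
            keep[i] = False
            keep[j] = False
            j += 1
    # omission fraction counts input exon *instances* lost; duplicates that
    # collapse onto a kept interval are the same projected exon, not losses
    omitted_set = {uniq[i] for i in range(len(uniq)) if not keep[i]}
    n_omitted = sum(1 for iv in ivs if iv in omitted_set)
    chrom = genes[0].chrom if genes else "chr"
    layout = ChromosomeLayout(
        chrom=chrom,
        orientation=orientation,
        length=chrom_length,
        exon_starts=starts[keep],
        exon_ends=ends[keep],
    )
    return ProjectionResult(layout, n_in, n_omitted, n_rejected)


# ---------------------------------------------------------------------------
# Layout BED round-trip
# ---------------------------------------------------------------------------


def write_layout_bed(layout: ChromosomeLayout, path) -> None:
    """4-column BED with element class (exon/NE) in the name field."""
    ne_s, ne_e = layout.ne_intervals()
    rows = [(int(s), int(e), "exon") for s, e in zip(layout.exon_starts, layout.exon_ends)]
    rows += [(int(s), int(e), "NE") for s, e in zip(ne_s, ne_e)]
    rows.sort()
    with open(path, "w") as fh:
        for s, e, cls in rows:
            fh.write(f"{layout.chrom}\t{s}\t{e}\t{cls}\n")


def read_layout_bed(path, orientation: str = "+") -> ChromosomeLayout:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    if df.empty:
        raise ValueError("empty layout BED")
    chrom = df["chrom"].iloc[0]
    length = int(df["end"].max())
    exons = df[df["name"] == "exon"]
    return ChromosomeLayout(
        chrom=chrom,
        orientation=orientation,
        length=length,
        exon_starts=exons["start"].to_numpy(np.int64),
        exon_ends=exons["end"].to_numpy(np.int64),
    )
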