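"""GC content and CTCF-core-motif (CCCTC) statistics on genomic regions.

Hinge elements are GC-enriched relative to exons and carry CTCF core motifs
more often, consistent with their proposed role as transcription-engaged
spacers between packing domains. These functions measure those contrasts on
any FASTA + region-set input and compare region classes per chromosome with
a Welch t-test (chromosomes are the test units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gc_content",
    "motif_fraction",
    "class_ttest",
    "seq_feature_table",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _fetch(sequences, chrom: str, start: int, end: int) -> str:
    """Fetch a subsequence from a pyfaidx.Fasta or a plain {chrom: str} dict."""
    if isinstance(sequences, dict):
        return sequences[chrom][start:end]
    return str(sequences[chrom][start:end])


def gc_content(regions, sequences):
    """GC fraction per region and length-weighted per chromosome.

    GC = (#G + #C) / (#A + #C + #G + #T); ambiguous bases (N) are excluded
    from the denominator. Regions that are entirely N are excluded and
    counted. ``regions`` is an iterable of objects with chrom/start/end (or
    (chrom, start, end) tuples); ``sequences`` a pyfaidx.Fasta or dict.

    Returns (per-region DataFrame, per-chromosome Series, n_excluded).
    """
    rows = []
    n_excluded = 0
    for reg in regions:
        chrom, start, end = _coords(reg)
        seq = _fetch(sequences, chrom, start, end).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        if acgt == 0:
            n_excluded += 1
            continue
        gc = (seq.count("G") + seq.count("C")) / acgt
        rows.append((chrom, start, end, acgt, gc))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_bases", "gc"])
    if df.empty:
        return df, pd.Series(dtype=float), n_excluded
    per_chrom = df.groupby("chrom").apply(
        lambda g: np.average(g["gc"], weights=g["n_bases"]),
        include_groups=False,
    )
    return df, per_chrom, n_excluded


def motif_fraction(regions, sequences, motif: str = "CCCTC",
                   both_strands: bool = True):
    """Fraction of regions containing >= 1 motif hit, per chromosome.

    A region counts once no matter how many hits it holds. With
    ``both_strands`` the literal motif and its reverse complement (GAGGG for
    CCCTC) are both scanned on the given sequence. Overlapping hits are
    allowed but irrelevant to presence/absence counting.

    Returns (per-region DataFrame with a ``hit`` column, per-chromosome
    Series of fractions).
    """
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over A/C/G/T")
    rc = reverse_complement(motif)
    rows = []
    for reg in regions:
        chrom, start, end = _coords(reg)
        seq = _fetch(sequences, chrom, start, end).upper()
        hit = motif in seq or (both_strands and rc in seq)
        rows.append((chrom, start, end, hit))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "hit"])
    per_chrom = df.groupby("chrom")["hit"].mean() if not df.empty \
        else pd.Series(dtype=float)
    return df, per_chrom


def _coords(reg):
    if hasattr(reg, "chrom"):
        return reg.chrom, reg.start, reg.end
    chrom, start, end = reg[:3]
    return chrom, int(start), int(end)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    pvalue: float
    mean_a: float
    mean_b: float


def class_ttest(values_a, values_b) -> TTestResult:
    """Welch two-sample two-tailed t-test on per-chromosome fractions."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 chromosomes per class")
    if np.std(a) == 0 and np.std(b) == 0:
        if np.mean(a) == np.mean(b):
            # identical constant vectors: no evidence of difference
            return TTestResult(0.0, 1.0, float(np.mean(a)), float(np.mean(b)))
        raise ValueError("zero variance in both classes with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p), float(np.mean(a)), float(np.mean(b)))


def seq_feature_table(region_sets: dict, sequences, motif: str = "CCCTC"):
    """Per-chromosome GC and motif-presence fractions for named region classes.

    ``region_sets`` maps class name (hinge/exon/control/...) to a region
    iterable. Returns a tidy DataFrame with columns
    [chrom, region_class, n_regions, gc_fraction, motif_fraction].
    """
    out = []
    for cls, regions in region_sets.items():
        regions = list(regions)
        _, gc_chrom, _ = gc_content(regions, sequences)
        df_m, motif_chrom = motif_fraction(regions, sequences, motif)
        counts = df_m.groupby("chrom").size() if not df_m.empty else pd.Series(dtype=int)
        for chrom in counts.index:
            out.append(
                (chrom, cls, int(counts[chrom]),
                 float(gc_chrom.get(chrom, np.nan)),
                 float(motif_chrom.get(chrom, np.nan)))
            )
    return pd.DataFrame(
        out, columns=["chrom", "region_class", "n_regions",
                      "gc_fraction", "motif_fraction"]
    )
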