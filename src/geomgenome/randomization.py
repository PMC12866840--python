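"""The two null models of the packing-geometry analysis.

* exon-only randomization — keep the exon length multiset, throw each exon
  uniformly onto the chromosome without overlap; everything else becomes NE.
  Destroys the exon/NE coupling, so it should collapse power-law structure
  to a length-independent E/I around f/(1-f) for global exonic fraction f.
* pair permutation — uniformly permute the order of (exon, NE) pairs along
  the chromosome. Keeps every pair intact (length and content conserved
  exactly), so power-law structure should survive.

Both are bit-reproducible under a fixed seed; one seed governs one
randomization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import ChromosomeLayout, GenomicInterval
from .segmentation import ExonNEPair

__all__ = [
    "RandomizationReport",
    "randomize_exons",
    "permute_pairs",
    "null_ei_distribution",
]

#: placement retry cap per exon before it is dropped (outcome envelope from
#: the analysis: length within 5%, >= 95% exon content retained)
MAX_RETRIES = 1000


@dataclass
class RandomizationReport:
    mode: str  # "exon_only" | "pair_permutation"
    seed: int
    length_change: float  # fractional change in chromosome length
    exon_retained: float  # fraction of exonic bp surviving
    n_dropped: int
    layout: ChromosomeLayout

    def check(self) -> None:
        """Assert the mode's conservation envelope (run on every call)."""
        if self.mode == "pair_permutation":
            if self.length_change != 0.0 or self.exon_retained != 1.0:
                raise AssertionError("pair permutation must conserve exactly")
        else:
            if abs(self.length_change) > 0.05:
                raise AssertionError(
                    f"length changed by {self.length_change:.3f} (> 5%)")
            if self.exon_retained < 0.95:
                raise AssertionError(
                    f"only {self.exon_retained:.3f} of exon bp retained (< 95%)")


def randomize_exons(layout: ChromosomeLayout, seed: int) -> RandomizationReport:
    """Re-throw each exon uniformly onto the chromosome, lengths preserved.

    Sequential dart-throwing: each exon draws uniform start positions until
    it lands without overlapping an already placed exon (up to
    ``MAX_RETRIES``); unplaceable exons are dropped and counted. Exons are
    placed longest-first, which keeps the drop rate negligible at realistic
    (~10%) exonic fractions. Chromosome length is unchanged; the complement
    of the placed exons is NE.
    """
    lengths = np.sort(layout.exon_ends - layout.exon_starts)[::-1]
    if lengths.sum() > 0.95 * layout.length:
        raise ValueError("exon content exceeds 95% of chromosome; "
                         "uniform placement infeasible")
    rng = np.random.default_rng(seed)
    placed_s: list[int] = []
    placed_e: list[int] = []
    occupied_s = np.empty(0, dtype=np.int64)  # kept sorted
    occupied_e = np.empty(0, dtype=np.int64)
    n_dropped = 0
    for ln in lengths:
        ln = int(ln)
        ok = False
        for _ in range(MAX_RETRIES):
            s = int(rng.integers(0, layout.length - ln + 1))
            e = s + ln
            i = np.searchsorted(occupied_s, e, side="left")
            # overlap iff a placed exon starting before e ends after s
            if i > 0 and occupied_e[:i].max(initial=0) > s:
                continue
            ok = True
            break
        if not ok:
            n_dropped += 1
            continue
        j = int(np.searchsorted(occupied_s, s))
        occupied_s = np.insert(occupied_s, j, s)
        occupied_e = np.insert(occupied_e, j, e)
        placed_s.append(s)
        placed_e.append(e)
    new = ChromosomeLayout(
        chrom=layout.chrom,
        orientation=layout.orientation,
        length=layout.length,
        exon_starts=np.array(placed_s, dtype=np.int64),
        exon_ends=np.array(placed_e, dtype=np.int64),
    )
    retained = new.exon_bp / layout.exon_bp if layout.exon_bp else 1.0
    report = RandomizationReport(
        mode="exon_only",
        seed=seed,
        length_change=0.0,
        exon_retained=retained,
        n_dropped=n_dropped,
        layout=new,
    )
    report.check()
    return report


def permute_pairs(pairs: list[ExonNEPair], seed: int) -> list[ExonNEPair]:
    """Uniform random permutation of the (exon_len, ne_len) pair order.

    The pair multiset — and therefore chromosome length, total exon bp and
    per-pair hinge status — is exactly preserved; only the order changes.
    Re-indexed pairs keep their new reading-order coordinates implicit (the
    length table is what downstream segmentation consumes).
    """
    if not pairs:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    chrom = pairs[0].exon_iv.chrom
    strand = pairs[0].exon_iv.strand
    out: list[ExonNEPair] = []
    pos = 0
    for new_idx, old_idx in enumerate(order):
        src = pairs[old_idx]
        exon_iv = GenomicInterval(chrom, pos, pos + src.exon_len, strand)
        ne_iv = (
            GenomicInterval(chrom, pos + src.exon_len,
                            pos + src.exon_len + src.ne_len, strand)
            if src.ne_len > 0
            else None
        )
        out.append(ExonNEPair(new_idx, src.exon_len, src.ne_len, exon_iv, ne_iv))
        pos += src.total_len
    return out


def permuted_layout(pairs: list[ExonNEPair], chrom: str, orientation: str,
                    length: int) -> ChromosomeLayout:
    """Materialize permuted pairs back into a layout (coordinates left-packed)."""
    starts = np.array([p.exon_iv.start for p in pairs], dtype=np.int64)
    ends = np.array([p.exon_iv.end for p in pairs], dtype=np.int64)
    return ChromosomeLayout(chrom=chrom, orientation=orientation, length=length,
                            exon_starts=starts, exon_ends=ends)


def exon_bp_in_windows(layout: ChromosomeLayout, starts, ends):
    """Exonic bp of a layout falling inside each [start, end) window."""
    ex_s, ex_e = layout.exon_starts, layout.exon_ends
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if ex_s.size == 0:
        return np.zeros(starts.shape, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(ex_e - ex_s)])

    def covered_before(x):
        # exons are disjoint+sorted, so only exon i-1 can straddle x
        i = np.searchsorted(ex_s, x, side="left")
        prev = np.maximum(i - 1, 0)
        partial = np.minimum(ex_e[prev], x) - ex_s[prev]
        return cum[prev] + np.where(i > 0, np.maximum(partial, 0), 0)

    return covered_before(ends) - covered_before(starts)


def null_ei_distribution(layout: ChromosomeLayout, seed: int, gene_windows):
    """Per-window E/I after exon-only randomization.

    ``gene_windows`` are the original gene spans as (start, end) pairs; E is
    the randomized exonic bp falling in each window, I the remainder.
    Windows with I = 0 are excluded and counted. Returns a dict with the
    per-window ratios, their median, the fitted length exponent n_hat of
    E/I ~ p / L^n over the windows, and the randomization report.
    """
    from .scaling import EIRatioModel

    report = randomize_exons(layout, seed)
    new = report.layout
    starts = np.asarray([w[0] for w in gene_windows], dtype=np.int64)
    ends = np.asarray([w[1] for w in gene_windows], dtype=np.int64)
    e_bp = exon_bp_in_windows(new, starts, ends)
    lengths = ends - starts
    i_bp = lengths - e_bp
    ok = i_bp > 0
    ratios = e_bp[ok] / i_bp[ok]
    fit = None
    if (e_bp[ok] > 0).sum() >= 3:
        from .scaling import FitError

        try:
            fit = EIRatioModel(e_bp[ok], i_bp[ok], lengths[ok]).fit()
        except FitError:
            pass
    return {
        "ratios": ratios,
        "median": float(np.median(ratios)) if ratios.size else float("nan"),
        "n_hat": fit.n_hat if fit is not None else float("nan"),
        "n_excluded": int((~ok).sum()),
        "report": report,
    }
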