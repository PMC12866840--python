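# Methods

## The model

Chromatin at the nanoscale organizes into packing domains: structures with a
dense core and a radially decaying density, characterized by a mass-fractal
dimension `D` (genomic content grows with radius as `N(r) ~ r^D`, with
`2 <= D <= 3` observed), a packing efficiency `A_D`, and an
intermediate-density shell (the ideal or "Goldilocks" zone) where
transcription is most efficient. The hypothesis implemented here is that the
linear arrangement of exons and non-exonic (NE) DNA — introns plus
intergenic segments — is a projection of this 3-D architecture: NE DNA
generates domain volume, exons fill the ideal-zone shell with a fractional
dimension `beta` (`0` = no shell geometry, `1` = hard shell).

The closed-form consequences, all implemented in `geomgenome.fractal`:

* volume fraction `phi(r) = phi0 (rc/r)^(3-D)`;
* domain content `N(r) = Nc A_D (r/rc)^D`;
* shell content, hard (`D Nc A_D (r/rc)^(D-1) (dR/rc)`) and fractional
  (`(D/beta) Nc A_D (r/rc)^(D-beta) (dR/rc)^beta`), the latter reducing to
  the former at `beta = 1`;
* Goldilocks radius `Rgl/rc = (L/(Nc A_D))^(1/D)`;
* exon content `E = Y L^C` with `C = (D-beta)/D`;
* the scaling exponents `gamma = 1 + D/(D-beta) = 1 + 1/C` coupling intron
  content to exon content (`I ~ E^gamma / p`) and the inverse-length law
  `E/I ~ p / L^n` with depth scalar `p` in bp;
* the imaging conversion `GenomicSize = A (R/2 nm)^D x 15 bp` and the
  beads-on-a-string compaction arithmetic (200 bp/nucleosome; 11 nm
  diameter, 5.5 nm height).

Two documented ambiguities in the source derivation:

* The chain limit. The narrative states `beta = 0` gives `gamma = 1`,
  while the closed form gives `gamma -> 2` as `beta -> 0`. We implement the
  closed form (`gamma_from(D, 0) == 2` for every `D`) and treat `beta = 0`
  as the chain regime where the power-law model does not apply; the
  fractional shell content is a domain error there (its prefactor diverges).
* The ideal-zone prefactor is printed once as `D k (...)` and once with a
  `1/beta` carried through the fractional derivative. The default
  implements `D k` with `k` documented as absorbing the `1/beta`; a
  `strict_prefactor` flag exposes the `(D/beta) k` reading. The
  extended-domain case (`E = k (D/3) D phi_gl^(beta/3) (dR/rc)^beta
  L^(1-beta/3)`) requires `phi_gl` as an explicit input; only its
  prefactor-free `beta -> 0` limit is asserted in tests.
* The printed bound `C in [2/3, 1]` is exact only for `beta <= D/3` (it is
  derived at `D = 3`); over the full domain the lower bound is `1/2`,
  reached at `(D=2, beta=1)` — the `gamma = 3` limit.

## Segmentation

A chromosome layout is the strand-oriented projection of all exons
(duplicates collapsed; exons that partially overlap another exon with
different boundaries — multi-start/multi-stop events — omitted and
counted). The layout is scanned as (exon, adjacent NE) pairs in reading
orientation; chromosome-end NE with no exon in reading direction is folded
onto the nearest pair so that pair totals always conserve chromosome length
exactly. Pairs with total length at most 300 bp (inclusive; 1-2
nucleosomes) are hinges; maximal runs of non-hinge pairs are power-law
segments. Hinges are excluded from flanking segments by default (they are
inter-domain spacers); a `hinge_keep="left"` flag reproduces list-split
semantics that keep the delimiter in the segment it closes.

## Fitting

All scaling fits are ordinary least squares on `(log10 x, log10 y)`,
unweighted; exponent = slope, prefactor = `10^intercept`. R^2 is reported in
log10 residual space for quantities spanning decades (E/I ratios) and in
Cartesian space against the back-transformed curve for NE-vs-exon scatter,
matching the two conventions of the source analysis. Nonpositive values are
excluded and counted. The headline chromosome R^2 was computed against an
unspecified single curve; the package reports the free-fit R^2 and,
separately, R^2 against any user-supplied fixed `(exponent, prefactor)`
(`r_squared_against`), choosing neither silently. Exponents are ensemble
quantities: one `(gamma, p)` per data set, never per gene.

`compare_to_null` fits the observed set, computes log10 residuals of both
sets against that single curve, and applies a Welch t-test; it also reports
both free-fit R^2 values. Per-chromosome class contrasts (GC, motif, peak
overlap) use Welch's unequal-variance two-tailed t-test with chromosomes as
units; the source states only "t-test", and Welch is the conservative
default.

## Null models

* Exon-only randomization re-throws each exon uniformly (sequential dart
  throwing, 1000 retries, longest-first, drops counted); chromosome length
  is unchanged and every run asserts the stated envelope (length within 5%,
  >= 95% exon bp retained). For a genome with global exonic fraction `f`,
  the per-window E/I after randomization concentrates around `f/(1-f)`
  provided windows contain many exon pieces (see below).
* Pair permutation uniformly permutes the order of (exon, NE) pairs;
  length, exon content and per-pair hinge status are conserved exactly.

## The synthetic world

`generate_genome` emits gene models whose NE budget follows the chosen
architecture: `power_law` (`I = E^gamma/p x 10^N(0, sigma)`; defaults
`gamma = 2.3`, `p = 5000` bp, `sigma = 0.1` — the most frequently observed
ensemble values), `linear` (`I = cE`), or `random_null` (uniform exon
placement). Design choices, fixed once:

* Exon totals are log-uniform on [300, 300000] bp — roughly the three-decade
  spread of real exonic totals. The spread matters: the claim that pair
  permutation preserves the fitted exponent requires the pair-level
  (exon, NE) sizes to be coupled across a wide range, so that re-segmented
  sums remain dominated by their largest pair.
* A gene's NE budget covers introns plus its trailing intergenic gap:
  introns and intergenic segments are one volumetric pool in the model, and
  this makes segment NE equal the budget exactly, so segmentation + fit
  recovers `(gamma, p)` without bias.
* Exon count is uniform on {2..5} with near-even exon splits (pair size
  tracks gene size, preserving pair-level coupling); intron shares are
  symmetric Dirichlet(1) with a 301-bp floor, and the trailing gap keeps
  >= 301 bp whenever any intron exists, so the planted hinges are provably
  the only hinges. An `"auto"` exon-count mode (`k ~ E/300`, fixed piece
  size) exists for dense-genome window analyses. Single-exon genes whose
  whole pair is <= 300 bp are themselves hinges — short genes with no NE
  are exactly what the hinge concept describes.
* Planted hinges (exon and NE each uniform on [50, 150] bp) sit between
  consecutive genes; `hinge_rate = 0.6` of all pairs by default, a short
  hinge train per boundary. Hinge density is not constrained by the source;
  this is the regime where domains are single-gene-scale and permuted
  genomes re-segment into short runs.
* An `exonic_fraction` target is optional and reached by appending spacer NE
  to trailing gaps. Spacers can only add NE, so the target must lie below
  the architecture's natural exonic fraction — with the wide default exon
  range a 9.8% target is infeasible and the generator raises. The dense
  stated world used for window-based null analyses is therefore exon totals
  log-uniform [1000, 6000] with `"auto"` exon counts: there the natural
  NE/exon ratio is ~8.3 < 9.2 = (1-f)/f, and gene windows hold enough exon
  pieces for the `f/(1-f)` median oracle to be valid (the estimator is
  biased low when windows hold only a few large pieces, a Jensen-type
  effect documented by the tests).

Sequence, peak and loop generators plant the observed contrasts (hinge GC
0.53 vs 0.41 background; CTCF-core motif CCCTC in 37% of hinges vs 22% of
exons; class-specific peak intensities; strong loops on segment spans with
frequency > 20, transient loops < 5). What a green test establishes is that
the estimators detect what was planted at the stated effect sizes and
sample counts — not that real genomes carry these effects; real-genome
features (isochores, repeats, overlapping genes on one strand, peak-caller
artifacts) are deliberately absent.

## What the randomization contrast does and does not show

Permuting intact pairs of the default synthetic genome preserves the fitted
exponent to within ~0.08 and exon-only randomization collapses the
exon/NE coupling (log10 R^2 of the gene-window scatter drops by ~0.45, and
no exon+NE pair of the randomized genome is short enough to be a hinge, so
no power-law segmentation survives at all). Note the two statistics live on
different supports: after exon-only randomization of an NE-dominated
genome, re-segmentation is degenerate (a single segment), so the collapse
is measured on the original gene windows; the flat window E/I slope
(|n| <= 0.05) is measured in the dense 9.8%-exonic world where windowed
E/I is well defined.

## Numerical and degenerate-input policy

Internal coordinates are 0-based half-open everywhere; GTF is converted at
the boundary. Fits require >= 3 usable points and raise on zero spread in
x. Welch tests on two identical constant vectors return p = 1; unequal
constants raise. Region GC excludes ambiguous bases from the denominator
and drops all-N regions with a count. Peak-to-peak distances use peak
midpoints. Random controls may overlap each other and the query features.
All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; there is no wall-clock seeding, and rerunning
any pipeline config is byte-identical.

## Known limitations

* Fitting `D` to tomograms is out of scope; `D`, `A`, `R` are inputs.
* No GC- or chromatin-state-matched nulls; no PWM motif scoring (literal
  5-mer only); no peak calling or coverage-track generation.
* The imaging-content comparison (Mann-Whitney utility) is provided, but
  the published tomography content distributions are not, so that
  comparison cannot be reproduced desk-side.
* Per-gene realized `(gamma, p)` are undefined by construction; only
  ensembles are fitted.
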