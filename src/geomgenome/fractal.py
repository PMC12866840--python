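"""Closed-form mass-fractal packing-domain model.

A packing domain is a nanoscopic chromatin structure whose genomic content
scales with radius as N(r) ~ r^D (mass fractal, 2 <= D <= 3), with a dense
core and a radially decaying volume fraction. Transcription is most
efficient in an intermediate-density shell (the ideal or "Goldilocks" zone);
exonic DNA is modelled as filling that shell with fractional dimension beta
(0 = no shell geometry, 1 = hard shell). The linear-genome consequences are
the scaling exponents

    gamma = 1 + D / (D - beta)      (intron ~ exon^gamma coupling)
    C     = (D - beta) / D          (exon ~ length^C),  gamma = 1 + 1/C

plus the beads-on-a-string compaction arithmetic used for worked examples.

Radii are in nm, contents in bp throughout; no unit inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "FractalParams",
    "ChainEstimate",
    "gamma_from",
    "C_from",
    "beta_from",
    "volume_fraction",
    "mass_in_radius",
    "shell_content",
    "goldilocks_radius",
    "exon_content",
    "chromstem_genomic_size",
    "chain_estimate",
    "compression_factor",
]

#: defaults for the nucleosome arithmetic (overridable everywhere)
BP_PER_NUCLEOSOME = 200
NUCLEOSOME_DIAMETER_NM = 11.0
NUCLEOSOME_HEIGHT_NM = 5.5
BP_PER_2NM_VOXEL = 15.0


def _check_domain(D: float, beta: float) -> None:
    if not 2.0 <= D <= 3.0:
        raise ValueError(f"fractal dimension D={D} outside [2, 3]")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"shell dimension beta={beta} outside [0, 1]")
    if D <= beta:
        raise ValueError(f"require D > beta (got D={D}, beta={beta})")


def gamma_from(D: float, beta: float) -> float:
    """Intron-exon scaling exponent gamma = 1 + D/(D - beta).

    At beta = 0 this evaluates to 2 for any D; beta = 0 is the chain
    (beads-on-a-string) regime where the power-law model itself no longer
    applies, so that value is a formal limit, not a physical prediction.
    """
    _check_domain(D, beta)
    return 1.0 + D / (D - beta)


def C_from(D: float, beta: float) -> float:
    """Exon-length exponent C = (D - beta)/D, bounded in [2/3, 1]."""
    _check_domain(D, beta)
    return (D - beta) / D


def beta_from(D: float, gamma: float) -> float:
    """Invert gamma = 1 + D/(D - beta) for beta (diagnostic convenience)."""
    if gamma <= 1:
        raise ValueError("gamma must exceed 1")
    beta = D * (1.0 - 1.0 / (gamma - 1.0))
    _check_domain(D, max(beta, 0.0) if beta > -1e-12 else beta)
    return beta


@dataclass
class FractalParams:
    """Parameter bundle tying the model symbols together.

    Parameters
    ----------
    D : float
        Mass-fractal dimension of the domain (2..3).
    beta : float
        Fractional dimension of exon filling on the ideal-zone shell (0..1).
    Nc : float
        Chain content in bp (content within the chain radius ``rc``).
    A_D : float
        Packing efficiency, (0, 1]; 1 = maximally efficient filling.
    rc : float
        Chain radius, nm.
    phi0 : float
        Chromatin volume fraction at the domain centre.
    dR : float
        Ideal-zone shell thickness, nm.
    k : float
        Fraction of ideal-zone bp that are exonic.
    p : float, optional
        Depth scalar in bp of the E/I ~ p/L^n relation.
    phi_gl, phi_e : float, optional
        Volume fractions at the Goldilocks and outer radius (extended mode).

    Derived ``gamma`` and ``C`` always satisfy gamma = 1 + 1/C.
    """

    D: float = 2.8
    beta: float = 0.7
    Nc: float = 1000.0
    A_D: float = 1.0
    rc: float = 10.0
    phi0: float = 0.6
    dR: float = 10.0
    k: float = 1.0
    p: Optional[float] = None
    phi_gl: Optional[float] = None
    phi_e: Optional[float] = None

    def __post_init__(self):
        _check_domain(self.D, self.beta)
        if not 0 < self.A_D <= 1:
            raise ValueError("packing efficiency A_D must be in (0, 1]")

    @property
    def gamma(self) -> float:
        return gamma_from(self.D, self.beta)

    @property
    def C(self) -> float:
        return C_from(self.D, self.beta)


def volume_fraction(r, params: FractalParams):
    """Chromatin volume fraction phi(r) = phi0 * (rc/r)^(3-D).

    Monotone non-increasing in r for D < 3 and uniform at D = 3. r = 0 is a
    domain error: the centre value is phi0 by definition, not by formula.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0 (centre value is phi0 by definition)")
    return params.phi0 * (params.rc / r) ** (3.0 - params.D)


def mass_in_radius(r, params: FractalParams):
    """Domain content N(r) = Nc * A_D * (r/rc)^D in bp."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    return params.Nc * params.A_D * (r / params.rc) ** params.D


def shell_content(r, params: FractalParams, mode: str = "fractional"):
    """Ideal-zone shell content Ns(r) in bp.

    ``hard``       : D * Nc * A_D * (r/rc)^(D-1) * (dR/rc)   — hard shell.
    ``fractional`` : (D/beta) * Nc * A_D * (r/rc)^(D-beta) * (dR/rc)^beta
                     — fractional derivative of N(r), capturing a chain that
                     wanders in and out of the shell. Reduces to ``hard`` at
                     beta = 1; diverges as beta -> 0 (domain error).
    """
    r = np.asarray(r, dtype=float)
    D, Nc, A_D, rc, dR = params.D, params.Nc, params.A_D, params.rc, params.dR
    if mode == "hard":
        return D * Nc * A_D * (r / rc) ** (D - 1.0) * (dR / rc)
    if mode == "fractional":
        if params.beta <= 0:
            raise ValueError("fractional shell undefined at beta = 0 "
                             "(prefactor diverges; chain regime)")
        b = params.beta
        return (D / b) * Nc * A_D * (r / rc) ** (D - b) * (dR / rc) ** b
    raise ValueError(f"unknown mode {mode!r}")


def goldilocks_radius(L, params: FractalParams):
    """Reduced Goldilocks radius Rgl/rc = (L / (Nc * A_D))^(1/D)."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("L must be > 0")
    return (L / (params.Nc * params.A_D)) ** (1.0 / params.D)


def exon_content(L, params: FractalParams, mode: str = "ideal",
                 strict_prefactor: bool = False):
    """Exonic content E(L) of a segment of length L bp.

    ``ideal`` mode evaluates E = Y * L^C with
    Y = D * k * (Nc * A_D)^(beta/D) * delta_gl, delta_gl = (dR_gl/rc)^beta,
    the domain-limited-by-its-ideal-zone case. The prefactor is written with
    ``D*k`` as printed; ``strict_prefactor=True`` exposes the (D/beta)*k
    variant carried through the fractional derivative (the two published
    prefactors differ; k absorbs 1/beta in the default reading).

    ``extended`` mode is the domain-extends-past-its-ideal-zone case
    E = k*(D/3)*D * phi_gl^(beta/3) * (dR/rc)^beta * L^(1 - beta/3),
    requiring ``params.phi_gl``. In either mode beta -> 0 gives E
    proportional to L (the chain limit).
    """
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("L must be > 0")
    D, b, k = params.D, params.beta, params.k
    dgl = (params.dR / params.rc) ** b
    if mode == "ideal":
        pref = (D / b) * k if strict_prefactor else D * k
        if strict_prefactor and b == 0:
            raise ValueError("strict prefactor diverges at beta = 0")
        Y = pref * (params.Nc * params.A_D) ** (b / D) * dgl
        return Y * L ** C_from(D, b)
    if mode == "extended":
        if params.phi_gl is None:
            raise ValueError("extended mode requires phi_gl")
        pref = k * (D / 3.0) * D * params.phi_gl ** (b / 3.0) * dgl
        return pref * L ** (1.0 - b / 3.0)
    raise ValueError(f"unknown mode {mode!r}")


def chromstem_genomic_size(A: float, R_domain_nm: float, D: float) -> float:
    """Genomic content of an imaged domain: A * (R/2 nm)^D * 15 bp.

    15 bp is the crystalline-DNA content of the brightest possible 2-nm
    voxel; A is the packing efficiency of the mass-correlation fit
    M(r) = A * (R/Rmin)^D.
    """
    if not 0 < A <= 1:
        raise ValueError("A must be in (0, 1]")
    if R_domain_nm < 2:
        raise ValueError("R_domain must be >= 2 nm")
    if not 2 <= D <= 3:
        raise ValueError("D must be in [2, 3]")
    return A * (R_domain_nm / 2.0) ** D * BP_PER_2NM_VOXEL


@dataclass(frozen=True)
class ChainEstimate:
    """Beads-on-a-string chain arithmetic for one gene."""

    bp: int
    bp_per_nucleosome: int
    extent_per_nucleosome_nm: float
    n_nucleosomes: int
    chain_length_nm: float


def chain_estimate(
    bp: int,
    bp_per_nucleosome: int = BP_PER_NUCLEOSOME,
    extent_nm: float = NUCLEOSOME_HEIGHT_NM,
) -> ChainEstimate:
    """Fully stretched beads-on-a-string extent of a gene of ``bp`` basepairs.

    ``extent_nm`` is the per-nucleosome extent: 11 nm stacking by diameter,
    5.5 nm stacking end-to-end by height.
    """
    if bp <= 0 or bp_per_nucleosome <= 0 or extent_nm <= 0:
        raise ValueError("all chain-estimate inputs must be positive")
    n = int(round(bp / bp_per_nucleosome))
    return ChainEstimate(bp, bp_per_nucleosome, extent_nm, n, n * extent_nm)


def compression_factor(chain_length_nm: float, observed_extent_nm: float) -> float:
    """Fold-compression between the stretched chain and the observed extent."""
    if observed_extent_nm <= 0:
        raise ValueError("observed extent must be > 0")
    return chain_length_nm / observed_extent_nm
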