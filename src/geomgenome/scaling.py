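"""Power-law scaling fits in the statsmodels Model/Results idiom.

Two model classes cover the scaling laws of the packing-domain framework:

* :class:`PowerLawModel` — y = a * x^b by ordinary least squares on
  (log10 x, log10 y); fits intron-vs-exon (gamma, p) and NE-vs-exon scaling
  of segments or loops. R^2 is reported either in log10 residual space (the
  convention for quantities spanning decades) or in Cartesian space against
  the back-transformed curve.
* :class:`EIRatioModel` — E/I = p / L^n on gene metrics, with an optional
  fixed-n mode (n = 1) estimating the depth scalar p alone as the geometric
  mean of (E/I) * L.

Nonpositive x or y are excluded before fitting and the exclusion count is
carried on the Results object. Exponents here are ensemble quantities: one
(gamma, p) per data set, never per gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FitResult",
    "PowerLawModel",
    "PowerLawResults",
    "EIRatioModel",
    "EIRatioResults",
    "fit_power_law",
    "fit_ei_vs_length",
    "classify_geometry",
    "compare_to_null",
]


class FitError(ValueError):
    """Raised when fewer than 3 usable points remain."""


def _clean_positive(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
    return x[ok], y[ok], int((~ok).sum())


def _r_squared(y_obs, y_hat):
    ss_res = float(np.sum((y_obs - y_hat) ** 2))
    ss_tot = float(np.sum((y_obs - np.mean(y_obs)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class FitResult:
    """Minimal fit record: exponent, prefactor, R^2 and its residual space."""

    exponent: float
    prefactor: float
    r_squared: float
    residual_space: str
    n_points: int
    n_excluded: int = 0


class PowerLawModel:
    """y = prefactor * x^exponent, estimated on log10-log10 axes.

    Parameters
    ----------
    x, y : array-like
        Positive values; nonpositive entries are dropped (counted on the
        results).
    residual_space : {"log10", "cartesian"}
        Space in which R^2 (and the residuals exposed by the results) are
        computed. The line is always fitted in log10 space.
    """

    def __init__(self, x, y, residual_space: str = "log10"):
        if residual_space not in ("log10", "cartesian"):
            raise ValueError("residual_space must be 'log10' or 'cartesian'")
        self.x, self.y, self.n_excluded = _clean_positive(x, y)
        if self.x.size < 3:
            raise FitError(f"need >= 3 usable points, have {self.x.size}")
        if np.ptp(self.x) == 0:
            raise FitError("x has no spread; exponent unidentifiable")
        self.residual_space = residual_space

    @classmethod
    def from_segments(cls, segments, residual_space: str = "cartesian"):
        """NE_bp vs exon_bp over power-law segments (chromosome-level law)."""
        from .segmentation import PowerLawSegment  # noqa: F401  (typing aid)

        x = [s.exon_bp for s in segments]
        y = [s.ne_bp for s in segments]
        return cls(x, y, residual_space)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str, y: str,
                       residual_space: str = "log10"):
        return cls(df[x].to_numpy(), df[y].to_numpy(), residual_space)

    def fit(self) -> "PowerLawResults":
        lx, ly = np.log10(self.x), np.log10(self.y)
        ols = sm.OLS(ly, sm.add_constant(lx)).fit()
        return PowerLawResults(self, ols)


class PowerLawResults:
    """Estimates, uncertainties and diagnostics of a power-law fit."""

    def __init__(self, model: PowerLawModel, ols):
        self.model = model
        self._ols = ols
        self.exponent = float(ols.params[1])
        self.prefactor = float(10.0 ** ols.params[0])
        #: delta-method standard errors (prefactor on its own scale)
        self.exponent_se = float(ols.bse[1])
        self.prefactor_se = float(
            self.prefactor * np.log(10.0) * ols.bse[0]
        )
        self.nobs = int(model.x.size)
        self.n_excluded = model.n_excluded
        self.residual_space = model.residual_space

    @property
    def log10_residuals(self):
        lx = np.log10(self.model.x)
        return np.log10(self.model.y) - (
            np.log10(self.prefactor) + self.exponent * lx
        )

    @property
    def cartesian_residuals(self):
        return self.model.y - self.predict(self.model.x)

    @property
    def r_squared(self) -> float:
        if self.residual_space == "log10":
            return _r_squared(np.log10(self.model.y),
                              np.log10(self.predict(self.model.x)))
        return _r_squared(self.model.y, self.predict(self.model.x))

    def r_squared_in(self, space: str) -> float:
        if space == "log10":
            return _r_squared(np.log10(self.model.y),
                              np.log10(self.predict(self.model.x)))
        if space == "cartesian":
            return _r_squared(self.model.y, self.predict(self.model.x))
        raise ValueError(space)

    def r_squared_against(self, exponent: float, prefactor: float,
                          space: str = "log10") -> float:
        """R^2 of the data against a user-supplied fixed curve."""
        y_hat = prefactor * self.model.x ** exponent
        if space == "log10":
            return _r_squared(np.log10(self.model.y), np.log10(y_hat))
        return _r_squared(self.model.y, y_hat)

    def predict(self, x):
        return self.prefactor * np.asarray(x, dtype=float) ** self.exponent

    def as_fit_result(self) -> FitResult:
        return FitResult(self.exponent, self.prefactor, self.r_squared,
                         self.residual_space, self.nobs, self.n_excluded)

    def summary(self) -> str:
        lines = [
            "Power-law fit: y = a * x^b  (OLS in log10 space)",
            "-" * 52,
            f"exponent b   {self.exponent:12.4f}  (se {self.exponent_se:.4f})",
            f"prefactor a  {self.prefactor:12.6g}  (se {self.prefactor_se:.3g})",
            f"R^2 ({self.residual_space:9s}) {self.r_squared:10.4f}",
            f"n = {self.nobs}   excluded (nonpositive) = {self.n_excluded}",
        ]
        return "\n".join(lines)

    def __repr__(self):
        return (f"<PowerLawResults exponent={self.exponent:.3f} "
                f"prefactor={self.prefactor:.4g} R2={self.r_squared:.3f}>")


def fit_power_law(x, y, residual_space: str = "log10") -> PowerLawResults:
    """Functional wrapper: ``PowerLawModel(x, y, residual_space).fit()``."""
    return PowerLawModel(x, y, residual_space).fit()


class EIRatioModel:
    """E/I = p / L^n on per-gene (or per-window) metrics.

    ``fixed_n=True`` pins n = 1 and estimates p alone as the geometric mean
    of (E/I) * L; otherwise both n and p come from OLS in log10 space.
    Genes with I = 0 or E = 0 are excluded and counted.
    """

    def __init__(self, exon_bp, intron_bp, length, fixed_n: bool = False):
        e = np.asarray(exon_bp, dtype=float)
        i = np.asarray(intron_bp, dtype=float)
        L = np.asarray(length, dtype=float)
        ok = (e > 0) & (i > 0) & (L > 0)
        self.n_excluded = int((~ok).sum())
        self.ratio = e[ok] / i[ok]
        self.length = L[ok]
        self.fixed_n = fixed_n
        if self.ratio.size < 3:
            raise FitError(f"need >= 3 usable genes, have {self.ratio.size}")
        if not fixed_n and np.ptp(self.length) == 0:
            raise FitError("window lengths have no spread; n unidentifiable")

    @classmethod
    def from_metrics(cls, metrics: pd.DataFrame, fixed_n: bool = False):
        """From a :func:`geomgenome.annotation.metrics_frame` table."""
        return cls(metrics["exon_bp"], metrics["intron_bp"], metrics["length"],
                   fixed_n)

    def fit(self) -> "EIRatioResults":
        if self.fixed_n:
            n_hat, n_se = 1.0, 0.0
            logp = np.log10(self.ratio * self.length)
            p_hat = float(10.0 ** np.mean(logp))
            p_se = float(p_hat * np.log(10) * np.std(logp, ddof=1)
                         / np.sqrt(logp.size))
            # R^2 of log10 ratio against the fixed-n curve
            r2 = _r_squared(np.log10(self.ratio),
                            np.log10(p_hat / self.length))
            return EIRatioResults(self, n_hat, p_hat, n_se, p_se, r2)
        lx = np.log10(self.length)
        ly = np.log10(self.ratio)
        ols = sm.OLS(ly, sm.add_constant(lx)).fit()
        n_hat = float(-ols.params[1])
        p_hat = float(10.0 ** ols.params[0])
        r2 = _r_squared(ly, ols.fittedvalues)
        return EIRatioResults(self, n_hat, p_hat, float(ols.bse[1]),
                              float(p_hat * np.log(10) * ols.bse[0]), r2)


class EIRatioResults:
    """Fitted depth scalar p and length exponent n of E/I = p / L^n."""

    def __init__(self, model, n_hat, p_hat, n_se, p_se, r_squared):
        self.model = model
        self.n_hat = n_hat
        self.p_hat = p_hat
        self.n_se = n_se
        self.p_se = p_se
        self.r_squared = r_squared
        self.nobs = int(model.ratio.size)
        self.n_excluded = model.n_excluded

    def predict(self, length):
        return self.p_hat / np.asarray(length, dtype=float) ** self.n_hat

    def summary(self) -> str:
        mode = "fixed n = 1" if self.model.fixed_n else "free n"
        return "\n".join([
            f"E/I = p / L^n   ({mode}; OLS in log10 space)",
            "-" * 52,
            f"n   {self.n_hat:12.4f}  (se {self.n_se:.4f})",
            f"p   {self.p_hat:12.4g} bp  (se {self.p_se:.3g})",
            f"R^2 (log10) {self.r_squared:10.4f}",
            f"n genes = {self.nobs}   excluded = {self.n_excluded}",
        ])

    def __repr__(self):
        return (f"<EIRatioResults n={self.n_hat:.3f} p={self.p_hat:.4g} "
                f"R2={self.r_squared:.3f}>")


def fit_ei_vs_length(metrics: pd.DataFrame, fixed_n: bool = False) -> EIRatioResults:
    """Functional wrapper over :class:`EIRatioModel`."""
    return EIRatioModel.from_metrics(metrics, fixed_n=fixed_n).fit()


def classify_geometry(exon_bp, intron_bp):
    """Label records linear (E/I > 1) or power_law (E/I <= 1).

    Linear geometry means the record is mostly exon — a beads-on-a-string
    chain rather than a volume-generating assembly.

    Returns (labels array, {"linear": count, "power_law": count}).
    """
    e = np.asarray(exon_bp, dtype=float)
    i = np.asarray(intron_bp, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        linear = np.where(i == 0, True, e / np.where(i == 0, 1, i) > 1)
    labels = np.where(linear, "linear", "power_law")
    return labels, {
        "linear": int(np.sum(linear)),
        "power_law": int(np.sum(~linear)),
    }


@dataclass(frozen=True)
class NullComparison:
    """Two-sample comparison of log10 residuals against the observed model."""

    statistic: float
    pvalue: float
    r_squared_obs: float
    r_squared_null: float
    degenerate: bool = False


def compare_to_null(x_obs, y_obs, x_null, y_null,
                    residual_space: str = "log10") -> NullComparison:
    """Test whether null data scatter differently around the observed fit.

    The power law is fitted to the observed set; log10 residuals of both
    sets against that single fitted curve are compared with a two-sample
    Welch t-test. Both free-fit R^2 values (each set fitted on its own, in
    ``residual_space``) are reported alongside.
    """
    res_obs = fit_power_law(x_obs, y_obs, residual_space)
    res_null_fit = fit_power_law(x_null, y_null, residual_space)

    def _log_resid(x, y, ref):
        x, y, _ = _clean_positive(x, y)
        return np.log10(y) - np.log10(ref.predict(x))

    r_obs = _log_resid(x_obs, y_obs, res_obs)
    r_null = _log_resid(x_null, y_null, res_obs)
    if np.std(r_obs) == 0 and np.std(r_null) == 0:
        return NullComparison(np.nan, np.nan, res_obs.r_squared,
                              res_null_fit.r_squared, degenerate=True)
    t, p = stats.ttest_ind(r_obs, r_null, equal_var=False)
    return NullComparison(float(t), float(p), res_obs.r_squared,
                          res_null_fit.r_squared)
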