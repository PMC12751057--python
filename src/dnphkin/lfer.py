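"""Bronsted linear free energy analysis and spectrophotometric calibrations.

The Bronsted slope beta_LG of log10(kcat/KM) against leaving-group pKa
diagnoses charge development at the transition state: a slope near -1
indicates near-complete negative charge accumulation on the departing
nucleobase.  The module also fits single-pKa absorbance titrations and
Beer-Lambert extinction-coefficient standard curves, the calibrations that
feed the Bronsted dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .eqfits import FitResult, fit_equation

__all__ = [
    "BronstedEntry",
    "BronstedDataset",
    "bronsted_fit",
    "pka_from_titration",
    "extinction_from_standard_curve",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class BronstedEntry:
    label: str
    pka: float
    kcat_over_km: float  # M^-1 s^-1
    stderr: float | None = None  # on kcat_over_km, same units

    def __post_init__(self) -> None:
        if not math.isfinite(self.pka):
            raise ValueError("pKa must be finite")
        if self.kcat_over_km <= 0:
            raise ValueError("kcat/KM must be > 0")
        if self.stderr is not None and self.stderr < 0:
            raise ValueError("stderr must be >= 0")


@dataclass(frozen=True)
class BronstedDataset:
    entries: tuple[BronstedEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 3:
            raise ValueError("Bronsted slope fitting needs at least 3 entries")

    @property
    def pka(self) -> np.ndarray:
        return np.array([e.pka for e in self.entries])

    @property
    def log_kcat_over_km(self) -> np.ndarray:
        return np.log10([e.kcat_over_km for e in self.entries])

    @property
    def log_stderr(self) -> np.ndarray | None:
        """Fitting errors propagated to the log10 scale; None when any absent."""
        if any(e.stderr is None or e.stderr == 0 for e in self.entries):
            return None
        return np.array([e.stderr / (e.kcat_over_km * _LN10) for e in self.entries])


def bronsted_fit(data: BronstedDataset) -> FitResult:
    """Weighted linear fit of log10(kcat/KM) against leaving-group pKa.

    Weights are 1/sigma_log^2 when every entry carries a fitting error,
    otherwise uniform.  Returns beta_lg (slope) and log_c (intercept).
    """
    x = data.pka
    y = data.log_kcat_over_km
    sig = data.log_stderr
    w = 1.0 / sig**2 if sig is not None else np.ones_like(y)
    design = np.column_stack([x, np.ones_like(x)])
    wd = design * w[:, None]
    normal = design.T @ wd
    beta = np.linalg.solve(normal, wd.T @ y)
    resid = y - design @ beta
    ssr = float(np.sum(w * resid**2))
    dof = y.size - 2
    s2 = ssr / dof if dof > 0 else float("nan")
    cov = s2 * np.linalg.inv(normal)
    return FitResult(
        model_id="bronsted",
        estimates={"beta_lg": float(beta[0]), "log_c": float(beta[1])},
        standard_errors={
            "beta_lg": float(np.sqrt(cov[0, 0])) if dof > 0 else float("nan"),
            "log_c": float(np.sqrt(cov[1, 1])) if dof > 0 else float("nan"),
        },
        ssr=ssr,
        n_points=int(y.size),
        converged=True,
        residuals=resid,
        diagnostics={"weighted": sig is not None},
    )


def pka_from_titration(ph, absorbance) -> FitResult:
    """Fit a single-pKa sigmoid A(pH) = A_acid + (A_base - A_acid)/(1 + 10^(pKa-pH)).

    Requires >= 5 pH points spanning the transition.  Data without a
    detectable transition (flat within the residual scatter) or with a
    fitted pKa outside the sampled range return converged = False.
    """
    ph = np.asarray(ph, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if ph.size < 5:
        raise ValueError("pKa titration requires at least 5 pH points")
    result = fit_equation("pka_sigmoid", (ph, a))
    amp = abs(result.estimates["a_base"] - result.estimates["a_acid"])
    scatter = float(np.std(result.residuals, ddof=min(3, ph.size - 1)))
    scale = max(float(np.max(np.abs(a))), 1e-30)
    no_transition = amp < max(3.0 * scatter, 1e-9 * scale)
    out_of_range = not (ph.min() <= result.estimates["pka"] <= ph.max())
    if no_transition or out_of_range:
        diag = dict(result.diagnostics)
        diag["message"] = (
            "no absorbance transition detected" if no_transition
            else "fitted pKa outside the sampled pH range"
        )
        return FitResult(
            model_id=result.model_id,
            estimates=result.estimates,
            standard_errors=result.standard_errors,
            ssr=result.ssr,
            n_points=result.n_points,
            converged=False,
            residuals=result.residuals,
            diagnostics=diag,
        )
    return result


def extinction_from_standard_curve(concentration, absorbance, path_length: float) -> FitResult:
    """Extinction coefficient (M^-1 cm^-1) from a Beer-Lambert standard curve.

    Ordinary least-squares slope divided by the path length; the intercept is
    fitted (never forced through zero) and reported as a diagnostic.
    """
    conc = np.asarray(concentration, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if path_length <= 0:
        raise ValueError("path_length must be > 0 cm")
    if conc.size < 3:
        raise ValueError("standard curve requires at least 3 concentrations")
    if np.ptp(conc) <= 0:
        raise ValueError("concentrations have zero spread; slope undefined")
    result = fit_equation(
        "standard_curve", (conc, a), fixed_inputs={"path_length": path_length}
    )
    if np.allclose(a, 0.0):
        warnings.warn(
            "all absorbance readings are zero; extinction coefficient is 0",
            stacklevel=2,
        )
    return result
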