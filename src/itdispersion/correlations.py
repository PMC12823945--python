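"""Empirical correlations for effective dispersion and caudocranial drift.

Three regression models link the experimentally inferred effective
dispersion coefficient D_exp (cm^2/min) to the amplitude and frequency
of CSF pulsation:

* dimensional:      log10 D_exp = a0 + a1 f + a2 f^2 + kappa * log10 Urms
* dimensionless:    log10 dD   = phi0 + phi1 a + phi2 a^2 + K * log10 Pe,
  with dD = (D_exp - D0)/D0, a the Womersley number, Pe the Peclet number
* scale analysis:   D_exp/D0 = eps * lambda(a),
  lambda(a) = l0 + l1 a + l2 a^2, eps the pulsatile amplitude ratio;
  fitted in the normalized form chi = (D_exp/D0)/eps ~ quadratic in a.

Two further linear laws describe the caudocranial velocity (CCV, cm/min)
as a function of frequency or of Urms.  All logarithms are base 10; in
the dimensional law Urms enters in cm/min, the unit system in which the
published coefficients reproduce dispersion coefficients of the observed
magnitude (a few cm^2/min) over the physiological frequency range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

#: Reference-fit coefficients of the dimensional law.
DIMENSIONAL_COEFFS = {
    "a0": -1.2220,
    "a1": 0.0067,
    "a2": -8.2069e-5,
    "kappa": 0.9830,
}
#: Reference-fit coefficients of the dimensionless (Womersley/Peclet) law.
DIMENSIONLESS_COEFFS = {
    "phi0": 0.4697,
    "phi1": -0.3977,
    "phi2": -1.2663,
    "kappa": 0.9873,
}
#: Reference-fit coefficients of the scale-analysis law.
SCALE_COEFFS = {
    "lambda0": -5477e3,
    "lambda1": 1580e3,
    "lambda2": -84.09e3,
}
#: Reference CCV laws: slope and intercept (cm/min) vs frequency (bpm)
#: and vs Urms (cm/min).
CCV_FREQUENCY_COEFFS = {"a": 0.0018, "b": 0.2144}
CCV_URMS_COEFFS = {"a": 0.0046, "b": 0.2650}

_MODEL_COEFF_NAMES = {
    "dimensional": ("a0", "a1", "a2", "kappa"),
    "dimensionless": ("phi0", "phi1", "phi2", "kappa"),
    "scale": ("lambda0", "lambda1", "lambda2"),
    "ccv_frequency": ("a", "b"),
    "ccv_urms": ("a", "b"),
}


@dataclass(frozen=True)
class ExperimentSummary:
    """Per-experiment descriptors and the inferred dispersion coefficient."""

    frequency: float  # bpm
    stroke_volume: float  # mL/beat
    urms: float  # cm/s
    womersley: float
    peclet: float
    amplitude_ratio: float
    d_exp: float  # cm^2/min
    ccv: float | None = None  # cm/min

    def __post_init__(self) -> None:
        for name in ("frequency", "stroke_volume", "urms", "womersley", "peclet",
                     "amplitude_ratio", "d_exp"):
            if getattr(self, name) <= 0 and name != "stroke_volume":
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CorrelationFit:
    """Fitted correlation: model tag, named coefficients, R^2 and n."""

    model: str
    coefficients: dict[str, float]
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        expected = _MODEL_COEFF_NAMES.get(self.model)
        if expected is None:
            raise ValueError(f"unknown model {self.model!r}")
        if tuple(self.coefficients) != expected:
            raise ValueError(
                f"model {self.model!r} expects coefficients {expected}, "
                f"got {tuple(self.coefficients)}"
            )
        if not -1e-9 <= self.r_squared <= 1.0 + 1e-9:
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")


def _urms_cm_min(urms_cm_s) -> np.ndarray:
    return np.asarray(urms_cm_s, dtype=float) * 60.0


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str], model: str) -> CorrelationFit:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for model {model!r}: regressors "
            f"{list(names)} are collinear (rank {rank} < {X.shape[1]})"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return CorrelationFit(
        model=model,
        coefficients={name: float(b) for name, b in zip(names, beta)},
        r_squared=r2,
        n=y.size,
    )


def dimensional_law(frequency, urms_cm_s, coeffs: dict[str, float] | None = None):
    """Evaluate the dimensional correlation; returns D in cm^2/min."""
    c = DIMENSIONAL_COEFFS if coeffs is None else coeffs
    f = np.asarray(frequency, dtype=float)
    u = _urms_cm_min(urms_cm_s)
    lam = c["a0"] + c["a1"] * f + c["a2"] * f**2
    return 10.0 ** (lam + c["kappa"] * np.log10(u))


def dimensionless_law(womersley, peclet, d0: float, coeffs: dict[str, float] | None = None):
    """Evaluate the Womersley/Peclet correlation; returns D in cm^2/min."""
    c = DIMENSIONLESS_COEFFS if coeffs is None else coeffs
    a = np.asarray(womersley, dtype=float)
    pe = np.asarray(peclet, dtype=float)
    lam = c["phi0"] + c["phi1"] * a + c["phi2"] * a**2
    delta = 10.0 ** (lam + c["kappa"] * np.log10(pe))
    return d0 * (1.0 + delta)


def scale_law(womersley, amplitude_ratio, d0: float, coeffs: dict[str, float] | None = None):
    """Evaluate the scale-analysis correlation; returns D in cm^2/min."""
    c = SCALE_COEFFS if coeffs is None else coeffs
    a = np.asarray(womersley, dtype=float)
    eps = np.asarray(amplitude_ratio, dtype=float)
    lam = c["lambda0"] + c["lambda1"] * a + c["lambda2"] * a**2
    return d0 * eps * lam


def ccv_law(value, coeffs: dict[str, float]):
    """Evaluate a linear CCV law a*x + b; returns CCV in cm/min."""
    return coeffs["a"] * np.asarray(value, dtype=float) + coeffs["b"]


def fit_dimensional(summaries: Sequence[ExperimentSummary]) -> CorrelationFit:
    """OLS fit of log10 D_exp on [1, f, f^2, log10 Urms]."""
    if len(summaries) < 5:
        raise ValueError("dimensional fit requires at least 5 experiments")
    f = np.array([s.frequency for s in summaries])
    u = _urms_cm_min([s.urms for s in summaries])
    d = np.array([s.d_exp for s in summaries])
    X = np.column_stack([np.ones_like(f), f, f**2, np.log10(u)])
    return _ols(X, np.log10(d), ("a0", "a1", "a2", "kappa"), "dimensional")


def fit_dimensionless(summaries: Sequence[ExperimentSummary], d0: float) -> CorrelationFit:
    """OLS fit of log10((D_exp - D0)/D0) on [1, alpha, alpha^2, log10 Pe]."""
    if len(summaries) < 5:
        raise ValueError("dimensionless fit requires at least 5 experiments")
    d = np.array([s.d_exp for s in summaries])
    if np.any(d <= d0):
        raise ValueError("all D_exp must exceed the molecular baseline D0")
    a = np.array([s.womersley for s in summaries])
    pe = np.array([s.peclet for s in summaries])
    X = np.column_stack([np.ones_like(a), a, a**2, np.log10(pe)])
    y = np.log10((d - d0) / d0)
    return _ols(X, y, ("phi0", "phi1", "phi2", "kappa"), "dimensionless")


def fit_scale(summaries: Sequence[ExperimentSummary], d0: float) -> CorrelationFit:
    """OLS fit of the normalized variable chi = (D_exp/D0)/eps on [1, alpha, alpha^2]."""
    if len(summaries) < 4:
        raise ValueError("scale fit requires at least 4 experiments")
    eps = np.array([s.amplitude_ratio for s in summaries])
    if np.any(eps <= 0):
        raise ValueError("amplitude ratios must be positive")
    a = np.array([s.womersley for s in summaries])
    d = np.array([s.d_exp for s in summaries])
    chi = (d / d0) / eps
    X = np.column_stack([np.ones_like(a), a, a**2])
    return _ols(X, chi, ("lambda0", "lambda1", "lambda2"), "scale")


def fit_ccv(summaries: Sequence[ExperimentSummary], regressor: str = "frequency") -> CorrelationFit:
    """Simple OLS line for the caudocranial velocity.

    ``regressor`` selects the abscissa: ``"frequency"`` (bpm) or
    ``"urms"`` (cm/min).
    """
    if regressor not in ("frequency", "urms"):
        raise ValueError(f"regressor must be 'frequency' or 'urms', got {regressor!r}")
    pts = [s for s in summaries if s.ccv is not None]
    if len(pts) < 3:
        raise ValueError("CCV fit requires at least 3 experiments with CCV")
    if regressor == "frequency":
        x = np.array([s.frequency for s in pts])
    else:
        x = _urms_cm_min([s.urms for s in pts])
    if np.allclose(x, x[0]):
        raise ValueError("all regressor values identical: CCV line is degenerate")
    y = np.array([s.ccv for s in pts])
    res = stats.linregress(x, y)
    return CorrelationFit(
        model=f"ccv_{regressor}",
        coefficients={"a": float(res.slope), "b": float(res.intercept)},
        r_squared=min(max(float(res.rvalue) ** 2, 0.0), 1.0),
        n=len(pts),
    )


def quadratic_vertex(fit: CorrelationFit) -> float:
    """Womersley number at the extremum of a fitted quadratic lambda(alpha)."""
    if fit.model == "scale":
        c1, c2 = fit.coefficients["lambda1"], fit.coefficients["lambda2"]
    elif fit.model == "dimensionless":
        c1, c2 = fit.coefficients["phi1"], fit.coefficients["phi2"]
    else:
        raise ValueError(f"model {fit.model!r} has no quadratic frequency term")
    if c2 == 0:
        raise ValueError("quadratic coefficient is zero: no vertex")
    return -c1 / (2.0 * c2)


def predict_dispersion(
    fit: CorrelationFit,
    frequency: float | None = None,
    urms: float | None = None,
    womersley: float | None = None,
    peclet: float | None = None,
    amplitude_ratio: float | None = None,
    d0: float | None = None,
) -> float:
    """Evaluate a fitted dispersion correlation, returning D in cm^2/min.

    The arguments required depend on ``fit.model``: dimensional needs
    ``frequency`` and ``urms`` (cm/s); dimensionless needs ``womersley``,
    ``peclet`` and ``d0``; scale needs ``womersley``, ``amplitude_ratio``
    and ``d0``.
    """
    if fit.model == "dimensional":
        if frequency is None or urms is None:
            raise ValueError("dimensional model needs frequency and urms")
        return float(dimensional_law(frequency, urms, fit.coefficients))
    if fit.model == "dimensionless":
        if womersley is None or peclet is None or d0 is None:
            raise ValueError("dimensionless model needs womersley, peclet and d0")
        return float(dimensionless_law(womersley, peclet, d0, fit.coefficients))
    if fit.model == "scale":
        if womersley is None or amplitude_ratio is None or d0 is None:
            raise ValueError("scale model needs womersley, amplitude_ratio and d0")
        return float(scale_law(womersley, amplitude_ratio, d0, fit.coefficients))
    raise ValueError(f"model {fit.model!r} does not predict dispersion")
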