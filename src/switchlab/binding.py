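"""Ligand-binding isotherm fitting for titration data.

Fluorescence-anisotropy (and microscale-thermophoresis) titrations of
fluorophore-labelled peptide against increasing sensor-domain concentration
are described by a Hill-type logistic in log10 concentration:

    F(x) = r_free + (r_max - r_free) / (1 + 10^((logK_half - x) * n_H))

where x is log10 of the titrant concentration (µM by convention throughout
this package), r_free / r_max are the response plateaus and n_H the Hill
coefficient.  The half-saturation point K_half = 10^logK_half is an
*apparent* constant: when the receptor itself interconverts between
monomers, dimers and oligomers the titration superimposes several coupled
equilibria, so K_half must not be read as a true dissociation constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "BindingParams",
    "BindingCurveData",
    "BindingFit",
    "binding_model",
    "fit_binding",
    "series_summary",
]

#: parameter order used throughout the fitting code
_PARAM_NAMES = ("r_free", "r_max", "logK_half", "n_H")


@dataclass(frozen=True)
class BindingParams:
    """Parameters of the log-dose binding model.

    Attributes
    ----------
    r_free : response at the low-concentration plateau (anisotropy units,
        or 0..1 for normalized MST response).
    r_max : response at saturation.
    logK_half : log10 of the apparent half-saturation concentration K_half,
        in log10(µM).  Apparent constant, not a Kd.
    n_H : Hill coefficient (dimensionless, > 0).
    """

    r_free: float
    r_max: float
    logK_half: float
    n_H: float = 1.0

    @property
    def K_half(self) -> float:
        """Apparent half-saturation concentration in µM."""
        return 10.0 ** self.logK_half

    def as_array(self) -> np.ndarray:
        return np.array([self.r_free, self.r_max, self.logK_half, self.n_H])

    @classmethod
    def from_array(cls, theta) -> "BindingParams":
        return cls(*(float(v) for v in theta))


@dataclass(frozen=True)
class BindingCurveData:
    """A titration: log10 concentrations (µM) and measured responses."""

    x: np.ndarray
    response: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "response", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and response must be 1-D arrays of equal length")
        if not np.all(np.isfinite(x)):
            raise ValueError("concentrations must be finite")

    @classmethod
    def from_concentrations(cls, conc_uM, response) -> "BindingCurveData":
        conc = np.asarray(conc_uM, dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive to take log10")
        return cls(np.log10(conc), np.asarray(response, dtype=float))


@dataclass
class BindingFit:
    """Result of fitting :func:`binding_model` to a titration."""

    params: BindingParams
    stderr: dict[str, float]
    r_squared: float
    converged: bool
    fixed: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    residuals: np.ndarray | None = None

    @property
    def K_half(self) -> float:
        return self.params.K_half

    @property
    def K_half_stderr(self) -> float:
        """Delta-method SE of K_half (µM) from the SE of logK_half."""
        se_log = self.stderr.get("logK_half", float("nan"))
        return abs(self.K_half * math.log(10.0) * se_log)


def binding_model(x, params: BindingParams):
    """Evaluate the binding isotherm at log10 concentration(s) ``x``.

    Strictly increasing in x whenever r_max > r_free and n_H > 0.
    """
    x = np.asarray(x, dtype=float)
    span = params.r_max - params.r_free
    return params.r_free + span / (1.0 + 10.0 ** ((params.logK_half - x) * params.n_H))


def _model_vec(theta, x, fixed_mask, fixed_vals):
    full = fixed_vals.copy()
    full[~fixed_mask] = theta
    return binding_model(x, BindingParams.from_array(full))


def fit_binding(
    data: BindingCurveData,
    init: BindingParams | None = None,
    fixed: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
) -> BindingFit:
    """Least-squares fit of the log-dose binding model to a titration.

    With no ``init``, a deterministic multistart is used: ``n_starts``
    values of logK_half spanning the sampled concentration range, n_H = 1,
    and plateaus taken from the data extremes.  ``fixed`` pins parameters
    by name (e.g. ``{"r_max": 0.25}`` for weak binders where the upper
    plateau is not reached).  Default bounds keep n_H in [0.3, 5] and the
    plateaus within the observed response range ± 50% of its span — minimal
    constraints that prevent plateau/K trade-off blow-ups.

    Raises
    ------
    ValueError
        If the data carry fewer than 6 points or no binding signal
        (flat response).
    """
    x, y = data.x, data.response
    if x.size < 6:
        raise ValueError("need at least 6 titration points for a fit")
    y_span = float(np.ptp(y))
    if y_span == 0.0 or not np.isfinite(y_span):
        raise ValueError("no binding signal: response is flat")

    fixed = dict(fixed or {})
    for name in fixed:
        if name not in _PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")

    lo = {
        "r_free": float(y.min() - 0.5 * y_span),
        "r_max": float(y.min() - 0.5 * y_span),
        "logK_half": float(x.min() - 3.0),
        "n_H": 0.3,
    }
    hi = {
        "r_free": float(y.max() + 0.5 * y_span),
        "r_max": float(y.max() + 0.5 * y_span),
        "logK_half": float(x.max() + 3.0),
        "n_H": 5.0,
    }
    for name, (a, b) in (bounds or {}).items():
        lo[name], hi[name] = float(a), float(b)

    fixed_mask = np.array([n in fixed for n in _PARAM_NAMES])
    fixed_vals = np.array([fixed.get(n, np.nan) for n in _PARAM_NAMES])

    if init is not None:
        starts = [init.as_array()]
    else:
        # ascending responses ⇒ plateau guesses from the curve ends
        order = np.argsort(x)
        r_lo = float(np.mean(y[order][:2]))
        r_hi = float(np.mean(y[order][-2:]))
        ks = np.linspace(x.min(), x.max(), n_starts)
        starts = [np.array([r_lo, r_hi, k, 1.0]) for k in ks]

    lo_vec = np.array([lo[n] for n in _PARAM_NAMES])
    hi_vec = np.array([hi[n] for n in _PARAM_NAMES])

    best = None
    for theta0 in starts:
        free0 = np.clip(theta0, lo_vec, hi_vec)[~fixed_mask]
        try:
            sol = least_squares(
                lambda th: _model_vec(th, x, fixed_mask, fixed_vals) - y,
                free0,
                bounds=(lo_vec[~fixed_mask], hi_vec[~fixed_mask]),
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
            )
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed")

    full = fixed_vals.copy()
    full[~fixed_mask] = best.x
    params = BindingParams.from_array(full)
    resid = binding_model(x, params) - y

    # SEs from the Gauss-Newton covariance of the free parameters
    dof = max(x.size - int((~fixed_mask).sum()), 1)
    s2 = float(best.cost * 2.0 / dof)
    stderr = {n: 0.0 for n in _PARAM_NAMES}
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.pinv(jtj) * s2
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        for n, se in zip(np.array(_PARAM_NAMES)[~fixed_mask], ses):
            stderr[str(n)] = float(se)
    except np.linalg.LinAlgError:
        pass

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")

    flags: list[str] = []
    converged = bool(best.success)
    if not converged:
        flags.append("non-convergence")
    # K_half more than 10x outside the sampled range is extrapolation
    if params.logK_half < x.min() - 1.0 or params.logK_half > x.max() + 1.0:
        flags.append("K_half outside sampled concentration range (extrapolated)")

    return BindingFit(
        params=params,
        stderr=stderr,
        r_squared=r2,
        converged=converged,
        fixed=fixed,
        flags=flags,
        residuals=resid,
    )


def series_summary(fits: dict[str, BindingFit], reference: str | None = None):
    """Summarize a labelled series of fits (truncations, tandem repeats...).

    Returns a pandas DataFrame with K_half (µM), its SE, fold-change of
    K_half relative to ``reference`` (first label if omitted; fold > 1
    means weaker binding than the reference), R² and propagated flags.
    """
    import pandas as pd

    if not fits:
        raise ValueError("need at least one fit")
    labels = list(fits)
    ref = reference if reference is not None else labels[0]
    if ref not in fits:
        raise ValueError(f"reference label {ref!r} not in series")
    k_ref = fits[ref].K_half
    rows = []
    for label in labels:
        f = fits[label]
        rows.append(
            {
                "label": label,
                "K_half_uM": f.K_half,
                "K_half_se_uM": f.K_half_stderr,
                "fold_change_vs_ref": f.K_half / k_ref,
                "r_squared": f.r_squared,
                "flags": ";".join(f.flags),
            }
        )
    return pd.DataFrame(rows)
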