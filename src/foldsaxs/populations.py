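"""Degree-of-folding estimation by constrained mixture fitting.

The experimental SAXS curve is modelled as a global scale (and optional
constant background) times a convex combination of per-state predicted
curves:

    I_model(q) = s · Σ_s w_s I_s(q) + b,   w_s ≥ 0,  Σ_s w_s = 1.

The simplex constraint makes the weights directly interpretable as state
populations; the weight of the folded ensemble is the degree of folding.
For fixed weights the optimal (s, b) have a closed weighted-least-squares
form, so the outer optimisation runs over the weight simplex only, with a
deterministic multi-start (vertices + barycenter).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
from scipy.optimize import minimize

from .analysis import interpolate_onto
from .models import ScatteringCurve, ValidationError

__all__ = [
    "PopulationFitResult",
    "IllConditionedBasisWarning",
    "fit_populations",
    "fold_fraction_uncertainty",
    "truncate_q_range",
]


class IllConditionedBasisWarning(UserWarning):
    """State curves are (nearly) indistinguishable; weights are unidentifiable."""


@dataclass
class PopulationFitResult:
    """Fitted state populations and nuisance parameters."""

    state_names: list[str]
    weights: np.ndarray  # on the simplex
    scale: float
    background: float
    chi2_reduced: float
    q_range_used: tuple[float, float]  # Å⁻¹
    weight_uncertainties: Optional[np.ndarray] = None  # (n_states, 2): 2.5/97.5 pct
    free_weights: Optional[np.ndarray] = None  # unconstrained-mode raw weights
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-9) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be non-negative and sum to 1")
        if self.scale <= 0:
            raise ValidationError("scale must be > 0")

    @property
    def degree_of_folding(self) -> float:
        """Weight of the 'fc' state when present, else the first state."""
        if "fc" in self.state_names:
            return float(self.weights[self.state_names.index("fc")])
        return float(self.weights[0])

    def as_dict(self) -> dict:
        d = {
            "states": self.state_names,
            "weights": self.weights.tolist(),
            "scale": self.scale,
            "background": self.background,
            "chi2_reduced": self.chi2_reduced,
            "q_range_used": list(self.q_range_used),
        }
        if self.weight_uncertainties is not None:
            d["weight_intervals_95"] = self.weight_uncertainties.tolist()
        if self.free_weights is not None:
            d["free_weights"] = self.free_weights.tolist()
        return d


def truncate_q_range(curve: ScatteringCurve, q_max: float) -> ScatteringCurve:
    """Keep only points with q ≤ q_max (low-q window of the analysis)."""
    if q_max <= curve.q[0]:
        raise ValidationError(f"q_max = {q_max} leaves no points (first q = {curve.q[0]})")
    keep = curve.q <= q_max
    return ScatteringCurve(
        curve.q[keep],
        curve.intensity[keep],
        None if curve.sigma is None else curve.sigma[keep],
        dict(curve.meta),
    )


def _profile_scale_background(
    mixture: np.ndarray, i_exp: np.ndarray, inv_var: np.ndarray, fit_background: bool
) -> tuple[float, float]:
    """Closed-form weighted LS for I_exp ≈ s·mixture (+ b)."""
    if fit_background:
        # 2x2 normal equations in (s, b)
        s_mm = (inv_var * mixture * mixture).sum()
        s_m1 = (inv_var * mixture).sum()
        s_11 = inv_var.sum()
        s_my = (inv_var * mixture * i_exp).sum()
        s_1y = (inv_var * i_exp).sum()
        det = s_mm * s_11 - s_m1**2
        if det <= 0:
            return 1.0, 0.0
        s = (s_my * s_11 - s_m1 * s_1y) / det
        b = (s_mm * s_1y - s_m1 * s_my) / det
        return float(s), float(b)
    denom = (inv_var * mixture * mixture).sum()
    if denom <= 0:
        return 1.0, 0.0
    return float((inv_var * mixture * i_exp).sum() / denom), 0.0


def _chi2_for_weights(
    w: np.ndarray,
    basis: np.ndarray,
    i_exp: np.ndarray,
    inv_var: np.ndarray,
    fit_background: bool,
) -> tuple[float, float, float]:
    mixture = basis @ w
    s, b = _profile_scale_background(mixture, i_exp, inv_var, fit_background)
    resid = s * mixture + b - i_exp
    return float((inv_var * resid**2).mean()), s, b


def fit_populations(
    experimental: ScatteringCurve,
    state_curves: Mapping[str, ScatteringCurve],
    q_max: Optional[float] = None,
    fit_background: bool = False,
) -> PopulationFitResult:
    """Fit a convex combination of state curves to an experimental curve.

    Parameters
    ----------
    experimental:
        The measured curve; σ is used for weighting when present, otherwise
        unweighted least squares.
    state_curves:
        Named predicted curves (conventionally ``{"fc": ..., "uf": ...}``);
        each must cover the experimental q range (after ``q_max`` truncation).
    q_max:
        Optional upper q cut, Å⁻¹ (the overall-shape regime; e.g. 0.4).
    fit_background:
        Also fit an additive constant (off by default).

    Returns the simplex-constrained solution; ``free_weights`` additionally
    records the unconstrained linear solution normalised post hoc, as a
    consistency diagnostic.
    """
    names = list(state_curves)
    if len(names) < 2:
        raise ValidationError("need at least 2 state curves")
    exp = truncate_q_range(experimental, q_max) if q_max is not None else experimental
    if len(exp) < len(names) + 1:
        raise ValidationError("experimental curve has too few points for the fit")
    basis = np.column_stack([interpolate_onto(state_curves[n], exp.q) for n in names])
    sigma = exp.sigma if exp.sigma is not None else np.ones_like(exp.q)
    # Rescale the problem to O(1) magnitudes for the optimiser; dividing
    # data, basis and sigma by the same factor leaves chi2 and the fitted
    # scale unchanged (background is mapped back below).
    norm = float(np.abs(exp.intensity).mean()) or 1.0
    i_exp = exp.intensity / norm
    basis = basis / norm
    inv_var = (norm / sigma) ** 2  # chi2 in scaled space == chi2 in original units
    # unit-mean weights keep the optimiser's objective O(1) regardless of
    # the data's absolute intensity scale (SLSQP is scale-sensitive)
    inv_var_opt = inv_var / inv_var.mean()
    n_states = len(names)

    # identifiability check: are the normalised basis curves distinguishable?
    normed = basis / np.abs(basis).mean(axis=0, keepdims=True)
    ill = False
    for i in range(n_states):
        for j in range(i + 1, n_states):
            denom = np.abs(normed[:, i]).mean()
            if np.abs(normed[:, i] - normed[:, j]).mean() < 1e-9 * max(denom, 1.0):
                ill = True
    if ill:
        warnings.warn(
            "state curves are indistinguishable up to scale; weights are not "
            "identifiable (uncertainty spans [0, 1])",
            IllConditionedBasisWarning,
            stacklevel=2,
        )

    def objective(w_free: np.ndarray) -> float:
        return _chi2_for_weights(w_free, basis, i_exp, inv_var_opt, fit_background)[0]

    starts = [np.full(n_states, 1.0 / n_states)]
    for k in range(n_states):
        v = np.full(n_states, 1e-6)
        v[k] = 1.0
        starts.append(v / v.sum())
    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * n_states
    best = None
    for w0 in starts:
        res = minimize(
            objective,
            w0,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 500, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    w = np.clip(best.x, 0.0, None)
    w = w / w.sum()
    chi2, s, b = _chi2_for_weights(w, basis, i_exp, inv_var, fit_background)
    b *= norm  # back to original intensity units
    if s <= 0:
        raise ValidationError("fitted scale is non-positive; state curves cannot describe data")

    # unconstrained diagnostic: LS on s·w jointly, normalised post hoc
    a = basis * np.sqrt(inv_var)[:, None]
    y = i_exp * np.sqrt(inv_var)
    if fit_background:
        a = np.column_stack([a, np.sqrt(inv_var)])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    raw = coef[:n_states]
    free = raw / raw.sum() if raw.sum() != 0 else np.full(n_states, np.nan)

    uncertainties = None
    if ill:
        uncertainties = np.tile([0.0, 1.0], (n_states, 1))
    return PopulationFitResult(
        state_names=names,
        weights=w,
        scale=s,
        background=b,
        chi2_reduced=chi2,
        q_range_used=(float(exp.q[0]), float(exp.q[-1])),
        weight_uncertainties=uncertainties,
        free_weights=free,
        meta={"fit_background": fit_background, "n_points": len(exp)},
    )


def fold_fraction_uncertainty(
    result: PopulationFitResult,
    experimental: ScatteringCurve,
    state_curves: Mapping[str, ScatteringCurve],
    n_boot: int = 200,
    seed: Optional[int] = None,
) -> np.ndarray:
    """95% bootstrap intervals for the state weights (residual resampling).

    Residuals of the fitted model are resampled with replacement, added back
    to the fitted curve, and the fit repeated ``n_boot`` times; the 2.5/97.5
    percentiles per weight are returned as an (n_states, 2) array and also
    stored on ``result.weight_uncertainties``.
    """
    if n_boot < 10:
        raise ValidationError("n_boot must be >= 10")
    q_max = result.q_range_used[1]
    exp = truncate_q_range(experimental, q_max + 1e-12)
    names = result.state_names
    basis = np.column_stack([interpolate_onto(state_curves[n], exp.q) for n in names])
    fitted = result.scale * (basis @ result.weights) + result.background
    residuals = exp.intensity - fitted
    rng = np.random.default_rng(seed)
    boot_weights = np.empty((n_boot, len(names)))
    fit_background = bool(result.meta.get("fit_background", False))
    for b in range(n_boot):
        resampled = fitted + rng.choice(residuals, size=residuals.size, replace=True)
        synth = ScatteringCurve(exp.q, resampled, exp.sigma)
        r = fit_populations(synth, state_curves, q_max=None, fit_background=fit_background)
        boot_weights[b] = r.weights
    intervals = np.column_stack(
        [np.percentile(boot_weights, 2.5, axis=0), np.percentile(boot_weights, 97.5, axis=0)]
    )
    result.weight_uncertainties = intervals
    return intervals
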