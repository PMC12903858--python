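"""Analysis of measured or pseudo-experimental scattering curves.

Guinier fitting (Rg and forward scattering from the low-q regime), the
Kratky transform (compactness diagnostic), and a reduced chi-square
goodness-of-fit between a predicted and a measured curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .models import ScatteringCurve, ValidationError

__all__ = ["GuinierResult", "guinier_fit", "kratky_transform", "chi_square", "interpolate_onto"]


@dataclass
class GuinierResult:
    """Result of a Guinier fit ln I = ln I0 − (Rg²/3) q²."""

    rg: float  # Å
    i0: float  # intensity units
    q_range_used: tuple[float, float]  # Å⁻¹
    fit_points: int
    r_squared: float
    qrg_limit: float

    def __post_init__(self) -> None:
        if self.rg <= 0:
            raise ValidationError("Guinier Rg must be > 0")
        if self.fit_points < 3:
            raise ValidationError("Guinier fit needs >= 3 points")


class NoGuinierRegionError(ValidationError):
    """The low-q region has no decaying (negative-slope) Guinier regime."""


def _weighted_linefit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted LS line y = a + b x; returns (a, b, r²)."""
    W = w.sum()
    xm = (w * x).sum() / W
    ym = (w * y).sum() / W
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    if sxx == 0:
        raise ValidationError("degenerate q grid in Guinier window")
    b = sxy / sxx
    a = ym - b * xm
    ss_res = (w * (y - a - b * x) ** 2).sum()
    ss_tot = (w * (y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2


def guinier_fit(
    curve: ScatteringCurve, qrg_limit: float = 1.3, q_min_points: int = 3
) -> GuinierResult:
    """Iterative Guinier fit over the largest valid low-q window.

    Fits ln I = ln I0 − (Rg²/3) q² by weighted least squares (weights from σ
    when present, via σ_lnI = σ/I), then shrinks/extends the window until
    q_max·Rg ≤ ``qrg_limit`` holds self-consistently. Rg is returned in Å
    (q in Å⁻¹).
    """
    if q_min_points < 3:
        raise ValidationError("q_min_points must be >= 3")
    mask = curve.intensity > 0
    # Guinier analysis only uses the low-q head: stop at the first
    # non-positive intensity to keep the window contiguous.
    if not mask[0:q_min_points].all():
        raise ValidationError(f"need at least {q_min_points} positive-intensity low-q points")
    n_pos = int(np.argmin(mask)) if not mask.all() else curve.q.size
    q = curve.q[:n_pos]
    i = curve.intensity[:n_pos]
    if q.size < q_min_points:
        raise ValidationError(f"need at least {q_min_points} positive-intensity low-q points")
    x = q**2
    y = np.log(i)
    if curve.sigma is not None:
        w_full = (i / curve.sigma[:n_pos]) ** 2  # ln-space weights
    else:
        w_full = np.ones_like(x)

    n = min(q.size, max(q_min_points, 10))
    last_n = -1
    rg = 0.0
    for _ in range(100):
        a, b, r2 = _weighted_linefit(x[:n], y[:n], w_full[:n])
        if b >= 0:
            # no decaying regime: try shrinking toward the minimum window
            if n > q_min_points:
                n -= 1
                continue
            raise NoGuinierRegionError(
                "low-q intensity is not decaying; no Guinier region found"
            )
        rg = float(np.sqrt(-3.0 * b))
        n_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        n_new = min(max(n_new, q_min_points), q.size)
        if n_new == n or n_new == last_n:  # converged (or 2-cycle: keep smaller)
            n = min(n, n_new)
            break
        last_n = n
        n = n_new
    a, b, r2 = _weighted_linefit(x[:n], y[:n], w_full[:n])
    if b >= 0:
        raise NoGuinierRegionError("low-q intensity is not decaying; no Guinier region found")
    rg = float(np.sqrt(-3.0 * b))
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(a)),
        q_range_used=(float(q[0]), float(q[n - 1])),
        fit_points=n,
        r_squared=float(r2),
        qrg_limit=qrg_limit,
    )


def kratky_transform(curve: ScatteringCurve) -> ScatteringCurve:
    """Kratky representation q²·I(q); σ propagates as q²·σ.

    Compact particles give a bell-shaped Kratky curve, extended/disordered
    chains a monotonically rising one. σ at q = 0 would propagate to zero,
    which ScatteringCurve forbids, so a zero-q point keeps a tiny positive σ.
    """
    q2 = curve.q**2
    sigma = None
    if curve.sigma is not None:
        sigma = np.maximum(q2 * curve.sigma, np.finfo(float).tiny)
    return ScatteringCurve(curve.q.copy(), q2 * curve.intensity, sigma, dict(curve.meta))


def interpolate_onto(predicted: ScatteringCurve, q: np.ndarray) -> np.ndarray:
    """Linear interpolation of a predicted curve onto a target q grid.

    The target grid must lie within the predicted span (no extrapolation).
    """
    q = np.asarray(q, dtype=float)
    if q.min() < predicted.q[0] - 1e-12 or q.max() > predicted.q[-1] + 1e-12:
        raise ValidationError(
            f"target q range [{q.min():.4g}, {q.max():.4g}] not covered by predicted "
            f"curve [{predicted.q[0]:.4g}, {predicted.q[-1]:.4g}]"
        )
    return np.interp(q, predicted.q, predicted.intensity)


def chi_square(
    predicted: ScatteringCurve,
    experimental: ScatteringCurve,
    scale: float = 1.0,
    background: float = 0.0,
) -> float:
    """Reduced chi-square of a (scaled, offset) prediction against data.

    χ²/N = (1/N) Σ_k ((s·I_pred(q_k) + b − I_exp(q_k)) / σ_k)², with the
    prediction linearly interpolated onto the experimental grid and σ_k = 1
    when the experimental curve carries no uncertainties.
    """
    i_pred = interpolate_onto(predicted, experimental.q)
    sigma = experimental.sigma if experimental.sigma is not None else np.ones_like(experimental.q)
    resid = (scale * i_pred + background - experimental.intensity) / sigma
    return float((resid**2).mean())
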