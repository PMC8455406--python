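"""Uniaxial stress-stretch curves and layer-specific HGO parameter fitting.

A uniaxial test record is a direction-labelled (circumferential or axial)
sequence of applied stretch and measured Cauchy stress.  Layer parameters
are fitted by simultaneous bounded nonlinear least squares on both
directions, each curve resampled at 50 equally spaced stretch increments
so the two directions receive equal weight:

    J = sum_m (t_circ,exp(m) - t_circ,model(m))^2
      + sum_n (t_ax,exp(n)  - t_ax,model(n))^2      [kPa^2]

Because the collagen nonlinearity parameter spans two orders of magnitude
across layers, the optimiser uses seeded Latin-hypercube multi-start.
The fibre angle and dispersion are only weakly identifiable from two
uniaxial directions (alpha and rho trade off against each other); recovery
guarantees therefore apply to predicted stresses, not raw parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .constitutive import (
    DomainError,
    EnergyOverflowError,
    HGOParams,
    SolverError,
    uniaxial_stress_curve,
)

__all__ = [
    "UniaxialCurve",
    "FitResult",
    "DEFAULT_BOUNDS",
    "resample_curve",
    "cost_J",
    "fit_layer",
]

#: Default fitting bounds: (lo, hi) per parameter (mu, c1, c2, alpha_deg, rho).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mu": (0.1, 200.0),
    "c1": (1.0, 1000.0),
    "c2": (0.1, 300.0),
    "alpha_deg": (0.0, 90.0),
    "rho": (0.0, 1.0 / 3.0),
}


@dataclass(frozen=True)
class UniaxialCurve:
    """One direction-labelled uniaxial stress-stretch record.

    ``stretch`` starts at 1 and is strictly increasing; ``stress`` is the
    loading-direction Cauchy stress in kPa.
    """

    direction: str
    stretch: np.ndarray
    stress: np.ndarray
    source: str = "measured"

    def __post_init__(self) -> None:
        if self.direction not in ("circ", "ax"):
            raise DomainError(f"direction must be 'circ' or 'ax', got {self.direction!r}")
        if self.source not in ("measured", "synthetic"):
            raise DomainError(f"source must be 'measured' or 'synthetic', got {self.source!r}")
        stretch = np.asarray(self.stretch, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "stretch", stretch)
        object.__setattr__(self, "stress", stress)
        if stretch.ndim != 1 or stretch.shape != stress.shape:
            raise DomainError("stretch and stress must be 1-D arrays of equal length")
        if stretch.size < 5:
            raise DomainError(f"need >= 5 points, got {stretch.size}")
        if np.any(np.diff(stretch) <= 0):
            bad = int(np.argmax(np.diff(stretch) <= 0)) + 1
            raise DomainError(f"stretch must be strictly increasing (violated at row {bad})")
        if abs(stretch[0] - 1.0) > 1e-9:
            raise DomainError(f"first stretch must be 1, got {stretch[0]}")

    @property
    def max_stretch(self) -> float:
        return float(self.stretch[-1])

    def sorted_by_stretch(self) -> "UniaxialCurve":
        order = np.argsort(self.stretch)
        return UniaxialCurve(self.direction, self.stretch[order], self.stress[order], self.source)


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus goodness-of-fit diagnostics."""

    params: HGOParams
    r_squared: float
    cost: float  # J at the optimum, kPa^2
    n_restarts_used: int
    converged: bool
    restart_costs: tuple[float, ...] = field(default=(), repr=False)


def resample_curve(c: UniaxialCurve, n: int = 50) -> UniaxialCurve:
    """Resample at ``n`` equally spaced stretches from 1 to max(stretch),
    with stresses linearly interpolated; endpoints preserved exactly."""
    if n < 2:
        raise DomainError(f"need n >= 2 resampling points, got {n}")
    new_stretch = np.linspace(1.0, c.max_stretch, n)
    new_stress = np.interp(new_stretch, c.stretch, c.stress)
    # guard against float drift at the endpoints
    new_stress[0] = c.stress[0]
    new_stress[-1] = c.stress[-1]
    return UniaxialCurve(c.direction, new_stretch, new_stress, c.source)


def cost_J(p: HGOParams, circ: UniaxialCurve, ax: UniaxialCurve) -> float:
    """Summed squared stress error over both directions, kPa^2."""
    r = _residuals_for(p, circ, ax)
    return float(r @ r)


def _residuals_for(p: HGOParams, circ: UniaxialCurve, ax: UniaxialCurve) -> np.ndarray:
    mod_c = uniaxial_stress_curve(p, "circ", circ.stretch)
    mod_a = uniaxial_stress_curve(p, "ax", ax.stretch)
    return np.concatenate([mod_c - circ.stress, mod_a - ax.stress])


def _bounds_arrays(bounds: dict[str, tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    keys = ("mu", "c1", "c2", "alpha_deg", "rho")
    lo = np.array([bounds[k][0] for k in keys])
    hi = np.array([bounds[k][1] for k in keys])
    if np.any(lo >= hi):
        raise DomainError("invalid bounds: lo >= hi")
    return lo, hi


def fit_layer(
    circ: UniaxialCurve,
    ax: UniaxialCurve,
    *,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_restarts: int = 10,
    n_resample: int = 50,
    seed: int | None = 0,
) -> FitResult:
    """Fit HGO parameters to one layer's circumferential and axial curves.

    Both curves are resampled to ``n_resample`` points and the pooled
    residual vector is minimised by bounded least squares started from
    ``n_restarts`` seeded Latin-hypercube points (log-spaced in mu, c1,
    c2).  Deterministic for a fixed seed.
    """
    lo, hi = _bounds_arrays(DEFAULT_BOUNDS if bounds is None else bounds)
    circ_r = resample_curve(circ.sorted_by_stretch(), n_resample)
    ax_r = resample_curve(ax.sorted_by_stretch(), n_resample)
    obs = np.concatenate([circ_r.stress, ax_r.stress])
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot <= 0:
        raise DomainError("degenerate input: all observed stresses are equal; R^2 undefined")

    def residuals(x: np.ndarray) -> np.ndarray:
        try:
            p = HGOParams(*x)
            r = _residuals_for(p, circ_r, ax_r)
        except (SolverError, EnergyOverflowError, DomainError):
            return np.full(obs.size, 1e6)
        return np.where(np.isfinite(r), r, 1e6)

    # log-spacing for the stiffness/nonlinearity scales, linear for angle
    # and dispersion
    log_mask = np.array([True, True, True, False, False])
    tlo = np.where(log_mask, np.log(np.maximum(lo, 1e-6)), lo)
    thi = np.where(log_mask, np.log(hi), hi)

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=5, seed=rng)
    unit = sampler.random(max(n_restarts, 1))
    starts = tlo + unit * (thi - tlo)
    starts = np.where(log_mask, np.exp(starts), starts)

    best: tuple[HGOParams, float, bool] | None = None
    costs = []
    for x0 in starts:
        sol = least_squares(
            residuals, np.clip(x0, lo, hi), bounds=(lo, hi), xtol=1e-12, ftol=1e-12
        )
        try:
            # restarts stuck in a pathological region (no transverse
            # equilibrium, fibre overflow) are discarded
            p = HGOParams(*sol.x)
            res = _residuals_for(p, circ_r, ax_r)
        except (SolverError, EnergyOverflowError, DomainError):
            costs.append(float("inf"))
            continue
        ss = float(res @ res)
        costs.append(ss)
        if np.isfinite(ss) and (best is None or ss < best[1]):
            best = (p, ss, bool(sol.success))
    if best is None:
        raise SolverError(
            f"all {len(starts)} restarts failed; restart costs (kPa^2): "
            f"{[f'{c:.4g}' for c in costs]}"
        )

    p, ss_res, success = best
    r2 = 1.0 - ss_res / ss_tot
    return FitResult(
        params=p,
        r_squared=r2,
        cost=ss_res,
        n_restarts_used=len(starts),
        converged=success,
        restart_costs=tuple(costs),
    )
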