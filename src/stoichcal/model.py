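"""Stoichiometric attenuation parameterization and calibration fits.

The linear attenuation coefficient of a mixture relative to water is
parameterized with two coefficients acting on powers of the atomic number
(photoelectric effect ~ Z^4.62, coherent scattering ~ Z^2.86, incoherent
scattering ~ Z):

    mu/mu_w(k1, k2) = (rho/rho_w)
        * sum_i (w_i/A_i) (Z_i + Z_i^2.86 k1 + Z_i^4.62 k2)
        / [ (w_H/A_H)(1 + k1 + k2) + (w_O/A_O)(8 + 8^2.86 k1 + 8^4.62 k2) ]

Two calibration models are provided:

* the conventional two-parameter model, which pins the theoretical CT
  number of air at -1000 HU:  H_t = 1000 (mu/mu_w - 1);
* a three-parameter model with an empirical scale alpha, so that air maps
  to -1000*alpha HU while water stays at exactly 0 HU for any alpha:
  H_t = 1000 alpha (mu/mu_w - 1).

Both fits minimize squared residuals in mu/mu_w space,
sum_n [ mu/mu_w(k1,k2)_n - (H_n/(1000 alpha) + 1) ]^2  (alpha = 1 fixed for
the two-parameter model), starting from k1 = 1.24e-3, k2 = 3.06e-5,
alpha = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .materials import (
    ELEMENTS,
    RESIDUAL_A_FACTOR,
    WATER,
    MaterialComposition,
    normalize_weights,
)

__all__ = [
    "EXP_COHERENT",
    "EXP_PHOTOELECTRIC",
    "DEFAULT_K1",
    "DEFAULT_K2",
    "DEFAULT_ALPHA",
    "AttenuationParams",
    "CTMeasurement",
    "FitResult",
    "ConvergenceError",
    "mu_ratio",
    "hu_to_ratio",
    "theoretical_hu",
    "fit_two_param",
    "fit_three_param",
]

# Fixed cross-section exponents for the coherent and photoelectric terms.
EXP_COHERENT = 2.86
EXP_PHOTOELECTRIC = 4.62

# Standard initial values for the least-squares fits.
DEFAULT_K1 = 1.24e-3
DEFAULT_K2 = 3.06e-5
DEFAULT_ALPHA = 1.0

# Distinct true elements needed across fitted materials for the parameters
# to be well determined; five elements (e.g. H, C, N, O, Ar) are not enough.
MIN_ELEMENTS_IDENTIFIABLE = 6

_HU_MIN, _HU_MAX = -1100.0, 4000.0


@dataclass(frozen=True)
class AttenuationParams:
    """Fitted coefficients (k1, k2) and optional HU scale alpha."""

    k1: float
    k2: float
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k1) and np.isfinite(self.k2)):
            raise ValueError("k1 and k2 must be finite")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


@dataclass(frozen=True)
class CTMeasurement:
    """A measured CT number (HU) for a characterized material."""

    material: MaterialComposition
    hu: float
    hu_sd: Optional[float] = None

    def __post_init__(self) -> None:
        if not _HU_MIN <= self.hu <= _HU_MAX:
            raise ValueError(
                f"{self.material.name}: CT number {self.hu} HU outside "
                f"plausibility bounds [{_HU_MIN}, {_HU_MAX}]"
            )
        object.__setattr__(self, "material", normalize_weights(self.material))


@dataclass(frozen=True)
class FitResult:
    """Parameters, residuals and identifiability diagnostics of a fit."""

    params: AttenuationParams
    model: str  # "two_param" | "three_param"
    residuals: np.ndarray
    n_materials: int
    n_elements: int
    identifiable: bool
    material_names: tuple[str, ...] = field(default=())

    @property
    def ssr(self) -> float:
        return float(np.dot(self.residuals, self.residuals))


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the last iterate in ``.params``."""

    def __init__(self, message: str, params: AttenuationParams):
        super().__init__(message)
        self.params = params


def _term(Z: float, A: float, w: float, k1: float, k2: float) -> float:
    return (w / A) * (Z + Z**EXP_COHERENT * k1 + Z**EXP_PHOTOELECTRIC * k2)


def _electron_cross_sum(m: MaterialComposition, k1: float, k2: float) -> float:
    total = 0.0
    for sym, w in m.weights.items():
        e = ELEMENTS[sym]
        total += _term(e.Z, e.A, w, k1, k2)
    if m.residual is not None:
        w_res, zbar = m.residual
        total += _term(zbar, RESIDUAL_A_FACTOR * zbar, w_res, k1, k2)
    return total


def mu_ratio(m: MaterialComposition, k1: float, k2: float) -> float:
    """Linear attenuation coefficient relative to water at (k1, k2).

    Water returns exactly 1 for any (k1, k2) because its numerator equals
    the denominator by construction.  At k1 = k2 = 0 the expression
    collapses to the relative electron density.
    """
    return (m.rho / WATER.rho) * _electron_cross_sum(m, k1, k2) / \
        _electron_cross_sum(WATER, k1, k2)


def hu_to_ratio(hu: float, alpha: float = 1.0) -> float:
    """Invert a CT number to its implied mu/mu_w: H/(1000*alpha) + 1."""
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return hu / (1000.0 * alpha) + 1.0


def theoretical_hu(m: MaterialComposition, p: AttenuationParams) -> float:
    """Theoretical CT number: 1000 * alpha * (mu/mu_w - 1).

    With ``alpha`` absent (two-parameter model) the scale is 1.  Water maps
    to exactly 0 HU for any alpha; a vanishing mu/mu_w maps to -1000*alpha.
    """
    alpha = 1.0 if p.alpha is None else p.alpha
    return 1000.0 * alpha * (mu_ratio(m, p.k1, p.k2) - 1.0)


def _is_water_equivalent(m: MaterialComposition) -> bool:
    # Water's mu/mu_w is parameter-independent and exactly 1; its CT-number
    # residual therefore carries no information about (k1, k2, alpha) except
    # through measurement error, so it is excluded from the 3-parameter fit.
    probes = [(0.0, 0.0), (2e-3, 1e-4)]
    return all(abs(mu_ratio(m, *kk) - 1.0) < 1e-12 for kk in probes)


def _distinct_elements(materials: Sequence[MaterialComposition]) -> int:
    symbols: set[str] = set()
    for m in materials:
        symbols.update(sym for sym, w in m.weights.items() if w > 0)
    return len(symbols)


def _run_fit(
    data: Sequence[CTMeasurement],
    three_param: bool,
    x0: Optional[Sequence[float]] = None,
    fix_alpha: Optional[float] = None,
) -> FitResult:
    if len(data) < 2:
        raise ValueError("at least 2 CT measurements are required for a fit")
    if three_param:
        data = [d for d in data if not _is_water_equivalent(d.material)]
        if len(data) < 2:
            raise ValueError(
                "fewer than 2 informative (non-water) measurements remain"
            )
    materials = [d.material for d in data]
    hu = np.array([d.hu for d in data])
    free_alpha = three_param and fix_alpha is None

    def residual_vec(x: np.ndarray) -> np.ndarray:
        k1, k2 = x[0], x[1]
        if free_alpha:
            alpha = np.exp(x[2])
        else:
            alpha = fix_alpha if three_param else 1.0
        model = np.array([mu_ratio(m, k1, k2) for m in materials])
        return model - (hu / (1000.0 * alpha) + 1.0)

    if x0 is None:
        x0 = [DEFAULT_K1, DEFAULT_K2] + ([np.log(DEFAULT_ALPHA)] if free_alpha else [])
    else:
        x0 = list(x0[:2]) + ([np.log(x0[2])] if free_alpha else [])

    # Characteristic parameter scales: under-determined fits then take
    # minimum-norm steps in natural units and stay near the initialization
    # instead of drifting along the flat direction of the objective.
    x_scale = [DEFAULT_K1, DEFAULT_K2] + ([0.05] if free_alpha else [])
    sol = least_squares(
        residual_vec, x0, method="trf", x_scale=x_scale,
        ftol=1e-15, xtol=1e-15, gtol=1e-15, max_nfev=10_000,
    )
    k1, k2 = float(sol.x[0]), float(sol.x[1])
    if three_param:
        alpha = float(np.exp(sol.x[2])) if free_alpha else float(fix_alpha)
    else:
        alpha = None
    params = AttenuationParams(k1, k2, alpha)
    if sol.status <= 0:
        raise ConvergenceError(
            f"least-squares fit did not converge: {sol.message}", params
        )

    n_free = 3 if three_param else 2
    n_elem = _distinct_elements(materials)
    return FitResult(
        params=params,
        model="three_param" if three_param else "two_param",
        residuals=np.asarray(sol.fun, dtype=float),
        n_materials=len(data),
        n_elements=n_elem,
        identifiable=(len(data) >= n_free and n_elem >= MIN_ELEMENTS_IDENTIFIABLE),
        material_names=tuple(m.name for m in materials),
    )


def fit_two_param(
    data: Sequence[CTMeasurement], x0: Optional[Sequence[float]] = None
) -> FitResult:
    """Fit (k1, k2) of the conventional model to measured CT numbers.

    Residuals are taken in mu/mu_w space, ``mu/mu_w(k1,k2) - (H/1000 + 1)``,
    which weights dense materials differently than an HU-space fit would.
    """
    return _run_fit(data, three_param=False, x0=x0)


def fit_three_param(
    data: Sequence[CTMeasurement],
    x0: Optional[Sequence[float]] = None,
    fix_alpha: Optional[float] = None,
) -> FitResult:
    """Fit (k1, k2, alpha) to measured CT numbers.

    ``fix_alpha`` freezes the HU scale at a given value and optimizes only
    (k1, k2); with ``fix_alpha=1`` the fit is exactly the two-parameter model.

    Water-equivalent measurements are excluded automatically (their
    residual is alpha-independent at H = 0 and carries no constraint).
    Fits to fewer materials than parameters are returned but flagged
    unidentifiable; the optimizer then stays near its initialization,
    which is the intended audit behaviour with only two insert materials.
    Alpha is kept positive through an internal log-parameterization;
    k1 and k2 are unbounded and may go slightly negative on noisy data.
    """
    return _run_fit(data, three_param=True, x0=x0, fix_alpha=fix_alpha)
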