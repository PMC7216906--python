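"""Elemental data, material compositions, and electron-density arithmetic.

A material is described by its mass density rho (g/cm^3) and elemental
weight fractions.  Minor ("residual") elements may be lumped into a single
pseudo-element characterised by their total weight fraction ``w_res`` and
mean atomic number ``zbar_res``; the pseudo-element's atomic mass is taken
as ``2.1 * zbar_res``, which holds to good approximation for the trace
elements found in human tissue (Na, Mg, S, Cl, K, Fe, I).

Electron densities are computed from the electron sum ``sum_i w_i Z_i / A_i``
and referenced to water (11.19 % H, 88.81 % O by weight, rho = 1 g/cm^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

__all__ = [
    "Element",
    "ELEMENTS",
    "PseudoElement",
    "MaterialComposition",
    "WATER",
    "RESIDUAL_A_FACTOR",
    "normalize_weights",
    "aggregate_residual",
    "electron_sum",
    "relative_electron_density",
]

# Atomic mass of the residual pseudo-element per unit mean atomic number.
RESIDUAL_A_FACTOR = 2.1


@dataclass(frozen=True)
class Element:
    """A chemical element: symbol, atomic number Z, standard atomic mass A (u)."""

    symbol: str
    Z: int
    A: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"atomic number must be >= 1, got {self.Z}")
        if self.A <= 0:
            raise ValueError(f"atomic mass must be positive, got {self.A}")


# IUPAC 2021 standard atomic weights (conventional values for intervals).
ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in [
        Element("H", 1, 1.008),
        Element("C", 6, 12.011),
        Element("N", 7, 14.007),
        Element("O", 8, 15.999),
        Element("F", 9, 18.998),
        Element("Na", 11, 22.990),
        Element("Mg", 12, 24.305),
        Element("Al", 13, 26.982),
        Element("Si", 14, 28.085),
        Element("P", 15, 30.974),
        Element("S", 16, 32.06),
        Element("Cl", 17, 35.45),
        Element("Ar", 18, 39.95),
        Element("K", 19, 39.098),
        Element("Ca", 20, 40.078),
        Element("Fe", 26, 55.845),
        Element("Sr", 38, 87.62),
        Element("I", 53, 126.904),
        Element("Ba", 56, 137.327),
    ]
}


@dataclass(frozen=True)
class PseudoElement:
    """Residual-element lump with mean atomic number Zbar and A = 2.1 * Zbar."""

    Zbar: float

    def __post_init__(self) -> None:
        if self.Zbar <= 0:
            raise ValueError(f"mean atomic number must be positive, got {self.Zbar}")

    @property
    def A(self) -> float:
        return RESIDUAL_A_FACTOR * self.Zbar


# Weight-sum closure bands (fractional deviation from unity).
_CLOSURE_SILENT = 0.005
_CLOSURE_WARN = 0.05


@dataclass(frozen=True)
class MaterialComposition:
    """A material's mass density and elemental weight fractions.

    Parameters
    ----------
    name
        Material label.
    rho
        Mass density in g/cm^3 (may be ~1e-3 for air-like materials).
    weights
        Mapping from element symbol to weight fraction in [0, 1].
    residual
        Optional ``(w_res, zbar_res)`` pair lumping minor elements into a
        pseudo-element; ``None`` means no residual contribution.
    """

    name: str
    rho: float
    weights: Mapping[str, float] = field(default_factory=dict)
    residual: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError(f"{self.name}: mass density must be positive")
        for sym, w in self.weights.items():
            if sym not in ELEMENTS:
                raise KeyError(f"{self.name}: unknown element symbol {sym!r}")
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{self.name}: weight fraction of {sym} outside [0, 1]")
        if self.residual is not None:
            w_res, zbar = self.residual
            if not 0.0 <= w_res <= 1.0:
                raise ValueError(f"{self.name}: residual weight outside [0, 1]")
            if zbar <= 0:
                raise ValueError(f"{self.name}: residual mean Z must be positive")
        object.__setattr__(self, "weights", dict(self.weights))

    @property
    def weight_sum(self) -> float:
        total = sum(self.weights.values())
        if self.residual is not None:
            total += self.residual[0]
        return total

    @property
    def w_res(self) -> float:
        return self.residual[0] if self.residual is not None else 0.0


WATER = MaterialComposition("water", 1.000, {"H": 0.1119, "O": 0.8881})


def normalize_weights(m: MaterialComposition) -> MaterialComposition:
    """Rescale weight fractions (including any residual) to sum exactly to 1.

    Sums within 0.5 % of unity are normalized silently; within 5 % a warning
    is emitted; beyond that the composition is rejected as malformed.  The
    mass density is never altered.  Idempotent.
    """
    total = m.weight_sum
    dev = abs(total - 1.0)
    if dev > _CLOSURE_WARN:
        raise ValueError(
            f"{m.name}: weight fractions sum to {total:.4f}; "
            f"more than 5% from unity — malformed composition"
        )
    if dev > _CLOSURE_SILENT:
        warnings.warn(
            f"{m.name}: weight fractions sum to {total:.4f}; normalizing",
            stacklevel=2,
        )
    if total == 1.0:
        return m
    scale = 1.0 / total
    weights = {sym: w * scale for sym, w in m.weights.items()}
    residual = None
    if m.residual is not None:
        residual = (m.residual[0] * scale, m.residual[1])
    return replace(m, weights=weights, residual=residual)


def aggregate_residual(minor: Mapping[str, float]) -> tuple[float, Optional[float]]:
    """Lump minor-element weights into ``(w_res, zbar_res)``.

    ``w_res`` is the summed weight fraction and ``zbar_res`` the
    weight-averaged atomic number of the minor elements.  An all-zero input
    yields ``(0.0, None)`` since the mean atomic number is then undefined.
    """
    if any(w < 0 for w in minor.values()):
        raise ValueError("minor-element weights must be non-negative")
    w_res = sum(minor.values())
    if w_res == 0.0:
        return 0.0, None
    zbar = sum(ELEMENTS[sym].Z * w for sym, w in minor.items()) / w_res
    return w_res, zbar


def electron_sum(m: MaterialComposition) -> float:
    """Electrons per unit mass, ``sum_i w_i Z_i / A_i`` (mol electrons / g).

    The residual pseudo-element contributes ``w_res * Zbar / (2.1 * Zbar)
    = w_res / 2.1``, independent of its mean atomic number.
    """
    total = sum(
        w * ELEMENTS[sym].Z / ELEMENTS[sym].A for sym, w in m.weights.items()
    )
    if m.residual is not None:
        total += m.residual[0] / RESIDUAL_A_FACTOR
    return total


_WATER_ELECTRON_SUM = electron_sum(WATER)


def relative_electron_density(m: MaterialComposition) -> float:
    """Electron density relative to water: (rho / rho_w) * S(m) / S(water)."""
    return (m.rho / WATER.rho) * electron_sum(m) / _WATER_ELECTRON_SUM
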