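"""Bundled material and tissue datasets.

Three groups of compositions ship with the package:

* the Kyoto Kagaku audit-phantom materials (tough water, tough lung, tough
  bone), both the manufacturer specifications and elemental-analyzer
  measurements;
* eleven representative human tissues derived from the ICRP-110 adult
  reference computational phantoms (air through hydroxyapatite), each with
  its published mass density and relative electron density;
* common tissue-equivalent plastics defined by chemical formula (LDPE,
  PMP, polystyrene, acrylic/PMMA, Delrin/POM, Teflon/PTFE) plus water
  and dry air.

All weight entries below are in percent as published; compositions are
normalized to unit weight sum on construction.
"""

from __future__ import annotations

from typing import Optional

from .materials import ELEMENTS, MaterialComposition, normalize_weights

__all__ = [
    "AUDIT_PHANTOM_MATERIALS",
    "REPRESENTATIVE_TISSUE_DATA",
    "FORMULA_MATERIALS",
    "get_material",
    "known_materials",
    "from_formula",
]


def _pct(name: str, rho: float, weights_pct: dict[str, float],
         residual: Optional[tuple[float, float]] = None) -> MaterialComposition:
    w = {sym: v / 100.0 for sym, v in weights_pct.items()}
    res = (residual[0] / 100.0, residual[1]) if residual is not None else None
    return normalize_weights(MaterialComposition(name, rho, w, res))


# Kyoto Kagaku audit-phantom materials.  Oxygen in the measured columns was
# determined by difference so those columns close to 100 % by construction;
# the 0.01 % "unknown" in measured tough bone is dropped and recovered by
# normalization.
AUDIT_PHANTOM_MATERIALS: dict[str, MaterialComposition] = {
    m.name: m
    for m in [
        _pct("tough_water", 1.018,
             {"H": 8.63, "C": 68.89, "N": 2.18, "O": 17.88, "Cl": 0.15,
              "Ca": 2.27}),
        _pct("tough_lung_manufacturer", 0.370,
             {"H": 7.00, "C": 50.20, "O": 35.10, "Al": 1.50, "Si": 5.00,
              "P": 0.10, "Cl": 1.00}),
        _pct("tough_bone_manufacturer", 1.500,
             {"H": 5.11, "C": 42.45, "N": 1.73, "O": 28.13, "Al": 7.00,
              "Cl": 0.09, "Ca": 15.49}),
        _pct("tough_lung", 0.360,
             {"H": 6.01, "C": 63.41, "N": 0.37, "O": 29.16, "Na": 0.10,
              "Al": 0.18, "Si": 0.67, "P": 0.01, "S": 0.01, "Cl": 0.03,
              "K": 0.03, "Ca": 0.01, "Fe": 0.01}),
        _pct("tough_bone", 1.495,
             {"H": 5.29, "C": 42.73, "N": 1.96, "O": 29.42, "Na": 0.56,
              "Mg": 0.08, "Si": 0.03, "P": 6.01, "S": 0.02, "Cl": 0.29,
              "K": 0.05, "Ca": 13.54, "Sr": 0.01}),
    ]
}


# Eleven ICRP-110-derived representative tissues: name, rho (g/cm^3),
# published RED, major-element weights (%), residual (w_res %, mean Z).
REPRESENTATIVE_TISSUE_DATA: list[
    tuple[str, float, float, dict[str, float], Optional[tuple[float, float]]]
] = [
    ("Air", 0.001, 0.001,
     {"C": 0.01, "N": 75.52, "O": 23.17}, (1.30, 18.0)),
    ("Lung", 0.384, 0.381,
     {"H": 10.3, "C": 10.7, "N": 3.2, "O": 74.6, "P": 0.2}, (1.0, 15.9)),
    ("Extra Lung", 0.80, 0.79,
     {"H": 10.3, "C": 10.7, "N": 3.2, "O": 74.6, "P": 0.2}, (1.0, 15.9)),
    ("Fat", 0.90, 0.91,
     {"H": 11.96, "C": 76.87, "O": 11.17}, None),
    ("Adipose/Marrow", 0.950, 0.951,
     {"H": 11.40, "C": 58.92, "N": 0.74, "O": 28.64}, (0.30, 14.7)),
    ("Muscle/General", 1.049, 1.040,
     {"H": 10.25, "C": 14.58, "N": 3.20, "O": 70.87, "P": 0.21, "Ca": 0.02},
     (0.87, 16.8)),
    ("Miscellaneous", 1.090, 1.077,
     {"H": 9.94, "C": 20.90, "N": 3.84, "O": 63.73, "P": 0.45, "Ca": 0.27},
     (0.87, 15.5)),
    ("Heavy Spongiosa", 1.136, 1.115,
     {"H": 9.30, "C": 39.15, "N": 2.22, "O": 41.71, "P": 2.36, "Ca": 4.60},
     (0.66, 14.9)),
    ("Mineral Bone", 1.92, 1.784,
     {"H": 3.6, "C": 15.9, "N": 4.2, "O": 44.8, "P": 9.4, "Ca": 21.3},
     (0.8, 13.1)),
    ("Tooth", 2.75, 2.518,
     {"H": 2.2, "C": 9.5, "N": 2.9, "O": 42.1, "P": 13.7, "Ca": 28.9},
     (0.7, 12.0)),
    # Printed hydroxyapatite weights sum to 99.73 %; normalized on load.
    ("Hydroxyapatite", 3.156, 2.830,
     {"H": 0.20, "O": 41.14, "P": 18.50, "Ca": 39.89}, None),
]


def from_formula(name: str, rho: float, formula: dict[str, int]) -> MaterialComposition:
    """Build a composition from an empirical formula (element -> atom count)."""
    mass = {sym: n * ELEMENTS[sym].A for sym, n in formula.items()}
    total = sum(mass.values())
    return MaterialComposition(name, rho, {sym: m / total for sym, m in mass.items()})


FORMULA_MATERIALS: dict[str, MaterialComposition] = {
    m.name: m
    for m in [
        MaterialComposition("water", 1.000, {"H": 0.1119, "O": 0.8881}),
        from_formula("ldpe", 0.920, {"C": 1, "H": 2}),
        from_formula("pmp", 0.830, {"C": 6, "H": 12}),
        from_formula("polystyrene", 1.030, {"C": 8, "H": 8}),
        from_formula("acrylic", 1.180, {"C": 5, "H": 8, "O": 2}),
        from_formula("delrin", 1.420, {"C": 1, "H": 2, "O": 1}),
        from_formula("teflon", 2.160, {"C": 2, "F": 4}),
        # Dry air near sea level; argon kept explicit.
        _pct("air", 1.205e-3, {"N": 75.52, "O": 23.18, "Ar": 1.28, "C": 0.02}),
    ]
}


def known_materials() -> list[str]:
    """Names resolvable by :func:`get_material`."""
    names = list(AUDIT_PHANTOM_MATERIALS) + list(FORMULA_MATERIALS)
    names += [t[0] for t in REPRESENTATIVE_TISSUE_DATA]
    return names


def get_material(name: str) -> MaterialComposition:
    """Look up a bundled composition by name (case-insensitive)."""
    key = name.strip()
    for registry in (AUDIT_PHANTOM_MATERIALS, FORMULA_MATERIALS):
        for k, v in registry.items():
            if k.lower() == key.lower():
                return v
    for tname, rho, _red, weights, residual in REPRESENTATIVE_TISSUE_DATA:
        if tname.lower() == key.lower():
            return _pct(tname, rho, weights, residual)
    raise KeyError(
        f"unknown material {name!r}; known materials: {', '.join(known_materials())}"
    )
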