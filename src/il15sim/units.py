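"""Unit conversions between mass concentration, molarity and per-cell counts.

IL-15 doses are quoted in the experimental literature as ng/ml; the binding
equations work in molar concentration; receptor species are tracked as
molecules per cell.  Everything that crosses one of those boundaries goes
through this module so that the conversion factors live in exactly one place.

The membrane conversion factors ``xi_surf`` and ``xi_endo`` translate a
per-cell count of membrane-anchored molecules into an effective molar
concentration inside the thin spherical shell of the plasma or endosomal
membrane.  They are consumed as constants (M per molecule); the shell
geometry behind them is not re-derived here.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

__all__ = [
    "AVOGADRO",
    "Dose",
    "GeometryConstants",
    "UnitError",
    "dose_to_molar",
    "molar_to_dose",
    "surface_effective_conc",
    "percell_flux_to_media_rate",
]

AVOGADRO = 6.02214076e23  # mol^-1

_DOSE_UNITS = ("ng/ml", "nM", "M")


class UnitError(ValueError):
    """Raised for unknown unit tags or physically invalid quantities."""


@dataclass(frozen=True)
class Dose:
    """An IL-15 dose with an explicit unit tag (ng/ml, nM or M)."""

    value: float
    unit: str = "ng/ml"

    def __post_init__(self) -> None:
        if self.unit not in _DOSE_UNITS:
            raise UnitError(f"unknown dose unit {self.unit!r}; expected one of {_DOSE_UNITS}")
        if not self.value >= 0:
            raise UnitError(f"dose must be non-negative, got {self.value}")


@dataclass(frozen=True)
class GeometryConstants:
    """Geometric and conversion constants of the cell-culture system.

    Defaults describe 25,000 NK cells in 200 µl of media, with a total
    endosomal volume of 1e-14 L per cell.  ``MW_IL15`` is the effective molar
    mass that makes 1 ng/ml of IL-15 correspond to 0.0667 nM.
    """

    N_A: float = AVOGADRO
    V_m: float = 2e-4       # media volume, L
    V_e: float = 1e-14      # endosomal volume per cell, L
    N_tot: float = 25_000.0  # cells
    xi_surf: float = 1.1e-9  # M per molecule, plasma-membrane shell
    xi_endo: float = 1.5e-8  # M per molecule, endosomal-membrane shell
    MW_IL15: float = 15_000.0  # g/mol

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise UnitError(f"geometry constant {f.name} must be positive, got {v}")

    @classmethod
    def from_config(cls, path) -> "GeometryConstants":
        """Load constants from a flat key-value YAML/JSON file.

        Keys use the field names above (N_tot, V_m, V_e, xi_surf, xi_endo,
        ...); missing keys keep their defaults, unknown keys are ignored.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in raw.items() if k in known})


def dose_to_molar(d: Dose, g: GeometryConstants | None = None) -> float:
    """Convert a dose to molar concentration (M)."""
    g = g or GeometryConstants()
    if d.unit == "M":
        return d.value
    if d.unit == "nM":
        return d.value * 1e-9
    if d.unit == "ng/ml":
        # ng/ml -> g/L is a factor 1e-6; divide by molar mass for mol/L.
        return d.value * 1e-6 / g.MW_IL15
    raise UnitError(f"unknown dose unit {d.unit!r}")


def molar_to_dose(molar: float, unit: str = "ng/ml", g: GeometryConstants | None = None) -> Dose:
    """Inverse of :func:`dose_to_molar`; round-trips to within 1e-12 relative."""
    g = g or GeometryConstants()
    if molar < 0:
        raise UnitError(f"concentration must be non-negative, got {molar}")
    if unit == "M":
        return Dose(molar, "M")
    if unit == "nM":
        return Dose(molar * 1e9, "nM")
    if unit == "ng/ml":
        return Dose(molar * g.MW_IL15 * 1e6, "ng/ml")
    raise UnitError(f"unknown dose unit {unit!r}")


def surface_effective_conc(count: float, xi: float) -> float:
    """Effective molar concentration of ``count`` membrane molecules per cell.

    Linear in the count: ``count * xi`` with ``xi`` in M per molecule.
    """
    if count < 0:
        raise UnitError(f"molecule count must be non-negative, got {count}")
    return count * xi


def percell_flux_to_media_rate(flux: float, g: GeometryConstants | None = None) -> float:
    """Convert a per-cell molecular flux (molecules/cell/h) to a bulk media
    concentration rate (M/h).

    Multiplies by the cell count and divides by Avogadro's number times the
    media volume; the sign of the flux is preserved.
    """
    g = g or GeometryConstants()
    return flux * g.N_tot / (g.N_A * g.V_m)
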