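"""Pseudo-CT synthesis by bulk tissue-property assignment.

MR intensities carry no electron-density information, so dose calculation
on an MR-derived segmentation works by assigning each of the three tissue
classes a fixed mass density and attenuation coefficient ("bulk
assignment").  The same table is applied to the reference CT segmentation
and to the MR-derived ones, so plan comparisons probe segmentation
differences, not the absolute property values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .volume import AIR, BONE, SOFT, ImageVolume, LabelVolume


class PropertyTableError(ValueError):
    pass


@dataclass(frozen=True)
class ClassProperties:
    """Radiological properties of one tissue class at the beam's effective
    energy: mass density (g/cm^3), linear attenuation coefficient mu
    (1/cm), and mass energy-absorption coefficient mu_en/rho (cm^2/g)."""

    mass_density: float
    mu_linear: float
    mu_en_over_rho: float

    def __post_init__(self) -> None:
        if min(self.mass_density, self.mu_linear, self.mu_en_over_rho) < 0:
            raise PropertyTableError("tissue properties must be non-negative")


@dataclass(frozen=True)
class TissueProperties:
    """Bulk-assignment table over the three classes."""

    air: ClassProperties
    soft: ClassProperties
    bone: ClassProperties

    def __post_init__(self) -> None:
        for attr in ("mass_density", "mu_linear"):
            a, s, b = (getattr(getattr(self, c), attr) for c in ("air", "soft", "bone"))
            if not (a < s < b):
                raise PropertyTableError(
                    f"{attr} must increase strictly from air to soft to bone "
                    f"(got {a}, {s}, {b})"
                )

    def by_class(self) -> dict[int, ClassProperties]:
        return {AIR: self.air, SOFT: self.soft, BONE: self.bone}


def default_tissue_properties() -> TissueProperties:
    """Representative kV-beam properties at ~40 keV effective energy
    (70 kVp beam quality).

    Mass attenuation and energy-absorption coefficients are standard
    tabulated values for dry air, water-equivalent soft tissue and a
    cortical-bone surrogate; mu_linear = (mu/rho) * density.
    """
    return TissueProperties(
        air=ClassProperties(mass_density=0.0012, mu_linear=0.0012 * 0.2485, mu_en_over_rho=0.0671),
        soft=ClassProperties(mass_density=1.00, mu_linear=1.00 * 0.2683, mu_en_over_rho=0.0647),
        bone=ClassProperties(mass_density=1.60, mu_linear=1.60 * 0.6655, mu_en_over_rho=0.3026),
    )


def assign_properties(labels: LabelVolume, table: TissueProperties | None = None) -> dict[str, ImageVolume]:
    """Voxel-wise lookup of density, mu and mu_en/rho from a label map.

    Returns three volumes on the label grid, keyed ``density`` (g/cm^3),
    ``mu`` (1/cm) and ``mu_en_rho`` (cm^2/g).
    """
    if table is None:
        table = default_tissue_properties()
    data = labels.data
    bad = np.setdiff1d(np.unique(data), (AIR, SOFT, BONE))
    if bad.size:
        raise PropertyTableError(f"labels outside the three classes: {bad.tolist()}")
    per_class = table.by_class()
    out: dict[str, ImageVolume] = {}
    for key, attr in (("density", "mass_density"), ("mu", "mu_linear"), ("mu_en_rho", "mu_en_over_rho")):
        lut = np.array([getattr(per_class[t], attr) for t in (AIR, SOFT, BONE)])
        out[key] = labels.like(lut[data])
    return out


def properties_to_yaml(table: TissueProperties) -> str:
    doc = {
        name: {
            "mass_density": getattr(table, name).mass_density,
            "mu_linear": getattr(table, name).mu_linear,
            "mu_en_over_rho": getattr(table, name).mu_en_over_rho,
        }
        for name in ("air", "soft", "bone")
    }
    return yaml.safe_dump(doc, sort_keys=True)


def properties_from_yaml(text: str) -> TissueProperties:
    doc = yaml.safe_load(text)
    try:
        return TissueProperties(
            **{name: ClassProperties(**doc[name]) for name in ("air", "soft", "bone")}
        )
    except (KeyError, TypeError) as exc:
        raise PropertyTableError(f"malformed tissue-property table: {exc}") from exc
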