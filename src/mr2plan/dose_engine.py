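"""Kilovoltage photon dose engine for small-animal plans.

A deliberately simple, fully documented primary-photon model at a single
effective energy: for voxels inside the diverging rectangular field cone,

    dose  ∝  (SAD / r)^2 · exp(-∫ mu dl) · (mu_en/rho)(voxel),

with inverse-square divergence from a point source at source-axis distance
SAD, exact voxel-intersection (Siddon-style) radiological paths, sharp
collimation at the field edge, and no scatter.  Plans combine static beams
and arcs (discretised into equal-weight static beams) and are scaled so
the target volume-of-interest receives the prescription dose.

Geometry convention (right-handed, fixed axes): at gantry 0 / couch 0 the
source sits on +z above the isocenter.  The gantry angle rotates the
source about the y axis, then the couch angle rotates the result about the
z axis (couch rotation applied last to the source position, equivalently
first to the patient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume


class PlanError(ValueError):
    pass


class PrescriptionError(RuntimeError):
    pass


@dataclass(frozen=True)
class BeamSpec:
    """One static beam aimed at the isocenter."""

    gantry_angle: float
    couch_angle: float
    isocenter: tuple[float, float, float]
    field_size: tuple[float, float] = (3.0, 3.0)
    source_axis_distance: float = 350.0

    def __post_init__(self) -> None:
        if min(self.field_size) <= 0:
            raise PlanError("field_size must be positive")
        if self.source_axis_distance <= 0:
            raise PlanError("source-axis distance must be positive")


@dataclass(frozen=True)
class ArcSpec:
    """A gantry arc at fixed couch angle, discretised into static beams."""

    couch_angle: float
    isocenter: tuple[float, float, float]
    arc_span: float = 120.0
    angular_step: float = 5.0
    gantry_start: float | None = None  # None -> arc centred on gantry 0
    field_size: tuple[float, float] = (3.0, 3.0)
    source_axis_distance: float = 350.0

    def __post_init__(self) -> None:
        if self.arc_span <= 0:
            raise PlanError("arc_span must be positive")
        n = self.arc_span / self.angular_step
        if abs(n - round(n)) > 1e-9:
            raise PlanError("angular_step must divide arc_span")

    def beams(self) -> list[BeamSpec]:
        n = int(round(self.arc_span / self.angular_step))
        start = self.gantry_start if self.gantry_start is not None else -0.5 * self.arc_span
        return [
            BeamSpec(
                gantry_angle=start + (i + 0.5) * self.angular_step,
                couch_angle=self.couch_angle,
                isocenter=self.isocenter,
                field_size=self.field_size,
                source_axis_distance=self.source_axis_distance,
            )
            for i in range(n)
        ]


@dataclass(frozen=True)
class TargetSpec:
    """Spherical target volume-of-interest."""

    center: tuple[float, float, float]
    diameter: float = 2.5


@dataclass(frozen=True)
class PlanSpec:
    segments: tuple
    target: TargetSpec
    prescription_dose: float = 15.0
    prescription_mode: str = "mean"  # "mean" or "d50"

    def __post_init__(self) -> None:
        if not self.segments:
            raise PlanError("plan needs at least one segment")
        if self.prescription_dose <= 0:
            raise PlanError("prescription dose must be positive")
        if self.prescription_mode not in ("mean", "d50"):
            raise PlanError("prescription_mode must be 'mean' or 'd50'")

    def static_beams(self) -> list[BeamSpec]:
        beams: list[BeamSpec] = []
        for seg in self.segments:
            if isinstance(seg, ArcSpec):
                beams.extend(seg.beams())
            elif isinstance(seg, BeamSpec):
                beams.append(seg)
            else:
                raise PlanError(f"unknown segment type {type(seg)!r}")
        return beams


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _rotation(gantry_deg: float, couch_deg: float) -> np.ndarray:
    g = np.deg2rad(gantry_deg)
    c = np.deg2rad(couch_deg)
    ry = np.array([[np.cos(g), 0, np.sin(g)], [0, 1, 0], [-np.sin(g), 0, np.cos(g)]])
    rz = np.array([[np.cos(c), -np.sin(c), 0], [np.sin(c), np.cos(c), 0], [0, 0, 1]])
    return rz @ ry


def beam_frame(beam: BeamSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Source position and the beam's orthonormal frame (u, v, axis)."""
    rot = _rotation(beam.gantry_angle, beam.couch_angle)
    iso = np.asarray(beam.isocenter, dtype=float)
    source = iso + rot @ np.array([0.0, 0.0, beam.source_axis_distance])
    axis = (iso - source) / beam.source_axis_distance
    u = rot @ np.array([1.0, 0.0, 0.0])
    v = rot @ np.array([0.0, 1.0, 0.0])
    return source, u, v, axis


def sphere_voi(center: tuple[float, float, float], diameter: float, grid: ImageVolume) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within the sphere."""
    ax = grid.axes()
    cx, cy, cz = center
    r2 = (
        (ax[0] - cx)[:, None, None] ** 2
        + (ax[1] - cy)[None, :, None] ** 2
        + (ax[2] - cz)[None, None, :] ** 2
    )
    voi = r2 <= (diameter / 2.0) ** 2
    if not voi.any():
        raise PlanError("spherical VOI contains no voxel centres")
    return voi


# ---------------------------------------------------------------------------
# radiological paths (exact voxel-intersection line integrals)
# ---------------------------------------------------------------------------

def _radiological_paths(
    mu: ImageVolume, source: np.ndarray, points: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """Exact attenuation integrals from one source to many points.

    For each ray the parametric crossings with every grid plane are merged
    (Siddon's method, vectorised over rays); each inter-crossing segment
    lies in a single voxel, identified by its midpoint.  ``mu`` is in 1/cm,
    coordinates in mm; the result is dimensionless.
    """
    data = np.asarray(mu.data, dtype=float)
    source = np.asarray(source, dtype=float)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    spacing = np.asarray(mu.spacing)
    origin = np.asarray(mu.origin)
    shape = np.asarray(mu.shape)

    # voxel boundary planes per axis
    planes = [origin[a] - 0.5 * spacing[a] + spacing[a] * np.arange(shape[a] + 1) for a in range(3)]

    out = np.empty(points.shape[0])
    for lo in range(0, points.shape[0], chunk):
        pts = points[lo : lo + chunk]
        d = pts - source  # (R, 3)
        length = np.linalg.norm(d, axis=1)
        alphas = [np.full((pts.shape[0], 1), 0.0), np.full((pts.shape[0], 1), 1.0)]
        for a in range(3):
            da = d[:, a][:, None]
            safe = np.where(np.abs(da) > 1e-12, da, np.inf)
            al = (planes[a][None, :] - source[a]) / safe
            alphas.append(np.clip(al, 0.0, 1.0))
        al = np.sort(np.concatenate(alphas, axis=1), axis=1)
        seg = np.diff(al, axis=1)  # (R, S)
        mid_alpha = 0.5 * (al[:, :-1] + al[:, 1:])
        # voxel index of each segment midpoint, axis by axis
        idx = []
        valid = seg > 0
        for a in range(3):
            coord = source[a] + mid_alpha * d[:, a][:, None]
            ia = np.floor((coord - origin[a]) / spacing[a] + 0.5).astype(np.int64)
            valid &= (ia >= 0) & (ia < shape[a])
            idx.append(np.clip(ia, 0, shape[a] - 1))
        mu_seg = data[idx[0], idx[1], idx[2]]
        total = (np.where(valid, mu_seg, 0.0) * seg).sum(axis=1) * length
        out[lo : lo + chunk] = total / 10.0  # mm -> cm
    return out


def radiological_path(
    mu: ImageVolume, source: tuple[float, float, float], point: tuple[float, float, float]
) -> float:
    """Attenuation integral ∫ mu dl from ``source`` to ``point``
    (dimensionless; zero outside the grid)."""
    return float(_radiological_paths(mu, np.asarray(source, float), np.asarray(point, float))[0])


# ---------------------------------------------------------------------------
# dose computation
# ---------------------------------------------------------------------------

def _grid_coords_dot(grid: ImageVolume, source: np.ndarray, vec: np.ndarray) -> np.ndarray:
    """(p - source) . vec for every voxel centre p, via separable broadcasting."""
    ax = grid.axes()
    return (
        (ax[0] - source[0])[:, None, None] * vec[0]
        + (ax[1] - source[1])[None, :, None] * vec[1]
        + (ax[2] - source[2])[None, None, :] * vec[2]
    )


def _check_isocenter(grid: ImageVolume, isocenter) -> None:
    ax = grid.axes()
    for a in range(3):
        if not (ax[a][0] - grid.spacing[a] <= isocenter[a] <= ax[a][-1] + grid.spacing[a]):
            raise PlanError(f"isocenter outside grid along axis {a}: {isocenter[a]}")


def beam_dose(props: dict[str, ImageVolume], beam: BeamSpec) -> ImageVolume:
    """Primary-photon dose of one static beam, in arbitrary machine units.

    Voxels outside the diverging field cone receive exactly zero (sharp
    collimation).
    """
    mu = props["mu"]
    mu_en = props["mu_en_rho"]
    mu.check_same_grid(mu_en)
    _check_isocenter(mu, beam.isocenter)
    source, u, v, axis = beam_frame(beam)
    sad = beam.source_axis_distance

    t = _grid_coords_dot(mu, source, axis)  # distance along beam axis
    wu = _grid_coords_dot(mu, source, u)
    wv = _grid_coords_dot(mu, source, v)
    with np.errstate(divide="ignore", invalid="ignore"):
        lu = np.abs(wu) * sad / np.maximum(t, 1e-9)
        lv = np.abs(wv) * sad / np.maximum(t, 1e-9)
    infield = (t > 1e-3) & (lu <= beam.field_size[0] / 2) & (lv <= beam.field_size[1] / 2)

    dose = np.zeros(mu.shape)
    if not infield.any():
        return mu.like(dose)
    ii, jj, kk = np.nonzero(infield)
    ax = mu.axes()
    pts = np.stack([ax[0][ii], ax[1][jj], ax[2][kk]], axis=1)
    paths = _radiological_paths(mu, source, pts)
    r2 = ((pts - source) ** 2).sum(axis=1)
    vals = (sad**2 / r2) * np.exp(-paths) * np.asarray(mu_en.data)[ii, jj, kk]
    dose[ii, jj, kk] = vals
    return mu.like(dose)


def _voi_metric(doses: np.ndarray, mode: str) -> float:
    if mode == "mean":
        return float(doses.mean())
    # d50: minimum dose received by the hottest 50 % of the VOI
    return float(np.quantile(doses, 0.5))


def plan_dose_raw(props: dict[str, ImageVolume], plan: PlanSpec) -> ImageVolume:
    """Unscaled plan dose: equal-weight sum over all static beams (arcs
    discretised at their angular step)."""
    beams = plan.static_beams()
    total = np.zeros(props["mu"].shape)
    for beam in beams:
        total += beam_dose(props, beam).data
    return props["mu"].like(total)


def prescription_scale(dose: ImageVolume, plan: PlanSpec) -> float:
    """Scale factor taking a raw plan dose to the prescription."""
    voi = sphere_voi(plan.target.center, plan.target.diameter, dose)
    doses = np.asarray(dose.data)[voi]
    ref = _voi_metric(doses, plan.prescription_mode)
    if ref <= 0:
        raise PrescriptionError("zero dose in target; cannot prescribe")
    return plan.prescription_dose / ref


def plan_dose(props: dict[str, ImageVolume], plan: PlanSpec) -> tuple[ImageVolume, float]:
    """Plan dose in Gy, scaled so the target receives the prescription
    (mean-dose convention by default).  Returns ``(dose, scale)`` so the
    same machine scaling can be reapplied on a different property volume.
    """
    raw = plan_dose_raw(props, plan)
    scale = prescription_scale(raw, plan)
    return raw.like(raw.data * scale), scale
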