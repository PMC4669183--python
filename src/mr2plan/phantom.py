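"""Synthetic rat-head phantoms for MR-only planning experiments.

The generator produces a three-class label map (air / soft tissue / bone)
with the gross structure of a rodent head: an ellipsoidal brain wrapped in
a thin skull shell, a soft-tissue scalp layer outside the shell, a
posterior aperture where the spinal canal exits the skull, optional
internal air cavities (tympanic bullae, nasal passages), and thin anterior
bone septa that emulate the intricate rostrum.  From the labels it
synthesises multi-sequence MR volumes (class-mean intensities, a smooth
multiplicative bias field, Rician noise) and a Gaussian-noised reference
CT in Hounsfield units.

Voxels are pure-class; no partial-volume mixing is simulated.  Default
geometry: a 128^3 matrix with 275 x 500 x 275 um voxels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .volume import AIR, BONE, SOFT, ImageVolume, LabelVolume

#: Canonical ordering of the five supported MR sequences.
SEQUENCES = ("T1", "T2", "UTE1", "UTE2", "ZTE")

#: Sequences with appreciable bone signal (acquired at (near-)zero echo time).
SHORT_TE = ("UTE1", "ZTE")

#: Conventional sequences: bone is dark (signal decayed before readout).
CONVENTIONAL = ("T1", "T2", "UTE2")


class PhantomSizingError(ValueError):
    """The requested head does not fit the requested grid."""


class ConfigurationError(ValueError):
    """A required configuration entry is missing or inconsistent."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic rat head.

    ``head_axes`` are the semi-axes (mm) of the soft-tissue (brain)
    ellipsoid; skull and scalp are concentric shells outside it.
    ``rostrum_complexity`` counts thin anterior bone septa,
    ``n_air_cavities`` internal air pockets.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.275, 0.5, 0.275)
    head_axes: tuple[float, float, float] = (13.0, 22.0, 12.0)
    skull_thickness: float = 0.7
    scalp_thickness: float = 1.2
    neck_aperture_deg: float = 50.0
    n_air_cavities: int = 2
    rostrum_complexity: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(n <= 0 for n in self.grid_shape):
            raise PhantomSizingError(f"invalid grid shape {self.grid_shape}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomSizingError(f"spacing must be positive, got {self.spacing}")
        if any(a <= 0 for a in self.head_axes):
            raise PhantomSizingError(f"head axes must be positive, got {self.head_axes}")
        if self.skull_thickness < min(self.spacing):
            raise PhantomSizingError(
                "skull_thickness must span at least one voxel along the "
                f"finest axis: {self.skull_thickness} < {min(self.spacing)}"
            )
        axis_names = "xyz"
        for a in range(3):
            extent = 2 * (self.head_axes[a] + self.skull_thickness + self.scalp_thickness)
            available = self.grid_shape[a] * self.spacing[a] - 2 * self.spacing[a]
            if extent > available:
                raise PhantomSizingError(
                    f"head does not fit along {axis_names[a]}: needs {extent:.1f} mm, "
                    f"grid offers {available:.1f} mm"
                )

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple(0.5 * (n - 1) * s for n, s in zip(self.grid_shape, self.spacing))


@dataclass(frozen=True)
class SequenceModel:
    """Per-sequence intensity model.

    ``class_means`` maps tissue class -> mean signal (arbitrary units);
    ``noise_sigma`` is the Rician scale; the bias field is a smooth
    multiplicative field within ``1 +/- bias_amplitude`` with correlation
    length ``bias_smoothness`` (mm).
    """

    name: str
    class_means: dict[int, float]
    noise_sigma: float = 0.0
    bias_amplitude: float = 0.0
    bias_smoothness: float = 12.0

    def __post_init__(self) -> None:
        if self.name not in SEQUENCES:
            raise ConfigurationError(f"unknown sequence {self.name!r}; expected one of {SEQUENCES}")
        for t in (AIR, SOFT, BONE):
            if t not in self.class_means:
                raise ConfigurationError(f"{self.name}: class_means missing tissue class {t}")
            if self.class_means[t] < 0:
                raise ConfigurationError(f"{self.name}: negative class mean for class {t}")
        if self.name in CONVENTIONAL and not self.class_means[BONE] < self.class_means[SOFT]:
            raise ConfigurationError(
                f"{self.name}: bone must be darker than soft tissue on conventional sequences"
            )
        if self.name in SHORT_TE:
            if self.class_means[BONE] < self.class_means[AIR] + 3 * self.noise_sigma:
                raise ConfigurationError(
                    f"{self.name}: bone mean must exceed air mean by >= 3 sigma "
                    "(short-TE sequences must resolve bone from air)"
                )
        if not 0 <= self.bias_amplitude < 1:
            raise ConfigurationError("bias_amplitude must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")


def default_sequence_models(
    noise_fraction: float = 0.05, bias_amplitude: float = 0.3
) -> dict[str, SequenceModel]:
    """Default intensity tables for the five sequences.

    The numbers are synthetic (chosen for realistic contrast, not measured):
    bone carries essentially no signal on T1/T2/UTE2 and is hyperintense on
    UTE1/ZTE, which is the contrast that makes air/bone separation possible
    at all.  ``noise_fraction`` sets each sequence's Rician sigma as a
    fraction of its soft-tissue mean.
    """
    tables = {
        "T1": {AIR: 0.0, SOFT: 100.0, BONE: 12.0},
        "T2": {AIR: 0.0, SOFT: 90.0, BONE: 8.0},
        "UTE1": {AIR: 0.0, SOFT: 55.0, BONE: 75.0},
        "UTE2": {AIR: 0.0, SOFT: 80.0, BONE: 15.0},
        "ZTE": {AIR: 0.0, SOFT: 65.0, BONE: 85.0},
    }
    return {
        name: SequenceModel(
            name=name,
            class_means=means,
            noise_sigma=noise_fraction * means[SOFT],
            bias_amplitude=bias_amplitude,
        )
        for name, means in tables.items()
    }


#: Default Hounsfield means for the reference CT (configuration values).
DEFAULT_HU_MEANS = {AIR: -1000.0, SOFT: 40.0, BONE: 700.0}


@dataclass
class PhantomTruth:
    """Everything the generator knows about one synthetic animal."""

    spec: PhantomSpec
    labels: LabelVolume
    bias_fields: dict[str, ImageVolume]
    clean_images: dict[str, ImageVolume]
    noisy_images: dict[str, ImageVolume]
    ct: ImageVolume


# ---------------------------------------------------------------------------
# label map generation
# ---------------------------------------------------------------------------

def _ellipsoid_radius(spec: PhantomSpec, axes: tuple[float, float, float]) -> np.ndarray:
    """Normalised ellipsoidal radius of every voxel centre (1 on the surface)."""
    cx, cy, cz = spec.center
    grids = np.ogrid[0 : spec.grid_shape[0], 0 : spec.grid_shape[1], 0 : spec.grid_shape[2]]
    x = grids[0] * spec.spacing[0] - cx
    y = grids[1] * spec.spacing[1] - cy
    z = grids[2] * spec.spacing[2] - cz
    return np.sqrt((x / axes[0]) ** 2 + (y / axes[1]) ** 2 + (z / axes[2]) ** 2)


def generate_labels(spec: PhantomSpec) -> LabelVolume:
    """Generate the three-class rat-head label map.

    Structure, inside-out: brain ellipsoid (soft), skull shell (bone) with
    a posterior aperture, scalp shell (soft), air outside.  Adds
    ``n_air_cavities`` internal air pockets and ``rostrum_complexity`` thin
    bone septa in the anterior (+y) soft tissue.  Deterministic for a fixed
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    a = spec.head_axes
    outer_skull = tuple(ax + spec.skull_thickness for ax in a)
    outer_scalp = tuple(ax + spec.scalp_thickness for ax in outer_skull)

    r_brain = _ellipsoid_radius(spec, a)
    r_skull = _ellipsoid_radius(spec, outer_skull)
    r_scalp = _ellipsoid_radius(spec, outer_scalp)

    labels = np.full(spec.grid_shape, AIR, dtype=np.int16)
    labels[r_scalp <= 1.0] = SOFT            # scalp (and everything inside, for now)
    labels[(r_skull <= 1.0) & (r_brain > 1.0)] = BONE
    # brain interior stays SOFT

    # posterior aperture: the skull is open where the spinal canal exits.
    cx, cy, cz = spec.center
    gx, gy, gz = np.ogrid[0 : spec.grid_shape[0], 0 : spec.grid_shape[1], 0 : spec.grid_shape[2]]
    x = gx * spec.spacing[0] - cx
    y = gy * spec.spacing[1] - cy
    z = gz * spec.spacing[2] - cz
    rad = np.sqrt(x**2 + y**2 + z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        # angle from the posterior (-y) direction
        cos_post = np.where(rad > 0, -y / np.maximum(rad, 1e-12), 1.0)
    aperture = cos_post >= np.cos(np.deg2rad(spec.neck_aperture_deg / 2.0))
    labels[(labels == BONE) & aperture] = SOFT

    # internal air cavities, kept well inside the brain
    for _ in range(spec.n_air_cavities):
        frac = rng.uniform(-0.55, 0.55, size=3)
        centre = np.array([cx, cy, cz]) + frac * np.array(a)
        radius = rng.uniform(0.8, 1.4)
        dist = np.sqrt(
            (x + cx - centre[0]) ** 2 + (y + cy - centre[1]) ** 2 + (z + cz - centre[2]) ** 2
        )
        labels[(dist <= radius) & (r_brain <= 0.8)] = AIR

    # rostrum: thin coronal bone septa in the anterior soft tissue
    sep_thick = max(spec.spacing)
    for _ in range(spec.rostrum_complexity):
        y_frac = rng.uniform(0.45, 0.85)
        y_pos = y_frac * a[1]
        plate = (np.abs(y - y_pos) <= 0.5 * sep_thick) & (r_brain <= 0.95) & (labels == SOFT)
        labels[plate] = BONE

    for t, name in ((AIR, "air"), (SOFT, "soft"), (BONE, "bone")):
        if not np.any(labels == t):
            raise PhantomSizingError(f"generated phantom lost tissue class {name!r}")
    return LabelVolume(labels, spec.spacing)


def missegment_rostrum(
    labels: LabelVolume, spec: PhantomSpec, grow_mm: float = 0.3
) -> LabelVolume:
    """Deliberately corrupt the anterior bone, emulating a segmentation that
    overestimates the intricate rostrum.

    Anterior (y beyond 35 % of the head semi-axis) bone is dilated by
    ``grow_mm`` into adjacent soft tissue.  The result plays the role of an
    MR-derived segmentation whose rostrum errors bias single-beam dose
    calculations.
    """
    data = labels.data.copy()
    cy = spec.center[1]
    ny = labels.shape[1]
    ycoord = np.arange(ny) * spec.spacing[1] - cy
    anterior = ycoord > 0.35 * spec.head_axes[1]
    bone = data == BONE
    bone_ant = bone & anterior[None, :, None]
    iters = max(1, int(round(grow_mm / min(spec.spacing))))
    grown = ndimage.binary_dilation(bone_ant, iterations=iters)
    data[grown & (data == SOFT) & anterior[None, :, None]] = BONE
    return labels.like_labels(data)


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def synthesize_bias_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    amplitude: float,
    smoothness_mm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A smooth positive multiplicative field with mean exactly 1.

    Gaussian-filtered white noise (correlation length ``smoothness_mm``),
    centred and scaled so the field spans ``[1 - amplitude, 1 + amplitude]``.
    This low-frequency random field is deliberately not expressible in the
    estimator's model so that recovery tests are honest.
    """
    if amplitude == 0:
        return np.ones(shape)
    # synthesise on a coarse grid and spline-upsample: the field only has
    # structure at the smoothness scale, so this is exact to within the
    # interpolation error while much cheaper than full-resolution filtering
    factor = max(1, int(min(smoothness_mm / s for s in spacing) / 4))
    coarse_shape = tuple(max(4, -(-n // factor)) for n in shape)
    white = rng.standard_normal(coarse_shape)
    sigma_vox = [smoothness_mm / (s * factor) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    if factor > 1:
        zoom = [n / c for n, c in zip(shape, coarse_shape)]
        smooth = ndimage.zoom(smooth, zoom, order=3, mode="nearest", grid_mode=True)
        smooth = smooth[: shape[0], : shape[1], : shape[2]]
    smooth -= smooth.mean()
    peak = np.abs(smooth).max()
    if peak == 0:
        return np.ones(shape)
    return 1.0 + amplitude * smooth / peak


def simulate_mr(
    labels: LabelVolume, model: SequenceModel, seed: int
) -> tuple[ImageVolume, ImageVolume]:
    """Simulate one MR acquisition from a label map.

    Returns ``(noisy, bias)``: the clean image is a pure class-mean lookup;
    the bias field multiplies it; Rician noise of scale ``noise_sigma`` is
    applied to the biased image (magnitude reconstruction of two Gaussian
    quadrature channels).
    """
    rng = np.random.default_rng(seed)
    lut = np.array([model.class_means[t] for t in (AIR, SOFT, BONE)])
    clean = lut[labels.data]
    bias = synthesize_bias_field(
        labels.shape, labels.spacing, model.bias_amplitude, model.bias_smoothness, rng
    )
    biased = clean * bias
    if model.noise_sigma > 0:
        n_real = rng.normal(0.0, model.noise_sigma, labels.shape)
        n_imag = rng.normal(0.0, model.noise_sigma, labels.shape)
        noisy = np.sqrt((biased + n_real) ** 2 + n_imag**2)
    else:
        noisy = biased
    return labels.like(noisy), labels.like(bias)


def simulate_clean_mr(labels: LabelVolume, model: SequenceModel) -> ImageVolume:
    """Noise-free, bias-free class-mean image for a sequence."""
    lut = np.array([model.class_means[t] for t in (AIR, SOFT, BONE)])
    return labels.like(lut[labels.data])


def simulate_ct(
    labels: LabelVolume,
    hu_means: dict[int, float] | None = None,
    noise_sigma: float = 30.0,
    seed: int = 0,
) -> ImageVolume:
    """Gaussian-noised reference CT in Hounsfield units."""
    if hu_means is None:
        hu_means = DEFAULT_HU_MEANS
    for t in (AIR, SOFT, BONE):
        if t not in hu_means:
            raise ConfigurationError(f"hu_means missing tissue class {t}")
    rng = np.random.default_rng(seed)
    lut = np.array([hu_means[t] for t in (AIR, SOFT, BONE)])
    ct = lut[labels.data].astype(float)
    if noise_sigma > 0:
        ct = ct + rng.normal(0.0, noise_sigma, labels.shape)
    return labels.like(ct)


def generate_phantom(
    spec: PhantomSpec,
    models: dict[str, SequenceModel] | None = None,
    ct_noise_sigma: float = 30.0,
) -> PhantomTruth:
    """Generate a complete synthetic animal: labels, five MR volumes with
    known bias fields, and a reference CT.

    Per-stage seeds are derived deterministically from ``spec.seed``.
    """
    if models is None:
        models = default_sequence_models()
    labels = generate_labels(spec)
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(len(models) + 1)
    bias_fields: dict[str, ImageVolume] = {}
    clean: dict[str, ImageVolume] = {}
    noisy: dict[str, ImageVolume] = {}
    for child, name in zip(children, sorted(models, key=SEQUENCES.index)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        img, bias = simulate_mr(labels, models[name], seed=sub_seed)
        noisy[name] = img
        bias_fields[name] = bias
        clean[name] = simulate_clean_mr(labels, models[name])
    ct_seed = int(children[-1].generate_state(1)[0] % (2**31))
    ct = simulate_ct(labels, noise_sigma=ct_noise_sigma, seed=ct_seed)
    return PhantomTruth(spec, labels, bias_fields, clean, noisy, ct)


def phantom_sidecar(spec: PhantomSpec, models: dict[str, SequenceModel]) -> str:
    """JSON sidecar recording the full provenance of a simulated dataset."""
    payload = {
        "spec": asdict(spec),
        "models": {
            name: {
                "class_means": {int(k): v for k, v in m.class_means.items()},
                "noise_sigma": m.noise_sigma,
                "bias_amplitude": m.bias_amplitude,
                "bias_smoothness": m.bias_smoothness,
            }
            for name, m in models.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True)
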