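"""Bias-field estimation by coherent local intensity clustering (CLIC).

MR images are corrupted by a smooth multiplicative intensity field caused
by coil/field inhomogeneity.  CLIC models the observed image inside a mask
as ``I(x) = b(x) * J(x) + noise`` with ``J`` piecewise-constant over a few
tissue classes, and minimises the energy

    E(u, c, b) = sum_x sum_i u_i(x)^q  [ K * (I(x) - b(.) c_i)^2 ](x)

where ``K`` is a Gaussian window, ``c_i`` are class centroids and ``u_i``
fuzzy memberships.  Each block (memberships, centroids, bias) has a
closed-form minimiser given the other two, so cyclic updates decrease the
energy monotonically; all window sums reduce to Gaussian convolutions.

Only the estimated bias field is used downstream — the fuzzy
classification produced here is a by-product and is discarded; the actual
tissue segmentation is done separately after correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

log = logging.getLogger(__name__)

_EPS = 1e-12


class DegenerateInputError(ValueError):
    """The masked image cannot support bias estimation (e.g. all zero)."""


class NumericalStateError(RuntimeError):
    """An internal state violates a numerical invariant (e.g. bias <= 0)."""


@dataclass(frozen=True)
class ClicParams:
    """Tunables of the CLIC estimator.

    ``kernel_sigma`` is the Gaussian window scale in mm (the spatial extent
    over which the bias is assumed locally constant); ``fuzzifier_q`` the
    membership softness exponent; ``tol`` the relative energy-change
    stopping threshold.
    """

    n_classes: int = 3
    kernel_sigma: float = 2.0
    fuzzifier_q: float = 2.0
    max_iters: int = 50
    tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_sigma <= 0:
            raise ValueError("kernel_sigma must be positive")
        if self.fuzzifier_q <= 1:
            raise ValueError("fuzzifier_q must exceed 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.n_classes < 2:
            raise ValueError("need at least two classes")


@dataclass
class ClicState:
    """Result of a CLIC run: bias field (mean 1 over the mask), centroids,
    memberships over the mask, and the energy trace."""

    bias: ImageVolume
    centroids: np.ndarray
    memberships: np.ndarray  # (n_mask_voxels, n_classes)
    energy_trace: list[float]
    converged: bool
    mask: np.ndarray


def _masked_convolver(mask: np.ndarray, spacing, sigma_mm: float):
    sigma_vox = [sigma_mm / s for s in spacing]
    m = mask.astype(float)

    def conv(f: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(f * m, sigma=sigma_vox, mode="constant", truncate=3.0)

    return conv


def estimate_bias(image: ImageVolume, mask: np.ndarray, params: ClicParams | None = None) -> ClicState:
    """Estimate the multiplicative bias field of ``image`` inside ``mask``.

    Cyclic closed-form updates of memberships, centroids and bias, each the
    analytic minimiser of the CLIC energy with the other blocks fixed.
    Stops when the relative energy change drops below ``params.tol`` or
    after ``params.max_iters`` cycles (then returned with
    ``converged=False`` rather than raising).  The returned bias field has
    mean 1 over the mask; centroids are rescaled accordingly.
    """
    if params is None:
        params = ClicParams()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise DegenerateInputError("mask is empty")
    I = np.asarray(image.data, dtype=float)
    if np.any(I[mask] < 0):
        raise ValueError("image must be non-negative inside the mask")
    vals = I[mask]
    if np.max(vals) <= 0:
        raise DegenerateInputError("image is identically zero inside the mask")

    q = params.fuzzifier_q
    n_cls = params.n_classes
    conv = _masked_convolver(mask, image.spacing, params.kernel_sigma)

    # deterministic quantile initialisation of centroids
    qs = np.linspace(10, 90, n_cls)
    centroids = np.percentile(vals, qs).astype(float)
    centroids = np.maximum(centroids, _EPS)

    bias = np.ones_like(I)
    KM = conv(np.ones_like(I))  # K * mask, the local window normaliser
    I_m = np.where(mask, I, 0.0)

    u = np.full((int(mask.sum()), n_cls), 1.0 / n_cls)
    energy_trace: list[float] = []
    converged = False
    expo = -1.0 / (q - 1.0)

    for _ in range(params.max_iters):
        Kb = conv(bias)[mask]
        Kb2 = conv(bias**2)[mask]
        km = KM[mask]
        iv = I[mask]

        # distances d_i(x) = K*(I(x) - b c_i)^2, one per class
        d = (
            iv[:, None] ** 2 * km[:, None]
            - 2.0 * centroids[None, :] * iv[:, None] * Kb[:, None]
            + centroids[None, :] ** 2 * Kb2[:, None]
        )
        d = np.maximum(d, _EPS)

        # membership update (closed form)
        w = d**expo
        u = w / w.sum(axis=1, keepdims=True)

        # centroid update
        uq = u**q
        num = (uq * (iv * Kb)[:, None]).sum(axis=0)
        den = (uq * Kb2[:, None]).sum(axis=0)
        centroids = num / np.maximum(den, _EPS)

        # bias update: b(y) = sum_i c_i K*(u_i^q I) / sum_i c_i^2 K*(u_i^q)
        num_f = np.zeros_like(I)
        den_f = np.zeros_like(I)
        uq_full = np.zeros_like(I)
        for i in range(n_cls):
            uq_full[mask] = uq[:, i]
            num_f += centroids[i] * conv(uq_full * I_m)
            den_f += centroids[i] ** 2 * conv(uq_full)
        bias = np.where(den_f > _EPS, num_f / np.maximum(den_f, _EPS), 1.0)
        bias = np.maximum(bias, _EPS)

        # energy at the current (u, c, b)
        Kb = conv(bias)[mask]
        Kb2 = conv(bias**2)[mask]
        d = (
            iv[:, None] ** 2 * km[:, None]
            - 2.0 * centroids[None, :] * iv[:, None] * Kb[:, None]
            + centroids[None, :] ** 2 * Kb2[:, None]
        )
        energy = float((u**q * np.maximum(d, 0.0)).sum())
        energy_trace.append(energy)
        if len(energy_trace) >= 2:
            prev = energy_trace[-2]
            if abs(prev - energy) <= params.tol * max(abs(prev), _EPS):
                converged = True
                break

    if not converged:
        log.warning("CLIC did not converge within %d iterations", params.max_iters)

    mean_b = float(bias[mask].mean())
    bias = bias / mean_b
    centroids = centroids * mean_b
    return ClicState(
        bias=image.like(bias),
        centroids=centroids,
        memberships=u,
        energy_trace=energy_trace,
        converged=converged,
        mask=mask,
    )


def apply_correction(image: ImageVolume, state: ClicState, mask: np.ndarray | None = None) -> ImageVolume:
    """Divide out the estimated bias inside the mask; leave the outside
    untouched.  Mean intensity over the mask is preserved to ~1 % by the
    mean-1 normalisation of the bias."""
    if mask is None:
        mask = state.mask
    mask = np.asarray(mask, dtype=bool)
    b = np.asarray(state.bias.data, dtype=float)
    if np.any(b[mask] <= 0):
        raise NumericalStateError("bias field is non-positive inside the mask")
    out = np.asarray(image.data, dtype=float).copy()
    out[mask] = out[mask] / b[mask]
    return image.like(out)


def clic_energy(
    image: ImageVolume,
    mask: np.ndarray,
    bias: np.ndarray,
    centroids: np.ndarray,
    memberships: np.ndarray,
    params: ClicParams,
) -> float:
    """Independent evaluation of the CLIC energy at an arbitrary state.

    Used by tests to verify monotonicity of the internal trace.
    """
    mask = np.asarray(mask, dtype=bool)
    conv = _masked_convolver(mask, image.spacing, params.kernel_sigma)
    I = np.asarray(image.data, dtype=float)
    km = conv(np.ones_like(I))[mask]
    Kb = conv(bias)[mask]
    Kb2 = conv(bias**2)[mask]
    iv = I[mask]
    d = (
        iv[:, None] ** 2 * km[:, None]
        - 2.0 * centroids[None, :] * iv[:, None] * Kb[:, None]
        + centroids[None, :] ** 2 * Kb2[:, None]
    )
    return float((memberships**params.fuzzifier_q * np.maximum(d, 0.0)).sum())
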