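"""Synthetic inputs with analytically known structure, for tests and demos.

Three generators cover the toolkit's input space without any downloaded
data:

* uniform-phantom slice stacks (flat HU background, optional quadratic
  cupping-like trend, noise with a prescribed NPS) emulating repeat scans
  of the uniform module of an image-quality phantom;
* deformation vector fields built as sums of closed-form components
  (constant shifts, affine maps, Gaussian bumps), so the true displacement
  at every voxel — and at arbitrary off-grid points — is known exactly;
* registration cases: a ground-truth field plus a perturbed test field
  (constant bias + i.i.d. Gaussian component noise) together with the
  error statistics the perturbation implies in closed form. Since the
  per-voxel error magnitude is ``‖b + ε‖`` with ε ~ N(0, σ²I₃), the error
  follows σ·χ₃ when b = 0 and a noncentral-χ (3 d.o.f.) law otherwise.

Default geometry mirrors a 512²-matrix CBCT head protocol with 0.475 mm
pixels, scaled down to 128² for desk-scale runtimes; pass full-size shapes
explicitly where needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .dvf_evaluation import ErrorStats
from .noise_synthesis import NoiseSpec, make_pseudo_cbct
from .nps_estimation import NPSProfile1D
from .volume_io import ImageVolume, VectorField

__all__ = [
    "PhantomSpec",
    "SyntheticDeformationSpec",
    "flat_noise_profile",
    "generate_uniform_phantom",
    "generate_dvf",
    "evaluate_deformation",
    "generate_registration_case",
    "perturbation_error_stats",
]

# offset between the RNG streams of the two repeat scans
_SCAN2_SEED_OFFSET = 1 << 20


def flat_noise_profile(sigma: float, nyquist: float, n: int = 256) -> NPSProfile1D:
    """White-noise radial profile: constant power whose polar integral is σ².

    ``σ² = 2π ∫₀^F f·c df = π·c·F²`` fixes the level ``c = σ²/(π·F²)``.
    """
    if sigma < 0 or nyquist <= 0:
        raise ValueError("sigma must be >= 0 and nyquist > 0")
    c = sigma**2 / (np.pi * nyquist**2)
    freqs = np.linspace(0.0, nyquist, n)
    return NPSProfile1D(frequencies=freqs, power=np.full(n, c))


@dataclass
class PhantomSpec:
    """A uniform phantom scan recipe.

    ``trend`` is an optional 6-vector of 2D polynomial coefficients for
    the basis ``[1, x, y, x², x·y, y²]`` over coordinates normalized to
    [−1, 1] across the slice — enough to emulate the bowl-shaped cupping a
    real uniform phantom shows.
    """

    shape: tuple[int, int, int] = (20, 128, 128)  # (nz, ny, nx)
    spacing: tuple[float, float, float] = (0.475, 0.475, 2.5)  # (sx, sy, sz) mm
    background_hu: float = 0.0
    trend: Sequence[float] | None = None
    noise: NoiseSpec | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if self.trend is not None and len(self.trend) != 6:
            raise ValueError("trend must have 6 coefficients [1,x,y,x²,xy,y²]")


def _trend_slice(shape_yx: tuple[int, int], coeffs: Sequence[float]) -> np.ndarray:
    ny, nx = shape_yx
    y, x = np.mgrid[0:ny, 0:nx]
    xs = (2.0 * x / max(nx - 1, 1)) - 1.0
    ys = (2.0 * y / max(ny - 1, 1)) - 1.0
    c = np.asarray(coeffs, dtype=float)
    return (
        c[0] + c[1] * xs + c[2] * ys + c[3] * xs**2 + c[4] * xs * ys + c[5] * ys**2
    )


def generate_uniform_phantom(spec: PhantomSpec) -> tuple[ImageVolume, ImageVolume]:
    """Two repeat scans: identical deterministic trend, independent noise.

    The repeat scan makes subtraction detrending testable, exactly as a
    twice-scanned physical phantom would. Scan 2 uses an RNG stream offset
    from scan 1 so the realizations are independent but both reproducible.
    """
    nz, ny, nx = spec.shape
    base = np.full((nz, ny, nx), float(spec.background_hu))
    if spec.trend is not None:
        base += _trend_slice((ny, nx), spec.trend)[None, :, :]
    clean = ImageVolume(voxels=base, spacing=np.asarray(spec.spacing, dtype=float))
    if spec.noise is None:
        return clean, ImageVolume(voxels=base.copy(), spacing=clean.spacing.copy())
    n1 = spec.noise
    n2 = NoiseSpec(
        source=n1.source,
        profile_or_params=n1.profile_or_params,
        target_sigma=n1.target_sigma,
        seed=n1.seed + _SCAN2_SEED_OFFSET,
    )
    return make_pseudo_cbct(clean, n1), make_pseudo_cbct(clean, n2)


@dataclass
class SyntheticDeformationSpec:
    """A DVF as a sum of closed-form components.

    Component types (world coordinates p = (x, y, z) in mm):

    * ``constant``: ``u(p) = d`` — params ``{"displacement": (dx, dy, dz)}``
    * ``affine``: ``u(p) = A·p + t`` — params ``{"matrix": 3×3, "translation": 3}``
    * ``gaussian_bump``: ``u(p) = d·exp(−Σᵢ((pᵢ−cᵢ)/wᵢ)²)`` — params
      ``{"center": 3, "peak": (dx, dy, dz), "width": scalar or 3}`` (mm);
      the displacement magnitude peaks at ``‖d‖`` at the bump centre.
    """

    shape: tuple[int, int, int] = (32, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)
    components: list[dict] = field(default_factory=list)
    direction_tag: str = "SOT->EOT"

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(s <= 0 for s in self.spacing):
            raise ValueError("shape and spacing must be positive")
        for comp in self.components:
            if comp.get("type") not in ("constant", "affine", "gaussian_bump"):
                raise ValueError(f"unknown component type {comp.get('type')!r}")
            if comp["type"] == "gaussian_bump":
                w = np.broadcast_to(np.asarray(comp["width"], dtype=float), (3,))
                if np.any(w <= 0):
                    raise ValueError("bump widths must be > 0")


def evaluate_deformation(
    spec: SyntheticDeformationSpec, points_xyz: np.ndarray
) -> np.ndarray:
    """Closed-form displacement (mm) of the spec at arbitrary world points."""
    pts = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    disp = np.zeros_like(pts)
    for comp in spec.components:
        if comp["type"] == "constant":
            disp += np.asarray(comp["displacement"], dtype=float)[None, :]
        elif comp["type"] == "affine":
            A = np.asarray(comp["matrix"], dtype=float)
            t = np.asarray(comp["translation"], dtype=float)
            disp += pts @ A.T + t[None, :]
        else:  # gaussian_bump
            c = np.asarray(comp["center"], dtype=float)
            d = np.asarray(comp["peak"], dtype=float)
            w = np.broadcast_to(np.asarray(comp["width"], dtype=float), (3,))
            arg = np.sum(((pts - c[None, :]) / w[None, :]) ** 2, axis=1)
            disp += d[None, :] * np.exp(-arg)[:, None]
    return disp.reshape(np.shape(points_xyz))


def generate_dvf(spec: SyntheticDeformationSpec) -> VectorField:
    """Evaluate the component sum on the grid."""
    nz, ny, nx = spec.shape
    sx, sy, sz = spec.spacing
    z, y, x = np.mgrid[0:nz, 0:ny, 0:nx]
    pts = np.stack([x * sx, y * sy, z * sz], axis=-1).reshape(-1, 3)
    vecs = evaluate_deformation(spec, pts).reshape(nz, ny, nx, 3)
    return VectorField(
        vectors=vecs,
        spacing=np.array([sx, sy, sz]),
        direction_tag=spec.direction_tag,
    )


def perturbation_error_stats(
    bias: Sequence[float], sd: float, n: int, threshold: float = 2.0
) -> ErrorStats:
    """Expected error statistics of ``‖b + ε‖``, ε ~ N(0, sd²·I₃), n samples.

    sd = 0 is exact; otherwise the error follows ``sd·χ₃`` (b = 0) or the
    square root of ``sd²·χ'²₃(‖b‖²/sd²)``. The expected max is reported as
    the median of the max order statistic, ``F⁻¹(0.5^(1/n))`` —
    deterministic and within the spread of an observed maximum.
    """
    b = float(np.linalg.norm(np.asarray(bias, dtype=float)))
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        frac = 100.0 if b < threshold else 0.0
        return ErrorStats(mean=b, median=b, max=b, frac_lt_2mm=frac, n=n)
    if b == 0:
        dist = stats.chi(3, scale=sd)
        mean, median = float(dist.mean()), float(dist.median())
        frac = 100.0 * float(dist.cdf(threshold))
        emax = float(dist.ppf(0.5 ** (1.0 / n)))
    else:
        nc = (b / sd) ** 2
        q = stats.ncx2(df=3, nc=nc)  # law of (error/sd)²
        mean = sd * float(
            integrate.quad(lambda u: np.sqrt(u) * q.pdf(u), 0, np.inf, limit=200)[0]
        )
        median = sd * float(np.sqrt(q.ppf(0.5)))
        frac = 100.0 * float(q.cdf((threshold / sd) ** 2))
        emax = sd * float(np.sqrt(q.ppf(0.5 ** (1.0 / n))))
    return ErrorStats(mean=mean, median=median, max=emax, frac_lt_2mm=frac, n=n)


def generate_registration_case(
    spec: SyntheticDeformationSpec,
    bias: Sequence[float] = (0.0, 0.0, 0.0),
    sd: float = 0.0,
    seed: int = 0,
) -> tuple[VectorField, VectorField, ErrorStats]:
    """Ground-truth field, perturbed test field, and the implied error stats.

    ``test = gt + bias + N(0, sd²)`` per component, i.i.d. across voxels.
    The returned statistics are the closed-form expectations from
    `perturbation_error_stats`; comparing them against the measured
    statistics of the evaluation module is the toolkit's end-to-end
    self-test.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    gt = generate_dvf(spec)
    rng = np.random.default_rng(seed)
    pert = np.asarray(bias, dtype=float)[None, None, None, :]
    if sd > 0:
        pert = pert + rng.normal(0.0, sd, size=gt.vectors.shape)
    test = VectorField(
        vectors=gt.vectors + pert,
        spacing=gt.spacing.copy(),
        origin=gt.origin.copy(),
        direction_tag=f"dEOT->{gt.target}" if gt.target else gt.direction_tag,
    )
    n = int(np.prod(spec.shape))
    return gt, test, perturbation_error_stats(bias, sd, n)
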