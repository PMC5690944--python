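"""Synthesis of noise matched to a prescribed NPS, and pseudo-CBCT creation.

A 1D radial NPS (measured or modelled) is expanded to a 2D spectrum by
radial symmetry, a complex spectrum with that magnitude and random phases
is built, and the inverse FFT yields a real, zero-mean noise image whose
texture matches the prescription. Adding such per-slice noise to a CT
volume produces a "pseudo-CBCT": a volume with CT anatomy but CBCT-like
noise magnitude and texture, the standard trick for probing how image
noise alone affects downstream algorithms (e.g. deformable registration)
with everything else held fixed.

Phases are uniform random with Hermitian symmetry enforced exactly, and
the spectral *amplitudes are fixed* (not Rayleigh-distributed as for true
Gaussian noise): each realization then carries exactly the prescribed
power in every frequency bin, which makes texture and magnitude checks
sharp. The Gaussian alternative would multiply each amplitude by an
independent Rayleigh variate; ensemble averages agree either way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .nps_estimation import NPS2D, NPSProfile1D
from .nps_model import NPSParams, eval_nps_model
from .volume_io import ImageVolume

__all__ = [
    "NoiseSpec",
    "NoiseField",
    "profile_to_nps2d",
    "synthesize_noise_slice",
    "make_pseudo_cbct",
]


@dataclass
class NoiseSpec:
    """Recipe for noise generation.

    ``source`` selects whether the spectral shape comes from a measured 1D
    profile or from model parameters; ``target_sigma`` (HU), when set,
    rescales the spectrum so the per-slice noise magnitude is exactly σ.
    ``seed`` makes the realization deterministic.
    """

    source: str  # "profile" | "model"
    profile_or_params: NPSProfile1D | NPSParams
    target_sigma: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("profile", "model"):
            raise ValueError("source must be 'profile' or 'model'")
        if self.target_sigma is not None and self.target_sigma < 0:
            raise ValueError("target_sigma must be >= 0")
        expected = NPSProfile1D if self.source == "profile" else NPSParams
        if not isinstance(self.profile_or_params, expected):
            raise TypeError(
                f"source {self.source!r} requires a {expected.__name__}"
            )

    def radial_power(self) -> Callable[[np.ndarray], np.ndarray]:
        """The spectral shape as a function of radial frequency (0 beyond range)."""
        if self.source == "profile":
            prof = self.profile_or_params
            return lambda r: np.interp(r, prof.frequencies, prof.power, right=0.0)
        params = self.profile_or_params
        cutoff = params.a2 + 12.0 * params.a3
        return lambda r: np.where(r <= cutoff, eval_nps_model(params, r), 0.0)


@dataclass
class NoiseField:
    """Zero-mean noise realization in HU."""

    voxels: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("noise values must be finite")


def profile_to_nps2d(
    profile: NPSProfile1D, shape: Sequence[int], spacing: Sequence[float]
) -> NPS2D:
    """Expand a 1D radial profile to a 2D DFT-grid spectrum by symmetry.

    Every frequency bin gets the profile value at its radial frequency by
    linear interpolation; radii beyond the profile's range (the corners of
    the frequency square) get zero.
    """
    ny, nx = int(shape[0]), int(shape[1])
    dy, dx = float(spacing[0]), float(spacing[1])
    if dy <= 0 or dx <= 0:
        raise ValueError("spacing must be positive")
    template = NPS2D(power=np.zeros((ny, nx)), freq_spacing=(1.0 / (ny * dy), 1.0 / (nx * dx)))
    r = template.frequency_grid()
    power = np.interp(r, profile.frequencies, profile.power, right=0.0)
    return NPS2D(power=power, freq_spacing=template.freq_spacing)


def _hermitian_phases(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Random phase array φ with φ(−k) = −φ(k) exactly (unshifted grid)."""
    theta = rng.uniform(0.0, 2.0 * np.pi, size=shape)
    # θ(k) − θ(−k) is antisymmetric by construction; self-conjugate bins get 0
    conj = np.roll(np.flip(theta, axis=(0, 1)), shift=(1, 1), axis=(0, 1))
    return theta - conj


def synthesize_noise_slice(
    nps2d: NPS2D,
    spacing: Sequence[float],
    seed: int | np.random.Generator = 0,
) -> NoiseField:
    """One real 2D noise realization with the prescribed spectrum.

    The complex spectrum has magnitude ``sqrt(P·Nx·Ny/(Δx·Δy))`` and random
    Hermitian-symmetric phases, so the inverse DFT is real and — because the
    amplitudes are fixed — the periodogram of every single realization
    equals ``nps2d`` exactly. The DC bin is forced to zero, so the output
    mean is exactly zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dy, dx = float(spacing[0]), float(spacing[1])
    if dy <= 0 or dx <= 0:
        raise ValueError("spacing must be positive")
    ny, nx = nps2d.power.shape
    power = np.fft.ifftshift(nps2d.power)  # back to unshifted DFT layout
    mag = np.sqrt(power * nx * ny / (dx * dy))
    spectrum = mag * np.exp(1j * _hermitian_phases((ny, nx), rng))
    spectrum[0, 0] = 0.0
    noise = np.fft.ifft2(spectrum)
    return NoiseField(voxels=noise.real, spacing=(dy, dx))


def _grid_nps(spec: NoiseSpec, shape: tuple[int, int], spacing: tuple[float, float]) -> NPS2D:
    """Spectrum on the synthesis grid, DC zeroed, renormalized to σ if requested.

    The renormalization acts on the *discrete* spectrum (``sum·Δu·Δv = σ²``):
    combined with fixed-amplitude synthesis this makes the per-slice sample
    variance exactly σ², with no polar-integral discretization error.
    """
    ny, nx = shape
    dy, dx = spacing
    template = NPS2D(power=np.zeros(shape), freq_spacing=(1.0 / (ny * dy), 1.0 / (nx * dx)))
    r = template.frequency_grid()
    power = np.clip(spec.radial_power()(r), 0.0, None)
    c0 = ny // 2, nx // 2  # DC bin in the shifted layout
    power[c0] = 0.0
    if spec.target_sigma is not None:
        du_dv = template.freq_spacing[0] * template.freq_spacing[1]
        total = power.sum() * du_dv
        if total <= 0:
            if spec.target_sigma > 0:
                raise ValueError("zero-power noise source cannot reach a nonzero sigma")
        else:
            power = power * (spec.target_sigma**2 / total)
    return NPS2D(power=power, freq_spacing=template.freq_spacing)


def make_pseudo_cbct(ct: ImageVolume, spec: NoiseSpec) -> ImageVolume:
    """Add per-slice noise realizations to a CT volume.

    Each axial slice receives an independent 2D realization (slice k uses
    seed ``spec.seed + k``); there is no inter-slice noise correlation.
    Spacing, origin and shape are untouched, and no HU clipping is applied.
    """
    if spec.target_sigma == 0:
        return ImageVolume(
            voxels=ct.voxels.copy(), spacing=ct.spacing.copy(), origin=ct.origin.copy()
        )
    nz, ny, nx = ct.shape
    dy, dx = float(ct.spacing[1]), float(ct.spacing[0])
    nps2d = _grid_nps(spec, (ny, nx), (dy, dx))
    out = ct.voxels.copy()
    for k in range(nz):
        noise = synthesize_noise_slice(nps2d, (dy, dx), seed=spec.seed + k)
        out[k] += noise.voxels
    return ImageVolume(voxels=out, spacing=ct.spacing.copy(), origin=ct.origin.copy())
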