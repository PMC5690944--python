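"""Noise-power-spectrum estimation from uniform-phantom slice stacks.

The NPS quantifies noise *texture*: it resolves the noise variance of a
reconstructed CT/CBCT image over spatial frequency (units HU²·mm² versus
mm⁻¹). The measurement follows the standard uniform-phantom recipe: square
ROIs are sampled at a fixed radius from the slice centre, each ROI is
detrended (either by subtracting a paired repeat scan or by removing a
fitted 2D polynomial surface), the scaled 2D periodograms are ensemble
averaged, and — because reconstruction filters are isotropic to good
approximation — the 2D spectrum is collapsed to a 1D radial profile.

Normalization convention: ``NPS(u, v) = (Δx·Δy / (Nx·Ny)) · ⟨|DFT(ROI)|²⟩``
so that the integral of the NPS over the frequency plane equals the noise
variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .volume_io import ImageVolume

__all__ = [
    "ROISamplingSpec",
    "NPSProfile1D",
    "NPS2D",
    "extract_rois",
    "detrend_roi",
    "roi_nps_2d",
    "radial_profile",
    "nps_variance",
]


@dataclass
class ROISamplingSpec:
    """Geometry of ROI sampling on uniform-phantom slices.

    Defaults mirror a typical CBCT phantom analysis: 16 ROIs of 40 px per
    slice, centred on a circle of radius 80 px, over 20 slices.
    """

    roi_size_px: int = 40
    n_rois_per_slice: int = 16
    circle_radius_px: int = 80
    slice_indices: Sequence[int] = field(default_factory=lambda: range(20))

    def __post_init__(self) -> None:
        if self.roi_size_px < 8:
            raise ValueError("roi_size_px must be >= 8")
        if self.n_rois_per_slice < 1:
            raise ValueError("n_rois_per_slice must be >= 1")
        if self.circle_radius_px < 0:
            raise ValueError("circle_radius_px must be >= 0")
        self.slice_indices = list(self.slice_indices)
        if not self.slice_indices:
            raise ValueError("slice_indices must be non-empty")


@dataclass
class NPSProfile1D:
    """Radially averaged 1D NPS: power (HU²·mm²) vs frequency (mm⁻¹)."""

    frequencies: np.ndarray
    power: np.ndarray
    n_averaged: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.ndim != 1 or self.frequencies.shape != self.power.shape:
            raise ValueError("frequencies and power must be 1D arrays of equal length")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if abs(self.frequencies[0]) > 1e-12:
            raise ValueError("first frequency must be 0")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")
        self.power = np.clip(self.power, 0.0, None)

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])


@dataclass
class NPS2D:
    """DC-centred 2D NPS on a DFT frequency grid.

    ``freq_spacing`` is the frequency-bin width per array axis
    ``(Δf_row, Δf_col)`` = ``(1/(Ny·Δy), 1/(Nx·Δx))`` in mm⁻¹.
    """

    power: np.ndarray
    freq_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if self.power.ndim != 2:
            raise ValueError("power must be 2D")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")
        self.power = np.clip(self.power, 0.0, None)
        if any(f <= 0 for f in self.freq_spacing):
            raise ValueError("freq_spacing must be positive")

    def frequency_grid(self) -> np.ndarray:
        """Radial frequency (mm⁻¹) of every bin, DC-centred."""
        n0, n1 = self.power.shape
        f0 = np.fft.fftshift(np.fft.fftfreq(n0)) * n0 * self.freq_spacing[0]
        f1 = np.fft.fftshift(np.fft.fftfreq(n1)) * n1 * self.freq_spacing[1]
        return np.hypot(f0[:, None], f1[None, :])


def extract_rois(volume: ImageVolume, spec: ROISamplingSpec) -> list[np.ndarray]:
    """Sample square ROIs on a circle around each slice centre.

    ROI centres are spaced uniformly in angle starting at the +x axis and
    proceeding counter-clockwise; the ROI corner is rounded to the nearest
    integer pixel. Raises if any ROI would leave the image.
    """
    nz, ny, nx = volume.shape
    size = spec.roi_size_px
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    angles = 2.0 * np.pi * np.arange(spec.n_rois_per_slice) / spec.n_rois_per_slice
    patches: list[np.ndarray] = []
    for k in spec.slice_indices:
        if not 0 <= k < nz:
            raise ValueError(f"slice index {k} outside volume of {nz} slices")
        sl = volume.voxels[k]
        for th in angles:
            ccx = cx + spec.circle_radius_px * np.cos(th)
            ccy = cy + spec.circle_radius_px * np.sin(th)
            x0 = int(round(ccx - size / 2.0))
            y0 = int(round(ccy - size / 2.0))
            if x0 < 0 or y0 < 0 or x0 + size > nx or y0 + size > ny:
                raise ValueError(
                    f"ROI at angle {th:.3f} rad exceeds image bounds "
                    f"(corner ({y0},{x0}), size {size}, image {ny}x{nx})"
                )
            patches.append(sl[y0 : y0 + size, x0 : x0 + size].copy())
    return patches


def _poly2d_design(ny: int, nx: int, order: int = 2) -> np.ndarray:
    y, x = np.mgrid[0:ny, 0:nx]
    # normalize to [-1, 1] to keep the normal equations well conditioned
    xs = (2.0 * x / max(nx - 1, 1)) - 1.0
    ys = (2.0 * y / max(ny - 1, 1)) - 1.0
    cols = [
        xs**i * ys**j
        for j in range(order + 1)
        for i in range(order + 1 - j)
    ]
    return np.stack([c.ravel() for c in cols], axis=1)


def detrend_roi(
    patch: np.ndarray,
    method: Literal["poly2d", "subtraction"] = "poly2d",
    paired_patch: np.ndarray | None = None,
) -> np.ndarray:
    """Remove deterministic low-frequency structure from an ROI.

    ``poly2d`` subtracts the least-squares 2D polynomial surface of total
    order 2 (removes cupping-like trends while leaving the stochastic noise).
    ``subtraction`` returns ``(patch - paired_patch)/sqrt(2)`` where the pair
    comes from a repeat scan at the identical location; the √2 restores the
    noise power of a single scan.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2:
        raise ValueError("patch must be 2D")
    if method == "subtraction":
        if paired_patch is None:
            raise ValueError("subtraction detrending requires paired_patch")
        paired = np.asarray(paired_patch, dtype=float)
        if paired.shape != patch.shape:
            raise ValueError("paired_patch shape mismatch")
        return (patch - paired) / np.sqrt(2.0)
    if method == "poly2d":
        A = _poly2d_design(*patch.shape)
        coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
        return patch - (A @ coef).reshape(patch.shape)
    raise ValueError(f"unknown detrending method {method!r}")


def roi_nps_2d(
    patches: Sequence[np.ndarray], pixel_spacing: Sequence[float]
) -> NPS2D:
    """Ensemble-averaged, DC-centred 2D NPS of detrended ROIs.

    ``pixel_spacing`` is ``(Δ_row, Δ_col)`` in mm. No taper window is
    applied before the DFT.
    """
    if len(patches) == 0:
        raise ValueError("empty patch list")
    shape = np.asarray(patches[0]).shape
    if any(np.asarray(p).shape != shape for p in patches):
        raise ValueError("all patches must have the same size")
    dy, dx = float(pixel_spacing[0]), float(pixel_spacing[1])
    if dy <= 0 or dx <= 0:
        raise ValueError("pixel spacing must be positive")
    ny, nx = shape
    acc = np.zeros(shape)
    for p in patches:
        acc += np.abs(np.fft.fft2(np.asarray(p, dtype=float))) ** 2
    power = np.fft.fftshift(acc / len(patches) * (dx * dy) / (nx * ny))
    return NPS2D(power=power, freq_spacing=(1.0 / (ny * dy), 1.0 / (nx * dx)))


def radial_profile(nps2d: NPS2D) -> NPSProfile1D:
    """Collapse a (near-)radially-symmetric 2D NPS to a 1D radial profile.

    Annular bins are one DFT bin wide; bin k collects all grid points whose
    radial frequency rounds to ``k·Δf``. Each annular mean is located at the
    *actual* mean radius of its contributing points — at small k that mean
    deviates from k·Δf, and pretending otherwise biases the low-frequency
    (ramp-up) part of the profile — and the result is then interpolated onto
    the uniform axis. Profile length is ``⌊N/2⌋ + 1`` so the last frequency
    is the axis Nyquist.
    """
    df = float(max(nps2d.freq_spacing))
    r = nps2d.frequency_grid()
    idx = np.rint(r / df).astype(int)
    n = min(nps2d.power.shape)
    nbins = min(n // 2 + 1, int(idx.max()) + 1)
    power_sums = np.bincount(idx.ravel(), weights=nps2d.power.ravel())
    radius_sums = np.bincount(idx.ravel(), weights=r.ravel())
    counts = np.maximum(np.bincount(idx.ravel()), 1)
    mean_power = power_sums / counts
    mean_radius = radius_sums / counts
    mean_radius[0] = 0.0  # the DC bin sits exactly at zero frequency
    freqs = df * np.arange(nbins)
    prof = np.interp(freqs, mean_radius, mean_power)
    return NPSProfile1D(frequencies=freqs, power=prof)


def nps_variance(profile: NPSProfile1D) -> float:
    """Noise variance (HU²) implied by a radial profile.

    Integrates the radially symmetric 2D spectrum in polar coordinates:
    ``σ² = 2π ∫ f · NPS(f) df`` (trapezoidal rule).
    """
    return float(
        2.0 * np.pi * np.trapezoid(profile.frequencies * profile.power, profile.frequencies)
    )
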