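"""Synthetic phantom generator.

Produces smooth ground-truth water-shift and B1 fields on a brain-like
ellipsoidal support, simulates the corresponding 4-D WASABI and WASSR
acquisitions (magnitude signal, M0 scaling, additive noise), and provides
single-spectrum corruption operators that mimic the failure modes seen in
vivo: one-sided amplitude asymmetry, single-offset motion spikes, and
on-resonance depolarization producing reflected magnitude lobes.

Every generator is a pure function of (specification, seed): repeated calls
are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import FieldMaps
from .model import AcquisitionContext, WasabiParams, ZSpectrum, wasabi_forward

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "make_field_maps",
    "simulate_wasabi_volume",
    "simulate_wassr_volume",
    "corrupt_spectrum",
    "make_default_phantom",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic phantom.

    dw_field_range
        Water-shift extremes in ppm; +-0.5 ppm reflects a shimmed head.
    b1_field_range
        Relative-B1 extremes (fraction of nominal); the low end mimics
        peripheral/inferior regions where the transmit field sags below 50%.
    smoothness
        Gaussian correlation length of the fields, in voxels.
    noise_sigma
        Additive Gaussian noise std on the normalized signal scale.
    slice_b1_degradation
        How strongly the relative-B1 field is pulled toward its low end in
        the extreme slices (0 disables), emulating the degradation of
        superior/inferior slices in 3-D readouts.
    n_artifact_patches / artifact_magnitude / artifact_radius
        Small seeded spherical patches whose spectra receive a one-sided
        amplitude asymmetry (motion/imaging-artifact surrogate).
    """

    shape: tuple[int, int, int] = (24, 24, 6)
    dw_field_range: tuple[float, float] = (-0.5, 0.5)
    b1_field_range: tuple[float, float] = (0.4, 1.2)
    smoothness: float = 4.0
    noise_sigma: float = 0.02
    seed: int = 0
    b1_nominal: float = 3.7
    slice_b1_degradation: float = 0.5
    n_artifact_patches: int = 2
    artifact_magnitude: float = 0.25
    artifact_radius: float = 2.0

    def __post_init__(self) -> None:
        if not all(s >= 3 for s in self.shape):
            raise ValueError("phantom shape must be at least 3 voxels per axis")
        for rng_ in (self.dw_field_range, self.b1_field_range):
            if not np.all(np.isfinite(rng_)):
                raise ValueError("field ranges must be finite")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class CorruptionSpec:
    """A single-spectrum corruption: kind, strength, spectral location."""

    kind: str  # asymmetry | spike | depolarization-shortfall
    magnitude: float = 0.0
    location: float = 0.0  # ppm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("corruption magnitude must be >= 0")


def _smooth_unit_field(shape, smoothness, rng) -> np.ndarray:
    """Low-pass filtered seeded noise rescaled to [0, 1]."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=smoothness)
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (raw - lo) / (hi - lo)


def _ellipsoid_mask(shape) -> np.ndarray:
    axes = [np.linspace(-1, 1, s) for s in shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    # z semi-axis > 1 so even the extreme slices keep some support, the way
    # superior/inferior brain slices do
    return (xx / 0.85) ** 2 + (yy / 0.85) ** 2 + (zz / 1.25) ** 2 <= 1.0


def make_field_maps(spec: PhantomSpec) -> FieldMaps:
    """Smooth seeded ground-truth fields on an ellipsoidal support.

    Relative B1 is additionally modulated along the slice axis so the
    extreme slices sit closer to the low end of the range.
    """
    rng = np.random.default_rng(spec.seed)
    dw_u = _smooth_unit_field(spec.shape, spec.smoothness, rng)
    b1_u = _smooth_unit_field(spec.shape, spec.smoothness, rng)

    dw_lo, dw_hi = spec.dw_field_range
    dw = dw_lo + (dw_hi - dw_lo) * dw_u

    nz = spec.shape[2]
    z = np.arange(nz)
    zc = (nz - 1) / 2.0
    slice_weight = 1.0 - spec.slice_b1_degradation * (np.abs(z - zc) / max(zc, 1)) ** 2
    rb1_lo, rb1_hi = spec.b1_field_range
    rb1 = rb1_lo + (rb1_hi - rb1_lo) * b1_u * slice_weight[None, None, :]

    mask = _ellipsoid_mask(spec.shape)
    dw = np.where(mask, dw, np.nan)
    rb1 = np.where(mask, rb1, np.nan)
    return FieldMaps(
        delta_omega_map=dw,
        b1_map=rb1 * spec.b1_nominal,
        rb1_map=rb1,
        valid_mask=mask.copy(),
        mask=mask,
    )


def _artifact_patch_centers(spec: PhantomSpec, mask: np.ndarray, rng) -> np.ndarray:
    coords = np.argwhere(mask)
    if coords.size == 0 or spec.n_artifact_patches == 0:
        return np.empty((0, 3), dtype=int)
    picks = rng.choice(coords.shape[0], size=min(spec.n_artifact_patches, coords.shape[0]), replace=False)
    return coords[picks]


def simulate_wasabi_volume(
    truth: FieldMaps,
    offsets,
    ctx: AcquisitionContext,
    noise_sigma: float = 0.02,
    seed: int = 0,
    m0_scale: float = 1000.0,
    spec: PhantomSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the 4-D WASABI magnitude volume and its M0 reference image.

    Per voxel the signed spectral model (c = 1, d = 1) is evaluated at the
    truth fields, scaled by a smooth M0 intensity field, perturbed by seeded
    Gaussian noise (std = noise_sigma x local M0), and magnitude-detected.
    When ``spec`` carries artifact patches, spectra inside them receive a
    one-sided amplitude asymmetry.  Outside the support the volume is noise
    floor only.
    """
    offsets = np.asarray(offsets, dtype=float)
    rng = np.random.default_rng(seed)
    shape = truth.delta_omega_map.shape
    mask = truth.mask if truth.mask is not None else np.isfinite(truth.delta_omega_map)

    m0_field = m0_scale * (0.7 + 0.6 * _smooth_unit_field(shape, 4.0, rng))
    m0 = np.where(mask, m0_field, 0.02 * m0_scale)

    volume = np.zeros(shape + (offsets.size,))
    patch_centers = (
        _artifact_patch_centers(spec, mask, rng) if spec is not None else np.empty((0, 3))
    )

    for idx in np.argwhere(mask):
        i, j, k = idx
        theta = WasabiParams(
            c=1.0,
            d=1.0,
            delta_omega=float(truth.delta_omega_map[i, j, k]),
            b1=float(truth.b1_map[i, j, k]),
        )
        z = wasabi_forward(offsets, theta, ctx)
        if patch_centers.size:
            dist = np.sqrt(((patch_centers - idx) ** 2).sum(axis=1)).min()
            if spec is not None and dist <= spec.artifact_radius:
                z = _apply_asymmetry(offsets, z, spec.artifact_magnitude, 0.0)
        volume[i, j, k, :] = z * m0[i, j, k]

    volume += rng.normal(0.0, noise_sigma, size=volume.shape) * m0[..., None]
    return np.abs(volume), m0


def simulate_wassr_volume(
    dw_field: np.ndarray,
    offsets,
    dip_params: tuple[float, float, float] = (0.01, 0.01, 1.0),
    noise_sigma: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a normalized 4-D WASSR volume: a reverse-Lorentzian dip
    centered at the truth water shift per voxel, plus seeded noise.

    ``dip_params`` are (p1 amplitude, p2 squared width in ppm^2, p3
    baseline).  Voxels with NaN truth are left at zero signal.
    """
    offsets = np.asarray(offsets, dtype=float)
    dw_field = np.asarray(dw_field, dtype=float)
    p1, p2, p3 = dip_params
    rng = np.random.default_rng(seed)
    volume = np.zeros(dw_field.shape + (offsets.size,))
    finite = np.isfinite(dw_field)
    for idx in np.argwhere(finite):
        i, j, k = idx
        dw = dw_field[i, j, k]
        volume[i, j, k, :] = p3 - p1 / ((offsets - dw) ** 2 + p2)
    volume[finite] += rng.normal(0.0, noise_sigma, size=(int(finite.sum()), offsets.size))
    return volume


def _apply_asymmetry(offsets, values, magnitude, location) -> np.ndarray:
    """Multiply the right side of the spectrum by a (1 + magnitude) taper
    ramping from the given location to the last offset."""
    out = np.array(values, dtype=float)
    right = offsets > location
    if right.any():
        span = offsets[-1] - location
        taper = np.zeros_like(out)
        taper[right] = (offsets[right] - location) / (span if span > 0 else 1.0)
        out *= 1.0 + magnitude * taper
    return out


def corrupt_spectrum(y: ZSpectrum, spec: CorruptionSpec) -> ZSpectrum:
    """Apply a single corruption operator to one spectrum.

    * ``asymmetry`` — one-sided multiplicative taper, emulating motion or
      coil-profile amplitude asymmetry.
    * ``spike`` — additive perturbation of the single offset nearest to
      ``location`` (an inter-offset motion event).
    * ``depolarization-shortfall`` — subtract a Gaussian lobe (sigma 0.2 ppm)
      at ``location`` and magnitude-detect, so a trough that would go
      negative folds back up the way depolarized magnitude images do.
    """
    offsets = y.offsets
    values = np.array(y.values, dtype=float)
    if spec.kind == "asymmetry":
        values = _apply_asymmetry(offsets, values, spec.magnitude, spec.location)
    elif spec.kind == "spike":
        idx = int(np.argmin(np.abs(offsets - spec.location)))
        values[idx] += spec.magnitude
    elif spec.kind == "depolarization-shortfall":
        lobe = spec.magnitude * np.exp(-((offsets - spec.location) ** 2) / (2 * 0.2**2))
        values = np.abs(values - lobe)
    else:
        raise ValueError(f"unknown corruption kind {spec.kind!r}")
    return ZSpectrum(offsets=offsets, values=values)


def make_default_phantom(
    seed: int = 0,
    spec: PhantomSpec | None = None,
    ctx: AcquisitionContext | None = None,
    n_offsets: int = 49,
):
    """Build the default study phantom in one call.

    Returns ``(truth, wasabi_4d, m0, offsets, ctx, spec)`` for a 7 T-like
    protocol: 49 offsets over -1.5..1.5 ppm, tp = 5 ms, nominal B1 = 3.7 uT.
    """
    spec = spec if spec is not None else PhantomSpec(seed=seed)
    if spec.seed != seed:
        spec = PhantomSpec(**{**spec.__dict__, "seed": seed})
    if ctx is None:
        ctx = AcquisitionContext(omega0=42.577 * 7.0, tp=5e-3, b1_nominal=spec.b1_nominal)
    offsets = np.linspace(-1.5, 1.5, n_offsets)
    truth = make_field_maps(spec)
    wasabi_4d, m0 = simulate_wasabi_volume(
        truth, offsets, ctx, noise_sigma=spec.noise_sigma, seed=seed + 1, spec=spec
    )
    return truth, wasabi_4d, m0, offsets, ctx, spec
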