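"""WASABI physics core.

The WASABI experiment applies a single short rectangular saturation pulse and
samples the water signal at offsets around the water resonance.  The resulting
Z-spectrum carries Rabi-oscillation sidebands whose spacing encodes the
effective saturation amplitude B1, while the symmetry axis of the spectrum
encodes the voxelwise water shift (off-resonance) delta-omega.

This module implements the signed forward model, the analytic relationship
between the distance of the two maxima flanking the water shift and B1
(including its branch logic), magnitude template construction, and the
derivative-based L1 objective used to score templates against measured
spectra.

Unit conventions
----------------
* offsets and water shift ``delta_omega``: ppm
* B1: microtesla (uT)
* pulse duration ``tp``: seconds
* reference (Larmor) frequency ``omega0``: MHz, so ``ppm * omega0`` is Hz
* ``gamma_bar``: MHz/T, so ``gamma_bar * B1`` (MHz/T x uT) is Hz
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAMMA_BAR_PROTON",
    "AcquisitionContext",
    "WasabiParams",
    "ZSpectrum",
    "PeakGeometry",
    "PeakDistanceError",
    "wasabi_forward",
    "peak_distance_to_b1",
    "b1_to_peak_distance",
    "build_template",
    "derivative_l1_objective",
]

#: Reduced proton gyromagnetic ratio, MHz/T.
GAMMA_BAR_PROTON = 42.577


class PeakDistanceError(ValueError):
    """Raised when a peak distance is geometrically impossible for any
    supported branch (or the requested power is outside the supported
    branches)."""


@dataclass(frozen=True)
class AcquisitionContext:
    """Physical constants and sequence parameters of a WASABI acquisition.

    Parameters
    ----------
    omega0 : float
        Reference (Larmor) frequency in MHz (e.g. ~298 MHz at 7 T).
    tp : float
        Duration of the single rectangular saturation pulse, in seconds.
    b1_nominal : float
        Nominal (prescribed) saturation amplitude in uT.
    offset_step : float, optional
        Nominal offset spacing in ppm.  When omitted, drivers derive it from
        the sampled offsets as ``(max - min) / (N - 1)``.
    gamma_bar : float
        Reduced gyromagnetic ratio in MHz/T.  Defaults to the proton value.
    """

    omega0: float
    tp: float
    b1_nominal: float = 3.7
    offset_step: float | None = None
    gamma_bar: float = GAMMA_BAR_PROTON

    def __post_init__(self) -> None:
        for name in ("omega0", "tp", "b1_nominal", "gamma_bar"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if self.offset_step is not None and not (
            np.isfinite(self.offset_step) and self.offset_step > 0
        ):
            raise ValueError("offset_step must be finite and positive")

    @property
    def branch_threshold(self) -> float:
        """Peak distance 2/(omega0*tp), in ppm, separating the two branches
        of the distance->B1 inversion.  This is also the point of maximal
        sensitivity of B1 to the measured distance."""
        return 2.0 / (self.omega0 * self.tp)

    @property
    def b1_max_supported(self) -> float:
        """Largest B1 (uT) with a defined peak distance on branches n <= 2."""
        return 2.0 / (self.gamma_bar * self.tp)


@dataclass(frozen=True)
class WasabiParams:
    """The four free parameters of the WASABI spectral model.

    ``c`` is a baseline amplitude and ``d`` a depth/depolarization factor;
    both are surrogates for relaxation and initial magnetization.  ``d`` is
    restricted to {1, 1.5, 2} when produced by case enumeration, but free
    here.
    """

    c: float
    d: float
    delta_omega: float  # ppm
    b1: float  # uT

    def __post_init__(self) -> None:
        vals = (self.c, self.d, self.delta_omega, self.b1)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite model parameter in {vals!r}")
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")


@dataclass(frozen=True)
class ZSpectrum:
    """One voxel's normalized magnitude signal versus saturation offset."""

    offsets: np.ndarray  # ppm, strictly increasing
    values: np.ndarray  # dimensionless, >= 0

    def __post_init__(self) -> None:
        offsets = np.asarray(self.offsets, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "offsets", offsets)
        object.__setattr__(self, "values", values)
        if offsets.ndim != 1 or offsets.shape != values.shape:
            raise ValueError("offsets and values must be 1-D and equal length")
        if offsets.size < 5:
            raise ValueError("a Z-spectrum needs at least 5 offsets")
        if not np.all(np.diff(offsets) > 0):
            raise ValueError("offsets must be strictly increasing")

    @property
    def n_offsets(self) -> int:
        return int(self.offsets.size)

    def is_finite(self) -> bool:
        return bool(np.all(np.isfinite(self.offsets)) and np.all(np.isfinite(self.values)))


@dataclass(frozen=True)
class PeakGeometry:
    """Distance ``x`` (ppm) between the two maxima flanking the water shift,
    together with the Rabi branch index ``n`` it lies on."""

    x: float
    n: int


def wasabi_forward(
    offsets,
    params: WasabiParams,
    ctx: AcquisitionContext,
) -> np.ndarray:
    """Evaluate the signed WASABI Z-spectrum model.

    Z(dw) = c - d * sin^2(atan(gB1 / D)) * sin^2(pi * tp * sqrt(gB1^2 + D^2))

    where ``D = (dw_ppm - delta_omega_ppm) * omega0`` is the offset from the
    shifted water line in Hz and ``gB1 = gamma_bar * B1`` is the Rabi
    frequency in Hz.  The amplitude factor takes its limit value 1 on
    resonance.  Values may be negative; magnitude reflection belongs to
    :func:`build_template`, not here.
    """
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    delta_hz = (offsets - params.delta_omega) * ctx.omega0
    gb1 = ctx.gamma_bar * params.b1  # Hz
    denom = gb1 * gb1 + delta_hz * delta_hz
    # sin^2(atan(gb1/D)) == gb1^2 / (gb1^2 + D^2); on resonance (D=0) the
    # limit is 1 for any gb1 > 0.  When both vanish the oscillatory factor is
    # zero anyway, so the fill value is immaterial.
    with np.errstate(divide="ignore", invalid="ignore"):
        amplitude = np.where(denom > 0.0, gb1 * gb1 / np.where(denom > 0, denom, 1.0), 1.0)
    oscillation = np.sin(np.pi * ctx.tp * np.sqrt(denom)) ** 2
    return params.c - params.d * amplitude * oscillation


def peak_distance_to_b1(x: float, ctx: AcquisitionContext) -> float:
    """Invert a flanking-maxima distance ``x`` (ppm) to the absolute B1 (uT).

    B1 = (1/gamma_bar) * sqrt((n/tp)^2 - (x*omega0)^2 / 4)

    with branch index n = 1 if ``x <= 2/(omega0*tp)``, else n = 2.  The two
    flanking maxima sit where the Rabi phase ``tp*sqrt(gB1^2 + D^2)`` reaches
    the integer n, which gives the relationship above at ``D = x/2``.
    """
    x = float(x)
    if not (np.isfinite(x) and x > 0):
        raise ValueError(f"peak distance must be finite and positive, got {x!r}")
    n = 1 if x <= ctx.branch_threshold else 2
    radicand = (n / ctx.tp) ** 2 - (x * ctx.omega0) ** 2 / 4.0
    if radicand < 0.0:
        raise PeakDistanceError(
            f"peak distance x={x:.4g} ppm exceeds the n=2 branch support "
            f"({2 * ctx.branch_threshold:.4g} ppm)"
        )
    return math.sqrt(radicand) / ctx.gamma_bar


def b1_to_peak_distance(b1: float, ctx: AcquisitionContext) -> PeakGeometry:
    """Forward map from B1 (uT) to the flanking-maxima distance (ppm).

    The maxima adjacent to the water shift are the first Rabi null on either
    side, at integer phase ``n = ceil(gamma_bar * b1 * tp)``; powers needing
    n > 2 are outside the supported range.
    """
    b1 = float(b1)
    if not (np.isfinite(b1) and b1 > 0):
        raise ValueError(f"b1 must be finite and positive, got {b1!r}")
    phase = ctx.gamma_bar * b1 * ctx.tp
    if phase > 2.0:
        raise PeakDistanceError(
            f"b1={b1:.4g} uT exceeds the supported range (gamma*b1*tp <= 2)"
        )
    n = max(1, math.ceil(phase))
    radicand = (n / ctx.tp) ** 2 - (ctx.gamma_bar * b1) ** 2
    x = (2.0 / ctx.omega0) * math.sqrt(max(radicand, 0.0))
    return PeakGeometry(x=x, n=n)


def build_template(
    theta: WasabiParams,
    offsets,
    ctx: AcquisitionContext,
) -> np.ndarray:
    """Magnitude template |Z(dw; theta)| on the sampled offsets.

    Templates are built with c = 1 (complete longitudinal recovery between
    offsets).  Taking the absolute value reflects negative lobes of the
    signed model across the x-axis, matching magnitude-reconstructed images
    where on-resonance depolarization shows up as a reflected lobe.
    """
    if theta.c != 1:
        raise ValueError(f"templates are defined for c=1, got c={theta.c!r}")
    return np.abs(wasabi_forward(offsets, theta, ctx))


def _first_derivative(values: np.ndarray) -> np.ndarray:
    """Central differences with one-sided differences at both endpoints,
    taken with respect to sample index (uniform unit spacing)."""
    return np.gradient(np.asarray(values, dtype=float))


def derivative_l1_objective(y, template, offsets=None) -> float:
    """L1 distance between the first derivatives of data and template.

    Because the derivative removes any constant offset, the baseline term c
    of the spectral model drops out of the comparison, reducing the search to
    {delta_omega, B1, d}.  Derivatives are taken with respect to sample index
    (on uniform grids this equals the physical-spacing derivative up to one
    global factor, which does not change the ranking of templates).
    """
    y = np.asarray(y, dtype=float)
    template = np.asarray(template, dtype=float)
    if y.shape != template.shape:
        raise ValueError("data and template must have equal length")
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need at least 3 samples to form derivatives")
    return float(np.abs(_first_derivative(y) - _first_derivative(template)).sum())
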