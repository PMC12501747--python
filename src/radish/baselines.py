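"""Baseline fitters the peak-distance search is compared against.

* :func:`lma_fit_voxel` — the original WASABI post-processing strategy:
  initialize from the closest member of a precomputed template dictionary,
  then run damped nonlinear least squares on the magnitude model over all
  four parameters {c, d, delta_omega, B1}.  Sensitive to local minima when
  spectra are asymmetric or depolarized.
* :func:`wassr_fit_voxel` — the WASSR reference water-shift fitter: a
  reverse-Lorentzian (dip-down) line fit to a low-power direct-saturation
  spectrum, returning the dip center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .core import VoxelEstimate
from .model import AcquisitionContext, WasabiParams, ZSpectrum, wasabi_forward

__all__ = [
    "TemplateDictionary",
    "WassrParams",
    "lma_fit_voxel",
    "wassr_fit_voxel",
]


@dataclass(frozen=True)
class WassrParams:
    """Reverse-Lorentzian dip parameters: center (ppm), amplitude surrogate
    p1, squared-width surrogate p2 (ppm^2), baseline p3."""

    delta_omega: float
    p1: float
    p2: float
    p3: float

    def __post_init__(self) -> None:
        if not (self.p2 > 0):
            raise ValueError("p2 (width surrogate) must be positive")


def _magnitude_model(offsets, c, d, dw, b1, ctx):
    return np.abs(wasabi_forward(offsets, WasabiParams(c=c, d=d, delta_omega=dw, b1=b1), ctx))


class TemplateDictionary:
    """Grid of starting parameters with precomputed magnitude templates.

    The dictionary spans the admissible delta_omega x B1 box, crossed with a
    few depth (d) and baseline (c) levels.  Its only job is to supply a
    reasonable starting point for the nonlinear fit.
    """

    def __init__(
        self,
        offsets,
        ctx: AcquisitionContext,
        dw_range: tuple[float, float] = (-0.6, 0.6),
        b1_range: tuple[float, float] | None = None,
        n_dw: int = 20,
        n_b1: int = 20,
        d_values: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0),
        c_values: tuple[float, ...] = (0.8, 1.0, 1.2),
    ) -> None:
        self.offsets = np.asarray(offsets, dtype=float)
        self.ctx = ctx
        self.dw_range = dw_range
        b1_hi = 1.5 * ctx.b1_nominal if b1_range is None else b1_range[1]
        b1_lo = 0.0 if b1_range is None else b1_range[0]
        self.b1_range = (b1_lo, b1_hi)
        dws = np.linspace(dw_range[0], dw_range[1], n_dw)
        b1s = np.linspace(b1_lo + (b1_hi - b1_lo) / n_b1, b1_hi, n_b1)
        params = []
        templates = []
        for c in c_values:
            for d in d_values:
                for dw in dws:
                    for b1 in b1s:
                        params.append((c, d, dw, b1))
                        templates.append(
                            _magnitude_model(self.offsets, c, d, dw, b1, ctx)
                        )
        self.params = np.asarray(params)
        self.templates = np.asarray(templates)

    @property
    def size(self) -> int:
        return self.params.shape[0]

    def lookup(self, values: np.ndarray) -> tuple[float, float, float, float]:
        """Starting parameters: the template with minimum sum-of-squares
        distance to the measured spectrum."""
        values = np.asarray(values, dtype=float)
        sse = ((self.templates - values[None, :]) ** 2).sum(axis=1)
        return tuple(self.params[int(np.argmin(sse))])


def lma_fit_voxel(
    y: ZSpectrum,
    ctx: AcquisitionContext,
    dictionary: TemplateDictionary,
    x0: tuple[float, float, float, float] | None = None,
    max_nfev: int = 400,
) -> VoxelEstimate:
    """Template-lookup-initialized nonlinear least squares on the magnitude
    model over {c, d, delta_omega, B1} within box bounds.

    ``x0`` overrides the dictionary lookup (useful to probe basin
    sensitivity).  Non-convergence returns the best iterate with
    ``refined=False``.
    """
    if not np.array_equal(dictionary.offsets, y.offsets):
        raise ValueError("dictionary was built on different offsets")
    start = np.asarray(x0 if x0 is not None else dictionary.lookup(y.values), dtype=float)
    lb = np.array([0.0, 0.0, dictionary.dw_range[0], max(dictionary.b1_range[0], 1e-6)])
    ub = np.array([3.0, 3.0, dictionary.dw_range[1], dictionary.b1_range[1]])
    start = np.clip(start, lb + 1e-9, ub - 1e-9)

    def residual(theta):
        c, d, dw, b1 = theta
        return _magnitude_model(y.offsets, c, d, dw, b1, ctx) - y.values

    res = least_squares(residual, start, bounds=(lb, ub), max_nfev=max_nfev)
    c, d, dw, b1 = res.x
    return VoxelEstimate(
        delta_omega=float(dw),
        b1=float(b1),
        d=float(d),
        case_id=0,
        objective_score=float(np.linalg.norm(res.fun)),
        valid=True,
        refined=bool(res.status > 0),
    )


def wassr_fit_voxel(
    y: ZSpectrum,
    init_delta_omega: float | None = None,
) -> WassrParams:
    """Fit a reverse Lorentzian z(dw) = p3 - p1 / ((dw - center)^2 + p2) to a
    low-power direct-saturation spectrum and return the dip parameters.

    Initialized at the spectrum minimum (or ``init_delta_omega``).  A
    spectrum whose minimum sits on the boundary has no interior dip and is
    rejected.
    """
    offsets, values = y.offsets, y.values
    imin = int(np.argmin(values))
    if init_delta_omega is None:
        if imin in (0, values.size - 1):
            raise ValueError("no interior absorption dip: spectrum is unfittable")
        init_delta_omega = float(offsets[imin])

    p3_0 = float(np.max(values))
    span = float(offsets[-1] - offsets[0])
    p2_0 = (0.1 * span) ** 2
    p1_0 = max((p3_0 - float(values[imin])) * p2_0, 1e-8)

    def model(x, dw, p1, p2, p3):
        return p3 - p1 / ((x - dw) ** 2 + p2)

    popt, _ = curve_fit(
        model,
        offsets,
        values,
        p0=(init_delta_omega, p1_0, p2_0, p3_0),
        bounds=(
            (offsets[0], 1e-12, 1e-12, -np.inf),
            (offsets[-1], np.inf, np.inf, np.inf),
        ),
        maxfev=10000,
    )
    return WassrParams(delta_omega=float(popt[0]), p1=float(popt[1]), p2=float(popt[2]), p3=float(popt[3]))


def wassr_fit_volume(
    wassr_4d: np.ndarray,
    m0_3d: np.ndarray,
    offsets,
    mask: np.ndarray,
) -> np.ndarray:
    """Voxelwise WASSR dip-center map (ppm); unfittable voxels hold NaN."""
    wassr_4d = np.asarray(wassr_4d, dtype=float)
    m0_3d = np.asarray(m0_3d, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    out = np.full(m0_3d.shape, np.nan)
    for idx in np.argwhere(np.asarray(mask, dtype=bool)):
        i, j, k = idx
        m0 = m0_3d[i, j, k]
        if not (np.isfinite(m0) and m0 > 0):
            continue
        try:
            spec = ZSpectrum(offsets=offsets, values=wassr_4d[i, j, k, :] / m0)
            out[i, j, k] = wassr_fit_voxel(spec).delta_omega
        except (ValueError, RuntimeError):
            continue
    return out
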