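"""The RADISH algorithm: water-shift and B1 estimation by peak-distance search.

Per voxel the pipeline is

1. fit a cubic smoothing spline to the normalized Z-spectrum,
2. locate the local maxima of the smoothed curve,
3. enumerate candidate (delta_omega, x, d) hypotheses from maxima pairs
   (three cases covering progressively stronger on-resonance depolarization),
4. build a magnitude template for each candidate (c = 1),
5. keep the candidate minimizing the derivative-L1 objective,
6. refine B1 by a bounded scalar search constrained through the
   peak-distance relationship,
7. repeat over all voxels to assemble delta_omega / B1 / relative-B1 maps.

Estimation rests only on maxima locations and spectral derivatives, which is
what makes the approach robust to amplitude asymmetries and localized
artifacts that derail full nonlinear least-squares fits.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq, minimize_scalar

from .model import (
    AcquisitionContext,
    PeakDistanceError,
    WasabiParams,
    ZSpectrum,
    build_template,
    derivative_l1_objective,
    peak_distance_to_b1,
)

__all__ = [
    "RadishOptions",
    "MaximaSet",
    "Candidate",
    "VoxelEstimate",
    "FieldMaps",
    "smooth_spectrum",
    "find_local_maxima",
    "enumerate_candidates",
    "select_best",
    "refine_b1",
    "fit_voxel",
    "fit_volume",
    "default_mask",
]

logger = logging.getLogger(__name__)

#: Case definitions: case_id -> (index gap between paired maxima, depth d).
_CASES = {1: (1, 1.0), 2: (2, 1.5), 3: (4, 2.0)}


@dataclass(frozen=True)
class RadishOptions:
    """Tunable parameters of the search (defaults tuned for 7 T in vivo use).

    epsilon
        Spline smoothing tolerance: upper bound on the mean squared residual
        of the smoothing spline to the data.
    b1_range
        Admissible B1 interval in uT, half-open (lo, hi].  ``None`` means
        (0, 1.5 x nominal B1], resolved against the acquisition context.
    dw_range
        Admissible water-shift interval in ppm.
    l1, l2
        Adjustment factors (in units of the offset step) that convert the
        measured peak distance into a B1 refinement interval
        [B1(x + l1*step), B1(x - l2*step)].  Constraining in distance rather
        than B1 matters because B1 is extremely sensitive to distance near
        the branch threshold.
    grid_resolution
        Step (ppm) of the dense grid on which spline maxima are located.
    """

    epsilon: float = 3e-4
    b1_range: tuple[float, float] | None = None
    dw_range: tuple[float, float] = (-0.6, 0.6)
    l1: float = 1.5
    l2: float = 2.5
    grid_resolution: float = 1e-3

    def __post_init__(self) -> None:
        if not (self.epsilon > 0):
            raise ValueError("epsilon must be positive")
        if not (self.l1 > 0 and self.l2 > 0):
            raise ValueError("l1 and l2 must be positive")
        if not (self.grid_resolution > 0):
            raise ValueError("grid_resolution must be positive")

    def resolved_b1_range(self, ctx: AcquisitionContext) -> tuple[float, float]:
        if self.b1_range is not None:
            return self.b1_range
        return (0.0, 1.5 * ctx.b1_nominal)


@dataclass(frozen=True)
class MaximaSet:
    """Ordered local-maximum positions (ppm) of a smoothed spectrum."""

    locations: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        object.__setattr__(self, "locations", loc)
        if loc.size and not np.all(np.diff(loc) > 0):
            raise ValueError("maxima locations must be strictly increasing")

    def __len__(self) -> int:
        return int(self.locations.size)


@dataclass(frozen=True)
class Candidate:
    """One (delta_omega, x, d, B1) hypothesis from a pair of maxima."""

    case_id: int
    delta_omega: float  # ppm
    x: float  # ppm
    d: float
    b1: float  # uT
    anchor_index: int


@dataclass(frozen=True)
class VoxelEstimate:
    """Result of fitting one voxel; failures are encoded, not raised."""

    delta_omega: float = math.nan
    b1: float = math.nan
    d: float = math.nan
    case_id: int = 0
    objective_score: float = math.nan
    valid: bool = False
    failure_reason: str | None = None
    peak_distance: float = math.nan
    refined: bool = False


@dataclass
class FieldMaps:
    """Voxelwise delta_omega / B1 / relative-B1 maps with validity flags.

    Invalid voxels hold NaN in all value maps.  ``artifact_mask`` is filled
    by map-comparison utilities, not by the fitter.
    """

    delta_omega_map: np.ndarray  # ppm
    b1_map: np.ndarray  # uT
    rb1_map: np.ndarray  # dimensionless
    valid_mask: np.ndarray  # bool
    artifact_mask: np.ndarray | None = None
    mask: np.ndarray | None = None
    failure_counts: dict = field(default_factory=dict)


def estimate_noise_sigma(values: np.ndarray) -> float:
    """Robust noise level of a sampled spectrum from fourth differences.

    Fourth differences annihilate cubics, so the smooth spectral shape
    contributes little; for i.i.d. Gaussian noise their variance is 70
    sigma^2, and the median absolute value is converted to sigma through the
    Gaussian MAD constant.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 6:
        return 0.0
    d4 = np.diff(values, 4)
    return float(np.median(np.abs(d4)) / (0.6745 * math.sqrt(70.0)))


def smooth_spectrum(y: ZSpectrum, epsilon: float = 3e-4) -> CubicSpline:
    """Cubic smoothing spline whose summed squared residual is bounded by
    ``epsilon`` plus a data-driven noise allowance.

    The curvature-penalized (Reinsch-type) spline is used: among curves with
    a given residual budget it is the one with least integrated squared
    curvature, which spreads the allowed deviation smoothly instead of
    concentrating it the way knot-minimal fits do.  The total budget is
    ``epsilon + 0.5 * N * sigma_hat^2`` with ``sigma_hat`` the robust noise
    estimate of :func:`estimate_noise_sigma`: on noiseless data the budget
    reduces to the tolerance epsilon (near-interpolation, preserving the
    ~1%-deep Rabi sidebands of low-B1 spectra), while on noisy data roughly
    half the noise energy is smoothed away, enough to suppress spurious
    maxima without flattening real ones.  The penalty weight is chosen by
    bisection as the largest (smoothest) value meeting the budget; exact
    interpolation is the epsilon -> 0 limit.
    """
    if not y.is_finite():
        raise ValueError("spectrum contains non-finite values")
    sigma = estimate_noise_sigma(y.values)
    budget = epsilon + 0.5 * y.n_offsets * sigma * sigma
    return _smooth_with_budget(y, budget)


class _ReinschSystem:
    """Precomputed matrices of the natural-smoothing-spline normal equations.

    Minimizing ``sum (y - f)^2 + lam * int f''^2`` over natural cubic splines
    with knots at the data sites reduces (Reinsch 1967) to the linear system
    ``(R + lam Q^T Q) gamma = Q^T y`` with fitted values ``f = y - lam Q
    gamma``; Q and R depend only on the knot spacings, so varying lam costs
    one small solve.
    """

    def __init__(self, x: np.ndarray, v: np.ndarray) -> None:
        self.v = v
        n = x.size
        h = np.diff(x)
        q = np.zeros((n, n - 2))
        i = np.arange(1, n - 1)
        q[i - 1, i - 1] = 1.0 / h[i - 1]
        q[i, i - 1] = -1.0 / h[i - 1] - 1.0 / h[i]
        q[i + 1, i - 1] = 1.0 / h[i]
        r = np.zeros((n - 2, n - 2))
        r[np.arange(n - 2), np.arange(n - 2)] = (h[:-1] + h[1:]) / 3.0
        off_diag = h[1:-1] / 6.0
        r[np.arange(n - 3), np.arange(1, n - 2)] = off_diag
        r[np.arange(1, n - 2), np.arange(n - 3)] = off_diag
        self.q = q
        self.r = r
        self.qtq = q.T @ q
        self.qty = q.T @ v

    def fitted(self, lam: float) -> np.ndarray:
        if lam <= 0.0:
            return self.v.copy()
        gamma = np.linalg.solve(self.r + lam * self.qtq, self.qty)
        return self.v - lam * (self.q @ gamma)

    def ssr(self, lam: float) -> float:
        return float(((self.fitted(lam) - self.v) ** 2).sum())


def _smooth_with_budget(y: ZSpectrum, budget: float) -> CubicSpline:
    """Natural smoothing spline whose summed squared residual meets an
    absolute budget (largest penalty, i.e. smoothest curve, that fits)."""
    sys_ = _ReinschSystem(y.offsets, y.values)
    lam_hi = 1e9
    if sys_.ssr(lam_hi) <= budget:
        lam = lam_hi
    else:
        lam_lo = 1e-14
        if sys_.ssr(lam_lo) > budget:
            lam = 0.0
        else:
            for _ in range(50):
                lam_mid = math.sqrt(lam_lo * lam_hi)
                if sys_.ssr(lam_mid) <= budget:
                    lam_lo = lam_mid
                else:
                    lam_hi = lam_mid
            lam = lam_lo
    return CubicSpline(y.offsets, sys_.fitted(lam), bc_type="natural")


def find_local_maxima(
    curve,
    offset_range: tuple[float, float],
    grid_resolution: float = 1e-3,
) -> MaximaSet:
    """Strict interior local maxima of a smooth curve.

    The curve is sampled on a uniform grid; a grid point counts as a maximum
    when it exceeds its left neighbor and is at least its right neighbor
    (so a plateau contributes its leftmost point only).  Each grid maximum is
    then polished to the nearest sign change of the spline derivative.
    Boundary grid points are never maxima.
    """
    lo, hi = offset_range
    n = max(int(round((hi - lo) / grid_resolution)) + 1, 5)
    grid = np.linspace(lo, hi, n)
    vals = np.asarray(curve(grid), dtype=float)
    interior = np.flatnonzero(
        (vals[1:-1] > vals[:-2]) & (vals[1:-1] >= vals[2:])
    ) + 1

    try:
        dcurve = curve.derivative()
    except AttributeError:
        dcurve = None

    locations = []
    for i in interior:
        pos = grid[i]
        if dcurve is not None:
            a, b = grid[i - 1], grid[i + 1]
            da, db = float(dcurve(a)), float(dcurve(b))
            if da > 0.0 > db:
                pos = brentq(dcurve, a, b, xtol=1e-12)
        locations.append(pos)
    locations = np.asarray(locations, dtype=float)
    # polishing can merge two grid maxima onto one root; deduplicate
    if locations.size > 1:
        keep = np.concatenate([[True], np.diff(locations) > grid_resolution / 2])
        locations = locations[keep]
    return MaximaSet(locations=locations)


def enumerate_candidates(
    maxima: MaximaSet,
    ctx: AcquisitionContext,
    opts: RadishOptions | None = None,
) -> list[Candidate]:
    """Enumerate case hypotheses from ordered maxima.

    Case 1 pairs adjacent maxima (d = 1, no depolarization); Case 2 pairs
    maxima two apart (d = 1.5, on-resonance lobe reflected in magnitude);
    Case 3 pairs maxima four apart (d = 2, reflected lobes off resonance).
    Each pair gives x = distance, delta_omega = midpoint, and B1 through the
    peak-distance inversion.  Candidates outside the admissible delta_omega
    or B1 ranges, or with geometrically impossible distances, are dropped,
    leaving at most 3m - 7 candidates for m maxima.
    """
    opts = opts or RadishOptions()
    b1_lo, b1_hi = opts.resolved_b1_range(ctx)
    dw_lo, dw_hi = opts.dw_range
    loc = maxima.locations
    m = len(maxima)
    out: list[Candidate] = []
    for case_id, (gap, d) in _CASES.items():
        for i in range(m - gap):
            x = float(loc[i + gap] - loc[i])
            dw = float(loc[i] + x / 2.0)
            if not (dw_lo <= dw <= dw_hi):
                continue
            try:
                b1 = peak_distance_to_b1(x, ctx)
            except (PeakDistanceError, ValueError):
                continue
            if not (b1_lo < b1 <= b1_hi):
                continue
            out.append(
                Candidate(case_id=case_id, delta_omega=dw, x=x, d=d, b1=b1, anchor_index=i)
            )
    return out


def _score_candidate(y: ZSpectrum, cand: Candidate, ctx: AcquisitionContext) -> float:
    theta = WasabiParams(c=1.0, d=cand.d, delta_omega=cand.delta_omega, b1=cand.b1)
    return derivative_l1_objective(y.values, build_template(theta, y.offsets, ctx))


def select_best(
    y: ZSpectrum,
    candidates: list[Candidate],
    ctx: AcquisitionContext,
) -> VoxelEstimate:
    """Score every candidate template against the data and keep the argmin.

    Ties on the objective are broken deterministically by lower case id, then
    smaller |delta_omega|, then smaller anchor index.
    """
    if not candidates:
        return VoxelEstimate(failure_reason="no-candidate-in-bounds")
    best = min(
        candidates,
        key=lambda c: (
            _score_candidate(y, c, ctx),
            c.case_id,
            abs(c.delta_omega),
            c.anchor_index,
        ),
    )
    return VoxelEstimate(
        delta_omega=best.delta_omega,
        b1=best.b1,
        d=best.d,
        case_id=best.case_id,
        objective_score=_score_candidate(y, best, ctx),
        valid=True,
        peak_distance=best.x,
    )


def _offset_step(y: ZSpectrum, ctx: AcquisitionContext) -> float:
    if ctx.offset_step is not None:
        return ctx.offset_step
    return float((y.offsets[-1] - y.offsets[0]) / (y.n_offsets - 1))


def refine_b1(
    y: ZSpectrum,
    est: VoxelEstimate,
    x: float,
    ctx: AcquisitionContext,
    opts: RadishOptions | None = None,
) -> VoxelEstimate:
    """Sharpen the B1 estimate by a bounded scalar search.

    The measured distance x is only resolved to the offset spacing, so B1 is
    re-optimized (delta_omega and d fixed, c = 1) over the interval implied
    by perturbing x by -l2..+l1 offset steps, mapped through the distance
    inversion.  The interval is intersected with the admissible B1 range; a
    degenerate interval returns the estimate unchanged.  The refined score is
    never worse than the incoming one.
    """
    if not est.valid:
        return est
    opts = opts or RadishOptions()
    step = _offset_step(y, ctx)
    b1_lo_opt, b1_hi_opt = opts.resolved_b1_range(ctx)

    # Stay on the branch the candidate's x was inverted on: letting the
    # perturbed distances re-decide the branch makes the bound jump across
    # the threshold and collapse the interval exactly where B1 is most
    # sensitive to x.
    n = 1 if x <= ctx.branch_threshold else 2

    def b1_on_branch(distance: float) -> float:
        radicand = (n / ctx.tp) ** 2 - (distance * ctx.omega0) ** 2 / 4.0
        return math.sqrt(max(radicand, 0.0)) / ctx.gamma_bar

    # larger distance -> smaller B1: the +l1 perturbation gives the lower end
    lo = b1_on_branch(x + opts.l1 * step)
    x_hi = x - opts.l2 * step
    hi = b1_on_branch(x_hi) if x_hi > 0 else n / (ctx.tp * ctx.gamma_bar)
    lo = max(lo, b1_lo_opt, 1e-9)
    hi = min(hi, b1_hi_opt)
    if not (lo < hi):
        return replace(est, refined=False)

    def score(b1: float) -> float:
        theta = WasabiParams(c=1.0, d=est.d, delta_omega=est.delta_omega, b1=b1)
        return derivative_l1_objective(y.values, build_template(theta, y.offsets, ctx))

    # The objective oscillates in B1 (templates gain/lose Rabi periods), so a
    # plain bracketing search can stall in a secondary valley: scan coarsely,
    # then polish the best bracket to the requested tolerance.
    grid = np.linspace(lo, hi, 64)
    scores = [score(b) for b in grid]
    ibest = int(np.argmin(scores))
    sub_lo = grid[max(ibest - 1, 0)]
    sub_hi = grid[min(ibest + 1, grid.size - 1)]
    res = minimize_scalar(
        score, bounds=(sub_lo, sub_hi), method="bounded", options={"xatol": 1e-4}
    )
    best_b1, best_fun = (
        (float(res.x), float(res.fun))
        if res.fun <= scores[ibest]
        else (float(grid[ibest]), float(scores[ibest]))
    )
    if best_fun <= est.objective_score:
        return replace(est, b1=best_b1, objective_score=best_fun, refined=True)
    return replace(est, refined=False)


#: Successive reductions of the smoothing budget whose maxima all contribute
#: candidate hypotheses; the last rung is effectively interpolation.
_SMOOTHING_SCALES = (1.0, 1e-2, 1e-4)
_BUDGET_FLOOR = 1e-7


def fit_voxel(
    y: ZSpectrum,
    ctx: AcquisitionContext,
    opts: RadishOptions | None = None,
) -> VoxelEstimate:
    """Full single-voxel pipeline: smooth, locate maxima, enumerate cases,
    select by the derivative-L1 objective, refine B1.

    Maxima are extracted at three smoothing scales (the default budget and
    two reductions down to near-interpolation) and their case hypotheses
    pooled before selection.  The coarse scale suppresses noise; the fine
    scales resolve structure the default tolerance cannot — weak-B1 spectra
    whose ~1%-deep Rabi sidebands would otherwise be smoothed away, and
    near-threshold peak distances where a small measurement error drops the
    true candidate from the admissible set.  Because every candidate is
    scored against the raw data, pooling adds hypotheses without biasing the
    choice among them.
    """
    opts = opts or RadishOptions()
    if not y.is_finite():
        return VoxelEstimate(failure_reason="non-finite-input")
    sigma = estimate_noise_sigma(y.values)
    base_budget = opts.epsilon + 0.5 * y.n_offsets * sigma * sigma

    pool: list[Candidate] = []
    seen: set[tuple] = set()
    any_maxima = False
    for scale in _SMOOTHING_SCALES:
        budget = max(base_budget * scale, _BUDGET_FLOOR)
        curve = _smooth_with_budget(y, budget)
        maxima = find_local_maxima(
            curve,
            (float(y.offsets[0]), float(y.offsets[-1])),
            opts.grid_resolution,
        )
        if len(maxima) >= 2:
            any_maxima = True
        for cand in enumerate_candidates(maxima, ctx, opts):
            key = (cand.case_id, round(cand.delta_omega, 4), round(cand.b1, 4))
            if key not in seen:
                seen.add(key)
                pool.append(cand)
        if budget <= _BUDGET_FLOOR:
            break
    if not any_maxima:
        return VoxelEstimate(failure_reason="too-few-maxima")
    est = select_best(y, pool, ctx)
    if not est.valid:
        return est
    return refine_b1(y, est, est.peak_distance, ctx, opts)


def default_mask(m0: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Foreground mask: voxels whose M0 exceeds ``fraction`` of the robust
    (99.5th percentile) M0 maximum."""
    m0 = np.asarray(m0, dtype=float)
    robust_max = np.nanpercentile(m0, 99.5)
    return m0 > fraction * robust_max


def fit_volume(
    wasabi_4d: np.ndarray,
    m0_3d: np.ndarray,
    offsets,
    ctx: AcquisitionContext,
    mask: np.ndarray | None = None,
    opts: RadishOptions | None = None,
) -> FieldMaps:
    """Apply the voxel fit over a 4-D WASABI volume.

    Each voxel spectrum is normalized by its M0 reference value and fitted
    independently (results do not depend on voxel visit order).  Voxels with
    non-positive M0 inside the mask are marked invalid.
    """
    opts = opts or RadishOptions()
    wasabi_4d = np.asarray(wasabi_4d, dtype=float)
    m0_3d = np.asarray(m0_3d, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if wasabi_4d.ndim != 4 or wasabi_4d.shape[3] != offsets.size:
        raise ValueError("wasabi volume 4th dimension must match number of offsets")
    if wasabi_4d.shape[:3] != m0_3d.shape:
        raise ValueError("M0 image shape must match the WASABI spatial shape")
    if mask is None:
        mask = default_mask(m0_3d)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != m0_3d.shape:
            raise ValueError("mask shape must match the WASABI spatial shape")

    shape = m0_3d.shape
    dw = np.full(shape, np.nan)
    b1 = np.full(shape, np.nan)
    valid = np.zeros(shape, dtype=bool)
    failures: Counter[str] = Counter()

    for idx in np.argwhere(mask):
        i, j, k = idx
        m0 = m0_3d[i, j, k]
        if not (np.isfinite(m0) and m0 > 0):
            failures["non-positive-m0"] += 1
            continue
        spec_vals = wasabi_4d[i, j, k, :] / m0
        try:
            spectrum = ZSpectrum(offsets=offsets, values=spec_vals)
        except ValueError:
            failures["non-finite-input"] += 1
            continue
        est = fit_voxel(spectrum, ctx, opts)
        if est.valid:
            dw[i, j, k] = est.delta_omega
            b1[i, j, k] = est.b1
            valid[i, j, k] = True
        else:
            failures[est.failure_reason or "unknown"] += 1

    n_masked = int(mask.sum())
    logger.info(
        "fit_volume: %d/%d masked voxels valid; failures: %s",
        int(valid.sum()),
        n_masked,
        dict(failures),
    )
    return FieldMaps(
        delta_omega_map=dw,
        b1_map=b1,
        rb1_map=b1 / ctx.b1_nominal,
        valid_mask=valid,
        mask=mask,
        failure_counts=dict(failures),
    )
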