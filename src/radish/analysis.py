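"""Map comparison statistics and CEST correction utilities.

Covers M0 normalization of 4-D spectral volumes, the ill-estimated-voxel
(artifact) rule used to grade field maps against a reference, Bland-Altman
agreement statistics, and the two downstream corrections field maps exist
for: water-shift (B0) correction of CEST Z-spectra by axis-shifting linear
interpolation, and two-point B1 correction of CEST contrast maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgreementStats",
    "normalize_m0",
    "quantify_artifacts",
    "bland_altman",
    "correct_cest_b0",
    "correct_cest_b1_two_point",
]


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman summary: mean difference and 1.96-SD limits of agreement."""

    bias: float
    loa_lower: float
    loa_upper: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not (self.loa_lower <= self.bias <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the bias")


def normalize_m0(wasabi_4d: np.ndarray, m0_3d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each voxel spectrum by its M0 reference value.

    Returns ``(normalized_4d, flagged_3d)`` where flagged marks voxels with
    non-positive or non-finite M0 (left as NaN rather than divided).
    """
    wasabi_4d = np.asarray(wasabi_4d, dtype=float)
    m0_3d = np.asarray(m0_3d, dtype=float)
    if wasabi_4d.shape[:3] != m0_3d.shape:
        raise ValueError("M0 shape must match the spatial shape of the volume")
    flagged = ~(np.isfinite(m0_3d) & (m0_3d > 0))
    safe_m0 = np.where(flagged, 1.0, m0_3d)
    out = wasabi_4d / safe_m0[..., None]
    out[flagged] = np.nan
    return out, flagged


def quantify_artifacts(
    dw_map: np.ndarray,
    dw_reference: np.ndarray,
    mask: np.ndarray,
    threshold: float = 0.15,
) -> tuple[np.ndarray, float]:
    """Ill-estimated-voxel rule: flag voxels whose water shift deviates from
    the reference by more than ``threshold`` ppm (about two sampling points
    of a standard protocol), or that are invalid in either map.

    Returns the artifact mask and the artifact percentage over the mask.
    """
    dw_map = np.asarray(dw_map, dtype=float)
    dw_reference = np.asarray(dw_reference, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dw_map.shape != dw_reference.shape or dw_map.shape != mask.shape:
        raise ValueError("maps and mask must share a shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    finite = np.isfinite(dw_map) & np.isfinite(dw_reference)
    with np.errstate(invalid="ignore"):
        deviant = np.abs(dw_map - dw_reference) > threshold
    artifact = mask & (~finite | deviant)
    return artifact, 100.0 * float(artifact.sum()) / n


def bland_altman(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray) -> AgreementStats:
    """Bland-Altman agreement of two maps over finite masked voxels:
    bias = mean(a - b), limits of agreement = bias -/+ 1.96 SD."""
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if map_a.shape != map_b.shape or map_a.shape != mask.shape:
        raise ValueError("maps and mask must share a shape")
    diffs = (map_a - map_b)[mask]
    diffs = diffs[np.isfinite(diffs)]
    if diffs.size < 2:
        raise ValueError("need at least 2 finite voxel pairs")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementStats(
        bias=bias,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
        n_voxels=int(diffs.size),
    )


def correct_cest_b0(
    cest_4d: np.ndarray,
    offsets,
    dw_map: np.ndarray,
) -> np.ndarray:
    """Water-shift correction of CEST spectra by linear interpolation.

    Each voxel spectrum is re-sampled at ``offsets + delta_omega`` so the
    water resonance sits at 0 ppm afterwards.  Samples falling outside the
    acquired range, and voxels without a finite shift estimate, are NaN.
    """
    cest_4d = np.asarray(cest_4d, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    dw_map = np.asarray(dw_map, dtype=float)
    if cest_4d.shape[:3] != dw_map.shape or cest_4d.shape[3] != offsets.size:
        raise ValueError("shapes of CEST volume, offsets and shift map disagree")
    out = np.full_like(cest_4d, np.nan)
    for idx in np.argwhere(np.isfinite(dw_map)):
        i, j, k = idx
        shifted = offsets + dw_map[i, j, k]
        vals = np.interp(shifted, offsets, cest_4d[i, j, k, :])
        vals[(shifted < offsets[0]) | (shifted > offsets[-1])] = np.nan
        out[i, j, k, :] = vals
    return out


def correct_cest_b1_two_point(
    contrast_a: np.ndarray,
    contrast_b: np.ndarray,
    rb1_levels: tuple[float, float],
    rb1_map: np.ndarray,
    target_level: float | None = None,
) -> np.ndarray:
    """Two-point B1 correction of a CEST contrast.

    Contrast maps acquired at two nominal B1 levels are interpolated (or
    extrapolated) linearly per voxel as a function of the *actual* local B1
    (relative B1 x nominal level) and evaluated at the target nominal level
    (default: the first level).
    """
    la, lb = rb1_levels
    if la == lb:
        raise ValueError("the two nominal B1 levels must differ")
    if target_level is None:
        target_level = la
    contrast_a = np.asarray(contrast_a, dtype=float)
    contrast_b = np.asarray(contrast_b, dtype=float)
    rb1_map = np.asarray(rb1_map, dtype=float)
    actual_a = rb1_map * la
    actual_b = rb1_map * lb
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = (contrast_a - contrast_b) / (actual_a - actual_b)
        return contrast_a + slope * (target_level - actual_a)
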