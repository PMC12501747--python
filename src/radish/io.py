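"""File I/O: NIfTI volumes, plain-text offsets files, YAML/JSON configs.

Affines are passed through untouched; all computation happens in voxel
space.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import RadishOptions
from .model import AcquisitionContext

__all__ = [
    "load_nifti",
    "save_nifti",
    "read_offsets",
    "write_offsets",
    "load_config",
    "save_config",
]


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (data, affine) from a .nii/.nii.gz file."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def save_nifti(path, data: np.ndarray, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def read_offsets(path) -> np.ndarray:
    """Read a plain-text offsets file: one ppm value per line."""
    vals = [float(line) for line in Path(path).read_text().split() if line.strip()]
    return np.asarray(vals, dtype=float)


def write_offsets(path, offsets) -> None:
    Path(path).write_text("\n".join(f"{v:.6f}" for v in np.asarray(offsets)) + "\n")


def save_config(path, ctx: AcquisitionContext, opts: RadishOptions) -> None:
    """Persist acquisition context + search options as YAML (or JSON)."""
    payload = {
        "acquisition": {
            "omega0": ctx.omega0,
            "tp": ctx.tp,
            "b1_nominal": ctx.b1_nominal,
            "offset_step": ctx.offset_step,
            "gamma_bar": ctx.gamma_bar,
        },
        "options": {
            "epsilon": opts.epsilon,
            "b1_range": list(opts.b1_range) if opts.b1_range else None,
            "dw_range": list(opts.dw_range),
            "l1": opts.l1,
            "l2": opts.l2,
            "grid_resolution": opts.grid_resolution,
        },
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload))


def load_config(path) -> tuple[AcquisitionContext, RadishOptions]:
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    acq = payload["acquisition"]
    opt = payload.get("options", {})
    ctx = AcquisitionContext(
        omega0=acq["omega0"],
        tp=acq["tp"],
        b1_nominal=acq.get("b1_nominal", 3.7),
        offset_step=acq.get("offset_step"),
        gamma_bar=acq.get("gamma_bar", 42.577),
    )
    b1_range = opt.get("b1_range")
    opts = RadishOptions(
        epsilon=opt.get("epsilon", 3e-4),
        b1_range=tuple(b1_range) if b1_range else None,
        dw_range=tuple(opt.get("dw_range", (-0.6, 0.6))),
        l1=opt.get("l1", 1.5),
        l2=opt.get("l2", 2.5),
        grid_resolution=opt.get("grid_resolution", 1e-3),
    )
    return ctx, opts
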