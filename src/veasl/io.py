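"""NIfTI readers/writers and run configuration for the decoding pipeline.

A VE-ASL acquisition is stored as a 4-D NIfTI whose volume axis interleaves
encoding cycles and time frames; the interleaving order is declared
explicitly (``cycle_fastest``: volume = frame * N + cycle, the default, or
``frame_fastest``) rather than guessed.  Magnitude/phase pairs combine into
complex-valued data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .encoding import AffineTransform6, RigidTransform3
from .model import VEASLImage, VEASLResults

__all__ = [
    "read_veasl_nifti",
    "write_veasl_nifti",
    "write_decode_outputs",
    "RunConfig",
]


def read_veasl_nifti(path, n_cycles: int, layout: str = "cycle_fastest",
                     phase_path=None) -> VEASLImage:
    """Load a 4-D NIfTI into a :class:`VEASLImage`.

    The volume count must be divisible by ``n_cycles``; the number of frames
    follows.  If ``phase_path`` is given the two images combine as
    ``magnitude * exp(i * phase)``.
    """
    if layout not in ("cycle_fastest", "frame_fastest"):
        raise ValueError("layout must be 'cycle_fastest' or 'frame_fastest'")
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 3:
        arr = arr[..., None]
    nx, ny, nz, nvol = arr.shape
    if nvol % n_cycles:
        raise ValueError(
            f"{nvol} volumes are not divisible by {n_cycles} cycles"
        )
    n_frames = nvol // n_cycles
    if phase_path is not None:
        ph = np.asanyarray(nib.load(str(phase_path)).dataobj)
        if ph.ndim == 3:
            ph = ph[..., None]
        if ph.shape != arr.shape:
            raise ValueError("magnitude and phase images differ in shape")
        arr = arr * np.exp(1j * ph)
    flat = arr.reshape(nx * ny * nz, nvol)
    if layout == "cycle_fastest":
        vals = flat.reshape(-1, n_frames, n_cycles).transpose(0, 2, 1)
    else:
        vals = flat.reshape(-1, n_cycles, n_frames)
    out = VEASLImage(vals, grid_shape=(nx, ny, nz), affine=img.affine)
    return out


def write_veasl_nifti(data: VEASLImage, path, layout: str = "cycle_fastest"):
    """Write a real-valued :class:`VEASLImage` back to 4-D NIfTI."""
    if data.is_complex:
        raise ValueError("write magnitude and phase separately for complex data")
    V, N, T = data.values.shape
    if layout == "cycle_fastest":
        flat = data.values.transpose(0, 2, 1).reshape(V, N * T)
    elif layout == "frame_fastest":
        flat = data.values.reshape(V, N * T)
    else:
        raise ValueError("layout must be 'cycle_fastest' or 'frame_fastest'")
    affine = data.affine if data.affine is not None else np.eye(4)
    img = nib.Nifti1Image(
        flat.reshape(*data.grid_shape, N * T).astype(np.float64), affine
    )
    nib.save(img, str(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_dict(res: VEASLResults) -> dict:
    p = res.params
    out = dict(
        method=res.method,
        artery_names=list(res.model.arteries.names),
        locations_mm=np.asarray(p.locations).tolist(),
        speeds_cm_s=np.asarray(p.speeds).tolist(),
        objective=None if not np.isfinite(p.objective) else float(p.objective),
        converged=bool(res.converged),
    )
    if p.pi is not None:
        out["class_proportions"] = np.asarray(p.pi).tolist()
        out["classes"] = [list(s) for s in res.model.classes.subsets]
    t = p.transform
    if isinstance(t, RigidTransform3):
        out["transform"] = dict(kind="rigid3", xd_mm=t.xd, yd_mm=t.yd,
                                theta_deg=t.theta_deg)
    elif isinstance(t, AffineTransform6):
        out["transform"] = dict(kind="affine6", a=t.a, b=t.b, c=t.c, d=t.d,
                                xd_mm=t.xd, yd_mm=t.yd)
    return out


def write_decode_outputs(res: VEASLResults, out_dir) -> dict:
    """Write per-source flow NIfTIs, class posteriors, parameters and a
    checksummed manifest; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = res.model.data.grid_shape
    affine = res.model.data.affine
    affine = affine if affine is not None else np.eye(4)
    files = []
    flow = res.flow
    mag = np.abs(flow) if np.iscomplexobj(flow) else flow
    for s, name in enumerate(res.source_names):
        p = out / f"flow_{name}.nii.gz"
        nib.save(nib.Nifti1Image(mag[:, s, :].reshape(*grid, -1).astype(np.float64), affine), str(p))
        files.append(p)
    if res.class_posteriors is not None:
        p = out / "class_posteriors.nii.gz"
        nib.save(
            nib.Nifti1Image(
                res.class_posteriors.reshape(*grid, -1).astype(np.float64), affine
            ),
            str(p),
        )
        files.append(p)
    pjson = out / "fitted_params.json"
    pjson.write_text(json.dumps(_params_dict(res), indent=2))
    files.append(pjson)
    plog = out / "decode.log"
    plog.write_text(res.summary() + "\n")
    files.append(plog)
    manifest = {
        "files": {f.name: _sha256(f) for f in files},
        "method": res.method,
        "sources": res.source_names,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


@dataclass
class RunConfig:
    """Paths and options for a command-line decode run."""

    data: str = ""
    scheme: str = ""
    arteries: str = ""
    lut: str | None = None
    out: str = "."
    method: str = "BT3"
    apc: int = 2
    class_mode: str = "upto"
    frames_for_global: str = "first"
    layout: str = "cycle_fastest"
    seed: int = 0
    verbosity: int = 1
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: raw.pop(k) for k in list(raw) if k in cls.__dataclass_fields__}
        return cls(**known, extras=raw) if "extras" not in known else cls(**known)

    def to_yaml(self, path):
        d = asdict(self)
        d.update(d.pop("extras"))
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
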