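"""NIfTI-1 reading/writing with JSON sidecars and subject manifests.

Acquisition parameters (echo times, flip angles, repetition times) travel
in JSON sidecars next to the image files rather than in NIfTI header
fields. A per-subject ``manifest.json`` lists the role of every file.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .relaxometry import EchoSeries
from .volume import VolumeMap

__all__ = [
    "read_volume",
    "write_volume",
    "read_echo_series",
    "write_echo_series",
    "write_mask",
    "read_mask",
    "write_manifest",
    "read_manifest",
    "write_json",
]


def write_volume(vmap: VolumeMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(vmap.values.astype(np.float64), vmap.affine)
    nib.save(img, str(path))
    sidecar = {"role": vmap.role, "units": vmap.units}
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def _sidecar_path(path: Path) -> Path:
    # foo.nii.gz / foo.nii -> foo.json
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, role: str | None = None) -> VolumeMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path} is not a 3D volume (ndim={data.ndim})")
    units = ""
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        role = role or meta.get("role")
        units = meta.get("units", "")
    return VolumeMap(data, np.asarray(img.affine), role=role or "other", units=units)


def write_echo_series(series: EchoSeries, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data.astype(np.float64), series.affine)
    nib.save(img, str(path))
    sidecar = {"echo_times_ms": series.echo_times.tolist()}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_echo_series(path: str | Path, mask_path: str | Path) -> EchoSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path} is not a 4D series")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"echo-time sidecar missing: {sidecar}")
    echo_times = np.asarray(json.loads(sidecar.read_text())["echo_times_ms"], float)
    mask = read_mask(mask_path)
    if mask.shape != data.shape[:3]:
        raise ValueError(f"grid mismatch between {path} and {mask_path}")
    return EchoSeries(data=data, echo_times=echo_times, mask=mask,
                      affine=np.asarray(img.affine))


def write_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask, np.uint8), affine)
    nib.save(img, str(path))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_manifest(subject_dir: str | Path, subject_id: str, group: str,
                   roles: dict[str, str], params: dict | None = None) -> Path:
    """Write a subject manifest mapping file roles to relative paths."""
    subject_dir = Path(subject_dir)
    manifest = {
        "subject": subject_id,
        "group": group,
        "roles": roles,
        "parameters": params or {},
    }
    return write_json(manifest, subject_dir / "manifest.json")


def read_manifest(subject_dir: str | Path) -> dict:
    subject_dir = Path(subject_dir)
    manifest = json.loads((subject_dir / "manifest.json").read_text())
    for role, rel in manifest["roles"].items():
        if not (subject_dir / rel).exists():
            raise FileNotFoundError(f"manifest role {role!r}: missing file {rel}")
    if manifest.get("group") not in ("healthy", "patient"):
        raise ValueError("manifest group must be 'healthy' or 'patient'")
    return manifest
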