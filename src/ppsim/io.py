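"""Reading and writing phantoms and scalar maps.

Two on-disk encodings are supported: NRRD (raw little-endian encoding,
implemented here) and NIfTI-1 (via nibabel).  A phantom is a label volume
plus a ``<stem>.classes.json`` sidecar carrying the tissue-class table,
voxel size and metadata; the target mask, when present, is written as
``<stem>.target.<ext>``.  Write→read round-trips are lossless for labels,
voxel size, class table and metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .optics import TissueClass
from .phantom import TissuePhantom

_NRRD_TYPES = {
    "int16": np.int16,
    "short": np.int16,
    "uint8": np.uint8,
    "uchar": np.uint8,
    "float": np.float32,
    "double": np.float64,
    "int32": np.int32,
    "int": np.int32,
}
_NP_TO_NRRD = {
    np.dtype(np.int16): "int16",
    np.dtype(np.uint8): "uint8",
    np.dtype(np.float32): "float",
    np.dtype(np.float64): "double",
    np.dtype(np.int32): "int32",
}


# ------------------------------------------------------------------- NRRD
def write_nrrd(
    path: str | Path,
    array: np.ndarray,
    voxel_size_um: tuple[float, float, float],
    extra_fields: dict | None = None,
) -> None:
    """Write a 3D array as NRRD, raw little-endian encoding."""
    path = Path(path)
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise ValueError("only 3D arrays are written")
    if arr.dtype not in _NP_TO_NRRD:
        raise ValueError(f"unsupported dtype {arr.dtype}")
    mm = [v / 1000.0 for v in voxel_size_um]
    lines = [
        "NRRD0004",
        "# ppsim volume",
        f"type: {_NP_TO_NRRD[arr.dtype]}",
        "dimension: 3",
        f"sizes: {arr.shape[0]} {arr.shape[1]} {arr.shape[2]}",
        "encoding: raw",
        "endian: little",
        "space dimension: 3",
        f"spacings: {mm[0]:.9g} {mm[1]:.9g} {mm[2]:.9g}",
        f"ppsim_voxel_size_um:={voxel_size_um[0]:.9g} "
        f"{voxel_size_um[1]:.9g} {voxel_size_um[2]:.9g}",
    ]
    for k, v in (extra_fields or {}).items():
        lines.append(f"{k}:={v}")
    header = "\n".join(lines) + "\n\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.astype(arr.dtype.newbyteorder("<")).tobytes(order="F"))


def read_nrrd(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float], dict]:
    """Read an NRRD volume (raw little-endian encoding only).

    Returns (array, voxel_size_um, key_value_fields).
    """
    raw = Path(path).read_bytes()
    sep = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or sep < 0:
        raise ValueError(f"{path} is not a NRRD file")
    fields: dict[str, str] = {}
    kv: dict[str, str] = {}
    for line in raw[:sep].decode("ascii").splitlines()[1:]:
        if line.startswith("#") or not line.strip():
            continue
        if ":=" in line:
            k, v = line.split(":=", 1)
            kv[k.strip()] = v.strip()
        elif ":" in line:
            k, v = line.split(":", 1)
            fields[k.strip().lower()] = v.strip()
    if fields.get("encoding") != "raw":
        raise ValueError("only raw encoding is supported")
    if fields.get("endian", "little") != "little":
        raise ValueError("only little-endian NRRD is supported")
    dtype = _NRRD_TYPES.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"unsupported NRRD type {fields.get('type')}")
    sizes = tuple(int(s) for s in fields["sizes"].split())
    if len(sizes) != int(fields.get("dimension", len(sizes))):
        raise ValueError("sizes/dimension mismatch")
    if "ppsim_voxel_size_um" in kv:
        vox = tuple(float(x) for x in kv["ppsim_voxel_size_um"].split())
    elif "spacings" in fields:
        vox = tuple(1000.0 * float(x) for x in fields["spacings"].split())
    else:
        vox = (1.0, 1.0, 1.0)
    data = np.frombuffer(
        raw, dtype=np.dtype(dtype).newbyteorder("<"), offset=sep + 2
    )
    n = int(np.prod(sizes))
    if data.size < n:
        raise ValueError("NRRD payload truncated")
    arr = data[:n].reshape(sizes, order="F").copy()
    return arr, vox, kv


# ------------------------------------------------------------------ NIfTI
def _write_nifti(path, array, voxel_size_um):
    affine = np.diag([voxel_size_um[0] / 1000.0, voxel_size_um[1] / 1000.0,
                      voxel_size_um[2] / 1000.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), str(path))


def _read_nifti(path):
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    vox = tuple(1000.0 * float(z) for z in img.header.get_zooms()[:3])
    return arr, vox


def _split(path: Path) -> tuple[Path, str]:
    name = path.name
    for ext in (".nii.gz", ".nii", ".nrrd"):
        if name.endswith(ext):
            return path.parent / name[: -len(ext)], ext
    raise ValueError(f"unknown volume extension on {path} (use .nrrd, .nii, .nii.gz)")


# ------------------------------------------------------------ scalar maps
def write_map(path: str | Path, array: np.ndarray,
              voxel_size_um: tuple[float, float, float]) -> None:
    """Write a float32 scalar volume (fluence, inhibition, ...)."""
    path = Path(path)
    _, ext = _split(path)
    arr = np.asarray(array, dtype=np.float32)
    if ext == ".nrrd":
        write_nrrd(path, arr, voxel_size_um)
    else:
        _write_nifti(path, arr, voxel_size_um)


def read_map(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    _, ext = _split(path)
    if ext == ".nrrd":
        arr, vox, _ = read_nrrd(path)
        return arr, vox
    return _read_nifti(path)


# --------------------------------------------------------------- phantoms
def write_phantom(phantom: TissuePhantom, path: str | Path) -> None:
    path = Path(path)
    stem, ext = _split(path)
    if ext == ".nrrd":
        write_nrrd(path, phantom.labels, phantom.voxel_size)
    else:
        _write_nifti(path, phantom.labels, phantom.voxel_size)

    meta = {}
    for k, v in phantom.metadata.items():
        if k == "target_mask":
            continue
        meta[k] = _jsonify(v)
    mask = phantom.metadata.get("target_mask")
    if mask is not None:
        mask_path = Path(str(stem) + ".target" + ext)
        if ext == ".nrrd":
            write_nrrd(mask_path, mask.astype(np.uint8), phantom.voxel_size)
        else:
            _write_nifti(mask_path, mask.astype(np.uint8), phantom.voxel_size)
        meta["target_mask_file"] = mask_path.name

    sidecar = {
        "voxel_size_um": list(phantom.voxel_size),
        "classes": [c.to_dict() for c in phantom.classes],
        "metadata": meta,
    }
    Path(str(stem) + ".classes.json").write_text(json.dumps(sidecar, indent=2))


def read_phantom(path: str | Path) -> TissuePhantom:
    path = Path(path)
    stem, ext = _split(path)
    sidecar_path = Path(str(stem) + ".classes.json")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"phantom sidecar {sidecar_path} not found; label grids require a "
            "class table"
        )
    sidecar = json.loads(sidecar_path.read_text())
    if ext == ".nrrd":
        labels, vox, _ = read_nrrd(path)
    else:
        labels, vox = _read_nifti(path)
    vox_sc = tuple(sidecar["voxel_size_um"])
    if not np.allclose(vox, vox_sc, rtol=1e-6):
        raise ValueError("voxel size mismatch between volume and sidecar")
    classes = [TissueClass.from_dict(d) for d in sidecar["classes"]]
    metadata = dict(sidecar.get("metadata", {}))
    mask_file = metadata.pop("target_mask_file", None)
    if mask_file:
        mpath = path.parent / mask_file
        marr = read_nrrd(mpath)[0] if mask_file.endswith(".nrrd") else _read_nifti(mpath)[0]
        metadata["target_mask"] = marr.astype(bool)
    # TissuePhantom.__post_init__ rejects grid labels missing from the table
    return TissuePhantom(
        labels=labels.astype(np.int16),
        voxel_size=vox_sc,
        classes=classes,
        metadata=metadata,
    )


def _jsonify(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict):
        return {k: _jsonify(x) for k, x in v.items()}
    return v
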