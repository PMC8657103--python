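"""Read/write masked patches as NIfTI or NRRD image/mask pairs.

NIfTI goes through nibabel.  NRRD support is a minimal self-contained
reader/writer for the subset this package emits (raw or gzip encoding,
little-endian, ``spacings`` or diagonal ``space directions``).
"""

from __future__ import annotations

import gzip
import os
from typing import Tuple

import numpy as np

from .features import VoxelPatch

__all__ = ["read_patch", "write_patch", "read_nrrd", "write_nrrd"]

_NRRD_DTYPES = {
    "double": np.float64,
    "float": np.float32,
    "int": np.int32,
    "short": np.int16,
    "uchar": np.uint8,
    "uint8": np.uint8,
    "int16": np.int16,
    "int32": np.int32,
    "float32": np.float32,
    "float64": np.float64,
}


def _read_nifti(path: str) -> Tuple[np.ndarray, tuple]:
    import nibabel as nib

    img = nib.load(path)
    data = np.asanyarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()[:3]
    # nibabel axis order is (i, j, k); we store patches as (slice, row, col)
    return data, tuple(float(z) for z in zooms)


def _write_nifti(path: str, data: np.ndarray, spacing: tuple) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data), affine), path)


def read_nrrd(path: str) -> Tuple[np.ndarray, tuple]:
    """Minimal NRRD reader: raw/gzip encoding, little-endian, 3D."""
    with open(path, "rb") as fh:
        raw = fh.read()
    header_end = raw.find(b"\n\n")
    if header_end < 0:
        raise ValueError(f"{path}: malformed NRRD (no blank line after header)")
    header_lines = raw[:header_end].decode("ascii", errors="replace").splitlines()
    fields = {}
    for line in header_lines[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        key, _, val = line.partition(":")
        fields[key.strip().lower()] = val.lstrip("= ").strip()
    dtype = _NRRD_DTYPES[fields["type"]]
    sizes = tuple(int(s) for s in fields["sizes"].split())
    encoding = fields.get("encoding", "raw")
    payload = raw[header_end + 2 :]
    if encoding == "gzip":
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    data = np.frombuffer(payload, dtype=np.dtype(dtype).newbyteorder("<"))
    data = data[: int(np.prod(sizes))].reshape(sizes[::-1]).transpose()
    if "spacings" in fields:
        spacing = tuple(float(s) for s in fields["spacings"].split())
    elif "space directions" in fields:
        spacing = tuple(
            float(np.linalg.norm([float(x) for x in vec.strip("()").split(",")]))
            for vec in fields["space directions"].split()
        )
    else:
        spacing = (1.0,) * len(sizes)
    return np.asarray(data, dtype=float), spacing


def write_nrrd(path: str, data: np.ndarray, spacing: tuple) -> None:
    data = np.asarray(data, dtype=np.float64)
    header = (
        "NRRD0004\n"
        "type: double\n"
        f"dimension: {data.ndim}\n"
        f"sizes: {' '.join(str(s) for s in data.shape)}\n"
        f"spacings: {' '.join(repr(float(s)) for s in spacing)}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.transpose().astype("<f8").tobytes())


def _load_any(path: str) -> Tuple[np.ndarray, tuple]:
    lower = path.lower()
    if lower.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if lower.endswith(".nrrd"):
        return read_nrrd(path)
    raise ValueError(f"unsupported image format: {path}")


def read_patch(image_path: str, mask_path: str) -> VoxelPatch:
    """Load an image/mask pair into a :class:`VoxelPatch`.

    Spacing is taken from the image; the mask must match in shape.
    """
    intensities, spacing = _load_any(image_path)
    mask, _ = _load_any(mask_path)
    return VoxelPatch(intensities=intensities, mask=mask > 0.5, spacing=spacing)


def write_patch(patch: VoxelPatch, image_path: str, mask_path: str) -> None:
    for path, data in ((image_path, patch.intensities), (mask_path, patch.mask.astype(np.uint8))):
        os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
        if path.lower().endswith((".nii", ".nii.gz")):
            _write_nifti(path, data, patch.spacing)
        elif path.lower().endswith(".nrrd"):
            write_nrrd(path, data, patch.spacing)
        else:
            raise ValueError(f"unsupported output format: {path}")
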