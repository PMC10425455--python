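"""Minimal ENVI header + flat-binary cube reader/writer.

Supports the dialect produced by common hyperspectral acquisition software:
BIL/BIP/BSQ interleaves, data types 4 (float32) and 12 (uint16), both byte
orders, and a mandatory ``wavelength`` block.  Cubes are exposed as
:class:`~hsifruit.cube.SpectralCube` with a ``(rows, cols, bands)`` layout.
"""
from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np

from .cube import SpectralCube, WavelengthGrid
from .errors import FormatError

_DTYPES = {4: np.dtype("float32"), 12: np.dtype("uint16")}
_DTYPE_CODES = {v: k for k, v in _DTYPES.items()}

# axis order of each interleave on disk, in terms of (line, sample, band)
_INTERLEAVE_AXES = {
    "bsq": (2, 0, 1),  # band, line, sample
    "bil": (0, 2, 1),  # line, band, sample
    "bip": (0, 1, 2),  # line, sample, band
}


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("not an ENVI header (missing 'ENVI' magic)")
    fields: dict[str, str] = {}
    body = text.split("\n", 1)[1]
    # join brace-delimited blocks onto one line
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, val = line.split("=", 1)
        fields[key.strip().lower()] = val.strip()
    return fields


def _parse_wavelengths(fields: dict) -> np.ndarray:
    block = fields.get("wavelength")
    if block is None:
        raise FormatError("ENVI header has no 'wavelength' field")
    inner = block.strip().lstrip("{").rstrip("}")
    return np.array([float(tok) for tok in inner.split(",") if tok.strip()])


def read_envi(header_path) -> SpectralCube:
    """Read an ENVI cube given its ``.hdr`` path.

    The binary is located by stripping the ``.hdr`` suffix, or from the
    header's ``data file`` field if present.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())
    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing field {exc}") from exc
    if dtype_code not in _DTYPES:
        raise FormatError(
            f"unsupported ENVI data type {dtype_code} (supported: 4=float32, 12=uint16)"
        )
    if interleave not in _INTERLEAVE_AXES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    dtype = _DTYPES[dtype_code]
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    wavelengths = _parse_wavelengths(fields)
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )

    binary_path = header_path.with_suffix("")
    if "data file" in fields:
        binary_path = header_path.parent / fields["data file"]
    if not binary_path.exists():
        raise FormatError(f"binary file {binary_path} not found")
    expected = lines * samples * bands * dtype.itemsize
    actual = os.path.getsize(binary_path)
    if actual != expected:
        raise FormatError(
            f"binary size {actual} bytes does not match header "
            f"(lines x samples x bands x itemsize = {expected})"
        )

    flat = np.fromfile(binary_path, dtype=dtype)
    axes = _INTERLEAVE_AXES[interleave]
    disk_shape = tuple((lines, samples, bands)[a] for a in axes)
    arr = flat.reshape(disk_shape).transpose(np.argsort(axes))
    kind = fields.get("hsifruit kind", "raw").strip()
    return SpectralCube(
        np.ascontiguousarray(arr.astype(arr.dtype.newbyteorder("="))),
        WavelengthGrid(wavelengths),
        kind=kind if kind in ("raw", "white_ref", "dark_ref", "reflectance") else "raw",
    )


def write_envi(
    cube: SpectralCube,
    path,
    interleave: str = "bil",
    dtype: str = "float32",
    byte_order: int = 0,
) -> Path:
    """Write a cube as ``<path>`` binary plus ``<path>.hdr``; returns the hdr path."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVE_AXES:
        raise FormatError(f"unsupported interleave {interleave!r}")
    np_dtype = np.dtype(dtype)
    if np_dtype not in _DTYPE_CODES:
        raise FormatError(f"unsupported dtype {dtype} (float32 or uint16)")
    out_dtype = np_dtype.newbyteorder(">" if byte_order == 1 else "<")

    path = Path(path)
    lines, samples, bands = cube.shape
    axes = _INTERLEAVE_AXES[interleave]
    arr = cube.values.transpose(axes).astype(out_dtype)
    arr.tofile(path)

    wl = ", ".join(f"{w:.6g}" for w in cube.grid.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np_dtype]}\n"
        f"interleave = {interleave}\n"
        f"byte order = {byte_order}\n"
        f"hsifruit kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    hdr_path.write_text(header)
    return hdr_path
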