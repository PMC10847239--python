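"""Cube and artifact I/O: minimal ENVI (hdr + raw binary), HDF5 fixtures,
mask PNGs and spectra CSV.

The ENVI support covers the plain hdr dialect (BSQ/BIL/BIP interleaves,
little/big endian, the common numeric data types) — enough to round-trip
reflectance cubes with their wavelength axis; exotic header features
(e.g. BIP offsets, spectral subsets) are out of scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_envi",
    "write_envi",
    "read_hdf5_cube",
    "write_hdf5_cube",
    "write_mask_png",
    "write_spectra_csv",
]

# ENVI numeric "data type" codes -> numpy dtypes
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(hdr_path: Path) -> dict:
    text = hdr_path.read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError(f"{hdr_path} is not an ENVI header")
    fields: dict = {}
    key, buf, in_braces = None, [], False
    for line in text.splitlines()[1:]:
        if in_braces:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf).strip()
                in_braces = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            buf, in_braces = [val], True
        else:
            fields[key] = val
    return fields


def _brace_list(value: str) -> list:
    inner = value.strip().lstrip("{").rstrip("}")
    return [v.strip() for v in inner.split(",") if v.strip()]


def read_envi(hdr_path):
    """Read an ENVI cube; returns ``(data H x W x B, wavelengths or None)``."""
    hdr_path = Path(hdr_path)
    fields = _parse_envi_header(hdr_path)
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    interleave = fields.get("interleave", "bsq").lower()
    code = int(fields.get("data type", 4))
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    byte_order = int(fields.get("byte order", 0))
    dtype = dtype.newbyteorder(">" if byte_order == 1 else "<")
    offset = int(fields.get("header offset", 0))

    bin_path = None
    for cand in (hdr_path.with_suffix(""), hdr_path.with_suffix(".img"),
                 hdr_path.with_suffix(".dat"), hdr_path.with_suffix(".raw")):
        if cand.exists() and cand != hdr_path:
            bin_path = cand
            break
    if bin_path is None:
        raise FileNotFoundError(f"no binary companion found for {hdr_path}")

    flat = np.fromfile(bin_path, dtype=dtype, offset=offset,
                       count=lines * samples * bands)
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    wavelengths = None
    if "wavelength" in fields:
        wavelengths = np.array([float(v) for v in _brace_list(fields["wavelength"])])
    return np.ascontiguousarray(data), wavelengths


def write_envi(hdr_path, data: np.ndarray, wavelengths=None, interleave: str = "bsq"):
    """Write ``data`` (H x W x B) as an ENVI hdr + raw binary pair."""
    hdr_path = Path(hdr_path)
    if hdr_path.suffix != ".hdr":
        hdr_path = hdr_path.with_suffix(".hdr")
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("cube must be H x W x B")
    dtype = data.dtype.newbyteorder("<")
    if np.dtype(dtype.str.lstrip("<>=")) not in _DTYPE_CODES:
        data = data.astype(np.float32)
        dtype = np.dtype("<f4")
    h, w, b = data.shape
    il = interleave.lower()
    if il == "bsq":
        out = data.transpose(2, 0, 1)
    elif il == "bil":
        out = data.transpose(0, 2, 1)
    elif il == "bip":
        out = data
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        f"data type = {_DTYPE_CODES[np.dtype(dtype.str.lstrip('<>='))]}",
        f"interleave = {il}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{v:.6f}" for v in np.asarray(wavelengths))
        lines.append("wavelength = {" + wl + "}")
    hdr_path.write_text("\n".join(lines) + "\n")
    np.ascontiguousarray(out, dtype=dtype).tofile(hdr_path.with_suffix(""))
    return hdr_path


def write_hdf5_cube(path, data, wavelengths, white=None, black=None):
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=np.asarray(data, dtype=np.float32))
        fh.create_dataset("wavelengths", data=np.asarray(wavelengths, dtype=np.float64))
        if white is not None:
            fh.create_dataset("white", data=np.asarray(white, dtype=np.float64))
        if black is not None:
            fh.create_dataset("black", data=np.asarray(black, dtype=np.float64))
    return Path(path)


def read_hdf5_cube(path):
    """Returns ``(data, wavelengths, white, black)``; frames may be None."""
    import h5py

    with h5py.File(path, "r") as fh:
        data = fh["cube"][...]
        wl = fh["wavelengths"][...]
        white = fh["white"][...] if "white" in fh else None
        black = fh["black"][...] if "black" in fh else None
    return data, wl, white, black


def write_mask_png(path, mask: np.ndarray):
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return Path(path)


def write_spectra_csv(path, sample_ids, spectra: np.ndarray, wavelengths) -> Path:
    """Spectra table: one row per sample, columns sample_id, lambda_<nm>..."""
    cols = [f"{wl:.2f}nm" for wl in np.asarray(wavelengths)]
    df = pd.DataFrame(np.asarray(spectra), columns=cols)
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False)
    return Path(path)
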