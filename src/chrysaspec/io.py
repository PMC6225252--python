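"""File I/O: minimal ENVI-style cubes, per-band TIFF stacks, CSV tables."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile

from .hypercube import Hypercube, WavelengthAxis

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def write_envi(path_base: str, cube: Hypercube) -> tuple[str, str]:
    """Write ``path_base``.img (BSQ binary) + ``path_base``.hdr (text header).

    The header carries dimensions, interleave, dtype and the wavelength
    list, which is enough for round-tripping and for third-party ENVI
    readers.  Returns (img_path, hdr_path).
    """
    data = np.ascontiguousarray(np.transpose(cube.data, (2, 0, 1)))  # BSQ
    code = _ENVI_CODES[data.dtype]
    img_path = path_base + ".img"
    hdr_path = path_base + ".hdr"
    lines, samples, bands = cube.data.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.axis.wavelengths_nm)
    header = (
        "ENVI\n"
        f"description = {{chrysaspec {cube.kind} cube}}\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {code}\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    data.tofile(img_path)
    with open(hdr_path, "w") as fh:
        fh.write(header)
    return img_path, hdr_path


def _parse_envi_header(hdr_path: str) -> dict:
    with open(hdr_path) as fh:
        text = fh.read()
    fields: dict = {}
    key = None
    buf = ""
    for line in text.splitlines():
        if key is None:
            if "=" not in line:
                continue
            key, _, rest = line.partition("=")
            key = key.strip().lower()
            buf = rest.strip()
        else:
            buf += " " + line.strip()
        if buf.startswith("{") and not buf.endswith("}"):
            continue  # multi-line braced value
        fields[key] = buf.strip("{} ").strip()
        key = None
        buf = ""
    return fields


def read_envi(path_base: str) -> Hypercube:
    """Read a cube written by :func:`write_envi` (BSQ, byte order 0)."""
    hdr = _parse_envi_header(path_base + ".hdr")
    samples = int(hdr["samples"])
    lines = int(hdr["lines"])
    bands = int(hdr["bands"])
    dtype = _ENVI_DTYPES[int(hdr["data type"])]
    if hdr.get("interleave", "bsq").lower() != "bsq":
        raise ValueError("only BSQ interleave is supported")
    wl = np.array([float(v) for v in hdr["wavelength"].split(",")])
    data = np.fromfile(path_base + ".img", dtype=dtype)
    data = data.reshape(bands, lines, samples).transpose(1, 2, 0)
    return Hypercube(data.astype(float), WavelengthAxis(wl))


def write_band_tiffs(path: str, cube: Hypercube) -> str:
    """Write the cube as a multi-page TIFF, one page per band."""
    tifffile.imwrite(path, np.transpose(cube.data, (2, 0, 1)).astype(np.float32))
    return path


def read_band_tiffs(path: str, axis: WavelengthAxis) -> Hypercube:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return Hypercube(np.transpose(stack, (1, 2, 0)).astype(float), axis)


def write_label_tiff(path: str, labels: np.ndarray) -> str:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))
    return path


def read_label_tiff(path: str) -> np.ndarray:
    return np.asarray(tifffile.imread(path))


def write_spectra_csv(path: str, sample_ids, X: np.ndarray,
                      wavelengths_nm: np.ndarray) -> str:
    """Per-sample mean spectra: sample_id column then one column per band."""
    cols = [f"{w:.4f}" for w in wavelengths_nm]
    df = pd.DataFrame(np.asarray(X, float), columns=cols)
    df.insert(0, "sample_id", list(sample_ids))
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_spectra_csv(path: str) -> tuple[pd.Series, np.ndarray, np.ndarray]:
    """Returns (sample_ids, X, wavelengths_nm)."""
    df = pd.read_csv(path)
    ids = df["sample_id"]
    wl = np.array([float(c) for c in df.columns[1:]])
    return ids, df.iloc[:, 1:].to_numpy(float), wl


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
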