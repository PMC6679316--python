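"""Minimal ENVI header/binary reader and writer.

ENVI stores a cube as a flat binary file plus a small text header that names
the dimensions, numeric type, byte order and band interleave:

* BSQ - band sequential, stored (bands, lines, samples)
* BIL - band interleaved by line, stored (lines, bands, samples)
* BIP - band interleaved by pixel, stored (lines, samples, bands)

Only little-endian data and the numeric types this pipeline emits are
supported (uint16, int32, float32, float64).  Cubes are always presented in
memory as (lines, samples, bands) regardless of the stored interleave.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Tuple

import numpy as np

from .grid import WavelengthGrid
from .hypercube import Hypercube

__all__ = ["read_envi", "write_envi", "read_envi_array", "write_envi_array"]

# ENVI data type codes <-> numpy dtypes (little-endian)
_DTYPES = {2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64, 12: np.uint16}
_CODES = {np.dtype(v).name: k for k, v in _DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


def _data_path(header_path: Path) -> Path:
    return header_path.with_suffix(".img")


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing ENVI magic line)")
    fields: dict = {}
    # join brace-delimited multi-line values before splitting into k = v pairs
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in body.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_envi_array(
    header_path: str | Path,
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Read an ENVI file into a (lines, samples, bands) array.

    Returns ``(data, wavelengths)`` where wavelengths is None when the header
    carries no wavelength list.
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
        raise ValueError(f"ENVI header missing required field: {exc}") from exc
    if int(fields.get("byte order", 0)) != 0:
        raise ValueError("only little-endian (byte order = 0) ENVI files supported")
    if dtype_code not in _DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")

    data_path = _data_path(header_path)
    raw = np.fromfile(data_path, dtype=_DTYPES[dtype_code])
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"{data_path} holds {raw.size} values but header implies {expected} "
            f"({lines} lines x {samples} samples x {bands} bands)"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = raw.reshape(lines, samples, bands)

    wavelengths = None
    if "wavelength" in fields:
        inner = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = np.array(
            [float(tok) for tok in inner.replace(",", " ").split()], dtype=float
        )
        if wavelengths.size != bands:
            raise ValueError(
                f"header lists {wavelengths.size} wavelengths for {bands} bands"
            )
    return np.ascontiguousarray(data), wavelengths


def write_envi_array(
    data: np.ndarray,
    header_path: str | Path,
    wavelengths: Optional[np.ndarray] = None,
    interleave: str = "bil",
    force: bool = False,
) -> Path:
    """Write a (lines, samples, bands) array as ENVI header + binary.

    Refuses to overwrite existing files unless ``force``.  Returns the header
    path; the binary goes to the same stem with an ``.img`` suffix.
    """
    header_path = Path(header_path)
    data = np.asarray(data)
    if data.ndim != 3:
        raise ValueError("ENVI writer expects a 3-D (lines, samples, bands) array")
    interleave = interleave.lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    if data.dtype.name not in _CODES:
        raise ValueError(f"unsupported dtype {data.dtype} for ENVI output")
    data_path = _data_path(header_path)
    if not force and (header_path.exists() or data_path.exists()):
        raise FileExistsError(
            f"{header_path} or {data_path} exists; pass force=True to overwrite"
        )
    header_path.parent.mkdir(parents=True, exist_ok=True)

    lines, samples, bands = data.shape
    if interleave == "bsq":
        stored = data.transpose(2, 0, 1)
    elif interleave == "bil":
        stored = data.transpose(0, 2, 1)
    else:
        stored = data
    np.ascontiguousarray(stored).tofile(data_path)

    parts = [
        "ENVI",
        "description = {grainspec export}",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_CODES[data.dtype.name]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths))
        parts.append("wavelength units = Nanometers")
        parts.append("wavelength = {" + wl + "}")
    header_path.write_text("\n".join(parts) + "\n")
    return header_path


def read_envi(header_path: str | Path, kind: str = "raw") -> Hypercube:
    """Read an ENVI cube; requires a wavelength list in the header."""
    data, wavelengths = read_envi_array(header_path)
    if wavelengths is None:
        raise ValueError(
            f"{header_path} has no wavelength list; a cube needs its band axis "
            "(use read_envi_array for wavelength-less rasters)"
        )
    return Hypercube(data, WavelengthGrid(wavelengths), kind=kind)


def write_envi(
    cube: Hypercube,
    header_path: str | Path,
    interleave: str = "bil",
    force: bool = False,
) -> Path:
    """Write a Hypercube as ENVI header + binary with its wavelength list."""
    return write_envi_array(
        cube.data, header_path, wavelengths=cube.wavelengths,
        interleave=interleave, force=force,
    )
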