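"""Output serialisation: CSV tables, 16-bit PGM graymaps, JSON summaries.

Writes are atomic (temp file + rename) and deterministic: two runs of
the same configuration produce byte-identical files, which the manifest
records with content hashes.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["write_pgm", "read_pgm", "write_outputs", "sha256_file"]

_PGM_MAXVAL = 65535


def _atomic_write(path: Path, data: bytes) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_pgm(path: "str | Path", array: np.ndarray) -> dict:
    """Write a 2D array as a 16-bit portable graymap (P5).

    Values are linearly mapped onto 0..65535; the scaling (offset and
    gain) is returned and also written to a JSON sidecar so the
    physical values can be recovered exactly to 16-bit precision.
    """
    path = Path(path)
    a = np.asarray(array, dtype=float)
    if a.ndim != 2:
        raise ValueError("PGM export needs a 2D array")
    lo, hi = float(a.min()), float(a.max())
    scale = (hi - lo) / _PGM_MAXVAL if hi > lo else 1.0
    scaled = np.round((a - lo) / scale).astype(np.uint16)
    import io as _io

    buf = _io.BytesIO()
    Image.fromarray(scaled).save(buf, format="PPM")
    _atomic_write(path, buf.getvalue())
    sidecar = {"offset": lo, "scale": scale, "maxval": _PGM_MAXVAL, "shape": list(a.shape)}
    _atomic_write(
        path.with_suffix(path.suffix + ".json"),
        (json.dumps(sidecar, sort_keys=True, indent=1) + "\n").encode(),
    )
    return sidecar


def read_pgm(path: "str | Path") -> np.ndarray:
    """Read a PGM written by :func:`write_pgm` back to physical values."""
    path = Path(path)
    raw = np.asarray(Image.open(path), dtype=float)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        sidecar = json.load(fh)
    return raw * sidecar["scale"] + sidecar["offset"]


def sha256_file(path: "str | Path") -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(results: Mapping[str, Any], out_dir: "str | Path") -> dict:
    """Write a result bundle and return its manifest.

    Dispatch by value type: DataFrame → CSV, 2D ndarray → 16-bit PGM
    (+ JSON scaling sidecar), mapping/list → JSON, str → text file.
    The manifest lists every written file with a SHA-256 content hash
    and is itself written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, value in results.items():
        if isinstance(value, pd.DataFrame):
            path = out / f"{name}.csv"
            _atomic_write(path, value.to_csv(index=False).encode())
        elif isinstance(value, np.ndarray):
            path = out / f"{name}.pgm"
            write_pgm(path, value)
            written.append(path.with_suffix(".pgm.json"))
        elif isinstance(value, (dict, list)):
            path = out / f"{name}.json"
            _atomic_write(path, (json.dumps(value, sort_keys=True, indent=1) + "\n").encode())
        elif isinstance(value, str):
            path = out / f"{name}.txt"
            _atomic_write(path, value.encode())
        else:
            raise TypeError(f"cannot serialise result {name!r} of type {type(value)}")
        written.append(path)
    manifest = {
        "files": [
            {"name": p.name, "sha256": sha256_file(p), "bytes": p.stat().st_size}
            for p in sorted(written)
        ]
    }
    _atomic_write(
        out / "manifest.json",
        (json.dumps(manifest, sort_keys=True, indent=1) + "\n").encode(),
    )
    return manifest
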