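"""Delimited-text readers and writers binding the stages together.

Matrices and time series travel as dense whitespace/comma/tab-delimited
text; parcellations as a header table (name, hemi, x, y, z, [network]).
Delimiters are auto-detected and round trips preserve values to float
formatting precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectome import Parcellation

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_series",
    "read_parcellation",
    "write_parcellation",
    "read_vector_map",
    "read_config",
    "write_config",
    "write_simulation",
]


class ParseError(ValueError):
    """Malformed input file (line number reported where known)."""


def _sniff_delimiter(sample: str) -> str | None:
    first = next((ln for ln in sample.splitlines() if ln.strip()), "")
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return None  # whitespace


def read_matrix(path) -> np.ndarray:
    """Dense numeric matrix from delimited text (delimiter auto-detected)."""
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    rows = []
    width = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(delim) if delim else line.split()
        try:
            row = [float(p) for p in parts if p != ""]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ParseError(
                f"{path}:{lineno}: ragged row ({len(row)} values, expected {width})"
            )
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty matrix file")
    return np.asarray(rows, dtype=float)


def write_matrix(path, matrix: np.ndarray, fmt: str = "%.10g") -> None:
    np.savetxt(path, np.atleast_2d(np.asarray(matrix)), fmt=fmt, delimiter="\t")


def read_series(path) -> np.ndarray:
    """Node-by-time series matrix (same format as :func:`read_matrix`)."""
    return read_matrix(path)


_HEMI_ALIASES = {
    "l": "left", "lh": "left", "left": "left",
    "r": "right", "rh": "right", "right": "right",
}


def read_parcellation(path) -> Parcellation:
    """Parcellation table with header: name, hemi, x, y, z, [network]."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"name", "hemi", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    hemis = []
    for i, h in enumerate(df["hemi"].astype(str).str.strip().str.lower()):
        if h not in _HEMI_ALIASES:
            raise ParseError(f"{path}: row {i + 2}: unknown hemisphere {h!r}")
        hemis.append(_HEMI_ALIASES[h])
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    network = df["network"].astype(str).tolist() if "network" in df.columns else None
    return Parcellation(
        names=df["name"].astype(str).tolist(),
        hemisphere=hemis,
        coords=coords,
        network=network,
    )


def write_parcellation(path, parc: Parcellation) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def read_vector_map(path) -> dict[str, float]:
    """Two-column (name, value) node map, delimiter auto-detected."""
    path = Path(path)
    out: dict[str, float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.replace(",", "\t").split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 'name value'")
        try:
            out[parts[0]] = float(parts[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {parts[1]!r}") from None
    return out


def write_simulation(prefix, result, params=None) -> None:
    """Write a simulated run as <prefix>.tsv plus a <prefix>.yaml sidecar.

    The matrix holds the BOLD-like real part (N x T); the sidecar
    records TR, seed, the per-volume forcing flags and, when given, the
    model parameters, so the run is reproducible from the sidecar alone.
    """
    prefix = Path(prefix)
    write_matrix(prefix.with_suffix(".tsv"), result.bold)
    meta: dict = {"TR": float(result.TR), "seed": result.seed}
    if result.forcing_on is not None:
        meta["forcing_on"] = [bool(v) for v in result.forcing_on]
    if params is not None:
        meta["params"] = {
            "a": np.asarray(params.a).tolist(),
            "omega": np.asarray(params.omega).tolist(),
            "beta": float(params.beta),
            "G": float(params.G),
            "nu": float(params.nu),
            "dt": float(params.dt),
            "TR": float(params.TR),
            "n_volumes": int(params.n_volumes),
            "discard": int(params.discard),
            "scheme": params.scheme,
        }
    write_config(prefix.with_suffix(".yaml"), meta)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
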