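"""Spectrum and table I/O: JCAMP-DX (AFFN XYDATA), two-column CSV,
feature-matrix CSV with a normalisation-state header comment.

The JCAMP-DX support covers the subset this package writes: an
``##XYDATA=(X++(Y..Y))`` block with AFFN (plain decimal) values, XFACTOR /
YFACTOR scaling and ppm or Hz X units.  Output is byte-deterministic for a
given spectrum (fixed float formatting), so identical runs produce identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spin import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_feature_matrix",
    "write_feature_matrix",
]

_FMT = "%.8g"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".jdx", ".dx", ".jcamp"):
        return "jcamp"
    if suffix == ".csv":
        return "csv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def write_spectrum(spectrum: Spectrum, path, format: str = None) -> Path:
    """Write a spectrum as JCAMP-DX or two-column CSV (ppm, intensity).

    Metadata (field MHz, scans, …) is preserved in header comments and can
    be recovered by :func:`read_spectrum`.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    x = spectrum.ppm
    y = np.real(spectrum.intensity)
    meta = {k: v for k, v in spectrum.meta.items()
            if isinstance(v, (str, int, float, bool))}
    if fmt == "csv":
        lines = [f"# benchnmr spectrum; meta={json.dumps(meta, sort_keys=True)}",
                 "ppm,intensity"]
        lines += [f"{_FMT % xi},{_FMT % yi}" for xi, yi in zip(x, y)]
        path.write_text("\n".join(lines) + "\n")
        return path
    if fmt != "jcamp":
        raise ValueError(f"unknown format {fmt!r}")
    n = x.size
    header = [
        "##TITLE=benchnmr spectrum",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        f"##$BENCHNMRMETA={json.dumps(meta, sort_keys=True)}",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={_FMT % x[0]}",
        f"##LASTX={_FMT % x[-1]}",
        f"##NPOINTS={n}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        "##XYDATA=(X++(Y..Y))",
    ]
    body = [f"{_FMT % xi} {_FMT % yi}" for xi, yi in zip(x, y)]
    path.write_text("\n".join(header + body + ["##END="]) + "\n")
    return path


def read_spectrum(path, format: str = None) -> Spectrum:
    """Read a JCAMP-DX or CSV spectrum; the ppm axis is stored ascending."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "jcamp":
        return _read_jcamp(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: Path) -> Spectrum:
    meta = {}
    first = path.open().readline()
    if first.startswith("#") and "meta=" in first:
        try:
            meta = json.loads(first.split("meta=", 1)[1])
        except json.JSONDecodeError:
            pass
    try:
        df = pd.read_csv(path, comment="#")
        x = df.iloc[:, 0].to_numpy(dtype=float)
        y = df.iloc[:, 1].to_numpy(dtype=float)
    except Exception as exc:
        raise ValueError(f"{path.name}: malformed CSV spectrum: {exc}") from exc
    return Spectrum(x, y, meta)


def _read_jcamp(path: Path) -> Spectrum:
    meta, fields = {}, {}
    xs, ys = [], []
    in_data = False
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            if key == "$BENCHNMRMETA":
                try:
                    meta = json.loads(val)
                except json.JSONDecodeError:
                    pass
            fields[key] = val.strip()
            continue
        if in_data:
            parts = line.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}:{ln}: non-numeric XYDATA: {raw!r}") from exc
            if len(vals) < 2:
                raise ValueError(f"{path.name}:{ln}: XYDATA row too short")
            x0 = vals[0]
            xf = float(fields.get("XFACTOR", 1.0))
            yf = float(fields.get("YFACTOR", 1.0))
            dx = _jcamp_dx(fields)
            for k, v in enumerate(vals[1:]):
                xs.append((x0 + k * dx) * xf)
                ys.append(v * yf)
    if not xs:
        raise ValueError(f"{path.name}: no XYDATA block found")
    return Spectrum(np.asarray(xs), np.asarray(ys), meta)


def _jcamp_dx(fields: dict) -> float:
    try:
        first = float(fields["FIRSTX"])
        last = float(fields["LASTX"])
        n = int(fields["NPOINTS"])
        return (last - first) / max(n - 1, 1)
    except (KeyError, ValueError):
        return 0.0


def write_feature_matrix(fm: pd.DataFrame, path) -> Path:
    """Feature matrix as CSV (UTF-8, comma, header row, ``# state:`` line)."""
    path = Path(path)
    state = ",".join(fm.attrs.get("state", ["raw"]))
    groups = fm.attrs.get("groups")
    lines = [f"# state: {state}"]
    if groups is not None:
        lines.append("# groups: " + ",".join(str(g) for g in groups))
    lines.append(fm.to_csv(index_label="sample").rstrip("\n"))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_feature_matrix(path) -> pd.DataFrame:
    path = Path(path)
    state, groups = ["raw"], None
    with path.open() as fh:
        for line in fh:
            if line.startswith("# state:"):
                state = line.split(":", 1)[1].strip().split(",")
            elif line.startswith("# groups:"):
                groups = line.split(":", 1)[1].strip().split(",")
            elif not line.startswith("#"):
                break
    fm = pd.read_csv(path, comment="#", index_col="sample")
    fm.index.name = None
    fm.attrs["state"] = state
    if groups is not None:
        fm.attrs["groups"] = groups
    return fm
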