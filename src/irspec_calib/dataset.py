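"""Core data types for spectra and responses, plus on-disk exchange formats.

The internal orientation is fixed to *samples as rows*: an ``n x p`` intensity
matrix with a length-``p`` wavenumber axis (cm^-1) and length-``n`` sample ids.
Readers normalize whatever orientation the file uses.

Supported formats
-----------------
CSV
    First row carries the wavenumbers, first column the sample ids, UTF-8,
    ``.`` decimal separator. Written with 17 significant digits so that
    read -> write -> read is bit-stable for doubles.
JCAMP-DX
    Single-spectrum files with plain-numeric (AFFN) ``##XYDATA`` or
    ``##XYPOINTS`` tables. Compressed encodings (SQZ/DIF/DUP) are rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigError,
    DegenerateDataError,
    FormatError,
    IntegrityError,
    ParseError,
    ShapeError,
)

__all__ = [
    "SpectraMatrix",
    "ResponseVector",
    "LinearCalibration",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcampdx",
    "fit_linear_calibration",
]


@dataclass
class SpectraMatrix:
    """An ``n x p`` absorbance matrix with wavenumber axis and sample ids.

    Parameters
    ----------
    intensities : ndarray of shape (n, p)
        Absorbance values (dimensionless), finite.
    wavenumbers : ndarray of shape (p,)
        Strictly monotone axis in cm^-1; descending order (4000 -> 400) is
        the convention matching instrument output, but ascending is accepted.
        Transforms never reorder this axis.
    sample_ids : sequence of str
        Unique per-sample labels, length ``n``.
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.intensities.ndim != 2:
            raise ShapeError("intensities must be a 2-D (n x p) array")
        n, p = self.intensities.shape
        if n < 1:
            raise ShapeError("at least one sample row is required")
        if p < 3:
            raise ShapeError(
                "at least 3 wavenumbers are required (per-spectrum variance "
                "would be degenerate otherwise)"
            )
        if self.wavenumbers.shape != (p,):
            raise ShapeError(
                f"wavenumber axis has length {self.wavenumbers.shape}, "
                f"expected ({p},)"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ShapeError("intensities contain non-finite values")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ShapeError("wavenumbers contain non-finite values")
        diffs = np.diff(self.wavenumbers)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise FormatError("wavenumbers must be strictly monotone")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(n)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n:
            raise ShapeError(
                f"{len(self.sample_ids)} sample ids for {n} sample rows"
            )
        if len(set(self.sample_ids)) != n:
            raise IntegrityError("sample_ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.intensities.shape[1]

    def subset(self, indices: Sequence[int]) -> "SpectraMatrix":
        """Row subset preserving ids and wavenumber axis."""
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
            raise IntegrityError("subset index out of bounds")
        return SpectraMatrix(
            intensities=self.intensities[idx],
            wavenumbers=self.wavenumbers.copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def copy(self) -> "SpectraMatrix":
        return SpectraMatrix(
            self.intensities.copy(), self.wavenumbers.copy(), list(self.sample_ids)
        )


@dataclass
class ResponseVector:
    """Per-sample reference concentration (mg L^-1), the model's ``y``."""

    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ShapeError("response values contain non-finite entries")
        if np.any(self.values < 0):
            raise ShapeError("concentrations must be >= 0")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(self.values.size)]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != self.values.size:
            raise ShapeError("sample_ids length does not match values")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def subset(self, indices: Sequence[int]) -> "ResponseVector":
        idx = np.asarray(indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
            raise IntegrityError("subset index out of bounds")
        return ResponseVector(
            values=self.values[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
        )

    def check_aligned(self, m: SpectraMatrix) -> None:
        """Raise IntegrityError unless paired in order with ``m``."""
        if self.sample_ids != m.sample_ids:
            raise IntegrityError(
                "response sample_ids do not match spectra sample_ids in order"
            )


@dataclass
class LinearCalibration:
    """Ordinary least squares line of absorbance versus concentration."""

    slope: float
    intercept: float
    r_squared: float
    stderr_slope: float = float("nan")

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ShapeError("r_squared must lie in [0, 1]")

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept

    def invert(self, absorbance: np.ndarray) -> np.ndarray:
        """Map absorbance back to concentration: (a - intercept) / slope."""
        if self.slope == 0:
            raise DegenerateDataError("cannot invert a zero-slope calibration")
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


# ---------------------------------------------------------------------------
# CSV exchange
# ---------------------------------------------------------------------------

def write_spectra_csv(m: SpectraMatrix, path: str | Path) -> None:
    """Write a SpectraMatrix to CSV (samples as rows).

    Intensities are written with 17 significant digits so the round trip
    through :func:`read_spectra_csv` is exact for IEEE doubles.
    """
    path = Path(path)
    if str(path) == "":
        raise OSError("empty output path")
    # repr() emits the shortest decimal that round-trips the double exactly,
    # so read -> write -> read is bit-stable
    lines = ["sample_id," + ",".join(repr(float(w)) for w in m.wavenumbers)]
    for sid, row in zip(m.sample_ids, m.intensities):
        lines.append(sid + "," + ",".join(repr(float(v)) for v in row))
    try:
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    except OSError as exc:  # unwritable path, missing directory, ...
        raise OSError(f"cannot write spectra CSV to {path!r}: {exc}") from exc


def read_spectra_csv(
    path: str | Path, orientation: str = "samples-as-rows"
) -> SpectraMatrix:
    """Read a spectra CSV into the internal samples-as-rows representation.

    Parameters
    ----------
    path : path
        CSV file; header row (or column, depending on orientation) carries
        the wavenumbers, the other margin carries sample ids.
    orientation : {"samples-as-rows", "samples-as-columns"}
        Layout of the file. Either way the returned matrix is samples-as-rows.
    """
    if orientation not in ("samples-as-rows", "samples-as-columns"):
        raise ConfigError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if orientation == "samples-as-columns":
        wn_strings = [str(v) for v in raw.index]
        raw = raw.T
    else:
        # pandas silently mangles duplicate column labels, so take the
        # wavenumber strings straight from the header line
        with open(path, encoding="utf-8") as fh:
            wn_strings = fh.readline().rstrip("\r\n").split(",")[1:]
    if len(wn_strings) != raw.shape[1]:
        raise FormatError("ragged header: wavenumber count mismatch")
    try:
        wavenumbers = np.array([float(c) for c in wn_strings])
    except ValueError as exc:
        raise ParseError(f"non-numeric wavenumber in header: {exc}") from exc
    if len(set(wavenumbers.tolist())) != wavenumbers.size:
        raise FormatError("duplicate wavenumber in header")
    cells = raw.to_numpy()
    body = np.empty(cells.shape, dtype=float)
    for r in range(cells.shape[0]):
        for c in range(cells.shape[1]):
            try:
                # python float() is a correctly-rounded parser, unlike the
                # fast csv float paths; exactness matters for round-trips
                body[r, c] = float(cells[r, c])
            except (TypeError, ValueError):
                raise ParseError(
                    f"non-numeric cell {cells[r, c]!r} at sample "
                    f"{raw.index[r]!r}, wavenumber column {raw.columns[c]!r}"
                ) from None
    return SpectraMatrix(
        intensities=body,
        wavenumbers=wavenumbers,
        sample_ids=[str(s) for s in raw.index],
    )


def write_response_csv(y: ResponseVector, path: str | Path, column: str = "concentration") -> None:
    """Write a response vector as a two-column CSV (sample_id, value)."""
    lines = [f"sample_id,{column}"]
    lines += [f"{sid},{repr(float(v))}" for sid, v in zip(y.sample_ids, y.values)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_response_csv(path: str | Path, column: str | None = None) -> ResponseVector:
    """Read a response vector written by :func:`write_response_csv`."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    col = column if column is not None else df.columns[0]
    return ResponseVector(
        values=df[col].to_numpy(dtype=float), sample_ids=[str(s) for s in df.index]
    )


# ---------------------------------------------------------------------------
# JCAMP-DX (single spectrum, AFFN tables only)
# ---------------------------------------------------------------------------

_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_COMPRESSION_CHARS = set("@ABCDEFGHIJKLMNOPQRabcdefghijklmnopqr%STUVWXYZs")


def _parse_affn_tokens(line: str, path: Path) -> list[float]:
    tokens = re.split(r"[,\s;]+", line.strip())
    values: list[float] = []
    for tok in tokens:
        if not tok:
            continue
        if _NUMERIC_RE.match(tok):
            values.append(float(tok))
        elif set(tok) & _COMPRESSION_CHARS:
            raise FormatError(
                f"{path}: compressed (SQZ/DIF/DUP) data tables are not "
                f"supported; token {tok!r}"
            )
        else:
            raise ParseError(f"{path}: cannot parse token {tok!r} in data table")
    return values


def read_jcampdx(path: str | Path) -> SpectraMatrix:
    """Read a single-spectrum JCAMP-DX file.

    Supports ``##XYDATA=(X++(Y..Y))`` (requires ##FIRSTX, ##LASTX, ##NPOINTS)
    and ``##XYPOINTS=(XY..XY)`` tables in plain-numeric AFFN form. ``##XFACTOR``
    and ``##YFACTOR`` scaling is applied; for XYDATA the abscissa is
    reconstructed from FIRSTX/LASTX/NPOINTS.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    labels: dict[str, str] = {}
    table_kind: str | None = None
    table_lines: list[str] = []
    in_table = False
    saw_end = False
    for rawline in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = rawline.split("$$")[0].rstrip()  # strip comments
        if not line:
            continue
        if line.startswith("##"):
            in_table = False
            label, _, value = line[2:].partition("=")
            key = label.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "END":
                saw_end = True
                break
            if key in ("XYDATA", "XYPOINTS"):
                table_kind = key
                in_table = True
            labels[key] = value
        elif in_table:
            table_lines.append(line)
    if not saw_end:
        raise FormatError(f"{path}: truncated JCAMP-DX file (missing ##END=)")
    if table_kind is None:
        raise FormatError(f"{path}: no ##XYDATA or ##XYPOINTS table found")
    if "XUNITS" not in labels:
        raise FormatError(f"{path}: missing required ##XUNITS label")

    xfactor = float(labels.get("XFACTOR", "1"))
    yfactor = float(labels.get("YFACTOR", "1"))
    numbers: list[float] = []
    for line in table_lines:
        numbers.extend(_parse_affn_tokens(line, path))
    if not numbers:
        raise FormatError(f"{path}: empty data table")

    if table_kind == "XYPOINTS":
        if len(numbers) % 2:
            raise FormatError(f"{path}: odd token count in XYPOINTS table")
        arr = np.array(numbers).reshape(-1, 2)
        x = arr[:, 0] * xfactor
        y = arr[:, 1] * yfactor
    else:  # XYDATA=(X++(Y..Y))
        for req in ("FIRSTX", "LASTX", "NPOINTS"):
            if req not in labels:
                raise FormatError(f"{path}: XYDATA table requires ##{req}")
        firstx = float(labels["FIRSTX"])
        lastx = float(labels["LASTX"])
        npoints = int(float(labels["NPOINTS"]))
        if npoints < 2:
            raise FormatError(f"{path}: NPOINTS must be >= 2")
        # each table line is "x y1 y2 ..."; drop the leading check value per line
        ys: list[float] = []
        for line in table_lines:
            vals = _parse_affn_tokens(line, path)
            if len(vals) < 2:
                raise FormatError(f"{path}: XYDATA line with no ordinates")
            ys.extend(vals[1:])
        if len(ys) != npoints:
            raise FormatError(
                f"{path}: XYDATA has {len(ys)} ordinates, ##NPOINTS says {npoints}"
            )
        x = np.linspace(firstx, lastx, npoints)
        y = np.array(ys) * yfactor

    title = labels.get("TITLE", path.stem) or path.stem
    return SpectraMatrix(
        intensities=y.reshape(1, -1),
        wavenumbers=x,
        sample_ids=[title],
    )


# ---------------------------------------------------------------------------
# Reference-method linear calibration
# ---------------------------------------------------------------------------

def fit_linear_calibration(
    x: ResponseVector | np.ndarray, y: np.ndarray
) -> LinearCalibration:
    """Ordinary least squares fit of absorbance ``y`` on concentration ``x``.

    Returns slope, intercept and ``r^2 = 1 - SS_res / SS_tot``.
    """
    xv = x.values if isinstance(x, ResponseVector) else np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ShapeError(f"x has {xv.size} points, y has {yv.size}")
    if xv.size < 3:
        raise DegenerateDataError("need at least 3 points for a calibration line")
    if np.ptp(xv) == 0:
        raise DegenerateDataError("constant x: degenerate design")
    res = stats.linregress(xv, yv)
    yhat = res.slope * xv + res.intercept
    ss_res = float(np.sum((yv - yhat) ** 2))
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return LinearCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=max(0.0, min(1.0, r2)),
        stderr_slope=float(res.stderr),
    )
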