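"""Kennard-Stone deterministic calibration/test splitting.

The first two selected objects are the pair at maximum Euclidean distance;
each subsequent object maximizes, over unselected points, the minimum
distance to the already-selected set (greedy max-min). Ties are broken by
lowest original index, so the split is deterministic without a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .dataset import ResponseVector, SpectraMatrix
from .exceptions import ConfigError, IntegrityError

__all__ = ["SplitIndices", "kennard_stone", "apply_split"]


@dataclass
class SplitIndices:
    """Calibration indices in Kennard-Stone selection order, plus the rest."""

    calibration: list[int]
    test: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        cal, test = set(self.calibration), set(self.test)
        if cal & test:
            raise IntegrityError("calibration and test indices overlap")
        if len(cal) != len(self.calibration) or len(test) != len(self.test):
            raise IntegrityError("duplicate index inside a split")

    @property
    def n_total(self) -> int:
        return len(self.calibration) + len(self.test)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"calibration": list(self.calibration), "test": list(self.test)},
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitIndices":
        d = json.loads(Path(path).read_text())
        return cls(
            calibration=[int(i) for i in d["calibration"]],
            test=[int(i) for i in d["test"]],
        )


def _as_points(m: SpectraMatrix | np.ndarray) -> np.ndarray:
    X = m.intensities if isinstance(m, SpectraMatrix) else np.asarray(m, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise IntegrityError("non-finite values in Kennard-Stone input")
    return X


def kennard_stone(m: SpectraMatrix | np.ndarray, n_cal: int) -> SplitIndices:
    """Greedy max-min Euclidean selection of ``n_cal`` calibration samples.

    Exact O(n^2) pairwise distances; fine at desk scale. Duplicate rows are
    handled by the lowest-index tie rule, never an error.
    """
    X = _as_points(m)
    n = X.shape[0]
    if not 2 <= n_cal <= n:
        raise ConfigError(f"n_cal must be in [2, {n}], got {n_cal}")

    D = squareform(pdist(X, metric="euclidean"))
    # initial pair: row-major argmax gives the lexicographically smallest
    # (i, j) with i < j among maximal pairs
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    if i > j:
        i, j = j, i
    selected = [int(i), int(j)]
    remaining = np.ones(n, dtype=bool)
    remaining[i] = remaining[j] = False

    min_dist = np.minimum(D[i], D[j])
    while len(selected) < n_cal:
        cand = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(cand))  # argmax returns lowest index on ties
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, D[nxt])

    test = [int(t) for t in np.flatnonzero(remaining)]
    return SplitIndices(calibration=selected, test=test)


def apply_split(
    m: SpectraMatrix, y: ResponseVector, s: SplitIndices
) -> tuple[SpectraMatrix, ResponseVector, SpectraMatrix | None, ResponseVector | None]:
    """Split spectra and responses into (cal_X, cal_y, test_X, test_y).

    Sample ids are preserved. With an empty test set a warning is emitted and
    ``(cal_X, cal_y, None, None)`` is returned.
    """
    if y.n_samples != m.n_samples:
        raise IntegrityError("spectra and response sample counts differ")
    y.check_aligned(m)
    if s.n_total != m.n_samples:
        raise IntegrityError(
            f"split covers {s.n_total} samples, data has {m.n_samples}"
        )
    all_idx = s.calibration + s.test
    if min(all_idx) < 0 or max(all_idx) >= m.n_samples:
        raise IntegrityError("split index out of bounds")
    cal_X = m.subset(s.calibration)
    cal_y = y.subset(s.calibration)
    if not s.test:
        warnings.warn("empty test set: n_cal equals the sample count", stacklevel=2)
        return cal_X, cal_y, None, None
    return cal_X, cal_y, m.subset(s.test), y.subset(s.test)
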