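"""Standard normal variate (SNV) transform.

Each spectrum is centered by its own mean and scaled by its own sample
standard deviation (denominator ``p - 1``):

    snv_i = (x_i - mean(x)) / sqrt(sum_i (x_i - mean(x))^2 / (p - 1))

This removes per-spectrum additive baseline offsets and multiplicative
scatter exactly: SNV(a*x + b) == SNV(x) for any a > 0 and any b.
"""

from __future__ import annotations

import numpy as np

from .dataset import SpectraMatrix
from .exceptions import DegenerateDataError, ShapeError

__all__ = ["snv_row", "snv_matrix"]


def snv_row(x: np.ndarray) -> np.ndarray:
    """SNV-transform a single spectrum (1-D array of length p >= 3)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise ShapeError("SNV needs at least 3 wavenumbers")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant spectrum: SNV undefined (sd = 0)")
    return (x - x.mean()) / sd


def snv_matrix(m: SpectraMatrix) -> SpectraMatrix:
    """Row-wise SNV; wavenumber axis and sample ids are unchanged.

    Raises
    ------
    DegenerateDataError
        If any row is constant; the message lists all offending sample ids.
    """
    X = m.intensities
    sd = X.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        ids = ", ".join(m.sample_ids[i] for i in flat)
        raise DegenerateDataError(f"constant spectra (sd = 0) for samples: {ids}")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return SpectraMatrix(
        intensities=out,
        wavenumbers=m.wavenumbers.copy(),
        sample_ids=list(m.sample_ids),
    )
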