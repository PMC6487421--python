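"""Model-quality computation: PRESS, r2/Q2, cross-validation, latent-variable
selection, external validation and the y-permutation chance-correlation test.

Conventions
-----------
* PRESS is the plain sum of squared prediction errors, so ``press = n * rmse^2``.
* Q2 (cross-validated r2) is computed against the mean of the *full*
  calibration response, not per-fold training means.
* All cross-validation and permutation draws are seeded and bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigError, DegenerateDataError, ShapeError
from .model import HybridModel, hybrid_fit
from .synthetic import derived_rng

__all__ = [
    "MetricSet",
    "ValidationReport",
    "PermutationResult",
    "press",
    "r2_score",
    "loo_cv",
    "lmo_cv",
    "select_n_lv",
    "external_validation",
    "y_permutation_test",
    "build_report",
]


@dataclass
class MetricSet:
    """r2 / PRESS / RMSE over a set of n predictions."""

    r_squared: float
    press: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "press": self.press,
            "rmse": self.rmse,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MetricSet":
        return cls(
            r_squared=float(d["r_squared"]),
            press=float(d["press"]),
            rmse=float(d["rmse"]),
            n=int(d["n"]),
        )

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray, ref_mean: float | None = None
    ) -> "MetricSet":
        y_true = np.asarray(y_true, dtype=float).ravel()
        y_pred = np.asarray(y_pred, dtype=float).ravel()
        p = press(y_true, y_pred)
        n = y_true.size
        return cls(
            r_squared=r2_score(y_true, y_pred, ref_mean=ref_mean),
            press=p,
            rmse=math.sqrt(p / n),
            n=n,
        )


def press(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Predicted residual error sum of squares, sum (y - yhat)^2."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ShapeError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    if y_true.size < 1:
        raise ShapeError("need at least one prediction")
    return float(np.sum((y_true - y_pred) ** 2))


def r2_score(
    y_true: np.ndarray, y_pred: np.ndarray, ref_mean: float | None = None
) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative).

    ``ref_mean`` overrides the centering mean in SS_tot; cross-validated Q2
    uses the full calibration mean here.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ShapeError(f"length mismatch: {y_true.size} vs {y_pred.size}")
    mu = float(np.mean(y_true)) if ref_mean is None else float(ref_mean)
    ss_tot = float(np.sum((y_true - mu) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("constant y_true: r2 undefined")
    return 1.0 - press(y_true, y_pred) / ss_tot


def _sigma2_for(A: int, sigma2, sigma2_by_lv) -> float:
    if sigma2_by_lv is not None and A in sigma2_by_lv:
        return float(sigma2_by_lv[A])
    return float(sigma2)


def loo_cv(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    A: int,
    gamma: float,
    sigma2: float,
) -> MetricSet:
    """Leave-one-out cross-validation of the full hybrid model.

    For every sample the whole chain (PLS + LS-SVM, fixed A, gamma, sigma2)
    is refit on the remaining samples and the held-out response predicted.
    """
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ShapeError("LOO needs at least 3 calibration samples")
    preds = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        try:
            sub = hybrid_fit(X[keep], y[keep], A, gamma, sigma2)
        except Exception as exc:
            raise type(exc)(f"LOO fold {i} ({exc})") from exc
        preds[i] = sub.predict(X[i : i + 1])[0]
    return MetricSet.from_predictions(y, preds, ref_mean=float(y.mean()))


def lmo_cv(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    A: int,
    gamma: float,
    sigma2: float,
    fraction: float = 0.2,
    n_repeats: int = 25,
    seed: int = 0,
) -> MetricSet:
    """Leave-many-out cross-validation: random holdouts of ceil(fraction*n).

    Each round refits the hybrid on the remainder and predicts the held-out
    block; Q2/PRESS are pooled over all held-out predictions of all rounds.
    """
    if not 0 < fraction < 1:
        raise ConfigError("fraction must be in (0, 1)")
    if n_repeats < 1:
        raise ConfigError("n_repeats must be >= 1")
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    n = X.shape[0]
    n_out = math.ceil(fraction * n)
    if n - n_out < 2:
        raise ConfigError("holdout fraction leaves too few training samples")
    rng = derived_rng(seed, "lmo")
    y_all: list[np.ndarray] = []
    p_all: list[np.ndarray] = []
    for rep in range(n_repeats):
        held = rng.choice(n, size=n_out, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[held] = False
        try:
            sub = hybrid_fit(X[keep], y[keep], A, gamma, sigma2)
        except Exception as exc:
            raise type(exc)(f"LMO round {rep} ({exc})") from exc
        y_all.append(y[held])
        p_all.append(sub.predict(X[held]))
    y_pool = np.concatenate(y_all)
    p_pool = np.concatenate(p_all)
    return MetricSet.from_predictions(y_pool, p_pool, ref_mean=float(y.mean()))


def select_n_lv(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    lv_range: Sequence[int],
    gamma: float,
    sigma2: float,
    sigma2_by_lv: Mapping[int, float] | None = None,
) -> tuple[int, dict[int, MetricSet]]:
    """Choose the latent-variable count by leave-one-out PRESS.

    Parsimony rule: the smallest A whose LOO PRESS is within 5% of the global
    minimum over ``lv_range``. ``sigma2_by_lv`` optionally supplies a
    bandwidth per A (score-space scale grows with A).
    """
    lvs = sorted(set(int(a) for a in lv_range))
    if not lvs:
        raise ConfigError("lv_range must be non-empty")
    table: dict[int, MetricSet] = {}
    for A in lvs:
        table[A] = loo_cv(X_cal, y_cal, A, gamma, _sigma2_for(A, sigma2, sigma2_by_lv))
    best_press = min(ms.press for ms in table.values())
    chosen = min(A for A, ms in table.items() if ms.press <= 1.05 * best_press)
    return chosen, table


def external_validation(
    model: HybridModel, X_test: np.ndarray, y_test: np.ndarray
) -> MetricSet:
    """Predict an untouched test set with a fitted model; never refits."""
    if X_test is None or y_test is None:
        raise ShapeError("empty test set: external validation impossible")
    X = np.asarray(X_test, dtype=float)
    y = np.asarray(y_test, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] < 1:
        raise ShapeError("test set must contain at least one spectrum")
    if X.shape[0] != y.size:
        raise ShapeError("test spectra and responses differ in length")
    preds = model.predict(X)
    return MetricSet.from_predictions(y, preds)


@dataclass
class PermutationResult:
    """Chance-correlation metrics under B scrambled response vectors."""

    observed_r2: float
    permuted_r2: np.ndarray
    permuted_q2_loo: np.ndarray
    permuted_q2_lmo: np.ndarray
    n_permutations: int
    seed: int

    @property
    def exceedance(self) -> float:
        """Proportion of permuted training r2 values >= the observed r2."""
        return float(np.mean(self.permuted_r2 >= self.observed_r2))

    def to_dict(self) -> dict:
        return {
            "observed_r2": self.observed_r2,
            "permuted_r2": [float(v) for v in self.permuted_r2],
            "permuted_q2_loo": [float(v) for v in self.permuted_q2_loo],
            "permuted_q2_lmo": [float(v) for v in self.permuted_q2_lmo],
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "exceedance": self.exceedance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PermutationResult":
        return cls(
            observed_r2=float(d["observed_r2"]),
            permuted_r2=np.asarray(d["permuted_r2"], dtype=float),
            permuted_q2_loo=np.asarray(d["permuted_q2_loo"], dtype=float),
            permuted_q2_lmo=np.asarray(d["permuted_q2_lmo"], dtype=float),
            n_permutations=int(d["n_permutations"]),
            seed=int(d["seed"]),
        )


def y_permutation_test(
    X_cal: np.ndarray,
    y_cal: np.ndarray,
    A: int,
    gamma: float,
    sigma2: float,
    B: int = 100,
    seed: int = 0,
    lmo_fraction: float = 0.2,
    lmo_repeats: int = 10,
    compute_loo: bool = True,
    compute_lmo: bool = True,
) -> PermutationResult:
    """Refit on B seeded permutations of y and record chance metrics.

    Per permutation: training r2, Q2 of LOO and of LMO cross-validation. A
    real model's observed r2 should exceed every permuted one (exceedance 0).
    """
    if B < 1:
        raise ConfigError("B must be >= 1")
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()

    observed_model = hybrid_fit(X, y, A, gamma, sigma2)
    observed_r2 = r2_score(y, observed_model.predict(X))

    rng = derived_rng(seed, "y-permutation")
    r2s = np.empty(B)
    q2_loo = np.full(B, np.nan)
    q2_lmo = np.full(B, np.nan)
    for b in range(B):
        y_perm = rng.permutation(y)
        fit = hybrid_fit(X, y_perm, A, gamma, sigma2)
        r2s[b] = r2_score(y_perm, fit.predict(X))
        if compute_loo:
            q2_loo[b] = loo_cv(X, y_perm, A, gamma, sigma2).r_squared
        if compute_lmo:
            q2_lmo[b] = lmo_cv(
                X,
                y_perm,
                A,
                gamma,
                sigma2,
                fraction=lmo_fraction,
                n_repeats=lmo_repeats,
                seed=seed + 1000 + b,
            ).r_squared
    return PermutationResult(
        observed_r2=observed_r2,
        permuted_r2=r2s,
        permuted_q2_loo=q2_loo,
        permuted_q2_lmo=q2_lmo,
        n_permutations=B,
        seed=seed,
    )


@dataclass
class ValidationReport:
    """Per-LV metric table plus external validation and permutation summary."""

    per_lv: dict[int, dict[str, MetricSet]]
    chosen_lv: int
    external: MetricSet | None = None
    permutation: PermutationResult | None = None
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chosen_lv not in self.per_lv:
            raise ConfigError("chosen_lv missing from per_lv table")

    def to_dict(self) -> dict:
        return {
            "per_lv": {
                str(A): {kind: ms.to_dict() for kind, ms in row.items()}
                for A, row in sorted(self.per_lv.items())
            },
            "chosen_lv": self.chosen_lv,
            "external": self.external.to_dict() if self.external else None,
            "permutation": self.permutation.to_dict() if self.permutation else None,
            "hyperparameters": self.hyperparameters,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ValidationReport":
        return cls(
            per_lv={
                int(A): {k: MetricSet.from_dict(v) for k, v in row.items()}
                for A, row in d["per_lv"].items()
            },
            chosen_lv=int(d["chosen_lv"]),
            external=MetricSet.from_dict(d["external"]) if d.get("external") else None,
            permutation=(
                PermutationResult.from_dict(d["permutation"])
                if d.get("permutation")
                else None
            ),
            hyperparameters=dict(d.get("hyperparameters", {})),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ValidationReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def render_text(self) -> str:
        """Aligned per-LV table: {r2, PRESS} x {Prediction, LOO, LMO}."""
        lvs = sorted(self.per_lv)
        header = ["NO. of LVs"] + [str(A) for A in lvs]
        rows: list[list[str]] = [header]
        for kind, label in (
            ("prediction", "Prediction"),
            ("loo", "Cross Validation (LOO)"),
            ("lmo", "Cross Validation (LMO)"),
        ):
            metric_name = "r2" if kind == "prediction" else "Q2"
            r2_cells = [f"{self.per_lv[A][kind].r_squared:.3f}" for A in lvs]
            press_cells = [f"{self.per_lv[A][kind].press:.4g}" for A in lvs]
            rows.append([f"{label}  {metric_name}"] + r2_cells)
            rows.append([f"{label}  PRESS"] + press_cells)
        widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
        lines = [
            "  ".join(cell.ljust(widths[c]) for c, cell in enumerate(row))
            for row in rows
        ]
        lines.append("")
        lines.append(f"chosen LVs: {self.chosen_lv}")
        if self.external is not None:
            lines.append(
                f"external validation: r2={self.external.r_squared:.3f} "
                f"PRESS={self.external.press:.4g} (n={self.external.n})"
            )
        if self.permutation is not None:
            pr = self.permutation
            lines.append(
                f"y-permutation (B={pr.n_permutations}): max permuted "
                f"r2={np.max(pr.permuted_r2):.3f} vs observed "
                f"r2={pr.observed_r2:.3f}; exceedance={pr.exceedance:.3f}"
            )
        return "\n".join(lines) + "\n"


def build_report(
    per_lv: Mapping[int, Mapping[str, MetricSet]],
    chosen_lv: int,
    external: MetricSet | None = None,
    permutation: PermutationResult | None = None,
    hyperparameters: Mapping | None = None,
) -> ValidationReport:
    """Assemble the final report; raises if a per-LV cell is missing."""
    table: dict[int, dict[str, MetricSet]] = {}
    for A, row in per_lv.items():
        missing = {"prediction", "loo", "lmo"} - set(row)
        if missing:
            raise ConfigError(f"per-LV table for A={A} missing {sorted(missing)}")
        table[int(A)] = {k: row[k] for k in ("prediction", "loo", "lmo")}
    return ValidationReport(
        per_lv=table,
        chosen_lv=int(chosen_lv),
        external=external,
        permutation=permutation,
        hyperparameters=dict(hyperparameters or {}),
    )
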