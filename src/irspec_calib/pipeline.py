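"""Config-driven orchestration of the full calibration analysis.

Stages, in order: generate (or load) spectra and reference responses -> SNV
-> Kennard-Stone split -> hyperparameter tuning -> latent-variable selection
-> final hybrid fit -> external validation -> y-permutation test -> report.

Every stage is logged (inputs/outputs shapes, chosen parameters, elapsed
time) and every random draw flows from the single config seed, so re-running
with the same config byte-reproduces every numeric artifact.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .dataset import (
    ResponseVector,
    SpectraMatrix,
    read_response_csv,
    read_spectra_csv,
    write_response_csv,
    write_spectra_csv,
)
from .exceptions import ConfigError, IrspecError
from .model import (
    HybridModel,
    LSSVMModel,
    PLSModel,
    hybrid_fit,
    median_sq_distance,
    nipals_pls_fit,
    pls_transform,
    tune_hyperparameters,
)
from .preprocess import snv_matrix
from .sampling import SplitIndices, apply_split, kennard_stone
from .synthetic import (
    BandSpec,
    GroundTruth,
    SyntheticConfig,
    generate_aas_absorbance,
    generate_spectra,
)
from .validation import (
    MetricSet,
    ValidationReport,
    build_report,
    external_validation,
    lmo_cv,
    loo_cv,
    select_n_lv,
    y_permutation_test,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "save_model",
    "load_model",
]

DEFAULT_GAMMA_GRID = (1.0, 1e1, 1e2, 1e3, 1e4, 1e5, 1e6)
DEFAULT_SIGMA2_MULTIPLIERS = (0.1, 0.3, 1.0, 3.0, 10.0, 30.0, 100.0)


@dataclass
class PipelineConfig:
    """Everything needed to run the end-to-end analysis.

    Either ``synthetic`` is set (data are generated) or both ``spectra_path``
    and ``response_path`` point to existing CSV files. ``sigma2_grid`` holds
    multipliers of the median squared pairwise score distance — the kernel
    bandwidth is scaled to the score space of each latent-variable count.
    """

    synthetic: SyntheticConfig | None = None
    spectra_path: str | None = None
    response_path: str | None = None
    aas_slope: float = 0.032
    aas_intercept: float = 0.001
    aas_noise_sd: float = 0.005
    n_cal: int = 158
    lv_range: tuple[int, ...] = tuple(range(1, 11))
    tune_lv: int = 5
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    sigma2_grid: tuple[float, ...] = DEFAULT_SIGMA2_MULTIPLIERS
    lmo_fraction: float = 0.2
    lmo_repeats: int = 25
    n_permutations: int = 100
    permutation_lmo_repeats: int = 10
    permutation_loo: bool = True
    seed: int = 1
    output_dir: str = "irspec_run"

    def __post_init__(self) -> None:
        if self.synthetic is None:
            if not (self.spectra_path and self.response_path):
                raise ConfigError(
                    "either a synthetic config or spectra_path + response_path "
                    "must be provided"
                )
            for p in (self.spectra_path, self.response_path):
                if not Path(p).exists():
                    raise ConfigError(f"input file does not exist: {p}")
        if not self.gamma_grid or not self.sigma2_grid:
            raise ConfigError("hyperparameter grids must be non-empty")
        if not self.lv_range:
            raise ConfigError("lv_range must be non-empty")
        if not 0 < self.lmo_fraction < 1:
            raise ConfigError("lmo_fraction must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = _synthetic_from_dict(syn)
        for key in ("lv_range", "gamma_grid", "sigma2_grid"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(synthetic=syn, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _synthetic_from_dict(d: Mapping[str, Any]) -> SyntheticConfig:
    d = dict(d)
    for key in ("analyte_bands", "interferent_bands", "background_bands"):
        if key in d and d[key] is not None:
            bands = []
            for b in d[key]:
                if isinstance(b, Mapping):
                    bands.append(BandSpec(**b))
                else:
                    c, w, a = b
                    bands.append(BandSpec(center=c, width=w, amplitude=a))
            d[key] = bands
    for key in ("conc_range", "wavenumber_grid"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SyntheticConfig(**d)


# ---------------------------------------------------------------------------
# model (de)serialization — plain numeric arrays, no binary state
# ---------------------------------------------------------------------------

def save_model(model: HybridModel, path: str | Path) -> None:
    d = {
        "preprocessing_tag": model.preprocessing_tag,
        "pls": {
            "x_mean": model.pls.x_mean.tolist(),
            "y_mean": model.pls.y_mean,
            "weights": model.pls.weights.tolist(),
            "loadings": model.pls.loadings.tolist(),
            "y_loadings": model.pls.y_loadings.tolist(),
            "rotation": model.pls.rotation.tolist(),
            "n_lv": model.pls.n_lv,
        },
        "lssvm": {
            "support_scores": model.lssvm.support_scores.tolist(),
            "alpha": model.lssvm.alpha.tolist(),
            "b": model.lssvm.b,
            "gamma": model.lssvm.gamma,
            "sigma2": model.lssvm.sigma2,
        },
    }
    Path(path).write_text(json.dumps(d, sort_keys=True) + "\n")


def load_model(path: str | Path) -> HybridModel:
    d = json.loads(Path(path).read_text())
    pls = PLSModel(
        x_mean=np.asarray(d["pls"]["x_mean"], dtype=float),
        y_mean=float(d["pls"]["y_mean"]),
        weights=np.asarray(d["pls"]["weights"], dtype=float),
        loadings=np.asarray(d["pls"]["loadings"], dtype=float),
        y_loadings=np.asarray(d["pls"]["y_loadings"], dtype=float),
        rotation=np.asarray(d["pls"]["rotation"], dtype=float),
        n_lv=int(d["pls"]["n_lv"]),
    )
    lssvm = LSSVMModel(
        support_scores=np.asarray(d["lssvm"]["support_scores"], dtype=float),
        alpha=np.asarray(d["lssvm"]["alpha"], dtype=float),
        b=float(d["lssvm"]["b"]),
        gamma=float(d["lssvm"]["gamma"]),
        sigma2=float(d["lssvm"]["sigma2"]),
    )
    return HybridModel(pls=pls, lssvm=lssvm, preprocessing_tag=d["preprocessing_tag"])


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

class _RunLog:
    def __init__(self) -> None:
        self.records: list[dict] = []

    def stage(self, name: str, **info) -> None:
        self.records.append({"stage": name, **info})

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.records, indent=2, sort_keys=True) + "\n")


def _acquire_data(
    cfg: PipelineConfig, log: _RunLog, outdir: Path | None
) -> tuple[SpectraMatrix, ResponseVector, GroundTruth | None]:
    if cfg.synthetic is not None:
        syn = cfg.synthetic
        m, truth = generate_spectra(syn)
        absorbance = generate_aas_absorbance(
            truth.concentrations,
            slope=cfg.aas_slope,
            intercept=cfg.aas_intercept,
            noise_sd=cfg.aas_noise_sd,
            seed=syn.seed,
        )
        # reference responses as the study would see them: concentrations
        # backed out of the AAS line, carrying the reference-method noise
        c_ref = (absorbance - cfg.aas_intercept) / cfg.aas_slope
        y = ResponseVector(
            values=np.maximum(c_ref, 0.0), sample_ids=list(m.sample_ids)
        )
        log.stage(
            "generate",
            n_samples=m.n_samples,
            n_wavenumbers=m.n_wavenumbers,
            seed=syn.seed,
            conc_range=list(syn.conc_range),
        )
        if outdir is not None:
            write_spectra_csv(m, outdir / "spectra.csv")
            write_response_csv(y, outdir / "response.csv")
        return m, y, truth
    m = read_spectra_csv(cfg.spectra_path)
    y = read_response_csv(cfg.response_path)
    y.check_aligned(m)
    log.stage(
        "load",
        spectra_path=cfg.spectra_path,
        response_path=cfg.response_path,
        n_samples=m.n_samples,
        n_wavenumbers=m.n_wavenumbers,
    )
    return m, y, None


def run_pipeline(
    cfg: PipelineConfig, write_artifacts: bool = True
) -> ValidationReport:
    """Execute all stages in order and return the validation report.

    Artifacts (spectra, split JSON, model JSON, report JSON, run log) are
    written under ``cfg.output_dir`` unless ``write_artifacts`` is False.
    """
    t0 = time.time()
    log = _RunLog()
    log.stage("config", config=_jsonable(cfg.to_dict()))
    outdir: Path | None = None
    if write_artifacts:
        outdir = Path(cfg.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "acquire-data"
    try:
        m, y, _truth = _acquire_data(cfg, log, outdir)

        stage = "snv"
        m_snv = snv_matrix(m)
        log.stage("snv", n_samples=m_snv.n_samples, n_wavenumbers=m_snv.n_wavenumbers)
        if outdir is not None:
            write_spectra_csv(m_snv, outdir / "spectra_snv.csv")

        stage = "kennard-stone"
        split = kennard_stone(m_snv, cfg.n_cal)
        cal_X, cal_y, test_X, test_y = apply_split(m_snv, y, split)
        log.stage("split", n_cal=len(split.calibration), n_test=len(split.test))
        if outdir is not None:
            split.to_json(outdir / "split.json")

        Xc, yc = cal_X.intensities, cal_y.values

        stage = "tune-hyperparameters"
        a_ref = min(cfg.tune_lv, max(cfg.lv_range))
        pls_ref = nipals_pls_fit(Xc, yc, a_ref)
        med_ref = median_sq_distance(pls_transform(pls_ref, Xc))
        sigma2_abs_grid = [mult * med_ref for mult in cfg.sigma2_grid]
        gamma, sigma2_ref = tune_hyperparameters(
            Xc, yc, a_ref, cfg.gamma_grid, sigma2_abs_grid
        )
        sigma2_mult = sigma2_ref / med_ref
        log.stage(
            "tune",
            reference_lv=a_ref,
            gamma=gamma,
            sigma2_multiplier=sigma2_mult,
            median_sq_score_distance=med_ref,
        )

        stage = "per-lv-bandwidths"
        sigma2_by_lv: dict[int, float] = {}
        for A in cfg.lv_range:
            pls_a = nipals_pls_fit(Xc, yc, A)
            sigma2_by_lv[A] = sigma2_mult * median_sq_distance(
                pls_transform(pls_a, Xc)
            )

        stage = "select-lv"
        chosen_lv, loo_table = select_n_lv(
            Xc, yc, cfg.lv_range, gamma, sigma2_ref, sigma2_by_lv=sigma2_by_lv
        )
        log.stage("select_lv", chosen_lv=chosen_lv,
                  loo_press={A: ms.press for A, ms in loo_table.items()})

        stage = "per-lv-metrics"
        per_lv: dict[int, dict[str, MetricSet]] = {}
        for A in sorted(set(int(a) for a in cfg.lv_range)):
            s2 = sigma2_by_lv[A]
            fit_a = hybrid_fit(Xc, yc, A, gamma, s2)
            per_lv[A] = {
                "prediction": MetricSet.from_predictions(yc, fit_a.predict(Xc)),
                "loo": loo_table[A],
                "lmo": lmo_cv(
                    Xc, yc, A, gamma, s2,
                    fraction=cfg.lmo_fraction,
                    n_repeats=cfg.lmo_repeats,
                    seed=cfg.seed,
                ),
            }

        stage = "final-fit"
        sigma2_star = sigma2_by_lv[chosen_lv]
        model = hybrid_fit(Xc, yc, chosen_lv, gamma, sigma2_star)
        if outdir is not None:
            save_model(model, outdir / "model.json")

        stage = "external-validation"
        external = None
        if test_X is not None:
            external = external_validation(model, test_X.intensities, test_y.values)
            log.stage("external", r_squared=external.r_squared, press=external.press)

        stage = "y-permutation"
        permutation = None
        if cfg.n_permutations > 0:
            permutation = y_permutation_test(
                Xc, yc, chosen_lv, gamma, sigma2_star,
                B=cfg.n_permutations,
                seed=cfg.seed,
                lmo_fraction=cfg.lmo_fraction,
                lmo_repeats=cfg.permutation_lmo_repeats,
                compute_loo=cfg.permutation_loo,
            )
            log.stage(
                "permutation",
                B=cfg.n_permutations,
                observed_r2=permutation.observed_r2,
                max_permuted_r2=float(np.max(permutation.permuted_r2)),
                exceedance=permutation.exceedance,
            )

        stage = "report"
        report = build_report(
            per_lv,
            chosen_lv,
            external=external,
            permutation=permutation,
            hyperparameters={
                "gamma": gamma,
                "sigma2": sigma2_star,
                "sigma2_multiplier": sigma2_mult,
                "sigma2_by_lv": {str(k): v for k, v in sigma2_by_lv.items()},
                "n_cal": len(split.calibration),
                "n_test": len(split.test),
                "seed": cfg.seed,
            },
        )
        log.stage("done", elapsed_s=round(time.time() - t0, 3))
        if outdir is not None:
            report.to_json(outdir / "report.json")
            (outdir / "report.txt").write_text(report.render_text())
            log.write(outdir / "run_log.json")
        return report
    except IrspecError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
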