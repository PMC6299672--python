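"""End-to-end campaign orchestration, configuration and report I/O.

``run_campaign`` ties every stage together the way a full assay campaign
runs: simulate (or load) spectra -> preprocess -> Kennard-Stone split ->
per-response outlier screen, variable selection (full / CARS / RF) and PLSR
calibration with the complete metric suite -> grey relational scoring of
the reference chemistry -> PLS-DA classification of the resulting quality
grades. Everything is deterministic given the campaign seed, and a failure
in one response/variant combination is recorded without aborting the rest.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    REFERENCE_COLUMNS,
    ConfigurationError,
    ReferenceTable,
    SpectralDataset,
)
from .gra import GRAConfig, GRAResult, grade_analysis
from .io import (
    read_reference_csv,
    read_spectra_csv,
    write_reference_csv,
    write_spectra_csv,
)
from .partition import SplitResult, chauvenet_outliers, kennard_stone_split
from .pls import (
    calibration_metrics,
    classification_metrics,
    fit_plsda,
    fit_plsr,
    select_components,
    validation_metrics,
)
from .preprocess import PreprocessConfig, msc, preprocess_pipeline, savgol_derivative
from .select import (
    CARSConfig,
    RandomFrogConfig,
    VariableSubset,
    cars_select,
    random_frog_select,
)
from .synth import SimulationConfig, make_component_library, simulate_dataset

VARIANTS = ("full", "cars", "rf")


@dataclass
class PipelineConfig:
    """One campaign: data source, stage settings, responses, seed."""

    seed: int = 0
    spectra_path: str | None = None  # load instead of simulate when set
    reference_path: str | None = None
    n_samples: int = 60
    grid_points: int = 1557
    validation_fraction: float = 0.2
    outlier_screen: str = "residual"  # "residual" | "reference" | "none"
    selectors: tuple[str, ...] = VARIANTS
    responses: tuple[str, ...] = REFERENCE_COLUMNS
    max_components: int = 10
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    cars: CARSConfig = field(default_factory=CARSConfig)
    random_frog: RandomFrogConfig = field(default_factory=RandomFrogConfig)
    gra: GRAConfig = field(default_factory=GRAConfig)
    classify: bool = True

    def validate(self) -> None:
        if (self.spectra_path is None) != (self.reference_path is None):
            raise ConfigurationError("set both spectra_path and reference_path or neither")
        unknown = [r for r in self.responses if r not in REFERENCE_COLUMNS]
        if unknown:
            raise ConfigurationError(f"unknown responses: {unknown}")
        bad = [v for v in self.selectors if v not in VARIANTS]
        if bad:
            raise ConfigurationError(f"unknown selector variants: {bad}")
        if self.outlier_screen not in ("residual", "reference", "none"):
            raise ConfigurationError("outlier_screen must be residual|reference|none")
        self.preprocess.validate()
        self.gra.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selectors"] = list(self.selectors)
        d["responses"] = list(self.responses)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("preprocess", PreprocessConfig), ("cars", CARSConfig),
                         ("random_frog", RandomFrogConfig), ("gra", GRAConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        for key in ("selectors", "responses"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _plain(obj):
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class CampaignReport:
    """Everything one campaign produced, serializable as plain CSV/YAML."""

    calibration: pd.DataFrame
    validation: pd.DataFrame
    classification: pd.DataFrame
    gra: GRAResult
    split: SplitResult
    subsets: dict[tuple[str, str], VariableSubset]
    outliers: dict[str, list[str]]
    errors: list[dict]
    provenance: dict
    log: list[str]

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.calibration.to_csv(out / "calibration.csv", index=False, float_format="%.10g")
        self.validation.to_csv(out / "validation.csv", index=False, float_format="%.10g")
        self.classification.to_csv(out / "classification.csv", index=False,
                                   float_format="%.10g")
        gra_df = pd.concat([self.gra.gamma, self.gra.fqs, self.gra.fqg], axis=1)
        gra_df.to_csv(out / "gra.csv", float_format="%.10g")
        split_rows = [(s, "calibration") for s in self.split.calibration_ids]
        split_rows += [(s, "validation") for s in self.split.validation_ids]
        pd.DataFrame(split_rows, columns=["sample_id", "subset"]).to_csv(
            out / "split.csv", index=False)
        subdir = out / "subsets"
        subdir.mkdir(exist_ok=True)
        wn = self.provenance.get("wavenumbers")
        for (response, variant), subset in self.subsets.items():
            df = pd.DataFrame({
                "index": subset.indices,
                "wavenumber_cm1": (np.asarray(wn)[subset.indices]
                                   if wn is not None else subset.indices),
            })
            if subset.probabilities is not None:
                df["selection_probability"] = subset.probabilities[subset.indices]
            df.to_csv(subdir / f"{response}_{variant}.csv", index=False,
                      float_format="%.10g")
        pd.DataFrame(
            [(resp, ";".join(ids)) for resp, ids in self.outliers.items()],
            columns=["response", "flagged_ids"],
        ).to_csv(out / "outliers.csv", index=False)
        prov = {k: _plain(v) for k, v in self.provenance.items() if k != "wavenumbers"}
        (out / "provenance.yaml").write_text(yaml.safe_dump(prov, sort_keys=True))
        (out / "log.txt").write_text("\n".join(self.log) + "\n")


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def run_campaign(
    config: PipelineConfig,
    spectra: SpectralDataset | None = None,
    reference: ReferenceTable | None = None,
) -> CampaignReport:
    """Execute the full assay campaign described by ``config``.

    ``spectra``/``reference`` override file loading and simulation when
    given (they must share sample IDs).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    log: list[str] = [f"seed={config.seed}", f"config_hash={config.config_hash()}"]
    errors: list[dict] = []

    # --- acquire data -----------------------------------------------------
    if spectra is None or reference is None:
        if config.spectra_path is not None:
            spectra = read_spectra_csv(config.spectra_path)
            reference = read_reference_csv(config.reference_path)
            log.append(f"loaded {spectra.n_samples} spectra from {config.spectra_path}")
        else:
            library = make_component_library(_spawn_seed(rng),
                                             grid_points=config.grid_points)
            sim = SimulationConfig(n=config.n_samples, seed=_spawn_seed(rng))
            spectra, reference = simulate_dataset(library, sim)
            log.append(f"simulated {spectra.n_samples} samples x "
                       f"{spectra.n_variables} wavenumbers")
    reference = reference.select_ids(spectra.ids)

    # --- preprocess & split ----------------------------------------------
    # KS partitioning sees spectra preprocessed with the whole-population MSC
    # mean (no response values involved); modeling matrices are rebuilt below
    # with the calibration-subset MSC reference to keep validation external.
    pre_all, _ = preprocess_pipeline(spectra, config.preprocess)
    split = kennard_stone_split(pre_all, config.validation_fraction)
    log.append(f"split: {len(split.calibration_ids)} calibration / "
               f"{len(split.validation_ids)} validation")

    cal_raw = spectra.select_ids(split.calibration_ids)
    cal_msc = msc(cal_raw, "mean")
    X_cal_ds = savgol_derivative(cal_msc.dataset, config.preprocess)
    if split.validation_ids:
        val_raw = spectra.select_ids(split.validation_ids)
        X_val_ds = savgol_derivative(
            msc(val_raw, cal_msc.reference).dataset, config.preprocess)
    else:
        X_val_ds = None

    X_cal = X_cal_ds.absorbance
    X_val = X_val_ds.absorbance if X_val_ds is not None else None
    ref_cal = reference.select_ids(split.calibration_ids)
    ref_val = (reference.select_ids(split.validation_ids)
               if split.validation_ids else None)

    # --- per-response regression -----------------------------------------
    cal_rows, val_rows = [], []
    subsets: dict[tuple[str, str], VariableSubset] = {}
    outliers: dict[str, list[str]] = {}
    for response in config.responses:
        y_cal_full = ref_cal.response(response)
        keep = np.arange(len(split.calibration_ids))
        flagged: list[str] = []
        if config.outlier_screen != "none":
            try:
                if config.outlier_screen == "residual":
                    k0, _ = select_components(X_cal, y_cal_full, config.max_components)
                    pre_model = fit_plsr(X_cal, y_cal_full, k0)
                    values = pre_model.predict(X_cal) - y_cal_full
                else:
                    values = y_cal_full
                report = chauvenet_outliers(values, split.calibration_ids)
                flagged = report.flagged_ids
            except ConfigurationError as exc:
                errors.append({"stage": "outliers", "response": response,
                               "error": str(exc)})
        outliers[response] = flagged
        if flagged:
            keep = np.array([i for i, s in enumerate(split.calibration_ids)
                             if s not in flagged])
            log.append(f"{response}: removed outliers {flagged}")
        Xc, yc = X_cal[keep], y_cal_full[keep]

        for variant in config.selectors:
            try:
                if variant == "full":
                    idx = np.arange(Xc.shape[1])
                    subset = None
                elif variant == "cars":
                    cfg = CARSConfig(**{**asdict(config.cars),
                                        "seed": _spawn_seed(rng),
                                        "max_components": config.max_components})
                    subset = cars_select(Xc, yc, cfg)
                    idx = subset.indices
                else:
                    cfg = RandomFrogConfig(**{**asdict(config.random_frog),
                                              "seed": _spawn_seed(rng),
                                              "max_components": config.max_components})
                    subset = random_frog_select(Xc, yc, cfg)
                    idx = subset.indices
                if subset is not None:
                    subsets[(response, variant)] = subset
                k, curve = select_components(Xc[:, idx], yc, config.max_components)
                model = fit_plsr(Xc[:, idx], yc, k)
                cal_rep = calibration_metrics(model, Xc[:, idx], yc, curve)
                cal_rows.append({"response": response, "variant": variant,
                                 "n_variables": int(idx.size), **asdict(cal_rep)})
                if X_val is not None and ref_val is not None:
                    val_rep = validation_metrics(model, X_val[:, idx],
                                                 ref_val.response(response))
                    val_rows.append({"response": response, "variant": variant,
                                     **asdict(val_rep)})
                log.append(f"{response}/{variant}: {idx.size} variables, {k} PCs")
            except Exception as exc:  # keep the campaign running
                errors.append({"stage": "regression", "response": response,
                               "variant": variant, "error": str(exc)})
                log.append(f"{response}/{variant}: FAILED ({exc})")

    # --- GRA scoring ------------------------------------------------------
    gra_result = grade_analysis(reference, config.gra)
    log.append("gra: grade counts " + str(gra_result.fqg.value_counts().to_dict()))

    # --- PLS-DA classification -------------------------------------------
    cls_rows = []
    if config.classify and X_val is not None:
        labels_cal = gra_result.fqg.loc[split.calibration_ids].tolist()
        labels_val = gra_result.fqg.loc[split.validation_ids].tolist()
        fqs_cal = gra_result.fqs.loc[split.calibration_ids].to_numpy()
        for variant in config.selectors:
            try:
                if variant == "full":
                    idx = np.arange(X_cal.shape[1])
                elif variant == "cars":
                    cfg = CARSConfig(**{**asdict(config.cars),
                                        "seed": _spawn_seed(rng),
                                        "max_components": config.max_components})
                    subset = cars_select(X_cal, fqs_cal, cfg)
                    subsets[("fqg", variant)] = subset
                    idx = subset.indices
                else:
                    cfg = RandomFrogConfig(**{**asdict(config.random_frog),
                                              "seed": _spawn_seed(rng),
                                              "max_components": config.max_components})
                    subset = random_frog_select(X_cal, fqs_cal, cfg)
                    subsets[("fqg", variant)] = subset
                    idx = subset.indices
                Y_onehot_k, _ = select_components(
                    X_cal[:, idx],
                    _onehot_for_selection(labels_cal),
                    config.max_components,
                )
                da = fit_plsda(X_cal[:, idx], labels_cal, Y_onehot_k)
                rep = classification_metrics(da, X_cal[:, idx], labels_cal,
                                             X_val[:, idx], labels_val)
                cls_rows.append({
                    "variant": variant, "n_variables": int(idx.size),
                    "n_components": rep.n_components, "r2": rep.r2, "q2": rep.q2,
                    "calibration_correct": rep.calibration_correct,
                    "validation_correct": rep.validation_correct,
                })
                log.append(f"fqg/{variant}: correct "
                           f"{rep.calibration_correct:.1f}/{rep.validation_correct:.1f}%")
            except Exception as exc:
                errors.append({"stage": "classification", "variant": variant,
                               "error": str(exc)})
                log.append(f"fqg/{variant}: FAILED ({exc})")

    provenance = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_samples": spectra.n_samples,
        "n_variables": spectra.n_variables,
        "n_calibration": len(split.calibration_ids),
        "n_validation": len(split.validation_ids),
        "wavenumbers": spectra.wavenumbers,
    }
    return CampaignReport(
        calibration=pd.DataFrame(cal_rows),
        validation=pd.DataFrame(val_rows),
        classification=pd.DataFrame(cls_rows),
        gra=gra_result,
        split=split,
        subsets=subsets,
        outliers=outliers,
        errors=errors,
        provenance=provenance,
        log=log,
    )


def _onehot_for_selection(labels: list[str]) -> np.ndarray:
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, l in enumerate(labels):
        Y[i, classes.index(l)] = 1.0
    return Y


def simulate_fixture(seed: int, n: int = 60, grid_points: int = 1557):
    """Convenience: one seeded synthetic campaign's raw inputs."""
    ss = np.random.SeedSequence(seed)
    lib_seed, sim_seed = (int(s.generate_state(1)[0] % (2**31 - 1))
                          for s in ss.spawn(2))
    library = make_component_library(lib_seed, grid_points=grid_points)
    sim = SimulationConfig(n=n, seed=sim_seed)
    spectra, reference = simulate_dataset(library, sim)
    return library, sim, spectra, reference


__all__ = [
    "CampaignReport",
    "PipelineConfig",
    "VARIANTS",
    "read_reference_csv",
    "read_spectra_csv",
    "run_campaign",
    "simulate_fixture",
    "write_reference_csv",
    "write_spectra_csv",
]
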