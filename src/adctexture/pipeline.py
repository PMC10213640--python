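"""End-to-end orchestration: simulate -> preprocess -> extract -> compare ->
split -> select -> train -> evaluate.

The pipeline operates either on files (NIfTI volumes + masks and a clinical
CSV) or fully in memory on synthetic cohorts.  Feature selection runs on
the training split only, so no validation information leaks into the
selected support.  Every stochastic stage derives its seed from the single
pipeline seed; a rerun with the same config is bit-identical for the
logistic model kind.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError
from .evaluation import operating_metrics, roc_auc
from .group_stats import compare_groups, significant_features
from .model import ModelConfig, SplitSpec, train_classifier, undersample_split
from .selection import select_features, solve_l0, standardize_features
from .synthetic import (
    CohortConfig,
    PhantomConfig,
    TextureEffect,
    generate_clinical_cohort,
    generate_lesion_phantom,
    write_cohort_csv,
)
from .texture import FEATURE_NAMES, extract_all
from .volumes import quantize, transfer_mask, window_normalize, write_mask, write_volume

__all__ = [
    "PipelineConfig",
    "CLINICAL_MODEL_COLUMNS",
    "simulate_imaging_cohort",
    "extract_feature_table",
    "clinical_design_matrix",
    "run_pipeline",
    "run_models",
]

logger = logging.getLogger("adctexture")

#: Numeric clinical covariates entering the clinical model (TOAST subtype is
#: one-hot encoded on top of these).
CLINICAL_MODEL_COLUMNS = (
    "age",
    "sex",
    "smoking",
    "drinking",
    "hypertension",
    "hyperlipidemia",
    "diabetes",
    "atrial_fibrillation",
    "nihss",
    "ldl_c",
    "discharge_statin",
    "discharge_antiplatelet",
    "discharge_anticoagulant",
    "stroke_volume",
)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "runs/run0"
    seed: int = 0
    # simulation
    n_patients: int = 300
    texture_effect_on: bool = True
    save_volumes: bool = False
    # file inputs (optional; override simulation)
    clinical_csv: str | None = None
    volumes_dir: str | None = None  # expects <id>_adc.nii.gz, <id>_dwi.nii.gz, <id>_mask.nii.gz
    # preprocessing / extraction
    n_bins: int = 32
    glcm_distance: int = 1
    # selection
    k_max: int = 10
    eta: float = 0.0
    threshold: float = 0.0
    # split / model
    unfav_train_fraction: float = 2.0 / 3.0
    fav_to_unfav_train_ratio: float = 1.5
    model_kind: str = "logistic"
    epochs: int = 300
    subtype: str = "all"  # all | LAA | SAO | ...

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _spawn_seed(seed: int, salt: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    h = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def simulate_imaging_cohort(
    n: int,
    seed: int,
    texture_effect: TextureEffect | None = None,
    phantom_config: PhantomConfig | None = None,
    cohort_config: CohortConfig | None = None,
    n_bins: int = 32,
    glcm_distance: int = 1,
    volumes_dir: Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort with per-patient lesion phantoms and extract features.

    Returns ``(cohort, features)``.  Outcome class drives each phantom's
    texture; the cohort's ``stroke_volume`` column is replaced by the true
    phantom mask volume so the table and the images agree.
    """
    cfg = cohort_config or CohortConfig(n_total=n, seed=_spawn_seed(seed, "cohort"))
    cohort = generate_clinical_cohort(cfg)
    effect = texture_effect if texture_effect is not None else TextureEffect()
    base = phantom_config or PhantomConfig(texture_effect=effect)
    base = PhantomConfig(**{**asdict_phantom(base), "texture_effect": effect})
    rng = np.random.default_rng(_spawn_seed(seed, "phantoms"))
    rows = []
    volumes_ml = np.empty(len(cohort))
    for k, (pid, mrs) in enumerate(zip(cohort["id"], cohort["mrs_90d"])):
        outcome = int(mrs > 2)
        adc, dwi, mask = generate_lesion_phantom(base, outcome, rng=rng)
        volumes_ml[k] = mask.volume_ml()
        lo, hi = float(adc.data.min()), float(adc.data.max())
        wn = window_normalize(adc, width=max(hi - lo, 1e-6), level=(hi + lo) / 2.0)
        q = quantize(wn, transfer_mask(mask, wn), n_bins=n_bins)
        fv = extract_all(q, glcm_distance=glcm_distance)
        rows.append({"id": pid, **fv.as_dict(), "quality_flag": fv.quality_flag})
        if volumes_dir is not None:
            write_volume(adc, volumes_dir / f"{pid}_adc.nii.gz")
            write_volume(dwi, volumes_dir / f"{pid}_dwi.nii.gz")
            write_mask(mask, volumes_dir / f"{pid}_mask.nii.gz")
    cohort = cohort.assign(stroke_volume=np.round(volumes_ml, 4))
    return cohort, pd.DataFrame(rows)


def asdict_phantom(cfg: PhantomConfig) -> dict:
    d = asdict(cfg)
    d.pop("texture_effect")
    return d


def extract_feature_table(
    cohort: pd.DataFrame, volumes_dir: Path, n_bins: int = 32, glcm_distance: int = 1
) -> pd.DataFrame:
    """Extract the 39-feature table from per-patient NIfTI files on disk."""
    from .volumes import read_mask, read_volume

    rows = []
    for pid in cohort["id"]:
        adc = read_volume(volumes_dir / f"{pid}_adc.nii.gz")
        mask = read_mask(volumes_dir / f"{pid}_mask.nii.gz")
        lo, hi = float(adc.data.min()), float(adc.data.max())
        wn = window_normalize(adc, width=max(hi - lo, 1e-6), level=(hi + lo) / 2.0)
        q = quantize(wn, transfer_mask(mask, wn), n_bins=n_bins)
        fv = extract_all(q, glcm_distance=glcm_distance)
        rows.append({"id": pid, **fv.as_dict(), "quality_flag": fv.quality_flag})
    return pd.DataFrame(rows)


def clinical_design_matrix(cohort: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    """Numeric clinical block: covariates plus one-hot TOAST subtype."""
    X = cohort.loc[:, list(CLINICAL_MODEL_COLUMNS)].astype(float)
    dummies = pd.get_dummies(cohort["toast_subtype"], prefix="toast").astype(float)
    X = pd.concat([X, dummies], axis=1)
    return X.to_numpy(), tuple(X.columns)


def run_models(
    cohort: pd.DataFrame,
    features: pd.DataFrame,
    seed: int,
    k_max: int = 10,
    eta: float = 0.0,
    threshold: float = 0.0,
    model_kind: str = "logistic",
    epochs: int = 300,
    split_spec: SplitSpec | None = None,
) -> dict:
    """Split, select texture features on the training set, fit the three
    models (clinical / texture / combined) and evaluate on validation.

    Returns a dict with the split manifest, the sparse-selection report and
    per-model ROC results and operating metrics.
    """
    usable = ~features["quality_flag"].astype(bool).to_numpy()
    cohort = cohort.loc[usable].reset_index(drop=True)
    features = features.loc[usable].reset_index(drop=True)

    spec = split_spec or SplitSpec(seed=_spawn_seed(seed, "split"))
    train_ids, val_ids = undersample_split(cohort, spec)
    idx = {pid: k for k, pid in enumerate(cohort["id"])}
    tr = np.array([idx[i] for i in train_ids])
    va = np.array([idx[i] for i in val_ids])
    y = (cohort["mrs_90d"].to_numpy() > 2).astype(int)

    tex = features.loc[:, list(FEATURE_NAMES)].to_numpy()
    fm = standardize_features(tex[tr], names=FEATURE_NAMES)
    sol = solve_l0(fm, np.where(y[tr] == 1, 1.0, -1.0), k_max=k_max, eta=eta)
    sel = select_features(sol, threshold=threshold)
    if not sel:  # nothing passed the threshold: keep every feature
        sel = tuple(range(len(FEATURE_NAMES)))
    sel_names = tuple(FEATURE_NAMES[j] for j in sel)

    clin, clin_names = clinical_design_matrix(cohort)
    blocks = {
        "clinical": (clin, clin_names),
        "texture": (tex[:, list(sel)], sel_names),
        "combined": (np.hstack([clin, tex[:, list(sel)]]), clin_names + sel_names),
    }
    out: dict = {
        "train_ids": train_ids,
        "val_ids": val_ids,
        "selection": {
            "support": [int(j) for j in sol.support],
            "selected": list(sel_names),
            "coefficients": {FEATURE_NAMES[j]: float(sol.w[j]) for j in sol.support},
            "residual_norms": list(sol.residual_norms),
            "eta": sol.eta,
        },
        "models": {},
    }
    for name, (X, names) in blocks.items():
        cfg = ModelConfig(
            model_kind=model_kind, epochs=epochs, seed=_spawn_seed(seed, f"model:{name}")
        )
        model = train_classifier(X[tr], y[tr], cfg, feature_names=names)
        scores = model.predict_proba(X[va])
        roc = roc_auc(scores, y[va])
        op = operating_metrics(roc)
        out["models"][name] = {"model": model, "roc": roc, "operating": op}
    return out


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact set into ``config.out_dir``.

    Artifacts: ``cohort.csv``, ``features.csv``, ``comparison.csv``,
    ``significant_features.csv``, ``selection.json``, ``split_train.csv`` /
    ``split_val.csv``, ``model_<name>.npz``, ``metrics.csv``,
    ``roc_points.csv``, ``manifest.json`` and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    input_hashes = {}
    try:
        logger.info("adctexture %s, numpy %s, seed %d", __version__, np.__version__, config.seed)
        if config.clinical_csv is not None:
            from .synthetic import read_cohort_csv

            cpath = Path(config.clinical_csv)
            if not cpath.exists():
                raise ConfigurationError(f"clinical table not found: {cpath}")
            cohort = read_cohort_csv(cpath)
            input_hashes[str(cpath)] = _hash_file(cpath)
            vdir = Path(config.volumes_dir or ".")
            if not vdir.exists():
                raise ConfigurationError(f"volumes directory not found: {vdir}")
            logger.info("extracting features for %d patients from %s", len(cohort), vdir)
            features = extract_feature_table(
                cohort, vdir, n_bins=config.n_bins, glcm_distance=config.glcm_distance
            )
        else:
            effect = TextureEffect() if config.texture_effect_on else TextureEffect.none()
            vdir = None
            if config.save_volumes:
                vdir = out / "volumes"
                vdir.mkdir(exist_ok=True)
            logger.info("simulating cohort of %d patients", config.n_patients)
            cohort, features = simulate_imaging_cohort(
                config.n_patients,
                config.seed,
                texture_effect=effect,
                n_bins=config.n_bins,
                glcm_distance=config.glcm_distance,
                volumes_dir=vdir,
            )
        if config.subtype != "all":
            keep = (cohort["toast_subtype"] == config.subtype).to_numpy()
            if keep.sum() < 20:
                raise ConfigurationError(
                    f"subtype {config.subtype!r} has only {int(keep.sum())} patients"
                )
            cohort = cohort.loc[keep].reset_index(drop=True)
            features = features.loc[keep].reset_index(drop=True)
            logger.info("restricted to subtype %s: %d patients", config.subtype, len(cohort))

        write_cohort_csv(cohort, out / "cohort.csv")
        features.to_csv(out / "features.csv", index=False)

        report = compare_groups(cohort, features)
        report.to_csv(out / "comparison.csv", index=False)
        significant_features(report).to_csv(out / "significant_features.csv", index=False)
        logger.info(
            "comparison: %d variables, %d significant texture features",
            len(report),
            len(significant_features(report)),
        )

        spec = SplitSpec(
            unfav_train_fraction=config.unfav_train_fraction,
            fav_to_unfav_train_ratio=config.fav_to_unfav_train_ratio,
            seed=_spawn_seed(config.seed, "split"),
        )
        res = run_models(
            cohort,
            features,
            seed=config.seed,
            k_max=config.k_max,
            eta=config.eta,
            threshold=config.threshold,
            model_kind=config.model_kind,
            epochs=config.epochs,
            split_spec=spec,
        )
        pd.DataFrame({"id": res["train_ids"]}).to_csv(out / "split_train.csv", index=False)
        pd.DataFrame({"id": res["val_ids"]}).to_csv(out / "split_val.csv", index=False)
        with open(out / "selection.json", "w") as fh:
            json.dump(res["selection"], fh, indent=2)

        metrics = pd.DataFrame(
            {
                name: {
                    "AUC": m["roc"].auc,
                    "Accuracy": m["operating"].accuracy,
                    "Sensitivity": m["operating"].sensitivity,
                    "Specificity": m["operating"].specificity,
                }
                for name, m in res["models"].items()
            }
        )
        metrics.to_csv(out / "metrics.csv")
        roc_rows = []
        for name, m in res["models"].items():
            roc = m["roc"]
            for t, fp, tp in zip(roc.thresholds, roc.fpr, roc.tpr):
                roc_rows.append({"model": name, "threshold": t, "fpr": fp, "tpr": tp})
            m["model"].save(out / f"model_{name}.npz")
        pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)
        logger.info("validation AUCs: %s", {k: round(v["roc"].auc, 3) for k, v in res["models"].items()})

        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "config": asdict(config),
            "seed": config.seed,
            "stage_seeds": {
                "cohort": _spawn_seed(config.seed, "cohort"),
                "phantoms": _spawn_seed(config.seed, "phantoms"),
                "split": _spawn_seed(config.seed, "split"),
                "models": {
                    n: _spawn_seed(config.seed, f"model:{n}") for n in ("clinical", "texture", "combined")
                },
            },
            "input_hashes": input_hashes,
            "artifact_hashes": {
                p.name: _hash_file(p) for p in sorted(out.glob("*.csv"))
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("run complete: %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
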