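"""End-to-end pipeline: simulate (or ingest) -> extract -> model -> report.

One :class:`PipelineConfig` drives every stage; all randomness flows from a
single root seed through named child streams, so changing e.g. the radiomics
settings cannot perturb the survival simulation.  All CSV outputs use a
fixed column order and a fixed float format, making two runs with the same
config byte-identical and diffs meaningful.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import survival as surv
from .estimators import BackwardEliminationCox, CoxPHModel, MedianRiskStratifier, UnivariableCoxScreen, WLTBFeatureExtractor
from .features import FEATURE_COLUMNS
from .phantom import (
    PhantomConfig,
    SurvivalSimConfig,
    config_hash,
    generate_phantom,
    read_segmentation,
    simulate_clinical,
    simulate_survival,
    write_cohort,
)
from .volumes import ImageVolume, SegmentationSet, load_nifti

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "ingest_external",
    "CohortHandle",
    "derive_seed",
]


def derive_seed(root_seed: int, stream: str) -> int:
    """Deterministic per-stage child seed (< 2^31) from a root seed."""
    ss = np.random.SeedSequence((int(root_seed), zlib.crc32(stream.encode())))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RadiomicsOptions:
    bin_width: float = 25.0
    aggregation: str = "merge"
    wavelet: str = "coif1"
    subband: str = "HLH"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    survival_sim: SurvivalSimConfig = field(
        default_factory=lambda: SurvivalSimConfig(
            beta={"tbs": 0.5, "bilobar": 0.4, "log_crp": 0.3}
        )
    )
    radiomics: RadiomicsOptions = field(default_factory=RadiomicsOptions)
    baseline_model: str = "haas"
    screen_alpha: float = 0.2
    write_volumes: bool = False
    write_plots: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "phantom" in d:
            d["phantom"] = PhantomConfig(**_detuple(d["phantom"]))
        if "survival_sim" in d:
            d["survival_sim"] = SurvivalSimConfig(**d["survival_sim"])
        if "radiomics" in d:
            d["radiomics"] = RadiomicsOptions(**d["radiomics"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _detuple(d: dict) -> dict:
    out = dict(d)
    for key in ("grid_shape", "voxel_spacing", "liver_semi_axes", "lobe_involvement_probs"):
        if key in out and out[key] is not None:
            out[key] = tuple(out[key])
    return out


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    n_subjects: int
    subjects_analyzed: int
    excluded: dict[str, int]
    stage_seconds: dict[str, float]
    files: list[str]
    warnings: list[str]
    candidates: list[str]
    retained: list[str]
    lr_statistic: float
    lr_p_value: float
    baseline_c_index: float
    extended_c_index: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _write_csv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full simulate -> extract -> model pipeline; write reports.

    Outputs under ``out_dir``: features.csv, clinical.csv, table2.csv
    (univariable screen), table3.csv (baseline and extended fits with
    C-indices and the LR p-value), stratification.csv, correlation.csv,
    manifest.json, plus optional NIfTI volumes and KM/heatmap plots.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    stage_seconds: dict[str, float] = {}
    files: list[str] = []
    cfg_hash = config_hash(config)

    phantom_cfg = dataclasses.replace(config.phantom, seed=derive_seed(config.seed, "phantom"))
    n = phantom_cfg.subjects

    t0 = _time.perf_counter()
    subjects = [generate_phantom(phantom_cfg, i) for i in range(n)]
    stage_seconds["simulate"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    extractor = WLTBFeatureExtractor(
        bin_width=config.radiomics.bin_width,
        aggregation=config.radiomics.aggregation,
        wavelet=config.radiomics.wavelet,
        subband=config.radiomics.subband,
    ).fit()
    features = extractor.transform(subjects)
    features.insert(0, "subject_id", [f"sub-{i:04d}" for i in range(n)])
    stage_seconds["extract"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    clinical = simulate_clinical(n, derive_seed(config.seed, "clinical"))
    joined = features.merge(clinical, on="subject_id")
    joined["log_crp"] = np.log(joined["crp_mg_dl"].clip(lower=0.01))
    joined["log_bilirubin"] = np.log(joined["bilirubin_mg_dl"].clip(lower=0.01))
    sim_cfg = dataclasses.replace(config.survival_sim, seed=derive_seed(config.seed, "survival"))
    outcome = simulate_survival(joined, sim_cfg)
    clinical = clinical.assign(
        time_months=outcome["time_months"].values, event=outcome["event"].values
    )
    stage_seconds["clinical"] = _time.perf_counter() - t0

    if config.write_volumes:
        write_cohort(out / "cohort", [s[0] for s in subjects], [s[1] for s in subjects], clinical, phantom_cfg)
        files.append("cohort/")
    _write_csv(features, out / "features.csv", index=False)
    _write_csv(clinical, out / "clinical.csv", index=False)
    files += ["features.csv", "clinical.csv"]

    time_m = clinical["time_months"].values
    event = clinical["event"].values

    t0 = _time.perf_counter()
    screen = UnivariableCoxScreen(alpha=config.screen_alpha).fit(
        features[FEATURE_COLUMNS], (time_m, event)
    )
    _write_csv(screen.report_, out / "table2.csv", index=True)
    files.append("table2.csv")
    stage_seconds["screen"] = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    if config.baseline_model == "haas":
        clin_design = surv.haas_design(clinical)
    elif config.baseline_model == "xue":
        clin_design = surv.xue_design(clinical)
    else:
        raise ValueError(f"unknown baseline model {config.baseline_model!r}")
    design = pd.concat([clin_design, features[screen.candidates_]], axis=1)
    elim = BackwardEliminationCox(forced=list(clin_design.columns)).fit(design, (time_m, event))
    comparison = elim.compare_to_baseline()
    stage_seconds["fit"] = _time.perf_counter() - t0
    warnings_log += elim.result_.warnings_

    rows = []
    for model_name, res in (("baseline", elim.baseline_result_), ("extended", elim.result_)):
        for term, s in res.summary.iterrows():
            rows.append(
                {
                    "model": model_name,
                    "term": term,
                    "hr": s["hr"],
                    "hr_ci_lower": s["hr_ci_lower"],
                    "hr_ci_upper": s["hr_ci_upper"],
                    "wald_p": s["wald_p"],
                    "c_index": res.c_index,
                    "aic": res.aic,
                    "lr_p_vs_baseline": comparison.p_value if model_name == "extended" else np.nan,
                }
            )
    _write_csv(pd.DataFrame(rows), out / "table3.csv", index=False)
    files.append("table3.csv")

    t0 = _time.perf_counter()
    strat = surv.stratify_risk(elim.result_, design, time_m, event)
    strat_df = pd.DataFrame(
        {
            "subject_id": features["subject_id"],
            "risk_group": strat.group_assignment.values,
            "time_months": time_m,
            "event": event,
        }
    )
    _write_csv(strat_df, out / "stratification.csv", index=False)
    files.append("stratification.csv")

    corr = surv.correlation_report(
        joined[FEATURE_COLUMNS + ["ecog", "crp_mg_dl", "bilirubin_mg_dl", "ca19_9_u_ml"]]
    )
    _write_csv(corr.ordered_matrix(), out / "correlation.csv", index=True)
    files.append("correlation.csv")
    stage_seconds["report"] = _time.perf_counter() - t0

    if config.write_plots:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        strat.km_high.plot_survival_function(ax=ax)
        strat.km_low.plot_survival_function(ax=ax)
        ax.set_xlabel("months")
        ax.set_ylabel("survival probability")
        ax.set_title(f"log-rank p = {strat.logrank_p:.2g}")
        fig.savefig(out / "km_risk_groups.png", dpi=150)
        plt.close(fig)
        corr.plot_heatmap(out / "correlation_heatmap.png")
        files += ["km_risk_groups.png", "correlation_heatmap.png"]

    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.seed,
        n_subjects=n,
        subjects_analyzed=n,
        excluded={},
        stage_seconds=stage_seconds,
        files=files,
        warnings=warnings_log,
        candidates=screen.candidates_,
        retained=elim.retained_candidates_,
        lr_statistic=comparison.lr_statistic,
        lr_p_value=comparison.p_value,
        baseline_c_index=comparison.baseline_c_index,
        extended_c_index=comparison.extended_c_index,
    )
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# external-cohort ingestion
# ---------------------------------------------------------------------------

@dataclass
class CohortHandle:
    """Validated external cohort: loaded subjects plus exclusion accounting."""

    subjects: list[tuple[str, ImageVolume, SegmentationSet]]
    clinical: pd.DataFrame
    excluded: dict[str, str]  # subject_id -> reason
    problems: list[str]

    @property
    def n_in(self) -> int:
        return len(self.subjects) + len(self.excluded)


def ingest_external(image_dir, labels_dir=None, clinical_csv=None, affine_tol: float = 1e-3) -> CohortHandle:
    """Load and validate an external cohort of NIfTI image/label pairs.

    Expects ``<id>_image.nii.gz`` and ``<id>_labels.nii.gz`` pairs (labels in
    the same directory unless ``labels_dir`` is given) and a clinical CSV
    keyed on ``subject_id``.  Subjects are rejected for grid/spacing
    mismatches, lesion voxels outside the liver, or missing clinical rows;
    subjects whose lesion map is empty are excluded with reason
    "no visible metastases".  Never raises on a bad subject — everything is
    reported in the returned handle.
    """
    image_dir = Path(image_dir)
    labels_dir = Path(labels_dir) if labels_dir is not None else image_dir
    clinical = pd.read_csv(clinical_csv) if clinical_csv is not None else None
    known = set(clinical["subject_id"]) if clinical is not None else None

    subjects: list[tuple[str, ImageVolume, SegmentationSet]] = []
    excluded: dict[str, str] = {}
    problems: list[str] = []
    for img_path in sorted(image_dir.glob("*_image.nii.gz")):
        sid = img_path.name[: -len("_image.nii.gz")]
        lbl_path = labels_dir / f"{sid}_labels.nii.gz"
        if not lbl_path.exists():
            excluded[sid] = "missing label volume"
            continue
        values, spacing = load_nifti(img_path)
        seg = read_segmentation(lbl_path)
        if values.shape != seg.shape:
            excluded[sid] = f"grid mismatch: image {values.shape} vs labels {seg.shape}"
            continue
        if np.any(np.abs(np.subtract(spacing, seg.spacing)) > affine_tol):
            excluded[sid] = f"spacing mismatch beyond tolerance: {spacing} vs {seg.spacing}"
            continue
        seg_problems = seg.validate()
        if seg_problems:
            excluded[sid] = "; ".join(seg_problems)
            continue
        if seg.n_lesions == 0:
            excluded[sid] = "no visible metastases"
            continue
        if known is not None and sid not in known:
            excluded[sid] = "no clinical record"
            continue
        subjects.append((sid, ImageVolume(values, spacing), seg))
    if clinical is not None:
        required = {"subject_id", "ecog", "crp_mg_dl", "bilirubin_mg_dl", "ca19_9_u_ml", "time_months", "event"}
        missing_cols = required - set(clinical.columns)
        if missing_cols:
            problems.append(f"clinical table missing columns: {sorted(missing_cols)}")
        ids = [s[0] for s in subjects]
        clinical = clinical[clinical["subject_id"].isin(ids)].reset_index(drop=True)
    for sid, reason in excluded.items():
        log.warning("ingest: subject %s excluded (%s)", sid, reason)
    return CohortHandle(
        subjects=subjects,
        clinical=clinical if clinical is not None else pd.DataFrame(),
        excluded=excluded,
        problems=problems,
    )
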