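"""End-to-end workflow: simulate (or ingest) -> extract -> aggregate ->
endpoints -> repeated-CV evaluation -> risk stratification.

Every stage writes plain-format artifacts (CSV/JSON, NIfTI for images) into
the run directory, stamped with a hash of the run configuration, and later
stages can resume from cached artifacts.  A single master seed fans out to
per-stage seeds through a documented SeedSequence derivation so stages are
reproducible yet statistically independent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import endpoints as ep
from . import evaluate as ev
from . import survival as sv
from .features import ExtractionConfig, LesionImage, extract_lesion_features, feature_schema
from .synth import (
    CLINICAL_COLUMNS,
    ClinicalRecord,
    GeneratorConfig,
    generate_cohort,
    write_clinical_csv,
    write_latent_csv,
    write_lesion_index,
)

log = logging.getLogger("melrad")

STAGES = ("simulate", "extract", "aggregate", "evaluate", "stratify")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str = "melrad_run"
    seed: int = 0
    n_patients: int = 120
    radiomic_effect: float = 0.3
    clinical_effects: dict[str, float] = field(default_factory=dict)
    lesion_count_scale: float = 1.0
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    wavelet: str | None = "coif1"
    bin_width: float = 25.0
    repetitions: int = 10
    folds: int = 5
    n_bootstrap: int = 1000
    fcbf_delta: float = 0.0
    write_niftis: bool = False
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["log_sigmas_mm"] = list(self.log_sigmas_mm)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "log_sigmas_mm" in d:
            d["log_sigmas_mm"] = tuple(d["log_sigmas_mm"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "stages")}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the master seed (documented order:
        SeedSequence(master).spawn, one child per pipeline stage)."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(
            np.random.default_rng(children[STAGES.index(stage)]).integers(2**31)
        )

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_patients=self.n_patients,
            seed=self.stage_seed("simulate"),
            radiomic_effect=self.radiomic_effect,
            clinical_effects=dict(self.clinical_effects) or {},
            lesion_count_scale=self.lesion_count_scale,
        )

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            log_sigmas_mm=tuple(self.log_sigmas_mm),
            wavelet=self.wavelet,
            bin_width=self.bin_width,
        )


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    payload = {"config_hash": cfg.config_hash, **obj} if isinstance(obj, dict) else obj
    path.write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


# ---------------------------------------------------------------------------
# real-data ingestion
# ---------------------------------------------------------------------------


def ingest_real(
    clinical_csv: str | Path,
    lesion_index_csv: str | Path,
    nifti_dir: str | Path,
) -> tuple[list[ClinicalRecord], list[agg.Lesion]]:
    """Load and validate external data shaped like the synthetic exports:
    a clinical table, a lesion index, and per-lesion image/mask NIfTI pairs
    named <lesion_id>_image.nii.gz / <lesion_id>_mask.nii.gz."""
    import nibabel as nib

    errors: list[str] = []
    clin = pd.read_csv(clinical_csv, dtype=str).fillna("n/a")
    missing_cols = set(CLINICAL_COLUMNS) - set(clin.columns)
    if missing_cols:
        raise ValueError(f"clinical table missing columns: {sorted(missing_cols)}")

    records: list[ClinicalRecord] = []
    for i, row in clin.iterrows():
        resp = row["response_3mo"]
        if resp not in ("CR", "PR", "SD", "PD", "n/a"):
            errors.append(f"clinical row {i}: unknown response code {resp!r}")
            continue
        records.append(
            ClinicalRecord(
                patient_id=row["patient_id"],
                age=float(row["age"]),
                sex=row["sex"],
                primary_site=row["primary_site"],
                histology=row["histology"],
                braf_mutated=_parse_bin(row["braf_mutated"]),
                ldh_elevated=_parse_bin(row["ldh_elevated"]),
                s100_elevated=_parse_bin(row["s100_elevated"]),
                gt3_metastatic_organs=int(row["gt3_metastatic_organs"]),
                cerebral_mets=int(row["cerebral_mets"]),
                hepatic_mets=int(row["hepatic_mets"]),
                therapy=row["therapy"],
                response_3mo=None if resp == "n/a" else resp,
                alive_6mo=_parse_bin(row["alive_6mo"]),
                alive_12mo=_parse_bin(row["alive_12mo"]),
                os_time=float(row["os_time"]),
                os_event=int(row["os_event"]),
            )
        )

    nifti_dir = Path(nifti_dir)
    idx = pd.read_csv(lesion_index_csv, dtype=str)
    lesions: list[agg.Lesion] = []
    for i, row in idx.iterrows():
        organ = row["organ_type"]
        if organ not in agg.ORGAN_TYPES:
            errors.append(
                f"lesion {row['lesion_id']}: organ {organ!r} not in vocabulary "
                f"{agg.ORGAN_TYPES}"
            )
            continue
        img_path = nifti_dir / f"{row['lesion_id']}_image.nii.gz"
        msk_path = nifti_dir / f"{row['lesion_id']}_mask.nii.gz"
        if not img_path.exists() or not msk_path.exists():
            errors.append(f"lesion {row['lesion_id']}: missing NIfTI pair")
            continue
        img = nib.load(img_path)
        msk = nib.load(msk_path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        mdata = np.asarray(msk.dataobj) > 0
        if data.shape != mdata.shape:
            errors.append(
                f"lesion {row['lesion_id']}: image shape {data.shape} != mask shape {mdata.shape}"
            )
            continue
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        image = LesionImage(data, mdata, spacing)
        vol = float(mdata.sum() * np.prod(spacing))
        lesions.append(
            agg.Lesion(
                lesion_id=row["lesion_id"],
                patient_id=row["patient_id"],
                organ_type=organ,
                volume=vol,
                image=image,
            )
        )
    if errors:
        raise ValueError("ingestion failed:\n" + "\n".join(errors))
    return records, lesions


def _parse_bin(v: str) -> int | None:
    return None if v in ("n/a", "", "nan") else int(float(v))


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the results bundle.

    Stages not selected are loaded from the cached artifacts of a previous
    run in the same directory (an error names the stage to re-run when an
    artifact is missing).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json({"config": cfg.to_dict()}, out / "run_config.json", cfg)
    bundle: dict = {}

    records: list[ClinicalRecord] | None = None
    lesions: list[agg.Lesion] | None = None

    if "simulate" in cfg.stages:
        log.info("simulate: n=%d seed=%d", cfg.n_patients, cfg.stage_seed("simulate"))
        records, lesions, z = generate_cohort(cfg.generator_config())
        write_clinical_csv(records, out / "clinical.csv")
        write_lesion_index(lesions, out / "lesion_index.csv")
        write_latent_csv(records, z, out / "latent_factors.csv")
        if cfg.write_niftis:
            from .synth import write_lesion_niftis

            write_lesion_niftis(lesions, out / "nifti")
    bundle["records"] = records

    feat_path = out / "lesion_features.csv"
    if "extract" in cfg.stages:
        if lesions is None:
            raise RuntimeError("no lesions in memory; run the 'simulate' stage first")
        xcfg = cfg.extraction_config()
        log.info("extract: %d lesions, %d features", len(lesions), len(feature_schema(xcfg)))
        rows = {}
        for l in lesions:
            l.features = extract_lesion_features(l.image, xcfg)
            rows[l.lesion_id] = l.features
        fdf = pd.DataFrame.from_dict(rows, orient="index")
        fdf.index.name = "lesion_id"
        fdf.to_csv(feat_path)
        _write_json(
            {"extraction_config": dataclasses.asdict(xcfg), "n_features": fdf.shape[1]},
            out / "lesion_features.json", cfg,
        )

    patient_path = out / "patient_features.csv"
    if "aggregate" in cfg.stages:
        if lesions is None or any(l.features is None for l in lesions):
            # resume from cached per-lesion features
            if not feat_path.exists() or not (out / "lesion_index.csv").exists():
                raise RuntimeError("lesion features unavailable; re-run the 'extract' stage")
            fdf = pd.read_csv(feat_path, index_col="lesion_id")
            idx = pd.read_csv(out / "lesion_index.csv")
            lesions = [
                agg.Lesion(
                    lesion_id=row.lesion_id, patient_id=row.patient_id,
                    organ_type=row.organ_type, volume=float(row.volume_mm3),
                    features=fdf.loc[row.lesion_id].to_dict(),
                )
                for row in idx.itertuples()
            ]
        pdf = agg.aggregate_cohort(lesions)
        pdf.to_csv(patient_path)
        log.info("aggregate: %d patients x %d features", *pdf.shape)
    elif {"evaluate", "stratify"} & set(cfg.stages):
        if not patient_path.exists():
            raise RuntimeError("missing patient_features.csv; re-run the 'aggregate' stage")
        pdf = pd.read_csv(patient_path, index_col="patient_id")
    else:
        pdf = None

    if {"evaluate", "stratify"} & set(cfg.stages):
        if records is None:
            clin_path = out / "clinical.csv"
            if not clin_path.exists():
                raise RuntimeError("missing clinical.csv; re-run the 'simulate' stage")
            records, _ = _load_records(clin_path)
        bundle["records"] = records

    if "evaluate" in cfg.stages:
        bundle.update(_evaluate_stage(cfg, records, pdf, out))

    if "stratify" in cfg.stages:
        cv12 = bundle.get("cv", {}).get("surv_12mo")
        if cv12 is None:
            raise RuntimeError("12-month CV predictions unavailable; re-run 'evaluate'")
        bundle["stratification"] = _stratify_stage(cfg, records, cv12, out)

    return bundle


def _load_records(path: Path) -> tuple[list[ClinicalRecord], pd.DataFrame]:
    df = pd.read_csv(path, dtype=str)
    from .pipeline import ingest_real  # reuse row parsing

    records = []
    for _, row in df.iterrows():
        resp = row["response_3mo"]
        records.append(
            ClinicalRecord(
                patient_id=row["patient_id"], age=float(row["age"]), sex=row["sex"],
                primary_site=row["primary_site"], histology=row["histology"],
                braf_mutated=_parse_bin(row["braf_mutated"]),
                ldh_elevated=_parse_bin(row["ldh_elevated"]),
                s100_elevated=_parse_bin(row["s100_elevated"]),
                gt3_metastatic_organs=int(row["gt3_metastatic_organs"]),
                cerebral_mets=int(row["cerebral_mets"]),
                hepatic_mets=int(row["hepatic_mets"]), therapy=row["therapy"],
                response_3mo=None if resp == "n/a" else resp,
                alive_6mo=_parse_bin(row["alive_6mo"]),
                alive_12mo=_parse_bin(row["alive_12mo"]),
                os_time=float(row["os_time"]), os_event=int(row["os_event"]),
            )
        )
    return records, df


def _evaluate_stage(cfg: RunConfig, records, pdf: pd.DataFrame, out: Path) -> dict:
    clinical = ep.clinical_feature_frame(records)
    labels = ep.build_endpoints(records)
    counts = ep.endpoint_counts(labels, len(records))
    scheme_seed = cfg.stage_seed("evaluate")
    boot_seed = cfg.stage_seed("stratify") + 1

    report_rows = []
    roc_frames = []
    cv_bundle: dict = {}
    logs_all: dict = {}
    for epname, lab in labels.items():
        scheme = ev.CVScheme(cfg.repetitions, cfg.folds, scheme_seed)
        res = ev.run_repeated_cv(
            clinical, pdf, lab, scheme, fcbf_delta=cfg.fcbf_delta, model_seed=scheme_seed
        )
        cv_bundle[epname] = res
        logs_all[epname] = res.selection_logs
        idx = ev.bootstrap_indices(len(lab), cfg.n_bootstrap, boot_seed)
        summaries = {}
        for ps in filter(None, (res.baseline, res.extended)):
            s = ev.bootstrap_auc_ci(ps, indices=idx, seed=boot_seed)
            summaries[ps.model] = s
            report_rows.append({
                **s.to_dict(),
                "n_class0": counts.loc[epname, "n_class0"],
                "n_class1": counts.loc[epname, "n_class1"],
            })
            roc = ev.mean_roc(ps, B=min(cfg.n_bootstrap, 250), seed=boot_seed)
            roc_frames.append(pd.DataFrame({
                "endpoint": epname, "model": ps.model, "fpr": roc.fpr,
                "tpr": roc.tpr_mean, "tpr_low": roc.tpr_low, "tpr_high": roc.tpr_high,
            }))
        if len(summaries) == 2:
            comp = ev.compare_models(summaries["baseline"], summaries["extended"])
            report_rows.append({"endpoint": epname, "model": "comparison", **comp})

    # audit artifacts: endpoint label tables and a preprocessor state fitted
    # on each endpoint's full included cohort (per-fold states are ephemeral)
    audit = {}
    for epname, lab in labels.items():
        state = fit_audit = None
        try:
            fit_audit = ep.fit_preprocessor(clinical.loc[lab.index], ep.CLINICAL_FEATURE_KINDS)
        except ValueError:
            pass
        audit[epname] = {
            "labels": {str(k): int(v) for k, v in lab.items()},
            "preprocessor": fit_audit.to_dict() if fit_audit else None,
        }
    _write_json({"endpoints": audit}, out / "endpoint_audit.json", cfg)

    report = pd.DataFrame(report_rows)
    report.to_csv(out / "auc_report.csv", index=False)
    _write_json({"report": report_rows}, out / "auc_report.json", cfg)
    pd.concat(roc_frames).to_csv(out / "roc_curves.csv", index=False)
    _write_json({"selection_logs": logs_all}, out / "fcbf_logs.json", cfg)
    counts.to_csv(out / "endpoint_counts.csv")
    return {"cv": cv_bundle, "report": report, "endpoint_counts": counts}


def _stratify_stage(cfg: RunConfig, records, cv12: ev.CVResult, out: Path) -> dict:
    result: dict = {}
    for ps in filter(None, (cv12.baseline, cv12.extended)):
        strat = sv.risk_stratification(records, ps, repetition=0)
        result[ps.model] = strat
        for g in ("low", "high"):
            strat[f"km_{g}"].to_frame().to_csv(
                out / f"km_{ps.model}_{g}.csv", index=False
            )
        _write_json(
            {
                "model": ps.model,
                "logrank_statistic": strat["logrank"].statistic,
                "logrank_p": strat["logrank"].p_value,
                "n_low": int((strat["groups"] == "low").sum()),
                "n_high": int((strat["groups"] == "high").sum()),
            },
            out / f"logrank_{ps.model}.json", cfg,
        )
        _plot_km(strat, out / f"km_{ps.model}.png", ps.model)
    return result


def _plot_km(strat: dict, path: Path, model: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, color in (("low", "tab:blue"), ("high", "tab:red")):
        c = strat[f"km_{g}"]
        ax.step(c.times, c.survival, where="post", color=color, label=f"{g}-risk")
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    ax.set_title(f"{model} model, p={strat['logrank'].p_value:.3f} (log-rank)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
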