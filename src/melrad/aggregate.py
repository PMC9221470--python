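"""Patient-level aggregation of lesion-wise radiomic features.

A metastatic patient carries many segmented lesions; models operate on one
vector per patient.  Each lesion-wise feature is aggregated four ways:

1. value of the largest lesion (by volume);
2. volume-weighted mean over the three largest lesions;
3. value of the most predictive lesion;
4. volume-weighted mean over the three most predictive lesions.

"Most predictive" orders lesions first by the clinical predictiveness of
their organ of origin (liver > adrenal gland/heart/spleen > skeletal > lung
> lymph nodes > soft tissue/skin > other), then by volume descending within
an organ tier.  In addition, 20 tumour-burden features are appended: lesion
count and total volume overall and per organ type.  With the full 1316-entry
lesion schema this yields 4 x 1316 + 20 = 5284 entries per patient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import LesionImage

ORGAN_TYPES = (
    "liver",
    "adrenal gland",
    "heart",
    "spleen",
    "skeletal",
    "lung",
    "lymph nodes",
    "soft tissue/skin",
    "other",
)

# predictiveness tiers; adrenal gland / heart / spleen share one tier and
# "other" (not placed by the clinical ordering) ranks last
ORGAN_PREDICTIVENESS_RANK = {
    "liver": 0,
    "adrenal gland": 1,
    "heart": 1,
    "spleen": 1,
    "skeletal": 2,
    "lung": 3,
    "lymph nodes": 4,
    "soft tissue/skin": 5,
    "other": 6,
}

AGGREGATION_SCHEMES = ("largest", "wmean3_largest", "predictive", "wmean3_predictive")


@dataclass
class Lesion:
    """One segmented metastasis."""

    lesion_id: str
    patient_id: str
    organ_type: str
    volume: float  # mm^3
    features: dict[str, float] | None = None
    image: LesionImage | None = None

    def __post_init__(self) -> None:
        if self.organ_type not in ORGAN_TYPES:
            raise ValueError(
                f"unknown organ type {self.organ_type!r}; expected one of {ORGAN_TYPES}"
            )
        if self.volume <= 0:
            raise ValueError(f"lesion volume must be positive, got {self.volume}")


def rank_lesions(lesions: list[Lesion]) -> list[Lesion]:
    """Order lesions from most to least predictive.

    Primary key: organ predictiveness tier; secondary: volume descending;
    ties broken by lesion_id so the order is a deterministic total order.
    """
    if not lesions:
        raise ValueError("cannot rank an empty lesion list")
    return sorted(
        lesions,
        key=lambda l: (ORGAN_PREDICTIVENESS_RANK[l.organ_type], -l.volume, l.lesion_id),
    )


def rank_by_volume(lesions: list[Lesion]) -> list[Lesion]:
    """Order lesions by volume descending (ties by lesion_id)."""
    if not lesions:
        raise ValueError("cannot rank an empty lesion list")
    return sorted(lesions, key=lambda l: (-l.volume, l.lesion_id))


def _weighted_mean(lesions: list[Lesion], names: list[str]) -> np.ndarray:
    """Volume-weighted mean feature vector of up to three lesions.

    NaN sentinel entries are excluded per feature; a feature missing in all
    contributing lesions stays NaN.
    """
    vals = np.array([[l.features[n] for n in names] for l in lesions], dtype=float)
    w = np.array([l.volume for l in lesions], dtype=float)[:, None]
    wv = np.where(np.isnan(vals), 0.0, vals) * w
    wsum = (w * ~np.isnan(vals)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        out = wv.sum(axis=0) / wsum
    out[wsum == 0] = np.nan
    return out


def burden_features(lesions: list[Lesion]) -> dict[str, float]:
    """Lesion count and total volume, overall and per organ type (20 values).

    Volumes are summed in lesion_id order so the result is invariant to the
    input ordering (floating-point summation is not associative).
    """
    lesions = sorted(lesions, key=lambda l: l.lesion_id)
    out: dict[str, float] = {
        "burden_count_all": float(len(lesions)),
        "burden_volume_all": float(sum(l.volume for l in lesions)),
    }
    for organ in ORGAN_TYPES:
        sub = [l for l in lesions if l.organ_type == organ]
        tag = organ.replace(" ", "_").replace("/", "_")
        out[f"burden_count_{tag}"] = float(len(sub))
        out[f"burden_volume_{tag}"] = float(sum(l.volume for l in sub))
    return out


def burden_schema() -> list[str]:
    return list(burden_features([]).keys())


def aggregated_schema(feature_names: list[str]) -> list[str]:
    """Patient-level column order: scheme-prefixed lesion features + burden."""
    cols = []
    for scheme in AGGREGATION_SCHEMES:
        cols += [f"{scheme}|{n}" for n in feature_names]
    cols += burden_schema()
    return cols


def aggregate_patient(lesions: list[Lesion]) -> dict[str, float]:
    """Collapse one patient's lesions into the aggregated feature vector."""
    if not lesions:
        raise ValueError("patient has no lesions; lesion-free patients are excluded")
    if any(l.features is None for l in lesions):
        raise ValueError("all lesions need an extracted feature vector")
    names = list(lesions[0].features.keys())
    by_volume = rank_by_volume(lesions)
    by_pred = rank_lesions(lesions)
    out: dict[str, float] = {}
    vecs = {
        "largest": np.array([by_volume[0].features[n] for n in names], dtype=float),
        "wmean3_largest": _weighted_mean(by_volume[:3], names),
        "predictive": np.array([by_pred[0].features[n] for n in names], dtype=float),
        "wmean3_predictive": _weighted_mean(by_pred[:3], names),
    }
    for scheme in AGGREGATION_SCHEMES:
        v = vecs[scheme]
        for n, x in zip(names, v):
            out[f"{scheme}|{n}"] = float(x)
    out.update(burden_features(lesions))
    return out


def aggregate_cohort(lesions: list[Lesion]) -> pd.DataFrame:
    """Patient-level feature table (rows = patients, deterministic order)."""
    by_patient: dict[str, list[Lesion]] = {}
    for l in lesions:
        by_patient.setdefault(l.patient_id, []).append(l)
    rows = {pid: aggregate_patient(ls) for pid, ls in sorted(by_patient.items())}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df
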