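"""Binary endpoints and per-fold preprocessing.

Three endpoints are modelled: objective response at three months (CR/PR = 1,
SD/PD = 0, progression after the first therapy cycle counting as
non-response), and survival at six and twelve months.  For each endpoint the
cohort is reduced to the patients with known outcome.

Preprocessing (ordinal encoding of nominal variables, imputation — 0.5 for
binary features, the median otherwise — and z-normalization) is fitted on a
training partition only and then applied to held-out rows, so no validation
information can leak into the fitted state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import ClinicalRecord

ENDPOINTS = ("response_3mo", "surv_6mo", "surv_12mo")

RESPONSE_CODES = ("CR", "PR", "SD", "PD")

#: feature kind per clinical covariate (Table-1 style variable list)
CLINICAL_FEATURE_KINDS: dict[str, str] = {
    "age": "continuous",
    "sex": "nominal",
    "primary_site": "nominal",
    "histology": "nominal",
    "braf_mutated": "binary",
    "ldh_elevated": "binary",
    "s100_elevated": "binary",
    "gt3_metastatic_organs": "binary",
    "cerebral_mets": "binary",
    "hepatic_mets": "binary",
    "therapy": "nominal",
}

_SD_FLOOR = 1e-12


def clinical_feature_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical covariate table indexed by patient_id (missing -> NaN)."""
    rows = {}
    for r in records:
        rows[r.patient_id] = {
            "age": r.age,
            "sex": r.sex,
            "primary_site": r.primary_site if r.primary_site != "n/a" else np.nan,
            "histology": r.histology if r.histology != "n/a" else np.nan,
            "braf_mutated": np.nan if r.braf_mutated is None else float(r.braf_mutated),
            "ldh_elevated": np.nan if r.ldh_elevated is None else float(r.ldh_elevated),
            "s100_elevated": np.nan if r.s100_elevated is None else float(r.s100_elevated),
            "gt3_metastatic_organs": float(r.gt3_metastatic_organs),
            "cerebral_mets": float(r.cerebral_mets),
            "hepatic_mets": float(r.hepatic_mets),
            "therapy": r.therapy,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df[list(CLINICAL_FEATURE_KINDS)]


def build_endpoints(records: list[ClinicalRecord]) -> dict[str, pd.Series]:
    """Per endpoint: a 0/1 label series over the patients with known outcome."""
    resp, s6, s12 = {}, {}, {}
    for r in records:
        if r.response_3mo is not None:
            if r.response_3mo not in RESPONSE_CODES:
                raise ValueError(
                    f"unknown response code {r.response_3mo!r}; expected {RESPONSE_CODES}"
                )
            resp[r.patient_id] = 1 if r.response_3mo in ("CR", "PR") else 0
        if r.alive_6mo is not None:
            s6[r.patient_id] = int(r.alive_6mo)
        if r.alive_12mo is not None:
            s12[r.patient_id] = int(r.alive_12mo)
    return {
        "response_3mo": pd.Series(resp, name="response_3mo", dtype=int),
        "surv_6mo": pd.Series(s6, name="surv_6mo", dtype=int),
        "surv_12mo": pd.Series(s12, name="surv_12mo", dtype=int),
    }


def endpoint_counts(labels: dict[str, pd.Series], cohort_size: int) -> pd.DataFrame:
    """Included/excluded and class counts per endpoint (report bookkeeping)."""
    rows = []
    for ep, s in labels.items():
        rows.append({
            "endpoint": ep,
            "n_included": len(s),
            "n_missing": cohort_size - len(s),
            "n_class0": int((s == 0).sum()),
            "n_class1": int((s == 1).sum()),
        })
    return pd.DataFrame(rows).set_index("endpoint")


# ---------------------------------------------------------------------------
# preprocessor
# ---------------------------------------------------------------------------


@dataclass
class PreprocessorState:
    """Fitted preprocessing state: nominal level encodings, per-feature
    imputation values and normalization mean/SD.  Fitted from training rows
    only."""

    columns: list[str]
    kinds: dict[str, str]
    encodings: dict[str, dict[str, int]] = field(default_factory=dict)
    impute: dict[str, float] = field(default_factory=dict)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns,
            "kinds": self.kinds,
            "encodings": self.encodings,
            "impute": self.impute,
            "mean": self.mean,
            "sd": self.sd,
        }


def fit_preprocessor(train: pd.DataFrame, kinds: dict[str, str]) -> PreprocessorState:
    """Fit encodings, imputation values and z-normalization on training rows.

    Nominal levels are ordinal-encoded in alphabetical order of the levels
    observed in training.  Binary features impute 0.5, all others the
    training median.  An all-missing training column imputes the documented
    global default (0.5 binary, 0 otherwise) with a warning.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training rows to fit the preprocessor")
    state = PreprocessorState(columns=list(train.columns), kinds=dict(kinds))
    encoded = _encode(train, state, fit=True)
    for col in state.columns:
        vals = encoded[col].to_numpy(dtype=float)
        known = vals[~np.isnan(vals)]
        kind = kinds.get(col, "continuous")
        if known.size == 0:
            warnings.warn(f"feature {col!r} has no observed training values; "
                          f"imputing the global default")
            state.impute[col] = 0.5 if kind == "binary" else 0.0
        elif kind == "binary":
            state.impute[col] = 0.5
        else:
            state.impute[col] = float(np.median(known))
        filled = np.where(np.isnan(vals), state.impute[col], vals)
        state.mean[col] = float(filled.mean())
        state.sd[col] = max(float(filled.std()), _SD_FLOOR)
    return state


def _encode(df: pd.DataFrame, state: PreprocessorState, fit: bool) -> pd.DataFrame:
    out = {}
    for col in state.columns:
        kind = state.kinds.get(col, "continuous")
        if kind != "nominal":
            out[col] = pd.to_numeric(df[col], errors="coerce")
            continue
        vals = df[col]
        if fit:
            levels = sorted(v for v in vals.dropna().unique())
            state.encodings[col] = {lv: i for i, lv in enumerate(levels)}
        enc = state.encodings[col]
        mapped = []
        for v in vals:
            if pd.isna(v):
                mapped.append(np.nan)
            elif v in enc:
                mapped.append(float(enc[v]))
            else:
                warnings.warn(f"unseen level {v!r} in feature {col!r}; treated as missing")
                mapped.append(np.nan)
        out[col] = pd.Series(mapped, index=df.index)
    return pd.DataFrame(out, index=df.index)


def apply_preprocessor(state: PreprocessorState, rows: pd.DataFrame) -> np.ndarray:
    """Encode, impute and z-normalize rows with a fitted state; output is a
    fully finite float matrix in state.columns order."""
    missing = [c for c in state.columns if c not in rows.columns]
    if missing:
        raise ValueError(f"rows are missing expected columns: {missing}")
    encoded = _encode(rows[state.columns], state, fit=False)
    mat = np.empty((len(rows), len(state.columns)))
    for j, col in enumerate(state.columns):
        vals = encoded[col].to_numpy(dtype=float)
        vals = np.where(np.isfinite(vals), vals, state.impute[col])
        mat[:, j] = (vals - state.mean[col]) / state.sd[col]
    return mat
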