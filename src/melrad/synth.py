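"""Synthetic stage-IV melanoma cohort generator.

Since no real registry/CT data ship with this package, every downstream
stage is exercised on a fully synthetic cohort whose marginal statistics
mirror a typical first-line immunotherapy cohort: covariate frequencies
(sex, primary site, histology, BRAF, LDH, S100, metastatic spread, therapy
type), per-organ lesion counts and prevalences, a ~37% response rate among
evaluable patients, ~69%/44% six-/twelve-month survival and a 22.1-month
median overall survival, plus realistic missingness.

Mechanism
---------
Each patient carries a scalar latent *radiomic risk factor* z.  Response is
drawn from a logistic model on the clinical covariates; z is then separated
between responders and non-responders by the configured standardized effect
size d (non-responders higher by d), so that when clinical effects are zero
the AUC of z against non-response is exactly the binormal Phi(d / sqrt(2)).
Overall survival is exponential with log-hazard linear in the clinical
score and in the same factor z; six-/twelve-month survival flags follow
from survival time under uniform administrative censoring (3-36 months of
follow-up), which also produces the "n/a" endpoint rows.  All of a
patient's lesions express z as a shift of in-mask intensity mean and of
spatial heterogeneity, which is what the radiomic features can detect.

Per-organ lesion counts use a zero-inflated negative binomial (organ
affected with its prevalence; count among affected = 1 + NB), volumes a
per-organ log-normal.  Every patient has at least one lesion (patients
without visible metastases are excluded from such studies).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.special import expit

from .aggregate import ORGAN_TYPES, Lesion
from .features import LesionImage

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganProfile:
    """Per-organ lesion statistics: patient prevalence, mean lesion count
    among affected patients, and log-volume mean/sd (volume in mm^3)."""

    prevalence: float
    mean_count: float
    logvol_mean: float
    logvol_sd: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.mean_count < 1.0:
            raise ValueError("mean lesion count among affected must be >= 1")


# prevalences and mean counts calibrated to a 262-patient cohort with 6404
# lesions (lung 2738/157, liver 1120/79, soft tissue 1111/110, nodes 876/154,
# skeletal 172/42, spleen 97/12, heart 8/3, other 238/54; adrenal gland takes
# the residual ~44 lesions).  Log-volume parameters are generator defaults:
# right-skewed volumes with medians of roughly 0.4-2 cm^3 per organ.
DEFAULT_ORGAN_PROFILES: dict[str, OrganProfile] = {
    "lung": OrganProfile(157 / 262, 2738 / 157, 6.6, 1.0),
    "liver": OrganProfile(79 / 262, 1120 / 79, 7.4, 1.0),
    "soft tissue/skin": OrganProfile(110 / 262, 1111 / 110, 6.6, 1.0),
    "lymph nodes": OrganProfile(154 / 262, 876 / 154, 6.9, 0.9),
    "skeletal": OrganProfile(42 / 262, 172 / 42, 7.0, 0.9),
    "spleen": OrganProfile(12 / 262, 97 / 12, 6.8, 0.9),
    "heart": OrganProfile(3 / 262, 8 / 3, 6.8, 0.8),
    "adrenal gland": OrganProfile(25 / 262, 44 / 25, 7.2, 0.9),
    "other": OrganProfile(54 / 262, 238 / 54, 6.8, 1.0),
}

# log-odds of a GOOD outcome (response / survival) per unit covariate
DEFAULT_CLINICAL_EFFECTS: dict[str, float] = {
    "ldh_elevated": -0.6,
    "s100_elevated": -0.4,
    "gt3_metastatic_organs": -0.4,
    "cerebral_mets": -0.3,
    "hepatic_mets": -0.3,
    "age_decade": -0.1,  # per decade above the cohort mean
    "therapy_combo": 0.2,
}

DEFAULT_MISSINGNESS: dict[str, float] = {
    "response_3mo": 42 / 262,
    "braf_mutated": 8 / 262,
    "ldh_elevated": 13 / 262,
    "s100_elevated": 20 / 262,
}

PRIMARY_SITES = ("head/neck", "torso", "upper extremity", "lower extremity", "other", "n/a")
PRIMARY_SITE_P = np.array([50, 63, 30, 71, 13, 35]) / 262.0
HISTOLOGIES = ("SSM", "NM", "LMM", "ALM", "mucosal", "occult", "n/a")
HISTOLOGY_P = np.array([71, 62, 13, 29, 13, 61, 13]) / 262.0

RESPONSE_RATE_TARGET = 82.0 / 220.0  # CR+PR among evaluable
CR_SHARE_OF_RESPONSE = 10.0 / 82.0
SD_SHARE_OF_NONRESPONSE = 42.0 / 138.0

ORGAN_BASE_HU = {
    "liver": 65.0, "adrenal gland": 45.0, "heart": 50.0, "spleen": 60.0,
    "skeletal": 55.0, "lung": 35.0, "lymph nodes": 45.0,
    "soft tissue/skin": 40.0, "other": 45.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort; the seed fully determines
    the output."""

    n_patients: int = 262
    seed: int = 0
    clinical_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_EFFECTS)
    )
    radiomic_effect: float = 0.3
    organ_profiles: dict[str, OrganProfile] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_PROFILES)
    )
    missingness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    os_median_months: float = 22.1
    followup_months: tuple[float, float] = (3.0, 36.0)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    lesion_count_scale: float = 1.0  # global multiplier on mean lesion counts
    render_images: bool = True
    nb_dispersion: float = 1.0  # negative-binomial size parameter

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise ValueError(
                "n_patients must be >= 10; smaller cohorts make the downstream "
                "cross-validation degenerate"
            )
        if self.os_median_months <= 0:
            raise ValueError("os_median_months must be positive")
        for organ in self.organ_profiles:
            if organ not in ORGAN_TYPES:
                raise ValueError(f"unknown organ {organ!r}")


@dataclass
class ClinicalRecord:
    """One patient's covariates and outcomes.  Binary fields use 0/1 with
    None for 'n/a'; response_3mo is one of CR/PR/SD/PD or None."""

    patient_id: str
    age: float
    sex: str  # "female" | "male"
    primary_site: str
    histology: str
    braf_mutated: int | None
    ldh_elevated: int | None
    s100_elevated: int | None
    gt3_metastatic_organs: int
    cerebral_mets: int
    hepatic_mets: int
    therapy: str  # "PD1" | "PD1+CTLA4"
    response_3mo: str | None
    alive_6mo: int | None
    alive_12mo: int | None
    os_time: float
    os_event: int


# ---------------------------------------------------------------------------
# lesion image synthesis
# ---------------------------------------------------------------------------


def generate_lesion_image(
    organ: str,
    volume: float,
    latent_factor: float,
    seed: int,
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0),
    anisotropy: float = 0.25,
) -> LesionImage:
    """Render a lesion patch: ellipsoidal mask of the requested volume with
    latent-factor-dependent intensity statistics.

    The in-mask mean shifts by +10 HU per unit of the latent factor and the
    in-mask heterogeneity (noise + smooth texture field) grows monotonically
    with it.  Background is a noisy organ-dependent plateau.
    """
    if organ not in ORGAN_TYPES:
        raise ValueError(f"unknown organ {organ!r}")
    voxvol = float(np.prod(spacing))
    if volume < voxvol:
        raise ValueError(
            f"volume {volume:.1f} mm^3 below the minimum representable volume "
            f"of one voxel ({voxvol:.1f} mm^3 at spacing {spacing})"
        )
    rng = np.random.default_rng(seed)
    r0 = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    if anisotropy > 0:
        scales = rng.uniform(1.0 - anisotropy, 1.0 + anisotropy, size=3)
        scales /= scales.prod() ** (1.0 / 3.0)
    else:
        scales = np.ones(3)
    radii = r0 * scales  # mm, per axis

    half = np.ceil(radii / np.asarray(spacing)).astype(int) + 3
    shape = tuple(2 * half + 1)
    grids = np.meshgrid(
        *[(np.arange(n) - h) * s for n, h, s in zip(shape, half, spacing)], indexing="ij"
    )
    # boundary-inclusive within numerical tolerance, so voxel centres that
    # lie exactly on the ellipsoid surface are part of the mask
    mask = sum((g / r) ** 2 for g, r in zip(grids, radii)) <= 1.0 + 1e-9
    if not mask.any():
        mask[tuple(half)] = True

    base = ORGAN_BASE_HU[organ]
    noise_sd = 8.0 * np.exp(0.2 * latent_factor)
    texture_sd = 6.0 * np.exp(0.3 * latent_factor)
    smooth = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.0)
    smooth /= max(smooth.std(), 1e-12)
    img = (base - 25.0) + 10.0 * rng.standard_normal(shape)  # background
    inside = (
        base
        + 10.0 * latent_factor
        + noise_sd * rng.standard_normal(shape)[mask]
        + texture_sd * smooth[mask]
    )
    img[mask] = inside
    return LesionImage(img, mask, spacing)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Intercept a s.t. mean(sigmoid(a + eta)) == target."""
    f = lambda a: expit(a + eta).mean() - target
    return brentq(f, -20.0, 20.0)


def _calibrate_base_hazard(log_hr: np.ndarray, median: float) -> float:
    """lambda0 s.t. the marginal survival at `median` months is 0.5."""
    f = lambda loglam: np.exp(-np.exp(loglam + log_hr) * median).mean() - 0.5
    return float(np.exp(brentq(f, -15.0, 5.0)))


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[ClinicalRecord], list[Lesion], np.ndarray]:
    """Generate the cohort.

    Returns (clinical records, lesions, latent risk factor per patient).
    Lesions carry rendered images when ``config.render_images`` is true;
    features are not yet extracted.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    eff = dict(DEFAULT_CLINICAL_EFFECTS)
    eff.update(config.clinical_effects)

    age = np.clip(rng.normal(68.0, 16.0, n), 25.0, 95.0)
    female = rng.random(n) < 109 / 262
    site = rng.choice(len(PRIMARY_SITES), size=n, p=PRIMARY_SITE_P / PRIMARY_SITE_P.sum())
    histo = rng.choice(len(HISTOLOGIES), size=n, p=HISTOLOGY_P / HISTOLOGY_P.sum())
    braf = (rng.random(n) < 74 / 254).astype(int)
    ldh = (rng.random(n) < 85 / 249).astype(int)
    s100 = (rng.random(n) < 125 / 242).astype(int)
    gt3 = (rng.random(n) < 30 / 262).astype(int)
    cerebral = (rng.random(n) < 48 / 262).astype(int)
    combo = (rng.random(n) < 116 / 262).astype(int)

    # per-organ lesion burden (zero-inflated negative binomial counts)
    organ_counts = np.zeros((n, len(ORGAN_TYPES)), dtype=int)
    for j, organ in enumerate(ORGAN_TYPES):
        prof = config.organ_profiles.get(organ)
        if prof is None:
            continue
        affected = rng.random(n) < prof.prevalence
        mean_extra = max(prof.mean_count * config.lesion_count_scale - 1.0, 0.0)
        if mean_extra > 0:
            r = config.nb_dispersion
            extra = rng.negative_binomial(r, r / (r + mean_extra), size=n)
        else:
            extra = np.zeros(n, dtype=int)
        organ_counts[:, j] = np.where(affected, 1 + extra, 0)
    none = organ_counts.sum(axis=1) == 0
    if none.any():  # every included patient has visible metastases
        prev = np.array(
            [config.organ_profiles[o].prevalence if o in config.organ_profiles else 0.0
             for o in ORGAN_TYPES]
        )
        prev = prev / prev.sum()
        forced = rng.choice(len(ORGAN_TYPES), size=int(none.sum()), p=prev)
        organ_counts[np.nonzero(none)[0], forced] = 1

    hepatic = (organ_counts[:, ORGAN_TYPES.index("liver")] > 0).astype(int)

    # clinical prognosis score (log-odds of a good outcome)
    eta = (
        eff["ldh_elevated"] * ldh
        + eff["s100_elevated"] * s100
        + eff["gt3_metastatic_organs"] * gt3
        + eff["cerebral_mets"] * cerebral
        + eff["hepatic_mets"] * hepatic
        + eff["age_decade"] * (age - age.mean()) / 10.0
        + eff["therapy_combo"] * combo
    )
    eta = eta - eta.mean()

    # response from a logistic model on the clinical score, intercept
    # calibrated to the target response rate
    alpha = _calibrate_intercept(eta, RESPONSE_RATE_TARGET)
    responder = rng.random(n) < expit(alpha + eta)

    # latent radiomic factor: standard normal, separated between responders
    # and non-responders by the standardized effect (binormal AUC Phi(d/sqrt2))
    d = config.radiomic_effect
    z = rng.standard_normal(n) + d * (0.5 - responder.astype(float))

    # overall survival: exponential, log-hazard linear in clinical score and z
    log_hr = -eta + d * (z - z.mean())
    lam0 = _calibrate_base_hazard(log_hr, config.os_median_months)
    os_true = rng.exponential(1.0 / (lam0 * np.exp(log_hr)))
    censor = rng.uniform(*config.followup_months, size=n)
    os_time = np.minimum(os_true, censor)
    os_event = (os_true <= censor).astype(int)

    # missingness masks
    miss = {k: rng.random(n) < v for k, v in config.missingness.items()}
    resp_cat = np.where(
        responder,
        np.where(rng.random(n) < CR_SHARE_OF_RESPONSE, "CR", "PR"),
        np.where(rng.random(n) < SD_SHARE_OF_NONRESPONSE, "SD", "PD"),
    )

    records: list[ClinicalRecord] = []
    lesions: list[Lesion] = []
    width = len(str(n - 1))
    for i in range(n):
        pid = f"P{i:0{width}d}"

        def surv_flag(h: float) -> int | None:
            if os_true[i] <= min(censor[i], h):
                return 0
            if censor[i] >= h:
                return 1
            return None  # lost to follow-up before horizon while alive

        records.append(
            ClinicalRecord(
                patient_id=pid,
                age=float(age[i]),
                sex="female" if female[i] else "male",
                primary_site=PRIMARY_SITES[site[i]],
                histology=HISTOLOGIES[histo[i]],
                braf_mutated=None if miss.get("braf_mutated", np.zeros(n, bool))[i] else int(braf[i]),
                ldh_elevated=None if miss.get("ldh_elevated", np.zeros(n, bool))[i] else int(ldh[i]),
                s100_elevated=None if miss.get("s100_elevated", np.zeros(n, bool))[i] else int(s100[i]),
                gt3_metastatic_organs=int(gt3[i]),
                cerebral_mets=int(cerebral[i]),
                hepatic_mets=int(hepatic[i]),
                therapy="PD1+CTLA4" if combo[i] else "PD1",
                response_3mo=None if miss.get("response_3mo", np.zeros(n, bool))[i] else str(resp_cat[i]),
                alive_6mo=surv_flag(6.0),
                alive_12mo=surv_flag(12.0),
                os_time=float(os_time[i]),
                os_event=int(os_event[i]),
            )
        )

        voxvol = float(np.prod(config.spacing))
        k = 0
        for j, organ in enumerate(ORGAN_TYPES):
            prof = config.organ_profiles.get(organ)
            for _ in range(organ_counts[i, j]):
                vol = float(
                    np.exp(rng.normal(prof.logvol_mean, prof.logvol_sd))
                )
                vol = max(vol, 1.5 * voxvol)
                image = None
                if config.render_images:
                    image = generate_lesion_image(
                        organ, vol, float(z[i]),
                        seed=int(rng.integers(2**31)), spacing=config.spacing,
                    )
                    vol = image.mask.sum() * voxvol  # realized mask volume
                lesions.append(
                    Lesion(
                        lesion_id=f"{pid}_L{k:03d}",
                        patient_id=pid,
                        organ_type=organ,
                        volume=vol,
                        image=image,
                    )
                )
                k += 1

    return records, lesions, z


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "patient_id", "age", "sex", "primary_site", "histology", "braf_mutated",
    "ldh_elevated", "s100_elevated", "gt3_metastatic_organs", "cerebral_mets",
    "hepatic_mets", "therapy", "response_3mo", "alive_6mo", "alive_12mo",
    "os_time", "os_event",
]


def write_clinical_csv(records: list[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CLINICAL_COLUMNS)
        for r in records:
            w.writerow([
                r.patient_id, f"{r.age:.1f}", r.sex, r.primary_site, r.histology,
                _na(r.braf_mutated), _na(r.ldh_elevated), _na(r.s100_elevated),
                r.gt3_metastatic_organs, r.cerebral_mets, r.hepatic_mets,
                r.therapy, r.response_3mo if r.response_3mo is not None else "n/a",
                _na(r.alive_6mo), _na(r.alive_12mo), f"{r.os_time:.3f}", r.os_event,
            ])


def _na(v) -> str:
    return "n/a" if v is None else str(v)


def write_lesion_index(lesions: list[Lesion], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "lesion_id", "organ_type", "volume_mm3"])
        for l in lesions:
            w.writerow([l.patient_id, l.lesion_id, l.organ_type, f"{l.volume:.1f}"])


def write_latent_csv(records: list[ClinicalRecord], z: np.ndarray, path: str | Path) -> None:
    """Ground-truth latent factors; for tests and audits only."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "latent_risk"])
        for r, zi in zip(records, z):
            w.writerow([r.patient_id, f"{zi:.6f}"])


def write_lesion_niftis(lesions: list[Lesion], directory: str | Path) -> None:
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for l in lesions:
        if l.image is None:
            continue
        affine = np.diag(list(l.image.spacing) + [1.0])
        nib.save(
            nib.Nifti1Image(l.image.intensities.astype(np.float32), affine),
            directory / f"{l.lesion_id}_image.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(l.image.mask.astype(np.uint8), affine),
            directory / f"{l.lesion_id}_mask.nii.gz",
        )
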