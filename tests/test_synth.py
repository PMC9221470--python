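"""Generator tests: calibration of the synthetic cohort, determinism,
planted-signal geometry, and lesion image rendering."""

import numpy as np
import pytest

from melrad import GeneratorConfig, generate_cohort, generate_lesion_image
from melrad.synth import DEFAULT_CLINICAL_EFFECTS

ZERO_EFFECTS = {k: 0.0 for k in DEFAULT_CLINICAL_EFFECTS}


def _brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# cohort-level behaviour
# ---------------------------------------------------------------------------


def test_seeded_determinism():
    cfg = GeneratorConfig(n_patients=25, seed=42, render_images=True, lesion_count_scale=0.1)
    r1, l1, z1 = generate_cohort(cfg)
    r2, l2, z2 = generate_cohort(cfg)
    assert np.array_equal(z1, z2)
    assert [vars(a) for a in r1] == [vars(b) for b in r2]
    assert len(l1) == len(l2)
    for a, b in zip(l1, l2):
        assert a.lesion_id == b.lesion_id and a.volume == b.volume
        assert np.array_equal(a.image.intensities, b.image.intensities)
        assert np.array_equal(a.image.mask, b.image.mask)


def test_refuses_degenerate_cohort():
    with pytest.raises(ValueError, match="n_patients"):
        GeneratorConfig(n_patients=5)


def test_every_patient_has_a_lesion(small_cohort):
    records, lesions, _ = small_cohort
    with_lesion = {l.patient_id for l in lesions}
    assert {r.patient_id for r in records} == with_lesion


def test_survival_flags_consistent(small_cohort):
    records, _, _ = small_cohort
    for r in records:
        if r.alive_12mo == 1:
            assert r.alive_6mo == 1
        if r.os_event == 1 and r.os_time <= 6:
            assert r.alive_6mo == 0


@pytest.mark.parametrize(
    "stat, target, n_eff",
    [
        ("female", 109 / 262, 262),
        ("ldh", 85 / 249, 249),
        ("s100", 125 / 242, 242),
        ("braf", 74 / 254, 254),
        ("gt3", 30 / 262, 262),
        ("cerebral", 48 / 262, 262),
        ("hepatic", 85 / 262, 262),
        ("combo", 116 / 262, 262),
        ("response", 82 / 220, 220),
        ("surv6", 181 / 230, 230),
        ("surv12", 115 / 188, 188),
        ("resp_na", 42 / 262, 262),
    ],
)
def test_marginal_calibration(calibration_cohort, stat, target, n_eff):
    """Cohort marginals reproduce the printed frequencies within 3 binomial
    SDs at the published cohort size."""
    records, _, _ = calibration_cohort

    def frac(vals):
        vals = [v for v in vals if v is not None]
        return np.mean(vals)

    obs = {
        "female": frac([r.sex == "female" for r in records]),
        "ldh": frac([r.ldh_elevated for r in records]),
        "s100": frac([r.s100_elevated for r in records]),
        "braf": frac([r.braf_mutated for r in records]),
        "gt3": frac([r.gt3_metastatic_organs for r in records]),
        "cerebral": frac([r.cerebral_mets for r in records]),
        "hepatic": frac([r.hepatic_mets for r in records]),
        "combo": frac([r.therapy == "PD1+CTLA4" for r in records]),
        "response": frac(
            [r.response_3mo in ("CR", "PR") if r.response_3mo else None for r in records]
        ),
        "surv6": frac([r.alive_6mo for r in records]),
        "surv12": frac([r.alive_12mo for r in records]),
        "resp_na": frac([r.response_3mo is None for r in records]),
    }[stat]
    sd = np.sqrt(target * (1 - target) / n_eff)
    assert abs(obs - target) <= 3 * sd


def test_organ_lesion_totals(calibration_cohort):
    """Per-organ lesion totals match the calibrated expectation: the lung
    dominates (~10.5 lesions/patient), liver ~4.3, within sampling slack."""
    _, lesions, _ = calibration_cohort
    n = 262
    lung = sum(1 for l in lesions if l.organ_type == "lung")
    liver = sum(1 for l in lesions if l.organ_type == "liver")
    assert 0.5 * 2738 < lung < 1.6 * 2738
    assert 0.5 * 1120 < liver < 1.6 * 1120
    # overall burden: ~24 lesions/patient
    assert 15 < len(lesions) / n < 35


def test_null_effects_give_null_association():
    cfg = GeneratorConfig(
        n_patients=2000, seed=3, radiomic_effect=0.0,
        clinical_effects=ZERO_EFFECTS, render_images=False,
    )
    records, _, z = generate_cohort(cfg)
    labels = np.array(
        [r.response_3mo in ("CR", "PR") for r in records if r.response_3mo is not None]
    ).astype(int)
    zz = np.array([zi for r, zi in zip(records, z) if r.response_3mo is not None])
    auc = _brute_force_auc(-zz, labels)
    assert abs(auc - 0.5) < 0.035  # ~3 MC standard errors


def test_planted_effect_matches_binormal_auc():
    """With a planted standardized effect d and zero clinical effects the
    latent factor separates responders from non-responders with the
    closed-form binormal AUC Phi(d / sqrt 2), checked by pair counting."""
    from scipy.stats import norm

    d = 1.0
    cfg = GeneratorConfig(
        n_patients=5000, seed=5, radiomic_effect=d,
        clinical_effects=ZERO_EFFECTS, missingness={}, render_images=False,
    )
    records, _, z = generate_cohort(cfg)
    labels = np.array([r.response_3mo in ("CR", "PR") for r in records]).astype(int)
    auc = _brute_force_auc(-z, labels)
    assert abs(auc - norm.cdf(d / np.sqrt(2))) < 0.02


# ---------------------------------------------------------------------------
# lesion images
# ---------------------------------------------------------------------------


def test_sphere_mask_matches_voxel_enumeration():
    """An isotropic lesion of the analytic sphere volume 4/3 pi (9mm)^3 at
    3mm spacing reproduces the voxel-centre enumeration of that sphere."""
    vol = 4.0 / 3.0 * np.pi * 9.0**3
    img = generate_lesion_image("lung", vol, 0.0, seed=0, anisotropy=0.0)
    # oracle: count lattice points (3i,3j,3k) inside radius 9
    r = np.arange(-5, 6)
    ii, jj, kk = np.meshgrid(r, r, r, indexing="ij")
    expected = int((9 * (ii**2 + jj**2 + kk**2) <= 81).sum())
    assert img.mask.sum() == expected
    # one-voxel-shell agreement with the analytic volume
    assert abs(img.mask.sum() * 27.0 - vol) <= 4 * np.pi * 9.0**2 * 3.0


def test_lesion_image_determinism_and_noise():
    vol = 3000.0
    a = generate_lesion_image("liver", vol, 0.5, seed=9)
    b = generate_lesion_image("liver", vol, 0.5, seed=9)
    assert np.array_equal(a.intensities, b.intensities)
    c = generate_lesion_image("liver", vol, 0.5, seed=10)
    # congruent up to noise: same requested volume, means differ only by the
    # noise scale (the smooth texture field is spatially correlated, so the
    # effective sample size is well below the voxel count)
    assert abs(a.intensities[a.mask].mean() - c.intensities[c.mask].mean()) < 10.0


def test_latent_factor_shifts_mean_and_heterogeneity():
    vol = 5000.0
    lo_means, hi_means, lo_vars, hi_vars = [], [], [], []
    for seed in range(50):
        lo = generate_lesion_image("lung", vol, -2.0, seed=seed)
        hi = generate_lesion_image("lung", vol, +2.0, seed=seed)
        lo_means.append(lo.intensities[lo.mask].mean())
        hi_means.append(hi.intensities[hi.mask].mean())
        lo_vars.append(lo.intensities[lo.mask].var())
        hi_vars.append(hi.intensities[hi.mask].var())
    assert np.mean(hi_means) - np.mean(lo_means) > 30.0  # 10 HU per unit
    assert all(h > l for h, l in zip(hi_vars, lo_vars))  # strict ordering


def test_volume_below_voxel_rejected():
    with pytest.raises(ValueError, match="minimum representable"):
        generate_lesion_image("lung", 10.0, 0.0, seed=0)
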