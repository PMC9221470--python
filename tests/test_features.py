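"""Feature-extraction tests: schema arithmetic, closed-form first-order
values, voxel-enumeration shape oracles, a hand-enumerated co-occurrence
matrix, and the core invariances (translation, intensity shift, mask-only
shape dependence)."""

import numpy as np
import pytest

from melrad import ExtractionConfig, LesionImage, extract_lesion_features, feature_schema
from melrad.features import (
    FIRSTORDER_FEATURES,
    GLCM_FEATURES,
    SHAPE_FEATURES,
    _glcm_single,
    glcm_features,
    is_degenerate,
    shape_features,
)

from conftest import FAST_EXTRACTION


def _ball_image(radius_vox=4, shape=(11, 11, 11), spacing=(1.0, 1.0, 1.0), seed=0):
    rng = np.random.default_rng(seed)
    c = np.array(shape) // 2
    g = np.meshgrid(*[np.arange(n) - ci for n, ci in zip(shape, c)], indexing="ij")
    mask = sum(x**2 for x in g) <= radius_vox**2
    img = 50.0 + 10.0 * rng.standard_normal(shape)
    return LesionImage(img, mask, spacing)


# ---------------------------------------------------------------------------
# schema
# ---------------------------------------------------------------------------


def test_schema_counts_default():
    names = feature_schema()
    assert len(names) == 1316
    assert sum(n.startswith("original_shape_") for n in names) == 14
    original = [n for n in names if n.startswith("original_") and "_shape_" not in n]
    log = [n for n in names if n.startswith("log-sigma-")]
    wav = [n for n in names if n.startswith("wavelet-")]
    assert len(original) == 93
    assert len(log) == 465
    assert len(wav) == 744
    assert sum("_firstorder_" in n for n in names) == 18 * 14
    per_type_texture = sum(
        n.startswith("original_") and n.split("_")[1] in ("glcm", "glrlm", "glszm", "gldm", "ngtdm")
        for n in names
    )
    assert per_type_texture == 75


def test_schema_reduced_config():
    cfg = ExtractionConfig(log_sigmas_mm=(), wavelet=None)
    assert len(feature_schema(cfg)) == 14 + 93


def test_schema_deterministic_order():
    assert feature_schema() == feature_schema()
    # names are unique
    names = feature_schema()
    assert len(set(names)) == len(names)


def test_vector_matches_schema(rng):
    img = _ball_image()
    vec = extract_lesion_features(img, FAST_EXTRACTION)
    assert list(vec.keys()) == feature_schema(FAST_EXTRACTION)
    assert all(np.isfinite(v) for v in vec.values())


# ---------------------------------------------------------------------------
# first-order closed forms
# ---------------------------------------------------------------------------


def test_constant_intensity_first_order():
    img = _ball_image()
    img.intensities[:] = 42.0
    vec = extract_lesion_features(img, FAST_EXTRACTION)
    assert vec["original_firstorder_Mean"] == 42.0
    assert vec["original_firstorder_Variance"] == 0.0
    assert vec["original_firstorder_Range"] == 0.0


def test_intensity_shift_invariance():
    img = _ball_image(seed=3)
    v1 = extract_lesion_features(img, FAST_EXTRACTION)
    shifted = LesionImage(img.intensities + 100.0, img.mask, img.spacing)
    v2 = extract_lesion_features(shifted, FAST_EXTRACTION)
    assert v2["original_firstorder_Mean"] == pytest.approx(
        v1["original_firstorder_Mean"] + 100.0
    )
    assert v2["original_firstorder_Variance"] == pytest.approx(
        v1["original_firstorder_Variance"]
    )


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


def test_sphere_shape_oracle():
    """Digital sphere r=5 voxels at 1mm spacing: voxel volume equals the
    enumeration count, mesh volume approximates the analytic ball."""
    img = _ball_image(radius_vox=5, shape=(13, 13, 13))
    nvox = int(img.mask.sum())
    sf = shape_features(img.mask, img.spacing)
    assert sf["VoxelVolume"] == nvox * 1.0
    assert abs(sf["MeshVolume"] - 4 / 3 * np.pi * 5**3) / (4 / 3 * np.pi * 5**3) < 0.15
    assert 0.9 < sf["Sphericity"] <= 1.05
    assert abs(sf["Maximum3DDiameter"] - 10.0) < 2.0
    assert sf["Elongation"] == pytest.approx(1.0, abs=0.1)


def test_shape_depends_only_on_mask(rng):
    img = _ball_image(seed=1)
    other = LesionImage(rng.standard_normal(img.mask.shape), img.mask, img.spacing)
    v1 = extract_lesion_features(img, FAST_EXTRACTION)
    v2 = extract_lesion_features(other, FAST_EXTRACTION)
    for f in SHAPE_FEATURES:
        assert v1[f"original_shape_{f}"] == v2[f"original_shape_{f}"]


def test_translation_invariance():
    """Shifting the patch grid (padding on one side) changes no feature."""
    img = _ball_image(seed=2)
    pad = ((2, 0), (0, 3), (1, 1))
    moved = LesionImage(
        np.pad(img.intensities, pad, mode="edge"),
        np.pad(img.mask, pad),
        img.spacing,
    )
    v1 = extract_lesion_features(img, FAST_EXTRACTION)
    v2 = extract_lesion_features(moved, FAST_EXTRACTION)
    for name in v1:
        assert v1[name] == pytest.approx(v2[name], rel=1e-9), name


# ---------------------------------------------------------------------------
# hand-enumerated co-occurrence oracle
# ---------------------------------------------------------------------------


def test_glcm_hand_oracle():
    """2x2x1 patch with intensities {1,1,2,2}: every admissible direction
    yields a two-cell co-occurrence matrix with joint entropy 1 bit; the
    average contrast over the four admissible directions is 3/4."""
    intens = np.array([[[1.0], [1.0]], [[2.0], [2.0]]])
    mask = np.ones((2, 2, 1), dtype=bool)
    levels = np.floor(intens - 1).astype(np.int64) + 1
    feats = glcm_features(levels, 2)
    assert feats["JointEntropy"] == pytest.approx(1.0)
    assert feats["Contrast"] == pytest.approx(0.75)
    assert feats["JointEnergy"] == pytest.approx(0.5)
    # single-offset check against the hand-built normalized matrix for the
    # offset along axis 0 (both pairs are (1,2)): P = [[0,.5],[.5,0]]
    P = np.array([[0.0, 0.5], [0.5, 0.0]])
    single = _glcm_single(P)
    assert single["JointEntropy"] == pytest.approx(1.0)
    assert single["Contrast"] == pytest.approx(1.0)
    assert single["MaximumProbability"] == pytest.approx(0.5)


def test_full_vector_on_generated_lesion():
    """Full default schema on a generated lesion: 1316 entries, all finite."""
    from melrad import generate_lesion_image

    img = generate_lesion_image("liver", 4000.0, 0.8, seed=5)
    vec = extract_lesion_features(img)
    assert len(vec) == 1316
    vals = np.array(list(vec.values()))
    assert np.isfinite(vals).all()


def test_isotropic_resampling_mode():
    """Real-data mode: anisotropic input resampled to an isotropic grid
    (linear intensities, nearest-neighbour mask) yields a valid vector."""
    img = _ball_image(spacing=(3.0, 1.0, 1.0))
    cfg = ExtractionConfig(log_sigmas_mm=(), wavelet=None, resample_spacing=1.0)
    vec = extract_lesion_features(img, cfg)
    assert list(vec.keys()) == feature_schema(cfg)
    # voxel volume is now 1 mm^3; total volume is roughly conserved
    native = img.mask.sum() * 3.0
    assert abs(vec["original_shape_VoxelVolume"] - native) / native < 0.4


def test_degenerate_single_voxel():
    mask = np.zeros((5, 5, 5), dtype=bool)
    mask[2, 2, 2] = True
    img = LesionImage(np.full((5, 5, 5), 7.0), mask, (1, 1, 1))
    assert is_degenerate(img)
    vec = extract_lesion_features(img, FAST_EXTRACTION)
    assert vec["original_shape_VoxelVolume"] == 1.0
    assert vec["original_firstorder_Mean"] == 7.0
    # texture undefined on a single voxel -> NaN sentinel
    assert all(np.isnan(vec[f"original_glcm_{f}"]) for f in GLCM_FEATURES)
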