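import numpy as np
import pytest

from cystex import (
    FeatureConfig,
    extract_all,
    extract_roi,
    glcm,
    glcm_features,
    gradient_features,
    histogram_features,
    normalize_quantize,
    parse_feature_name,
    render_feature_name,
    rlm_features,
    wavelet_energies,
)
from cystex.errors import EmptyMatrixError, FeatureNameError
from cystex.imaging_io import ROI, SliceView
from cystex.preprocess import QuantizedROI
from cystex.texture_features import DIRECTIONS, extract_features

from _oracles import naive_glcm, naive_rlm_features, naive_runs
from conftest import lesion_from_slices


def qroi_from(levels, mask=None, bits=6):
    levels = np.atleast_2d(np.asarray(levels, dtype=np.int64))
    if mask is None:
        mask = np.ones(levels.shape, dtype=bool)
    return QuantizedROI(
        slices=[(levels, np.asarray(mask, dtype=bool))],
        bits=bits, mu=0.0, sigma=1.0, norm_code="S",
    )


# ---------------------------------------------------------------------------
# feature-name grammar
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name,family,attrs",
    [
        ("CV2S6Entropy", "glcm",
         {"channel": "C", "direction": "V", "distance": 2, "bits": 6,
          "base": "Entropy"}),
        ("WavEnLL_s-2", "wavelet", {"subband": "LL", "scale": 2}),
        ("RHS6RLNonUni", "rlm",
         {"channel": "R", "direction": "H", "distance": None, "bits": 6,
          "base": "RLNonUni"}),
        ("CS4GrMean", "gradient", {"bits": 4, "base": "GrMean"}),
        ("Perc99", "histogram", {"base": "Perc99"}),
        ("CN1S4SumAverg", "glcm",
         {"direction": "N", "distance": 1, "bits": 4, "base": "SumAverg"}),
    ],
)
def test_name_grammar_parses_and_round_trips(name, family, attrs):
    fn = parse_feature_name(name)
    assert fn.family == family
    for key, val in attrs.items():
        assert getattr(fn, key) == val
    assert render_feature_name(fn) == name


@pytest.mark.parametrize(
    "bad",
    [
        "CV2S6Bogus",       # unknown base
        "CVS6Entropy",      # co-occurrence base without a distance
        "CH2S6RLNonUni",    # run-length base with a distance
        "CH1S6GrMean",      # gradient base with direction/distance
        "XV2S6Entropy",     # unknown channel
        "WavEnXX_s-1",      # unknown subband
    ],
)
def test_name_grammar_rejects_malformed_names(bad):
    with pytest.raises(FeatureNameError):
        parse_feature_name(bad)


def test_every_extracted_column_round_trips_through_the_grammar(
    small_feature_table,
):
    for name in small_feature_table.columns.drop("class_label"):
        fn = parse_feature_name(name)
        assert render_feature_name(fn) == name


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

def test_histogram_constant_roi():
    h = histogram_features(np.array([5, 5, 5]))
    assert h["Variance"] == 0
    assert all(h[f"Perc{q:02d}"] == 5 for q in (1, 10, 50, 90, 99))


def test_histogram_percentile_rule_on_1_to_100():
    # Perc-n = smallest value with cumulative fraction >= n%
    h = histogram_features(np.arange(1, 101))
    assert h["Perc90"] == 90
    assert h["Perc99"] == 99
    assert h["Perc01"] == 1
    assert h["Perc50"] == 50


def test_histogram_population_moments():
    h = histogram_features(np.array([0, 0, 0, 10]))
    assert h["Mean"] == pytest.approx(2.5)
    assert h["Variance"] == pytest.approx(18.75)


# ---------------------------------------------------------------------------
# co-occurrence matrix
# ---------------------------------------------------------------------------

def test_glcm_alternating_row_horizontal():
    p = glcm(qroi_from([[0, 1, 0, 1]], bits=1), "H", 1)
    assert p[0, 1] == pytest.approx(0.5)
    assert p[1, 0] == pytest.approx(0.5)
    assert p.sum() == pytest.approx(1.0)


def test_glcm_constant_roi_concentrates_on_diagonal():
    p = glcm(qroi_from(np.full((4, 4), 3)), "V", 1)
    assert p[3, 3] == pytest.approx(1.0)
    feats = glcm_features(p)
    assert feats["AngScMom"] == pytest.approx(1.0)
    assert feats["Entropy"] == pytest.approx(0.0)
    assert feats["Contrast"] == pytest.approx(0.0)
    assert np.isnan(feats["Correlat"])  # zero marginal variance


def test_glcm_no_valid_pairs_raises():
    with pytest.raises(EmptyMatrixError):
        glcm(qroi_from([[0, 1, 0, 1]]), "V", 1)  # single row, vertical offset


def test_glcm_features_on_two_cell_matrix():
    p = np.array([[0.0, 0.5], [0.5, 0.0]])
    feats = glcm_features(p)
    assert feats["AngScMom"] == pytest.approx(0.5)
    assert feats["Entropy"] == pytest.approx(np.log(2))
    # 1-based marginals: levels 1, 2 -> x+y = 3 always
    assert feats["SumAverg"] == pytest.approx(3.0)
    assert feats["SumVarnc"] == pytest.approx(0.0)
    assert feats["Correlat"] == pytest.approx(-1.0)


def test_glcm_uniform_matrix_reaches_maximum_entropy():
    k = 8
    p = np.full((k, k), 1.0 / k**2)
    assert glcm_features(p)["Entropy"] == pytest.approx(np.log(k**2))


@pytest.mark.parametrize("direction", DIRECTIONS)
def test_glcm_matches_naive_pair_enumeration(direction):
    rng = np.random.default_rng(12)
    for trial in range(6):
        levels = rng.integers(0, 8, size=(6, 6))
        mask = rng.random((6, 6)) > 0.25
        mask[2:4, 2:4] = True
        qroi = qroi_from(levels, mask, bits=3)
        for d in (1, 2, 3):
            expected = naive_glcm(levels, mask, direction, d, 8)
            if expected is None:
                with pytest.raises(EmptyMatrixError):
                    glcm(qroi, direction, d)
            else:
                np.testing.assert_allclose(
                    glcm(qroi, direction, d), expected, atol=1e-15
                )


def test_glcm_symmetry_and_normalization_property():
    rng = np.random.default_rng(3)
    levels = rng.integers(0, 16, size=(9, 9))
    p = glcm(qroi_from(levels, bits=4), "Z", 2)
    np.testing.assert_allclose(p, p.T)
    assert p.sum() == pytest.approx(1.0)
    feats = glcm_features(p)
    assert 0 < feats["AngScMom"] <= 1
    assert 0 <= feats["Entropy"] <= np.log(16**2)


# ---------------------------------------------------------------------------
# run-length matrix
# ---------------------------------------------------------------------------

def test_rlm_hand_enumerated_row():
    feats = rlm_features(qroi_from([[0, 0, 1, 1, 1]], bits=1), "H")
    assert feats["RLNonUni"] == pytest.approx(1.0)
    assert feats["ShrtREmp"] == pytest.approx((1 / 4 + 1 / 9) / 2)
    assert feats["LngREmph"] == pytest.approx((4 + 9) / 2)
    assert feats["GLevNonU"] == pytest.approx(1.0)
    assert feats["Fraction"] == pytest.approx(2 / 5)


def test_rlm_single_run_row():
    n = 7
    feats = rlm_features(qroi_from([np.zeros(n, dtype=int)], bits=1), "H")
    assert feats["LngREmph"] == pytest.approx(n**2)
    assert feats["Fraction"] == pytest.approx(1 / n)


def test_rlm_checkerboard_row_is_all_short_runs():
    feats = rlm_features(qroi_from([[0, 1] * 4], bits=1), "H")
    assert feats["ShrtREmp"] == pytest.approx(1.0)
    assert feats["LngREmph"] == pytest.approx(1.0)


@pytest.mark.parametrize("direction", DIRECTIONS)
def test_rlm_matches_naive_run_enumeration(direction):
    rng = np.random.default_rng(21)
    for trial in range(6):
        levels = rng.integers(0, 4, size=(6, 6))
        mask = rng.random((6, 6)) > 0.25
        mask[3, 3] = True
        runs = naive_runs(levels, mask, direction)
        expected = naive_rlm_features(runs, int(mask.sum()), 4)
        got = rlm_features(qroi_from(levels, mask, bits=2), direction)
        for key, val in expected.items():
            assert got[key] == pytest.approx(val), (key, trial)


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

def test_gradient_constant_roi_is_flat():
    feats = gradient_features(qroi_from(np.full((5, 5), 2)))
    assert feats["GrMean"] == 0
    assert feats["GrNonZeros"] == 0


def test_gradient_step_slice_hand_computed():
    # columns [0, 0, 4, 4, 4]: interior magnitudes per row are {2, 2, 0}
    levels = np.tile([0, 0, 4, 4, 4], (3, 1))
    feats = gradient_features(qroi_from(levels))
    assert feats["GrMean"] == pytest.approx((2 + 2 + 0) / 3)
    assert feats["GrNonZeros"] == pytest.approx(2 / 3)


def test_gradient_linear_ramp_has_zero_variance():
    ramp = np.tile(np.arange(6), (6, 1))
    feats = gradient_features(qroi_from(ramp))
    assert feats["GrVariance"] == pytest.approx(0.0)
    assert feats["GrMean"] == pytest.approx(1.0)


def test_gradient_undefined_without_interior_voxels():
    feats = gradient_features(qroi_from([[1, 2, 3]]))
    assert all(np.isnan(v) for v in feats.values())


# ---------------------------------------------------------------------------
# wavelet energies
# ---------------------------------------------------------------------------

def roi_from_image(image, mask=None):
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    return ROI(values=image[mask], slices=[SliceView(0, image, mask)])


def test_wavelet_constant_image_has_no_detail_energy():
    en = wavelet_energies(roi_from_image(np.full((8, 8), 7.0)), max_scale=2)
    for sb in ("LH", "HL", "HH"):
        for k in (1, 2):
            assert en[f"WavEn{sb}_s-{k}"] == pytest.approx(0.0)
    assert en["WavEnLL_s-1"] == pytest.approx(4 * 49.0)


def test_wavelet_single_tile_matches_hand_haar_step():
    a = 3.0
    en = wavelet_energies(roi_from_image(np.full((2, 2), a)), max_scale=1)
    assert en["WavEnLL_s-1"] == pytest.approx(4 * a * a)


def test_wavelet_energy_is_conserved_at_each_scale_split():
    rng = np.random.default_rng(8)
    img = rng.normal(size=(8, 8))
    en = wavelet_energies(roi_from_image(img), max_scale=1)
    # orthonormal Haar: 16 coefficients per subband at scale 1
    total = sum(16 * en[f"WavEn{sb}_s-1"] for sb in ("LL", "LH", "HL", "HH"))
    assert total == pytest.approx((img**2).sum())


def test_wavelet_scale_unreachable_is_nan():
    en = wavelet_energies(roi_from_image(np.ones((2, 2))), max_scale=2)
    assert np.isnan(en["WavEnLL_s-2"])


def test_heterogeneous_class_has_more_high_frequency_energy(small_cohort):
    from cystex.imaging_io import POSITIVE

    hh = {True: [], False: []}
    for les in small_cohort:
        roi = extract_roi(les)
        en = wavelet_energies(roi, max_scale=1)
        hh[les.class_label == POSITIVE].append(en["WavEnHH_s-1"])
    assert np.median(hh[True]) > np.median(hh[False])


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def test_extract_all_produces_at_least_300_named_columns(small_feature_table):
    features = small_feature_table.drop(columns=["class_label"])
    assert features.shape[1] >= 300
    assert features.columns.is_unique
    assert not features.isna().any().any()


def test_identical_lesions_get_identical_rows():
    img = np.random.default_rng(5).integers(100, 4000, size=(4, 12, 12))
    mask = np.zeros_like(img, dtype=bool)
    mask[1:3, 3:9, 3:9] = True
    a = lesion_from_slices(img, mask, lesion_id="a", label="positive")
    b = lesion_from_slices(img, mask, lesion_id="b", label="positive")
    table = extract_all([a, b])
    assert table.drop(columns="class_label").iloc[0].equals(
        table.drop(columns="class_label").iloc[1]
    )


def test_slice_order_does_not_affect_accumulated_matrices():
    rng = np.random.default_rng(6)
    img = rng.integers(100, 4000, size=(4, 10, 10))
    mask = np.ones_like(img, dtype=bool)
    fwd = lesion_from_slices(img, mask)
    rev = lesion_from_slices(img[::-1], mask[::-1])
    config = FeatureConfig(bits=(6,), directions=("H",), distances=(1, 2))
    f1 = extract_features(fwd, config)
    f2 = extract_features(rev, config)
    for name, val in f1.items():
        if "H" in name or name in ("Mean", "Variance"):
            assert f2[name] == pytest.approx(val), name
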