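"""Texture feature math: frozen hand examples, brute-force oracle
equivalence, and structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from oracles import (
    oracle_glcm_features,
    oracle_glcm_probs,
    oracle_glrlm_counts,
    oracle_glrlm_features,
    oracle_hs,
    oracle_texture_vector,
)
from thermotex.features import (
    GLCM_FEATURES,
    TEXTURE_FEATURES,
    TextureFeatureExtractor,
    build_glcm,
    build_glrlm,
    compute_histogram,
    extract_all_features,
    glcm_features,
    glrlm_features,
    hs_features,
    texture_feature_vector,
)
from thermotex.imaging import RoiMask

RTOL = 1e-9


def _vec(plane, **kw):
    return texture_feature_vector(np.asarray(plane), **kw)


# --------------------------------------------------------------------------
# Histogram statistics


def test_histogram_two_point():
    h = compute_histogram(np.array([0, 0, 255, 255]))
    assert h.bins[0] == 0.5 and h.bins[255] == 0.5
    assert h.bins.sum() == pytest.approx(1.0)
    assert np.count_nonzero(h.bins) == 2


def test_histogram_constant_and_validation():
    h = compute_histogram(np.full(10, 7))
    assert h.bins[7] == 1.0
    with pytest.raises(ValueError):
        compute_histogram(np.array([256]))
    with pytest.raises(ValueError):
        compute_histogram(np.array([], dtype=int))


def test_hs_two_point_symmetric():
    f = hs_features(compute_histogram(np.array([0, 0, 255, 255])))
    assert f["Mean"] == pytest.approx(127.5)
    assert f["Variance"] == pytest.approx(16256.25)
    assert f["Skewness"] == 0.0
    assert f["Kurtosis"] == pytest.approx(-2.0)
    assert (f["Perc01"], f["Perc50"], f["Perc90"]) == (0.0, 0.0, 255.0)


def test_hs_constant_plane():
    f = hs_features(compute_histogram(np.full(25, 42)))
    assert f["Variance"] == 0.0 and f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0
    assert f["Maxm01"] == 1.0
    assert f["Perc01"] == f["Perc99"] == 42.0
    assert f["Domn01"] == 42.0


# --------------------------------------------------------------------------
# GLRLM


def test_glrlm_single_run():
    m = build_glrlm(np.array([[5, 5, 5, 5]]), direction=0)
    assert m.counts[5, 3] == 1 and m.n_runs == 1 and m.n_pixels == 4
    f = glrlm_features(m)
    assert f == {
        "GLN": 1.0, "RLN": 1.0, "LRE": 16.0, "SRE": 0.0625,
        "Fraction": 0.25, "MRLN": 1.0, "MGLN": 1.0,
    }


def test_glrlm_alternating_row_is_four_unit_runs():
    m = build_glrlm(np.array([[1, 2, 1, 2]]), direction=0)
    assert m.n_runs == 4
    f = glrlm_features(m)
    assert f["LRE"] == f["SRE"] == f["Fraction"] == 1.0  # all runs length 1


def test_glrlm_mask_gaps_break_runs():
    plane = np.array([[3, 3, 3, 3, 3]])
    mask = np.array([[True, True, False, True, True]])
    m = build_glrlm(plane, mask, direction=0)
    assert m.counts[3, 1] == 2  # two runs of length 2, none of length 5
    assert m.n_pixels == 4


def test_glrlm_invalid_direction():
    with pytest.raises(ValueError):
        build_glrlm(np.zeros((2, 2), dtype=int), direction=30)


@pytest.mark.parametrize("direction", [0, 45, 90, 135])
def test_glrlm_matches_oracle_each_direction(rng, direction):
    for _ in range(5):
        plane = rng.integers(0, 8, size=(8, 8))
        m = build_glrlm(plane, direction=direction, bits=3)
        got = {
            (i, j + 1): int(m.counts[i, j])
            for i, j in zip(*np.nonzero(m.counts))
        }
        assert got == oracle_glrlm_counts(plane.tolist(), direction)
        expected = oracle_glrlm_features(got)
        for name, value in glrlm_features(m).items():
            assert value == pytest.approx(expected[name], rel=RTOL)


# --------------------------------------------------------------------------
# GLCM


def test_glcm_single_pair_is_symmetric():
    m = build_glcm(np.array([[1, 2]]), normalize=False)
    assert m.entries[1, 2] == 1 and m.entries[2, 1] == 1
    assert m.entries.sum() == 2


def test_glcm_checkerboard():
    m = build_glcm(np.array([[0, 1], [1, 0]]), direction=0)
    assert m.entries[0, 1] == pytest.approx(0.5)
    assert m.entries[1, 0] == pytest.approx(0.5)
    f = glcm_features(m)
    assert f["Contrast"] == pytest.approx(1.0)
    assert f["AngScMom"] == pytest.approx(0.5)
    assert f["Entropy"] == pytest.approx(1.0)  # one bit, log base 2
    assert f["Correlat"] == pytest.approx(-1.0)


def test_glcm_constant_plane_degenerate():
    f = glcm_features(build_glcm(np.full((4, 4), 9)))
    assert f["AngScMom"] == 1.0 and f["InvDefMom"] == 1.0
    assert f["Contrast"] == 0.0 and f["Entropy"] == 0.0
    assert f["Correlat"] == 0.0  # zero-variance convention


def test_glcm_validation():
    with pytest.raises(ValueError):
        build_glcm(np.array([[1, 2]]), distance=0)
    with pytest.raises(ValueError):
        build_glcm(np.array([[1, 2]]), direction=10)
    with pytest.raises(ValueError):  # no pair fits inside a 1-pixel ROI
        build_glcm(np.array([[1, 2]]), mask=np.array([[True, False]]))
    raw = build_glcm(np.array([[1, 2]]), normalize=False)
    with pytest.raises(ValueError):
        glcm_features(raw)


# --------------------------------------------------------------------------
# Oracle equivalence of the full 31-feature vector


def test_all_features_match_oracle_on_random_planes(rng):
    """Randomized cross-validation of every feature against the brute-force
    oracles, on full 8-bit planes and on masked ROIs."""
    for trial in range(25):
        shape = [(8, 8), (16, 16), (8, 16)][trial % 3]
        plane = rng.integers(0, 256, size=shape)
        got = _vec(plane)
        expected = oracle_texture_vector(plane.tolist())
        for name in TEXTURE_FEATURES:
            assert got[name] == pytest.approx(expected[name], rel=RTOL, abs=1e-12), name


def test_masked_features_match_oracle_on_submatrix(rng):
    """A rectangular ROI must give exactly the features of the cropped
    submatrix (runs and pairs cannot cross the ROI boundary)."""
    plane = rng.integers(0, 256, size=(12, 12))
    mask = RoiMask.from_rectangle(1, plane.shape, 2, 3, 8, 8)
    got = _vec(plane, mask=mask)
    expected = oracle_texture_vector(plane[2:10, 3:11].tolist())
    for name in TEXTURE_FEATURES:
        assert got[name] == pytest.approx(expected[name], rel=RTOL, abs=1e-12), name


# --------------------------------------------------------------------------
# Structural invariants


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    arrays(np.int64, (6, 6), elements=st.integers(0, 255)),
    st.permutations(range(36)),
)
def test_histogram_features_permutation_invariant(plane, perm):
    shuffled = plane.ravel()[np.asarray(perm)].reshape(plane.shape)
    a = hs_features(compute_histogram(plane.ravel()))
    b = hs_features(compute_histogram(shuffled.ravel()))
    assert a == b


@settings(max_examples=20, deadline=None, derandomize=True)
@given(arrays(np.int64, (8, 8), elements=st.integers(0, 200)), st.integers(1, 55))
def test_gray_level_shift_property(plane, shift):
    """Adding a constant (without clipping) leaves the spread/texture
    features unchanged and translates the location features."""
    a = _vec(plane)
    b = _vec(plane + shift)
    for name in ("Variance", "Contrast", "Entropy", "AngScMom", "SumEntrp",
                 "DifEntrp", "DifVarnc", "SumVarnc", "SumOfSqs", "InvDefMom",
                 "Skewness", "Kurtosis", "Maxm01", "Maxm10",
                 "GLN", "RLN", "LRE", "SRE", "Fraction", "MRLN", "MGLN"):
        assert b[name] == pytest.approx(a[name], rel=1e-9, abs=1e-12), name
    assert b["Mean"] == pytest.approx(a["Mean"] + shift, rel=1e-9)
    for q in ("Perc01", "Perc10", "Perc50", "Perc90", "Perc99"):
        assert b[q] == a[q] + shift
    assert b["SumAverg"] == pytest.approx(a["SumAverg"] + 2 * shift, rel=1e-9)


def test_horizontal_mirror_leaves_glcm_invariant(rng):
    """Symmetric accumulation makes 0-degree GLCM features mirror-invariant."""
    plane = rng.integers(0, 256, size=(10, 10))
    a = glcm_features(build_glcm(plane, direction=0))
    b = glcm_features(build_glcm(np.fliplr(plane), direction=0))
    for name in GLCM_FEATURES:
        assert b[name] == pytest.approx(a[name], rel=1e-12), name


def test_constant_plane_degenerate_vector():
    f = _vec(np.full((6, 6), 99))
    assert f["Variance"] == f["Contrast"] == f["Entropy"] == 0.0
    assert f["SumEntrp"] == f["DifEntrp"] == 0.0
    assert f["AngScMom"] == f["InvDefMom"] == 1.0


def test_feature_vector_bounds(rng):
    for _ in range(5):
        f = _vec(rng.integers(0, 256, size=(10, 10)))
        assert all(np.isfinite(v) for v in f.values())
        assert 0 < f["AngScMom"] <= 1
        assert 0 < f["SRE"] <= 1
        assert f["Entropy"] >= 0 and f["SumEntrp"] >= 0 and f["DifEntrp"] >= 0


# --------------------------------------------------------------------------
# Extractor and table assembly


def test_extractor_transform_order_and_params(rng):
    planes = [rng.integers(0, 256, size=(8, 8)) for _ in range(3)]
    ext = TextureFeatureExtractor()
    X = ext.fit_transform(planes)
    assert X.shape == (3, 31)
    assert list(ext.get_feature_names_out()) == list(TEXTURE_FEATURES)
    direct = _vec(planes[1])
    np.testing.assert_allclose(X[1], [direct[n] for n in TEXTURE_FEATURES])
    # sklearn parameter plumbing
    assert ext.get_params()["distance"] == 1
    ext.set_params(bits=4)
    with pytest.raises(ValueError):
        ext.transform([np.full((4, 4), 200)])  # out of range for 4 bits


def test_extract_all_features_layout(rng):
    image = rng.integers(0, 256, size=(24, 24, 3), dtype=np.uint8)
    masks = [
        RoiMask.from_rectangle(label, (24, 24), 6 * (label - 1), 2, 5, 20)
        for label in (1, 2, 3, 4)
    ]
    field = rng.normal(30, 1, size=(24, 24))
    key = ("A", "1", "pre")
    table = extract_all_features({key: image}, masks, {key: field})
    texture_cols = [c for c in table.columns if not c.split("_")[1].startswith("T")]
    assert len(texture_cols) == 372
    assert len([c for c in table.columns if "_T" in c]) == 12
    assert not table.isna().any().any()


def test_extract_all_features_determinism_and_error_recording(rng):
    image = rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8)
    masks = [RoiMask.from_rectangle(i, (16, 16), 0, 0, 16, 16) for i in (1, 2, 3, 4)]
    images = {
        ("A", "1", "pre"): image,
        ("A", "1", "post"): image.copy(),
        ("B", "2", "pre"): rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8),  # wrong shape
    }
    errors = []
    table = extract_all_features(images, masks, errors=errors)
    assert len(table) == 2  # bad image skipped, run continued
    assert len(errors) == 1 and errors[0][0] == ("B", "2", "pre")
    np.testing.assert_array_equal(
        table.loc[("A", "1", "pre")].to_numpy(), table.loc[("A", "1", "post")].to_numpy()
    )
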