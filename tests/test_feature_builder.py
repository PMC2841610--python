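import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixpack.feature_builder import (
    FeatureConfig,
    build_lipid_features,
    build_pair_features,
    enumerate_pairs,
    fit_apply_zscore,
    profile_window,
    relative_position,
    relative_position_pair,
    separation_encoding,
)
from helixpack.io_formats import (
    HelixSpan,
    ProteinRecord,
    SequenceProfile,
    Topology,
    ValidationError,
)


class TestProfileWindow:
    def test_window_length_is_140_at_defaults(self, small_profile):
        assert profile_window(small_profile, 10, 7).shape == (140,)

    def test_terminus_padding_zero(self, small_profile):
        first = profile_window(small_profile, 1, 7)
        assert np.all(first[: 3 * 20] == 0)
        assert np.array_equal(first[3 * 20 : 4 * 20], small_profile.scores[0])
        last = profile_window(small_profile, small_profile.length, 7)
        assert np.all(last[-3 * 20 :] == 0)

    def test_center_out_of_range(self, small_profile):
        with pytest.raises(ValidationError):
            profile_window(small_profile, small_profile.length + 1, 7)


class TestZScore:
    def test_population_zscore_values(self):
        train = np.array([[1.0], [2.0], [3.0]])
        normed, stats = fit_apply_zscore(train)
        np.testing.assert_allclose(
            normed.ravel(), [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_constant_column_maps_to_zero(self):
        train = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        normed, stats = fit_apply_zscore(train)
        assert np.all(normed[:, 0] == 0)

    def test_heldout_uses_training_stats(self):
        train = np.array([[1.0], [2.0], [3.0]])
        test = np.array([[2.0], [4.0]])
        _, test_n, stats = fit_apply_zscore(train, test)
        assert test_n[0, 0] == 0.0  # equals the training mean
        assert test_n[1, 0] > 1.0

    def test_normalized_columns_standard(self):
        rng = np.random.default_rng(0)
        train = rng.normal(3, 7, size=(50, 6))
        normed, _ = fit_apply_zscore(train)
        assert np.all(np.abs(normed.mean(axis=0)) < 1e-9)
        assert np.all(np.abs(normed.std(axis=0) - 1) < 1e-6)


class TestSeparationEncoding:
    @pytest.mark.parametrize(
        "d,slot",
        [(1, 0), (30, 0), (50, 0), (51, 1), (75, 1), (100, 2), (200, 6), (201, 7)],
    )
    def test_inclusive_left_bins(self, d, slot):
        vec = separation_encoding(d)
        assert vec[slot] == 1.0

    @given(st.integers(min_value=1, max_value=5000))
    @settings(max_examples=60, deadline=None)
    def test_one_hot_sums_to_one(self, d):
        assert separation_encoding(d).sum() == 1.0

    def test_thermometer_variant_cumulative(self):
        cfg = FeatureConfig(thermometer_separation=True)
        assert separation_encoding(30, cfg).sum() == 8.0
        assert separation_encoding(201, cfg).sum() == 1.0

    def test_invalid_distance(self):
        with pytest.raises(ValidationError):
            separation_encoding(0)


class TestRelativePosition:
    def test_first_residue_of_20mer(self):
        h = HelixSpan(1, 20, 1)
        assert relative_position(1, h) == pytest.approx(0.05)

    def test_flip_complement(self):
        h = HelixSpan(1, 20, 1)
        assert relative_position(1, h, flip=True) == pytest.approx(0.95 + 0.05)

    def test_flip_is_involution_on_values(self):
        h = HelixSpan(11, 30, 2)
        for pos in range(11, 31):
            z = relative_position(pos, h)
            zf = relative_position(pos, h, flip=True)
            assert 0 < z <= 1 and 0 < zf <= 1
            # flipping maps position p to the mirrored position's value
            mirror = h.start + (h.end - pos)
            assert zf == pytest.approx(relative_position(mirror, h))

    def test_adjacent_helices_flip_odd_parity(self):
        h1 = HelixSpan(1, 10, 1)
        h2 = HelixSpan(21, 30, 2)
        h3 = HelixSpan(41, 50, 3)
        z1, z2 = relative_position_pair(1, h1, 21, h2)
        assert z2 == pytest.approx(1.0)  # first residue flipped
        z1, z3 = relative_position_pair(1, h1, 41, h3)
        assert z3 == pytest.approx(0.1)  # same parity: no flip

    def test_outside_span_rejected(self):
        with pytest.raises(ValidationError):
            relative_position(5, HelixSpan(10, 20, 1))


class TestFeatureAssembly:
    def test_lipid_matrix_shape(self, small_record, small_profile, two_helix_topology):
        X, residues = build_lipid_features(
            small_record, small_profile, two_helix_topology
        )
        assert X.shape == (40, 140)
        assert residues[0] == 5
        np.testing.assert_array_equal(X[0], profile_window(small_profile, 5, 7))

    def test_pair_matrix_width_and_count(self, small_record, small_profile):
        topo = Topology(helices=(HelixSpan(5, 9, 1), HelixSpan(20, 24, 2)))
        scores = {p: 0.1 * p for p in topo.tm_residues()}
        X, pairs = build_pair_features(small_record, small_profile, topo, scores)
        assert X.shape == (25, 292)
        assert len(enumerate_pairs(topo)) == 25
        assert all(i < j for i, j in pairs)

    def test_pair_row_layout(self, small_record, small_profile):
        topo = Topology(helices=(HelixSpan(5, 9, 1), HelixSpan(20, 24, 2)))
        scores = {p: float(p) for p in topo.tm_residues()}
        X, pairs = build_pair_features(small_record, small_profile, topo, scores)
        r = pairs.index((5, 20))
        row = X[r]
        np.testing.assert_array_equal(row[:140], profile_window(small_profile, 5, 7))
        np.testing.assert_array_equal(row[140:280], profile_window(small_profile, 20, 7))
        assert row[280] == 5.0 and row[281] == 20.0
        assert row[282:290].sum() == 1.0
        zi, zj = relative_position_pair(
            5, topo.helices[0], 20, topo.helices[1]
        )
        assert row[290] == pytest.approx(zi) and row[291] == pytest.approx(zj)

    def test_missing_lipid_score_rejected(self, small_record, small_profile):
        topo = Topology(helices=(HelixSpan(5, 9, 1), HelixSpan(20, 24, 2)))
        with pytest.raises(ValidationError, match="lipid score"):
            build_pair_features(small_record, small_profile, topo, {5: 0.0})

    def test_no_tm_helices_rejected(self, small_record, small_profile):
        with pytest.raises(Exception):
            build_lipid_features(
                small_record, small_profile, Topology(helices=())
            )
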