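"""AAC / ACT / CCT descriptors: worked examples, oracle equivalence,
layout and invariances."""

import numpy as np
import pytest

from hmmdbp import FeatureSpec, HmmProfile, aac, act, cct, featurize
from hmmdbp.features import featurize_profiles

from conftest import profile_with_columns


def naive_features(H: np.ndarray, G: int) -> np.ndarray:
    """Brute-force double-loop evaluation of the three descriptor families,
    kept deliberately independent of the vectorized implementation."""
    L = H.shape[0]
    mean = [sum(H[i, j] for i in range(L)) / L for j in range(20)]
    out = list(mean)
    for j in range(20):
        for g in range(1, G + 1):
            s = 0.0
            for i in range(L - g):
                s += (H[i, j] - mean[j]) * (H[i + g, j] - mean[j])
            out.append(s / (L - g))
    for j in range(20):
        for k in range(20):
            if k == j:
                continue
            for g in range(1, G + 1):
                s = 0.0
                for i in range(L - g):
                    s += (H[i, j] - mean[j]) * (H[i + g, k] - mean[k])
                out.append(s / (L - g))
    return np.array(out)


class TestAac:
    def test_constant_profile_gives_constant_means(self):
        prof = HmmProfile("c", np.full((7, 20), 0.5))
        np.testing.assert_allclose(aac(prof), 0.5)

    def test_two_row_profile_is_componentwise_midpoint(self, rng):
        r1, r2 = rng.uniform(size=20), rng.uniform(size=20)
        prof = HmmProfile("two", np.stack([r1, r2]))
        np.testing.assert_allclose(aac(prof), (r1 + r2) / 2, atol=1e-15)

    def test_matches_double_loop_oracle(self, rng):
        H = rng.uniform(size=(5, 20))
        expected = [sum(H[i, j] for i in range(5)) / 5 for j in range(20)]
        np.testing.assert_allclose(aac(HmmProfile("r", H)), expected, atol=1e-14)

    def test_values_bounded_by_unit_interval(self, random_profile):
        v = aac(random_profile)
        assert (v >= 0).all() and (v <= 1).all()


class TestAct:
    def test_constant_column_has_zero_autocovariance(self):
        prof = profile_with_columns({0: [0.3] * 6})
        for g in range(1, 5):
            assert act(prof, 0, g) == 0.0

    def test_alternating_column_lag1(self):
        # column (1, 0, 1, 0): mean 0.5, lag-1 products sum to -0.75, /3
        prof = profile_with_columns({0: [1.0, 0.0, 1.0, 0.0]})
        assert act(prof, 0, 1) == pytest.approx(-0.25, abs=1e-12)

    def test_shift_invariance(self, rng):
        col = rng.uniform(0.0, 0.5, size=12)
        a = act(profile_with_columns({3: list(col)}), 3, 2)
        b = act(profile_with_columns({3: list(col + 0.4)}), 3, 2)
        assert a == pytest.approx(b, abs=1e-12)

    def test_lag_must_be_below_length(self):
        prof = profile_with_columns({0: [0.1, 0.9, 0.4]})
        with pytest.raises(ValueError, match="too short"):
            act(prof, 0, 3)


class TestCct:
    def test_constant_column_zeroes_the_product(self, rng):
        prof = profile_with_columns({0: list(rng.uniform(size=8)), 1: [0.2] * 8})
        assert cct(prof, 0, 1, 1) == pytest.approx(0.0, abs=1e-15)
        assert cct(prof, 1, 0, 1) == pytest.approx(0.0, abs=1e-15)

    def test_antiphase_columns_lag1(self):
        # j=(1,0,1,0), k=(0,1,0,1): centered products 0.25 each over 3 terms
        prof = profile_with_columns(
            {0: [1.0, 0.0, 1.0, 0.0], 1: [0.0, 1.0, 0.0, 1.0]}
        )
        assert cct(prof, 0, 1, 1) == pytest.approx(0.25, abs=1e-12)

    def test_ordered_pairs_are_distinct_features(self, random_profile):
        assert cct(random_profile, 2, 9, 1) != pytest.approx(
            cct(random_profile, 9, 2, 1), abs=1e-6
        )

    def test_same_column_rejected(self, random_profile):
        with pytest.raises(ValueError, match="must differ"):
            cct(random_profile, 4, 4, 1)


class TestFeaturize:
    @pytest.mark.parametrize("G,expected", [(1, 420), (3, 1220), (5, 2020), (10, 4020)])
    def test_dimension_law(self, G, expected, random_profile):
        spec = FeatureSpec(max_lag=G)
        assert spec.n_features == expected
        assert featurize(random_profile, spec).shape == (expected,)
        assert len(spec.feature_names()) == expected

    def test_family_block_sizes_at_g5(self):
        names = FeatureSpec(max_lag=5).feature_names()
        assert sum(n.startswith("AAC") for n in names) == 20
        assert sum(n.startswith("ACT") for n in names) == 100
        assert sum(n.startswith("CCT") for n in names) == 1900

    def test_names_unique_and_layout_canonical(self):
        spec = FeatureSpec(max_lag=2)
        names = spec.feature_names()
        assert len(names) == len(set(names))
        assert names[0] == "AAC[A]"
        assert names[20] == "ACT[A,1]"
        assert names[21] == "ACT[A,2]"
        assert names[60] == "CCT[A,C,1]"  # first ordered pair, lag innermost
        assert names[61] == "CCT[A,C,2]"

    def test_vector_follows_name_layout(self, random_profile):
        """The concatenated vector agrees with per-feature evaluation at the
        positions the name layout promises."""
        spec = FeatureSpec(max_lag=2)
        v = featurize(random_profile, spec)
        names = spec.feature_names()
        assert v[names.index("AAC[D]")] == pytest.approx(
            aac(random_profile)[2], abs=1e-14
        )
        assert v[names.index("ACT[C,2]")] == pytest.approx(
            act(random_profile, 1, 2), abs=1e-14
        )
        assert v[names.index("CCT[E,A,1]")] == pytest.approx(
            cct(random_profile, 3, 0, 1), abs=1e-14
        )

    def test_matches_naive_oracle_on_random_profiles(self, rng):
        for _ in range(5):
            L = int(rng.integers(8, 50))
            H = rng.uniform(size=(L, 20))
            G = int(rng.integers(1, 5))
            got = featurize(HmmProfile("r", H), FeatureSpec(max_lag=G))
            np.testing.assert_allclose(got, naive_features(H, G), atol=1e-10)

    def test_too_short_profile_rejected(self, rng):
        prof = HmmProfile("short", rng.uniform(size=(4, 20)))
        with pytest.raises(ValueError, match="too short"):
            featurize(prof, FeatureSpec(max_lag=4))

    def test_row_permutation_changes_act_cct_but_not_aac(self, rng):
        H = rng.uniform(size=(30, 20))
        perm = rng.permutation(30)
        spec = FeatureSpec(max_lag=2)
        v1 = featurize(HmmProfile("a", H), spec)
        v2 = featurize(HmmProfile("b", H[perm]), spec)
        np.testing.assert_allclose(v1[:20], v2[:20], atol=1e-14)
        assert not np.allclose(v1[20:], v2[20:], atol=1e-8)

    def test_covariance_features_bounded_on_unit_profiles(self, rng):
        spec = FeatureSpec(max_lag=3, include_aac=False, include_cct=False)
        for _ in range(10):
            H = rng.uniform(size=(50, 20))
            v = featurize(HmmProfile("r", H), spec)
            assert np.abs(v).max() <= 0.25

    def test_at_least_one_family_required(self):
        with pytest.raises(ValueError, match="at least one"):
            FeatureSpec(include_aac=False, include_act=False, include_cct=False)


class TestBatch:
    def test_feature_table_layout(self, rng):
        profiles = [
            HmmProfile(f"p{i}", rng.uniform(size=(20, 20))) for i in range(4)
        ]
        labels = {f"p{i}": i % 2 for i in range(4)}
        ds = featurize_profiles(profiles, labels, FeatureSpec(max_lag=1))
        assert ds.X.shape == (4, 420)
        assert ds.ids == ["p0", "p1", "p2", "p3"]
        assert list(ds.y) == [0, 1, 0, 1]

    def test_duplicate_ids_rejected(self, rng):
        profiles = [HmmProfile("dup", rng.uniform(size=(20, 20)))] * 2
        with pytest.raises(ValueError, match="duplicate"):
            featurize_profiles(profiles, {"dup": 1}, FeatureSpec(max_lag=1))
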