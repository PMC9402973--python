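"""Feature encoders: propensity factors, weight matrices, entropy, component."""

import warnings

import numpy as np
import pytest

import ionbind as ib
from ionbind.discretizers import AMINO_ACIDS, SCHEMES
from ionbind.encoders import (
    FragmentFeaturizer,
    LeakageError,
    NotFittedEncoderError,
    PropensityTable,
    encode_component,
    encode_conservation,
    encode_entropy,
    encode_propensity,
    feature_dimension,
    fit_propensity,
    fit_weight_matrices,
    stack_fragments,
)
from ionbind.windows import Fragment


def _fragment(states, label=0, chain_id="t", center=0):
    return Fragment(chain_id=chain_id, center_index=center,
                    states=np.asarray(states, dtype=np.int16), label=label)


def _uniform_states(L, aa_code=0, disorder=0, charge=2, hydro=4):
    """A fragment state matrix with constant codes and no padding."""
    row = np.array([aa_code, 2, 0, 0, 0, disorder, charge, hydro], dtype=np.int16)
    return np.tile(row, (L, 1))


# ---------------------------------------------------------------------------
# propensity factors


class TestPropensity:
    def test_worked_fixture_matches_hand_computed_factors(self, worked_fragments,
                                                          worked_fixture):
        _, ref = worked_fixture
        tables = fit_propensity(worked_fragments)
        aa = tables["amino_acid"]
        for letter, expected in ref["F_binding"].items():
            assert aa.F[AMINO_ACIDS.index(letter), 0] == pytest.approx(expected)
        for letter, expected in ref["F_nonbinding"].items():
            assert aa.F[AMINO_ACIDS.index(letter), 1] == pytest.approx(expected)
        charge = tables["charge"]
        ccats = SCHEMES["charge"].categories
        for cls, expected in ref["F_charge_binding"].items():
            assert charge.F[ccats.index(cls), 0] == pytest.approx(expected)
        hyd = tables["hydropathy"]
        hcats = SCHEMES["hydropathy"].categories
        for cls, expected in ref["F_hydropathy_binding"].items():
            assert hyd.F[hcats.index(cls), 0] == pytest.approx(expected)

    def test_audit_counts_match_reference(self, worked_fragments, worked_fixture):
        _, ref = worked_fixture
        aa = fit_propensity(worked_fragments)["amino_acid"]
        assert aa.N_t == ref["total_residues"]
        assert aa.N_j[0] == ref["binding_residues"]
        for letter, n in ref["aa_counts"].items():
            assert aa.N_i[AMINO_ACIDS.index(letter)] == n
        for letter, n in ref["aa_binding_counts"].items():
            assert aa.n_ij[AMINO_ACIDS.index(letter), 0] == n

    def test_weighted_normalization_identity(self, worked_fragments):
        # sum_i (N_i/N_t) F_ij == 1 for each class j
        for table in fit_propensity(worked_fragments).values():
            weighted = (table.N_i / table.N_t) @ table.F
            np.testing.assert_allclose(weighted, [1.0, 1.0], atol=1e-10)

    def test_no_preference_limit_gives_unit_factors(self):
        # class proportions identical in every category -> all F = 1
        n_ij = np.array([[2.0, 8.0], [5.0, 20.0], [3.0, 12.0]])
        table = PropensityTable("charge", ("positive", "negative", "neutral"), n_ij)
        np.testing.assert_allclose(table.F, 1.0, atol=1e-12)

    def test_unseen_category_gets_neutral_factor_with_warning(self):
        n_ij = np.zeros((4, 2))
        n_ij[0] = [3, 7]
        n_ij[1] = [1, 9]
        with pytest.warns(UserWarning, match="unseen"):
            table = PropensityTable("charge", ("a", "b", "c", "d"), n_ij)
        np.testing.assert_allclose(table.F[2], 1.0)
        np.testing.assert_allclose(table.F[3], 1.0)

    def test_single_class_training_data_rejected(self):
        with pytest.raises(ValueError, match="both binding and non-binding"):
            PropensityTable("charge", ("a", "b"), np.array([[3.0, 0.0], [2.0, 0.0]]))

    def test_encode_emits_central_residue_pairs(self, worked_fragments):
        tables = fit_propensity(worked_fragments)
        frag = next(f for f in worked_fragments
                    if AMINO_ACIDS[f.states[4, 0]] == "D" and f.label == 1)
        vec = encode_propensity(frag, tables)
        assert vec.shape == (6,)
        assert vec[0] == pytest.approx(2.5)         # F_{D,binding}
        assert vec[1] == pytest.approx(0.5 / 0.8)   # F_{D,non-binding}


# ---------------------------------------------------------------------------
# position weight matrices


class TestWeightMatrices:
    def test_pseudocount_arithmetic_oracle(self):
        # 100 positive fragments, q=3-ish track (phi), all category 0 at
        # every position: p = (100 + 10/3) / (100 + 10), m = ln(p / p0)
        L = 5
        states = np.zeros((200, L, 8), dtype=np.int16)
        labels = np.array([1] * 100 + [0] * 100)
        pair = fit_weight_matrices(None, "phi", states=states, labels=labels)
        p = (100 + 10 / 3) / (100 + 10)
        p0 = pair.p0[0]
        assert pair.M_pos[0, 0] == pytest.approx(np.log(p / p0))
        assert pair.M_neg[0, 0] == pytest.approx(np.log(p / p0))

    def test_score_is_zero_when_position_matches_background(self):
        # every category equally frequent at every position and overall:
        # p_ij = (N/q + sqrt(N)/q)/(N + sqrt(N)) = 1/q = p0 -> m = 0
        L = 3
        reps = 30
        base = np.array([[0, 1, 2], [1, 2, 0], [2, 0, 1]], dtype=np.int16)
        track = np.vstack([np.tile(base, (reps, 1))] * 2)  # both classes balanced
        states = np.zeros((len(track), L, 8), dtype=np.int16)
        states[:, :, 3] = track  # phi column (q = 3)
        labels = np.array([1] * (3 * reps) + [0] * (3 * reps))
        pair = fit_weight_matrices(None, "phi", states=states, labels=labels)
        np.testing.assert_allclose(pair.M_pos, 0.0, atol=1e-12)
        np.testing.assert_allclose(pair.M_neg, 0.0, atol=1e-12)

    def test_all_elements_finite_even_with_unseen_categories(self, rng):
        states = np.zeros((40, 9, 8), dtype=np.int16)
        states[:, :, 0] = rng.integers(0, 3, size=(40, 9))  # only 3 of 21 aa codes
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pair = fit_weight_matrices(None, "aa", states=states, labels=labels)
        assert np.isfinite(pair.M_pos).all() and np.isfinite(pair.M_neg).all()
        assert (pair.p0 > 0).all()

    def test_category_relabelling_permutes_matrix_columns(self, rng):
        # permuting category codes consistently in the data permutes columns
        q = SCHEMES["psi"].q
        states = np.zeros((60, 7, 8), dtype=np.int16)
        states[:, :, 4] = rng.integers(0, q, size=(60, 7))
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        pair = fit_weight_matrices(None, "psi", states=states, labels=labels)
        perm = np.array([2, 0, 3, 1])
        permuted = states.copy()
        permuted[:, :, 4] = perm[states[:, :, 4]]
        pair2 = fit_weight_matrices(None, "psi", states=permuted, labels=labels)
        np.testing.assert_allclose(pair2.M_pos[:, perm], pair.M_pos, atol=1e-12)
        np.testing.assert_allclose(pair2.M_neg[:, perm], pair.M_neg, atol=1e-12)

    def test_consensus_fragment_outscores_random_under_positive_matrix(
        self, small_fragments, rng
    ):
        fz = FragmentFeaturizer("full").fit(small_fragments)
        pair = fz.matrices_["aa"]
        consensus = np.argmax(pair.M_pos, axis=1)
        idx = np.arange(pair.window_length)
        consensus_score = pair.M_pos[idx, consensus].sum()
        random_scores = [
            pair.M_pos[idx, rng.integers(0, pair.q, size=pair.window_length)].sum()
            for _ in range(200)
        ]
        assert consensus_score > np.quantile(random_scores, 0.99)

    def test_vacancy_positions_score_through_vacancy_column(self, worked_fragments):
        fz = FragmentFeaturizer("full").fit(worked_fragments)
        first = worked_fragments[0]  # has leading padding
        vec = encode_conservation(first, fz.matrices_)
        assert np.isfinite(vec).all()
        assert vec.shape == (6 * 2 * 9,)


# ---------------------------------------------------------------------------
# entropy and component information


class TestEntropyAndComponent:
    def test_single_class_fragment_has_zero_entropy(self):
        frag = _fragment(_uniform_states(13))
        h = encode_entropy(frag)
        np.testing.assert_allclose(h, [0.0, 0.0], atol=1e-12)

    def test_even_two_class_split_gives_one_bit(self):
        states = _uniform_states(8)
        states[:4, 6] = 0  # charge: positive
        states[4:, 6] = 1  # charge: negative
        h = encode_entropy(_fragment(states))
        assert h[0] == pytest.approx(1.0)

    def test_entropy_bounded_by_log2_q_with_uniform_maximum(self, rng):
        for _ in range(50):
            states = _uniform_states(12)
            states[:, 6] = rng.integers(0, 4, size=12)
            states[:, 7] = rng.integers(0, 7, size=12)
            frag = _fragment(states)
            h = encode_entropy(frag)
            # brute-force oracle
            for k, (col, q) in enumerate(((6, 4), (7, 7))):
                counts = np.bincount(states[:, col], minlength=q) / 12
                expected = -sum(p * np.log2(p) for p in counts if p > 0)
                assert h[k] == pytest.approx(expected)
                assert h[k] <= np.log2(q) + 1e-12
        # exact uniform distribution attains the bound
        states = _uniform_states(8)
        states[:, 6] = [0, 1, 2, 3, 0, 1, 2, 3]
        assert encode_entropy(_fragment(states))[0] == pytest.approx(2.0)

    def test_component_dimensions_and_normalization(self, small_fragments):
        frag = small_fragments[10]
        full = encode_component(frag, "full")
        basic = encode_component(frag, "basic")
        assert full.shape == (40,)
        assert basic.shape == (37,)
        offsets = np.cumsum([0, 21, 4, 5, 3, 4, 3])
        for a, b in zip(offsets[:-1], offsets[1:]):
            assert full[a:b].sum() == pytest.approx(1.0, abs=1e-12)
            assert (full[a:b] >= 0).all()

    def test_homogeneous_unpadded_fragment_is_delta_distribution(self):
        frag = _fragment(_uniform_states(13, aa_code=0))  # thirteen alanines
        comp = encode_component(frag, "full")
        expected = np.zeros(21)
        expected[0] = 1.0
        np.testing.assert_allclose(comp[:21], expected)


# ---------------------------------------------------------------------------
# assembled featurizer


class TestFragmentFeaturizer:
    def test_full_dimension_is_48_plus_12L(self, small_fragments):
        fz = FragmentFeaturizer("full").fit(small_fragments)
        X = fz.transform(small_fragments[:7])
        assert X.shape == (7, 48 + 12 * 13)
        assert fz.n_features_out_ == feature_dimension("full", 13) == 204

    def test_basic_dimension_is_39_plus_10L(self, small_fragments):
        fz = FragmentFeaturizer("basic").fit(small_fragments)
        assert fz.n_features_out_ == feature_dimension("basic", 13) == 169

    def test_basic_set_excludes_disorder_and_propensity_everywhere(
        self, small_fragments
    ):
        fz = FragmentFeaturizer("basic").fit(small_fragments)
        assert not any("disorder" in n or "propensity" in n for n in fz.feature_names_)
        assert "disorder" not in fz.matrices_
        assert fz.tables_ == {}

    def test_feature_names_align_with_columns(self, small_fragments):
        fz = FragmentFeaturizer("full").fit(small_fragments)
        assert len(fz.feature_names_) == fz.n_features_out_
        assert fz.feature_names_[0] == "component:aa:A"
        assert fz.feature_names_[-1] == "propensity:hydropathy:non_binding"

    def test_transform_before_fit_raises(self, small_fragments):
        with pytest.raises(NotFittedEncoderError):
            FragmentFeaturizer("full").transform(small_fragments[:1])

    def test_window_length_mismatch_raises(self, small_chains, small_fragments):
        fz = FragmentFeaturizer("full").fit(small_fragments)
        other = ib.fragments_from_chains(
            [ib.discretize_chain(small_chains[0])], 9
        )
        with pytest.raises(ValueError, match="window length"):
            fz.transform(other)

    def test_leakage_guard_flags_training_fragments(self, small_fragments):
        fz = FragmentFeaturizer("full").fit(small_fragments[:300])
        fz.assert_disjoint(small_fragments[300:310])  # disjoint: fine
        with pytest.raises(LeakageError):
            fz.assert_disjoint(small_fragments[295:305])

    def test_fitted_encoders_ignore_heldout_labels(self, small_fragments):
        train = small_fragments[:300]
        held = [
            Fragment(f.chain_id, f.center_index, f.states, 1 - f.label)
            for f in small_fragments[300:]
        ]
        fz1 = FragmentFeaturizer("full").fit(train)
        fz2 = FragmentFeaturizer("full").fit(train)  # same training partition
        # corrupting held-out labels cannot reach the fitted state
        np.testing.assert_array_equal(
            fz1.tables_["amino_acid"].F, fz2.tables_["amino_acid"].F
        )
        X1, X2 = fz1.transform(held), fz2.transform(held)
        np.testing.assert_allclose(X1, X2)

    def test_scalar_encoders_agree_with_vectorized_transform(self, small_fragments):
        fz = FragmentFeaturizer("full").fit(small_fragments)
        frag = small_fragments[25]
        expected = np.concatenate([
            encode_component(frag, "full"),
            encode_conservation(frag, fz.matrices_),
            encode_entropy(frag),
            encode_propensity(frag, fz.tables_),
        ])
        np.testing.assert_allclose(fz.transform([frag])[0], expected, atol=1e-12)

    def test_json_round_trip_preserves_transform(self, small_fragments, tmp_path):
        from ionbind.encoders import save_bundle, load_bundle
        from sklearn.preprocessing import StandardScaler

        fz = FragmentFeaturizer("full").fit(small_fragments)
        X = fz.transform(small_fragments[:20])
        scaler = StandardScaler().fit(X)
        path = tmp_path / "bundle.json"
        save_bundle(fz, scaler, path)
        fz2, scaler2 = load_bundle(path)
        np.testing.assert_allclose(fz2.transform(small_fragments[:20]), X, atol=1e-12)
        np.testing.assert_allclose(
            scaler2.transform(X), scaler.transform(X), atol=1e-12
        )

    def test_stack_rejects_empty_and_mixed_lengths(self, small_fragments):
        with pytest.raises(ValueError):
            stack_fragments([])
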