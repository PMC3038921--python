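"""Feature channels: amino-acid bins, targeting scores, co-expression,
GOscores, nucleolar proximity of interactors, and discretization."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleoclass.features import (
    MISSING,
    BinningConfig,
    aa_frequencies,
    coexpression_score,
    discretize,
    equal_frequency_thresholds,
    extract_features,
    go_bin,
    go_scores,
    interactor_np,
    npi_score,
    targeting_bin,
    targeting_scores,
    GoScoreVector,
)
from nucleoclass.types import NUCLEOLAR_CLASSES, AnnotationBundle, ProteinRecord

from _oracles import go_score_oracle, npi_oracle

E, NP, NC = NUCLEOLAR_CLASSES


class TestAaFrequencies:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("SSSS", {"S": 1.0, "L": 0.0, "I": 0.0, "K": 0.0}),
            ("SLIK", {"S": 0.25, "L": 0.25, "I": 0.25, "K": 0.25}),
            ("SLIKAAAA", {"S": 0.125, "L": 0.125, "I": 0.125, "K": 0.125}),
        ],
    )
    def test_known_frequencies(self, seq, expected):
        assert aa_frequencies(seq) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=60))
    def test_tracked_plus_complement_sums_to_one(self, seq):
        freqs = aa_frequencies(seq)
        complement = sum(
            seq.count(aa) for aa in set(seq) if aa not in "SLIK"
        ) / len(seq)
        assert sum(freqs.values()) + complement == pytest.approx(1.0)


class TestDiscretize:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.12, 2), (0.0, 0), (0.20, 4), (0.05, 1), (0.9, 4)],
    )
    def test_half_open_bins_with_upward_ties(self, value, expected):
        assert discretize(value, [0.05, 0.10, 0.15, 0.20]) == expected

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            discretize(0.5, [0.1, 0.1, 0.2])


class TestEqualFrequencyThresholds:
    def test_quantiles_of_1_to_100(self):
        thresholds = equal_frequency_thresholds(list(range(1, 101)), 4)
        assert thresholds == pytest.approx([25.75, 50.5, 75.25])
        bins = [discretize(v, thresholds) for v in range(1, 101)]
        assert [bins.count(b) for b in range(4)] == [25, 25, 25, 25]

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            equal_frequency_thresholds([3.0] * 10, 4)

    def test_two_bins_split_evenly(self):
        thresholds = equal_frequency_thresholds([1, 2, 3, 4], 2)
        assert len(thresholds) == 1
        bins = [discretize(v, thresholds) for v in [1, 2, 3, 4]]
        assert bins.count(0) == 2 and bins.count(1) == 2

    def test_occupancy_within_20_percent_on_noisy_data(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=400)
        for n_bins in (4, 5):
            thresholds = equal_frequency_thresholds(values, n_bins)
            bins = [discretize(v, thresholds) for v in values]
            uniform = len(values) / n_bins
            for b in range(n_bins):
                assert abs(bins.count(b) - uniform) <= 0.2 * uniform


class TestTargeting:
    @pytest.mark.parametrize(
        "sp,tmd,mito,nols,expected",
        [
            (False, 0, True, 0.5, dict(s_M=1, s_S=0, s_N=0, s_C=1)),
            (True, 0, True, 0.95, dict(s_M=1, s_S=1, s_N=2, s_C=2)),
            (False, 0, False, 0.85, dict(s_M=0, s_S=0, s_N=1, s_C=0)),
            (False, 2, False, None, dict(s_M=0, s_S=1, s_N=0, s_C=2)),
            (False, 0, False, 0.9, dict(s_M=0, s_S=0, s_N=2, s_C=0)),
        ],
    )
    def test_score_combinations(self, sp, tmd, mito, nols, expected):
        scores = targeting_scores(sp, tmd, mito, nols)
        for key, value in expected.items():
            assert getattr(scores, key) == value

    def test_nols_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="nols_max"):
            targeting_scores(False, 0, False, 1.5)

    def test_bin_is_bijective_over_the_grid(self):
        bins = set()
        for s_C, s_N in itertools.product(range(3), range(3)):
            s_S = 1 if s_C == 2 else 0
            s_M = 1 if s_C == 1 else 0
            scores = targeting_scores(s_S == 1, 0, s_M == 1, [0.0, 0.85, 0.95][s_N])
            assert (scores.s_C, scores.s_N) == (s_C, s_N)
            bins.add(targeting_bin(scores))
        assert bins == set(range(9))


class TestCoexpression:
    def test_identical_profile_gives_one(self):
        q = np.array([1.0, 2.0, 3.0, 4.0])
        assert coexpression_score(q, [q]) == pytest.approx(1.0)

    def test_anticorrelated_gives_minus_one(self):
        q = np.array([1.0, 2.0, 3.0, 4.0])
        assert coexpression_score(q, [-q]) == pytest.approx(-1.0)

    def test_opposite_references_average_to_zero(self):
        q = np.array([1.0, 2.0, 3.0, 4.0])
        assert coexpression_score(q, [q, -q]) == pytest.approx(0.0)

    def test_flat_query_or_references_undefined(self):
        q = np.array([1.0, 2.0, 3.0])
        assert coexpression_score(np.ones(3), [q]) is None
        assert coexpression_score(q, [np.ones(3)]) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            coexpression_score(np.arange(4.0), [np.arange(5.0)])


class TestGoScores:
    def test_single_term_ratio(self):
        vec = go_scores({"t1"}, {E: {"t1": 2}}, {"t1": 10})
        assert vec.g[E] == pytest.approx(0.2)
        assert vec.n_terms == 1

    def test_two_term_average(self):
        vec = go_scores(
            {"t1", "t2"}, {E: {"t1": 2, "t2": 1}}, {"t1": 10, "t2": 5}
        )
        assert vec.g[E] == pytest.approx(0.2)

    def test_no_terms_undefined(self):
        vec = go_scores(set(), {E: {}}, {})
        assert vec.g is None and vec.n_terms == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_double_loop_oracle(self, data):
        terms = data.draw(
            st.sets(st.sampled_from([f"t{i}" for i in range(20)]), min_size=1)
        )
        proteome = {
            f"t{i}": data.draw(st.integers(min_value=1, max_value=50))
            for i in range(20)
        }
        counts = {
            cls: {
                f"t{i}": data.draw(st.integers(min_value=0, max_value=10))
                for i in range(20)
            }
            for cls in NUCLEOLAR_CLASSES
        }
        vec = go_scores(terms, counts, proteome)
        oracle = go_score_oracle(terms, counts, proteome)
        for cls in NUCLEOLAR_CLASSES:
            assert vec.g[cls] == pytest.approx(oracle[cls], abs=1e-12)


class TestGoBin:
    def test_dominant_class_indexes_bin(self):
        assert go_bin(GoScoreVector({E: 0.5, NP: 0.1, NC: 0.1}, 3)) == 0
        assert go_bin(GoScoreVector({E: 0.1, NP: 0.5, NC: 0.1}, 3)) == 1
        assert go_bin(GoScoreVector({E: 0.1, NP: 0.1, NC: 0.5}, 3)) == 2

    def test_all_below_threshold_falls_in_last_bin(self):
        vec = GoScoreVector({E: 0.001, NP: 0.002, NC: 0.0025}, 3)
        assert go_bin(vec, 0.003) == 3

    def test_tie_resolves_by_class_precedence(self):
        vec = GoScoreVector({E: 0.2, NP: 0.2, NC: 0.1}, 2)
        assert go_bin(vec, 0.003) == 0


class TestNucleolarProximity:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ({"nucleolus"}, 0.0),
            ({"nuclear"}, 0.8),
            ({"nucleolus", "cytosol"}, 1.5),
            ({"nucleoplasm"}, 1.2),
        ],
    )
    def test_interactor_np_mean_distance(self, labels, expected):
        assert interactor_np(labels) == pytest.approx(expected)

    def test_npi_averages_over_partners(self):
        adj = AnnotationBundle.adjacency_from_edges([("p", "a"), ("p", "b")])
        locs = {"a": {"nucleolus"}, "b": {"cytosol"}}
        assert npi_score("p", adj, locs) == pytest.approx(1.5)

    def test_excluded_partner_makes_score_missing(self):
        adj = AnnotationBundle.adjacency_from_edges([("p", "a")])
        locs = {"a": {"nucleolus"}}
        assert npi_score("p", adj, locs, excluded_ids={"a"}) is None

    def test_no_partners_missing(self):
        assert npi_score("p", {}, {}) is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_oracle_on_random_graphs(self, data):
        n = data.draw(st.integers(min_value=2, max_value=30))
        ids = [f"n{i}" for i in range(n)]
        edges = data.draw(
            st.lists(
                st.tuples(st.sampled_from(ids), st.sampled_from(ids)), max_size=60
            )
        )
        label_pool = ["nucleolus", "nucleoplasm", "cytosol", "nuclear"]
        distance = {"nucleolus": 0.0, "nucleoplasm": 1.2, "cytosol": 3.0, "nuclear": 0.8}
        locs = {
            i: data.draw(st.sets(st.sampled_from(label_pool), max_size=3))
            for i in ids
        }
        excluded = data.draw(st.sets(st.sampled_from(ids), max_size=3))
        adj = AnnotationBundle.adjacency_from_edges(edges)
        query = ids[0]
        got = npi_score(query, adj, locs, excluded_ids=excluded)
        want = npi_oracle(query, edges, locs, distance, excluded | {query})
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want, abs=1e-12)


class TestExtractFeatures:
    def _bundle(self, **kwargs):
        return AnnotationBundle(**kwargs)

    def test_sequence_only_protein(self):
        protein = ProteinRecord("p", "SLIKSLIKAA")
        vec = extract_features(
            protein, self._bundle(), BinningConfig(), {c: {} for c in NUCLEOLAR_CLASSES},
            {}, [],
        )
        assert vec.coexpr is MISSING and vec.npi is MISSING
        assert vec.go == 3
        assert vec.targeting == 0

    def test_nucleolar_interactor_lands_in_first_npi_bin(self):
        protein = ProteinRecord("p", "SLIK")
        bundle = self._bundle(
            interactions=AnnotationBundle.adjacency_from_edges([("p", "q")]),
            localisations={"q": frozenset({"nucleolus"})},
        )
        config = BinningConfig(npi_thresholds=(0.4, 0.8, 1.6, 2.4))
        vec = extract_features(
            protein, bundle, config, {c: {} for c in NUCLEOLAR_CLASSES}, {}, []
        )
        assert vec.npi == 0

    def test_deterministic(self):
        protein = ProteinRecord("p", "SLIKMKV")
        args = (
            protein,
            self._bundle(),
            BinningConfig(),
            {c: {} for c in NUCLEOLAR_CLASSES},
            {},
            [],
        )
        assert extract_features(*args) == extract_features(*args)
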