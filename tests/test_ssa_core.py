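"""Transition rates, TRATE costs, optimal matching, entropies,
time-in-state summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from medseq.ssa_core import (
    CostMatrix,
    DissimilarityMatrix,
    complexity_index,
    dissimilarity_matrix,
    longitudinal_entropy,
    mean_time_in_states,
    om_distance,
    time_in_state_contrast,
    transition_rates,
    transversal_entropy,
    trate_costs,
    unique_index,
)
from medseq.states import ALPHABET, CENSORED, LACK, LITHIUM

ABC = ("A", "B", "C")


def _unit_costs(alphabet=ABC, sub=2.0, indel=1.0):
    m = np.full((len(alphabet), len(alphabet)), sub)
    np.fill_diagonal(m, 0.0)
    return CostMatrix(sub=m, indel=indel, alphabet=alphabet)


class TestTransitionRates:
    def test_single_sequence_counts(self):
        tm = transition_rates([list("AAAB")], alphabet=ABC)
        assert tm.probs[0, 0] == pytest.approx(2 / 3)
        assert tm.probs[0, 1] == pytest.approx(1 / 3)

    def test_constant_sequence_never_leaves(self):
        tm = transition_rates([list("AAAA")], alphabet=ABC)
        assert tm.probs[0, 0] == 1.0
        assert tm.leave_probability()[0] == 0.0

    def test_pooled_counts_over_sequences(self):
        tm = transition_rates([list("AB"), list("BA")], alphabet=ABC)
        assert tm.probs[0, 1] == 1.0 and tm.probs[1, 0] == 1.0

    def test_unobserved_origin_flagged_not_nan(self):
        tm = transition_rates([list("AAAA")], alphabet=ABC)
        assert not tm.observed[2]
        assert not np.isnan(tm.probs).any()

    def test_rows_stochastic(self):
        rng = np.random.default_rng(3)
        seqs = rng.integers(0, 3, size=(20, 12))
        tm = transition_rates(seqs, alphabet=ABC)
        sums = tm.probs.sum(axis=1)
        assert np.allclose(sums[tm.observed], 1.0)

    def test_weights_scale_counts(self):
        tm = transition_rates([list("AB"), list("AA")], weights=[3, 1], alphabet=ABC)
        assert tm.probs[0, 1] == pytest.approx(0.75)


class TestTrateCosts:
    def test_never_interchanged_costs_cval(self):
        tm = transition_rates([list("AACC")], alphabet=ABC)
        cm = trate_costs(tm, cval=2.0)
        assert cm.sub[0, 1] == 2.0  # A and B never interchange

    def test_formula_and_symmetry(self):
        # p(A->B)=0.5 via AB,AA ; p(B->A)=0.25 via four B-origins
        tm = transition_rates(
            [list("AB"), list("AA"), list("BA"), list("BB"), list("BB"), list("BB")],
            alphabet=ABC,
        )
        cm = trate_costs(tm, cval=2.0)
        assert cm.sub[0, 1] == pytest.approx(2.0 - 0.5 - 0.25)
        assert np.allclose(cm.sub, cm.sub.T)
        assert np.diag(cm.sub).sum() == 0.0

    def test_default_indel_is_half_cval(self):
        tm = transition_rates([list("AB")], alphabet=ABC)
        assert trate_costs(tm, cval=3.0).indel == 1.5


class TestOmDistance:
    def test_identical_sequences_zero(self):
        cm = _unit_costs()
        assert om_distance(list("ABCA"), list("ABCA"), cm) == 0.0

    def test_single_substitution(self):
        cm = _unit_costs()
        assert om_distance(list("AA"), list("AB"), cm) == 2.0

    def test_indel_beats_double_substitution(self):
        """AB -> BA: delete A + insert A (cost 2) beats two
        substitutions (cost 4)."""
        cm = _unit_costs()
        assert om_distance(list("AB"), list("BA"), cm) == 2.0

    def test_unequal_lengths(self):
        cm = _unit_costs()
        assert om_distance(list("A"), list("AAA"), cm) == 2.0

    def test_symbol_outside_alphabet_raises(self):
        with pytest.raises(ValueError, match="outside"):
            om_distance(list("AZ"), list("AA"), _unit_costs())

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_pseudometric_on_random_instances(self, seed):
        """Symmetry and triangle inequality under metric costs."""
        rng = np.random.default_rng(seed)
        cm = _unit_costs(sub=float(rng.uniform(0.5, 2.0)), indel=1.0)
        seqs = [tuple(ABC[i] for i in rng.integers(0, 3, size=5)) for _ in range(3)]
        a, b, c = seqs
        dab = om_distance(a, b, cm)
        assert dab == pytest.approx(om_distance(b, a, cm))
        assert dab <= om_distance(a, c, cm) + om_distance(c, b, cm) + 1e-9


class TestDissimilarityMatrix:
    def test_identical_sequences_pool_into_one_row(self):
        d = dissimilarity_matrix([list("AB")] * 5, _unit_costs())
        assert d.matrix.shape == (1, 1) and d.matrix[0, 0] == 0.0
        assert d.weights[0] == 5

    def test_matches_elementwise_om(self):
        seqs = [list("AAB"), list("ABB"), list("CCC")]
        cm = _unit_costs()
        d = dissimilarity_matrix(seqs, cm)
        for i, j in itertools.combinations(range(3), 2):
            si = [cm.alphabet[x] for x in d.sequences[i]]
            sj = [cm.alphabet[x] for x in d.sequences[j]]
            assert d.matrix[i, j] == pytest.approx(om_distance(si, sj, cm))

    def test_input_order_invariance(self):
        seqs = [list("AAB"), list("ABB"), list("CCC"), list("AAB")]
        cm = _unit_costs()
        d1 = dissimilarity_matrix(seqs, cm)
        d2 = dissimilarity_matrix(seqs[::-1], cm)
        assert np.array_equal(d1.sequences, d2.sequences)
        assert np.allclose(d1.matrix, d2.matrix)
        assert np.array_equal(d1.weights, d2.weights)

    def test_weights_sum_to_total(self):
        rng = np.random.default_rng(0)
        seqs = rng.integers(0, 2, size=(40, 6))
        d = dissimilarity_matrix(seqs, _unit_costs())
        assert d.weights.sum() == 40

    def test_unique_index_round_trip(self):
        seqs = [list("AAB"), list("CCC"), list("AAB")]
        d = dissimilarity_matrix(seqs, _unit_costs())
        idx = unique_index(seqs, d)
        assert idx[0] == idx[2] != idx[1]


class TestEntropy:
    def test_shared_state_zero(self):
        assert transversal_entropy([list("AA"), list("AA")], alphabet=ABC)[0] == 0.0

    def test_uniform_over_alphabet_is_one(self):
        seqs = [[a] for a in ABC]
        assert transversal_entropy(seqs, alphabet=ABC)[0] == pytest.approx(1.0)

    def test_two_state_half_split(self):
        """50/50 over 2 of 8 states: ln 2 / ln 8 = 1/3."""
        seqs = [[LACK], [LITHIUM]]
        ent = transversal_entropy(seqs, alphabet=ALPHABET)
        assert ent[0] == pytest.approx(np.log(2) / np.log(8))

    def test_longitudinal_constant_zero(self):
        assert longitudinal_entropy([LACK] * 12) == 0.0

    def test_complexity_alternating(self):
        seq = [LACK, LITHIUM] * 6
        expected = np.sqrt(1.0 * np.log(2) / np.log(8))
        assert complexity_index(seq) == pytest.approx(expected)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_bounds(self, seed):
        rng = np.random.default_rng(seed)
        seq = [ALPHABET[i] for i in rng.integers(0, 8, size=12)]
        assert 0.0 <= longitudinal_entropy(seq) <= 1.0
        assert 0.0 <= complexity_index(seq) <= 1.0


class TestTimeInStates:
    def test_half_lack_share(self):
        seq = [[LACK] * 6 + [LITHIUM] * 6]
        out = mean_time_in_states(seq, ["g"])
        lack = out[(out["state"] == LACK)].iloc[0]
        assert lack["mean_periods"] == 6.0 and lack["proportion"] == 0.5

    def test_censored_excluded_from_denominator(self):
        seq = [[LACK] * 6 + [CENSORED] * 6]
        out = mean_time_in_states(seq, ["g"])
        assert out[out["state"] == LACK].iloc[0]["proportion"] == 1.0
        assert out[out["state"] == CENSORED].iloc[0]["proportion"] == 0.5

    def test_identical_groups_null_rate_ratios(self):
        seqs = [[LACK] * 6 + [LITHIUM] * 6] * 8
        groups = ["a"] * 4 + ["b"] * 4
        out = time_in_state_contrast(seqs, groups, reference_group="a")
        assert np.allclose(out["rate_ratio"], 1.0)

    def test_twofold_difference_recovered(self):
        seqs = [[LACK] * 3 + [LITHIUM] * 9] * 6 + [[LACK] * 6 + [LITHIUM] * 6] * 6
        groups = ["a"] * 6 + ["b"] * 6
        out = time_in_state_contrast(seqs, groups, reference_group="a")
        row = out[(out["state"] == LACK) & (out["group"] == "b")].iloc[0]
        assert row["rate_ratio"] == pytest.approx(2.0, rel=1e-6)
        assert row["ci_low"] < 2.0 < row["ci_high"]
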