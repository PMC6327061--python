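import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossfeed.cosim import IterationResult, PairExperimentRecord
from crossfeed.interactions import (
    NO_PAIR_GROWTH,
    CooperativityInputs,
    classify_interaction,
    cooperativity_index,
    obligate_syntrophy,
    summarize_sweep,
)


def make_record(
    secretions_i,
    secretions_j,
    uptakes_i,
    uptakes_j,
    carbons=("glc_e",),
    growth=(True, True),
    solo=(True, True),
):
    """Single-iteration record with explicit final-state fluxes."""
    it = IterationResult(
        iteration=1,
        growth=growth,
        growth_rates=(float(growth[0]), float(growth[1])),
        secretions=(secretions_i, secretions_j),
        uptakes=(uptakes_i, uptakes_j),
        medium_metabolites=frozenset(carbons),
    )
    return PairExperimentRecord(
        organisms=("orgA", "orgB"),
        carbon_sources=carbons,
        oxygen=(False, False),
        iterations=[it],
        final_iteration=1,
        solo_growth=solo,
    )


class TestClassifyInteraction:
    def test_competitive_exclusion_n1b(self):
        record = make_record(
            {"co2_e": 5.0},
            {"co2_e": 5.0},
            {"glc_e": -10.0},
            {"glc_e": -10.0},
        )
        label = classify_interaction(record)
        assert label.motif_code == "N1b"
        assert label.competition and label.iclass == "N"
        assert label.exchange_edges == []

    def test_commensal_direction(self):
        record = make_record(
            {"ac_e": 10.0},
            {},
            {"glc_e": -10.0},
            {"ac_e": -10.0},
        )
        label = classify_interaction(record)
        assert label.motif_code == "C1a"
        assert label.direction == "i->j"
        assert label.exchange_edges == [("orgA", "ac_e", "orgB")]

    def test_mutualism_reciprocal_edges(self):
        record = make_record(
            {"ac_e": 10.0},
            {"nh4_e": 4.0},
            {"glc_e": -10.0, "nh4_e": -2.0},
            {"glc_e": -10.0, "ac_e": -10.0},
        )
        label = classify_interaction(record)
        assert label.motif_code == "M1b"
        assert label.direction == "both"

    def test_exclusion_list(self):
        record = make_record(
            {"h2o_e": 10.0},
            {},
            {"glc_e": -10.0},
            {"h2o_e": -5.0, "glc_e": -10.0},
        )
        label = classify_interaction(record)
        assert label.iclass == "N"  # water never counts as an exchange
        label2 = classify_interaction(record, exclusion=())
        assert label2.iclass == "C"

    def test_co2_not_excluded_by_default(self):
        record = make_record(
            {"co2_e": 5.0},
            {},
            {"glc_e": -10.0},
            {"co2_e": -1.0, "glc_e": -10.0},
        )
        assert classify_interaction(record).iclass == "C"

    def test_two_carbon_count(self):
        record = make_record(
            {},
            {},
            {"glc_e": -10.0},
            {"xyl_e": -10.0},
            carbons=("glc_e", "xyl_e"),
        )
        label = classify_interaction(record)
        assert label.motif_code == "N2a"
        assert not label.competition

    def test_no_pair_growth_sentinel(self):
        record = make_record({}, {}, {}, {}, growth=(True, False))
        label = classify_interaction(record)
        assert label.motif_code == NO_PAIR_GROWTH

    def test_nonterminated_rejected(self):
        record = make_record({}, {}, {"glc_e": -1.0}, {"glc_e": -1.0})
        record.nonterminated = True
        with pytest.raises(ValueError, match="nonterminated"):
            classify_interaction(record)

    def test_label_symmetry_under_swap(self):
        record = make_record(
            {"ac_e": 10.0},
            {},
            {"glc_e": -10.0},
            {"ac_e": -10.0, "glc_e": -10.0},
        )
        fwd = classify_interaction(record)
        rev = classify_interaction(record.swapped())
        assert fwd.iclass == rev.iclass
        assert fwd.motif_code == rev.motif_code
        assert fwd.direction == "i->j" and rev.direction == "j->i"

    def test_grammar(self):
        record = make_record({}, {}, {"glc_e": -1.0}, {"glc_e": -1.0})
        code = classify_interaction(record).motif_code
        assert len(code) == 3 and code[0] in "NCM" and code[1] in "12" and code[2] in "ab"


class TestObligateSyntrophy:
    def test_flags(self):
        record = make_record({}, {}, {}, {}, solo=(True, False), growth=(True, True))
        assert obligate_syntrophy(record) == (False, True)

    def test_both_solo(self):
        record = make_record({}, {}, {}, {})
        assert obligate_syntrophy(record) == (False, False)


class TestCooperativityIndex:
    def test_independence_null(self):
        # pair frequency equal to product of singles: 45.5... use exact case
        inputs = CooperativityInputs(
            g_pair=0, n_pair=14, g_alpha=0, n_alpha=14, g_beta=50, n_beta=14
        )
        assert cooperativity_index(inputs) == 0.0

    def test_boundary_one(self):
        inputs = CooperativityInputs(
            g_pair=91, n_pair=14, g_alpha=0, n_alpha=14, g_beta=0, n_beta=14
        )
        assert cooperativity_index(inputs) == pytest.approx(1.0)

    def test_derived_value(self):
        inputs = CooperativityInputs(
            g_pair=45, n_pair=14, g_alpha=30, n_alpha=14, g_beta=60, n_beta=14
        )
        # 45/91 - (30/91)(60/91) = 0.27714...
        assert cooperativity_index(inputs) == pytest.approx(0.2771, abs=5e-5)

    def test_normalizer_zero(self):
        with pytest.raises(ValueError, match="normalizer"):
            cooperativity_index(
                CooperativityInputs(1, 1, 0, 14, 0, 14)
            )

    def test_count_exceeds_normalizer(self):
        with pytest.raises(ValueError, match="outside"):
            cooperativity_index(
                CooperativityInputs(92, 14, 0, 14, 0, 14)
            )

    @given(
        n=st.integers(2, 30),
        data=st.data(),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_exact_fraction_arithmetic(self, n, data):
        norm = math.comb(n, 2)
        g_pair = data.draw(st.integers(0, norm))
        g_a = data.draw(st.integers(0, norm))
        g_b = data.draw(st.integers(0, norm))
        got = cooperativity_index(
            CooperativityInputs(g_pair, n, g_a, n, g_b, n)
        )
        exact = Fraction(g_pair, norm) - Fraction(g_a, norm) * Fraction(g_b, norm)
        assert got == pytest.approx(float(exact), abs=1e-12)
        assert -1.0 <= got <= 1.0


class TestSummarizeSweep:
    def _frame(self):
        rows = [
            # org pair grows, C1a, secretes ac+co2
            dict(org_i="A", org_j="B", carbon_a="glc_e", carbon_b="xyl_e",
                 o2_i=0, o2_j=0, grow_i=1, grow_j=1, solo_grow_i=1, solo_grow_j=0,
                 c_s=2, secreted_i="ac_e:10;co2_e:10", secreted_j="co2_e:5",
                 uptaken_i="glc_e:-10", uptaken_j="ac_e:-10",
                 interaction="C", motif="C1a"),
            dict(org_i="A", org_j="C", carbon_a="glc_e", carbon_b="xyl_e",
                 o2_i=0, o2_j=0, grow_i=1, grow_j=1, solo_grow_i=1, solo_grow_j=1,
                 c_s=1, secreted_i="ac_e:10;co2_e:10", secreted_j="co2_e:5",
                 uptaken_i="glc_e:-10", uptaken_j="glc_e:-10",
                 interaction="N", motif="N1b"),
            dict(org_i="B", org_j="C", carbon_a="glc_e", carbon_b="xyl_e",
                 o2_i=0, o2_j=0, grow_i=0, grow_j=1, solo_grow_i=0, solo_grow_j=1,
                 c_s=1, secreted_i="", secreted_j="co2_e:5",
                 uptaken_i="", uptaken_j="glc_e:-10",
                 interaction="", motif="no-pair-growth"),
        ]
        return pd.DataFrame(rows)

    def test_motif_counts_partition_pair_growth(self):
        tables = summarize_sweep(self._frame())
        motif = tables["motif_frequencies"]
        assert motif["count"].sum() == 2  # rows with pair growth

    def test_secretion_frequencies(self):
        tables = summarize_sweep(self._frame())
        freq = tables["secretion_frequencies"].set_index("metabolite_id")
        assert freq.loc["co2_e", "n_secreted"] == 3
        assert freq.loc["ac_e", "n_secreted"] == 2

    def test_spearman_identical_columns(self):
        tables = summarize_sweep(self._frame())
        rho = tables["cooccurrence_spearman"]
        # ac_e secreted in exactly the growth rows where A participates
        assert rho.loc["ac_e", "ac_e"] == pytest.approx(1.0)
        # co2_e is constant across growth-yielding rows -> missing correlation
        assert np.isnan(rho.loc["co2_e", "ac_e"])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_sweep(pd.DataFrame())
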