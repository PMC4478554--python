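"""Genotype-classifier tests: worked strain examples, the skew statistic,
table aggregation and the simulate-then-infer round trip."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from octadkit import (
    DerivativeObs,
    ObservationError,
    ObservationRecord,
    balanced_split_probability,
    get_preset,
    infer_heterokaryon_genotype,
    load_table2,
    make_heterokaryon,
    observe_heterokaryon,
    summarize_observation_table,
)
from octadkit.fixtures import DEFAULT_GENOTYPES
from conftest import worked_observations


class TestBalancedSplit:
    @pytest.mark.parametrize("n1,n2,expected", [
        (6, 0, 0.03125),   # 2 * (1/2)^6
        (5, 5, 1.0),
        (0, 0, 1.0),
        (1, 0, 1.0),
    ])
    def test_exact_binomial_values(self, n1, n2, expected):
        assert balanced_split_probability(n1, n2) == pytest.approx(expected)

    @settings(deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40))
    def test_symmetric_in_arguments(self, a, b):
        assert balanced_split_probability(a, b) == pytest.approx(
            balanced_split_probability(b, a)
        )

    @settings(deadline=None)
    @given(st.integers(2, 60))
    def test_non_increasing_in_skew_at_fixed_total(self, n):
        ps = [balanced_split_probability(k, n - k) for k in range(n // 2, -1, -1)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


class TestWorkedExamples:
    """The published reference strains the classifier must reproduce."""

    def test_all_one_mat_dp_pattern_calls_dp_plus_df(self, eb4):
        call = infer_heterokaryon_genotype(worked_observations()["1E1"], eb4)
        assert call.label == "[Df a + Dp A]"
        assert call.flags == []

    def test_balanced_t_and_n_patterns_call_t_plus_n(self, eb4):
        call = infer_heterokaryon_genotype(worked_observations()["2E1"], eb4)
        assert call.label == "[N a + T A]"
        assert call.flags == []

    def test_small_single_class_t_gets_not_excluded_flag(self, eb4):
        call = infer_heterokaryon_genotype(worked_observations()["3E1"], eb4)
        assert call.label == "[T a + Df A]"
        assert any("[T a + N A] not excluded" in f for f in call.flags)
        assert call.skew_p == pytest.approx(0.03125)

    def test_a_junction_only_derivatives_reveal_triple_heterokaryon(self, ibj5):
        # derivatives amplifying only junction A must be [N + Df]
        # heterokaryons (a bare Df homokaryon is inviable)
        call = infer_heterokaryon_genotype(worked_observations()["3I1"], ibj5)
        assert call.label == "[T a + N A + Df A]"
        assert len(call.nuclei) == 3

    def test_single_derivative_leaves_partner_undetermined(self, ibj5):
        obs = ObservationRecord(
            "1I4",
            frozenset({"A", "B"}),
            [DerivativeObs(False, "A", frozenset({"A", "B"}))],
        )
        call = infer_heterokaryon_genotype(obs, ibj5)
        assert call.label == "[? a + T A]"

    def test_no_self_steriles_gives_nd(self, eb4):
        obs = ObservationRecord(
            "13E1", frozenset({"A", "B", "C"}),
            [DerivativeObs(True, "het", None)] * 5,
        )
        call = infer_heterokaryon_genotype(obs, eb4)
        assert call.label == "ND"
        assert call.evidence == "none"

    def test_large_single_class_needs_no_flag(self, eb4):
        obs = ObservationRecord(
            "x", frozenset({"A", "B", "C"}),
            [DerivativeObs(False, "a", frozenset({"A", "B", "C"}))] * 20,
        )
        call = infer_heterokaryon_genotype(obs, eb4)
        assert call.label == "[T a + Df A]"
        assert call.flags == []

    def test_mat_only_fallback_is_flagged(self, eb4):
        obs = ObservationRecord(
            "y", frozenset({"A", "B", "C"}),
            [DerivativeObs(False, "a", None)] * 12
            + [DerivativeObs(False, "A", None)] * 13,
        )
        call = infer_heterokaryon_genotype(obs, eb4)
        assert call.evidence == "mat-only"
        assert "mat-only evidence" in call.flags

    def test_mat_only_single_class_calls_dp_df_with_caveat(self, b362i):
        obs = ObservationRecord(
            "z", frozenset({"A", "B", "C"}),
            [DerivativeObs(False, "a", None)] * 6,
        )
        call = infer_heterokaryon_genotype(obs, b362i)
        assert call.label == "[Dp a + Df A]"
        assert any("not excluded" in f for f in call.flags)

    def test_derivative_junctions_must_be_subset_of_heterokaryon(self):
        with pytest.raises(ObservationError):
            ObservationRecord(
                "bad", frozenset({"B", "C"}),
                [DerivativeObs(False, "a", frozenset({"A"}))],
            )


class TestRoundTrip:
    @pytest.mark.parametrize("name", sorted(set(DEFAULT_GENOTYPES) -
                                            {"Dp+Df_nucleus_limited"}))
    def test_simulated_heterokaryons_are_recovered(self, name):
        """Simulate >= 20 derivatives from each constructible heterokaryon
        genotype and check the classifier returns exactly that genotype."""
        spec = get_preset("EB4")
        comps = DEFAULT_GENOTYPES[name]
        het = make_heterokaryon(spec, comps)
        seed = 1000 + sorted(DEFAULT_GENOTYPES).index(name)
        rng = np.random.default_rng(seed)
        obs = observe_heterokaryon(het, spec, name, n=150, rng=rng)
        assert sum(not d.self_fertile for d in obs.derivatives) >= 10
        call = infer_heterokaryon_genotype(obs, spec)
        expected = {(g, m) for g, m, _ in comps}
        assert {(c.genotype, c.mat) for c in call.nuclei} == expected
        assert not any("not excluded" in f for f in call.flags)

    def test_classifier_never_calls_a_viable_df_homokaryon(self):
        # across all round-trip calls, Df nuclei only ever appear as
        # heterokaryon components, never as the type of a viable derivative
        spec = get_preset("EB4")
        het = make_heterokaryon(spec, (("Dp", "a", 1.0), ("Df", "A", 1.0)))
        rng = np.random.default_rng(8)
        obs = observe_heterokaryon(het, spec, "dpdf", n=80, rng=rng)
        # viable self-sterile derivatives never carry the bare-Df pattern
        bare_df = [
            d for d in obs.derivatives
            if not d.self_fertile and d.junctions == frozenset({"A"})
        ]
        assert bare_df == []


class TestTableAggregation:
    def test_packaged_table_parses_fully(self):
        df = load_table2()
        assert len(df) == 47
        assert list(df["serial"]) == list(range(1, 48))

    def test_dp_df_b362i_rows_total_117_all_self_sterile(self):
        df = load_table2()
        mask = (df["rearrangement"] == "B362i") & (
            df["genotype"] == "[Dp a + Df A]"
        )
        summary = summarize_observation_table(df, mask)
        assert summary.n_strains == 7
        assert summary.total_derivatives == 117
        assert summary.total_self_sterile == 117
        assert summary.all_self_sterile
        assert summary.fraction_self_fertile == 0.0

    def test_single_row_totals_equal_the_row(self):
        df = load_table2()
        summary = summarize_observation_table(df, df["strain"] == "6E1")
        assert (
            summary.total_derivatives,
            summary.total_self_sterile,
            summary.total_mat_a,
            summary.total_mat_A,
        ) == (129, 30, 10, 20)

    def test_empty_filter_gives_zeros(self):
        df = load_table2()
        summary = summarize_observation_table(df, df["strain"] == "nope")
        assert summary.n_strains == 0
        assert summary.total_derivatives == 0

    def test_malformed_row_raises_with_strain_id(self):
        df = pd.DataFrame(
            [{"strain": "bad1", "n_conidial_derivatives": 5,
              "n_self_sterile": 9, "n_mat_a": 0, "n_mat_A": 0}]
        )
        with pytest.raises(ObservationError, match="bad1"):
            summarize_observation_table(df)
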