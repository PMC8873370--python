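"""PRR, chi-square, signal rule, shares and the screening/OC harness."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from advesig.disproportionality import (
    ContingencyTable,
    SignalRule,
    build_contingency,
    chi2_is_degenerate,
    compute_chi2,
    compute_prr,
    evaluate_signal,
    operating_characteristics,
    prr_fraction,
    prr_screen,
    reaction_share,
)
from advesig.errors import ConfigError, DataError, DegenerateTableError
from advesig.synthetic_data import expected_prr, recovery_config, simulate_line_listing

from conftest import make_listing

cells = st.integers(min_value=0, max_value=500)
tables = st.builds(ContingencyTable, a=cells, b=cells, c=cells, d=cells)


def prr_by_enumeration(df, drug, reaction, class_drugs):
    """Independent oracle: row-by-row recount and exact rational arithmetic."""
    a = b = c = d = 0
    class_norm = {x.casefold() for x in class_drugs}
    for row in df.itertuples():
        dr, rc = row.drug.casefold(), row.reaction_pt.casefold()
        if dr not in class_norm:
            continue
        if dr == drug.casefold():
            if rc == reaction.casefold():
                a += 1
            else:
                c += 1
        else:
            if rc == reaction.casefold():
                b += 1
            else:
                d += 1
    return (a, b, c, d), Fraction(a * (b + d), b * (a + c)) if b and a + c else None


class TestComputePRR:
    def test_equal_proportions_give_exactly_one(self):
        assert compute_prr(ContingencyTable(5, 10, 45, 90)) == 1.0

    def test_hand_arithmetic(self):
        # 0.10 vs 0.05
        assert compute_prr(ContingencyTable(10, 10, 90, 190)) == pytest.approx(2.0)

    def test_printed_count_worked_example(self):
        # blood-count shares worked example: 286/623 vs 327/4557
        table = ContingencyTable(a=286, b=327, c=337, d=4230)
        assert compute_prr(table) == pytest.approx(6.40, abs=0.01)

    def test_strict_zero_policy_raises(self):
        with pytest.raises(DegenerateTableError):
            compute_prr(ContingencyTable(3, 0, 7, 10), zero_policy="strict")

    def test_haldane_zero_policy(self):
        t = ContingencyTable(3, 0, 7, 10)
        expected = (3.5 / 11.0) / (0.5 / 11.0)
        assert compute_prr(t, zero_policy="haldane") == pytest.approx(expected)

    def test_empty_arm_always_raises(self):
        with pytest.raises(DegenerateTableError):
            compute_prr(ContingencyTable(0, 5, 0, 10))
        with pytest.raises(DegenerateTableError):
            compute_prr(ContingencyTable(5, 0, 10, 0), zero_policy="haldane")

    def test_negative_cells_rejected(self):
        with pytest.raises(DataError):
            ContingencyTable(-1, 2, 3, 4)

    @given(tables, st.integers(min_value=1, max_value=7), st.integers(min_value=1, max_value=7))
    @settings(max_examples=200, deadline=None)
    def test_arm_scaling_invariance(self, t, k1, k2):
        if t.a + t.c == 0 or t.b == 0:
            return
        base = prr_fraction(t)
        scaled = ContingencyTable(t.a * k1, t.b * k2, t.c * k1, t.d * k2)
        assert prr_fraction(scaled) == base

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_arm_swap_reciprocal(self, t):
        if t.a == 0 or t.b == 0 or t.c + t.a == 0 or t.d + t.b == 0:
            return
        swapped = ContingencyTable(t.b, t.a, t.d, t.c)
        assert prr_fraction(t) * prr_fraction(swapped) == 1


class TestComputeChi2:
    def test_exact_independence_is_zero(self):
        assert compute_chi2(ContingencyTable(10, 20, 90, 180)) == 0.0

    def test_formula_oracle(self):
        t = ContingencyTable(30, 10, 70, 190)
        n = 300
        expected = n * (30 * 190 - 10 * 70) ** 2 / (40 * 260 * 100 * 200)
        assert compute_chi2(t, yates=False) == pytest.approx(expected)

    @given(tables)
    @settings(max_examples=200, deadline=None)
    def test_matches_scipy(self, t):
        if chi2_is_degenerate(t):
            assert compute_chi2(t) == 0.0
            return
        obs = [[t.a, t.b], [t.c, t.d]]
        for yates in (False, True):
            ref = chi2_contingency(obs, correction=yates)[0]
            assert compute_chi2(t, yates=yates) == pytest.approx(ref, rel=1e-10, abs=1e-10)

    @given(tables)
    @settings(max_examples=100, deadline=None)
    def test_yates_never_exceeds_uncorrected(self, t):
        assert compute_chi2(t, yates=True) <= compute_chi2(t, yates=False) + 1e-12

    def test_zero_margin_degenerate(self):
        assert compute_chi2(ContingencyTable(0, 0, 10, 20)) == 0.0


class TestEvaluateSignal:
    def test_all_criteria_met(self):
        assert evaluate_signal(2.5, 5, 5.0) == (True, ())

    def test_min_cases_blocks(self):
        ok, reasons = evaluate_signal(3.0, 2, 6.0)
        assert not ok and reasons == ("min_cases",)

    def test_prr_unity_never_signals(self):
        ok, reasons = evaluate_signal(1.0, 100, 50.0)
        assert not ok and "prr_unity" in reasons

    def test_exact_unity_on_fractions(self):
        ok, reasons = evaluate_signal(Fraction(1, 1), 100, 50.0, SignalRule(prr_min=0.5))
        assert not ok and reasons == ("prr_unity",)

    def test_all_reasons_reported(self):
        ok, reasons = evaluate_signal(1.5, 1, 2.0)
        assert not ok and set(reasons) == {"prr_min", "min_cases", "chi2_min"}

    @given(
        st.floats(min_value=0, max_value=50, allow_nan=False),
        st.integers(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100, allow_nan=False),
        st.floats(min_value=0, max_value=5),
        st.integers(min_value=0, max_value=10),
        st.floats(min_value=0, max_value=10),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_away_from_unity(self, prr, n, chi2, dprr, dn, dchi2):
        # increasing any input never turns a signal off (unity exclusion aside)
        if prr <= 1 < prr + dprr or prr + dprr == 1 or prr == 1:
            return
        before, _ = evaluate_signal(prr, n, chi2)
        after, _ = evaluate_signal(prr + dprr, n + dn, chi2 + dchi2)
        assert after or not before

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DataError):
            evaluate_signal(float("nan"), 3, 4.0)
        with pytest.raises(ConfigError):
            SignalRule(prr_min=-1)


class TestReactionShare:
    @pytest.mark.parametrize(
        "count,total,ndigits,expected",
        [
            (286, 623, 1, 45.9),
            (21, 623, 2, 3.37),
            (9, 623, 1, 1.4),
            (6, 623, 2, 0.96),
            (128, 1122, 1, 11.4),
            (10, 1122, 2, 0.89),
            (258, 3435, 1, 7.5),
            (32, 3435, 2, 0.93),
            (0, 623, 1, 0.0),
        ],
    )
    def test_published_share_values(self, count, total, ndigits, expected):
        assert reaction_share(count, total, ndigits=ndigits) == expected

    def test_round_half_even(self):
        assert reaction_share(125, 1000, ndigits=1) == 12.5
        assert reaction_share(1250, 100000, ndigits=2) == 1.25
        # 0.125 -> 12.5 -> at 0 digits banker's rounding gives 12
        assert reaction_share(125, 1000, ndigits=0) == 12.0

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            reaction_share(1, 0)
        with pytest.raises(DataError):
            reaction_share(5, 4)


class TestBuildContingency:
    def test_fixture_by_construction(self, listing_two_drugs):
        t = build_contingency(listing_two_drugs, "A", "R", ["A", "B"])
        assert (t.a, t.b, t.c, t.d) == (2, 1, 3, 4)
        assert t.n == len(listing_two_drugs)

    def test_drug_not_in_class(self, listing_two_drugs):
        with pytest.raises(ConfigError):
            build_contingency(listing_two_drugs, "C", "R", ["A", "B"])
        with pytest.raises(ConfigError):
            build_contingency(listing_two_drugs, "A", "R", ["A"])

    def test_comparator_absent_from_data(self, listing_two_drugs):
        t = build_contingency(listing_two_drugs, "A", "R", ["A", "Z"])
        assert t.b == t.d == 0  # surfaced downstream by compute_prr
        with pytest.raises(DegenerateTableError):
            compute_prr(t)

    def test_matches_enumeration_on_random_listings(self):
        rng = np.random.default_rng(0)
        drugs = ["a", "b", "c"]
        pts = ["r1", "r2", "r3", "r4"]
        for _ in range(20):
            rows = [
                {"drug": rng.choice(drugs), "reaction_pt": rng.choice(pts)}
                for _ in range(rng.integers(10, 60))
            ]
            df = make_listing(rows)
            t = build_contingency(df, "a", "r1", drugs)
            (a, b, c, d), _ = prr_by_enumeration(df, "a", "r1", drugs)
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)


class TestPRRScreen:
    def test_single_reaction_all_unity(self):
        df = make_listing(
            [{"drug": d, "reaction_pt": "R"} for d in ("a", "a", "b", "b", "b")]
        )
        screen = prr_screen(df, ["a", "b"])
        assert (screen["prr"] == 1.0).all()
        assert not screen["signal"].any()
        assert (screen["reasons"].str.contains("prr_unity")).all()

    def test_compositional_equality_with_unit_ops(self, listing_two_drugs):
        screen = prr_screen(listing_two_drugs, ["A", "B"], rule=SignalRule())
        row = screen[(screen["drug"] == "A") & (screen["reaction"] == "r")].iloc[0]
        t = build_contingency(listing_two_drugs, "A", "R", ["A", "B"])
        assert row["prr"] == pytest.approx(compute_prr(t))
        assert row["chi2"] == pytest.approx(compute_chi2(t))
        assert row["n_cases"] == t.a

    def test_sorted_by_drug_then_descending_prr(self, small_pv_config):
        listing = simulate_line_listing(small_pv_config)
        screen = prr_screen(listing, ["A", "B"])
        for _, grp in screen.groupby("drug"):
            vals = grp["prr"].dropna().tolist()
            assert vals == sorted(vals, reverse=True)

    def test_injected_signal_flagged(self):
        cfg = recovery_config(multiplier=5.0, reports_per_drug=5000, seed=21)
        listing = simulate_line_listing(cfg)
        screen = prr_screen(listing, cfg.drugs, zero_policy="haldane")
        flagged = screen[screen["signal"]]
        assert set(zip(flagged["drug"], flagged["reaction"])) == {("drug_a", "reaction_01")}

    def test_degenerate_cells_flagged_not_fatal(self):
        df = make_listing(
            [{"drug": "a", "reaction_pt": "R"}] * 3 + [{"drug": "b", "reaction_pt": "other"}] * 3
        )
        screen = prr_screen(df, ["a", "b"], zero_policy="strict")
        row = screen[(screen["drug"] == "a") & (screen["reaction"] == "r")].iloc[0]
        assert math.isnan(row["prr"]) and not row["signal"]
        assert "prr_undefined" in row["notes"]

    def test_soc_level_screen(self, small_pv_config):
        listing = simulate_line_listing(small_pv_config)
        screen = prr_screen(listing, ["A", "B"], level="soc")
        assert set(screen["reaction"]) == {"soc1", "soc2"}


class TestOperatingCharacteristics:
    def test_null_configuration_false_positive_rate(self):
        cfg = recovery_config(multiplier=1.0, reports_per_drug=2000, seed=0)
        oc = operating_characteristics(cfg, n_replicates=20, seed=5)
        assert math.isnan(oc.power)  # no true signal pairs
        assert oc.false_positive_rate < 0.5
        assert oc.false_positive_rate_se < 0.1

    def test_power_near_one_at_large_effect(self):
        cfg = recovery_config(multiplier=5.0, baseline=0.05, reports_per_drug=5000)
        oc = operating_characteristics(cfg, n_replicates=25, seed=9)
        assert oc.power > 0.95
        assert oc.false_positive_rate < 0.05

    def test_mean_prr_tracks_analytic_oracle(self):
        cfg = recovery_config(multiplier=3.0, baseline=0.1, reports_per_drug=5000)
        oc = operating_characteristics(cfg, n_replicates=30, seed=13)
        row = oc.pairs[(oc.pairs["drug"] == "drug_a") & (oc.pairs["reaction"] == "reaction_01")]
        row = row.iloc[0]
        truth = expected_prr(cfg, "drug_a", "reaction_01")
        assert row["expected_prr"] == pytest.approx(truth)
        assert abs(row["mean_prr"] - truth) < 3 * row["se_prr"] + 0.01 * truth

    def test_deterministic_given_seed(self):
        cfg = recovery_config(multiplier=2.0, reports_per_drug=500)
        a = operating_characteristics(cfg, n_replicates=5, seed=3)
        b = operating_characteristics(cfg, n_replicates=5, seed=3)
        assert a.pairs.to_csv() == b.pairs.to_csv()

    def test_replicate_count_validated(self):
        cfg = recovery_config(reports_per_drug=100)
        with pytest.raises(ConfigError):
            operating_characteristics(cfg, n_replicates=0)
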