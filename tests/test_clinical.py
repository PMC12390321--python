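import numpy as np
import pandas as pd
import pytest

from neoim import simulate as sim
from neoim.clinical import (
    LogrankResult,
    MutationContext,
    enumerate_covering_peptides,
    hitrate_paired_z,
    km_logrank,
    median_split,
    patient_maxmean_table,
    stratified_survival_analysis,
    tumor_maxmean,
)


def make_context(window, span, mutation_id="m1"):
    return MutationContext(
        patient_id="p1", mutation_id=mutation_id,
        mutant_protein_window=window, mutated_span=span,
    )


def brute_force_windows(window, span):
    """Oracle: enumerate every 9-11 window overlapping the span."""
    out = []
    for L in (9, 10, 11):
        for s in range(len(window) - L + 1):
            if s + 1 <= span[1] and s + L >= span[0]:
                out.append(window[s : s + L])
    seen, unique = set(), []
    for p in out:
        if p not in seen:
            seen.add(p)
            unique.append(p)
    return unique


class TestEnumeration:
    def test_interior_substitution_gives_30_windows(self, rng):
        window = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 25))
        ctx = make_context(window, (13, 13))  # >=10 flanks each side
        peptides = enumerate_covering_peptides(ctx)
        assert len(peptides) == 9 + 10 + 11 == 30
        assert all(window[12] in p for p in peptides)

    def test_mutation_at_protein_start_gives_3_windows(self):
        window = "MKTAYIAKQRQISFV"
        peptides = enumerate_covering_peptides(make_context(window, (1, 1)))
        assert peptides == [window[:9], window[:10], window[:11]]

    def test_multi_residue_span_matches_brute_force(self, rng):
        window = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 30))
        span = (12, 14)
        ctx = make_context(window, span)
        assert enumerate_covering_peptides(ctx) == brute_force_windows(window, span)

    def test_short_window_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert enumerate_covering_peptides(make_context("ACDEFGH", (3, 3))) == []

    def test_span_outside_window_rejected(self):
        with pytest.raises(ValueError, match="span"):
            make_context("ACDEFGHIK", (5, 12))


class TestMaxMean:
    def test_mean_then_max(self):
        ctx1 = make_context("A" * 21, (11, 11), "m1")
        ctx2 = make_context("C" * 21, (11, 11), "m2")
        table = {"A": 0.3, "C": 0.5}

        def scorer(peptides):
            return np.array([table[p[0]] for p in peptides])

        assert tumor_maxmean([ctx1], scorer) == pytest.approx(0.3)
        assert tumor_maxmean([ctx1, ctx2], scorer) == pytest.approx(0.5)

    def test_mixed_scores_average_within_mutation(self):
        # a 10-residue window with the mutation at position 1 yields
        # exactly two covering peptides (one 9-mer, one 10-mer)
        ctx = make_context("MKTAYIAKQR", (1, 1))
        assert len(enumerate_covering_peptides(ctx)) == 2

        def scorer(peptides):
            return np.array([0.2, 0.4])

        assert tumor_maxmean([ctx], scorer) == pytest.approx(0.3)

    def test_adding_mutations_never_decreases(self, rng):
        contexts = [
            make_context("".join(rng.choice(list("ACDEFGHIK"), 25)), (13, 13), f"m{i}")
            for i in range(4)
        ]

        def scorer(peptides):
            return np.array([sum(map(ord, p)) % 100 / 100 for p in peptides])

        values = [tumor_maxmean(contexts[: i + 1], scorer) for i in range(4)]
        assert all(b >= a for a, b in zip(values, values[1:]))
        # invariant to mutation order
        assert tumor_maxmean(contexts[::-1], scorer) == values[-1]

    def test_no_scorable_peptides_rejected(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no scorable"):
                tumor_maxmean([make_context("ACDEFGH", (3, 3))], lambda p: np.ones(len(p)))

    def test_patient_table(self):
        mutations = sim.make_mutation_table(seed=4, n_patients=3)
        out = patient_maxmean_table(mutations, lambda p: np.full(len(p), 0.42))
        assert list(out.columns) == ["patient_id", "maxmean_score"]
        assert len(out) == 3
        np.testing.assert_allclose(out["maxmean_score"], 0.42)


class TestMedianSplit:
    def test_even_distinct_values(self):
        records = pd.DataFrame({"b": np.arange(1, 11, dtype=float)})
        high, low = median_split(records, "b")
        assert sorted(low["b"]) == list(range(1, 6))
        assert sorted(high["b"]) == list(range(6, 11))

    def test_odd_n_median_lands_low(self):
        records = pd.DataFrame({"b": [1.0, 2.0, 3.0, 4.0, 5.0]})
        high, low = median_split(records, "b")
        assert len(low) == 3 and len(high) == 2
        assert 3.0 in low["b"].to_numpy()

    def test_ties_at_median_go_low(self):
        records = pd.DataFrame({"b": [1.0, 2.0, 2.0, 2.0, 5.0, 6.0]})
        high, low = median_split(records, "b")
        assert (low["b"] <= 2.0).all() and len(low) == 4

    def test_partition_is_complete(self, rng):
        records = pd.DataFrame({"b": rng.random(17)})
        high, low = median_split(records, "b")
        assert len(high) + len(low) == 17
        assert low["b"].max() <= high["b"].min()

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split(pd.DataFrame({"b": [2.0, 2.0, 2.0]}), "b")


def hand_logrank(times_a, events_a, times_b, events_b):
    """Oracle: observed-minus-expected over the pooled event times."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.array([0] * len(times_a) + [1] * len(times_b))
    O_minus_E, V = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (group == 0)).sum()
        O_minus_E += d_a - d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestKMLogrank:
    def test_identical_groups_null(self):
        g = pd.DataFrame({"os_days": [10, 20, 30, 40], "event": [1, 0, 1, 1]})
        res = km_logrank(g, g.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_patient_example_matches_hand_tables(self):
        ta, ea = np.array([5.0, 10.0, 25.0]), np.array([1, 1, 0])
        tb, eb = np.array([15.0, 30.0, 35.0]), np.array([1, 1, 1])
        res = km_logrank(
            pd.DataFrame({"os_days": ta, "event": ea}),
            pd.DataFrame({"os_days": tb, "event": eb}),
        )
        assert res.statistic == pytest.approx(hand_logrank(ta, ea, tb, eb), rel=1e-6)

    def test_statistic_symmetric_in_group_labels(self, rng):
        a = pd.DataFrame({"os_days": rng.exponential(100, 20), "event": rng.integers(0, 2, 20)})
        b = pd.DataFrame({"os_days": rng.exponential(50, 20), "event": np.ones(20, int)})
        assert km_logrank(a, b).statistic == pytest.approx(km_logrank(b, a).statistic)

    def test_km_curve_shape(self, rng):
        a = pd.DataFrame({"os_days": rng.exponential(100, 30), "event": np.ones(30, int)})
        b = pd.DataFrame({"os_days": rng.exponential(100, 30), "event": np.ones(30, int)})
        res = km_logrank(a, b)
        for curve in (res.km_a, res.km_b):
            assert curve["survival"].iloc[0] == pytest.approx(1.0)
            assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_zero_events_rejected(self):
        g = pd.DataFrame({"os_days": [10.0, 20.0], "event": [0, 0]})
        with pytest.raises(ValueError, match="events"):
            km_logrank(g, g.copy())

    def test_stratified_analysis_splits_by_burden(self):
        cohort = sim.make_survival_cohort(sim.FixtureSpec(seed=6, n_patients=80))
        out = stratified_survival_analysis(cohort, "maxmean_score", mutation_threshold=100)
        assert set(out) <= {"low_burden", "high_burden"}
        for res in out.values():
            assert isinstance(res, LogrankResult)
            assert 0 <= res.p_value <= 1


def designs_from_rates(rates_a, rates_b, n_epitopes=10):
    rows = []
    for method, rates in (("original", rates_a), ("neoim", rates_b)):
        for i, r in enumerate(rates):
            hits = int(round(r * n_epitopes))
            for j in range(n_epitopes):
                rows.append(
                    {"patient_id": f"P{i}", "epitope": f"E{j}",
                     "responded": int(j < hits), "method": method}
                )
    df = pd.DataFrame(rows)
    return df[df.method == "original"], df[df.method == "neoim"]


class TestPairedZ:
    def test_identical_designs_null(self):
        a, b = designs_from_rates([0.4, 0.6, 0.2], [0.4, 0.6, 0.2])
        res = hitrate_paired_z(a, b)
        assert res.z == 0.0 and res.p_value == 1.0

    def test_hand_worked_differences(self):
        # d = (0.2, 0.1, 0.3, 0.0, 0.4): mean 0.2, sample sd 0.15811
        a, b = designs_from_rates(
            [0.1, 0.2, 0.1, 0.3, 0.1], [0.3, 0.3, 0.4, 0.3, 0.5]
        )
        res = hitrate_paired_z(a, b)
        assert res.mean_difference == pytest.approx(0.2)
        assert res.z == pytest.approx(0.2 / (0.15811388 / np.sqrt(5)), rel=1e-6)
        assert res.p_value == pytest.approx(0.004678, abs=1e-5)

    def test_constant_nonzero_differences_degenerate(self):
        a, b = designs_from_rates([0.1, 0.2, 0.3], [0.3, 0.4, 0.5])
        with pytest.raises(ValueError, match="degenerate"):
            hitrate_paired_z(a, b)

    def test_mismatched_patient_sets_rejected(self):
        a, _ = designs_from_rates([0.1, 0.2], [0.1, 0.2])
        _, b = designs_from_rates([0.1, 0.2, 0.3], [0.3, 0.4, 0.2])
        with pytest.raises(ValueError, match="patient"):
            hitrate_paired_z(a, b)

    def test_single_patient_rejected(self):
        a, b = designs_from_rates([0.1], [0.5])
        with pytest.raises(ValueError, match="2 patients"):
            hitrate_paired_z(a, b)
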