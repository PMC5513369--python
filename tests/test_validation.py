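from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from phenokit.concepts import Disease
from phenokit.records import GoldLabel, Mechanism, ProblemType
from phenokit.validation import (
    ErrorCase,
    TwoByTwo,
    ValidationError,
    check_mechanism_consistency,
    cohen_kappa,
    confusion_matrix,
    error_taxonomy,
    extract_error_cases,
    interrater_agreement,
    mechanism_table,
    operating_characteristics,
    percent,
    problem_type_table,
    proportion_ci,
    sensitivity,
    specificity,
)

from test_phenotyper import call


class TestPercent:
    @pytest.mark.parametrize(
        "count,total,expected",
        [(20, 98, 20.41), (43, 66, 65.15), (0, 7, 0.0), (9, 32, 28.13),
         (1, 32, 3.13), (164, 1106, 14.83)],
    )
    def test_round_half_up_to_two_decimals(self, count, total, expected):
        assert percent(count, total) == expected

    def test_half_way_rounds_up_not_to_even(self):
        assert percent(1, 8) == 12.5
        assert percent(9, 32) == 28.13  # 28.125 -> up, not banker's 28.12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            percent(1, 0)
        with pytest.raises(ValidationError):
            percent(5, 4)


def wilson_oracle(k, n, level=0.95):
    """Hand-rolled Wilson score interval, independent of the implementation."""
    z = sps.norm.ppf(0.5 + level / 2)
    p = k / n
    center = (k + z * z / 2) / (n + z * z)
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
    return max(0.0, center - half), min(1.0, center + half)


def clopper_pearson_oracle(k, n, level=0.95):
    alpha = 1 - level
    lo = 0.0 if k == 0 else sps.beta.ppf(alpha / 2, k, n - k + 1)
    hi = 1.0 if k == n else sps.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return lo, hi


def normal_oracle(k, n, level=0.95):
    z = sps.norm.ppf(0.5 + level / 2)
    p = k / n
    h = z * np.sqrt(p * (1 - p) / n)
    return max(0.0, p - h), min(1.0, p + h)


class TestProportionCI:
    def test_clopper_pearson_boundaries_are_exact(self):
        assert proportion_ci(10, 10, 0.95, "clopper_pearson")[1] == 1.0
        assert proportion_ci(0, 10, 0.95, "clopper_pearson")[0] == 0.0

    @pytest.mark.parametrize("method,oracle", [
        ("wilson", wilson_oracle),
        ("clopper_pearson", clopper_pearson_oracle),
        ("normal", normal_oracle),
    ])
    def test_matches_independent_oracle_on_random_tables(self, method, oracle):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = int(rng.integers(1, 2000))
            k = int(rng.integers(0, n + 1))
            got = proportion_ci(k, n, 0.95, method)
            want = oracle(k, n)
            assert got == pytest.approx(want, abs=1e-9)

    def test_widening_level_never_narrows_interval(self):
        for method in ("wilson", "clopper_pearson", "normal"):
            lo90, hi90 = proportion_ci(30, 80, 0.90, method)
            lo99, hi99 = proportion_ci(30, 80, 0.99, method)
            assert lo99 <= lo90 and hi99 >= hi90

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            proportion_ci(5, 4)
        with pytest.raises(ValidationError):
            proportion_ci(1, 10, level=1.5)
        with pytest.raises(ValidationError):
            proportion_ci(1, 10, method="bootstrap")


class TestSensitivitySpecificity:
    def test_point_estimates(self):
        assert sensitivity(TwoByTwo(tp=5, fp=0, fn=0, tn=0)).value == 1.0
        assert sensitivity(TwoByTwo(tp=8, fp=0, fn=2, tn=0)).value == 0.8
        assert specificity(TwoByTwo(tp=0, fp=0, fn=0, tn=5)).value == 1.0
        assert specificity(TwoByTwo(tp=0, fp=1, fn=0, tn=3)).value == 0.75

    def test_wilson_ci_matches_oracle(self):
        est = sensitivity(TwoByTwo(tp=449, fp=0, fn=21, tn=0))
        assert est.value == pytest.approx(449 / 470)
        assert (est.ci_low, est.ci_high) == pytest.approx(wilson_oracle(449, 470), abs=1e-9)

    def test_zero_denominator_flagged_undefined(self):
        est = sensitivity(TwoByTwo(tp=0, fp=3, fn=0, tn=7))
        assert not est.defined and est.value is None

    def test_estimate_inside_its_ci(self):
        for tp, fn in [(1, 9), (50, 50), (99, 1)]:
            est = sensitivity(TwoByTwo(tp=tp, fp=0, fn=fn, tn=0))
            assert est.ci_low <= est.value <= est.ci_high


def kappa_brute_force(table):
    """First-principles p_o / p_e recomputation."""
    t = np.asarray(table, float)
    n = t.sum()
    p_o = np.trace(t) / n
    p_e = sum(t[i, :].sum() * t[:, i].sum() for i in range(t.shape[0])) / n**2
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_perfect_agreement_is_exactly_one(self):
        assert cohen_kappa([[50, 0], [0, 50]]).value == 1.0

    def test_agreement_equal_to_chance_is_zero(self):
        assert cohen_kappa([[25, 25], [25, 25]]).value == pytest.approx(0.0, abs=1e-12)

    def test_value_matches_brute_force_oracle(self):
        table = [[40, 10], [5, 45]]
        assert cohen_kappa(table).value == pytest.approx(kappa_brute_force(table), abs=1e-12)

    def test_matches_independent_implementation_on_random_tables(self):
        from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

        rng = np.random.default_rng(777)
        z = sps.norm.ppf(0.975)
        checked = 0
        while checked < 100:
            t = rng.integers(0, 200, size=(2, 2)).astype(float)
            if t.sum() == 0:
                continue
            mine = cohen_kappa(t)
            if not mine.defined:
                continue
            ref = sm_kappa(t, return_results=True)
            assert mine.value == pytest.approx(ref.kappa, abs=1e-9)
            if -1 < mine.ci_low and mine.ci_high < 1:  # unclipped
                assert (mine.value - mine.ci_low) / z == pytest.approx(
                    np.sqrt(ref.var_kappa), abs=1e-9
                )
            checked += 1

    def test_kappa_never_exceeds_observed_agreement(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(1, 100, size=(2, 2))
            est = cohen_kappa(t)
            p_o = np.trace(t) / t.sum()
            assert est.value <= p_o + 1e-12

    def test_symmetric_under_rater_swap(self):
        t = np.array([[40, 10], [5, 45]])
        assert cohen_kappa(t).value == pytest.approx(cohen_kappa(t.T).value, abs=1e-12)

    def test_kappa_is_one_iff_off_diagonal_zero(self):
        assert cohen_kappa([[3, 0], [0, 97]]).value == 1.0
        assert cohen_kappa([[3, 1], [0, 96]]).value < 1.0

    def test_degenerate_marginals_flagged(self):
        est = cohen_kappa([[10, 0], [0, 0]])
        assert not est.defined


def gold(pid, disease, truth, mech=Mechanism.NONE, pt=ProblemType.NONE):
    return GoldLabel(patient_id=pid, disease=disease, truth=truth,
                     mechanism=mech, problem_type=pt)


class TestInterrater:
    def test_identical_labels_give_kappa_one(self):
        a = [gold(f"p{i}", Disease.CAVD, i % 3 == 0) for i in range(50)]
        assert interrater_agreement(a, list(a)).value == 1.0

    def test_independent_reviewers_give_kappa_near_zero(self):
        rng = np.random.default_rng(99)
        pids = [f"p{i}" for i in range(4000)]
        a = [gold(p, Disease.CAVD, bool(rng.random() < 0.5)) for p in pids]
        b = [gold(p, Disease.CAVD, bool(rng.random() < 0.5)) for p in pids]
        est = interrater_agreement(a, b)
        # independence by construction: kappa ~ 0 within Monte-Carlo error
        assert abs(est.value) < 3 / np.sqrt(4000)

    def test_disjoint_record_sets_rejected(self):
        a = [gold("p1", Disease.CAVD, True)]
        b = [gold("p2", Disease.CAVD, True)]
        with pytest.raises(ValidationError, match="different records"):
            interrater_agreement(a, b)


class TestConfusionMatrix:
    def test_perfect_agreement_has_no_errors(self):
        calls = [call(f"p{i}", Disease.CAVD, i < 8) for i in range(20)]
        labels = [gold(f"p{i}", Disease.CAVD, i < 8) for i in range(20)]
        t = confusion_matrix(calls, labels, Disease.CAVD)
        assert (t.fp, t.fn) == (0, 0) and t.n == 20

    def test_single_missed_case_counts_as_fn(self):
        calls = [call("p1", Disease.CAVD, False)]
        labels = [gold("p1", Disease.CAVD, True)]
        t = confusion_matrix(calls, labels, Disease.CAVD)
        assert (t.tp, t.fp, t.fn, t.tn) == (0, 0, 1, 0)

    def test_missing_gold_label_rejected_with_ids(self):
        calls = [call("p1", Disease.CAVD, True)]
        with pytest.raises(ValidationError, match="p1"):
            confusion_matrix(calls, [], Disease.CAVD)

    def test_combined_outcome_matches_brute_force_enumeration(self):
        """All 16 (call, gold) x (CaVD, CeVD) combinations, one patient each."""
        calls, labels, expected = [], [], {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for i, (ca_call, ca_gold, ce_call, ce_gold) in enumerate(
            itertools.product([False, True], repeat=4)
        ):
            pid = f"p{i}"
            calls += [call(pid, Disease.CAVD, ca_call), call(pid, Disease.CEVD, ce_call)]
            labels += [gold(pid, Disease.CAVD, ca_gold), gold(pid, Disease.CEVD, ce_gold)]
            test, truth = ca_call or ce_call, ca_gold or ce_gold  # oracle rule
            expected["tp" if test and truth else
                     "fp" if test else
                     "fn" if truth else "tn"] += 1
        t = confusion_matrix(calls, labels, "combined")
        assert t.as_dict() == expected

    def test_cavd_fp_but_cevd_tp_is_combined_tp(self):
        calls = [call("p", Disease.CAVD, True), call("p", Disease.CEVD, True)]
        labels = [gold("p", Disease.CAVD, False), gold("p", Disease.CEVD, True)]
        t = confusion_matrix(calls, labels, "combined")
        assert (t.tp, t.fp) == (1, 0)

    def test_cells_sum_to_matched_patients(self):
        rng = np.random.default_rng(5)
        calls, labels = [], []
        for i in range(100):
            for d in Disease:
                calls.append(call(f"p{i}", d, bool(rng.random() < 0.3)))
                labels.append(gold(f"p{i}", d, bool(rng.random() < 0.3)))
        for scope in (Disease.CAVD, Disease.CEVD, "combined"):
            assert confusion_matrix(calls, labels, scope).n == 100


class TestErrorTaxonomy:
    def test_no_discordance_gives_empty_tables(self):
        calls = [call("p1", Disease.CAVD, True)]
        labels = [gold("p1", Disease.CAVD, True)]
        cases, mech, pt = error_taxonomy(calls, labels)
        assert cases == [] and mech.empty and pt.empty

    def test_unannotated_discordance_surfaces_explicitly(self):
        calls = [call("p1", Disease.CAVD, True)]
        labels = [gold("p1", Disease.CAVD, False)]  # no mechanism annotation
        cases, mech, _ = error_taxonomy(calls, labels)
        assert len(cases) == 1
        assert mech.iloc[0]["category"] == "unannotated"

    def test_planted_mechanisms_recovered_per_kind(self):
        calls = [call("p1", Disease.CAVD, True), call("p2", Disease.CEVD, False)]
        labels = [
            gold("p1", Disease.CAVD, False, Mechanism.DISMISSED_DIAGNOSIS, ProblemType.MI),
            gold("p2", Disease.CEVD, True, Mechanism.FREETEXT_ONLY, ProblemType.STROKE),
        ]
        cases, mech, pt = error_taxonomy(calls, labels)
        kinds = {(c.kind, c.mechanism) for c in cases}
        assert kinds == {("FP", Mechanism.DISMISSED_DIAGNOSIS),
                         ("FN", Mechanism.FREETEXT_ONLY)}
        assert check_mechanism_consistency(cases) == []
        assert set(pt["problem_type"]) == {"MI", "stroke"}

    def test_counts_reconcile_across_table_margins(self):
        rng = np.random.default_rng(11)
        mechs_fp = list({m for m in Mechanism if m.value.startswith(("dis", "inc", "cod"))})
        cases = []
        for i in range(60):
            kind = "FP" if rng.random() < 0.6 else "FN"
            mech = (Mechanism.DISMISSED_DIAGNOSIS if kind == "FP"
                    else Mechanism.CODE_NOT_IN_SET)
            d = Disease.CAVD if rng.random() < 0.5 else Disease.CEVD
            cases.append(ErrorCase(f"p{i}", d, kind, mech, ProblemType.MI))
        mech_df = mechanism_table(cases)
        pt_df = problem_type_table(cases)
        assert mech_df["count"].sum() == len(cases)
        assert pt_df["count"].sum() == len(cases)
        assert pt_df["fn_count"].sum() == sum(1 for c in cases if c.kind == "FN")
        # percent cells equal percent(count, total) exactly
        for _, row in mech_df.iterrows():
            assert row["pct_total_errors"] == percent(int(row["count"]), len(cases))


class TestOperatingCharacteristics:
    def test_bundles_all_three_statistics(self):
        calls = [call(f"p{i}", Disease.CAVD, i < 10) for i in range(30)]
        labels = [gold(f"p{i}", Disease.CAVD, i < 12) for i in range(30)]
        oc = operating_characteristics(calls, labels, Disease.CAVD)
        assert oc.scope == "CaVD"
        assert oc.sensitivity.value == pytest.approx(10 / 12)
        assert oc.specificity.value == pytest.approx(18 / 18)
        assert oc.kappa.value == pytest.approx(
            kappa_brute_force([[10, 2], [0, 18]]), abs=1e-12
        )
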