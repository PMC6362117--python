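"""Survival statistics: stratification, rank correlations, concordance, Cox."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from medh import phantom, survival
from medh.survival import (
    concordance_index,
    dice,
    fit_cox,
    partial_spearman,
    run_association_analysis,
    significance_marker,
    spearman,
    stratify_survival,
)

DAYS = survival.DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def average_ranks(x):
    """Independent average-rank implementation (sort-based, no scipy)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_spearman(x, y):
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_concordance(risk, time, event):
    conc = ties = n = 0
    for i, j in itertools.permutations(range(len(risk)), 2):
        if time[i] < time[j] and event[i]:
            n += 1
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] == risk[j]:
                ties += 1
    return (conc + 0.5 * ties) / n


class TestStratification:
    @pytest.mark.parametrize("months,expected", [
        (6.0, "short"), (7.0, "short"), (7.01, "medium"), (12.0, "medium"),
        (18.0, "medium"), (18.01, "long"), (19.0, "long"),
    ])
    def test_cutoffs(self, months, expected):
        assert stratify_survival(months * DAYS) == expected

    def test_nonpositive_days_rejected(self):
        with pytest.raises(ValueError):
            stratify_survival(0.0)

    def test_marker_convention(self):
        assert significance_marker(0.04) == "**"
        assert significance_marker(0.07) == "*"
        assert significance_marker(0.2) == ""


class TestSpearman:
    def test_perfect_anti_monotone(self):
        r, p = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # ranks are the data themselves; Pearson on ranks = 0.8
        r, _ = spearman([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_tied_data_matches_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(5, 25))
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=n).astype(float) + 0.1 * x
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, _ = spearman(x, y)
            assert r == pytest.approx(brute_spearman(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x), y**3 + 5 * y)
        # y**3+5y is strictly monotone; exp strictly monotone
        assert r2 == pytest.approx(r1, abs=1e-12)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_exact_permutation_p_for_small_n(self):
        # n = 5, perfect correlation: exact two-sided p = 2/5! * 2 = 2*1/120
        r, p = spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_constant_input_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            r, p = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(r) and np.isnan(p)


class TestPartialSpearman:
    def test_constant_confounder_equals_plain(self, rng):
        x = rng.normal(size=20)
        y = 0.5 * x + rng.normal(size=20)
        r_plain, p_plain = spearman(x, y, p_method="asymptotic")
        r_part, p_part = partial_spearman(x, y, np.full((20, 1), 3.0))
        assert r_part == pytest.approx(r_plain, abs=1e-12)

    def test_single_confounder_matches_recursion_formula(self, rng):
        """Residual route equals r_xy.c = (r_xy - r_xc r_yc)/sqrt(...) on ranks."""
        for seed in range(10):
            g = np.random.default_rng(seed)
            n = 25
            c = g.normal(size=n)
            x = 0.6 * c + g.normal(size=n)
            y = -0.4 * c + g.normal(size=n)
            r, _ = partial_spearman(x, y, c)
            rk = stats.rankdata
            r_xy = stats.pearsonr(rk(x), rk(y)).statistic
            r_xc = stats.pearsonr(rk(x), rk(c)).statistic
            r_yc = stats.pearsonr(rk(y), rk(c)).statistic
            expected = (r_xy - r_xc * r_yc) / np.sqrt(
                (1 - r_xc**2) * (1 - r_yc**2))
            assert r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 40
        df = pd.DataFrame({
            "x": rng.normal(size=n), "y": rng.normal(size=n),
            "c1": rng.normal(size=n), "c2": rng.normal(size=n),
        })
        df["y"] += 0.5 * df["c1"]
        r, p = partial_spearman(df["x"], df["y"], df[["c1", "c2"]].to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                                    method="spearman")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_confounder_driven_association_suppressed(self):
        """y monotone in the confounder, x independent: adjustment kills the
        spurious significance (median over 20 seeds)."""
        parts, plains, ps = [], [], []
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = 30
            # y monotone in the confounder (tiny jitter keeps ranks of y from
            # being literally identical to ranks of c, which would leave zero
            # residual variance and an undefined partial correlation)
            c = g.normal(size=n)
            y = np.exp(c) + 0.01 * g.normal(size=n)
            x = g.normal(size=n)
            r_plain, _ = spearman(x, y, p_method="asymptotic")
            r_part, p_part = partial_spearman(x, y, c)
            plains.append(abs(r_plain))
            parts.append(abs(r_part))
            ps.append(p_part)
        assert np.median(ps) > 0.05

    def test_collinear_confounders_rejected(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            partial_spearman(x, y, np.column_stack([c, 2 * c]))


class TestConcordance:
    def test_perfect_reverse_ranking(self, rng):
        t = rng.uniform(10, 1000, size=50)
        assert concordance_index(-t, t) == 1.0

    def test_all_tied_risks_give_half(self, rng):
        t = rng.uniform(10, 1000, size=20)
        assert concordance_index(np.ones(20), t) == 0.5

    def test_hand_enumerated_example(self):
        # survival (10, 20, 30), risks (3, 5, 1): pairs (1,2) disc, (1,3) conc,
        # (2,3) conc -> 2/3
        assert concordance_index([3, 5, 1], [10, 20, 30]) == pytest.approx(2 / 3)

    def test_matches_brute_force_with_censoring(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 30))
            risk = rng.integers(0, 6, size=n).astype(float)
            time = rng.integers(1, 15, size=n).astype(float)
            event = rng.integers(0, 2, size=n).astype(bool)
            if not ((time[:, None] < time[None, :]) & event[:, None]).any():
                continue
            ours = concordance_index(risk, time, event)
            assert ours == pytest.approx(brute_concordance(risk, time, event))

    def test_matches_lifelines(self, rng):
        lifelines_utils = pytest.importorskip("lifelines.utils")
        for _ in range(10):
            n = 40
            risk = rng.normal(size=n)
            time = rng.uniform(1, 100, size=n)
            event = rng.integers(0, 2, size=n)
            if event.sum() == 0:
                continue
            ours = concordance_index(risk, time, event)
            ref = lifelines_utils.concordance_index(time, -risk, event)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_complement_under_risk_negation(self, rng):
        t = rng.uniform(1, 100, size=30)
        risk = rng.normal(size=30)
        ci = concordance_index(risk, t)
        assert ci + concordance_index(-risk, t) == pytest.approx(1.0)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], [5.0, 5.0])


class TestCox:
    def test_perfect_ranking_feature(self, rng):
        t = rng.uniform(10, 1000, size=40)
        coef, risk = fit_cox((-t)[:, None], t)
        assert concordance_index(risk, t) == 1.0

    def test_planted_hazard_sign_recovered(self):
        hits = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            n = 60
            x = g.normal(size=n)
            # higher x -> higher hazard -> shorter survival
            t = g.exponential(scale=np.exp(-x))
            coef, _ = fit_cox(x[:, None], t)
            hits += coef[0] > 0
        assert hits >= 95

    def test_constant_feature_rejected(self, rng):
        t = rng.uniform(1, 100, size=20)
        with pytest.raises(ValueError, match="constant"):
            fit_cox(np.ones((20, 1)), t)


class TestDice:
    def test_identical_masks(self, rng):
        m = rng.integers(0, 2, size=(8, 8, 8)).astype(bool)
        m[0, 0, 0] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[0], b[1] = True, True
        assert dice(a, b) == 0.0

    def test_nested_masks_two_thirds(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[0, 0, :4] = True
        b = a.copy()
        b[0, 1, :4] = True  # |B| = 2|A|, A subset of B
        assert dice(a, b) == pytest.approx(2 / 3)

    def test_both_empty_rejected(self):
        z = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            dice(z, z)


class TestAssociationBattery:
    @pytest.fixture(scope="class")
    def cohort_tables(self):
        cohort = phantom.simulate_cohort(
            phantom.CohortConfig(n_subjects=40, make_images=False, seed=21))
        long = (cohort.truth.true_variance
                .rename_axis("subject_id").reset_index()
                .melt(id_vars="subject_id", var_name="region_id",
                      value_name="medh_mm2"))
        long = long.merge(cohort.atlas.regions, on="region_id")
        return cohort, long

    def test_planted_regions_found_negative_significant(self, cohort_tables):
        cohort, long = cohort_tables
        report = run_association_analysis(long, cohort.records)
        corr = report.correlations
        pl = corr[(corr["group"] == "long+short") & (corr["analysis"] == "plain")]
        planted = cohort.truth.designated_region_ids["right"]
        found = pl[pl["region_id"].isin(planted)]
        assert ((found["r"] < 0) & (found["p"] < 0.05)).mean() >= 5 / 6

    def test_report_mirrors_table_structure(self, cohort_tables):
        cohort, long = cohort_tables
        report = run_association_analysis(long, cohort.records)
        corr = report.correlations
        assert set(corr["analysis"]) == {"plain", "partial"}
        assert set(corr["group"]) <= {"long+short", "medium"}
        assert {"region_name", "hemisphere", "r", "p", "marker",
                "q_bh"} <= set(corr.columns)
        sig = corr[np.isfinite(corr["p"]) & (corr["p"] < 0.05)]
        assert (sig["marker"] == "**").all()
        if len(report.concordance):
            assert report.concordance["ci"].between(0, 1).all()

    def test_multivariate_tends_to_beat_univariate(self):
        """Multivariate Cox over the significant regions usually improves on
        the best single region (training-cohort tendency)."""
        wins = trials = 0
        for seed in (31, 32, 33, 34, 35):
            cohort = phantom.simulate_cohort(
                phantom.CohortConfig(n_subjects=40, make_images=False, seed=seed))
            long = (cohort.truth.true_variance
                    .rename_axis("subject_id").reset_index()
                    .melt(id_vars="subject_id", var_name="region_id",
                          value_name="medh_mm2"))
            long = long.merge(cohort.atlas.regions, on="region_id")
            report = run_association_analysis(long, cohort.records)
            if not len(report.multivariate) or not len(report.concordance):
                continue
            trials += 1
            if (report.multivariate["ci"].iloc[0]
                    >= report.concordance["ci"].max() - 1e-9):
                wins += 1
        assert trials >= 3
        assert wins / trials >= 0.8

    def test_small_group_skipped_with_warning(self, cohort_tables):
        cohort, long = cohort_tables
        few = cohort.records.head(6).copy()
        few["survival_days"] = [100.0, 200.0, 300.0, 400.0, 500.0, 600.0]
        long_few = long[long["subject_id"].isin(few["subject_id"])]
        report = run_association_analysis(long_few, few, min_group_size=4)
        assert any("skipped" in w for w in report.warnings)

    def test_unjoinable_subjects_rejected(self, cohort_tables):
        cohort, long = cohort_tables
        bad = cohort.records.copy()
        bad.loc[0, "subject_id"] = "sub-999"
        with pytest.raises(ValueError, match="absent"):
            run_association_analysis(long, bad)
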