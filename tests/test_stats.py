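"""Reliability, mixed ANOVA with generalized eta-squared, effect sizes."""

import numpy as np
import pandas as pd
import pytest

from strengthlab.errors import ImbalanceError, InvalidParameterError
from strengthlab.stats import (
    DMagnitude,
    EffectSizeResult,
    GesMagnitude,
    cohens_d,
    ges_magnitude,
    magnitude_inference,
    mixed_anova,
    reliability,
)
from strengthlab.synth import gen_study

TOY1 = np.array([100.0, 110.0, 120.0, 130.0])
TOY2 = np.array([102.0, 108.0, 123.0, 128.0])


def icc2_by_hand(x, y):
    """ICC(2,1) from the two-way ANOVA mean squares, written out."""
    n, k = x.size, 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    subj_means = data.mean(axis=1)
    day_means = data.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((day_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestReliability:
    def test_perfect_agreement(self):
        r = reliability(TOY1, TOY1)
        assert r.icc == 1.0
        assert r.cv_pct == 0.0
        assert r.icc_ci95 == (1.0, 1.0)

    def test_matches_variance_component_oracle(self):
        r = reliability(TOY1, TOY2)
        assert r.icc == pytest.approx(icc2_by_hand(TOY1, TOY2), abs=1e-9)
        # typical-error CV by hand
        diffs = TOY2 - TOY1
        te = np.std(diffs, ddof=1) / np.sqrt(2.0)
        grand = np.mean(np.concatenate([TOY1, TOY2]))
        assert r.cv_pct == pytest.approx(100.0 * te / grand, abs=1e-9)
        assert r.cv_ci95[0] <= r.cv_pct <= r.cv_ci95[1]
        assert r.icc_ci95[0] <= r.icc <= r.icc_ci95[1]

    def test_independent_noise_gives_near_zero_icc(self, rng):
        x = rng.normal(100.0, 10.0, 200)
        y = rng.normal(100.0, 10.0, 200)
        r = reliability(x, y)
        assert abs(r.icc) < 0.15

    def test_consistency_vs_agreement_with_offset(self):
        shifted = TOY1 + 8.0
        agree = reliability(TOY1, shifted, icc_form="ICC2")
        consist = reliability(TOY1, shifted, icc_form="ICC3")
        assert consist.icc == pytest.approx(1.0)
        assert agree.icc < 1.0

    def test_preconditions(self):
        with pytest.raises(InvalidParameterError):
            reliability([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(InvalidParameterError):
            reliability([1.0, -1.0, 0.0], [1.0, -1.0, 0.0])


def hand_two_by_two_anova(data):
    """Sums of squares for a 2-group x 2-time mixed design, written as
    explicit loops over cells (independent of the implementation)."""
    subjects = sorted(data["subject"].unique())
    times = sorted(data["time"].unique())
    groups = sorted(data["group"].unique())
    get = lambda s, t: float(
        data[(data.subject == s) & (data.time == t)]["value"].iloc[0])
    grp_of = {s: data[data.subject == s]["group"].iloc[0] for s in subjects}
    grand = float(data["value"].mean())
    k = len(times)

    subj_mean = {s: np.mean([get(s, t) for t in times]) for s in subjects}
    grp_mean = {g: np.mean([subj_mean[s] for s in subjects if grp_of[s] == g])
                for g in groups}
    time_mean = {t: float(data[data.time == t]["value"].mean()) for t in times}
    cell_mean = {(g, t): float(data[(data.group == g) & (data.time == t)]
                               ["value"].mean()) for g in groups for t in times}
    n_g = {g: sum(1 for s in subjects if grp_of[s] == g) for g in groups}

    ss_group = k * sum(n_g[g] * (grp_mean[g] - grand) ** 2 for g in groups)
    ss_subj = k * sum((subj_mean[s] - grp_mean[grp_of[s]]) ** 2 for s in subjects)
    ss_time = len(subjects) * sum((time_mean[t] - grand) ** 2 for t in times)
    ss_inter = sum(n_g[g] * (cell_mean[(g, t)] - grp_mean[g] - time_mean[t] + grand) ** 2
                   for g in groups for t in times)
    ss_total = sum((get(s, t) - grand) ** 2 for s in subjects for t in times)
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_inter
    return dict(group=ss_group, subj=ss_subj, time=ss_time, inter=ss_inter,
                err=ss_err, total=ss_total)


def toy_mixed_table():
    rows = []
    values = {
        ("A", "S1"): (10.0, 14.0), ("A", "S2"): (12.0, 17.0),
        ("A", "S3"): (11.0, 16.0),
        ("B", "S4"): (10.0, 11.0), ("B", "S5"): (13.0, 12.0),
        ("B", "S6"): (12.0, 14.0),
    }
    for (g, s), (pre, post) in values.items():
        rows.append((s, g, "pre", pre))
        rows.append((s, g, "post", post))
    return pd.DataFrame(rows, columns=["subject", "group", "time", "value"])


class TestMixedAnova:
    def test_matches_hand_sums_of_squares(self):
        tab = toy_mixed_table()
        ss = hand_two_by_two_anova(tab)
        effects = {e.term: e for e in mixed_anova(tab, dv="value", within=["time"])}

        n_subj, g, k = 6, 2, 2
        f_group = (ss["group"] / (g - 1)) / (ss["subj"] / (n_subj - g))
        f_time = (ss["time"] / (k - 1)) / (ss["err"] / ((n_subj - g) * (k - 1)))
        f_inter = (ss["inter"] / ((g - 1) * (k - 1))) / (ss["err"] / ((n_subj - g) * (k - 1)))
        assert effects["group"].F == pytest.approx(f_group, rel=1e-9)
        assert effects["time"].F == pytest.approx(f_time, rel=1e-9)
        assert effects["group*time"].F == pytest.approx(f_inter, rel=1e-9)

        pooled_err = ss["subj"] + ss["err"]
        for term, ss_eff in (("group", ss["group"]), ("time", ss["time"]),
                             ("group*time", ss["inter"])):
            assert effects[term].ges == pytest.approx(
                ss_eff / (ss_eff + pooled_err), rel=1e-9)

    def test_matches_pingouin_f_and_p(self, rng):
        import pingouin as pg

        tab, _ = gen_study(n_per_group=8, effects={"mvf_n": 0.6}, rng=rng,
                           measures={"mvf_n": (890.0, 185.0, 35.0)})
        ours = {e.term: e for e in mixed_anova(tab, dv="value", within=["time"])}
        theirs = pg.mixed_anova(data=tab, dv="value", within="time",
                                subject="subject", between="group")
        by_src = theirs.set_index("Source")
        assert ours["group"].F == pytest.approx(float(by_src.loc["group", "F"]))
        assert ours["time"].F == pytest.approx(float(by_src.loc["time", "F"]))
        assert ours["group*time"].F == pytest.approx(
            float(by_src.loc["Interaction", "F"]))
        assert ours["group*time"].p == pytest.approx(
            float(by_src.loc["Interaction", "p_unc"]), abs=1e-9)

    def test_three_factor_partition_closes(self, rng):
        rows = []
        for gi, grp in enumerate(("A", "B")):
            for s in range(4):
                subj = f"{grp}{s}"
                for t in ("pre", "post"):
                    for load in ("L1", "L2", "L3"):
                        rows.append((subj, grp, t, load, float(rng.normal(10, 3))))
        tab = pd.DataFrame(rows, columns=["subject", "group", "time", "load",
                                          "value"])
        effects = mixed_anova(tab, dv="value", within=["time", "load"])
        # reconstruct the full partition and compare with total SS
        terms = {e.term: e for e in effects}
        ss_strata = sum(e.ss for e in effects)
        ss_err1 = terms["time"].ss_error
        ss_err2 = terms["load"].ss_error
        ss_err12 = terms["time*load"].ss_error
        # subject SS stratum from the group effect's error term
        ss_subj = terms["group"].ss_error
        total = float(((tab["value"] - tab["value"].mean()) ** 2).sum())
        assert ss_strata + ss_err1 + ss_err2 + ss_err12 + ss_subj == pytest.approx(
            total, rel=1e-10)

    def test_constant_dv(self):
        tab = toy_mixed_table()
        tab["value"] = 5.0
        for e in mixed_anova(tab, dv="value", within=["time"]):
            assert e.F == 0.0
            assert e.ges == 0.0

    def test_ges_affine_invariance(self):
        tab = toy_mixed_table()
        base = {e.term: e.ges for e in mixed_anova(tab, dv="value", within=["time"])}
        tab2 = tab.copy()
        tab2["value"] = tab2["value"] * 3.7 - 12.0
        scaled = {e.term: e.ges for e in mixed_anova(tab2, dv="value", within=["time"])}
        for term in base:
            assert base[term] == pytest.approx(scaled[term], rel=1e-9)

    def test_missing_cell_rejected(self):
        tab = toy_mixed_table().iloc[:-1]
        with pytest.raises(ImbalanceError):
            mixed_anova(tab, dv="value", within=["time"])


class TestThresholdBinning:
    @pytest.mark.parametrize("ges,expected", [
        (0.01, GesMagnitude.NEGLIGIBLE),
        (0.02, GesMagnitude.SMALL),
        (0.12, GesMagnitude.SMALL),
        (0.13, GesMagnitude.MEDIUM),
        (0.26, GesMagnitude.LARGE),
        (0.30, GesMagnitude.LARGE),
    ])
    def test_ges_bins(self, ges, expected):
        assert ges_magnitude(ges) is expected

    def test_ges_out_of_range(self):
        with pytest.raises(InvalidParameterError):
            ges_magnitude(1.5)

    @pytest.mark.parametrize("d,expected", [
        (0.1, DMagnitude.TRIVIAL), (0.2, DMagnitude.TRIVIAL),
        (0.21, DMagnitude.SMALL), (0.6, DMagnitude.SMALL),
        (0.61, DMagnitude.MODERATE), (1.2, DMagnitude.MODERATE),
        (1.21, DMagnitude.LARGE), (2.0, DMagnitude.LARGE),
        (2.01, DMagnitude.VERY_LARGE), (-1.5, DMagnitude.LARGE),
    ])
    def test_d_bins(self, d, expected):
        from strengthlab.stats import d_magnitude

        assert d_magnitude(d) is expected


class TestCohensD:
    def test_identical_samples_trivial(self):
        res = cohens_d([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.d == 0.0
        assert res.magnitude is DMagnitude.TRIVIAL

    def test_unit_effect_by_definition(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = cohens_d(a + np.std(a, ddof=1), a)
        assert res.d == pytest.approx(1.0)

    def test_matches_textbook_pooled_sd(self, rng):
        a = rng.normal(10.0, 2.0, 15)
        b = rng.normal(9.0, 3.0, 12)
        res = cohens_d(a, b)
        sp = np.sqrt(((a.size - 1) * np.var(a, ddof=1)
                      + (b.size - 1) * np.var(b, ddof=1))
                     / (a.size + b.size - 2))
        assert res.d == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-12)

    def test_antisymmetry(self, rng):
        a = rng.normal(10.0, 2.0, 10)
        b = rng.normal(11.0, 2.0, 10)
        r1, r2 = cohens_d(a, b), cohens_d(b, a)
        assert r1.d == pytest.approx(-r2.d, abs=1e-12)
        assert r1.ci90[0] == pytest.approx(-r2.ci90[1], abs=1e-6)

    def test_ci_contains_point_estimate(self, rng):
        a = rng.normal(10.0, 2.0, 12)
        b = rng.normal(9.0, 2.0, 12)
        for method in ("nct", "normal"):
            res = cohens_d(a, b, ci_method=method)
            assert res.ci90[0] <= res.d <= res.ci90[1]

    def test_paired_uses_pre_test_sd(self, rng):
        pre = rng.normal(100.0, 10.0, 12)
        post = pre + rng.normal(5.0, 3.0, 12)
        res = cohens_d(post, pre, paired=True)
        assert res.d == pytest.approx(
            np.mean(post - pre) / np.std(pre, ddof=1), abs=1e-12)

    def test_zero_spread_errors(self):
        with pytest.raises(InvalidParameterError):
            cohens_d([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


class TestMagnitudeInference:
    def es(self, d, lo, hi):
        return EffectSizeResult(d=d, ci90=(lo, hi),
                                magnitude=DMagnitude.TRIVIAL, n1=10, n2=10,
                                paired=False)

    def test_tight_trivial(self):
        label = magnitude_inference(self.es(0.0, -0.1, 0.1))
        assert label in ("most likely trivial", "almost certainly trivial")

    def test_clearly_positive(self):
        # P(d > 0.2) for N(1.0, se from CI (0.7, 1.3)) exceeds 99.5%
        label = magnitude_inference(self.es(1.0, 0.7, 1.3))
        assert label == "almost certainly moderate"

    def test_unclear_when_both_tails_exceed_5pct(self):
        assert magnitude_inference(self.es(0.3, -0.4, 1.0)) == "unclear"

    def test_confidence_bands_move_with_probability(self):
        # widen the CI around the same point estimate: confidence drops
        tight = magnitude_inference(self.es(0.5, 0.4, 0.6))
        loose = magnitude_inference(self.es(0.5, 0.15, 0.85))
        assert tight.startswith("almost certainly")
        assert loose.split()[0] in ("likely", "possibly")


class TestPowerSanity:
    def test_true_effect_detected_more_than_null(self, rng):
        null_rej, eff_rej = 0, 0
        n_rep = 120
        for _ in range(n_rep):
            tab, _ = gen_study(n_per_group=12, rng=rng,
                               measures={"m": (100.0, 10.0, 3.0)})
            e = {x.term: x for x in mixed_anova(tab, dv="value", within=["time"])}
            null_rej += e["group*time"].p < 0.05
            tab, _ = gen_study(n_per_group=12, rng=rng, effects={"m": 0.8},
                               measures={"m": (100.0, 10.0, 3.0)})
            e = {x.term: x for x in mixed_anova(tab, dv="value", within=["time"])}
            eff_rej += e["group*time"].p < 0.05
        assert eff_rej > null_rej
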