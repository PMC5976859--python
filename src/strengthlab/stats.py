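"""Inferential layer: reliability, mixed ANOVA, effect sizes and
magnitude-based inference.

Reliability of repeated test days is summarised by an intraclass
correlation coefficient (two-way random, absolute agreement, single
measure by default; consistency form available) and a typical-error
coefficient of variation, CV% = 100 * (SD of the within-pair
differences / sqrt(2)) / grand mean, both with 95% confidence
intervals.

Mixed ANOVAs (one between-subject grouping factor plus one or two
within-subject factors) are computed from the classical
sums-of-squares partition with subject-level error strata, returning
F, p and generalized eta-squared (effect SS over effect SS plus all
subject-related error SS), the effect-size index that is comparable
across designs.  No sphericity correction is applied by default.

Standardized differences (Cohen's d) carry 90% confidence intervals
(noncentral-t by default) and are labelled with magnitude thresholds
0.2 / 0.6 / 1.2 / 2.0 (small / moderate / large / very large) plus a
qualitative probabilistic inference (possibly / likely / most likely /
almost certainly) against a smallest worthwhile change of 0.2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as _optimize
from scipy import stats as _stats

from .errors import ImbalanceError, InvalidParameterError

__all__ = [
    "ReliabilityResult",
    "AnovaEffect",
    "EffectSizeResult",
    "GesMagnitude",
    "DMagnitude",
    "reliability",
    "mixed_anova",
    "ges_magnitude",
    "cohens_d",
    "magnitude_inference",
]


# ---------------------------------------------------------------------------
# Reliability
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    icc_ci95: tuple
    cv_pct: float
    cv_ci95: tuple
    n: int
    icc_form: str


def reliability(
    test1: Sequence[float],
    test2: Sequence[float],
    icc_form: str = "ICC2",
    cv_mode: str = "typical_error",
) -> ReliabilityResult:
    """Test-retest reliability of paired measurements.

    ``icc_form`` is ``"ICC2"`` (two-way random, absolute agreement,
    single measure) or ``"ICC3"`` (two-way mixed, consistency).
    ``cv_mode`` is ``"typical_error"`` (SD of differences / sqrt(2),
    over the grand mean) or ``"per_subject"`` (mean of per-subject
    CVs).
    """
    import pingouin as pg

    x = np.asarray(test1, dtype=float)
    y = np.asarray(test2, dtype=float)
    if x.size != y.size:
        raise InvalidParameterError("test1 and test2 must be paired")
    n = x.size
    if n < 3:
        raise InvalidParameterError("need at least three subjects")
    grand = float(np.mean(np.concatenate([x, y])))
    if grand == 0:
        raise InvalidParameterError("grand mean is zero: CV undefined")
    if icc_form not in ("ICC2", "ICC3"):
        raise InvalidParameterError("icc_form must be ICC2 or ICC3")

    diffs = y - x
    sd_diff = float(np.std(diffs, ddof=1))
    if np.allclose(x, y):
        # degenerate perfect agreement: variance components collapse
        icc, ci = 1.0, (1.0, 1.0)
    else:
        long = pd.DataFrame({
            "subject": np.tile(np.arange(n), 2),
            "day": np.repeat([1, 2], n),
            "value": np.concatenate([x, y]),
        })
        import warnings as _warnings
        with _warnings.catch_warnings():
            # degenerate inputs (zero residual variance) are resolved below
            _warnings.simplefilter("ignore", RuntimeWarning)
            tab = pg.intraclass_corr(data=long, targets="subject", raters="day",
                                     ratings="value")
        # ICC2 = two-way random, absolute agreement, single measure;
        # ICC3 = two-way mixed, consistency, single measure.
        label = "ICC(A,1)" if icc_form == "ICC2" else "ICC(C,1)"
        tab = tab.set_index("Type")
        ci_col = "CI95%" if "CI95%" in tab.columns else "CI95"
        row = tab.loc[label]
        icc = float(row["ICC"])
        ci = (float(row[ci_col][0]), float(row[ci_col][1]))

    if cv_mode == "typical_error":
        te = sd_diff / math.sqrt(2.0)
        cv = 100.0 * te / abs(grand)
        df = n - 1
        lo = cv * math.sqrt(df / _stats.chi2.ppf(0.975, df))
        hi = cv * math.sqrt(df / _stats.chi2.ppf(0.025, df))
        cv_ci = (lo, hi)
    elif cv_mode == "per_subject":
        pair_mean = (x + y) / 2.0
        pair_sd = np.abs(diffs) / math.sqrt(2.0)
        per = 100.0 * pair_sd / np.abs(pair_mean)
        cv = float(np.mean(per))
        se = float(np.std(per, ddof=1)) / math.sqrt(n)
        tcrit = _stats.t.ppf(0.975, n - 1)
        cv_ci = (cv - tcrit * se, cv + tcrit * se)
    else:
        raise InvalidParameterError("cv_mode must be typical_error or per_subject")
    return ReliabilityResult(icc=icc, icc_ci95=ci, cv_pct=cv, cv_ci95=cv_ci,
                             n=n, icc_form=icc_form)


# ---------------------------------------------------------------------------
# Mixed ANOVA with generalized eta-squared
# ---------------------------------------------------------------------------

class GesMagnitude(enum.Enum):
    NEGLIGIBLE = "negligible"
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


def ges_magnitude(ges: float) -> GesMagnitude:
    """Bin a generalized eta-squared at thresholds 0.02 / 0.13 / 0.26."""
    if not 0 <= ges <= 1:
        raise InvalidParameterError("generalized eta-squared must lie in [0, 1]")
    if ges >= 0.26:
        return GesMagnitude.LARGE
    if ges >= 0.13:
        return GesMagnitude.MEDIUM
    if ges >= 0.02:
        return GesMagnitude.SMALL
    return GesMagnitude.NEGLIGIBLE


@dataclass(frozen=True)
class AnovaEffect:
    term: str
    F: float
    p: float
    ges: float
    magnitude: GesMagnitude
    df1: int
    df2: int
    ss: float
    ss_error: float


def _ss(weights, means, grand):
    return float(np.sum(np.asarray(weights) * (np.asarray(means) - grand) ** 2))


def mixed_anova(
    table: pd.DataFrame,
    dv: str = "value",
    within: Sequence[str] = ("time",),
    subject: str = "subject",
    between: str = "group",
) -> list[AnovaEffect]:
    """Mixed ANOVA for one between factor and one or two within factors.

    The design must be complete: every subject contributes exactly one
    observation per within-factor cell.  Sums of squares are
    partitioned with subject-level error strata (the univariate
    repeated-measures approach); F-ratios use the error stratum
    matching each effect, and generalized eta-squared divides each
    effect SS by itself plus all subject-related error SS.
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise InvalidParameterError("one or two within factors supported")
    cols = [subject, between, *within, dv]
    df = table[cols].copy()
    counts = df.groupby([subject, *within], observed=True).size()
    if counts.min() != 1 or counts.max() != 1:
        raise ImbalanceError("each subject must have exactly one value per within cell")
    gmap = df.groupby(subject, observed=True)[between].nunique()
    if gmap.max() != 1:
        raise ImbalanceError("each subject must belong to exactly one group")

    # pivot to Y[s, i(, j)]
    subjects = np.array(sorted(df[subject].unique(), key=str))
    levels = [sorted(df[w].unique(), key=str) for w in within]
    wide = df.pivot_table(index=subject, columns=within, values=dv, observed=True)
    # order columns consistently
    if len(within) == 1:
        wide = wide.reindex(columns=levels[0])
    else:
        wide = wide.reindex(columns=pd.MultiIndex.from_product(levels))
    wide = wide.reindex(index=subjects)
    if wide.isna().any().any():
        raise ImbalanceError("missing cells after pivoting")
    shape = [len(subjects)] + [len(l) for l in levels]
    Y = wide.to_numpy(dtype=float).reshape(shape)
    sub_groups = df.drop_duplicates(subject).set_index(subject)[between].reindex(subjects)
    groups = np.array(sorted(sub_groups.unique(), key=str))
    if groups.size < 2:
        raise ImbalanceError("need at least two groups for a mixed design")
    gidx = np.array([np.where(groups == g)[0][0] for g in sub_groups])
    n_g = np.array([(gidx == k).sum() for k in range(groups.size)])
    if n_g.min() < 2:
        raise ImbalanceError("need at least two subjects per group")

    if len(within) == 1:
        Y = Y[:, :, None]
    N, k1, k2 = Y.shape
    g = groups.size
    grand = Y.mean()
    ss_total = float(np.sum((Y - grand) ** 2))

    subj_mean = Y.mean(axis=(1, 2))
    grp_mean = np.array([subj_mean[gidx == k].mean() for k in range(g)])
    ss_between_subj = k1 * k2 * float(np.sum((subj_mean - grand) ** 2))
    ss_group = k1 * k2 * _ss(n_g, grp_mean, grand)
    ss_subj = ss_between_subj - ss_group

    def w_mean(axis):  # marginal over all observations
        return Y.mean(axis=axis)

    w1_mean = Y.mean(axis=(0, 2))                        # (k1,)
    gw1_mean = np.stack([Y[gidx == k].mean(axis=(0, 2)) for k in range(g)])  # (g, k1)
    sw1_mean = Y.mean(axis=2)                            # (N, k1)

    ss_w1 = N * k2 * float(np.sum((w1_mean - grand) ** 2))
    dev_gw1 = gw1_mean - grp_mean[:, None] - w1_mean[None, :] + grand
    ss_gw1 = k2 * float(np.sum(n_g[:, None] * dev_gw1**2))
    dev_e1 = sw1_mean - subj_mean[:, None] - gw1_mean[gidx] + grp_mean[gidx][:, None]
    ss_err1 = k2 * float(np.sum(dev_e1**2))

    effects = []
    error_pool = ss_subj + ss_err1

    if k2 > 1:
        w2_mean = Y.mean(axis=(0, 1))
        gw2_mean = np.stack([Y[gidx == k].mean(axis=(0, 1)) for k in range(g)])
        sw2_mean = Y.mean(axis=1)
        ss_w2 = N * k1 * float(np.sum((w2_mean - grand) ** 2))
        dev_gw2 = gw2_mean - grp_mean[:, None] - w2_mean[None, :] + grand
        ss_gw2 = k1 * float(np.sum(n_g[:, None] * dev_gw2**2))
        dev_e2 = sw2_mean - subj_mean[:, None] - gw2_mean[gidx] + grp_mean[gidx][:, None]
        ss_err2 = k1 * float(np.sum(dev_e2**2))

        w12_mean = Y.mean(axis=0)                        # (k1, k2)
        gw12_mean = np.stack([Y[gidx == k].mean(axis=0) for k in range(g)])
        dev_w12 = w12_mean - w1_mean[:, None] - w2_mean[None, :] + grand
        ss_w12 = N * float(np.sum(dev_w12**2))
        dev_g12 = (gw12_mean
                   - gw1_mean[:, :, None] - gw2_mean[:, None, :] - w12_mean[None, :, :]
                   + grp_mean[:, None, None] + w1_mean[None, :, None]
                   + w2_mean[None, None, :] - grand)
        ss_gw12 = float(np.sum(n_g[:, None, None] * dev_g12**2))
        ss_err12 = ss_total - (ss_group + ss_subj + ss_w1 + ss_gw1 + ss_err1
                               + ss_w2 + ss_gw2 + ss_err2 + ss_w12 + ss_gw12)
        ss_err12 = max(ss_err12, 0.0)
        error_pool += ss_err2 + ss_err12

    def eff(term, ss_e, df1, ss_err, df2):
        ms_e = ss_e / df1 if df1 else 0.0
        ms_r = ss_err / df2 if df2 else 0.0
        if ms_r == 0:
            F = 0.0 if ms_e == 0 else float("inf")
            p = 1.0 if ms_e == 0 else 0.0
        else:
            F = ms_e / ms_r
            p = float(_stats.f.sf(F, df1, df2))
        denom = ss_e + error_pool
        ges = 0.0 if denom == 0 else ss_e / denom
        ges = min(max(ges, 0.0), 1.0)
        return AnovaEffect(term=term, F=F, p=p, ges=ges,
                           magnitude=ges_magnitude(ges),
                           df1=df1, df2=df2, ss=ss_e, ss_error=ss_err)

    w1, = within[:1]
    effects.append(eff(between, ss_group, g - 1, ss_subj, N - g))
    effects.append(eff(w1, ss_w1, k1 - 1, ss_err1, (N - g) * (k1 - 1)))
    effects.append(eff(f"{between}*{w1}", ss_gw1, (g - 1) * (k1 - 1),
                       ss_err1, (N - g) * (k1 - 1)))
    if k2 > 1:
        w2 = within[1]
        effects.append(eff(w2, ss_w2, k2 - 1, ss_err2, (N - g) * (k2 - 1)))
        effects.append(eff(f"{between}*{w2}", ss_gw2, (g - 1) * (k2 - 1),
                           ss_err2, (N - g) * (k2 - 1)))
        effects.append(eff(f"{w1}*{w2}", ss_w12, (k1 - 1) * (k2 - 1),
                           ss_err12, (N - g) * (k1 - 1) * (k2 - 1)))
        effects.append(eff(f"{between}*{w1}*{w2}", ss_gw12,
                           (g - 1) * (k1 - 1) * (k2 - 1),
                           ss_err12, (N - g) * (k1 - 1) * (k2 - 1)))
    return effects


# ---------------------------------------------------------------------------
# Cohen's d with 90% CI and magnitude-based inference
# ---------------------------------------------------------------------------

class DMagnitude(enum.Enum):
    TRIVIAL = "trivial"
    SMALL = "small"
    MODERATE = "moderate"
    LARGE = "large"
    VERY_LARGE = "very large"


def d_magnitude(d: float) -> DMagnitude:
    """Magnitude bins for |d|: >0.2 small, >0.6 moderate, >1.2 large,
    >2 very large."""
    a = abs(d)
    if a > 2.0:
        return DMagnitude.VERY_LARGE
    if a > 1.2:
        return DMagnitude.LARGE
    if a > 0.6:
        return DMagnitude.MODERATE
    if a > 0.2:
        return DMagnitude.SMALL
    return DMagnitude.TRIVIAL


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    ci90: tuple
    magnitude: DMagnitude
    n1: int
    n2: int
    paired: bool
    inference: Optional[str] = None


def _nct_ci(t: float, df: int, scale: float, level: float) -> tuple:
    """CI for d = ncp * scale by pivoting the noncentral-t CDF."""
    alpha = (1.0 - level) / 2.0

    def cdf(nc):
        val = _stats.nct.cdf(t, df, nc)
        if np.isnan(val):           # far tails underflow; use the limit value
            return 0.0 if nc > t else 1.0
        return float(val)

    def solve(prob):
        # cdf is decreasing in nc; expand the bracket until it straddles prob
        lo, hi, step = t, t, 2.0
        while cdf(lo) < prob and step < 1e6:
            lo -= step
            step *= 2.0
        step = 2.0
        while cdf(hi) > prob and step < 1e6:
            hi += step
            step *= 2.0
        return _optimize.brentq(lambda nc: cdf(nc) - prob, lo, hi, xtol=1e-8)

    nc_lo = solve(1.0 - alpha)
    nc_hi = solve(alpha)
    return (nc_lo * scale, nc_hi * scale)


def cohens_d(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool = False,
    ci_method: str = "nct",
    level: float = 0.90,
) -> EffectSizeResult:
    """Standardized difference between ``a`` and ``b`` (a minus b).

    Independent samples use the pooled SD.  Paired samples (``a`` =
    post, ``b`` = pre) standardize the mean change by the pre-test SD,
    avoiding the inflation that the change-score SD suffers when
    pre/post are correlated.  The CI (default noncentral-t; ``ci_method
    = "normal"`` for the large-sample approximation) is on the same
    scale as d.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidParameterError("need at least two observations per sample")
    if paired:
        if x.size != y.size:
            raise InvalidParameterError("paired samples must have equal length")
        n = x.size
        diffs = x - y
        sd_pre = float(np.std(y, ddof=1))
        sd_diff = float(np.std(diffs, ddof=1))
        if sd_pre == 0:
            raise InvalidParameterError("zero pre-test SD")
        d = float(np.mean(diffs)) / sd_pre
        df = n - 1
        if sd_diff == 0:
            ci = (d, d)
        elif ci_method == "nct":
            t = float(np.mean(diffs)) / (sd_diff / math.sqrt(n))
            # CI is exact for mean/sd_diff, rescaled onto the pre-SD metric
            ci = _nct_ci(t, df, sd_diff / (sd_pre * math.sqrt(n)), level)
        else:
            se = math.sqrt(sd_diff**2 / (n * sd_pre**2) + d**2 / (2 * df))
            z = _stats.norm.ppf(0.5 + level / 2)
            ci = (d - z * se, d + z * se)
    else:
        n1, n2 = x.size, y.size
        df = n1 + n2 - 2
        sp = math.sqrt(((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df)
        if sp == 0:
            raise InvalidParameterError("zero pooled SD")
        d = (float(np.mean(x)) - float(np.mean(y))) / sp
        ntilde = n1 * n2 / (n1 + n2)
        if ci_method == "nct":
            t = d * math.sqrt(ntilde)
            ci = _nct_ci(t, df, 1.0 / math.sqrt(ntilde), level)
        else:
            se = math.sqrt(1.0 / ntilde + d**2 / (2 * df))
            z = _stats.norm.ppf(0.5 + level / 2)
            ci = (d - z * se, d + z * se)
    res = EffectSizeResult(
        d=d, ci90=(float(min(ci)), float(max(ci))), magnitude=d_magnitude(d),
        n1=x.size, n2=y.size, paired=paired,
    )
    return replace(res, inference=magnitude_inference(res))


_CONFIDENCE_BANDS = (
    (0.995, "almost certainly"),
    (0.95, "most likely"),
    (0.75, "likely"),
    (0.25, "possibly"),
)

_Z90 = float(_stats.norm.ppf(0.95))


def magnitude_inference(es: EffectSizeResult, swc: float = 0.2) -> str:
    """Qualitative probabilistic label for a standardized effect.

    The sampling distribution of the true effect is approximated as
    normal, centred on d with SE recovered from the 90% CI.  The label
    combines the confidence band of the most probable region
    (beneficial / trivial / harmful relative to the smallest
    worthwhile change) with the magnitude of the point estimate;
    "unclear" when both substantive directions exceed 5%.
    """
    lo, hi = es.ci90
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise InvalidParameterError("effect CI must be finite")
    se = (hi - lo) / (2.0 * _Z90)
    if se <= 0:
        p_pos = 1.0 if es.d > swc else 0.0
        p_neg = 1.0 if es.d < -swc else 0.0
    else:
        p_pos = 1.0 - _stats.norm.cdf((swc - es.d) / se)
        p_neg = _stats.norm.cdf((-swc - es.d) / se)
    p_triv = max(1.0 - p_pos - p_neg, 0.0)
    if p_pos > 0.05 and p_neg > 0.05:
        return "unclear"
    probs = {"positive": p_pos, "trivial": p_triv, "negative": p_neg}
    region = max(probs, key=probs.get)
    conf = probs[region]
    word = "possibly"
    for cut, label in _CONFIDENCE_BANDS:
        if conf > cut:
            word = label
            break
    mag = DMagnitude.TRIVIAL if region == "trivial" else d_magnitude(es.d)
    return f"{word} {mag.value}"
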