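"""Differential-variability tests for two-phenotype methylation data.

Implements six per-feature tests, each returning a :class:`DVResultTable`:

* ``run_bt`` -- Bartlett's test of equal variances on beta values, ranked by
  ascending P-value.  Powerful for outlier-driven variance but sensitive to
  departures from normality.
* ``run_ievora`` -- iEVORA: significance is assessed with Bartlett's test
  (q-value < FDR threshold), but the significant features are re-ranked by an
  ordinary differential-methylation t-statistic, so outlier-only features are
  ranked highly only when no mean-shifted features exist.
* ``run_diffvar`` -- an empirical-Bayes Levene-type test: absolute (or
  squared) deviations of M-values from the group mean, compared between
  groups with a moderated t-test.
* ``run_jdmdv`` -- a 2-df joint score test for a group effect on the mean
  and on the (log-linear) variance of M-values in a linear-regression
  setting.
* ``run_gamlss_ls`` -- a nested Gaussian location-scale scheme on M-values:
  null model, mean-only model, mean+variance model; two 1-df likelihood
  ratio tests (mean, then variance-given-mean) give two P-values, and a
  feature is significant if either q-value clears the threshold.
* ``run_ttest_dmc`` -- the differential-mean baseline: a moderated t-test on
  beta values.

Per-feature degeneracies (too few non-missing values, zero variance in both
groups) yield missing rows (NaN P-value) which are excluded from FDR
estimation and ranking.  Direction ("hyper"/"hypo") is always the sign of
the group-1 minus group-0 mean beta value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core import DEFAULT_CLIP_EPSILON, MethylationDataset, to_mvalues
from .multiple_testing import qvalues

__all__ = [
    "FeatureTestResult",
    "DVResultTable",
    "ModeratedVariancePrior",
    "bartlett_test",
    "two_sample_t",
    "fit_variance_prior",
    "run_bt",
    "run_ievora",
    "run_diffvar",
    "run_jdmdv",
    "run_gamlss_ls",
    "run_ttest_dmc",
    "ALGORITHMS",
]

logger = logging.getLogger(__name__)

#: Minimum non-missing values per group for a variance-based test.
MIN_PER_GROUP = 3

RESULT_COLUMNS = ["feature_id", "statistic", "p_value", "q_value",
                  "direction", "significant", "rank"]


@dataclass
class FeatureTestResult:
    """One feature's test outcome (row view of a :class:`DVResultTable`)."""

    feature_id: str
    statistic: float
    p_value: float
    q_value: float
    direction: str
    auxiliary: dict


@dataclass
class DVResultTable:
    """Per-feature results for one algorithm.

    ``table`` has one row per input feature, in input order, with columns
    ``feature_id, statistic, p_value, q_value, direction, significant,
    rank`` plus algorithm-specific extras.  ``rank`` is 1-based over the
    algorithm's ranked set (all testable features for BT/DiffVar/J-DMDV/
    t-test; the significant set for iEVORA and GAMLSS) and NaN elsewhere.
    """

    table: pd.DataFrame
    algorithm: str
    significance_threshold: float
    pi0: float

    @property
    def significant_features(self) -> np.ndarray:
        return self.table.loc[self.table["significant"], "feature_id"].to_numpy()

    def ranked_features(self) -> np.ndarray:
        """Feature ids of the ranked set, in rank order."""
        ranked = self.table.dropna(subset=["rank"]).sort_values("rank")
        return ranked["feature_id"].to_numpy()

    def feature(self, feature_id: str) -> FeatureTestResult:
        row = self.table.set_index("feature_id").loc[feature_id]
        aux = {c: row[c] for c in self.table.columns
               if c not in RESULT_COLUMNS}
        return FeatureTestResult(
            feature_id=feature_id, statistic=row["statistic"],
            p_value=row["p_value"], q_value=row["q_value"],
            direction=row["direction"], auxiliary=aux,
        )

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False, na_rep="NA")


@dataclass
class ModeratedVariancePrior:
    """Scaled inverse-chi-square prior for feature variances.

    ``d0`` is the prior degrees of freedom (may be ``inf``), ``s0_squared``
    the prior variance.  The posterior variance for a feature with sample
    variance s2 on df degrees of freedom is
    ``(d0*s0^2 + df*s2) / (d0 + df)``, which shrinks s2 toward s0^2.
    """

    d0: float
    s0_squared: float

    def posterior_variance(self, s2: np.ndarray, df: np.ndarray) -> np.ndarray:
        if np.isinf(self.d0):
            return np.full_like(np.asarray(s2, float), self.s0_squared)
        return (self.d0 * self.s0_squared + df * s2) / (self.d0 + df)


# ---------------------------------------------------------------------------
# group summary helpers (NaN aware, vectorized over features)

def _group_summaries(values: np.ndarray, group: np.ndarray):
    """Per-feature count, mean, and unbiased variance for each group."""
    out = {}
    for g in (0, 1):
        x = values[:, group == g]
        finite = ~np.isnan(x)
        n = finite.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(finite, x, np.nan), axis=1)
            centered = np.where(finite, x - mean[:, None], 0.0)
            ss = (centered**2).sum(axis=1)
            var = np.where(n > 1, ss / np.maximum(n - 1, 1), np.nan)
        out[g] = (n, mean, var, ss)
    return out


def _beta_direction(ds: MethylationDataset) -> np.ndarray:
    g = _group_summaries(ds.values, ds.group)
    diff = g[1][1] - g[0][1]
    return np.where(diff >= 0, "hyper", "hypo").astype(object)


# ---------------------------------------------------------------------------
# elementary two-sample tests

def _bartlett_matrix(values: np.ndarray, group: np.ndarray):
    """Vectorized two-group Bartlett statistic and chi-square(1) P-value.

    Returns (stat, p); rows with < 3 values in a group, or zero variance in
    either group, are NaN (zero variance in exactly one group would give an
    infinite statistic and is treated as a degenerate missing result).
    """
    g = _group_summaries(values, group)
    n0, _, v0, _ = g[0]
    n1, _, v1, _ = g[1]
    N = n0 + n1
    valid = (n0 >= MIN_PER_GROUP) & (n1 >= MIN_PER_GROUP)
    both_const = valid & (v0 == 0) & (v1 == 0)
    one_const = valid & ((v0 == 0) ^ (v1 == 0))
    if one_const.any():
        logger.debug("%d features with zero variance in one group -> missing",
                     int(one_const.sum()))
    ok = valid & (v0 > 0) & (v1 > 0)

    stat = np.full(values.shape[0], np.nan)
    p = np.full(values.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (N - 2)
        num = (N - 2) * np.log(sp2) - (n0 - 1) * np.log(v0) - (n1 - 1) * np.log(v1)
        den = 1.0 + (1.0 / (n0 - 1) + 1.0 / (n1 - 1) - 1.0 / (N - 2)) / 3.0
        t = num / den
    stat[ok] = np.maximum(t[ok], 0.0)
    p[ok] = stats.chi2.sf(stat[ok], df=1)
    # identical zero variance in both groups: perfectly homoscedastic is a
    # defensible stat=0 but carries no variance information -> missing
    stat[both_const] = np.nan
    p[both_const] = np.nan
    return stat, p


def bartlett_test(x0, x1) -> tuple[float, float]:
    """Two-group Bartlett test of equal variances.

    Returns ``(statistic, p_value)`` with the P-value from chi-square with
    one degree of freedom.  Each group needs >= 3 finite values; zero
    variance in either group yields ``(nan, nan)`` (degenerate).
    """
    x0 = np.asarray(x0, float)[None, :]
    x1 = np.asarray(x1, float)[None, :]
    values = np.full((1, x0.size + x1.size), np.nan)
    values[0, : x0.size] = x0
    values[0, x0.size:] = x1
    group = np.concatenate([np.zeros(x0.size, int), np.ones(x1.size, int)])
    stat, p = _bartlett_matrix(values, group)
    return float(stat[0]), float(p[0])


def _t_matrix(values: np.ndarray, group: np.ndarray, variant: str = "welch"):
    """Vectorized two-sample t (group 1 minus group 0): (stat, p, df)."""
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    g = _group_summaries(values, group)
    n0, m0, v0, ss0 = g[0]
    n1, m1, v1, ss1 = g[1]
    valid = (n0 >= 2) & (n1 >= 2)
    diff = m1 - m0

    stat = np.full(values.shape[0], np.nan)
    p = np.full(values.shape[0], np.nan)
    df = np.full(values.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "welch":
            se2 = v0 / n0 + v1 / n1
            df_w = se2**2 / (
                (v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1)
            )
        else:
            sp2 = (ss0 + ss1) / (n0 + n1 - 2)
            se2 = sp2 * (1.0 / n0 + 1.0 / n1)
            df_w = n0 + n1 - 2.0
        ok = valid & (se2 > 0)
        stat[ok] = diff[ok] / np.sqrt(se2[ok])
        df[ok] = df_w[ok]
        p[ok] = 2.0 * stats.t.sf(np.abs(stat[ok]), df[ok])
    # both groups constant: equal means -> t = 0, p = 1; unequal -> missing
    const = valid & (se2 == 0)
    equal = const & (diff == 0)
    stat[equal], p[equal] = 0.0, 1.0
    return stat, p, df


def two_sample_t(x0, x1, variant: str = "welch") -> tuple[float, float]:
    """Two-sample t-test of group 1 vs group 0 means.

    ``variant`` chooses Welch-Satterthwaite ("welch") or pooled-variance
    ("pooled") degrees of freedom.  The statistic is positive iff
    ``mean(x1) > mean(x0)``.
    """
    x0 = np.asarray(x0, float)
    x1 = np.asarray(x1, float)
    values = np.full((1, x0.size + x1.size), np.nan)
    values[0, : x0.size] = x0
    values[0, x0.size:] = x1
    group = np.concatenate([np.zeros(x0.size, int), np.ones(x1.size, int)])
    stat, p, _ = _t_matrix(values, group, variant)
    return float(stat[0]), float(p[0])


# ---------------------------------------------------------------------------
# empirical-Bayes variance prior (moderated t machinery)

def fit_variance_prior(s2, df: float) -> ModeratedVariancePrior:
    """Method-of-moments fit of a scaled inverse-chi-square variance prior.

    Given per-feature sample variances ``s2`` on a common ``df`` degrees of
    freedom, matches the mean and variance of
    ``e_j = ln(s2_j) - digamma(df/2) + ln(df/2)``:
    solves ``trigamma(d0/2) = var(e) - trigamma(df/2)`` for ``d0`` (infinite
    when the right-hand side is <= 0), then
    ``s0^2 = exp(mean(e) + digamma(d0/2) - ln(d0/2))``.
    """
    s2 = np.asarray(s2, float)
    pos = s2[np.isfinite(s2) & (s2 > 0)]
    if pos.size < s2.size:
        logger.warning("excluded %d non-positive/non-finite variances from "
                       "prior fit", s2.size - pos.size)
    if pos.size == 0:
        raise ValueError("no positive variances to fit the prior")
    if pos.size < 10:
        raise ValueError("need >= 10 positive variances to fit the prior")
    half_df = df / 2.0
    e = np.log(pos) - special.digamma(half_df) + np.log(half_df)
    rhs = float(np.var(e, ddof=1)) - float(special.polygamma(1, half_df))
    if rhs <= 0:
        return ModeratedVariancePrior(d0=np.inf, s0_squared=float(np.exp(e.mean())))

    def f(x):  # x = d0/2; trigamma is strictly decreasing so the root is unique
        return special.polygamma(1, x) - rhs

    lo, hi = 1e-8, 1.0
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            return ModeratedVariancePrior(d0=np.inf,
                                          s0_squared=float(np.exp(e.mean())))
    half_d0 = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-12)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0)))
    return ModeratedVariancePrior(d0=d0, s0_squared=s0_sq)


def _moderated_t(diff, s2, df, n0, n1, prior: ModeratedVariancePrior | None):
    """Moderated two-sample t given per-feature pooled variances.

    Fits the variance prior across features unless one is supplied; returns
    (stat, p, prior).  With d0 = 0 this is the ordinary pooled t.
    """
    s2 = np.asarray(s2, float)
    ok = np.isfinite(s2) & (df > 0)
    if prior is None:
        df_fit = float(np.median(df[ok])) if ok.any() else 1.0
        try:
            prior = fit_variance_prior(s2[ok & (s2 > 0)], df_fit)
        except ValueError:
            logger.warning("variance-prior fit failed; using d0 = inf")
            fallback = float(np.nanmean(s2[ok])) if ok.any() else np.nan
            prior = ModeratedVariancePrior(d0=np.inf, s0_squared=fallback)
    s2_post = prior.posterior_variance(s2, df)
    stat = np.full(s2.shape, np.nan)
    p = np.full(s2.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_post * (1.0 / n0 + 1.0 / n1))
        good = ok & (se > 0)
        stat[good] = np.asarray(diff, float)[good] / se[good]
        df_total = df + (0.0 if np.isinf(prior.d0) else prior.d0)
        if np.isinf(prior.d0):
            p[good] = 2.0 * stats.norm.sf(np.abs(stat[good]))
        else:
            p[good] = 2.0 * stats.t.sf(np.abs(stat[good]), df_total[good])
    zero = ok & (se == 0) & (np.asarray(diff, float) == 0)
    stat[zero], p[zero] = 0.0, 1.0
    return stat, p, prior


# ---------------------------------------------------------------------------
# result assembly

def _assemble(ds, algorithm, stat, p, fdr, *, rank_p=None, select=None,
              extras=None) -> DVResultTable:
    """Build a DVResultTable from per-feature statistics.

    ``rank_p`` (default ``p``) orders the ranked set ascending with ties
    broken by input feature order.  If ``select`` is given it defines both
    the significant set and the ranked set (iEVORA/GAMLSS style); otherwise
    features are significant when q < fdr and all testable features are
    ranked by ``p``.
    """
    n = ds.n_features
    p = np.asarray(p, float)
    valid = np.isfinite(p)
    n_missing = int((~valid).sum())
    if n_missing:
        logger.info("%s: %d features with missing/degenerate results "
                    "(excluded from FDR estimation)", algorithm, n_missing)
    q = np.full(n, np.nan)
    pi0 = 1.0
    if valid.any():
        res = qvalues(p[valid], pi0="auto")
        q[valid] = res.q_values
        pi0 = res.pi0

    if select is None:
        significant = valid & (q < fdr)
        ranked_set = valid
    else:
        significant = np.asarray(select, bool) & valid
        ranked_set = significant

    keys = p if rank_p is None else np.asarray(rank_p, float)
    rank = np.full(n, np.nan)
    idx = np.where(ranked_set)[0]
    order = idx[np.argsort(keys[idx], kind="stable")]
    rank[order] = np.arange(1, order.size + 1)

    table = pd.DataFrame({
        "feature_id": ds.feature_ids,
        "statistic": np.asarray(stat, float),
        "p_value": p,
        "q_value": q,
        "direction": _beta_direction(ds),
        "significant": significant,
        "rank": rank,
    })
    for name, col in (extras or {}).items():
        table[name] = col
    return DVResultTable(table=table, algorithm=algorithm,
                         significance_threshold=fdr, pi0=pi0)


# ---------------------------------------------------------------------------
# the six algorithms

def run_bt(ds: MethylationDataset, fdr: float = 0.05) -> DVResultTable:
    """Bartlett's test on beta values; q-values; rank by ascending P."""
    stat, p = _bartlett_matrix(ds.values, ds.group)
    return _assemble(ds, "BT", stat, p, fdr)


def run_ievora(ds: MethylationDataset, bt_fdr: float = 0.05,
               t_variant: str = "welch") -> DVResultTable:
    """iEVORA: Bartlett significance, t-statistic re-ranking.

    Features with Bartlett q-value < ``bt_fdr`` form the significant set —
    identical to :func:`run_bt` at the same threshold — and are re-ranked by
    ascending t-test P-value so that larger mean-methylation shifts come
    first.  Unselected features are unranked.
    """
    stat, p = _bartlett_matrix(ds.values, ds.group)
    t_stat, t_p, _ = _t_matrix(ds.values, ds.group, t_variant)
    n = ds.n_features
    valid = np.isfinite(p)
    q = np.full(n, np.nan)
    if valid.any():
        q[valid] = qvalues(p[valid], pi0="auto").q_values
    select = valid & (q < bt_fdr)
    # rank significant set by t P-value; missing t -> rank last via +inf
    rank_key = np.where(np.isfinite(t_p), t_p, np.inf)
    return _assemble(ds, "iEVORA", stat, p, bt_fdr, rank_p=rank_key,
                     select=select, extras={"t_stat": t_stat, "t_p": t_p})


def run_diffvar(ds: MethylationDataset, deviation: str = "absolute",
                fdr: float = 0.05,
                prior: ModeratedVariancePrior | None = None,
                clip_epsilon: float = DEFAULT_CLIP_EPSILON) -> DVResultTable:
    """Empirical-Bayes Levene-type test (moderated t on M-value deviations).

    Per feature, samples' absolute (or squared) deviations from their own
    group's mean M-value are compared between groups with a moderated
    two-sample t-test; the variance prior is fitted across all features
    (pass ``prior`` to override, e.g. ``d0=0`` for the ordinary t).
    """
    if deviation not in ("absolute", "squared"):
        raise ValueError("deviation must be 'absolute' or 'squared'")
    mv = to_mvalues(ds, clip_epsilon)
    g = _group_summaries(mv.values, ds.group)
    z = np.full_like(mv.values, np.nan)
    for grp in (0, 1):
        cols = ds.group == grp
        dev = mv.values[:, cols] - g[grp][1][:, None]
        z[:, cols] = np.abs(dev) if deviation == "absolute" else dev**2
    zg = _group_summaries(z, ds.group)
    n0, zm0, _, zss0 = zg[0]
    n1, zm1, _, zss1 = zg[1]
    valid = (n0 >= MIN_PER_GROUP) & (n1 >= MIN_PER_GROUP)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = np.where(valid, n0 + n1 - 2.0, np.nan)
        s2 = np.where(valid, (zss0 + zss1) / (n0 + n1 - 2.0), np.nan)
    stat, p, _ = _moderated_t(zm1 - zm0, s2, df, n0, n1, prior)
    return _assemble(ds, "DiffVar", stat, p, fdr)


def run_jdmdv(ds: MethylationDataset, fdr: float = 0.05,
              clip_epsilon: float = DEFAULT_CLIP_EPSILON) -> DVResultTable:
    """Joint 2-df score test for group effects on mean and variance.

    Works on M-values under the location-scale regression
    ``y = mu + beta*x + eps`` with ``Var(eps) = sigma^2 * exp(gamma*x)``,
    x in {0, 1}.  The score statistic for H0: beta = gamma = 0 (with mu and
    sigma^2 profiled out) is referred to chi-square with 2 df.
    """
    mv = to_mvalues(ds, clip_epsilon)
    Y = mv.values
    finite = ~np.isnan(Y)
    in1 = (ds.group == 1)[None, :] & finite
    in0 = (ds.group == 0)[None, :] & finite
    n1 = in1.sum(axis=1).astype(float)
    n0 = in0.sum(axis=1).astype(float)
    N = n0 + n1
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.nansum(np.where(finite, Y, 0.0), axis=1) / N
        resid = np.where(finite, Y - ybar[:, None], 0.0)
        sigma2 = (resid**2).sum(axis=1) / N          # MLE under H0
        ybar1 = np.where(in1, Y, 0.0).sum(axis=1) / n1
        ybar0 = np.where(in0, Y, 0.0).sum(axis=1) / n0
        ss1 = np.where(in1, resid, 0.0)
        ss1 = (ss1**2).sum(axis=1)
        # efficient score statistic: mean and log-variance parts decouple
        u_gamma = 0.5 * (ss1 / sigma2 - n1)
        stat_mean = n0 * n1 * (ybar1 - ybar0) ** 2 / (N * sigma2)
        stat_var = 2.0 * N * u_gamma**2 / (n0 * n1)
        stat = stat_mean + stat_var
    valid = (n0 >= MIN_PER_GROUP) & (n1 >= MIN_PER_GROUP) & (sigma2 > 0)
    stat = np.where(valid, stat, np.nan)
    p = np.full(ds.n_features, np.nan)
    p[valid] = stats.chi2.sf(stat[valid], df=2)
    return _assemble(ds, "JDMDV", stat, p, fdr)


def run_gamlss_ls(ds: MethylationDataset, fdr: float = 0.05,
                  clip_epsilon: float = DEFAULT_CLIP_EPSILON) -> DVResultTable:
    """Nested Gaussian location-scale LRTs on M-values.

    Three closed-form fits per feature: common mean/variance (M0), group
    means with common variance (M1), group means and group variances (M2).
    LRT1 = 2(l1 - l0) tests the mean, LRT2 = 2(l2 - l1) tests variance given
    the mean; both are referred to chi-square with 1 df and converted to
    q-values separately.  A feature is significant when either q-value is
    below ``fdr``; the significant set is ranked by the variance (DV)
    P-value.  There is no variance-only-vs-null comparison.
    """
    mv = to_mvalues(ds, clip_epsilon)
    g = _group_summaries(mv.values, ds.group)
    n0, m0, _, ss0 = g[0]
    n1, m1, _, ss1 = g[1]
    N = n0 + n1
    finite = ~np.isnan(mv.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = np.nansum(np.where(finite, mv.values, 0.0), axis=1) / N
        ss_tot = (np.where(finite, mv.values - grand[:, None], 0.0) ** 2).sum(axis=1)
        sig2_0 = ss_tot / N                 # M0 MLE variance
        sig2_1 = (ss0 + ss1) / N            # M1 (within-group) MLE variance
        sig2_g0 = ss0 / n0                  # M2 group variances
        sig2_g1 = ss1 / n1
        lrt1 = N * np.log(sig2_0 / sig2_1)
        lrt2 = N * np.log(sig2_1) - n0 * np.log(sig2_g0) - n1 * np.log(sig2_g1)
    valid = ((n0 >= MIN_PER_GROUP) & (n1 >= MIN_PER_GROUP)
             & (sig2_g0 > 0) & (sig2_g1 > 0))
    lrt1 = np.where(valid, np.maximum(lrt1, 0.0), np.nan)
    lrt2 = np.where(valid, np.maximum(lrt2, 0.0), np.nan)
    n = ds.n_features
    p_mean = np.full(n, np.nan)
    p_dv = np.full(n, np.nan)
    p_mean[valid] = stats.chi2.sf(lrt1[valid], df=1)
    p_dv[valid] = stats.chi2.sf(lrt2[valid], df=1)
    q_mean = np.full(n, np.nan)
    q_dv = np.full(n, np.nan)
    if valid.any():
        q_mean[valid] = qvalues(p_mean[valid], pi0="auto").q_values
        q_dv[valid] = qvalues(p_dv[valid], pi0="auto").q_values
    select = valid & ((q_mean < fdr) | (q_dv < fdr))
    return _assemble(
        ds, "GAMLSS", lrt2, p_dv, fdr, rank_p=p_dv, select=select,
        extras={"p_mean": p_mean, "p_dv": p_dv, "q_mean": q_mean, "q_dv": q_dv},
    )


def run_ttest_dmc(ds: MethylationDataset, fdr: float = 0.05,
                  prior: ModeratedVariancePrior | None = None) -> DVResultTable:
    """Moderated t-test on beta values: the differential-mean baseline."""
    g = _group_summaries(ds.values, ds.group)
    n0, m0, _, ss0 = g[0]
    n1, m1, _, ss1 = g[1]
    valid = (n0 >= 2) & (n1 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = np.where(valid, n0 + n1 - 2.0, np.nan)
        s2 = np.where(valid, (ss0 + ss1) / (n0 + n1 - 2.0), np.nan)
    stat, p, _ = _moderated_t(m1 - m0, s2, df, n0, n1, prior)
    return _assemble(ds, "TTEST", stat, p, fdr)


#: Registry used by the benchmark and the CLI; every entry takes (ds, fdr).
ALGORITHMS = {
    "bt": run_bt,
    "ievora": lambda ds, fdr=0.05: run_ievora(ds, bt_fdr=fdr),
    "diffvar": lambda ds, fdr=0.05: run_diffvar(ds, fdr=fdr),
    "jdmdv": run_jdmdv,
    "gamlss": run_gamlss_ls,
    "ttest": run_ttest_dmc,
}
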