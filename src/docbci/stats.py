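"""Nonparametric group-contrast battery.

Between-group comparisons use the Wilcoxon rank-sum test, within-group
(task vs rest) comparisons the Wilcoxon signed-rank test; demographic
and accuracy comparisons use Welch's unequal-variance t (from raw
samples or mean/SD/n summaries) and the Pearson chi-square for 2x2
counts; attention-vs-CRS-R association uses Spearman's rank correlation
with a seeded percentile-bootstrap CI.

Both rank tests use midranks for ties and switch between exact
enumeration (small samples) and a tie-corrected normal approximation
with continuity correction.  Exact p-values match full-enumeration
oracles by construction; scipy implementations serve as independent
cross-checks in the test suite, not as the implementation, because
scipy's exact modes decline ties.  Quartile summaries use linear
(type-7) interpolation throughout.  No multiple-testing correction is
applied; the number of contrasts is reported alongside.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupContrast",
    "CorrelationResult",
    "quartiles",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "welch_t",
    "pearson_chi2",
    "spearman_rho",
    "build_contrast_tables",
    "contrast_pvalues",
]

EXACT_RANKSUM_MAX = 10   # exact enumeration if both groups <= this
EXACT_SIGNRANK_MAX = 15  # exact enumeration if nonzero pairs <= this
EXACT_SPEARMAN_MAX = 9   # exact permutation if n <= this


@dataclass
class GroupContrast:
    """One statistical comparison: statistic, p, and summaries."""

    label: str
    stat_name: str
    statistic: float
    p: float
    n: Tuple[int, ...]
    z: Optional[float] = None
    method: str = ""
    summaries: Dict[str, Tuple[float, ...]] = field(default_factory=dict)
    extra: Dict[str, float] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    rho: float
    p: float
    n: int
    ci_low: float
    ci_high: float
    method: str = ""


def quartiles(x: Sequence[float]) -> Tuple[float, float, float]:
    """median, Q1, Q3 with linear (type-7) interpolation."""
    q1, med, q3 = np.percentile(np.asarray(x, dtype=float), [25, 50, 75])
    return float(med), float(q1), float(q3)


def _norm_sf2(z: float) -> float:
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float],
                      exact: Optional[bool] = None,
                      label: str = "") -> GroupContrast:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) with midranks.

    Exact enumeration of all C(n+m, n) rank splits when both samples
    have <= 10 observations, otherwise a normal approximation with tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 3 or ny < 3:
        raise ValueError("each sample needs n >= 3")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[:nx].sum())
    n = nx + ny
    mu = nx * (n + 1) / 2.0

    if np.ptp(combined) == 0:
        warnings.warn("all values identical in both samples; p = 1")
        return GroupContrast(label=label, stat_name="W", statistic=w, p=1.0,
                             n=(nx, ny), z=0.0, method="degenerate",
                             summaries={"x": quartiles(x), "y": quartiles(y)})

    if exact is None:
        exact = max(nx, ny) <= EXACT_RANKSUM_MAX
    if exact:
        sums = np.fromiter(
            (sum(c) for c in itertools.combinations(ranks, nx)),
            dtype=float)
        eps = 1e-9
        p_low = np.mean(sums <= w + eps)
        p_high = np.mean(sums >= w - eps)
        p = float(min(1.0, 2.0 * min(p_low, p_high)))
        z = None
        method = "exact"
    else:
        _, counts = np.unique(combined, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        cc = 0.5 * np.sign(w - mu)
        z = (w - mu - cc) / np.sqrt(var) if var > 0 else 0.0
        p = _norm_sf2(z)
        method = "normal_tie_corrected"
    # report a Z on the same convention even in exact mode (descriptive)
    z_desc = (w - mu) / np.sqrt(nx * ny * (n + 1) / 12.0)
    return GroupContrast(label=label, stat_name="W", statistic=w, p=p,
                         n=(nx, ny), z=float(z if z is not None else z_desc),
                         method=method,
                         summaries={"x": quartiles(x), "y": quartiles(y)})


def wilcoxon_signed_rank(pre: Sequence[float], post: Sequence[float],
                         exact: Optional[bool] = None,
                         label: str = "") -> GroupContrast:
    """Two-sided Wilcoxon signed-rank on paired samples.

    Zero differences are dropped (classical procedure); |differences|
    receive midranks.  The reported statistic is the sum of negative
    ranks (0 when every post > pre); W+ and a Z value are attached.
    Exact enumeration of all 2^n sign assignments when n <= 15.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired samples must have equal length")
    d = post - pre
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences zero; p = 1")
        return GroupContrast(label=label, stat_name="W-", statistic=0.0,
                             p=1.0, n=(0,), z=0.0, method="degenerate",
                             summaries={"delta": (0.0, 0.0, 0.0)})
    if n < 5:
        warnings.warn("fewer than 5 nonzero pairs; exact p is coarse")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    s = float(ranks.sum())
    d_obs = w_plus - w_minus

    if exact is None:
        exact = n <= EXACT_SIGNRANK_MAX
    if exact:
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1)
        wp = signs @ ranks  # distribution of W+ over all sign patterns
        dd = 2.0 * wp - s
        p = float(min(1.0, np.mean(np.abs(dd) >= abs(d_obs) - 1e-9)))
        method = "exact"
    else:
        var = float(np.sum(ranks**2)) / 4.0
        cc = 0.5 * np.sign(w_plus - s / 2.0)
        z = (w_plus - s / 2.0 - cc) / np.sqrt(var) if var > 0 else 0.0
        p = _norm_sf2(z)
        method = "normal_tie_corrected"
    z_desc = (w_plus - s / 2.0) / np.sqrt(max(np.sum(ranks**2) / 4.0, 1e-12))
    return GroupContrast(
        label=label, stat_name="W-", statistic=w_minus, p=p, n=(n,),
        z=float(z_desc), method=method,
        summaries={"delta": quartiles(post - pre)},
        extra={"w_plus": w_plus, "w_minus": w_minus})


def welch_t(x: Union[Sequence[float], Tuple[float, float, int]],
            y: Union[Sequence[float], Tuple[float, float, int]],
            pooled: bool = False,
            label: str = "") -> GroupContrast:
    """Two-sided independent-samples t test, Welch (unequal variance) by
    default; accepts raw samples or (mean, SD, n) summaries."""
    def _stats(s):
        if isinstance(s, tuple) and len(s) == 3:
            return float(s[0]), float(s[1]), int(s[2])
        arr = np.asarray(s, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = _stats(x)
    m2, s2, n2 = _stats(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 == 0 and s2 == 0:
        raise ValueError("zero variance in both groups; t undefined")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2,
                                   equal_var=pooled)
    return GroupContrast(
        label=label, stat_name="t", statistic=float(res.statistic),
        p=float(res.pvalue), n=(n1, n2),
        method="pooled" if pooled else "welch",
        summaries={"x": (m1, s1), "y": (m2, s2)})


def pearson_chi2(table: Sequence[Sequence[float]],
                 label: str = "") -> GroupContrast:
    """Pearson chi-square for a 2x2 table, without continuity
    correction: n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)).  The Fisher exact
    p is attached."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("zero margin; chi-square undefined")
    chi2 = n * (a * d - b * c) ** 2 / np.prod(margins)
    p = float(sps.chi2.sf(chi2, df=1))
    fisher_p = float(sps.fisher_exact(np.round(t).astype(int))[1])
    return GroupContrast(label=label, stat_name="chi2",
                         statistic=float(chi2), p=p, n=(int(a + b), int(c + d)),
                         method="pearson_uncorrected",
                         extra={"fisher_p": fisher_p})


def spearman_rho(a: Sequence[float], b: Sequence[float],
                 n_boot: int = 2000, seed: int = 0,
                 exact: Optional[bool] = None) -> CorrelationResult:
    """Midrank Spearman correlation.

    p via exact permutation for n <= 9, else via the t approximation;
    95% CI via seeded percentile bootstrap.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("samples must have equal length")
    n = a.size
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input; rho undefined")
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    rho = float(np.corrcoef(ra, rb)[0, 1])

    if exact is None:
        exact = n <= EXACT_SPEARMAN_MAX
    if exact:
        ra_c = ra - ra.mean()
        rb_c = rb - rb.mean()
        denom = np.sqrt((ra_c**2).sum() * (rb_c**2).sum())
        perms = np.array(list(itertools.permutations(rb_c)))
        rhos = perms @ ra_c / denom
        p = float(min(1.0, np.mean(np.abs(rhos) >= abs(rho) - 1e-12)))
        method = "exact_permutation"
    else:
        t = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-12))
        p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2)))
        method = "t_approx"

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        while np.ptp(a[idx]) == 0 or np.ptp(b[idx]) == 0:
            idx = rng.integers(0, n, size=n)
        boots[i] = np.corrcoef(sps.rankdata(a[idx]),
                               sps.rankdata(b[idx]))[0, 1]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(rho=rho, p=p, n=n, ci_low=float(lo),
                             ci_high=float(hi), method=method)


# --- report assembly -------------------------------------------------

CONTRAST_REGIONS = ("frontal", "parietal")


def _cell(rpt: pd.DataFrame, group: str, condition: str, region: str,
          band: str) -> pd.Series:
    sel = rpt[(rpt.group == group) & (rpt.condition == condition)
              & (rpt.region == region) & (rpt.band == band)]
    return sel.set_index("subject_id")["rel_power"]


def build_contrast_tables(rpt: pd.DataFrame,
                          sessions: Optional[pd.DataFrame] = None,
                          meta: Optional[pd.DataFrame] = None,
                          bands: Sequence[str] = ("delta", "theta", "alpha",
                                                  "beta", "gamma"),
                          regions: Sequence[str] = CONTRAST_REGIONS
                          ) -> Dict[str, pd.DataFrame]:
    """Assemble the report tables from tidy inputs.

    For each of the region x band blocks: within-group signed-rank
    (rest vs task) per group, between-group rank-sum at rest, at task,
    and on the per-subject delta = task - rest.  Optionally a
    demographics table (Welch t / chi-square), the accuracy contrast and
    the attention-vs-CRS-R correlation when session results and
    metadata are supplied.
    """
    within_rows, between_rows, skipped = [], [], []
    groups = ("MCS", "UWS")
    for region in regions:
        for band in bands:
            cells = {}
            ok = True
            for g in groups:
                rest = _cell(rpt, g, "rest", region, band)
                task = _cell(rpt, g, "task", region, band)
                common = rest.index.intersection(task.index)
                if len(common) < 5:
                    skipped.append({"region": region, "band": band,
                                    "group": g,
                                    "reason": f"only {len(common)} complete"})
                    ok = False
                    continue
                cells[g] = (rest.loc[common], task.loc[common])
            if not ok:
                continue
            for g in groups:
                rest, task = cells[g]
                gc = wilcoxon_signed_rank(rest.to_numpy(), task.to_numpy(),
                                          label=f"{region}_{band}_{g}")
                med_r = quartiles(rest)
                med_t = quartiles(task)
                med_d = quartiles(task.to_numpy() - rest.to_numpy())
                within_rows.append({
                    "region": region, "band": band, "group": g,
                    "n": len(rest),
                    "rest_median": med_r[0], "rest_q1": med_r[1],
                    "rest_q3": med_r[2],
                    "task_median": med_t[0], "task_q1": med_t[1],
                    "task_q3": med_t[2],
                    "w_minus": gc.extra["w_minus"],
                    "w_plus": gc.extra["w_plus"],
                    "z": gc.z, "p": gc.p,
                    "delta_median": med_d[0], "delta_q1": med_d[1],
                    "delta_q3": med_d[2]})
            for comparison in ("rest", "task", "delta"):
                if comparison == "delta":
                    x = cells["MCS"][1].to_numpy() - cells["MCS"][0].to_numpy()
                    y = cells["UWS"][1].to_numpy() - cells["UWS"][0].to_numpy()
                else:
                    k = 0 if comparison == "rest" else 1
                    x = cells["MCS"][k].to_numpy()
                    y = cells["UWS"][k].to_numpy()
                gc = wilcoxon_rank_sum(
                    x, y, label=f"{region}_{band}_{comparison}")
                between_rows.append({
                    "region": region, "band": band,
                    "comparison": comparison, "w": gc.statistic,
                    "z": gc.z, "p": gc.p,
                    "mcs_median": quartiles(x)[0],
                    "uws_median": quartiles(y)[0]})
    out: Dict[str, pd.DataFrame] = {
        "table2_within": pd.DataFrame(within_rows),
        "table2_between": pd.DataFrame(between_rows),
        "skipped": pd.DataFrame(skipped),
    }

    if meta is not None and sessions is not None:
        t1_rows = []
        mcs = meta[meta.group == "MCS"]
        uws = meta[meta.group == "UWS"]
        for var, col in (("age_years", "age"),
                         ("duration_months", "duration_months")):
            gc = welch_t(uws[col].to_numpy(), mcs[col].to_numpy(), label=var)
            t1_rows.append({"variable": var, "stat_name": "t",
                            "statistic": gc.statistic, "p": gc.p,
                            "uws_mean": gc.summaries["x"][0],
                            "uws_sd": gc.summaries["x"][1],
                            "mcs_mean": gc.summaries["y"][0],
                            "mcs_sd": gc.summaries["y"][1]})
        tab = [[int((uws.sex == "M").sum()),
                int((uws.sex == "F").sum())],
               [int((mcs.sex == "M").sum()),
                int((mcs.sex == "F").sum())]]
        try:
            gc = pearson_chi2(tab, label="sex")
            t1_rows.append({"variable": "sex_male", "stat_name": "chi2",
                            "statistic": gc.statistic, "p": gc.p,
                            "uws_mean": tab[0][0], "uws_sd": np.nan,
                            "mcs_mean": tab[1][0], "mcs_sd": np.nan})
        except ValueError:
            pass
        if "error" in sessions:
            err = sessions["error"].fillna("")
            ses = sessions[err == ""]
        else:
            ses = sessions
        s_u = ses[ses.group == "UWS"]["n_success"].to_numpy()
        s_m = ses[ses.group == "MCS"]["n_success"].to_numpy()
        gc = welch_t(s_u, s_m, label="mi_successes")
        t1_rows.append({"variable": "successful_mi_trials",
                        "stat_name": "t", "statistic": gc.statistic,
                        "p": gc.p,
                        "uws_mean": gc.summaries["x"][0],
                        "uws_sd": gc.summaries["x"][1],
                        "mcs_mean": gc.summaries["y"][0],
                        "mcs_sd": gc.summaries["y"][1]})
        out["table1"] = pd.DataFrame(t1_rows)

        acc_u = ses[ses.group == "UWS"]["accuracy_pct"].to_numpy()
        acc_m = ses[ses.group == "MCS"]["accuracy_pct"].to_numpy()
        gc = welch_t(acc_u, acc_m, label="accuracy")
        out["accuracy_contrast"] = pd.DataFrame([{
            "uws_mean_pct": gc.summaries["x"][0],
            "uws_sd": gc.summaries["x"][1],
            "mcs_mean_pct": gc.summaries["y"][0],
            "mcs_sd": gc.summaries["y"][1],
            "t": gc.statistic, "p": gc.p}])

        corr = spearman_rho(ses["mean_attention_index"].to_numpy(),
                            ses["crs_r"].to_numpy())
        out["attention_crsr_correlation"] = pd.DataFrame([{
            "rho": corr.rho, "p": corr.p, "n": corr.n,
            "ci_low": corr.ci_low, "ci_high": corr.ci_high,
            "method": corr.method}])
    return out


def contrast_pvalues(tables: Dict[str, pd.DataFrame]) -> np.ndarray:
    """All p-values of the region x band contrast battery (within-group
    and between-group), for calibration studies."""
    ps = []
    if len(tables.get("table2_within", [])):
        ps.append(tables["table2_within"]["p"].to_numpy())
    if len(tables.get("table2_between", [])):
        ps.append(tables["table2_between"]["p"].to_numpy())
    return np.concatenate(ps) if ps else np.array([])
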