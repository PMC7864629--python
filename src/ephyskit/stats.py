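"""Statistical tests for the phenotyping pipeline.

Implements, self-contained over numpy/scipy distributions, the tests the
analysis uses: Student/Welch/paired t-tests, one-way ANOVA, two-way ANOVA
with interaction (Type III partial sums of squares by default, Type II by
flag), univariate mixed-design repeated-measures ANOVA (one between-subjects
factor crossed with one within-subjects factor), and Fisher's protected LSD
post hoc.  Sums of squares are computed by explicit least-squares model
comparison with sum-to-zero (effects) coding, so every number is
reproducible by a hand-built projection.

Conventions: p-values are two-sided; repeated-measures designs require
complete within-subject series (incomplete subjects are dropped with a
count returned in the result); no sphericity correction is applied by
default (Greenhouse-Geisser optional).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "AnovaResult",
    "PosthocResult",
    "t_test",
    "one_way_anova",
    "two_way_anova",
    "rm_anova",
    "fisher_plsd",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    mean_diff: float

    def __iter__(self):
        return iter((self.t, self.df, self.p))


@dataclass
class AnovaResult:
    """Effect table: one row per effect plus the error stratum/strata.

    ``table`` has columns ss, df, ms, F, p indexed by effect name.  For
    repeated-measures designs the relevant error stratum for each effect is
    recorded in ``error_terms``.
    """

    table: pd.DataFrame
    design: str
    error_terms: dict[str, str] = field(default_factory=dict)
    n_dropped_subjects: int = 0

    def f_string(self, effect: str, decimals: int = 2) -> str:
        """Report an effect the way ephys papers print it,
        e.g. ``F_(2,400) = 7.20, p = 0.0008``."""
        row = self.table.loc[effect]
        err = self.error_terms.get(effect, "error")
        df_err = int(self.table.loc[err, "df"])
        return (f"F_({int(row['df'])},{df_err}) = {row['F']:.{decimals}f}, "
                f"p = {row['p']:.4g}")

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


@dataclass
class PosthocResult:
    """Pairwise comparisons from Fisher's protected LSD."""

    table: pd.DataFrame  # group_a, group_b, mean_diff, lsd, t, p, significant
    protected: bool
    omnibus_p: float

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        if self.table.empty:
            return []
        sig = self.table[self.table["significant"]]
        return list(zip(sig["group_a"], sig["group_b"]))


# ---------------------------------------------------------------------------
# t-test

def t_test(x, y, paired: bool = False, welch: bool = False) -> TTestResult:
    """Two-sided t-test.

    Unpaired defaults to the pooled-variance Student form; ``welch=True``
    uses the Welch-Satterthwaite approximation.  Paired tests the mean of
    the differences.  Zero variance with equal means returns t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired t-test requires equal-length samples")
        d = x - y
        n = d.size
        if n < 2:
            raise ValueError("need at least 2 pairs")
        sd = d.std(ddof=1)
        df = n - 1
        if sd == 0:
            t = 0.0 if d.mean() == 0 else np.inf * np.sign(d.mean())
        else:
            t = d.mean() / (sd / np.sqrt(n))
        return TTestResult(float(t), float(df), _t_p(t, df), float(d.mean()))

    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if welch:
        se2 = vx / nx + vy / ny
        if se2 == 0:
            return TTestResult(0.0 if diff == 0 else np.inf * np.sign(diff),
                               float(nx + ny - 2), 1.0 if diff == 0 else 0.0,
                               float(diff))
        df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        t = diff / np.sqrt(se2)
    else:
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        if sp2 == 0:
            return TTestResult(0.0 if diff == 0 else np.inf * np.sign(diff),
                               float(df), 1.0 if diff == 0 else 0.0,
                               float(diff))
        t = diff / np.sqrt(sp2 * (1 / nx + 1 / ny))
    return TTestResult(float(t), float(df), _t_p(t, df), float(diff))


def _t_p(t: float, df: float) -> float:
    if not np.isfinite(t):
        return 0.0
    return float(2.0 * sps.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# design-matrix helpers (sum-to-zero coding)

def _effects_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero coded columns for a categorical factor.

    k levels -> k-1 columns; the last level is coded -1 in every column.
    """
    levels = list(pd.unique(labels))
    k = len(levels)
    if k < 2:
        raise ValueError("factor needs at least 2 levels")
    idx = {lv: i for i, lv in enumerate(levels)}
    X = np.zeros((labels.size, k - 1))
    for row, lab in enumerate(labels):
        i = idx[lab]
        if i < k - 1:
            X[row, i] = 1.0
        else:
            X[row, :] = -1.0
    return X, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


# ---------------------------------------------------------------------------
# one-way ANOVA

def one_way_anova(values, groups) -> AnovaResult:
    """Fixed-effects one-way ANOVA; with two groups F equals t-squared of
    the pooled-variance t-test exactly."""
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.size != g.size:
        raise ValueError("values and groups must align")
    levels = pd.unique(g)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    ss_between = 0.0
    for lv in levels:
        sel = y[g == lv]
        if sel.size == 0:
            raise ValueError(f"empty group {lv!r}")
        ss_between += sel.size * (sel.mean() - grand) ** 2
    ss_error = ss_total - ss_between
    df_b, df_e = len(levels) - 1, y.size - len(levels)
    if df_e <= 0:
        raise ValueError("no error degrees of freedom")
    ms_b, ms_e = ss_between / df_b, ss_error / df_e
    F = ms_b / ms_e if ms_e > 0 else (0.0 if ms_b == 0 else np.inf)
    p = float(sps.f.sf(F, df_b, df_e)) if np.isfinite(F) else 0.0
    table = pd.DataFrame(
        {"ss": [ss_between, ss_error], "df": [df_b, df_e],
         "ms": [ms_b, ms_e], "F": [F, np.nan], "p": [p, np.nan]},
        index=["group", "error"])
    return AnovaResult(table, design="one_way",
                       error_terms={"group": "error"})


# ---------------------------------------------------------------------------
# two-way ANOVA

def two_way_anova(data: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str, ss_type: int = 3) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction on possibly unbalanced
    cells.

    Type III (default): each effect's SS is the reduction in residual SS
    when its sum-to-zero-coded columns are added last to the full model.
    Type II: main effects adjusted for each other but not the interaction.
    Empty cells raise, naming the cell.
    """
    if ss_type not in (2, 3):
        raise ValueError("ss_type must be 2 or 3")
    y = np.asarray(data[value], dtype=float)
    a = np.asarray(data[factor_a])
    b = np.asarray(data[factor_b])
    for la in pd.unique(a):
        for lb in pd.unique(b):
            if not np.any((a == la) & (b == lb)):
                raise ValueError(
                    f"empty cell: {factor_a}={la}, {factor_b}={lb}")
    Xa, lev_a = _effects_code(a)
    Xb, lev_b = _effects_code(b)
    Xab = np.column_stack([Xa[:, i] * Xb[:, j]
                           for i in range(Xa.shape[1])
                           for j in range(Xb.shape[1])])
    ones = np.ones((y.size, 1))
    full = np.column_stack([ones, Xa, Xb, Xab])
    rss_full = _rss(full, y)
    df_error = y.size - full.shape[1]
    if df_error <= 0:
        raise ValueError("no error degrees of freedom")

    def drop(*parts):
        return _rss(np.column_stack([ones, *parts]), y)

    if ss_type == 3:
        ss_a = drop(Xb, Xab) - rss_full
        ss_b = drop(Xa, Xab) - rss_full
    else:  # Type II: main effects ignore the interaction
        rss_ab_base = drop(Xa, Xb)
        ss_a = drop(Xb) - rss_ab_base
        ss_b = drop(Xa) - rss_ab_base
    ss_ab = drop(Xa, Xb) - rss_full
    ss_a, ss_b, ss_ab = (max(s, 0.0) for s in (ss_a, ss_b, ss_ab))

    rows, names = [], []
    ms_e = rss_full / df_error
    for name, ss, df in [(factor_a, ss_a, len(lev_a) - 1),
                         (factor_b, ss_b, len(lev_b) - 1),
                         (f"{factor_a}:{factor_b}", ss_ab,
                          (len(lev_a) - 1) * (len(lev_b) - 1))]:
        ms = ss / df
        F = ms / ms_e if ms_e > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(F, df, df_error)) if np.isfinite(F) else 0.0
        rows.append([ss, df, ms, F, p])
        names.append(name)
    rows.append([rss_full, df_error, ms_e, np.nan, np.nan])
    names.append("error")
    table = pd.DataFrame(rows, index=names,
                         columns=["ss", "df", "ms", "F", "p"])
    return AnovaResult(table, design="two_way",
                       error_terms={n: "error" for n in names[:3]})


# ---------------------------------------------------------------------------
# repeated-measures (mixed-design) ANOVA

def rm_anova(data: pd.DataFrame, value: str, between: str, within: str,
             subject: str, gg_correction: bool = False) -> AnovaResult:
    """Univariate mixed-design ANOVA: one between-subjects factor crossed
    with one within-subjects factor.

    The between effect is tested against subject-within-group variation
    (a one-way ANOVA on subject means); the within and interaction effects
    are tested against the subject-by-within residual, computed from the
    within-subject deviations by partial (Type III) sums of squares.
    Subjects with incomplete within-factor series are dropped (count kept
    in the result).  ``gg_correction`` applies Greenhouse-Geisser epsilon
    to the within-stratum dfs.
    """
    df = data[[value, between, within, subject]].dropna().copy()
    w_levels = list(pd.unique(df[within]))
    t = len(w_levels)
    if t < 2:
        raise ValueError("within factor needs at least 2 levels")

    # keep complete subjects only (one observation per within level)
    counts = df.groupby(subject)[within].nunique()
    sizes = df.groupby(subject).size()
    complete = counts[(counts == t) & (sizes == t)].index
    n_dropped = counts.size - complete.size
    df = df[df[subject].isin(complete)]
    if df.empty:
        raise ValueError("no complete subjects")

    # subject-level frame
    subj = df.groupby(subject).agg(
        mean=(value, "mean"), grp=(between, "first")).reset_index()
    group_sizes = subj.groupby("grp").size()
    if (group_sizes < 2).any() or group_sizes.size < 2:
        raise ValueError("need >= 2 subjects in each of >= 2 groups")

    n_subj = len(subj)
    a = group_sizes.size
    grand = df[value].mean()

    # between stratum: one-way ANOVA on subject means, scaled by t
    sm = subj["mean"].to_numpy()
    gm = subj["grp"].to_numpy()
    grand_sm = sm.mean()
    ss_between_grp = t * sum(
        (gm == lv).sum() * (sm[gm == lv].mean() - grand_sm) ** 2
        for lv in pd.unique(gm))
    ss_subj = t * sum(
        ((sm[gm == lv] - sm[gm == lv].mean()) ** 2).sum()
        for lv in pd.unique(gm))
    df_grp, df_subj = a - 1, n_subj - a

    # within stratum: deviations from each subject's own mean
    df = df.merge(subj[[subject, "mean"]], on=subject, how="left")
    d = (df[value] - df["mean"]).to_numpy(dtype=float)
    Xw, lev_w = _effects_code(df[within].to_numpy())
    Xg, lev_g = _effects_code(df[between].to_numpy())
    Xgw = np.column_stack([Xg[:, i] * Xw[:, j]
                           for i in range(Xg.shape[1])
                           for j in range(Xw.shape[1])])
    ones = np.ones((d.size, 1))
    full = np.column_stack([ones, Xw, Xgw])
    rss_full = _rss(full, d)
    ss_within = _rss(np.column_stack([ones, Xgw]), d) - rss_full
    ss_inter = _rss(np.column_stack([ones, Xw]), d) - rss_full
    ss_within, ss_inter = max(ss_within, 0.0), max(ss_inter, 0.0)
    df_w = t - 1
    df_gw = (a - 1) * (t - 1)
    df_err_w = (n_subj - a) * (t - 1)
    ss_err_w = rss_full

    eps = 1.0
    if gg_correction:
        eps = _gg_epsilon(df, value, within, subject, w_levels)

    ms_grp = ss_between_grp / df_grp
    ms_subj = ss_subj / df_subj
    F_grp = ms_grp / ms_subj if ms_subj > 0 else (
        0.0 if ms_grp == 0 else np.inf)
    p_grp = float(sps.f.sf(F_grp, df_grp, df_subj)) if np.isfinite(F_grp) \
        else 0.0

    ms_w = ss_within / df_w
    ms_gw = ss_inter / df_gw
    ms_err = ss_err_w / df_err_w if df_err_w > 0 else np.nan
    F_w = ms_w / ms_err if ms_err > 0 else (0.0 if ms_w == 0 else np.inf)
    F_gw = ms_gw / ms_err if ms_err > 0 else (0.0 if ms_gw == 0 else np.inf)
    p_w = float(sps.f.sf(F_w, df_w * eps, df_err_w * eps)) \
        if np.isfinite(F_w) else 0.0
    p_gw = float(sps.f.sf(F_gw, df_gw * eps, df_err_w * eps)) \
        if np.isfinite(F_gw) else 0.0

    table = pd.DataFrame(
        [[ss_between_grp, df_grp, ms_grp, F_grp, p_grp],
         [ss_subj, df_subj, ms_subj, np.nan, np.nan],
         [ss_within, df_w, ms_w, F_w, p_w],
         [ss_inter, df_gw, ms_gw, F_gw, p_gw],
         [ss_err_w, df_err_w, ms_err, np.nan, np.nan]],
        index=[between, "subject(group)", within, f"{between}:{within}",
               "subject:within"],
        columns=["ss", "df", "ms", "F", "p"])
    return AnovaResult(
        table, design="rm",
        error_terms={between: "subject(group)",
                     within: "subject:within",
                     f"{between}:{within}": "subject:within"},
        n_dropped_subjects=int(n_dropped))


def _gg_epsilon(df: pd.DataFrame, value: str, within: str, subject: str,
                w_levels: list) -> float:
    wide = df.pivot_table(index=subject, columns=within, values=value)
    wide = wide[w_levels].to_numpy()
    S = np.cov(wide, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (np.sum(S ** 2) - 2 * k * np.sum(row_means ** 2)
                     + k * k * mean_all ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


# ---------------------------------------------------------------------------
# Fisher's protected LSD

def fisher_plsd(values, groups, anova: AnovaResult | None = None,
                alpha: float = 0.05, effect: str = "group",
                protected: bool = True) -> PosthocResult:
    """Fisher's protected least-significant-difference pairwise comparisons.

    ``Protected``: the pairwise tests run only when the omnibus ANOVA effect
    is significant at ``alpha``; otherwise an empty table is returned.  The
    LSD criterion for groups i, j is
    t_(1-alpha/2, df_error) * sqrt(MS_error * (1/n_i + 1/n_j)) and the
    pairwise p comes from the pooled-error t statistic.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if anova is None:
        anova = one_way_anova(y, g)
    err = anova.error_terms.get(effect, "error")
    ms_error = float(anova.table.loc[err, "ms"])
    df_error = float(anova.table.loc[err, "df"])
    omnibus_p = anova.p_value(effect)
    cols = ["group_a", "group_b", "mean_diff", "lsd", "t", "p", "significant"]
    if protected and not (omnibus_p < alpha):
        return PosthocResult(pd.DataFrame(columns=cols), True, omnibus_p)
    levels = list(pd.unique(g))
    tcrit = float(sps.t.ppf(1 - alpha / 2, df_error))
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            xi, xj = y[g == levels[i]], y[g == levels[j]]
            se = np.sqrt(ms_error * (1 / xi.size + 1 / xj.size))
            diff = xi.mean() - xj.mean()
            lsd = tcrit * se
            tstat = diff / se if se > 0 else 0.0
            p = _t_p(tstat, df_error)
            rows.append([levels[i], levels[j], diff, lsd, tstat, p,
                         bool(abs(diff) > lsd)])
    return PosthocResult(pd.DataFrame(rows, columns=cols), protected,
                         omnibus_p)
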