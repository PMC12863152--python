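"""Group-statistics layer: SES scoring, extreme-group split, correlations,
mixed-design repeated-measures ANCOVA, Bonferroni post hocs, transition
t-tests.

The repeated-measures ANCOVA follows the univariate (split-plot) approach of
mainstream statistics packages: subject means are analyzed in a
between-subjects model with the group factor plus the covariates, and the
within-subject deviations are analyzed in an orthonormal contrast space with
class, class x covariate, and class x group terms.  With two groups of 29 and
two covariates this yields the df pattern F(1, 54) between and F(3, 162)
within.  Covariates are mean-centered and the group factor effect-coded, so
the within-subject main effect is evaluated at the covariate means.  No
sphericity correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

GENDER_CODES = {"F": 0.0, "M": 1.0}


@dataclass
class TestResult:
    """One inferential test: statistic, df, p, effect size."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    effect_size: float = float("nan")
    effect_size_name: str = ""
    p_adjusted: float = float("nan")
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "effect": self.name,
            "statistic": self.statistic,
            "df1": self.df[0] if len(self.df) > 0 else float("nan"),
            "df2": self.df[1] if len(self.df) > 1 else float("nan"),
            "p": self.p,
            "p_adj": self.p_adjusted,
            "effect_size": self.effect_size,
            "effect_size_name": self.effect_size_name,
        }


def results_to_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


# ---------------------------------------------------------------------------
# SES composite and grouping


def ses_score(records: pd.DataFrame) -> pd.DataFrame:
    """Composite SES: family education and occupation means, z-scored, summed.

    Parental education (1-5) and occupation (1-10) are first averaged over
    the two parents into one family education and one family occupation
    score; each is standardized across the sample (sample sd, divisor n-1)
    and the two z-scores are summed into ``ses_z``.
    """
    df = records.copy()
    n = len(df)
    if n < 2:
        raise ValueError("z-scoring needs at least 2 records")
    for col, lohi in (("parent_edu_1", (1, 5)), ("parent_edu_2", (1, 5)),
                      ("parent_occ_1", (1, 10)), ("parent_occ_2", (1, 10))):
        v = df[col].to_numpy(dtype=float)
        if np.any((v < lohi[0]) | (v > lohi[1])):
            raise ValueError(f"{col} outside its scale {lohi}")
    fam_edu = df[["parent_edu_1", "parent_edu_2"]].mean(axis=1)
    fam_occ = df[["parent_occ_1", "parent_occ_2"]].mean(axis=1)
    z = {}
    for name, v in (("edu", fam_edu), ("occ", fam_occ)):
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"family {name} scores have zero variance; "
                             "SES composite undefined")
        z[name] = (v - v.mean()) / sd
    df["ses_z"] = z["edu"] + z["occ"]
    return df


def extreme_group_split(records: pd.DataFrame, fraction: float = 0.27) -> pd.DataFrame:
    """Label the top/bottom ``fraction`` of subjects by ``ses_z`` high/low.

    ``m = ceil(fraction * n)`` per tail; everyone else is ``middle``.  Ties
    at a boundary are broken by subject_id order (deterministic).
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    df = records.copy()
    n = len(df)
    m = math.ceil(fraction * n)
    if 2 * m > n:
        raise ValueError(f"2 x {m} extreme subjects exceed the sample of {n}")
    order = df.sort_values(["ses_z", "subject_id"], ascending=[False, True]).index
    group = pd.Series("middle", index=df.index)
    group.loc[order[:m]] = "high"
    group.loc[order[-m:]] = "low"
    df["group"] = group
    return df


# ---------------------------------------------------------------------------
# correlations


def correlate(x: np.ndarray, y: np.ndarray, name: str = "pearson") -> TestResult:
    """Pearson r with the two-sided t-test p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = scipy.stats.pearsonr(x, y)
    return TestResult(name=name, statistic=float(r), df=(float(x.size - 2),),
                      p=float(p), effect_size=float(r), effect_size_name="r")


def ses_parameter_correlations(param_df: pd.DataFrame, ses: pd.DataFrame,
                               dvs: tuple[str, ...] = ("duration_ms", "occurrence", "coverage"),
                               ) -> list[TestResult]:
    """SES vs each microstate parameter, per class and parameter family."""
    merged = param_df.merge(ses[["subject_id", "ses_z"]],
                            left_on="subject", right_on="subject_id")
    out = []
    for dv in dvs:
        for cls, sub in merged.groupby("class", sort=True):
            res = correlate(sub["ses_z"].to_numpy(), sub[dv].to_numpy(),
                            name=f"ses~{dv}[{cls}]")
            out.append(res)
    return out


# ---------------------------------------------------------------------------
# mixed-design repeated-measures ANCOVA


def _design_matrix(groups: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, list[str]]:
    n = groups.size
    gcodes = np.unique(groups)
    if gcodes.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(gcodes)}")
    g = np.where(groups == gcodes[0], -0.5, 0.5)
    cols = [np.ones(n), g]
    names = ["intercept", "group"]
    if covariates is not None:
        for j in range(covariates.shape[1]):
            c = covariates[:, j] - covariates[:, j].mean()
            X_try = np.column_stack(cols + [c])
            # constant or aliased covariates (e.g. gender confounded with
            # group in a tiny sample) carry no estimable information
            if np.linalg.matrix_rank(X_try) <= len(cols):
                continue
            cols.append(c)
            names.append(f"cov{j}")
    return np.column_stack(cols), names


def _sse(X: np.ndarray, Y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return float(np.sum(resid**2))


def _type3_ss(X: np.ndarray, Y: np.ndarray, term: int) -> float:
    full = _sse(X, Y)
    red = _sse(np.delete(X, term, axis=1), Y)
    return red - full


def mixed_ancova(
    param_df: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    between: str = "group",
    within: str = "class",
    covariates: tuple[str, ...] | None = ("age", "gender"),
) -> list[TestResult]:
    """Two-way mixed ANCOVA: between-subject group, within-subject class.

    ``param_df`` is the tidy subject x class table; covariate columns must be
    constant within subject (gender may be 'F'/'M' and is coded 0/1).
    Returns the group main effect, the class main effect, and the
    group x class interaction, each with partial eta squared.
    """
    wide = param_df.pivot_table(index=subject, columns=within, values=dv, sort=True)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"subjects missing a class level: {missing}")
    subj_info = (param_df.drop_duplicates(subject).set_index(subject).loc[wide.index])
    groups = subj_info[between].to_numpy()
    cov = None
    if covariates:
        cov_cols = []
        for c in covariates:
            v = subj_info[c]
            if v.dtype == object:
                v = v.map(GENDER_CODES)
            cov_cols.append(v.to_numpy(dtype=float))
        cov = np.column_stack(cov_cols)
    Y = wide.to_numpy(dtype=float)
    n, K = Y.shape
    X, names = _design_matrix(groups, cov)
    p = X.shape[1]
    if n <= p:
        raise ValueError("too few subjects for the model")

    results: list[TestResult] = []
    # between-subjects part: subject means
    ybar = Y.mean(axis=1)
    sse_b = _sse(X, ybar)
    df_err_b = n - p
    ss_g = _type3_ss(X, ybar, names.index("group"))
    f_g = (ss_g / 1) / (sse_b / df_err_b)
    results.append(TestResult(
        name=f"{between}", statistic=float(f_g), df=(1.0, float(df_err_b)),
        p=float(scipy.stats.f.sf(f_g, 1, df_err_b)),
        effect_size=float(ss_g / (ss_g + sse_b)), effect_size_name="partial_eta2"))

    # within-subjects part: orthonormal contrast space
    C = scipy.linalg.helmert(K).T  # (K, K-1), columns orthonormal, mean-free
    M = Y @ C
    sse_w = _sse(X, M)
    df_err_w = (K - 1) * (n - p)
    for label, term in ((f"{within}", "intercept"), (f"{within}*{between}", "group")):
        ss = _type3_ss(X, M, names.index(term))
        f = (ss / (K - 1)) / (sse_w / df_err_w)
        results.append(TestResult(
            name=label, statistic=float(f), df=(float(K - 1), float(df_err_w)),
            p=float(scipy.stats.f.sf(f, K - 1, df_err_w)),
            effect_size=float(ss / (ss + sse_w)), effect_size_name="partial_eta2"))
    return results


def posthoc_bonferroni(
    param_df: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    between: str = "group",
    within: str = "class",
    covariates: tuple[str, ...] | None = ("age", "gender"),
) -> list[TestResult]:
    """Per-class covariate-adjusted group contrasts, Bonferroni-corrected.

    Each class gets an ANCOVA of its values on group + covariates; the
    group-coefficient t-test p is multiplied by the number of classes
    (capped at 1).  Effect size is Cohen's d from the t statistic.
    """
    classes = sorted(param_df[within].unique())
    K = len(classes)
    out = []
    for cls in classes:
        sub = param_df[param_df[within] == cls]
        groups = sub[between].to_numpy()
        cov = None
        if covariates:
            cov_cols = []
            for c in covariates:
                v = sub[c]
                if v.dtype == object:
                    v = v.map(GENDER_CODES)
                cov_cols.append(v.to_numpy(dtype=float))
            cov = np.column_stack(cov_cols)
        y = sub[dv].to_numpy(dtype=float)
        X, names = _design_matrix(groups, cov)
        n, p = X.shape
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sse = float(resid @ resid)
        dof = n - p
        XtX_inv = np.linalg.inv(X.T @ X)
        j = names.index("group")
        se = math.sqrt(sse / dof * XtX_inv[j, j])
        t = beta[j] / se
        pval = 2 * scipy.stats.t.sf(abs(t), dof)
        n1 = int((groups == np.unique(groups)[0]).sum())
        n2 = n - n1
        d = t * math.sqrt(1 / n1 + 1 / n2)
        out.append(TestResult(
            name=f"{dv}[{cls}] {between} contrast", statistic=float(t),
            df=(float(dof),), p=float(pval), p_adjusted=float(min(1.0, pval * K)),
            effect_size=float(d), effect_size_name="cohen_d",
            note="positive = second group larger (adjusted for covariates)"))
    return out


# ---------------------------------------------------------------------------
# transition t-tests


def transition_ttests(
    trans_df: pd.DataFrame,
    between: str = "group",
    welch: bool = False,
    adjust: str | None = None,
) -> list[TestResult]:
    """Independent-samples t-test per ordered class pair.

    Pooled-variance Student's t by default (``welch=True`` for unequal
    variances); p-values unadjusted unless ``adjust`` is ``"bonferroni"`` or
    ``"holm"``.  Pairs where both groups have zero variance are flagged and
    given NaN statistics.
    """
    gcodes = sorted(trans_df[between].unique())
    if len(gcodes) != 2:
        raise ValueError(f"expected exactly 2 groups, got {gcodes}")
    results = []
    pvals = []
    for (src, dst), sub in trans_df.groupby(["from", "to"], sort=True):
        a = sub.loc[sub[between] == gcodes[0], "probability"].to_numpy(dtype=float)
        b = sub.loc[sub[between] == gcodes[1], "probability"].to_numpy(dtype=float)
        if min(a.size, b.size) < 2:
            raise ValueError("need at least 2 subjects per group")
        name = f"P({src}->{dst}) {gcodes[0]} vs {gcodes[1]}"
        if a.std() == 0 and b.std() == 0:
            results.append(TestResult(name=name, statistic=float("nan"),
                                      df=(float("nan"),), p=float("nan"),
                                      note="zero variance in both groups"))
            pvals.append(np.nan)
            continue
        t, p = scipy.stats.ttest_ind(a, b, equal_var=not welch)
        dof = (a.size + b.size - 2) if not welch else _welch_df(a, b)
        sp = math.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                       / (a.size + b.size - 2))
        d = (a.mean() - b.mean()) / sp if sp > 0 else float("nan")
        results.append(TestResult(name=name, statistic=float(t), df=(float(dof),),
                                  p=float(p), effect_size=float(d),
                                  effect_size_name="cohen_d"))
        pvals.append(p)
    if adjust:
        import statsmodels.stats.multitest as smm

        mask = ~np.isnan(pvals)
        adj = np.full(len(pvals), np.nan)
        if mask.any():
            adj[mask] = smm.multipletests(np.asarray(pvals)[mask], method=adjust)[1]
        for r, pa in zip(results, adj):
            r.p_adjusted = float(pa)
    return results


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    return (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
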