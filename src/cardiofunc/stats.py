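"""Group-comparison statistics for per-cell/ROI measurement tables.

Implements the downstream statistics of a genotype x treatment phenotyping
study: one- and two-way fixed-effects ANOVA followed by Holm-Sidak
step-down multiple comparisons, unpaired two-tailed t-tests, mean +/- SEM
summaries, and 2^-ddCT relative gene expression from qPCR cycle thresholds.

Tables are long-format pandas DataFrames with columns
``unit_id, factor_a, factor_b, measurement, value`` (``factor_b`` optional).
Balanced two-way designs use the classical sum-of-squares partition;
unbalanced designs (the usual case with per-cell imaging counts) use
Type-II sums of squares via statsmodels OLS.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "TTestResult",
    "DdctResult",
    "holm_sidak",
    "two_way_anova",
    "one_way_anova",
    "t_test",
    "summarize",
    "ddct",
]


@dataclass
class AnovaResult:
    """ANOVA table plus post hoc pairwise comparisons.

    ``table`` has one row per effect (and 'Residual') with sum_sq, df, F, p;
    degenerate zero-variance designs report F as NaN ('undefined') with
    p = 1 rather than raising.  ``comparisons`` lists all pairwise group
    contrasts with raw and Holm-Sidak-adjusted p-values; ``means`` gives
    per-group mean, SEM and n.
    """

    table: pd.DataFrame
    comparisons: pd.DataFrame
    means: pd.DataFrame
    ss_type: str
    balanced: bool


@dataclass
class TTestResult:
    t: float
    p: float
    df: float


@dataclass
class DdctResult:
    """Per-sample relative expression by the 2^-ddCT method.

    ``samples`` has columns sample, group, delta_ct, delta_delta_ct, fold.
    The calibrator group's geometric-mean fold change is exactly 1.
    """

    samples: pd.DataFrame
    target_gene: str
    reference_gene: str
    calibrator_group: str


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def holm_sidak(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Sidak adjustment.

    Sort p ascending; ``adj_(i) = 1 - (1 - p_(i))^(m - i + 1)`` (1-based
    rank i over m tests); enforce monotone nondecreasing adjusted values by
    a running maximum; return (adjusted p in input order, reject flags at
    ``alpha``).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj, adj < alpha


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def _f_p(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float]:
    """F and p, guarding the degenerate zero-error-variance case."""
    if df_eff <= 0 or df_err <= 0:
        return math.nan, 1.0
    ms_err = ss_err / df_err
    if ms_err <= 0:
        return math.nan, 1.0  # undefined F, reported with p = 1
    f = (ss_eff / df_eff) / ms_err
    return f, float(sps.f.sf(f, df_eff, df_err))


def _group_means(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    g = df.groupby(keys, observed=True)["value"]
    out = g.agg(["mean", "count", "std"]).reset_index()
    out["sem"] = out["std"] / np.sqrt(out["count"])
    out.loc[out["count"] < 2, "sem"] = np.nan
    return out.rename(columns={"count": "n"}).drop(columns="std")


def _pairwise(
    df: pd.DataFrame, keys: list[str], ms_err: float, df_err: int,
    alpha: float, welch: bool,
) -> pd.DataFrame:
    groups = {k: sub["value"].to_numpy() for k, sub in df.groupby(keys, observed=True)}
    labels = list(groups)
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        x, y = groups[g1], groups[g2]
        diff = float(x.mean() - y.mean())
        if welch or ms_err <= 0 or not np.isfinite(ms_err):
            if ms_err <= 0 and not welch:
                t, p, dfree = math.nan, 1.0, math.nan  # zero-variance degenerate
            else:
                res = sps.ttest_ind(x, y, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
                dfree = float(res.df)
        else:
            se = math.sqrt(ms_err * (1.0 / len(x) + 1.0 / len(y)))
            t = diff / se
            dfree = df_err
            p = float(2.0 * sps.t.sf(abs(t), df_err))
        rows.append(
            dict(group_1=_fmt(g1), group_2=_fmt(g2), mean_diff=diff, t=t, df=dfree, p_raw=p)
        )
    out = pd.DataFrame(rows)
    adj, rej = holm_sidak(out["p_raw"].to_numpy(), alpha=alpha)
    out["p_adj"] = adj
    out["reject"] = rej
    return out


def _fmt(key) -> str:
    if isinstance(key, tuple):
        return ":".join(str(k) for k in key)
    return str(key)


def _check_table(df: pd.DataFrame, two_way: bool) -> None:
    needed = {"factor_a", "value"} | ({"factor_b"} if two_way else set())
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("values must be finite")


def two_way_anova(
    table: pd.DataFrame, alpha: float = 0.05, welch: bool = False
) -> AnovaResult:
    """Two-way crossed fixed-effects ANOVA with Holm-Sidak post hoc.

    Balanced designs use the classical SS partition
    (SS_A + SS_B + SS_AB + SS_error = SS_total); unbalanced designs use
    Type-II sums of squares via statsmodels.  Pairwise comparisons between
    all factor-combination cells use the pooled error MS by default
    (``welch=True`` switches to per-pair Welch t-tests).
    """
    df = table.copy()
    _check_table(df, two_way=True)
    a_levels = sorted(df["factor_a"].unique())
    b_levels = sorted(df["factor_b"].unique())
    counts = df.groupby(["factor_a", "factor_b"], observed=True)["value"].count()
    missing = [
        (a, b) for a in a_levels for b in b_levels
        if (a, b) not in counts.index or counts[(a, b)] < 2
    ]
    if missing:
        raise ValueError(f"cells missing or with < 2 units: {missing}")
    balanced = counts.nunique() == 1

    if balanced:
        y = df["value"].to_numpy(dtype=float)
        grand = y.mean()
        ss_total = float(((y - grand) ** 2).sum())
        ma = df.groupby("factor_a", observed=True)["value"].agg(["mean", "count"])
        mb = df.groupby("factor_b", observed=True)["value"].agg(["mean", "count"])
        mab = df.groupby(["factor_a", "factor_b"], observed=True)["value"].agg(["mean", "count"])
        ss_a = float((ma["count"] * (ma["mean"] - grand) ** 2).sum())
        ss_b = float((mb["count"] * (mb["mean"] - grand) ** 2).sum())
        ss_cells = float((mab["count"] * (mab["mean"] - grand) ** 2).sum())
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ss_total - ss_cells
        df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
        df_ab = df_a * df_b
        df_err = len(y) - len(a_levels) * len(b_levels)
        rows = []
        for name, ss, dfe in (
            ("factor_a", ss_a, df_a), ("factor_b", ss_b, df_b),
            ("factor_a:factor_b", ss_ab, df_ab),
        ):
            f, p = _f_p(ss, dfe, ss_err, df_err)
            rows.append(dict(effect=name, sum_sq=ss, df=dfe, F=f, p=p))
        rows.append(dict(effect="Residual", sum_sq=ss_err, df=df_err, F=math.nan, p=math.nan))
        anova_table = pd.DataFrame(rows).set_index("effect")
        ss_type = "classical"
    else:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        model = smf.ols("value ~ C(factor_a) * C(factor_b)", data=df).fit()
        tab = anova_lm(model, typ=2)
        rename = {
            "C(factor_a)": "factor_a",
            "C(factor_b)": "factor_b",
            "C(factor_a):C(factor_b)": "factor_a:factor_b",
        }
        tab = tab.rename(index=rename)
        anova_table = pd.DataFrame(
            dict(sum_sq=tab["sum_sq"], df=tab["df"].astype(int),
                 F=tab["F"], p=tab["PR(>F)"])
        )
        anova_table.index.name = "effect"
        ss_err = float(tab.loc["Residual", "sum_sq"])
        df_err = int(tab.loc["Residual", "df"])
        if ss_err <= 0:  # degenerate: undefined F, p = 1
            anova_table.loc[anova_table.index != "Residual", "F"] = math.nan
            anova_table.loc[anova_table.index != "Residual", "p"] = 1.0
        ss_type = "type-II"

    df_err = int(anova_table.loc["Residual", "df"])
    ss_err = float(anova_table.loc["Residual", "sum_sq"])
    ms_err = ss_err / df_err if df_err > 0 else math.nan
    comparisons = _pairwise(df, ["factor_a", "factor_b"], ms_err, df_err, alpha, welch)
    means = _group_means(df, ["factor_a", "factor_b"])
    return AnovaResult(anova_table, comparisons, means, ss_type, balanced)


def one_way_anova(
    table: pd.DataFrame, alpha: float = 0.05, welch: bool = False
) -> AnovaResult:
    """One-way fixed-effects ANOVA with Holm-Sidak pairwise post hoc."""
    df = table.copy()
    _check_table(df, two_way=False)
    levels = sorted(df["factor_a"].unique())
    counts = df.groupby("factor_a", observed=True)["value"].count()
    if (counts < 2).any():
        raise ValueError(f"groups with < 2 units: {list(counts[counts < 2].index)}")
    y = df["value"].to_numpy(dtype=float)
    grand = y.mean()
    ma = df.groupby("factor_a", observed=True)["value"].agg(["mean", "count"])
    ss_between = float((ma["count"] * (ma["mean"] - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_between
    df_b, df_err = len(levels) - 1, len(y) - len(levels)
    f, p = _f_p(ss_between, df_b, ss_err, df_err)
    anova_table = pd.DataFrame(
        [
            dict(effect="factor_a", sum_sq=ss_between, df=df_b, F=f, p=p),
            dict(effect="Residual", sum_sq=ss_err, df=df_err, F=math.nan, p=math.nan),
        ]
    ).set_index("effect")
    ms_err = ss_err / df_err if df_err > 0 else math.nan
    comparisons = _pairwise(df, ["factor_a"], ms_err, df_err, alpha, welch)
    means = _group_means(df, ["factor_a"])
    return AnovaResult(anova_table, comparisons, means, "classical", counts.nunique() == 1)


def t_test(x, y) -> TTestResult:
    """Unpaired two-tailed Student's t-test (pooled variance).

    Two identical groups give t = 0, p = 1; zero pooled variance with
    unequal means is reported as infinite t with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    res = sps.ttest_ind(x, y, equal_var=True)
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(t):  # zero variance, equal means
        t, p = 0.0, 1.0
    return TTestResult(t=t, p=p, df=float(len(x) + len(y) - 2))


def summarize(
    table: pd.DataFrame, by: list[str] | None = None
) -> pd.DataFrame:
    """Per-group mean, SEM (SD/sqrt(n); NaN for n = 1) and n.

    Groups by the given columns (default: every factor/measurement column
    present) for each measurement.
    """
    df = table.copy()
    if by is None:
        by = [c for c in ("factor_a", "factor_b", "measurement") if c in df.columns]
    if not by:
        raise ValueError("no grouping columns found or given")
    return _group_means(df, by)


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------

def ddct(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> DdctResult:
    """Relative gene expression by the 2^-ddCT method.

    ``ct_table`` columns: sample, group, gene, ct (replicate rows are
    averaged per sample and gene first).  Per sample,
    dCT = CT(target) - CT(reference); ddCT subtracts the calibrator
    group's mean dCT; fold change = 2^-ddCT.  Adding a constant to both
    genes of a sample leaves its fold unchanged.
    """
    needed = {"sample", "group", "gene", "ct"}
    if not needed <= set(ct_table.columns):
        raise ValueError(f"ct_table must have columns {sorted(needed)}")
    mean_ct = (
        ct_table.groupby(["sample", "group", "gene"], observed=True)["ct"]
        .mean()
        .reset_index()
    )
    wide = mean_ct.pivot_table(
        index=["sample", "group"], columns="gene", values="ct", observed=True
    ).reset_index()
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} missing from ct_table")
        bad = wide.loc[wide[gene].isna(), "sample"].tolist()
        if bad:
            raise ValueError(f"samples missing CT for {gene!r}: {bad}")
    wide["delta_ct"] = wide[target_gene] - wide[reference_gene]
    cal = wide.loc[wide["group"] == calibrator_group, "delta_ct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    wide["delta_delta_ct"] = wide["delta_ct"] - cal.mean()
    wide["fold"] = 2.0 ** (-wide["delta_delta_ct"])
    out = wide[["sample", "group", "delta_ct", "delta_delta_ct", "fold"]].copy()
    return DdctResult(
        samples=out, target_gene=target_gene,
        reference_gene=reference_gene, calibrator_group=calibrator_group,
    )
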