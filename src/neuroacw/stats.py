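"""Group-level statistics for core-periphery comparisons.

Two-sample Student's t with Cohen's d, one- and two-way ANOVA with
eta-squared effect sizes, Tukey HSD post-hoc contrasts, Benjamini-
Hochberg FDR correction, and removal of the anterior-posterior gradient
by linear regression. The observational unit throughout is the region
(subject-averaged values), so a 200-region template across 3 task
conditions yields the 6-cell design with error df 594 and the 360-region
template df 1074.

Sign convention: core-periphery contrasts are reported as
``periphery - core``, so a longer timescale in the core gives negative
t and d.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestReport",
    "AnovaReport",
    "PosthocReport",
    "cohens_d",
    "ttest_core_periphery",
    "one_way_anova",
    "two_way_anova",
    "tukey_posthoc",
    "bh_fdr",
    "regress_out_axis",
]


@dataclass(frozen=True)
class TTestReport:
    t: float
    df: float
    p: float
    cohens_d: float
    n1: int
    n2: int
    mean1: float
    mean2: float

    def to_dict(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "cohens_d": self.cohens_d,
            "n1": self.n1,
            "n2": self.n2,
            "mean1": self.mean1,
            "mean2": self.mean2,
        }


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df_effect: float
    df_error: float
    p: float
    eta_sq: float


@dataclass(frozen=True)
class AnovaReport:
    effects: tuple[AnovaEffect, ...]

    def __getitem__(self, name: str) -> AnovaEffect:
        for effect in self.effects:
            if effect.name == name:
                return effect
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])


@dataclass(frozen=True)
class PosthocContrast:
    task: str
    t: float
    cohens_d: float
    p_adj: float
    mean_periphery: float
    mean_core: float


@dataclass(frozen=True)
class PosthocReport:
    contrasts: tuple[PosthocContrast, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.contrasts])


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def ttest_core_periphery(
    values: pd.Series | np.ndarray,
    cp_labels: pd.Series | np.ndarray,
    *,
    equal_var: bool = True,
    division_name: str = "",
) -> TTestReport:
    """Student's t-test of periphery vs core regional values.

    Regions labelled ``excluded`` are dropped. The contrast is
    ``periphery - core``; Welch's correction is available through
    ``equal_var=False``.
    """
    values = np.asarray(values, float)
    labels = np.asarray(cp_labels)
    periphery = values[labels == "periphery"]
    core = values[labels == "core"]
    name = f" in division {division_name}" if division_name else ""
    if periphery.size < 2 or core.size < 2:
        raise ValueError(
            f"need >= 2 regions per group{name}; got "
            f"{periphery.size} periphery, {core.size} core"
        )
    res = sps.ttest_ind(periphery, core, equal_var=equal_var)
    return TTestReport(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        cohens_d=cohens_d(periphery, core),
        n1=periphery.size,
        n2=core.size,
        mean1=float(periphery.mean()),
        mean2=float(core.mean()),
    )


def one_way_anova(values, groups) -> AnovaReport:
    """Classical one-way ANOVA with eta-squared = SS_between / SS_total."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if levels.size < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    cells = [values[groups == g] for g in levels]
    grand = values.mean()
    ss_between = sum(c.size * (c.mean() - grand) ** 2 for c in cells)
    ss_within = sum(((c - c.mean()) ** 2).sum() for c in cells)
    df_between = levels.size - 1
    df_within = values.size - levels.size
    if df_within < 1 or ss_within <= 0:
        raise ValueError("no within-group degrees of freedom or variance")
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f_stat, df_between, df_within))
    eta_sq = ss_between / (ss_between + ss_within)
    return AnovaReport(
        effects=(
            AnovaEffect("group", float(f_stat), df_between, df_within, p, float(eta_sq)),
        )
    )


def _check_cells(frame: pd.DataFrame) -> None:
    counts = frame.groupby(["task", "cp"], observed=True).size()
    tasks = frame["task"].unique()
    cps = frame["cp"].unique()
    for task in tasks:
        for cp in cps:
            if (task, cp) not in counts.index:
                raise ValueError(f"empty design cell (task={task!r}, cp={cp!r})")


def two_way_anova(values, task_factor, cp_factor) -> AnovaReport:
    """Full-factorial task x CP ANOVA with interaction (Type-II SS).

    Eta-squared is each effect's share of the total sum of squares
    (effects + residual), so shares sum to 1 over the decomposition.
    """
    frame = pd.DataFrame(
        {
            "value": np.asarray(values, float),
            "task": np.asarray(task_factor),
            "cp": np.asarray(cp_factor),
        }
    )
    _check_cells(frame)
    for factor in ("task", "cp"):
        if frame[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs at least 2 levels")
    model = smf.ols("value ~ C(task) * C(cp)", data=frame).fit()
    table = anova_lm(model, typ=2)
    ss_total = float(table["sum_sq"].sum())
    df_error = float(table.loc["Residual", "df"])
    rename = {"C(task)": "task", "C(cp)": "cp", "C(task):C(cp)": "task:cp"}
    effects = []
    for row_name, label in rename.items():
        row = table.loc[row_name]
        effects.append(
            AnovaEffect(
                name=label,
                F=float(row["F"]),
                df_effect=float(row["df"]),
                df_error=df_error,
                p=float(row["PR(>F)"]),
                eta_sq=float(row["sum_sq"] / ss_total),
            )
        )
    effects.append(
        AnovaEffect(
            name="residual",
            F=float("nan"),
            df_effect=df_error,
            df_error=df_error,
            p=float("nan"),
            eta_sq=float(table.loc["Residual", "sum_sq"] / ss_total),
        )
    )
    return AnovaReport(effects=tuple(effects))


def tukey_posthoc(values, task_factor, cp_factor) -> PosthocReport:
    """Tukey-HSD periphery-vs-core contrasts within each task level.

    The adjusted p comes from the studentized-range distribution over
    all pairwise comparisons of the 6 task x CP cells; the per-contrast
    t and Cohen's d are computed directly on the two cells involved
    (periphery - core).
    """
    frame = pd.DataFrame(
        {
            "value": np.asarray(values, float),
            "task": np.asarray(task_factor),
            "cp": np.asarray(cp_factor),
        }
    )
    _check_cells(frame)
    cell = frame["task"].astype(str) + "|" + frame["cp"].astype(str)
    tukey = pairwise_tukeyhsd(frame["value"].to_numpy(), cell.to_numpy())
    groups = [str(g) for g in tukey.groupsunique]
    adj = {}
    for (i, j), p_adj in zip(combinations(range(len(groups)), 2), tukey.pvalues):
        adj[frozenset((groups[i], groups[j]))] = float(p_adj)
    contrasts = []
    for task in pd.unique(frame["task"]):
        periphery = frame.loc[
            (frame["task"] == task) & (frame["cp"] == "periphery"), "value"
        ].to_numpy()
        core = frame.loc[(frame["task"] == task) & (frame["cp"] == "core"), "value"].to_numpy()
        key = frozenset((f"{task}|periphery", f"{task}|core"))
        t_stat = float(sps.ttest_ind(periphery, core, equal_var=True).statistic)
        contrasts.append(
            PosthocContrast(
                task=str(task),
                t=t_stat,
                cohens_d=cohens_d(periphery, core),
                p_adj=adj[key],
                mean_periphery=float(periphery.mean()),
                mean_core=float(core.mean()),
            )
        )
    return PosthocReport(contrasts=tuple(contrasts))


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    pvalues = np.asarray(pvalues, float)
    if pvalues.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((pvalues < 0) | (pvalues > 1) | ~np.isfinite(pvalues)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def regress_out_axis(values, y_mm) -> np.ndarray:
    """Residual values after OLS on the anterior-posterior coordinate.

    Fits ``value ~ 1 + y_mm`` across regions and returns the residuals,
    which are mean-zero and uncorrelated with the axis.
    """
    values = np.asarray(values, float)
    y = np.asarray(y_mm, float)
    if values.size < 3:
        raise ValueError("need at least 3 regions for the axis regression")
    if np.ptp(y) == 0:
        raise ValueError("anterior-posterior coordinate is constant")
    design = sm.add_constant(y)
    return np.asarray(sm.OLS(values, design).fit().resid)
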