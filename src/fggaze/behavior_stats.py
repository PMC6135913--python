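"""Scoring, correct rates, t-tests and factorial ANOVA with partial eta^2.

2AFC responses are scored against the stimulus ground truth: in the DOF
task a response is correct when it matches the side toward the surface
whose contour passes through the stimulus centre; in the FG task when it
names the color of the physically front surface.

The factorial ANOVA is a fixed-effects crossed design with a single
residual error term (participant is treated as a fixed factor tested
against the residual, matching how such tables are conventionally
reported).  Balanced data reduce to the classical sums-of-squares
decomposition; unbalanced data are handled by the Type III convention with
sum-to-zero contrasts.  Effect sizes are partial eta squared,
``SS_effect / (SS_effect + SS_error)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests


class DegenerateDataError(ValueError):
    """The requested statistic is undefined for this input."""


class DesignError(ValueError):
    """The factorial design is invalid (empty cell, singular design...)."""


class ResponseDomainError(ValueError):
    """A response value outside the task's response domain."""


RESPONSE_DOMAINS = {"DOF": ("left", "right"), "FG": ("red", "green")}


def score_response(task: str, response: str, meta) -> bool:
    """Correctness of one 2AFC response against the stimulus ground truth."""
    if task not in RESPONSE_DOMAINS:
        raise ResponseDomainError(f"unknown task {task!r}")
    if response not in RESPONSE_DOMAINS[task]:
        raise ResponseDomainError(
            f"response {response!r} invalid for task {task!r}; expected one "
            f"of {RESPONSE_DOMAINS[task]}")
    truth = meta.dof_truth if task == "DOF" else meta.figure_color_truth
    return response == truth


def score_responses(trials: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Vectorized scoring: adds a ``correct`` column to a trial table."""
    merged = trials.merge(
        manifest[["stimulus_id", "dof_truth", "figure_color_truth"]],
        on="stimulus_id", how="left", validate="many_to_one")
    if merged["dof_truth"].isna().any():
        bad = merged.loc[merged["dof_truth"].isna(), "stimulus_id"].iloc[0]
        raise KeyError(f"trial references unknown stimulus {bad!r}")
    for task, domain in RESPONSE_DOMAINS.items():
        sel = merged["task"] == task
        bad = sel & ~merged["response"].isin(domain)
        if bad.any():
            raise ResponseDomainError(
                f"response {merged.loc[bad, 'response'].iloc[0]!r} invalid "
                f"for task {task!r}")
    truth = np.where(merged["task"] == "DOF", merged["dof_truth"],
                     merged["figure_color_truth"])
    out = trials.copy()
    out["correct"] = (merged["response"].to_numpy() == truth).astype(int)
    return out


def correct_rate_cells(scored: pd.DataFrame) -> pd.DataFrame:
    """Per participant x task x condition correct-rate cells."""
    g = (scored.groupby(["participant", "task", "condition"], observed=True)
         ["correct"].agg(n_trials="size", rate="mean").reset_index())
    return g


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: int
    pvalue: float
    variant: str  # "paired" | "pooled two-sample"


def paired_t(x: Sequence[float], y: Sequence[float],
             alternative: str = "two-sided") -> TTestResult:
    """Paired t-test on participant-level values; df = n - 1.

    Identical inputs give t = 0; a nonzero constant difference (zero
    spread) is degenerate and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if d[0] == 0:
            return TTestResult(0.0, x.size - 1, 1.0, "paired")
        raise DegenerateDataError("differences have zero variance")
    res = sps.ttest_rel(x, y, alternative=alternative)
    return TTestResult(float(res.statistic), x.size - 1, float(res.pvalue),
                       "paired")


def pooled_two_sample_t(a: Sequence[float], b: Sequence[float],
                        alternative: str = "two-sided") -> TTestResult:
    """Student (pooled-variance) two-sample t; df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    df = a.size + b.size - 2
    if df <= 0:
        raise ValueError("need n_a + n_b - 2 > 0")
    if np.var(a, ddof=0) == 0 and np.var(b, ddof=0) == 0:
        if np.mean(a) == np.mean(b):
            return TTestResult(0.0, df, 1.0, "pooled two-sample")
        raise DegenerateDataError("combined zero variance")
    res = sps.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return TTestResult(float(res.statistic), df, float(res.pvalue),
                       "pooled two-sample")


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Effect size ``SS_effect / (SS_effect + SS_error)``."""
    if ss_effect < 0:
        raise ValueError("ss_effect must be >= 0")
    if ss_error <= 0:
        raise ValueError("ss_error must be > 0")
    return ss_effect / (ss_effect + ss_error)


@dataclass(frozen=True)
class FTestResult:
    statistic: float
    df_num: int
    df_den: int
    pvalue: float


def f_from_ss(ss_effect: float, df_effect: int, ss_error: float,
              df_error: int) -> FTestResult:
    """F ratio (and p) from sums of squares and degrees of freedom."""
    if df_effect <= 0 or df_error <= 0:
        raise ValueError("degrees of freedom must be positive")
    f = (ss_effect / df_effect) / (ss_error / df_error)
    p = float(sps.f.sf(f, df_effect, df_error))
    return FTestResult(float(f), int(df_effect), int(df_error), p)


def holm(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    return multipletests(np.asarray(pvalues, dtype=float),
                         method="holm")[1]


def _pretty_term(name: str) -> str:
    parts = name.split(":")
    cleaned = []
    for p in parts:
        p = p.strip()
        if p.startswith("C(") and p.endswith(")"):
            p = p[2:-1].split(",")[0].strip()
        cleaned.append(p)
    return " × ".join(cleaned)


def factorial_anova(data: pd.DataFrame, dv: str = "dff_ms",
                    factors: Sequence[str] = ("condition", "region",
                                              "participant"),
                    include_interactions: bool = True) -> pd.DataFrame:
    """Fixed-effects crossed ANOVA with a residual error term.

    Returns a table indexed by factor (plus an ``Error`` row) with columns
    ``df, sum_sq, mean_sq, F, p, partial_eta_sq``.  Sums of squares follow
    the Type III convention with sum-to-zero contrasts, which coincides
    with the classical decomposition on balanced data.
    """
    data = data.dropna(subset=[dv]).copy()
    if len(data) == 0:
        raise DesignError("no observations")
    levels = {}
    for f in factors:
        if f not in data.columns:
            raise DesignError(f"factor column {f!r} missing")
        lv = sorted(data[f].astype(str).unique())
        if len(lv) < 2:
            raise DesignError(f"factor {f!r} has fewer than 2 observed levels")
        levels[f] = lv
        data[f] = data[f].astype(str)
    counts = data.groupby(list(factors), observed=False).size()
    for cell in product(*(levels[f] for f in factors)):
        key = cell if len(factors) > 1 else cell[0]
        if key not in counts.index or counts.loc[key] == 0:
            name = ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
            raise DesignError(f"empty design cell ({name})")

    op = " * " if include_interactions else " + "
    rhs = op.join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"{dv} ~ {rhs}", data=data).fit()
    if model.df_resid <= 0:
        raise DesignError("no residual degrees of freedom")
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise DesignError("singular design matrix")
    raw = anova_lm(model, typ=3)
    raw = raw.drop(index="Intercept")
    raw = raw.rename(index={"Residual": "Error"})
    raw.index = [n if n == "Error" else _pretty_term(n) for n in raw.index]

    ss_error = float(raw.loc["Error", "sum_sq"])
    out = pd.DataFrame({
        "df": raw["df"].astype(int),
        "sum_sq": raw["sum_sq"].astype(float),
    })
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out["F"] = raw["F"].astype(float)
    out["p"] = raw["PR(>F)"].astype(float)
    pes = [partial_eta_squared(ss, ss_error) if name != "Error" else np.nan
           for name, ss in out["sum_sq"].items()]
    out["partial_eta_sq"] = pes
    out.index.name = "factor"
    return out
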