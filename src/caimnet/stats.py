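"""Statistical layer: proportion CIs, exact and rank tests, linear models
with the two-factor interaction scheme, simple regression, and the
session/group report.

The linear-model layer mirrors a common neuroscience analysis recipe:
fit ``Y ~ 1 + genotype + behavior + genotype:behavior`` by maximum
likelihood, gate all coefficient reporting on a likelihood-ratio
(deviance) test against the intercept-only model, and — only when the
interaction is significant — fit per-level post-hoc sub-models
``Y ~ 1 + behavior``.  With two-level factors no further post-hoc
correction is needed, and no multiple-comparison correction is applied
anywhere in this layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

ALPHA = 0.05


def binomial_ci_halfwidth(P: float, n: int) -> float:
    """Half-width of the normal-approximation 95% CI for a proportion.

    ``1.96 * sqrt(P (1 - P) / n)``, with ``P`` a proportion in [0, 1];
    returned on the percent scale.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError("P must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(1.96 * np.sqrt(P * (1.0 - P) / n) * 100.0)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p (two independent groups)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 observations per group")
    return float(sps.ranksums(x, y).pvalue)


def signed_rank(x) -> float:
    """Two-sided Wilcoxon signed-rank p for median different from 0."""
    x = np.asarray(x, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == 0):
        raise ValueError("all observations are zero (degenerate)")
    return float(sps.wilcoxon(x).pvalue)


@dataclass
class LMResult:
    coefficients: dict
    coef_p: dict
    deviance_p: float
    interaction_p: float | None
    posthoc_p: dict = field(default_factory=dict)

    @property
    def model_significant(self) -> bool:
        return self.deviance_p < ALPHA


def _lr_deviance_p(full, null) -> float:
    lr = 2.0 * (full.llf - null.llf)
    df = full.df_model - null.df_model
    return float(sps.chi2.sf(max(lr, 0.0), max(df, 1)))


def fit_interaction_lm(
    data: pd.DataFrame,
    dv: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "behavior",
    posthoc: str = "on-interaction",
) -> LMResult:
    """Gaussian linear model ``dv ~ a * b`` with deviance gating.

    ``posthoc`` controls when per-level ``dv ~ b`` sub-models are fitted:
    "on-interaction" (only when the interaction is significant),
    "always", or "never".
    """
    for col in (dv, factor_a, factor_b):
        if col not in data:
            raise ValueError(f"missing column {col!r}")
    for col in (factor_a, factor_b):
        if data[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs two levels (rank-deficient design)")
    formula = f"{dv} ~ C({factor_a}) * C({factor_b})"
    full = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(full.model.exog) < full.model.exog.shape[1]:
        raise ValueError("rank-deficient design (a factor cell is empty)")
    null = smf.ols(f"{dv} ~ 1", data=data).fit()
    dev_p = _lr_deviance_p(full, null)
    inter_name = next((nm for nm in full.params.index if ":" in nm), None)
    inter_p = float(full.pvalues[inter_name]) if inter_name else None
    result = LMResult(
        coefficients=dict(full.params),
        coef_p=dict(full.pvalues),
        deviance_p=dev_p,
        interaction_p=inter_p,
    )
    trigger = (
        posthoc == "always"
        or (posthoc == "on-interaction" and inter_p is not None and inter_p < ALPHA)
    )
    if trigger:
        for level, sub in data.groupby(factor_a):
            if sub[factor_b].nunique() < 2:
                continue
            m = smf.ols(f"{dv} ~ C({factor_b})", data=sub).fit()
            slope = next(nm for nm in m.params.index if nm != "Intercept")
            result.posthoc_p[str(level)] = float(m.pvalues[slope])
    return result


def simple_regression(x, y) -> tuple[float, float, float]:
    """OLS slope, intercept and two-sided slope p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant x")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)


def build_report(sessions: list[dict]) -> dict:
    """Assemble a structured cross-session report.

    Each session dict may carry: ``group`` label, ``kinematics`` (bout
    summary), ``event_rate_rest`` / ``event_rate_run`` (events/min),
    ``n_cells`` / ``n_modulated``, ``pair_fractions`` (per scope),
    ``mean_r`` (per scope/state), ``centrality_difference``.  Group
    summaries report means, SDs and modulated-fraction binomial CIs; the
    rest-vs-run event-rate contrast is tested with the interaction linear
    model when two groups are present.  No multiple-testing correction is
    applied.
    """
    report: dict = {"n_sessions": len(sessions), "groups": {}, "tests": {},
                    "multiple_testing_correction": "none"}
    if not sessions:
        return report
    df = pd.DataFrame(sessions)
    for group, sub in df.groupby("group") if "group" in df else [("all", df)]:
        entry: dict = {"n_sessions": int(len(sub))}
        for col in ("event_rate_rest", "event_rate_run", "centrality_difference"):
            if col in sub and sub[col].notna().any():
                entry[col] = {
                    "mean": float(sub[col].mean()),
                    "sd": float(sub[col].std(ddof=1)) if len(sub) > 1 else 0.0,
                    "n": int(sub[col].notna().sum()),
                }
        if {"n_cells", "n_modulated"}.issubset(sub.columns):
            n_cells = int(sub["n_cells"].sum())
            n_mod = int(sub["n_modulated"].sum())
            if n_cells:
                p = n_mod / n_cells
                entry["modulated_percent"] = {
                    "value": 100.0 * p,
                    "ci_halfwidth": binomial_ci_halfwidth(p, n_cells),
                    "n_cells": n_cells,
                }
        if "kinematics" in sub.columns:
            kin = pd.DataFrame(list(sub["kinematics"].dropna()))
            entry["kinematics"] = {c: float(kin[c].mean()) for c in kin.columns}
        report["groups"][str(group)] = entry
    # rest-vs-run event rate contrast across groups, when testable
    if {"group", "event_rate_rest", "event_rate_run"}.issubset(df.columns):
        long = df.melt(
            id_vars=["group"],
            value_vars=["event_rate_rest", "event_rate_run"],
            var_name="behavior", value_name="value",
        ).dropna(subset=["value"])
        long["behavior"] = long["behavior"].str.replace("event_rate_", "")
        counts = long.groupby(["group", "behavior"]).size()
        if df["group"].nunique() == 2 and (counts >= 2).all() and len(counts) == 4:
            lm = fit_interaction_lm(long, dv="value", factor_a="group",
                                    factor_b="behavior")
            report["tests"]["event_rate_lm"] = {
                "deviance_p": lm.deviance_p,
                "interaction_p": lm.interaction_p,
                "coef_p": {k: float(v) for k, v in lm.coef_p.items()},
                "posthoc_p": lm.posthoc_p,
            }
    if "centrality_difference" in df.columns and "group" in df.columns:
        for group, sub in df.groupby("group"):
            vals = sub["centrality_difference"].dropna().to_numpy()
            if vals.size >= 3 and not np.all(vals == 0):
                report["tests"][f"centrality_diff_vs_zero_{group}"] = signed_rank(vals)
    return report
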