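"""Standardized-mean-difference meta-analysis.

Per-study effects are Hedges' g (bias-corrected standardized mean difference)
with the usual large-sample variance. Pooling uses inverse-variance weights:
the fixed-effect model directly, the random-effects model after adding the
DerSimonian-Laird between-study variance tau^2. Heterogeneity is summarized
by Cochran's Q and I^2 = max(0, (Q - df) / Q) * 100, the model-selection rule
switches to random effects when p_Q < 0.05 or I^2 > 50%, and funnel-plot
asymmetry is assessed by Egger's regression of g/se on 1/se (asymmetric when
its intercept's two-sided p < 0.1). Confidence intervals use the normal 1.96
multiplier throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import StudyTable


@dataclass
class MetaEffect:
    """One study's standardized mean difference and its variance."""

    study_id: str
    g: float
    var_g: float
    n_case: int
    n_control: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.var_g))


@dataclass
class MetaResult:
    """Pooled effect with heterogeneity statistics."""

    pooled: float
    ci_low: float
    ci_high: float
    model: str  # "fixed" or "random"
    Q: float
    df: int
    p_Q: float
    I2: float  # percent
    tau2: float

    def to_dict(self) -> dict:
        return asdict(self)


def study_smd(study: StudyTable) -> MetaEffect:
    """Hedges' g of one two-group study.

    d = (mean_case - mean_control) / s_pooled, corrected by
    J = 1 - 3 / (4 (n1 + n2 - 2) - 1); var_g = (n1 + n2) / (n1 n2)
    + g^2 / (2 (n1 + n2)).
    """
    case = np.asarray(study.case, dtype=float)
    control = np.asarray(study.control, dtype=float)
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 values")
    s_pooled = np.sqrt(
        ((n1 - 1) * case.var(ddof=1) + (n2 - 1) * control.var(ddof=1)) / (n1 + n2 - 2)
    )
    if s_pooled == 0:
        raise ValueError(f"study {study.study_id!r} has zero pooled SD")
    d = (case.mean() - control.mean()) / s_pooled
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = j * d
    var_g = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
    return MetaEffect(study_id=study.study_id, g=float(g), var_g=float(var_g), n_case=n1, n_control=n2)


def _heterogeneity(g: np.ndarray, w: np.ndarray) -> tuple[float, int, float, float, float]:
    """Q, df, p_Q, I2 (percent) and DL tau^2 from fixed-effect weights."""
    pooled = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - pooled) ** 2))
    df = len(g) - 1
    p_q = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    return q, df, p_q, i2, tau2


def pool_fixed(effects: list[MetaEffect]) -> MetaResult:
    """Inverse-variance fixed-effect pooling."""
    if len(effects) < 2:
        raise ValueError("need at least 2 studies to pool")
    g = np.array([e.g for e in effects])
    w = 1.0 / np.array([e.var_g for e in effects])
    pooled = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    q, df, p_q, i2, tau2 = _heterogeneity(g, w)
    return MetaResult(
        pooled=pooled, ci_low=pooled - 1.96 * se, ci_high=pooled + 1.96 * se,
        model="fixed", Q=q, df=df, p_Q=p_q, I2=i2, tau2=tau2,
    )


def pool_random(effects: list[MetaEffect]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) from the fixed-effect
    weights, then inverse-variance pooling with w* = 1 / (var + tau^2).
    """
    if len(effects) < 2:
        raise ValueError("need at least 2 studies to pool")
    g = np.array([e.g for e in effects])
    v = np.array([e.var_g for e in effects])
    q, df, p_q, i2, tau2 = _heterogeneity(g, 1.0 / v)
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * g) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    return MetaResult(
        pooled=pooled, ci_low=pooled - 1.96 * se, ci_high=pooled + 1.96 * se,
        model="random", Q=q, df=df, p_Q=p_q, I2=i2, tau2=tau2,
    )


def select_model(p_Q: float, I2: float) -> str:
    """Random effects iff heterogeneity is shown (p_Q < 0.05 or I2 > 50%)."""
    return "random" if (p_Q < 0.05 or I2 > 50.0) else "fixed"


def egger_test(effects: list[MetaEffect]) -> tuple[float, float, float]:
    """Egger's funnel-asymmetry regression of g/se on 1/se.

    Returns (intercept, intercept SE, two-sided p from the t distribution with
    k - 2 df). Asymmetry is conventionally called at p < 0.1.
    """
    if len(effects) < 3:
        raise ValueError("Egger's test needs at least 3 studies")
    se = np.array([e.se for e in effects])
    y = np.array([e.g for e in effects]) / se
    x = 1.0 / se
    design = np.column_stack([np.ones_like(x), x])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    dof = len(y) - 2
    if dof <= 0:
        raise ValueError("Egger's test needs at least 3 studies")
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    intercept = float(coef[0])
    se_int = float(np.sqrt(cov[0, 0]))
    if se_int == 0:
        p = 1.0 if intercept == 0 else 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(intercept / se_int), dof))
    return intercept, se_int, p


def forest_table(effects: list[MetaEffect], result: MetaResult) -> pd.DataFrame:
    """Per-study forest-plot table: g, 95% CI and model weight percentage."""
    v = np.array([e.var_g for e in effects])
    w = 1.0 / (v + (result.tau2 if result.model == "random" else 0.0))
    w_pct = 100.0 * w / w.sum()
    return pd.DataFrame(
        {
            "study": [e.study_id for e in effects],
            "g": [e.g for e in effects],
            "ci_low": [e.g - 1.96 * e.se for e in effects],
            "ci_high": [e.g + 1.96 * e.se for e in effects],
            "weight_pct": w_pct,
        }
    )


def effects_from_long(table: pd.DataFrame) -> list[MetaEffect]:
    """Per-study effects from a long-form table (study, group, value)."""
    effects = []
    for sid, sub in table.groupby("study", sort=True):
        study = StudyTable(
            study_id=str(sid),
            case=sub.loc[sub["group"] == "case", "value"].to_numpy(dtype=float),
            control=sub.loc[sub["group"] == "control", "value"].to_numpy(dtype=float),
        )
        effects.append(study_smd(study))
    return effects


def effects_from_summary(table: pd.DataFrame) -> list[MetaEffect]:
    """Per-study effects from summary rows (n, mean, sd per group)."""
    effects = []
    for row in table.itertuples(index=False):
        n1, n2 = int(row.n_case), int(row.n_control)
        s_pooled = np.sqrt(
            ((n1 - 1) * row.sd_case**2 + (n2 - 1) * row.sd_control**2) / (n1 + n2 - 2)
        )
        if s_pooled == 0:
            raise ValueError(f"study {row.study!r} has zero pooled SD")
        d = (row.mean_case - row.mean_control) / s_pooled
        j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
        g = j * d
        var_g = (n1 + n2) / (n1 * n2) + g * g / (2.0 * (n1 + n2))
        effects.append(
            MetaEffect(study_id=str(row.study), g=float(g), var_g=float(var_g), n_case=n1, n_control=n2)
        )
    return effects


def meta_analyze(effects: list[MetaEffect], model: str = "auto") -> dict:
    """Pool effects, apply the heterogeneity-driven model choice, run Egger.

    Returns a JSON-ready summary containing the selected model's pooled
    estimate, CI, Q, df, p_Q, I2, tau2 and (when k >= 3) the Egger intercept
    and p-value, plus the per-study forest table.
    """
    fixed = pool_fixed(effects)
    random = pool_random(effects)
    if model == "auto":
        model = select_model(fixed.p_Q, fixed.I2)
    chosen = random if model == "random" else fixed
    summary = chosen.to_dict()
    summary["model"] = model
    if len(effects) >= 3:
        intercept, se_int, p = egger_test(effects)
        summary["egger_intercept"] = intercept
        summary["egger_se"] = se_int
        summary["egger_p"] = p
        summary["egger_asymmetric"] = bool(p < 0.1)
    return {"summary": summary, "forest": forest_table(effects, chosen)}
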