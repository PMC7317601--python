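"""Marker evaluation: ROC/AUC, survival comparison, over-representation.

ROC curves are computed at every distinct score threshold; the AUC is the
trapezoid area, which equals the tie-corrected rank (concordance) statistic,
and its significance uses the normal approximation to the Mann-Whitney U
statistic. Survival uses the Kaplan-Meier product-limit estimator and a
two-group log-rank test with chi2 = (O1-E1)^2/E1 + (O2-E2)^2/E2 and the
hazard ratio estimated from the observed/expected event ratio. Gene-set
over-representation is a hypergeometric upper-tail test with Benjamini-
Hochberg adjustment across sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# ROC


@dataclass
class ROCResult:
    auc: float
    p_value: float
    curve: pd.DataFrame  # threshold, fpr, tpr


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and AUC of a score against a binary label (1 = tumor).

    The AUC is the trapezoid area under the (FPR, TPR) curve; ties contribute
    1/2, making it identical to the rank statistic U / (n1 n0). The two-sided
    p-value for AUC = 0.5 is the asymptotic normal Mann-Whitney p.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    area = float(_trapezoid_auc(fpr, tpr))
    pos, neg = scores[labels == 1], scores[labels == 0]
    mw = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    curve = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    return ROCResult(auc=area, p_value=float(mw.pvalue), curve=curve)


# ---------------------------------------------------------------------------
# survival


def dichotomize_median(values: pd.Series | np.ndarray) -> np.ndarray:
    """Median split: 1 (high) where value > median, 0 (low) where value <= median."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to split")
    if np.all(v == v[0]):
        raise ValueError("all values identical; no median split possible")
    return (v > np.median(v)).astype(int)


def km_curve(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[int, float]]:
    """Kaplan-Meier survival per group.

    Returns a step table (group, time, survival, at_risk) and the median
    survival per group — the smallest time with S(t) <= 0.5, or inf if the
    curve never reaches 0.5.
    """
    if (records["time"] < 0).any():
        raise ValueError("negative survival times")
    tables = []
    medians: dict[int, float] = {}
    for grp, sub in records.groupby("group", sort=True):
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill()
        tables.append(
            pd.DataFrame(
                {
                    "group": grp,
                    "time": sf.index.to_numpy(dtype=float),
                    "survival": sf.iloc[:, 0].to_numpy(dtype=float),
                    "at_risk": at_risk.to_numpy(dtype=float),
                }
            )
        )
        medians[grp] = float(kmf.median_survival_time_)
    return pd.concat(tables, ignore_index=True), medians


def logrank(records: pd.DataFrame) -> dict:
    """Two-group log-rank test with an O/E hazard-ratio estimate.

    At every pooled event time the expected events in group 1 are tallied from
    the risk sets; chi2 = (O1-E1)^2/E1 + (O2-E2)^2/E2 with 1 df,
    HR = (O1/E1)/(O0/E0) and CI = exp(ln HR +- 1.96 sqrt(1/E1 + 1/E0)).
    Group 1 is the "high" group; HR > 1 means higher hazard in group 1.
    """
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValueError("log-rank test needs exactly two groups")
    time = records["time"].to_numpy(dtype=float)
    event = records["event"].to_numpy(dtype=int)
    grp = (records["group"].to_numpy() == groups[1]).astype(int)
    if event.sum() == 0:
        raise ValueError("no events observed")

    chi2, o, e = _logrank_oe(time, event, grp)
    p = float(stats.chi2.sf(chi2, df=1))
    o0, o1 = o
    e0, e1 = e
    if e0 > 0 and e1 > 0 and o0 > 0 and o1 > 0:
        hr = (o1 / e1) / (o0 / e0)
        half = 1.96 * np.sqrt(1.0 / e1 + 1.0 / e0)
        ci = (float(hr * np.exp(-half)), float(hr * np.exp(half)))
    else:
        hr, ci = float("nan"), (float("nan"), float("nan"))
    return {
        "chi2": float(chi2),
        "p": p,
        "hazard_ratio": float(hr),
        "hr_ci_low": ci[0],
        "hr_ci_high": ci[1],
        "observed": [float(o0), float(o1)],
        "expected": [float(e0), float(e1)],
    }


def _logrank_oe(
    time: np.ndarray, event: np.ndarray, grp: np.ndarray
) -> tuple[float, tuple[float, float], tuple[float, float]]:
    """Vectorized observed/expected tally over the pooled event times."""
    event_times = np.unique(time[event == 1])
    t1_sorted = np.sort(time[grp == 1])
    t_all_sorted = np.sort(time)
    n1 = len(t1_sorted) - np.searchsorted(t1_sorted, event_times, side="left")
    n_tot = len(t_all_sorted) - np.searchsorted(t_all_sorted, event_times, side="left")
    te1 = np.sort(time[(event == 1) & (grp == 1)])
    te_all = np.sort(time[event == 1])
    d1 = np.searchsorted(te1, event_times, side="right") - np.searchsorted(te1, event_times, side="left")
    d_tot = np.searchsorted(te_all, event_times, side="right") - np.searchsorted(
        te_all, event_times, side="left"
    )
    e1_terms = d_tot * n1 / n_tot
    e1 = float(e1_terms.sum())
    o1 = float(d1.sum())
    o_tot = float(d_tot.sum())
    o0, e0 = o_tot - o1, o_tot - e1
    chi2 = 0.0
    if e1 > 0:
        chi2 += (o1 - e1) ** 2 / e1
    if e0 > 0:
        chi2 += (o0 - e0) ** 2 / e0
    return chi2, (o0, o1), (e0, e1)


# ---------------------------------------------------------------------------
# over-representation analysis


def ora(
    query: list[str],
    background: list[str],
    sets: dict[str, list[str]],
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against gene sets.

    For each set, the overlap count with the query and the upper-tail
    hypergeometric p (probability of an overlap at least this large given the
    background) are computed; with ``ease=True`` the overlap is reduced by one
    (the conservative EASE-style variant). Benjamini-Hochberg FDR is applied
    across all sets and the table is ranked by descending count then ascending
    p. Set members outside the background are ignored for counting.
    """
    bg = set(background)
    q = set(query)
    outside = q - bg
    if outside:
        raise ValueError(f"query genes outside the background: {sorted(outside)[:5]}")
    m_total = len(bg)
    n_query = len(q)
    rows = []
    for name, members in sets.items():
        mem = set(members) & bg
        k = len(q & mem)
        k_eff = max(k - 1, 0) if ease else k
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k_eff - 1, m_total, len(mem), n_query))
        rows.append({"set": name, "size": len(mem), "count": k, "p": p})
    table = pd.DataFrame(rows)
    if len(table):
        table["bh_fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["count", "p", "set"], ascending=[False, True, True]).reset_index(
            drop=True
        )
    else:
        table["bh_fdr"] = []
    return table
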