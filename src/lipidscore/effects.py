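"""Per-lipid diet-intervention effect estimation and component selection.

For each lipid the post-intervention log concentration is regressed on the
trial arm indicator (control as reference), the baseline log concentration,
age, BMI and sex.  The arm coefficient, its model-based standard error and a
two-sided t-test p-value form the effect table; Benjamini-Hochberg selection
at a configurable FDR level picks the score components, whose weights equal
the estimated effects.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import ols
from .scoring import ScoreDefinition
from .synth import TrialDataset

logger = logging.getLogger(__name__)


def estimate_diet_effects(trial: TrialDataset, fdr_level: float = 0.05) -> pd.DataFrame:
    """Baseline-adjusted arm effects per lipid, with BH q-values and selection flags.

    Returns a data frame indexed by lipid name with columns
    ``beta, se, p, q, selected`` plus the residual degrees of freedom.
    Constant lipids are excluded with a log entry.
    """
    if trial.baseline.scale != "log" or trial.post.scale != "log":
        raise ValueError("trial matrices must be log transformed")
    subj = trial.subjects
    arm = subj["arm"].to_numpy(dtype=float)
    if set(np.unique(arm)) - {0.0, 1.0}:
        raise ValueError("arm must be coded 0 (control) / 1 (intervention)")
    covs = np.column_stack([
        np.ones(len(subj)),
        arm,
        np.zeros(len(subj)),  # placeholder for baseline concentration
        subj["age"].to_numpy(dtype=float),
        subj["bmi"].to_numpy(dtype=float),
        subj["sex"].to_numpy(dtype=float),
    ])
    names = ("intercept", "arm", "baseline", "age", "bmi", "sex")
    base = trial.baseline.values.to_numpy(dtype=float)
    post = trial.post.values.to_numpy(dtype=float)
    rows = []
    excluded = []
    for j, lipid in enumerate(trial.post.values.columns):
        if np.std(post[:, j]) == 0 or np.std(base[:, j]) == 0:
            excluded.append(lipid)
            continue
        X = covs.copy()
        X[:, 2] = base[:, j]
        fit = ols(post[:, j], X, names)
        rows.append((lipid, fit.beta[1], fit.se[1], fit.p[1], fit.df_resid))
    if excluded:
        logger.info("estimate_diet_effects: excluded constant lipids: %s", excluded)
    table = pd.DataFrame(rows, columns=["lipid", "beta", "se", "p", "df_resid"]).set_index("lipid")
    q, reject = bh_fdr(table["p"].to_numpy(), level=fdr_level)
    table["q"] = q
    table["selected"] = reject
    table.attrs["fdr_level"] = fdr_level
    table.attrs["excluded"] = excluded
    return table


def bh_fdr(p_values, level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and the rejection set at ``level``.

    q-values are the monotone step-up adjusted p-values; the rejection set
    ``q < level`` coincides with the classic step-up rule.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    # classic step-up rejection: largest k with p_(k) <= k/m * level
    thresh = np.arange(1, m + 1) / m * level
    below = p[order] <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        kmax = int(np.max(np.flatnonzero(below)))
        reject[order[: kmax + 1]] = True
    return q, reject


def select_components(effects: pd.DataFrame, level: float = 0.05) -> ScoreDefinition:
    """Build an unscaled score definition from the FDR-selected effect rows."""
    q, reject = bh_fdr(effects["p"].to_numpy(), level=level)
    sel = effects.loc[reject]
    if sel.empty:
        logger.warning("select_components: no lipid passed the FDR threshold; empty score")
    return ScoreDefinition(
        variables=tuple(sel.index),
        weights=tuple(float(b) for b in sel["beta"]),
        scale=1.0,
        variant="MLS",
        provenance={"fdr_level": level, "n_candidates": int(len(effects)),
                    "n_selected": int(len(sel))},
    )
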