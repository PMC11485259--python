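"""Synthetic trial / cohort / matched / two-platform data with known ground truth.

All generators take explicit integer seeds and are bit-reproducible.  The
lipidome is modelled as multivariate normal on the natural-log scale with a
sparse precision matrix (random spanning tree plus extra random edges,
positive-definiteness guaranteed by diagonal loading).  Intervention effects
are additive log-concentration shifts on a designated affected subset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._stats import require_seed
from .lipids import LipidMatrix, fa_sum_catalog

logger = logging.getLogger(__name__)

# config defaults for covariate distributions (assumptions, not calibrations)
AGE_RANGE = (35.0, 65.0)
BMI_MEAN, BMI_SD = 26.0, 3.5
RHO_TIME_DEFAULT = 0.6


@dataclass
class GroundTruth:
    """Generating model for the synthetic lipidome and outcomes."""

    variables: list[str]
    precision: np.ndarray
    graph: nx.Graph
    mu: np.ndarray
    affected: np.ndarray          # sorted indices with nonzero effect
    delta: np.ndarray             # per-lipid additive log-shift (intervention arm)
    hazard_coef: float = 0.0      # log-hazard per s.d. of true score
    baseline_hazard: float = 0.004  # events per person-year
    censor_age: float = 85.0
    missing_rate: float = 0.0
    censor_quantile: float = 0.05
    rho_time: float = RHO_TIME_DEFAULT
    _covariance: np.ndarray | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def covariance(self) -> np.ndarray:
        if self._covariance is None:
            object.__setattr__(self, "_covariance", np.linalg.inv(self.precision))
        return self._covariance

    def __post_init__(self):
        np.linalg.cholesky(self.precision)  # raises if not positive definite
        nz = np.flatnonzero(self.delta)
        if not np.array_equal(np.sort(nz), np.sort(self.affected)):
            raise ValueError("delta must be nonzero exactly on the affected set")
        if self.baseline_hazard < 0 or self.censor_age < 0:
            raise ValueError("rates and ages must be nonnegative")


def generate_ground_truth(p: int, n_affected: int, graph_density: float,
                          effect_scale: float = 0.5, seed=None, *,
                          effect_sign: int = -1, hazard_coef: float = 0.0,
                          baseline_hazard: float = 0.004) -> GroundTruth:
    """Draw a sparse-precision lipidome model with an additive trial effect.

    The precision graph is a uniform random spanning tree plus random extra
    edges up to the requested density; ``graph_density=0`` yields a diagonal
    precision (independent lipids).  Effects are all negative by default
    (``effect_sign=-1``) with magnitudes ``effect_scale * U(0.8, 1.2)``.
    """
    rng = require_seed(seed)
    if not (0 <= n_affected <= p):
        raise ValueError("need 0 <= n_affected <= p")
    if not (0 <= graph_density < 1):
        raise ValueError("graph_density must be in [0, 1)")
    variables = fa_sum_catalog(p)

    g = nx.empty_graph(p)
    if graph_density > 0 and p > 1:
        # random spanning tree via a random-walk style attachment
        order = rng.permutation(p)
        for k in range(1, p):
            g.add_edge(int(order[k]), int(order[rng.integers(0, k)]))
        target = int(round(graph_density * p * (p - 1) / 2))
        while g.number_of_edges() < target:
            i, j = rng.integers(0, p, size=2)
            if i != j:
                g.add_edge(int(i), int(j))

    omega = np.eye(p)
    for i, j in g.edges:
        w = rng.uniform(0.1, 0.25) * rng.choice([-1.0, 1.0])
        omega[i, j] = omega[j, i] = w
    eigmin = float(np.linalg.eigvalsh(omega)[0])
    if eigmin < 0.1:
        omega += (0.1 - eigmin) * np.eye(p)
    d = 1.0 / np.sqrt(np.diag(omega))
    omega = omega * np.outer(d, d)
    try:
        np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - loading guarantees PD
        raise RuntimeError("precision matrix not positive definite after diagonal loading") from exc

    mu = rng.normal(np.log(50.0), 0.4, size=p)
    delta = np.zeros(p)
    affected = np.sort(rng.choice(p, size=n_affected, replace=False)) if n_affected else np.array([], dtype=int)
    if n_affected:
        delta[affected] = effect_sign * effect_scale * rng.uniform(0.8, 1.2, size=n_affected)
    return GroundTruth(variables=variables, precision=omega, graph=g, mu=mu,
                       affected=affected, delta=delta, hazard_coef=hazard_coef,
                       baseline_hazard=baseline_hazard)


# ---------------------------------------------------------------------------
# Trial
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    subjects: pd.DataFrame           # id, arm (0 control / 1 intervention), age, bmi, sex
    baseline: LipidMatrix            # log scale
    post: LipidMatrix                # log scale

    def __post_init__(self):
        if list(self.baseline.values.columns) != list(self.post.values.columns):
            raise ValueError("baseline and post matrices must share lipid variables")
        if not self.subjects.index.equals(self.baseline.values.index):
            raise ValueError("every subject needs both visits")


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame({
        "age": rng.uniform(*AGE_RANGE, size=n),
        "bmi": rng.normal(BMI_MEAN, BMI_SD, size=n),
        "sex": rng.integers(0, 2, size=n),
    })


def simulate_trial(gt: GroundTruth, n_per_arm, seed=None, rho_time: float | None = None) -> TrialDataset:
    """Two-visit, two-arm trial: post = correlated redraw of baseline + arm effect."""
    rng = require_seed(seed)
    if np.isscalar(n_per_arm):
        n_per_arm = (int(n_per_arm), int(n_per_arm))
    n0, n1 = n_per_arm
    if n0 < 2 or n1 < 2:
        raise ValueError("need at least 2 subjects per arm")
    n = n0 + n1
    rho = gt.rho_time if rho_time is None else rho_time
    chol = np.linalg.cholesky(gt.covariance)
    base = gt.mu + rng.standard_normal((n, gt.p)) @ chol.T
    post = (gt.mu + rho * (base - gt.mu)
            + np.sqrt(1 - rho ** 2) * (rng.standard_normal((n, gt.p)) @ chol.T))
    arm = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    post = post + np.outer(arm, gt.delta)
    ids = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    subjects = _draw_covariates(rng, n)
    subjects.index = ids
    subjects.insert(0, "arm", arm)
    return TrialDataset(
        subjects=subjects,
        baseline=LipidMatrix(pd.DataFrame(base, index=ids, columns=gt.variables), "log"),
        post=LipidMatrix(pd.DataFrame(post, index=ids, columns=gt.variables), "log"),
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

@dataclass
class CohortDataset:
    table: pd.DataFrame              # id-indexed: entry_age, exit_age, event, age, bmi, sex
    lipids: LipidMatrix              # log scale, baseline
    lipids_t2: LipidMatrix | None = None  # optional second timepoint (log)
    true_score: pd.Series | None = None   # standardized generating score

    def __post_init__(self):
        t = self.table
        if (t["exit_age"] <= t["entry_age"]).any():
            raise ValueError("exit_age must exceed entry_age")


def simulate_cohort(gt: GroundTruth, n: int, followup_years: float, score_def,
                    seed=None, *, second_timepoint: bool = False,
                    timepoint_gap: float = 10.0, drift_sd: float = 0.0) -> CohortDataset:
    """Cohort with exponential event times driven by the true (standardized) score.

    The hazard is ``baseline_hazard * exp(hazard_coef * z)`` where ``z`` is
    the score computed from ``score_def`` on the log lipid matrix,
    standardized within the simulated population.  Censoring is
    administrative at ``entry + followup_years`` (capped at ``censor_age``).
    """
    from .scoring import compute_score  # local import to avoid a cycle

    rng = require_seed(seed)
    if followup_years <= 0:
        raise ValueError("followup_years must be positive")
    if not np.isfinite(gt.hazard_coef):
        raise ValueError("hazard coefficient must be finite")
    if gt.baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    chol = np.linalg.cholesky(gt.covariance)
    ids = pd.Index([f"C{i:06d}" for i in range(n)], name="sample_id")
    x = gt.mu + rng.standard_normal((n, gt.p)) @ chol.T
    lipids = LipidMatrix(pd.DataFrame(x, index=ids, columns=gt.variables), "log")

    raw = compute_score(lipids, score_def)
    z = (raw - raw.mean()) / raw.std(ddof=0)

    cov = _draw_covariates(rng, n)
    cov.index = ids
    rate = gt.baseline_hazard * np.exp(gt.hazard_coef * z.to_numpy())
    t_event = rng.exponential(1.0 / rate)
    entry = cov["age"].to_numpy()
    t_cens = np.minimum(followup_years, np.maximum(gt.censor_age - entry, 1e-6))
    event = t_event < t_cens
    exit_age = entry + np.minimum(t_event, t_cens)
    table = cov.copy()
    table["entry_age"] = entry
    table["exit_age"] = exit_age
    table["event"] = event.astype(int)
    table["true_score"] = z

    lipids_t2 = None
    if second_timepoint:
        rho = gt.rho_time
        x2 = (gt.mu + rho * (x - gt.mu)
              + np.sqrt(1 - rho ** 2) * (rng.standard_normal((n, gt.p)) @ chol.T))
        if drift_sd > 0:
            x2 = x2 + rng.normal(0.0, drift_sd, size=(n, 1))
        lipids_t2 = LipidMatrix(pd.DataFrame(x2, index=ids, columns=gt.variables), "log")
        table["t2_before_events"] = True  # by construction both measures precede events
    return CohortDataset(table=table, lipids=lipids, lipids_t2=lipids_t2, true_score=z)


def draw_case_cohort(table: pd.DataFrame, subcohort_fraction: float, seed=None,
                     event_col: str = "event") -> pd.DataFrame:
    """Random subcohort (uniform, without replacement) plus all cases outside it."""
    rng = require_seed(seed)
    if not (0 < subcohort_fraction <= 1):
        raise ValueError("subcohort_fraction must be in (0, 1]")
    n = len(table)
    n_sub = int(round(subcohort_fraction * n))
    sub_idx = rng.choice(n, size=n_sub, replace=False)
    sub_mask = np.zeros(n, dtype=bool)
    sub_mask[sub_idx] = True
    is_case = table[event_col].astype(bool).to_numpy()
    if not is_case.any():
        logger.warning("draw_case_cohort: no cases for endpoint %r", event_col)
    keep = sub_mask | is_case
    out = table.loc[keep].copy()
    out["subcohort"] = sub_mask[keep]
    n_overlap = int((sub_mask & is_case).sum())
    out.attrs["subcohort_cases"] = n_overlap
    logger.info("draw_case_cohort: subcohort=%d, cases=%d (overlap %d)",
                n_sub, int(is_case.sum()), n_overlap)
    return out


def draw_matched_pairs(table: pd.DataFrame, matching_vars, seed=None, *,
                       event_col: str = "event", caliper: dict | None = None) -> pd.DataFrame:
    """1:1 matching of each case to a unique control within exact strata.

    ``matching_vars`` are matched exactly; ``caliper`` maps continuous
    columns to maximum absolute differences (the nearest eligible control is
    taken).  Controls are used at most once.  Unmatched cases are dropped
    with a logged count.  The pairing is invariant to input row order for a
    fixed seed (rows are canonically sorted before randomization).
    """
    rng = require_seed(seed)
    caliper = caliper or {}
    t = table.sort_index()
    is_case = t[event_col].astype(bool)
    cases = t.loc[is_case]
    controls = t.loc[~is_case]
    key_cols = list(matching_vars)
    cal_cols = list(caliper)

    def stratum(df):
        if not key_cols or df.empty:
            return pd.Series("", index=df.index, dtype=str)
        return df[key_cols].astype(str).agg("|".join, axis=1)

    ctrl_by_stratum: dict[str, list] = {}
    for cid, key in stratum(controls).items():
        ctrl_by_stratum.setdefault(key, []).append(cid)
    case_order = cases.index.to_numpy()[rng.permutation(len(cases))]
    case_strata = stratum(cases)
    rows = []
    n_unmatched = 0
    pair = 0
    for cid in case_order:
        key = case_strata.loc[cid]
        pool = ctrl_by_stratum.get(key, [])
        if cal_cols and pool:
            dists = []
            for ctl in pool:
                d = sum(abs(float(t.at[cid, c]) - float(t.at[ctl, c])) / caliper[c] for c in cal_cols)
                ok = all(abs(float(t.at[cid, c]) - float(t.at[ctl, c])) <= caliper[c] for c in cal_cols)
                dists.append((d, ctl, ok))
            dists = [x for x in dists if x[2]]
            chosen = min(dists)[1] if dists else None
        else:
            chosen = pool[int(rng.integers(0, len(pool)))] if pool else None
        if chosen is None:
            n_unmatched += 1
            continue
        ctrl_by_stratum[key].remove(chosen)
        for sid, role in ((cid, 1), (chosen, 0)):
            row = t.loc[sid].to_dict()
            row.update({"pair_id": pair, "subject_id": sid, "case": role})
            rows.append(row)
        pair += 1
    if n_unmatched:
        logger.info("draw_matched_pairs: %d unmatched case(s) dropped", n_unmatched)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["pair_id", "case"], ascending=[True, False]).reset_index(drop=True)
    out.attrs["n_unmatched"] = n_unmatched
    return out


def simulate_effect_modified_trial(n: int, hr_low: float, hr_high: float, seed=None, *,
                                   rho_scores: float = 0.7, baseline_hazard: float = 0.05,
                                   followup_years: float = 4.0,
                                   score_main_loghr: float = -0.2,
                                   arm_score_shift: float = 0.8) -> pd.DataFrame:
    """Randomized intervention cohort whose arm effect depends on the
    pre-intervention score stratum (below/above the median).

    Two correlated score measurements are drawn: pre-intervention, and 1 year
    in, where the intervention additionally raises the 1-year score by
    ``arm_score_shift`` (the diet moves the lipidome).  The event hazard is
    ``baseline_hazard * exp(score_main_loghr * pre + log(hr_stratum) * arm)``
    with ``hr_low`` applying below the population median (0) and ``hr_high``
    above.  Returns an analysis-ready table (full cohort: subcohort=True).
    """
    rng = require_seed(seed)
    pre = rng.standard_normal(n)
    arm = rng.integers(0, 2, size=n)
    post1 = (rho_scores * pre + arm_score_shift * arm
             + np.sqrt(1 - rho_scores ** 2) * rng.standard_normal(n))
    low = pre <= 0.0
    log_hr_arm = np.where(low, np.log(hr_low), np.log(hr_high))
    rate = baseline_hazard * np.exp(score_main_loghr * pre + log_hr_arm * arm)
    t_event = rng.exponential(1.0 / rate)
    cov = _draw_covariates(rng, n)
    entry = cov["age"].to_numpy()
    event = t_event < followup_years
    exit_age = entry + np.minimum(t_event, followup_years)
    table = cov.copy()
    table.index = pd.Index([f"P{i:06d}" for i in range(n)], name="sample_id")
    table["arm"] = arm
    table["pre_score"] = pre
    table["post1_score"] = post1
    table["entry_age"] = entry
    table["exit_age"] = exit_age
    table["event"] = event.astype(int)
    table["subcohort"] = True
    return table


# ---------------------------------------------------------------------------
# Macronutrients
# ---------------------------------------------------------------------------

def simulate_macronutrients(cohort: CohortDataset, coupling: float, seed=None, *,
                            noise_sd: float = 1.0) -> tuple[pd.DataFrame, pd.Series]:
    """Macronutrient densities plus a score coupled to the UFA-for-SFA contrast.

    Returns ``(macros, score)`` where the score equals
    ``coupling * UFA%E / 8 + noise`` so that the isocaloric leave-SFA-out
    substitution model recovers ``coupling`` per 8 %E of UFA-for-SFA
    replacement and zero for the other macronutrients.  Rows whose %E
    components would exceed 100 are redrawn (and counted in ``attrs``).
    """
    rng = require_seed(seed)
    n = len(cohort.table)
    idx = cohort.table.index

    def draw(k):
        sfa = rng.normal(12.0, 3.0, k).clip(3, 25)
        mufa = rng.normal(12.0, 3.0, k).clip(3, 25)
        pufa = rng.normal(6.0, 2.0, k).clip(1, 15)
        protein = rng.normal(16.0, 3.0, k).clip(8, 30)
        alcohol_g = rng.exponential(6.0, k).clip(0, 60)
        energy = rng.normal(2000.0, 350.0, k).clip(1100, 3600)
        alc_pct = alcohol_g * 7.0 / energy * 100.0
        carb = 100.0 - sfa - mufa - pufa - protein - alc_pct
        return pd.DataFrame({"sfa_pct": sfa, "mufa_pct": mufa, "pufa_pct": pufa,
                             "ufa_pct": mufa + pufa, "protein_pct": protein,
                             "carb_pct": carb, "alcohol_g": alcohol_g,
                             "energy_kcal": energy})

    macros = draw(n)
    n_rejected = 0
    bad = macros["carb_pct"] < 5.0
    while bad.any():
        n_rejected += int(bad.sum())
        macros.loc[bad.to_numpy(), :] = draw(int(bad.sum())).to_numpy()
        bad = macros["carb_pct"] < 5.0
    if n_rejected:
        logger.info("simulate_macronutrients: redrew %d rows with invalid %%E totals", n_rejected)
    macros.index = idx
    # animal/vegetable splits for the low-carbohydrate-diet score variants
    animal_frac = rng.uniform(0.3, 0.9, n)
    macros["animal_fat_pct"] = (macros["sfa_pct"] + macros["ufa_pct"]) * animal_frac
    macros["vegetable_fat_pct"] = (macros["sfa_pct"] + macros["ufa_pct"]) * (1 - animal_frac)
    macros["animal_protein_pct"] = macros["protein_pct"] * animal_frac
    macros["vegetable_protein_pct"] = macros["protein_pct"] * (1 - animal_frac)
    macros.attrs["n_rejected"] = n_rejected

    score = coupling * macros["ufa_pct"] / 8.0 + rng.normal(0.0, noise_sd, n)
    score.name = "score"
    return macros, score
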