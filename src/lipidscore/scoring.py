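"""Weighted lipid scores: computation, standardization and cross-platform reduction.

A score is a weighted sum of log lipid concentrations divided by a scaling
constant.  Standardization sets the scale either to the estimated trial-arm
contrast (one score unit = the trial diet effect) or to a reference-sample
standard deviation (per-s.d. reporting).  Reduction ports a score to a
lower-resolution platform by keeping directly available variables and
regression-imputing the rest from isobaric species of the same class, with
weights learned in a reference dataset carrying both resolutions.

Sign convention: selected trial effects are negative (the intervention
lowers the component lipids), so the weighted sum *rises* under the
intervention and a higher score reflects the intervention-like lipidome.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._stats import ols
from .lipids import (FA_SUM, ISOBARIC, MOLECULAR, CLASSES, LipidMatrix,
                     LipidVariable, parse_lipid_name)

logger = logging.getLogger(__name__)

CONTRAST_TOLERANCE = 1e-10


@dataclass(frozen=True)
class ScoreDefinition:
    """Ordered lipid variables, weights, scaling constant and provenance."""

    variables: tuple[str, ...]
    weights: tuple[float, ...]
    scale: float = 1.0
    offset: float = 0.0
    variant: str = "MLS"
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if len(self.variables) != len(set(self.variables)):
            raise ValueError("score variables must be unique")
        if len(self.variables) != len(self.weights):
            raise ValueError("variables and weights must align")
        w = np.asarray(self.weights, dtype=float)
        if len(w) and not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if not (np.isfinite(self.scale) and self.scale > 0):
            raise ValueError("scaling constant must be positive and finite")

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant,
            "scale": self.scale,
            "offset": self.offset,
            "weights": dict(zip(self.variables, self.weights)),
            "variables": list(self.variables),
            "provenance": self.provenance,
        }, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ScoreDefinition":
        blob = json.loads(text)
        variables = tuple(blob["variables"])
        return cls(variables=variables,
                   weights=tuple(blob["weights"][v] for v in variables),
                   scale=float(blob["scale"]),
                   offset=float(blob.get("offset", 0.0)),
                   variant=blob.get("variant", "MLS"),
                   provenance=blob.get("provenance", {}))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path) -> "ScoreDefinition":
        return cls.from_json(Path(path).read_text())


def compute_score(m: LipidMatrix, sdef: ScoreDefinition) -> pd.Series:
    """Per-sample score: (sum_j w_j * x_ij + offset) / scale on log values."""
    if m.scale != "log":
        raise ValueError("compute_score requires a log-scale matrix")
    missing = [v for v in sdef.variables if v not in m.values.columns]
    if missing:
        raise KeyError(f"matrix lacks score variables: {missing}")
    if not sdef.variables:
        return pd.Series(np.full(len(m.values), sdef.offset / sdef.scale),
                         index=m.values.index, name="score")
    x = m.values[list(sdef.variables)].to_numpy(dtype=float)
    s = (x @ sdef.weight_array + sdef.offset) / sdef.scale
    return pd.Series(s, index=m.values.index, name="score")


def _arm_effect_on_score(sdef: ScoreDefinition, trial) -> tuple[float, float]:
    """Baseline-adjusted arm effect on the (already scaled) score; same model
    family as the per-lipid effect estimation."""
    s_base = compute_score(trial.baseline, sdef)
    s_post = compute_score(trial.post, sdef)
    subj = trial.subjects
    X = np.column_stack([
        np.ones(len(subj)),
        subj["arm"].to_numpy(dtype=float),
        s_base.to_numpy(),
        subj["age"].to_numpy(dtype=float),
        subj["bmi"].to_numpy(dtype=float),
        subj["sex"].to_numpy(dtype=float),
    ])
    fit = ols(s_post.to_numpy(), X, ("intercept", "arm", "baseline", "age", "bmi", "sex"))
    return float(fit.beta[1]), float(fit.se[1])


def standardize_to_contrast(sdef: ScoreDefinition, trial) -> ScoreDefinition:
    """Set the scale so one score unit equals the estimated trial-arm contrast.

    After scaling, re-estimating the arm effect on the scaled score yields
    exactly 1 (the model is linear, so the effect divides through).
    """
    unscaled = replace(sdef, scale=1.0)
    effect, _ = _arm_effect_on_score(unscaled, trial)
    if abs(effect) < CONTRAST_TOLERANCE:
        raise ValueError("arm effect on the score is ~0; contrast scale undefined")
    if effect < 0:
        raise ValueError("arm effect on the score is negative; check the sign convention")
    prov = {**sdef.provenance, "standardization": "intervention_contrast",
            "contrast": effect}
    return replace(sdef, scale=effect, provenance=prov)


def standardize_to_sd(sdef: ScoreDefinition, reference: LipidMatrix) -> ScoreDefinition:
    """Per-s.d. variant: scale = standard deviation of the unscaled score in a
    reference sample (e.g. the subcohort)."""
    unscaled = replace(sdef, scale=1.0)
    sd = float(compute_score(reference, unscaled).std(ddof=1))
    if sd < CONTRAST_TOLERANCE:
        raise ValueError("score has ~0 variance in the reference sample")
    prov = {**sdef.provenance, "standardization": "reference_sd", "sd": sd}
    return replace(sdef, scale=sd, provenance=prov)


def subscore(sdef: ScoreDefinition, variable_subset, variant: str | None = None) -> ScoreDefinition:
    """Restrict a score to a subset of its variables (weights carried over)."""
    subset = tuple(variable_subset)
    if not subset:
        raise ValueError("subscore requires a nonempty variable subset")
    extra = set(subset) - set(sdef.variables)
    if extra:
        raise KeyError(f"subset variables not in score definition: {sorted(extra)}")
    wmap = dict(zip(sdef.variables, sdef.weights))
    keep = tuple(v for v in sdef.variables if v in set(subset))
    return ScoreDefinition(variables=keep, weights=tuple(wmap[v] for v in keep),
                           scale=sdef.scale, offset=0.0,
                           variant=variant or "subscore",
                           provenance={**sdef.provenance, "parent": sdef.variant,
                                       "subset_size": len(keep)})


# ---------------------------------------------------------------------------
# Cross-platform reduction
# ---------------------------------------------------------------------------

@dataclass
class ReducedScoreMap:
    """Audit record: per original variable, kept / imputed / skipped status."""

    entries: dict[str, dict]

    def status_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries.values():
            counts[e["status"]] = counts.get(e["status"], 0) + 1
        return counts

    def to_json(self) -> str:
        return json.dumps(self.entries, sort_keys=True, indent=1)


def _can_contain(species: LipidVariable, target: LipidVariable) -> bool:
    """Could an isobaric species of the target's class contain the target fatty acid?"""
    if species.lipid_class != target.lipid_class:
        return False
    k = CLASSES[species.lipid_class].n_chains
    c, d = target.fatty_acid
    if species.resolution == MOLECULAR:
        return (c, d) in species.chains
    if species.resolution != ISOBARIC:
        return False
    rc = species.total_carbons - c
    rd = species.total_double_bonds - d
    return (12 * (k - 1) <= rc <= 26 * (k - 1)) and (0 <= rd <= 6 * (k - 1))


def reduce_score(sdef: ScoreDefinition, available, reference: LipidMatrix,
                 variant: str = "rMLS") -> tuple[ScoreDefinition, ReducedScoreMap]:
    """Port a score onto a platform that only measures ``available`` variables.

    Each original variable is kept when directly available; otherwise it is
    imputed by OLS of its log value on the log values of available isobaric
    species of the same class that could contain its fatty acid (weights
    learned in ``reference``, which must carry both resolutions); otherwise
    it is skipped.  The result is flattened into a single linear score over
    the available variables (plus an intercept offset), rescaled by the
    original scaling constant.
    """
    if reference.scale != "log":
        raise ValueError("reference matrix must be log scale")
    available = list(dict.fromkeys(available))
    avail_set = set(available)
    missing_ref = [v for v in sdef.variables if v not in reference.values.columns]
    if missing_ref:
        raise KeyError(f"reference lacks original score variables: {missing_ref}")
    new_weights: dict[str, float] = {}
    offset = sdef.offset
    entries: dict[str, dict] = {}
    parsed_avail = {a: parse_lipid_name(a) for a in available}
    for var, w in zip(sdef.variables, sdef.weights):
        if var in avail_set:
            new_weights[var] = new_weights.get(var, 0.0) + w
            entries[var] = {"status": "kept"}
            continue
        target = parse_lipid_name(var)
        if target.resolution != FA_SUM:
            entries[var] = {"status": "skipped", "reason": "no imputation rule"}
            continue
        preds = [a for a in available
                 if a in reference.values.columns and _can_contain(parsed_avail[a], target)]
        if not preds:
            entries[var] = {"status": "skipped", "reason": "no eligible predictors"}
            continue
        y = reference.values[var].to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(y))] +
                            [reference.values[p].to_numpy(dtype=float) for p in preds])
        fit = ols(y, X, ("intercept", *preds))
        offset += w * fit.beta[0]
        for p, b in zip(preds, fit.beta[1:]):
            new_weights[p] = new_weights.get(p, 0.0) + w * float(b)
        entries[var] = {"status": "imputed", "predictors": preds,
                        "coefficients": [float(b) for b in fit.beta[1:]],
                        "intercept": float(fit.beta[0])}
    statuses = {e["status"] for e in entries.values()}
    if statuses <= {"skipped"}:
        raise ValueError("reduction failed: no original variable kept or imputed")
    ordered = tuple(v for v in available if v in new_weights)
    reduced = ScoreDefinition(
        variables=ordered,
        weights=tuple(new_weights[v] for v in ordered),
        scale=sdef.scale,
        offset=offset,
        variant=variant,
        provenance={**sdef.provenance, "reduced_from": sdef.variant,
                    "status_counts": ReducedScoreMap(entries).status_counts()},
    )
    return reduced, ReducedScoreMap(entries)
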