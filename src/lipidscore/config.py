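"""Run configuration: seeds, presets, thresholds and named covariate sets."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

# Named multivariable adjustment sets; "MV" is the full multivariable model.
DEFAULT_COVARIATE_SETS = {
    "age_sex": ["age", "sex"],
    "MV": ["age", "sex", "bmi"],
}

# Preset parameterizations for the synthetic study designs.  Sizes are scaled
# down from the emulated designs to keep end-to-end runs fast.
PRESETS = {
    "divas-like": dict(p=40, n_affected=16, graph_density=0.05, effect_scale=0.7,
                       n_per_arm=[65, 130], cohort_n=3000, followup_years=10.0,
                       subcohort_fraction=0.3, hazard_coef=-0.386,
                       baseline_hazard=0.004),
    "epic-like": dict(p=60, n_affected=24, graph_density=0.05, effect_scale=0.7,
                      n_per_arm=[65, 130], cohort_n=6000, followup_years=12.0,
                      subcohort_fraction=0.2, hazard_coef=-0.386,
                      baseline_hazard=0.004),
    "nhs-like": dict(p=40, n_affected=16, graph_density=0.05, effect_scale=0.7,
                     n_per_arm=[65, 130], cohort_n=4000, followup_years=10.0,
                     subcohort_fraction=0.25, hazard_coef=-0.33,
                     baseline_hazard=0.005),
    "predimed-like": dict(p=30, n_affected=12, graph_density=0.06, effect_scale=0.7,
                          n_per_arm=[65, 130], cohort_n=1500, followup_years=4.0,
                          subcohort_fraction=0.5, hazard_coef=-0.386,
                          baseline_hazard=0.03),
}


@dataclass
class RunConfig:
    seed: int = 1
    preset: str = "divas-like"
    fdr_level: float = 0.05
    alpha_ci: float = 0.01
    netcoupler_p: float = 0.05
    max_missing_fraction: float = 0.70
    covariate_sets: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_SETS))
    out_dir: str = "results"
    network_max_nodes: int = 20

    def __post_init__(self):
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        for name, val, lo, hi in (("fdr_level", self.fdr_level, 0.0, 1.0),
                                  ("alpha_ci", self.alpha_ci, 0.0, 1.0),
                                  ("netcoupler_p", self.netcoupler_p, 0.0, 1.0),
                                  ("max_missing_fraction", self.max_missing_fraction, 0.0, 1.0)):
            if not (lo < val < hi):
                raise ValueError(f"{name} must lie strictly within ({lo}, {hi}); got {val}")
        self.seed = int(self.seed)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        blob = yaml.safe_load(text) or {}
        return cls(**blob)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @property
    def preset_params(self) -> dict:
        return dict(PRESETS[self.preset])
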