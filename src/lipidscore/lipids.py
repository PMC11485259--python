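"""Lipid nomenclature and matrix preprocessing.

Covers the 16 lipid classes handled by the scoring workflow (7 phospholipid
(sub)classes, 5 sphingolipid classes, 3 neutral glycerolipid classes and
cholesterol esters), three variable resolutions (molecular species, isobaric
species, within-class fatty-acid sums), and the preprocessing chain:
missingness filtering, left-censored imputation, dilution correction and the
natural-log transform.

Naming grammar (canonical forms, aliases accepted on parse):

* molecular species   ``CE(16:0)``, ``DAG(16:0/18:1)``, ``CER(d18:1/24:0)``,
  ``TAG(16:0/18:1/18:2)``, ``PE-P(18:0/20:4)``
* isobaric species    ``TAG 52:2``, ``PE P-38:4``
* class fatty-acid sum ``CE.FA16:0``, ``PE-P.FA18:0``

Within-class fatty-acid sums count a fatty acid once per chain carrying it,
so a double-chain species such as DAG(16:0/16:0) contributes twice to
(DAG, 16:0).  This additive convention is a documented choice.
"""
from __future__ import annotations

import itertools
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import require_seed

logger = logging.getLogger(__name__)

MOLECULAR = "molecular_species"
ISOBARIC = "isobaric_species"
FA_SUM = "class_fatty_acid_sum"

FA_CARBON_RANGE = (12, 26)
FA_DOUBLE_BOND_RANGE = (0, 6)


class LipidNameError(ValueError):
    """Unparseable lipid name or unknown class token."""


class ScaleError(ValueError):
    """Operation applied to a matrix on the wrong scale."""


@dataclass(frozen=True)
class ClassInfo:
    token: str
    n_chains: int  # number of variable fatty-acid chains per molecule
    category: str


_CLASS_DEFS = [
    ClassInfo("CE", 1, "cholesterol_ester"),
    ClassInfo("MG", 1, "neutral_glycerolipid"),
    ClassInfo("DAG", 2, "neutral_glycerolipid"),
    ClassInfo("TAG", 3, "neutral_glycerolipid"),
    ClassInfo("CER", 1, "sphingolipid"),
    ClassInfo("DCER", 1, "sphingolipid"),
    ClassInfo("LCER", 1, "sphingolipid"),
    ClassInfo("HCER", 1, "sphingolipid"),
    ClassInfo("SM", 1, "sphingolipid"),
    ClassInfo("LPC", 1, "phospholipid"),
    ClassInfo("LPE", 1, "phospholipid"),
    ClassInfo("PC", 2, "phospholipid"),
    ClassInfo("PE", 2, "phospholipid"),
    ClassInfo("PE-O", 2, "phospholipid"),
    ClassInfo("PE-P", 2, "phospholipid"),
    ClassInfo("PI", 2, "phospholipid"),
]
CLASSES: dict[str, ClassInfo] = {c.token: c for c in _CLASS_DEFS}

_ALIASES = {
    "CHE": "CE",
    "MAG": "MG",
    "DG": "DAG",
    "TG": "TAG",
    "DHCER": "DCER",
    "LACCER": "LCER",
    "HEXCER": "HCER",
    "PE-O": "PE-O",
    "PE-P": "PE-P",
    "PE O": "PE-O",
    "PE P": "PE-P",
    "PEO": "PE-O",
    "PEP": "PE-P",
}

ONE_FA_CLASSES = tuple(c.token for c in _CLASS_DEFS if c.n_chains == 1)
MULTI_FA_CLASSES = tuple(c.token for c in _CLASS_DEFS if c.n_chains > 1)


def _canon_class(token: str) -> str:
    t = token.strip().rstrip("-").strip().upper().replace(" ", "-")
    t = _ALIASES.get(t, t)
    if t not in CLASSES:
        raise LipidNameError(f"unknown lipid class token: {token!r}")
    return t


@dataclass(frozen=True, order=True)
class LipidVariable:
    """Identity of one lipid measurement column."""

    lipid_class: str
    resolution: str
    fatty_acid: tuple[int, int] | None = None
    total_carbons: int | None = None
    total_double_bonds: int | None = None
    chains: tuple[tuple[int, int], ...] | None = None
    backbone: tuple[int, int] | None = None

    def __post_init__(self):
        if self.lipid_class not in CLASSES:
            raise LipidNameError(f"unknown lipid class: {self.lipid_class!r}")
        if self.resolution == FA_SUM:
            if self.fatty_acid is None:
                raise LipidNameError("class fatty-acid sums require a fatty acid")
            c, d = self.fatty_acid
            if not (FA_CARBON_RANGE[0] <= c <= FA_CARBON_RANGE[1]):
                raise LipidNameError(f"fatty acid carbons {c} outside {FA_CARBON_RANGE}")
            if not (FA_DOUBLE_BOND_RANGE[0] <= d <= FA_DOUBLE_BOND_RANGE[1]):
                raise LipidNameError(f"double bonds {d} outside {FA_DOUBLE_BOND_RANGE}")
        elif self.resolution == ISOBARIC:
            if self.total_carbons is None or self.total_double_bonds is None:
                raise LipidNameError("isobaric species require total carbons/double bonds")
        elif self.resolution == MOLECULAR:
            if not self.chains:
                raise LipidNameError("molecular species require chains")
        else:
            raise LipidNameError(f"unknown resolution: {self.resolution!r}")

    # -- constructors --------------------------------------------------
    @classmethod
    def fa_sum(cls, lipid_class: str, carbons: int, double_bonds: int) -> "LipidVariable":
        return cls(_canon_class(lipid_class), FA_SUM, fatty_acid=(carbons, double_bonds))

    @classmethod
    def isobaric(cls, lipid_class: str, total_carbons: int, total_double_bonds: int) -> "LipidVariable":
        return cls(_canon_class(lipid_class), ISOBARIC,
                   total_carbons=total_carbons, total_double_bonds=total_double_bonds)

    @classmethod
    def molecular(cls, lipid_class: str, chains, backbone=None) -> "LipidVariable":
        return cls(_canon_class(lipid_class), MOLECULAR,
                   chains=tuple(tuple(ch) for ch in chains),
                   backbone=tuple(backbone) if backbone is not None else None)

    @property
    def name(self) -> str:
        return format_lipid_name(self)

    @property
    def category(self) -> str:
        return CLASSES[self.lipid_class].category


_FA_SUM_RE = re.compile(r"^(?P<cls>[A-Za-z][A-Za-z \-]*?)\.FA(?P<c>\d{1,2}):(?P<d>\d)$")
_MOLECULAR_RE = re.compile(r"^(?P<cls>[A-Za-z][A-Za-z \-]*?)\((?P<chains>[^()]+)\)$")
_ISOBARIC_RE = re.compile(r"^(?P<cls>[A-Za-z][A-Za-z \-]*?)[ \-]?(?P<c>\d{1,2}):(?P<d>\d)$")
_CHAIN_RE = re.compile(r"^(?P<pref>d|t|O-|P-)?(?P<c>\d{1,2}):(?P<d>\d)$")


def parse_lipid_name(name: str) -> LipidVariable:
    """Parse a lipid name in the documented grammar into a :class:`LipidVariable`."""
    s = str(name).strip()
    m = _FA_SUM_RE.match(s)
    if m:
        return LipidVariable.fa_sum(m["cls"], int(m["c"]), int(m["d"]))
    m = _MOLECULAR_RE.match(s)
    if m:
        cls = _canon_class(m["cls"])
        chains: list[tuple[int, int]] = []
        backbone = None
        for tok in m["chains"].split("/"):
            cm = _CHAIN_RE.match(tok.strip())
            if not cm:
                raise LipidNameError(f"cannot parse chain {tok!r} in {name!r}")
            c, d = int(cm["c"]), int(cm["d"])
            pref = cm["pref"]
            if pref in ("d", "t"):
                backbone = (c, d)
            else:
                if pref == "P-" and cls == "PE":
                    cls = "PE-P"
                elif pref == "O-" and cls == "PE":
                    cls = "PE-O"
                chains.append((c, d))
        info = CLASSES[cls]
        if len(chains) != info.n_chains:
            raise LipidNameError(
                f"{name!r}: class {cls} expects {info.n_chains} variable chain(s), got {len(chains)}")
        return LipidVariable(cls, MOLECULAR, chains=tuple(chains), backbone=backbone)
    m = _ISOBARIC_RE.match(s)
    if m:
        cls = _canon_class(m["cls"])
        c, d = int(m["c"]), int(m["d"])
        if CLASSES[cls].n_chains == 1:
            # single-chain classes: a bare composition is the molecular species
            return LipidVariable(cls, MOLECULAR, chains=((c, d),))
        return LipidVariable(cls, ISOBARIC, total_carbons=c, total_double_bonds=d)
    raise LipidNameError(f"cannot parse lipid name: {name!r}")


def format_lipid_name(v: LipidVariable) -> str:
    """Canonical formatter; ``parse_lipid_name(format_lipid_name(v))`` round-trips."""
    if v.resolution == FA_SUM:
        c, d = v.fatty_acid
        return f"{v.lipid_class}.FA{c}:{d}"
    if v.resolution == ISOBARIC:
        return f"{v.lipid_class} {v.total_carbons}:{v.total_double_bonds}"
    parts = []
    if v.backbone is not None:
        parts.append(f"d{v.backbone[0]}:{v.backbone[1]}")
    parts.extend(f"{c}:{d}" for c, d in v.chains)
    return f"{v.lipid_class}({'/'.join(parts)})"


# ---------------------------------------------------------------------------
# Lipid matrix
# ---------------------------------------------------------------------------

@dataclass
class LipidMatrix:
    """Samples x lipid-variables grid with an explicit scale flag.

    ``values`` holds NaN where a measurement is missing.  ``scale`` is
    either ``"raw"`` (strictly positive concentrations / abundances) or
    ``"log"`` (natural log, applied at most once).
    """

    values: pd.DataFrame
    scale: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale not in ("raw", "log"):
            raise ScaleError(f"scale must be 'raw' or 'log', got {self.scale!r}")
        if self.scale == "raw":
            arr = self.values.to_numpy(dtype=float)
            if np.any(arr[~np.isnan(arr)] <= 0):
                raise ValueError("raw-scale values must be strictly positive where observed")

    @property
    def variables(self) -> list[LipidVariable]:
        return [parse_lipid_name(c) for c in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def copy(self) -> "LipidMatrix":
        return LipidMatrix(self.values.copy(), self.scale, dict(self.meta))


def log_transform(m: LipidMatrix) -> LipidMatrix:
    """Natural-log transform (applied at most once)."""
    if m.scale == "log":
        raise ScaleError("matrix is already log transformed")
    return LipidMatrix(np.log(m.values), "log", {**m.meta, "log": True})


def exp_transform(m: LipidMatrix) -> LipidMatrix:
    if m.scale == "raw":
        raise ScaleError("matrix is already on the raw scale")
    return LipidMatrix(np.exp(m.values), "raw", {k: v for k, v in m.meta.items() if k != "log"})


def _require_raw(m: LipidMatrix, op: str) -> None:
    if m.scale != "raw":
        raise ScaleError(f"{op} must operate on raw concentrations, not log values")


def within_class_fatty_acid_sums(m: LipidMatrix) -> LipidMatrix:
    """Sum molecular-species concentrations into (class, fatty acid) variables.

    A species carrying fatty acid F on k chains contributes k times its
    concentration.  Sphingoid backbones (the ``d18:1`` part) are not counted
    as variable fatty acids.  Requires raw-scale input: sums are taken on
    concentrations, never on logs.
    """
    _require_raw(m, "within-class fatty-acid summation")
    cols = list(m.values.columns)
    variables = m.variables
    arr = m.values.to_numpy(dtype=float)
    acc: dict[str, np.ndarray] = {}
    cnt: dict[str, np.ndarray] = {}
    for j, (col, var) in enumerate(zip(cols, variables)):
        if var.resolution != MOLECULAR:
            raise ValueError(f"expected molecular species input, got {col!r} ({var.resolution})")
        x = arr[:, j]
        obs = ~np.isnan(x)
        for (c, d) in var.chains:
            key = LipidVariable.fa_sum(var.lipid_class, c, d).name
            if key not in acc:
                acc[key] = np.zeros(arr.shape[0])
                cnt[key] = np.zeros(arr.shape[0], dtype=int)
            acc[key][obs] += x[obs]
            cnt[key][obs] += 1
    out = {}
    for key in acc:
        vals = acc[key].copy()
        vals[cnt[key] == 0] = np.nan
        out[key] = vals
    df = pd.DataFrame(out, index=m.values.index)
    df = df[sorted(df.columns)]
    return LipidMatrix(df, "raw", {**m.meta, "aggregation": "class_fatty_acid_sum"})


def isobaric_species_sums(m: LipidMatrix, classes=None) -> LipidMatrix:
    """Sum molecular species sharing (class, total carbons, total double bonds).

    Only defined for classes with more than one variable fatty acid per
    molecule (diglycerides, triglycerides, phosphatidylcholines,
    phosphatidylethanolamines incl. ether/plasmalogen, phosphatidylinositol).
    """
    _require_raw(m, "isobaric-species summation")
    if classes is None:
        classes = MULTI_FA_CLASSES
    classes = tuple(_canon_class(c) for c in classes)
    for c in classes:
        if CLASSES[c].n_chains == 1:
            raise ValueError(f"isobaric aggregation undefined for one-fatty-acid class {c}")
    cols = list(m.values.columns)
    variables = m.variables
    arr = m.values.to_numpy(dtype=float)
    acc: dict[str, np.ndarray] = {}
    cnt: dict[str, np.ndarray] = {}
    for j, (col, var) in enumerate(zip(cols, variables)):
        if var.lipid_class not in classes or var.resolution != MOLECULAR:
            continue
        tot_c = sum(c for c, _ in var.chains)
        tot_d = sum(d for _, d in var.chains)
        key = LipidVariable.isobaric(var.lipid_class, tot_c, tot_d).name
        x = arr[:, j]
        obs = ~np.isnan(x)
        if key not in acc:
            acc[key] = np.zeros(arr.shape[0])
            cnt[key] = np.zeros(arr.shape[0], dtype=int)
        acc[key][obs] += x[obs]
        cnt[key][obs] += 1
    out = {}
    for key in acc:
        vals = acc[key].copy()
        vals[cnt[key] == 0] = np.nan
        out[key] = vals
    df = pd.DataFrame(out, index=m.values.index)
    df = df[sorted(df.columns)]
    return LipidMatrix(df, "raw", {**m.meta, "aggregation": "isobaric_species"})


def filter_missing(m: LipidMatrix, max_missing_fraction: float = 0.70) -> LipidMatrix:
    """Drop variables whose missing fraction strictly exceeds the threshold.

    The boundary is a strict inequality: a variable missing in exactly 70%
    of samples is retained.
    """
    frac = m.values.isna().mean(axis=0)
    dropped = list(frac.index[frac > max_missing_fraction])
    if dropped:
        logger.info("filter_missing: dropped %d variables: %s", len(dropped), dropped)
    kept = m.values.drop(columns=dropped)
    meta = {**m.meta, "filtered_out": dropped, "max_missing_fraction": max_missing_fraction}
    return LipidMatrix(kept, m.scale, meta)


def impute_left_censored(m: LipidMatrix, method: str = "qrilc_like", seed=None) -> LipidMatrix:
    """Impute left-censored missing values.

    ``half_min`` replaces missing entries with half the observed per-variable
    minimum.  ``qrilc_like`` fits a normal distribution to the observed log
    values via regression of order statistics on normal quantiles and draws
    imputations from the truncated left tail below the censoring point (a
    simplified reimplementation of the QRILC idea, not a port).  Imputed
    values never exceed the observed per-variable minimum.
    """
    _require_raw(m, "left-censored imputation")
    if method not in ("qrilc_like", "half_min"):
        raise ValueError(f"unknown imputation method: {method!r}")
    rng = require_seed(seed) if method == "qrilc_like" else None
    df = m.values.copy()
    n = len(df)
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        miss = np.isnan(x)
        n_mis = int(miss.sum())
        if n_mis == 0:
            continue
        obs = x[~miss]
        use_method = method
        if method == "qrilc_like" and len(obs) < 4:
            logger.warning("impute_left_censored: %s has <4 observed values; falling back to half_min", col)
            use_method = "half_min"
        if use_method == "half_min":
            x[miss] = obs.min() / 2.0
        else:
            lo = np.log(np.sort(obs))
            ranks = np.arange(n_mis + 1, n + 1)
            pp = (ranks - 0.5) / n
            q = stats.norm.ppf(pp)
            sigma, mu = np.polyfit(q, lo, 1)
            sigma = max(float(sigma), 1e-12)
            zbound = stats.norm.ppf(max(n_mis / n, 1.0 / n))
            z = stats.truncnorm.rvs(-np.inf, zbound, size=n_mis, random_state=rng)
            vals = mu + sigma * z
            vals = np.minimum(vals, np.log(obs.min()))
            x[miss] = np.exp(vals)
        df[col] = x
    return LipidMatrix(df, "raw", {**m.meta, "imputation": method})


def dilution_correct(m: LipidMatrix, factor: float = 1.0 / 0.9) -> LipidMatrix:
    """Multiply all raw concentrations by a scalar dilution factor.

    Default 1/0.9 corrects for a diluent making up 10% of total volume.
    """
    _require_raw(m, "dilution correction")
    if factor <= 0:
        raise ValueError(f"dilution factor must be positive, got {factor}")
    return LipidMatrix(m.values * factor, "raw", {**m.meta, "dilution_factor": factor})


def censor_left(m: LipidMatrix, quantile: float = 0.05, variables=None) -> LipidMatrix:
    """Delete values below a per-variable quantile (left-censoring mechanism)."""
    _require_raw(m, "left censoring")
    if not (0 <= quantile < 1):
        raise ValueError("censor quantile must be in [0, 1)")
    df = m.values.copy()
    cols = variables if variables is not None else df.columns
    for col in cols:
        cut = df[col].quantile(quantile)
        df.loc[df[col] < cut, col] = np.nan
    return LipidMatrix(df, "raw", {**m.meta, "censor_quantile": quantile})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_matrix(m: LipidMatrix, path) -> None:
    """Write matrix as TSV plus a JSON sidecar recording scale and metadata."""
    path = Path(path)
    m.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")
    sidecar = {"scale": m.scale, "meta": _jsonable(m.meta)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))


def read_matrix(path, scale: str | None = None) -> LipidMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        blob = json.loads(sidecar.read_text())
        scale = scale or blob.get("scale")
        meta = blob.get("meta", {})
    return LipidMatrix(df, scale or "raw", meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def fa_sum_catalog(p: int) -> list[str]:
    """Deterministic catalog of `p` within-class fatty-acid sum names.

    Interleaves the 16 classes with a panel of plausible fatty acids
    (12-26 carbons, 0-6 double bonds) so any prefix covers many classes.
    """
    fas = [(12, 0), (14, 0), (14, 1), (15, 0), (16, 0), (16, 1), (17, 0),
           (18, 0), (18, 1), (18, 2), (18, 3), (20, 0), (20, 1), (20, 3),
           (20, 4), (20, 5), (22, 0), (22, 1), (22, 5), (22, 6), (23, 0),
           (24, 0), (24, 1), (25, 0), (26, 0), (26, 1), (16, 2), (17, 1)]
    tokens = [c.token for c in _CLASS_DEFS]
    names = []
    for fa, cls in itertools.product(fas, tokens):
        names.append(LipidVariable.fa_sum(cls, *fa).name)
        if len(names) == p:
            return names
    if len(names) < p:
        raise ValueError(f"catalog exhausted: at most {len(names)} variables available")
    return names
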