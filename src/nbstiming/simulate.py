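"""Synthetic newborn-screening cohort generator.

Population newborn-screening registries are access-restricted, so every
downstream stage of this package is exercised against simulated cohorts that
carry the statistical structure the analysis assumes:

* each of the 41 MS/MS analytes follows a smooth mean trajectory over age at
  blood collection (AaBC, 12-168 h) drawn from one of three parametric
  templates — exponential decay to a plateau, saturating rise, or a quadratic
  dip with recovery — matching the decreasing / increasing / dip-then-rise
  profiles seen in real screening panels;
* clinical covariates (gestational age, birth weight, sex, reported
  race/ethnicity, TPN) shift analyte levels multiplicatively, parameterised
  as additive offsets on the log scale in units of the analyte's log-SD;
* measurement and biological noise is multiplicative lognormal with a
  configurable coefficient of variation, keeping concentrations positive and
  right-skewed;
* false-positive case tables are drawn per disease as a multinomial over the
  early/standard/late collection windows.

Concentrations are in abstract units with micromol/L semantics.  A single
global seed is expanded into independent sub-streams (covariates, metabolite
noise, false positives) so each table can be regenerated independently, and
an identical config + seed always reproduces a bit-identical cohort.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CATEGORIES, RECORD_COLUMNS, assign_categories

__all__ = [
    "PANEL",
    "MetaboliteSpec",
    "CovariateModel",
    "FPModel",
    "GeneratorConfig",
    "default_config",
    "default_metabolite_specs",
    "default_fp_model",
    "trajectory_mean",
    "generate_cohort",
    "plant_effect",
    "generate_fp_cases",
]

#: The 41-analyte MS/MS screening panel: 11 amino acids, 29 acylcarnitines,
#: and succinylacetone.
PANEL = [
    # amino acids
    "Ala", "Arg", "Cit", "Gly", "Leu-Ile", "Met", "Orn", "Phe", "Pro", "Tyr", "Val",
    # acylcarnitines
    "C0", "C2", "C3", "C3DC", "C4", "C4DC", "C5", "C5:1", "C5DC", "C5OH",
    "C6", "C6DC", "C8", "C8:1", "C10", "C10:1", "C12", "C12:1", "C14",
    "C14:1", "C14OH", "C16", "C16:1", "C16OH", "C18", "C18:1", "C18:2",
    "C18OH", "C18:1OH",
    # succinylacetone
    "SA",
]

_SHAPES = ("decreasing", "increasing", "dip_then_rise", "constant")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class MetaboliteSpec:
    """Mean trajectory, covariate shifts and noise model for one analyte.

    Parameters
    ----------
    name
        Analyte identifier (e.g. ``"Phe"``, ``"C0"``).
    shape
        Trajectory template: ``decreasing`` (exponential decay from an
        elevated level at 12 h to the plateau ``base``), ``increasing``
        (saturating rise from ``base`` toward ``base * (1 + amp_sd * cv)``),
        ``dip_then_rise`` (quadratic dip of depth ``amp_sd`` SD centred at
        ``nadir`` with half-width ``width``), or ``constant``.
    base
        Plateau concentration (abstract units, micromol/L semantics).
    amp_sd
        Trajectory swing in units of the analyte's own SD (``base * cv``).
    tau
        Time constant (hours) of the exponential templates.
    nadir, width
        Centre and half-width (hours) of the dip template.
    cv
        Coefficient of variation of the multiplicative lognormal noise.
    shifts
        Covariate offsets in units of the log-scale SD; recognised keys are
        ``preterm``, ``male``, ``tpn`` and ``race:<category>``.
    planted
        Additive effects injected by :func:`plant_effect`, as
        ``(category, delta_sd)`` pairs.
    """

    name: str
    shape: str = "constant"
    base: float = 1.0
    amp_sd: float = 0.0
    tau: float = 20.0
    nadir: float = 30.0
    width: float = 40.0
    cv: float = 0.25
    shifts: Mapping[str, float] = field(default_factory=dict)
    planted: tuple = ()

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ConfigurationError(f"unknown trajectory shape {self.shape!r}")
        if self.base <= 0:
            raise ConfigurationError(f"{self.name}: base must be positive")
        if self.cv < 0:
            raise ConfigurationError(f"{self.name}: cv must be non-negative")
        if self.shape != "constant" and self.amp_sd * self.cv <= -1:
            raise ConfigurationError(f"{self.name}: trajectory dips below zero")

    @property
    def sigma_log(self) -> float:
        """Log-scale SD implied by the coefficient of variation."""
        return float(np.sqrt(np.log1p(self.cv**2)))

    def base_trajectory(self, aabc) -> np.ndarray:
        """Noise-free mean without covariate shifts or planted effects."""
        t = np.asarray(aabc, dtype=float)
        if np.any((t < 12) | (t > 168)):
            raise ValueError("aabc outside the 12-168 h collection window")
        swing = self.amp_sd * self.cv
        if self.shape == "constant":
            m = np.ones_like(t)
        elif self.shape == "decreasing":
            m = 1.0 + swing * np.exp(-(t - 12.0) / self.tau)
        elif self.shape == "increasing":
            m = 1.0 + swing * (1.0 - np.exp(-(t - 12.0) / self.tau))
        else:  # dip_then_rise: quadratic dip, recovery to plateau beyond width
            u = np.minimum(((t - self.nadir) / self.width) ** 2, 1.0)
            m = 1.0 - abs(swing) * (1.0 - u)
        return self.base * m

    def covariate_multiplier(self, covariates: Mapping[str, object]) -> float:
        """Multiplicative shift implied by one record's covariates."""
        s = 0.0
        s += self.shifts.get("preterm", 0.0) * (covariates.get("preterm", False) is True)
        s += self.shifts.get("male", 0.0) * (covariates.get("sex") == "male")
        s += self.shifts.get("tpn", 0.0) * (covariates.get("tpn") == "yes")
        race = covariates.get("race")
        if race is not None:
            s += self.shifts.get(f"race:{race}", 0.0)
        return float(np.exp(s * self.sigma_log))


def trajectory_mean(
    spec: MetaboliteSpec, aabc: float, covariates: Mapping[str, object] | None = None
) -> float:
    """Noise-free conditional mean concentration at ``aabc`` hours.

    Pure function of the spec: the generated values have exactly this
    expectation (the lognormal noise is mean-one and planted effects are
    additive on the concentration scale).
    """
    covariates = covariates or {}
    m = spec.base_trajectory(aabc) * spec.covariate_multiplier(covariates)
    delta = sum(d for cat, d in spec.planted if _in_category(aabc, cat))
    return float(m * (1.0 + delta * spec.cv))


def _in_category(aabc: float, category: str) -> bool:
    lo, hi = CATEGORIES[category]
    return lo <= aabc <= hi


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions of the clinical covariates.

    Defaults emulate a large screening population: ~5% preterm (28-36 wk),
    ~2% post-term; birth weight normal around a GA-dependent mean; a small
    male excess; reported race/ethnicity dominated by Hispanic and White; TPN
    far more frequent among preterm (12.1%) than term (0.45%) infants.
    """

    ga_weights: Mapping[int, float] = field(default_factory=lambda: {
        28: 0.002, 29: 0.002, 30: 0.003, 31: 0.003, 32: 0.004, 33: 0.006,
        34: 0.008, 35: 0.010, 36: 0.012, 37: 0.100, 38: 0.210, 39: 0.290,
        40: 0.230, 41: 0.100, 42: 0.020,
    })
    bw_mean_at_40: float = 3450.0
    bw_per_week: float = 170.0
    bw_sd: float = 440.0
    p_male: float = 0.512
    race_weights: Mapping[str, float] = field(default_factory=lambda: {
        "Hispanic": 0.500, "White": 0.260, "Asian": 0.153,
        "Black": 0.066, "Other/Unknown": 0.021,
    })
    p_multi_report: float = 0.30
    tpn_rate_preterm: float = 0.1213
    tpn_rate_term: float = 0.0045
    p_tpn_unknown: float = 0.002

    def __post_init__(self) -> None:
        for name in ("ga_weights", "race_weights"):
            w = np.array(list(getattr(self, name).values()), dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ConfigurationError(f"{name} must be non-negative and sum to 1")


@dataclass(frozen=True)
class FPModel:
    """Per-disease false-positive totals and collection-window shares."""

    neg_sizes: tuple = (90060, 305674, 19135)
    diseases: Mapping[str, tuple] = field(default_factory=dict)
    # diseases maps name -> (total_fp, (share_early, share_standard, share_late))

    def __post_init__(self) -> None:
        for name, (total, shares) in self.diseases.items():
            s = np.asarray(shares, dtype=float)
            if total < 0 or np.any(s < 0) or not np.isclose(s.sum(), 1.0):
                raise ConfigurationError(f"{name}: invalid FP total or shares")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything needed to generate one synthetic screening cohort."""

    n_newborns: int
    seed: int
    aabc_weights: Mapping[int, float]
    metabolites: Sequence[MetaboliteSpec]
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    fp_model: FPModel = field(default_factory=lambda: default_fp_model())

    def __post_init__(self) -> None:
        if self.n_newborns <= 0:
            raise ConfigurationError("n_newborns must be positive")
        w = np.array(list(self.aabc_weights.values()), dtype=float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ConfigurationError("aabc weights must be non-negative and sum to 1")
        hours = np.array(list(self.aabc_weights.keys()))
        if hours.min() < 12 or hours.max() > 168:
            raise ConfigurationError("aabc weights must cover only 12-168 h")
        names = [m.name for m in self.metabolites]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate metabolite names")

    def spec(self, metabolite: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.name == metabolite:
                return m
        raise KeyError(f"unknown metabolite {metabolite!r}")


def default_aabc_weights(
    category_shares: tuple = (0.217, 0.737, 0.046)
) -> dict:
    """Hour-of-collection weights concentrated in the 24-48 h standard window.

    Within-category profiles: a linear ramp through the early hours (birth
    logistics make 12 h collections rarer than 20 h ones), a broad peak near
    30-36 h in the standard window, and a geometric tail through the late
    window.  Category masses default to the early/standard/late shares of a
    large screening program (21.7% / 73.7% / 4.6%).
    """
    w = {}
    for h in range(12, 24):
        w[h] = 0.3 + 0.7 * (h - 12) / 11.0
    for h in range(24, 49):
        w[h] = 1.0 - 0.8 * abs(h - 33) / 15.0
    for h in range(49, 169):
        w[h] = 0.97 ** (h - 49)
    out = {}
    for share, (lo, hi) in zip(category_shares, CATEGORIES.values()):
        mass = sum(w[h] for h in range(lo, hi + 1))
        for h in range(lo, hi + 1):
            out[h] = share * w[h] / mass
    total = sum(out.values())
    return {h: v / total for h, v in out.items()}


# (shape, base, amp_sd, tau or (nadir, width)) per analyte.  Shapes follow the
# two observed trajectory clusters: amino acids and long-chain hydroxylated /
# dicarboxylic species tend to fall after birth, short/medium straight-chain
# acylcarnitines tend to rise; free carnitine, leucine-isoleucine and C5 dip
# around the standard window and recover.
_DEFAULT_TRAJECTORIES = {
    "Phe": ("decreasing", 55.0, 1.60, 14.0),
    "Tyr": ("decreasing", 90.0, 1.00, 20.0),
    "Met": ("decreasing", 24.0, 1.20, 16.0),
    "Cit": ("decreasing", 13.0, 0.80, 55.0),
    "Arg": ("decreasing", 10.0, 0.70, 25.0),
    "Orn": ("decreasing", 85.0, 0.80, 22.0),
    "Leu-Ile": ("dip_then_rise", 125.0, 0.80, (30.0, 45.0)),
    "C0": ("dip_then_rise", 25.0, 0.90, (48.0, 60.0)),
    "C5": ("dip_then_rise", 0.15, 0.70, (36.0, 45.0)),
    "Ala": ("increasing", 250.0, 0.90, 30.0),
    "Gly": ("increasing", 350.0, 0.60, 35.0),
    "Pro": ("increasing", 150.0, 0.70, 28.0),
    "Val": ("increasing", 110.0, 0.80, 30.0),
    "C2": ("increasing", 20.0, 0.90, 25.0),
    "C3": ("decreasing", 2.5, 0.80, 18.0),
    "C3DC": ("decreasing", 0.05, 0.50, 25.0),
    "C4": ("increasing", 0.30, 0.60, 25.0),
    "C4DC": ("decreasing", 0.15, 0.50, 25.0),
    "C5:1": ("decreasing", 0.03, 0.40, 25.0),
    "C5DC": ("decreasing", 0.08, 0.50, 30.0),
    "C5OH": ("decreasing", 0.20, 0.50, 30.0),
    "C6": ("increasing", 0.06, 0.60, 25.0),
    "C6DC": ("decreasing", 0.05, 0.40, 30.0),
    "C8": ("increasing", 0.08, 0.70, 25.0),
    "C8:1": ("increasing", 0.08, 0.50, 25.0),
    "C10": ("increasing", 0.12, 0.70, 28.0),
    "C10:1": ("increasing", 0.10, 0.50, 28.0),
    "C12": ("increasing", 0.10, 0.80, 30.0),
    "C12:1": ("increasing", 0.10, 0.60, 30.0),
    "C14": ("increasing", 0.25, 0.80, 30.0),
    "C14:1": ("decreasing", 0.15, 0.60, 45.0),
    "C14OH": ("decreasing", 0.03, 0.50, 35.0),
    "C16": ("increasing", 3.5, 0.90, 30.0),
    "C16:1": ("increasing", 0.25, 0.60, 30.0),
    "C16OH": ("decreasing", 0.03, 0.80, 40.0),
    "C18": ("increasing", 1.0, 0.90, 32.0),
    "C18:1": ("increasing", 1.3, 1.10, 32.0),
    "C18:2": ("increasing", 0.35, 0.80, 32.0),
    "C18OH": ("decreasing", 0.02, 0.50, 40.0),
    "C18:1OH": ("decreasing", 0.03, 0.50, 40.0),
    "SA": ("decreasing", 0.80, 0.30, 30.0),
}

# Covariate offsets (log-SD units) for analytes where real panels show clear
# stratified separation; everything else gets the generic defaults below.
_DEFAULT_SHIFTS = {
    "Phe": {"preterm": 0.30, "tpn": 1.50},
    "C0": {"preterm": 0.40, "male": 0.15, "race:Asian": 0.20,
           "race:Black": -0.20, "tpn": 1.00},
    "Leu-Ile": {"preterm": 0.20, "tpn": 0.80},
    "C18:1": {"male": 0.15, "tpn": -0.50},
    "Tyr": {"preterm": 0.45, "tpn": 0.60},
}
_GENERIC_SHIFTS = {"preterm": 0.10, "tpn": 0.30}


def default_metabolite_specs() -> list:
    """The default 41-analyte panel with field-realistic trajectories."""
    specs = []
    for name in PANEL:
        shape, base, amp, t = _DEFAULT_TRAJECTORIES[name]
        kwargs = dict(name=name, shape=shape, base=base, amp_sd=amp, cv=0.25,
                      shifts=_DEFAULT_SHIFTS.get(name, dict(_GENERIC_SHIFTS)))
        if shape == "dip_then_rise":
            kwargs["nadir"], kwargs["width"] = t
        else:
            kwargs["tau"] = t
        specs.append(MetaboliteSpec(**kwargs))
    return specs


def default_fp_model() -> FPModel:
    """False-positive model matching published per-disease totals and shares."""
    printed = {
        # disease: (early, standard, late) observed counts
        "CTD": (44, 381, 46), "PA": (29, 65, 4), "MMA": (66, 97, 27),
        "IVA": (12, 16, 1), "VLCADD": (20, 97, 15), "CITR": (19, 68, 10),
        "OTCD": (27, 129, 89), "HCY": (3, 9, 0), "PKU": (51, 112, 0),
    }
    diseases = {}
    for name, counts in printed.items():
        total = sum(counts)
        diseases[name] = (total, tuple(c / total for c in counts))
    return FPModel(diseases=diseases)


def default_config(n_newborns: int = 50_000, seed: int = 0) -> GeneratorConfig:
    """Generator configuration emulating a large screening cohort."""
    return GeneratorConfig(
        n_newborns=n_newborns,
        seed=seed,
        aabc_weights=default_aabc_weights(),
        metabolites=default_metabolite_specs(),
    )


def _draw_covariates(rng: np.random.Generator, n: int, model: CovariateModel) -> pd.DataFrame:
    ga_vals = np.array(list(model.ga_weights.keys()))
    ga_p = np.array(list(model.ga_weights.values()), dtype=float)
    ga = rng.choice(ga_vals, size=n, p=ga_p / ga_p.sum())
    bw = rng.normal(model.bw_mean_at_40 - model.bw_per_week * (40 - ga), model.bw_sd)
    bw = np.clip(np.round(bw), 450, 5600).astype(int)
    sex = np.where(rng.random(n) < model.p_male, "male", "female")

    cats = np.array(list(model.race_weights.keys()))
    cat_p = np.array(list(model.race_weights.values()), dtype=float)
    race_cat = rng.choice(cats, size=n, p=cat_p / cat_p.sum())
    multi = rng.random(n) < model.p_multi_report
    extras = {"Hispanic": ["White", "other", "Asian"],
              "Black": ["White", "Asian", "other"],
              "Asian": ["White", "other"]}
    reported = []
    for cat, m in zip(race_cat, multi):
        if cat == "Other/Unknown":
            reported.append("" if rng.random() < 0.5 else "other")
        elif cat == "White" or not m:
            reported.append(cat if cat != "Other/Unknown" else "")
        else:
            reported.append("|".join(sorted([cat, extras[cat][rng.integers(len(extras[cat]))]])))
    preterm = ga <= 36
    tpn_rate = np.where(preterm, model.tpn_rate_preterm, model.tpn_rate_term)
    u = rng.random(n)
    tpn = np.where(u < tpn_rate, "yes",
                   np.where(u < tpn_rate + model.p_tpn_unknown, "unknown", "no"))
    return pd.DataFrame({
        "ga": ga, "bw": bw, "sex": sex, "race_reported": reported,
        "race": [  # collapsed category, regenerated downstream from the set
            c for c in race_cat
        ],
        "tpn": tpn, "preterm": preterm,
    })


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate ``config.n_newborns`` screen-negative newborn records.

    Each analyte value is drawn as ``trajectory(AaBC) * exp(covariate
    shifts) * lognormal noise`` plus any planted additive effect; the noise
    is mean-one so :func:`trajectory_mean` is the exact conditional mean.
    Identical config + seed reproduces a bit-identical table.
    """
    ss = np.random.SeedSequence(config.seed)
    s_cov, s_met, _ = ss.spawn(3)
    rng = np.random.default_rng(s_cov)
    n = config.n_newborns

    hours = np.array(list(config.aabc_weights.keys()))
    probs = np.array(list(config.aabc_weights.values()), dtype=float)
    aabc = rng.choice(hours, size=n, p=probs / probs.sum())

    cov = _draw_covariates(rng, n, config.covariate_model)
    df = pd.DataFrame({
        "id": [f"NB{i:07d}" for i in range(n)],
        "aabc": aabc.astype(int),
        "ga": cov["ga"].to_numpy(),
        "bw": cov["bw"].to_numpy(),
        "sex": cov["sex"].to_numpy(),
        "race_reported": cov["race_reported"].to_numpy(),
        "tpn": cov["tpn"].to_numpy(),
        "screen": "negative",
    })

    preterm = cov["preterm"].to_numpy()
    male = cov["sex"].to_numpy() == "male"
    is_tpn = cov["tpn"].to_numpy() == "yes"
    race = cov["race"].to_numpy()
    category = assign_categories(aabc)

    rng_m = np.random.default_rng(s_met)
    for spec in config.metabolites:
        m0 = spec.base_trajectory(aabc)
        shift = np.zeros(n)
        shift += spec.shifts.get("preterm", 0.0) * preterm
        shift += spec.shifts.get("male", 0.0) * male
        shift += spec.shifts.get("tpn", 0.0) * is_tpn
        for r in sorted(set(race)):
            key = f"race:{r}"
            if key in spec.shifts:
                shift += spec.shifts[key] * (race == r)
        mean = m0 * np.exp(shift * spec.sigma_log)

        sigma = spec.sigma_log
        noise = np.exp(rng_m.normal(-sigma**2 / 2.0, sigma, n)) if sigma > 0 else 1.0
        values = mean * noise
        for cat, delta in spec.planted:
            mask = (category == cat).to_numpy(dtype=bool)
            values = values + delta * spec.cv * mean * mask
        df[spec.name] = np.maximum(values, 1e-9)
    return df


def plant_effect(
    config: GeneratorConfig, metabolite: str, category: str, delta_sd: float
) -> GeneratorConfig:
    """Return a config with an extra effect of ``delta_sd`` SD planted.

    The analyte's conditional mean is raised by ``delta_sd`` standard
    deviations uniformly over the hour range of ``category``; other hours and
    all other analytes are untouched.  Planting is additive on the
    concentration scale after the noise draw, so the group SD is preserved
    and the downstream Cohen's d between the planted and an unplanted window
    recovers ``delta_sd`` (for a flat-trajectory analyte, exactly in
    expectation).  Stacked plants add.
    """
    if category not in CATEGORIES:
        raise ConfigurationError(f"unknown collection category {category!r}")
    spec = config.spec(metabolite)  # KeyError for unknown metabolite
    new_spec = replace(spec, planted=spec.planted + ((category, float(delta_sd)),))
    mets = [new_spec if m.name == metabolite else m for m in config.metabolites]
    return replace(config, metabolites=tuple(mets))


def generate_fp_cases(fp_model: FPModel, seed: int) -> pd.DataFrame:
    """Draw a false-positive case table from the per-disease window shares.

    Each disease's ``total_fp`` cases are assigned a collection category by a
    multinomial draw over the early/standard/late shares, an AaBC hour
    uniform within that category, and reference-range covariates (term GA,
    normal BW, no TPN) so the table survives the reference restriction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    cat_bounds = list(CATEGORIES.items())
    rows = []
    for disease, (total, shares) in fp_model.diseases.items():
        counts = rng.multinomial(total, np.asarray(shares, dtype=float))
        for (cat, (lo, hi)), k in zip(cat_bounds, counts):
            if k == 0:
                continue
            aabc = rng.integers(lo, hi + 1, size=k)
            ga = rng.integers(37, 42, size=k)
            bw = rng.integers(2500, 4001, size=k)
            sex = np.where(rng.random(k) < 0.5, "male", "female")
            for a, g, b, s in zip(aabc, ga, bw, sex):
                rows.append((disease, int(a), int(g), int(b), s, "no"))
    df = pd.DataFrame(rows, columns=["disease", "aabc", "ga", "bw", "sex", "tpn"])
    return df.sort_values(["disease", "aabc"], kind="stable").reset_index(drop=True)


def config_to_dict(config: GeneratorConfig) -> dict:
    """Plain-dict form of a config for serialisation and provenance hashing."""
    d = {
        "n_newborns": config.n_newborns,
        "seed": config.seed,
        "aabc_weights": {int(k): float(v) for k, v in config.aabc_weights.items()},
        "metabolites": [
            {
                "name": m.name, "shape": m.shape, "base": m.base,
                "amp_sd": m.amp_sd, "tau": m.tau, "nadir": m.nadir,
                "width": m.width, "cv": m.cv, "shifts": dict(m.shifts),
                "planted": [list(p) for p in m.planted],
            }
            for m in config.metabolites
        ],
        "covariate_model": {
            "ga_weights": {int(k): float(v) for k, v in config.covariate_model.ga_weights.items()},
            "bw_mean_at_40": config.covariate_model.bw_mean_at_40,
            "bw_per_week": config.covariate_model.bw_per_week,
            "bw_sd": config.covariate_model.bw_sd,
            "p_male": config.covariate_model.p_male,
            "race_weights": dict(config.covariate_model.race_weights),
            "p_multi_report": config.covariate_model.p_multi_report,
            "tpn_rate_preterm": config.covariate_model.tpn_rate_preterm,
            "tpn_rate_term": config.covariate_model.tpn_rate_term,
            "p_tpn_unknown": config.covariate_model.p_tpn_unknown,
        },
        "fp_model": {
            "neg_sizes": list(config.fp_model.neg_sizes),
            "diseases": {
                k: [int(t), [float(s) for s in sh]]
                for k, (t, sh) in config.fp_model.diseases.items()
            },
        },
    }
    return copy.deepcopy(d)


def config_from_dict(d: Mapping) -> GeneratorConfig:
    """Inverse of :func:`config_to_dict`."""
    mets = tuple(
        MetaboliteSpec(
            name=m["name"], shape=m["shape"], base=m["base"], amp_sd=m["amp_sd"],
            tau=m["tau"], nadir=m["nadir"], width=m["width"], cv=m["cv"],
            shifts=dict(m["shifts"]),
            planted=tuple((c, float(x)) for c, x in m.get("planted", [])),
        )
        for m in d["metabolites"]
    )
    cm = CovariateModel(**{**d["covariate_model"],
                           "ga_weights": {int(k): v for k, v in d["covariate_model"]["ga_weights"].items()},
                           })
    fp = FPModel(
        neg_sizes=tuple(d["fp_model"]["neg_sizes"]),
        diseases={k: (int(t), tuple(sh)) for k, (t, sh) in d["fp_model"]["diseases"].items()},
    )
    return GeneratorConfig(
        n_newborns=int(d["n_newborns"]), seed=int(d["seed"]),
        aabc_weights={int(k): float(v) for k, v in d["aabc_weights"].items()},
        metabolites=mets, covariate_model=cm, fp_model=fp,
    )
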