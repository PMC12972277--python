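"""Synthetic aging-cohort generator.

Simulates the derived variables an aging-cohort analysis consumes — 19
cognitive test scores, 9 brain-pathology proxies (plus total intracranial
volume), 30 lifestyle/health variables in 8 domains, APOE e4 carrier status,
sex and age — together with the generative ground truth needed for recovery
tests.

The generative model, in outline:

* chronological age is drawn from a configurable distribution on
  ``age_range`` (uniform by default, an optional bimodal mixture mimicking a
  sparse 75-80 stratum);
* a per-subject *brain age gap* ``u = a*F2 + e_B`` and *cognitive age gap*
  ``v = c'*F2 + b*u + e_C`` (years) embed a lifestyle -> brain-pathology ->
  cognition mediation path, where ``F2`` is the second latent lifestyle
  factor ("active life");
* each cognitive score loads on standardized cognitive age ``age + v`` with
  a per-score target correlation spread across the configured band, plus a
  common cognitive factor and idiosyncratic noise; brain markers load on
  ``age + u`` analogously, with TICV components on volumes and additive
  APOE e4 shifts on the Alzheimer's plasma markers;
* the 30 lifestyle variables follow a K-factor model (default K=7,
  block-sparse loadings by domain) with age/sex effects on a subset, so the
  residualization stage downstream has real work to do;
* variables destined for Box-Cox transformation are generated on a log
  scale and exponentiated, guaranteeing positive right-skewed inputs (the
  TMT B/A ratio is the exponential of a latent log-ratio of the two trail
  times, so its inversion rule is meaningful).

Missingness is injected separately (:func:`inject_missingness`) and is MCAR
only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .cohort import CohortTable

__all__ = [
    "GeneratorConfig",
    "GenerativeTruth",
    "MediationPaths",
    "MissingnessPlan",
    "TrueMediation",
    "block_loadings",
    "default_factor_loadings",
    "default_missingness_plan",
    "generate_cohort",
    "inject_missingness",
    "true_mediation_effects",
    "worked_example_cohort",
    "COGNITIVE_VARS",
    "BRAIN_VARS",
    "LIFESTYLE_VARS",
]


# ---------------------------------------------------------------------------
# variable registries
# ---------------------------------------------------------------------------

class _Var(NamedTuple):
    name: str
    skewed: bool      # generated as exp(logmu + logsd * latent)
    loc: float        # mu (normal) or log-median (skewed)
    scale: float      # sd (normal) or log-sd (skewed)
    direction: int    # +1: value rises with age/pathology; -1: falls
    round_to_int: bool = False


#: 19 cognitive test scores.  direction=-1 (higher = better) for all but the
#: TMT B/A ratio and the go/no-go reaction-time score.
COGNITIVE_VARS: tuple[_Var, ...] = (
    _Var("vlmt_sum_1_5", False, 48.0, 9.0, -1),
    _Var("vlmt_immediate", True, math.log(10.0), 0.22, -1),
    _Var("vlmt_delayed", True, math.log(9.5), 0.25, -1),
    _Var("vlmt_recognition", True, math.log(12.0), 0.20, -1),
    _Var("rcft_immediate", False, 20.0, 6.0, -1),
    _Var("rcft_delayed", False, 19.0, 6.0, -1),
    _Var("rcft_recognition", False, 20.0, 2.5, -1),
    _Var("sdmt", False, 45.0, 9.0, -1),
    _Var("rwt_food", True, math.log(24.0), 0.25, -1),
    _Var("rwt_jobs", True, math.log(20.0), 0.25, -1),
    _Var("fcsrt_free_recall", True, math.log(30.0), 0.20, -1),
    _Var("wms_lm_immediate", True, math.log(14.0), 0.25, -1),
    _Var("wms_lm_delayed", True, math.log(12.0), 0.30, -1),
    _Var("wms_lm_recognition", True, math.log(22.0), 0.12, -1),
    _Var("fluency_animals", True, math.log(23.0), 0.25, -1),
    _Var("wordlist_total", True, math.log(21.0), 0.15, -1),
    _Var("wordlist_recall", True, math.log(7.5), 0.20, -1),
    _Var("tmt_ba_ratio", True, math.log(2.2), 0.30, +1),
    _Var("gonogo_median_rt", True, math.log(520.0), 0.18, +1),
)

#: memory-flavoured scores carry a small male disadvantage (drives the
#: observed male > female cognitive age gap)
_COG_SEX_EFFECT = {
    "vlmt_sum_1_5": -0.20, "vlmt_immediate": -0.20, "vlmt_delayed": -0.20,
    "fcsrt_free_recall": -0.20, "wms_lm_immediate": -0.15,
    "wms_lm_delayed": -0.15, "wordlist_total": -0.20, "wordlist_recall": -0.20,
}


class _BrainVar(NamedTuple):
    name: str
    skewed: bool
    loc: float
    scale: float
    direction: int
    ticv_coef: float      # loading on standardized TICV (volumes only)
    apoe_coef: float      # additive shift (latent SD units) for e4 carriers
    round_to_int: bool = False


#: 9 brain-pathology proxies ("bilateral hippocampal volume" = left + right)
BRAIN_VARS: tuple[_BrainVar, ...] = (
    _BrainVar("csf_volume", True, math.log(1400.0), 0.25, +1, 0.50, 0.0),
    _BrainVar("hippocampus_left_volume", False, 3600.0, 380.0, -1, 0.55, -0.10),
    _BrainVar("hippocampus_right_volume", False, 3650.0, 380.0, -1, 0.55, -0.10),
    _BrainVar("gm_thickness", False, 2.40, 0.11, -1, 0.0, 0.0),
    _BrainVar("wmh_volume", True, math.log(3000.0), 0.90, +1, 0.0, 0.10),
    _BrainVar("pvs_bg_count", True, math.log(25.0), 0.50, +1, 0.0, 0.0, True),
    _BrainVar("pvs_cso_count", True, math.log(120.0), 0.50, +1, 0.0, 0.0, True),
    _BrainVar("abeta_ratio", False, 0.090, 0.011, -1, 0.0, -0.30),
    _BrainVar("ptau217", True, math.log(0.115), 0.45, +1, 0.0, 0.35),
)


class _LifeVar(NamedTuple):
    name: str
    domain: str
    skewed: bool
    loc: float
    scale: float
    age_effect: float    # loading on standardized age
    sex_effect: float    # coefficient on (sex - 0.5)
    round_to_int: bool = False


#: 30 lifestyle/health variables across the 8 domains
LIFESTYLE_VARS: tuple[_LifeVar, ...] = (
    _LifeVar("psqi_sleep_quality", "sleep", True, math.log(5.0), 0.45, 0.0, 0.0, True),
    _LifeVar("ess_daytime_sleepiness", "sleep", True, math.log(6.0), 0.40, 0.0, 0.0, True),
    _LifeVar("hei_degs", "diet", False, 60.0, 10.0, 0.0, -0.20),
    _LifeVar("alcohol_g_day", "diet", True, math.log(8.0), 0.80, 0.0, 0.30),
    _LifeVar("pa_basic_met", "physical_activity", True, math.log(60.0), 0.50, 0.0, 0.0),
    _LifeVar("pa_leisure_met", "physical_activity", True, math.log(35.0), 0.60, 0.0, 0.0),
    _LifeVar("pa_sports_met", "physical_activity", True, math.log(15.0), 0.90, -0.15, 0.0),
    _LifeVar("timed_up_go", "physical_fitness", True, math.log(8.5), 0.25, 0.30, 0.0),
    _LifeVar("asmm", "physical_fitness", False, 20.0, 3.5, -0.20, 0.50),
    _LifeVar("handgrip_strength", "physical_fitness", False, 33.0, 8.0, -0.25, 0.55),
    _LifeVar("education_years", "mental_activity", False, 14.8, 2.4, 0.0, 0.20),
    _LifeVar("leq_early_life", "mental_activity", False, 25.0, 6.0, 0.0, 0.0),
    _LifeVar("leq_midlife", "mental_activity", False, 25.0, 6.0, 0.0, 0.0),
    _LifeVar("n_antihypertensives", "cardiovascular_risk", True, math.log(0.8), 0.90, 0.30, 0.0, True),
    _LifeVar("bp_systolic", "cardiovascular_risk", False, 133.0, 16.0, 0.25, 0.0),
    _LifeVar("bp_diastolic", "cardiovascular_risk", False, 80.0, 9.0, 0.0, 0.0),
    _LifeVar("hba1c", "cardiovascular_risk", True, math.log(5.5), 0.08, 0.20, 0.0),
    _LifeVar("bmi", "cardiovascular_risk", True, math.log(26.0), 0.13, 0.0, 0.0),
    _LifeVar("pack_years", "cardiovascular_risk", True, math.log(4.0), 1.20, 0.0, 0.25),
    _LifeVar("sf36_mental", "mental_health", False, 52.0, 8.0, 0.0, 0.0),
    _LifeVar("gds_depression", "mental_health", True, math.log(3.5), 0.80, 0.0, 0.0, True),
    _LifeVar("stai_trait", "mental_health", True, math.log(34.0), 0.20, 0.0, 0.0),
    _LifeVar("stai_state", "mental_health", True, math.log(33.0), 0.20, 0.0, 0.0),
    _LifeVar("sf36_physical", "physical_health", False, 48.0, 8.0, -0.20, 0.0),
    _LifeVar("homocysteine", "physical_health", True, math.log(12.0), 0.30, 0.25, 0.20),
    _LifeVar("egfr", "physical_health", False, 80.0, 13.0, -0.35, 0.0),
    _LifeVar("albumin", "physical_health", False, 44.0, 2.5, -0.20, 0.0),
    _LifeVar("leukocytes", "physical_health", True, math.log(6.0), 0.25, 0.0, 0.0),
    _LifeVar("hemoglobin", "physical_health", False, 14.2, 1.1, -0.15, 0.40),
    _LifeVar("platelets", "physical_health", False, 240.0, 50.0, 0.0, -0.20),
)

_LIFESTYLE_NAMES = tuple(v.name for v in LIFESTYLE_VARS)

#: CERAD-based screening battery (age/sex/education-adjusted z-scores) and
#: the cognitive-domain map used by the Jak/Bondi rules
SCREENING_TESTS: tuple[str, ...] = (
    "cerad_z_fluency_animals", "cerad_z_bnt", "cerad_z_wordlist_total",
    "cerad_z_wordlist_recall", "cerad_z_wordlist_recognition",
    "cerad_z_figures_copy", "cerad_z_figures_recall", "cerad_z_fluency_s",
    "cerad_z_tmt_a", "cerad_z_tmt_b",
)

SCREENING_DOMAIN_MAP: dict[str, str] = {
    "cerad_z_wordlist_total": "memory",
    "cerad_z_wordlist_recall": "memory",
    "cerad_z_wordlist_recognition": "memory",
    "cerad_z_figures_recall": "memory",
    "cerad_z_fluency_animals": "language",
    "cerad_z_bnt": "language",
    "cerad_z_fluency_s": "language",
    "cerad_z_tmt_a": "speed_executive",
    "cerad_z_tmt_b": "speed_executive",
    "cerad_z_figures_copy": "speed_executive",
}


# ---------------------------------------------------------------------------
# configuration / truth objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MediationPaths:
    """Linear no-interaction mediation coefficients (years per SD of F2)."""

    a: float = -0.52       # treatment (F2) -> mediator (brain age gap)
    b: float = 0.167       # mediator -> outcome (cognitive age gap)
    c_prime: float = -0.437  # direct treatment -> outcome


def default_factor_loadings() -> np.ndarray:
    """Default 30 x 7 lifestyle loading matrix (block-sparse by domain).

    Factor 2 is the broad "active life" profile that carries the mediation
    path; factors 6 and 7 are deliberately weak.
    """
    L = {v.name: [0.0] * 7 for v in LIFESTYLE_VARS}
    L["psqi_sleep_quality"] = [0.55, 0, 0, 0.35, 0, 0, 0]
    L["ess_daytime_sleepiness"] = [0.50, 0, 0, 0.30, 0, 0, 0]
    L["hei_degs"] = [0, 0, -0.40, 0, 0, 0.60, 0]
    L["alcohol_g_day"] = [0, 0, 0, 0.65, 0, 0, 0.30]
    L["pa_basic_met"] = [0, 0, 0, 0.40, 0.50, 0, 0]
    L["pa_leisure_met"] = [0, 0.50, 0, 0.30, 0.40, 0, 0]
    L["pa_sports_met"] = [0, 0.55, 0, 0, 0.45, 0, 0]
    L["timed_up_go"] = [0, -0.50, 0, 0, 0, 0, -0.30]
    L["asmm"] = [0, 0, 0.40, 0.45, -0.40, 0, 0]
    L["handgrip_strength"] = [0, 0.50, 0.35, 0, -0.40, 0, 0]
    L["education_years"] = [0, 0.60, 0, 0, -0.50, 0, 0]
    L["leq_early_life"] = [-0.30, 0.50, 0, 0, -0.50, 0, 0]
    L["leq_midlife"] = [-0.30, 0.55, 0, 0.30, -0.45, 0, 0]
    L["n_antihypertensives"] = [0, -0.40, 0, 0.35, 0, 0, 0]
    L["bp_systolic"] = [0, 0, 0.70, 0, 0.30, 0, 0]
    L["bp_diastolic"] = [0, 0.25, 0.65, 0, 0, 0, 0]
    L["hba1c"] = [0, -0.40, 0, 0, 0, 0.30, 0]
    L["bmi"] = [0, -0.45, 0.40, 0.40, 0, 0, 0]
    L["pack_years"] = [0, -0.40, 0, 0, -0.35, 0, 0]
    L["sf36_mental"] = [-0.60, -0.30, 0, 0.30, 0.35, 0, 0]
    L["gds_depression"] = [0.70, 0, 0, 0, 0, 0, 0]
    L["stai_trait"] = [0.70, 0, 0, 0, 0, 0, 0]
    L["stai_state"] = [0.65, 0, 0, 0, 0, 0, 0]
    L["sf36_physical"] = [-0.30, 0, 0, -0.45, 0, 0, 0.35]
    L["homocysteine"] = [0, 0, 0, -0.35, 0, 0.45, 0]
    L["egfr"] = [0, 0, 0, 0.35, 0.30, -0.40, 0]
    L["albumin"] = [0, 0, 0, 0.30, 0, 0.40, 0]
    L["leukocytes"] = [0, -0.40, 0, -0.30, 0, 0, 0.50]
    L["hemoglobin"] = [0, 0, 0.50, 0, 0, 0, 0.45]
    L["platelets"] = [0, 0, -0.40, -0.30, 0, 0.30, 0.45]
    return np.array([L[v.name] for v in LIFESTYLE_VARS], dtype=float)


def block_loadings(
    n_vars: int = 30, n_factors: int = 7, loading: float = 0.7
) -> np.ndarray:
    """Clean block-sparse loading matrix: variable i loads ``loading`` on
    factor ``i % n_factors`` and nothing else.  Used for strong-signal
    recovery experiments (e.g. parallel-analysis retention)."""
    L = np.zeros((n_vars, n_factors))
    for i in range(n_vars):
        L[i, i % n_factors] = loading
    return L


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings for :func:`generate_cohort`.

    Defaults reproduce the cohort conditions the analysis assumes: age
    60-95, cognitive score-age correlations spread over ``cognitive_band``
    (pathology-aligned sign), brain marker-age correlations over
    ``brain_band``, a 7-factor lifestyle structure, ~23% APOE e4 prevalence
    and an embedded lifestyle -> brain -> cognition mediation path.
    """

    n: int = 350
    age_range: tuple[float, float] = (60.0, 95.0)
    age_distribution: str = "uniform"      # "uniform" | "bimodal"
    cognitive_band: tuple[float, float] = (0.19, 0.46)   # |corr| targets
    brain_band: tuple[float, float] = (0.21, 0.55)
    factor_loadings: np.ndarray | None = None   # 30 x K; default 7-factor
    mediation: MediationPaths = MediationPaths()
    bag_noise_sd: float = 3.4       # years; residual SD of the brain age gap
    cag_noise_sd: float = 3.9       # years; residual SD of the cognitive gap
    apoe_prevalence: float = 0.23
    male_fraction: float = 0.5
    cognitive_common_var: float = 0.30   # share of non-age variance on g
    brain_common_var: float = 0.25
    include_screening: bool = True
    treatment_factor: int = 2       # 1-based index of the mediating factor


@dataclass
class GenerativeTruth:
    """Ground truth paired with a generated cohort (for recovery tests)."""

    age_slopes: dict[str, float]        # population corr(variable, age)
    sex_effects: dict[str, float]       # latent-SD shift for males
    factor_loadings: np.ndarray         # 30 x K lifestyle loadings
    noise_sds: dict[str, float]         # unique latent SD per variable
    mediation_paths: MediationPaths
    apoe_effects: dict[str, float]      # latent-SD shift for e4 carriers
    seed: int
    directions: dict[str, int]          # +1 / -1 pathology alignment
    factor_scores: np.ndarray           # n x K latent lifestyle factors
    bag_true: np.ndarray                # years
    cag_true: np.ndarray                # years
    treatment_factor: int = 2

    def to_jsonable(self) -> dict:
        return {
            "age_slopes": self.age_slopes,
            "sex_effects": self.sex_effects,
            "factor_loadings": self.factor_loadings.tolist(),
            "noise_sds": self.noise_sds,
            "mediation_paths": {
                "a": self.mediation_paths.a,
                "b": self.mediation_paths.b,
                "c_prime": self.mediation_paths.c_prime,
            },
            "apoe_effects": self.apoe_effects,
            "seed": self.seed,
            "directions": self.directions,
            "treatment_factor": self.treatment_factor,
        }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_age(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[np.ndarray, float, float]:
    """Sample ages; return (ages, population mean, population sd)."""
    lo, hi = cfg.age_range
    if cfg.age_distribution == "uniform":
        ages = rng.uniform(lo, hi, cfg.n)
        mean = (lo + hi) / 2.0
        sd = (hi - lo) / math.sqrt(12.0)
        return ages, mean, sd
    if cfg.age_distribution == "bimodal":
        # sparse 75-80 stratum: mixture 0.5*U(lo,75) + 0.1*U(75,80) + 0.4*U(80,hi)
        comps = [(lo, 75.0, 0.5), (75.0, 80.0, 0.1), (80.0, hi, 0.4)]
        which = rng.choice(3, size=cfg.n, p=[w for _, _, w in comps])
        ages = np.empty(cfg.n)
        for k, (a, b, _) in enumerate(comps):
            m = which == k
            ages[m] = rng.uniform(a, b, m.sum())
        mean = sum(w * (a + b) / 2 for a, b, w in comps)
        second = sum(w * ((b - a) ** 2 / 12 + ((a + b) / 2) ** 2) for a, b, w in comps)
        return ages, mean, math.sqrt(second - mean**2)
    raise ValueError(f"unknown age_distribution {cfg.age_distribution!r}")


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[CohortTable, GenerativeTruth]:
    """Generate a complete cohort (no missing cells) plus its ground truth.

    Deterministic: identical ``(config, seed)`` give identical output.

    Raises
    ------
    ValueError
        If ``config.n < 30`` (correlation calibration unverifiable) or the
        loading matrix does not have one row per lifestyle variable.
    """
    cfg = config or GeneratorConfig()
    if cfg.n < 30:
        raise ValueError(f"n={cfg.n} < 30: correlation targets unverifiable")
    loadings = (
        np.asarray(cfg.factor_loadings, float)
        if cfg.factor_loadings is not None
        else default_factor_loadings()
    )
    if loadings.ndim != 2 or loadings.shape[0] != len(LIFESTYLE_VARS):
        raise ValueError(
            f"factor_loadings must be ({len(LIFESTYLE_VARS)}, K); got {loadings.shape}"
        )
    n_factors = loadings.shape[1]
    if n_factors < 1:
        raise ValueError("need at least one lifestyle factor")
    if not (1 <= cfg.treatment_factor <= n_factors):
        raise ValueError("treatment_factor out of range")

    rng = np.random.default_rng(seed)
    n = cfg.n

    ages, age_mean, age_sd = _draw_age(rng, cfg)
    z_age = (ages - age_mean) / age_sd
    sex = (rng.random(n) < cfg.male_fraction).astype(float)   # male = 1
    sex_c = sex - 0.5
    apoe = (rng.random(n) < cfg.apoe_prevalence).astype(float)
    apoe_c = apoe - cfg.apoe_prevalence

    # latent lifestyle factors and the mediation path
    F = rng.standard_normal((n, n_factors))
    f_treat = F[:, cfg.treatment_factor - 1]
    paths = cfg.mediation
    bag = paths.a * f_treat + cfg.bag_noise_sd * rng.standard_normal(n)
    cag = paths.c_prime * f_treat + paths.b * bag + cfg.cag_noise_sd * rng.standard_normal(n)

    # standardized "brain age" / "cognitive age" signals
    sd_ba = math.sqrt(age_sd**2 + paths.a**2 + cfg.bag_noise_sd**2)
    var_cag = (paths.c_prime + paths.b * paths.a) ** 2 + (paths.b * cfg.bag_noise_sd) ** 2 + cfg.cag_noise_sd**2
    sd_ca = math.sqrt(age_sd**2 + var_cag)
    z_ba = (ages + bag - age_mean) / sd_ba
    z_ca = (ages + cag - age_mean) / sd_ca
    kappa_b = age_sd / sd_ba    # corr(brain age, age)
    kappa_c = age_sd / sd_ca

    # TICV (males larger); standardized including the sex component
    ticv_mean, ticv_sd, ticv_sex = 1.45e6, 1.4e5, 1.0e5
    z_ticv_core = rng.standard_normal(n)
    ticv = ticv_mean + ticv_sd * z_ticv_core + ticv_sex * sex_c
    ticv_pop_sd = math.sqrt(ticv_sd**2 + ticv_sex**2 / 4)
    z_ticv = (ticv - ticv_mean) / ticv_pop_sd

    age_slopes: dict[str, float] = {}
    sex_effects: dict[str, float] = {}
    noise_sds: dict[str, float] = {}
    apoe_effects: dict[str, float] = {}
    directions: dict[str, int] = {}
    cols: dict[str, np.ndarray] = {}

    def _finish(var, latent):
        if var.skewed:
            vals = np.exp(var.loc + var.scale * latent)
        else:
            vals = var.loc + var.scale * latent
        if var.round_to_int:
            vals = np.round(vals)
        return vals

    # cognitive scores -----------------------------------------------------
    lo_b, hi_b = cfg.cognitive_band
    cog_targets = np.linspace(lo_b, hi_b, len(COGNITIVE_VARS))
    g_cog = rng.standard_normal(n)
    for var, t in zip(COGNITIVE_VARS, cog_targets):
        beta = var.direction * t / kappa_c        # loading on z_ca
        s = _COG_SEX_EFFECT.get(var.name, 0.0)
        resvar = 1.0 - beta**2 - s**2 / 4
        w = math.sqrt(cfg.cognitive_common_var * resvar)
        u = math.sqrt((1 - cfg.cognitive_common_var) * resvar)
        latent = beta * z_ca + s * sex_c + w * g_cog + u * rng.standard_normal(n)
        cols[var.name] = _finish(var, latent)
        age_slopes[var.name] = var.direction * t
        sex_effects[var.name] = s
        noise_sds[var.name] = u
        directions[var.name] = var.direction

    # brain markers --------------------------------------------------------
    lo_b, hi_b = cfg.brain_band
    brain_targets = np.linspace(lo_b, hi_b, len(BRAIN_VARS))
    g_brain = rng.standard_normal(n)
    for var, t in zip(BRAIN_VARS, brain_targets):
        beta = var.direction * t / kappa_b
        a_sh = var.apoe_coef
        resvar = (
            1.0 - beta**2 - var.ticv_coef**2
            - a_sh**2 * cfg.apoe_prevalence * (1 - cfg.apoe_prevalence)
        )
        w = math.sqrt(cfg.brain_common_var * resvar)
        u = math.sqrt((1 - cfg.brain_common_var) * resvar)
        latent = (
            beta * z_ba + var.ticv_coef * z_ticv + a_sh * apoe_c
            + w * g_brain + u * rng.standard_normal(n)
        )
        cols[var.name] = _finish(var, latent)
        age_slopes[var.name] = var.direction * t
        sex_effects[var.name] = 0.0
        noise_sds[var.name] = u
        apoe_effects[var.name] = a_sh
        directions[var.name] = var.direction

    # lifestyle variables --------------------------------------------------
    for i, var in enumerate(LIFESTYLE_VARS):
        lam = loadings[i]
        communality = float(lam @ lam)
        resvar = 1.0 - communality - var.age_effect**2 - var.sex_effect**2 / 4
        if resvar <= 0:
            raise ValueError(
                f"loading row for {var.name!r} leaves non-positive unique variance"
            )
        u = math.sqrt(resvar)
        latent = (
            F @ lam + var.age_effect * z_age + var.sex_effect * sex_c
            + u * rng.standard_normal(n)
        )
        cols[var.name] = _finish(var, latent)
        age_slopes[var.name] = var.age_effect
        sex_effects[var.name] = var.sex_effect
        noise_sds[var.name] = u
        directions[var.name] = +1

    # screening battery (already age/sex/education adjusted by construction)
    roles: dict[str, str] = {}
    if cfg.include_screening:
        q = -0.5 * cag / math.sqrt(var_cag) + math.sqrt(0.75) * rng.standard_normal(n)
        for t_name in SCREENING_TESTS:
            z = 0.5 + 0.75 * (0.7 * q + math.sqrt(1 - 0.49) * rng.standard_normal(n))
            cols[t_name] = np.round(z, 3)
            roles[t_name] = "screening"
        mmse = np.clip(np.round(28.6 + 1.1 * (0.5 * q + math.sqrt(0.75) * rng.standard_normal(n))), 20, 30)
        cols["mmse_raw"] = mmse
        roles["mmse_raw"] = "mmse"

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n)],
            "age": np.round(ages, 2),
            "sex": sex,
            "apoe4_carrier": apoe,
            "ticv": np.round(ticv, 1),
            **{k: np.round(v, 6) for k, v in cols.items()},
        }
    )
    roles.update(
        {
            "subject_id": "id", "age": "age", "sex": "sex",
            "apoe4_carrier": "apoe4", "ticv": "ticv",
        }
    )
    roles.update({v.name: "cognitive" for v in COGNITIVE_VARS})
    roles.update({v.name: "brain" for v in BRAIN_VARS})
    roles.update({v.name: "lifestyle" for v in LIFESTYLE_VARS})
    domains = {v.name: v.domain for v in LIFESTYLE_VARS}

    table = CohortTable(df, roles, domains)
    table.validate(age_range=cfg.age_range)
    truth = GenerativeTruth(
        age_slopes=age_slopes,
        sex_effects=sex_effects,
        factor_loadings=loadings,
        noise_sds=noise_sds,
        mediation_paths=paths,
        apoe_effects=apoe_effects,
        seed=seed,
        directions=directions,
        factor_scores=F,
        bag_true=bag,
        cag_true=cag,
        treatment_factor=cfg.treatment_factor,
    )
    return table, truth


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MissingnessPlan:
    """MCAR missingness: per-variable cell rates plus whole-block
    availability (a subject without an MRI/plasma visit loses all brain
    markers; without the fitness/questionnaire assessments, all lifestyle
    variables)."""

    per_variable_rates: dict[str, float] = field(default_factory=dict)
    max_cognitive_missing: int = 3
    seed: int = 0
    brain_block_rate: float = 0.0
    lifestyle_block_rate: float = 0.0

    def __post_init__(self):
        for name, rate in self.per_variable_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate for {name!r} outside [0, 1]: {rate}")
        for rate in (self.brain_block_rate, self.lifestyle_block_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"block rate outside [0, 1]: {rate}")


def default_missingness_plan(seed: int = 0) -> MissingnessPlan:
    """Cohort-realistic MCAR plan: 17 lifestyle variables complete, 11
    missing at 3%, 2 at 11.4%; sporadic cognitive missingness at 0.2% per
    cell; ~25% of subjects without brain markers and ~39% without the
    lifestyle assessment block."""
    rates: dict[str, float] = {}
    low = (
        "psqi_sleep_quality", "ess_daytime_sleepiness", "hei_degs",
        "alcohol_g_day", "pa_basic_met", "pa_leisure_met", "pa_sports_met",
        "gds_depression", "stai_trait", "stai_state", "sf36_mental",
    )
    rates.update({name: 0.03 for name in low})
    rates.update({"leq_early_life": 0.114, "leq_midlife": 0.114})
    rates.update({v.name: 0.002 for v in COGNITIVE_VARS})
    return MissingnessPlan(
        per_variable_rates=rates,
        max_cognitive_missing=3,
        seed=seed,
        brain_block_rate=0.25,
        lifestyle_block_rate=0.39,
    )


def inject_missingness(table: CohortTable, plan: MissingnessPlan) -> CohortTable:
    """Punch MCAR holes into a copy of ``table`` (the input is unmodified).

    Deterministic for a given ``plan.seed``; draws are consumed in table
    column order, then for the brain and lifestyle blocks.
    """
    unknown = [v for v in plan.per_variable_rates if v not in table.data.columns]
    if unknown:
        raise ValueError(f"missingness plan names unknown variables: {unknown}")
    out = table.copy()
    rng = np.random.default_rng(plan.seed)
    n = out.n_subjects
    for col in out.data.columns:
        rate = plan.per_variable_rates.get(col, 0.0)
        if rate > 0:
            holes = rng.random(n) < rate
            out.data.loc[holes, col] = np.nan
    if plan.brain_block_rate > 0:
        gone = rng.random(n) < plan.brain_block_rate
        out.data.loc[gone, out.brain_columns + ["ticv"]] = np.nan
    if plan.lifestyle_block_rate > 0:
        gone = rng.random(n) < plan.lifestyle_block_rate
        out.data.loc[gone, out.lifestyle_columns] = np.nan
    return out


# ---------------------------------------------------------------------------
# analytic mediation truth
# ---------------------------------------------------------------------------

class TrueMediation(NamedTuple):
    acme: float
    ade: float
    total: float
    proportion: float          # NaN when undefined
    proportion_defined: bool


def true_mediation_effects(truth: GenerativeTruth | MediationPaths) -> TrueMediation:
    """Analytic effect decomposition of the generative linear paths.

    For a linear no-interaction model the mediated (indirect) effect is
    ``a*b``, the direct effect ``c'``, and their sum the total effect; the
    proportion mediated is ``a*b / total`` (undefined for total = 0).
    """
    paths = truth.mediation_paths if isinstance(truth, GenerativeTruth) else truth
    acme = paths.a * paths.b
    ade = paths.c_prime
    total = acme + ade
    if total == 0.0:
        return TrueMediation(acme, ade, total, float("nan"), False)
    return TrueMediation(acme, ade, total, acme / total, True)


# ---------------------------------------------------------------------------
# worked example
# ---------------------------------------------------------------------------

def worked_example_cohort() -> CohortTable:
    """A fixed 18-subject cohort used by unit tests and the documentation.

    Deterministically derived from the generator (seed 20240101), with
    hand-placed missing cells: subject 1 misses two cognitive scores
    (imputable), subject 2 misses four (excluded by the <=3-of-19 rule),
    subject 3 misses one lifestyle variable.
    """
    cfg = GeneratorConfig(n=36, include_screening=True)
    table, _ = generate_cohort(cfg, seed=20240101)
    df = table.data.iloc[:18].reset_index(drop=True)
    out = CohortTable(df, dict(table.roles), dict(table.lifestyle_domains))
    cog = out.cognitive_columns
    out.data.loc[0, cog[:2]] = np.nan
    out.data.loc[1, cog[:4]] = np.nan
    out.data.loc[2, out.lifestyle_columns[0]] = np.nan
    return out
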