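"""Synthetic cohort generator emulating the 115-patient neoadjuvant study.

Every pipeline stage (response model, survival model, covariate screen, VPC,
bootstrap, descriptives) is testable on cohorts produced here.  Covariate
marginals follow the published characteristics table; the response trajectory
comes from the ordered-categorical Markov model; metastasis appearance is a
constant-hazard process (no metastasis-model parameters were published, so
the default rate is a generator truth value, not a literature value); death
times come from the overall-survival hazard with the simulated metastasis
switch; censoring combines uniform accrual with an administrative cutoff.
Pathologic ypT/ypN staging is coupled to clinical staging through a Gaussian
copula calibrated to configurable Spearman concordance targets, with the
complete-pathologic-response coupling ypT0 => ypN0 so the injected pCR count
equals the number of ypT0 draws.

The generator matches marginal structure and the configured clinical-
pathologic dependence only; baseline covariates are sampled independently of
each other, visit times are an invented fixed schedule, and no attempt is
made to reproduce any real dataset row-for-row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

from . import _copula
from .cohort import CohortTable, EVENT_COLUMNS, PATIENT_COLUMNS, VISIT_COLUMNS
from .response import ResponseParams, _simulate_dv_matrix, build_covariate_matrix
from .survival import HazardParams, simulate_event_times_constant

__all__ = ["TABLE_FREQUENCIES", "SimulationConfig", "sample_covariates",
           "generate_pathologic_stage", "simulate_cohort"]

DAYS_PER_YEAR = 365.25

#: published cohort marginals (fractions); keys are canonical field levels
TABLE_FREQUENCIES: dict = {
    "male": 0.704,
    "ecog_0": 0.052,
    "gastric": 0.696,
    "location": {"cardias": 0.304, "antrum": 0.357, "body": 0.313, "pylorus": 0.017},
    "clinical_t": {2: 0.087, 3: 0.652, 4: 0.217, 5: 0.043},  # cT2/cT3/cT4a/cT4b ranks
    "cn_positive": 0.722,
    "stage3": 0.696,
    "grade": {"well": 0.035, "moderate": 0.409, "poor": 0.556},
    "linitis": 0.243,
    "lauren_diffuse": 0.539,
    "crt_arm": 0.565,
    "ypt": {0: 0.148, 1: 0.096, 2: 0.226, 3: 0.435, 4: 0.070, 5: 0.026},
    "ypn": {0: 0.609, 1: 0.226, 2: 0.070, 3: 0.087, 4: 0.009},
}


def _default_response_params() -> ResponseParams:
    # published clinical response estimates; omega2 was not reported -> 1.0
    return ResponseParams(
        beta=(19.7, -4.62),
        theta_markov={"PR": 18.1, "SD": 19.4, "DP": 18.8},
        omega2=1.0,
    )


def _default_os_params() -> HazardParams:
    return HazardParams(
        family="constant", lambda0=1e-4, delta_stage=1e-4, delta_linitis=2e-4,
        beta_met=3.43,
    )


@dataclass
class SimulationConfig:
    """Everything needed to generate a synthetic cohort reproducibly."""

    n_patients: int = 115
    covariate_frequencies: dict = field(default_factory=lambda: dict(TABLE_FREQUENCIES))
    age_min: float = 31.0
    age_mode: float = 62.0
    age_max: float = 83.0
    her2_prevalence: float = 0.15           # not published; configurable
    dose_intensity_range: tuple[float, float] = (0.7, 1.0)
    true_response_params: ResponseParams = field(default_factory=_default_response_params)
    true_os_params: HazardParams = field(default_factory=_default_os_params)
    true_metastasis_hazard: float = 2e-4    # per day; generator truth value
    visit_schedule_days: tuple[float, ...] = (0.0, 42.0, 84.0, 120.0)
    pathology_copula_rho: dict = field(
        default_factory=lambda: {"t": 0.32, "n": 0.19, "response": -0.29}
    )
    response_covariate_keys: tuple[str, ...] = ()
    accrual_years: float = 5.0
    admin_censor_years: float = 10.0
    pcr_coupling: bool = True               # ypT0 forces ypN0
    seed: int = 12345

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        freq = self.covariate_frequencies
        for key in ("male", "ecog_0", "gastric", "cn_positive", "stage3",
                    "linitis", "lauren_diffuse", "crt_arm"):
            if not 0.0 <= freq[key] <= 1.0:
                raise ValueError(f"frequency {key!r} outside [0, 1]")
        for key in ("location", "clinical_t", "grade", "ypt", "ypn"):
            probs = np.array(list(freq[key].values()), dtype=float)
            if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=0.02):
                raise ValueError(f"categorical block {key!r} must sum to 1")
        if not 1 <= len(self.visit_schedule_days) <= 4:
            raise ValueError("visit schedule must have 1..4 visits")
        if np.any(np.diff(self.visit_schedule_days) <= 0):
            raise ValueError("visit schedule times must be strictly increasing")
        if self.true_metastasis_hazard <= 0:
            raise ValueError("true_metastasis_hazard must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_response_params"] = asdict(self.true_response_params)
        d["true_os_params"] = asdict(self.true_os_params)
        return d


def _categorical(rng, levels, probs, size):
    probs = np.asarray(probs, dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.asarray(levels), size=size, p=probs)


def sample_covariates(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample the patients table (without pathology, filled in later)."""
    n = config.n_patients
    freq = config.covariate_frequencies
    ages = np.clip(
        np.round(rng.triangular(config.age_min, config.age_mode, config.age_max, n)),
        config.age_min, config.age_max,
    )
    loc = freq["location"]
    ct = freq["clinical_t"]
    grade = freq["grade"]
    lo, hi = config.dose_intensity_range
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n)],
            "age_years": ages,
            "sex": np.where(rng.random(n) < freq["male"], "male", "female"),
            "ecog": np.where(rng.random(n) < freq["ecog_0"], 0, 1),
            "tumor_site": np.where(rng.random(n) < freq["gastric"], "gastric", "gej"),
            "location": _categorical(rng, list(loc), list(loc.values()), n),
            "linitis": rng.random(n) < freq["linitis"],
            "lauren": np.where(
                rng.random(n) < freq["lauren_diffuse"], "diffuse", "intestinal"
            ),
            "grade": _categorical(rng, list(grade), list(grade.values()), n),
            "her2": rng.random(n) < config.her2_prevalence,
            "ctnm_stage": np.where(rng.random(n) < freq["stage3"], 3, 2),
            "treatment": np.where(rng.random(n) < freq["crt_arm"], "CRT", "ChT"),
            "dose_intensity": np.round(lo + (hi - lo) * rng.random(n), 3),
            "ct_n_positive": rng.random(n) < freq["cn_positive"],
            "ypt": pd.array([pd.NA] * n, dtype="Int64"),
            "ypn": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    df["clinical_t_rank"] = _categorical(
        rng, [int(k) for k in ct], list(ct.values()), n
    )
    return df


def generate_pathologic_stage(
    clinical_t_rank: np.ndarray,
    cn_rank: np.ndarray,
    rho_targets: dict,
    rng: np.random.Generator,
    ypt_marginal: dict | None = None,
    ypn_marginal: dict | None = None,
    final_response_dv: np.ndarray | None = None,
    pcr_coupling: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ypT, ypN) ranks coupled to clinical staging.

    ypT is linked to the clinical T rank with Spearman target
    ``rho_targets["t"]`` and ypN to the clinical nodal rank (0/1) with target
    ``rho_targets["n"]``; marginals default to the published ypT/ypN
    distributions.  The empirical marginal of the supplied clinical ranks is
    used on the clinical side of each copula.  ``final_response_dv`` is
    accepted for interface completeness: the clinical-response /
    pathologic-response concordance is an emergent quantity here, not a third
    enforced target (enforcing all three pairwise targets simultaneously would
    over-determine the copula).  With ``pcr_coupling`` every ypT0 draw is
    assigned ypN0, so complete pathologic responses equal the ypT0 count.
    """
    ypt_marginal = ypt_marginal or TABLE_FREQUENCIES["ypt"]
    ypn_marginal = ypn_marginal or TABLE_FREQUENCIES["ypn"]
    ct = np.asarray(clinical_t_rank)
    cn = np.asarray(cn_rank)

    def empirical(values):
        levels, counts = np.unique(values, return_counts=True)
        return levels, counts / counts.sum()

    for name in ("t", "n"):
        r = rho_targets.get(name, 0.0)
        if r is not None and not -1.0 <= r <= 1.0:
            raise ValueError(f"rho target {name!r}={r} outside [-1, 1]")

    ct_levels, ct_probs = empirical(ct)
    ypt_levels = np.array([int(k) for k in ypt_marginal])
    ypt_probs = np.array(list(ypt_marginal.values()), dtype=float)
    if len(ct_levels) < 2:
        # degenerate clinical marginal: no dependence is expressible
        ypt = _copula.copula_draw(
            ct, ct_levels, ct_probs, ypt_levels, ypt_probs / ypt_probs.sum(),
            None, rng, latent_rho=0.0,
        )
    else:
        ypt = _copula.copula_draw(
            ct, ct_levels, ct_probs, ypt_levels, ypt_probs / ypt_probs.sum(),
            rho_targets.get("t", 0.0), rng,
        )
    cn_levels, cn_probs = empirical(cn)
    ypn_levels = np.array([int(k) for k in ypn_marginal])
    ypn_probs = np.array(list(ypn_marginal.values()), dtype=float)
    if len(cn_levels) < 2:
        # degenerate nodal marginal: no dependence is expressible
        ypn = _copula.copula_draw(
            cn, cn_levels, np.asarray(cn_probs), ypn_levels,
            ypn_probs / ypn_probs.sum(), None, rng, latent_rho=0.0,
        )
    else:
        ypn = _copula.copula_draw(
            cn, cn_levels, cn_probs, ypn_levels, ypn_probs / ypn_probs.sum(),
            rho_targets.get("n", 0.0), rng,
        )
    if pcr_coupling:
        ypn = np.where(ypt == 0, 0, ypn)
    return ypt.astype(int), ypn.astype(int)


def simulate_cohort(
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Generate a full validated cohort under the configured study design."""
    config = config if config is not None else SimulationConfig()
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)

    pats = sample_covariates(config, rng)
    n = len(pats)
    ct_rank = pats.pop("clinical_t_rank").to_numpy()

    # --- response trajectories at the visit schedule ----------------------
    schedule = np.asarray(config.visit_schedule_days, dtype=float)
    n_visits = schedule.size
    rp = config.true_response_params
    if config.response_covariate_keys:
        theta = np.array(
            [rp.theta_cov.get(k, 0.0) for k in config.response_covariate_keys]
        )
        lin = build_covariate_matrix(pats, config.response_covariate_keys) @ theta
    else:
        lin = np.zeros(n)
    dv = _simulate_dv_matrix(rp, n, n_visits, rng, lin)

    visits = pd.DataFrame(
        {
            "patient_id": np.repeat(pats["patient_id"].to_numpy(), n_visits),
            "visit_index": np.tile(np.arange(1, n_visits + 1), n),
            "time_days": np.tile(schedule, n),
            "clinical_t": pd.array(
                [ct_rank[i] if j == 0 else pd.NA for i in range(n) for j in range(n_visits)],
                dtype="Int64",
            ),
            "clinical_n": pd.array(
                [bool(pats["ct_n_positive"].iloc[i]) if j == 0 else pd.NA
                 for i in range(n) for j in range(n_visits)],
                dtype="boolean",
            ),
            "response_dv": dv.reshape(-1),
        }
    )

    # --- events: metastasis then death with the hazard switch -------------
    stage3 = (pats["ctnm_stage"].to_numpy() >= 3)
    linitis = pats["linitis"].to_numpy(dtype=bool)
    t_met_latent = rng.exponential(1.0 / config.true_metastasis_hazard, size=n)
    accrual = rng.random(n) * config.accrual_years * DAYS_PER_YEAR
    follow = config.admin_censor_years * DAYS_PER_YEAR - accrual
    t_death, death_obs = simulate_event_times_constant(
        config.true_os_params, stage3, linitis, t_met_latent, follow, rng
    )
    met_obs = t_met_latent <= t_death
    t_met_rec = np.where(met_obs, t_met_latent, t_death)

    events = pd.DataFrame(
        {
            "patient_id": np.concatenate([pats["patient_id"]] * 2),
            "event_type": ["metastasis"] * n + ["death"] * n,
            "time_days": np.concatenate([t_met_rec, t_death]),
            "observed": np.concatenate([met_obs, death_obs]),
        }
    )

    # --- pathologic staging via the concordance copula --------------------
    final_dv = dv[:, -1]
    ypt, ypn = generate_pathologic_stage(
        ct_rank,
        pats["ct_n_positive"].to_numpy(dtype=int),
        config.pathology_copula_rho,
        rng,
        config.covariate_frequencies["ypt"],
        config.covariate_frequencies["ypn"],
        final_response_dv=final_dv,
        pcr_coupling=config.pcr_coupling,
    )
    pats["ypt"] = pd.array(ypt, dtype="Int64")
    pats["ypn"] = pd.array(ypn, dtype="Int64")

    cohort = CohortTable(pats[PATIENT_COLUMNS], visits[VISIT_COLUMNS],
                         events[EVENT_COLUMNS])
    cohort.validate()
    return cohort
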