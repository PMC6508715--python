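"""Model evaluation: visual predictive checks and nonparametric bootstrap.

VPCs simulate many replicate datasets under the fitted (fixed) parameters and
the original study design, then compare the observed statistic — per-visit
category proportions for the response model, the Kaplan-Meier curve for the
survival model — with the 2.5th / 50th / 97.5th percentile envelope of the
simulated statistic.  Parameter uncertainty is deliberately not propagated.

The bootstrap resamples *subjects* with replacement (each subject's visits
and events travel together, preserving within-subject correlation) and refits
the model on every replicate.  Percentiles use the linear-interpolation
empirical quantile convention (``numpy.percentile`` default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .response import ResponseParams, _simulate_dv_matrix, build_covariate_matrix
from .survival import (
    HazardParams,
    kaplan_meier,
    km_at,
    simulate_event_times_constant,
    survival_frame,
)

__all__ = [
    "VPCResult",
    "categorical_vpc_design",
    "vpc_categorical",
    "survival_vpc_design",
    "vpc_survival",
    "BootstrapResult",
    "bootstrap",
]

_PCTL = (2.5, 50.0, 97.5)


@dataclass
class VPCResult:
    """Percentile envelope (p2.5 <= p50 <= p97.5) plus the observed statistic.

    ``table`` columns: stratum, x, observed, p2.5, p50, p97.5.
    """

    table: pd.DataFrame
    n_sim: int
    kind: str

    def coverage_fraction(self) -> float:
        """Fraction of cells whose observed value lies inside the envelope."""
        t = self.table.dropna(subset=["observed"])
        inside = (t["observed"] >= t["p2.5"]) & (t["observed"] <= t["p97.5"])
        return float(inside.mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# categorical VPC
# ---------------------------------------------------------------------------

@dataclass
class CategoricalVPCDesign:
    """Visit structure extracted from a cohort: who is observed when."""

    dv_observed: np.ndarray      # (n_subj, n_visits) int, -1 = missing
    visit_index: np.ndarray      # (n_visits,) visit labels
    lin_cov: np.ndarray          # (n_subj,) covariate logit offset

    @property
    def n_subjects(self) -> int:
        return self.dv_observed.shape[0]

    @property
    def n_visits(self) -> int:
        return self.dv_observed.shape[1]


def categorical_vpc_design(
    cohort: CohortTable,
    params: ResponseParams | None = None,
    covariate_keys: Sequence[str] = (),
) -> CategoricalVPCDesign:
    pats = cohort.patients.reset_index(drop=True)
    index_of = {pid: i for i, pid in enumerate(pats["patient_id"])}
    vis = cohort.visits
    n_visits = int(vis["visit_index"].max()) if len(vis) else 1
    dv = np.full((len(pats), n_visits), -1, dtype=int)
    for _, row in vis.iterrows():
        if not pd.isna(row["response_dv"]):
            dv[index_of[row["patient_id"]], int(row["visit_index"]) - 1] = int(
                row["response_dv"]
            )
    if params is not None and covariate_keys:
        theta = np.array([params.theta_cov.get(k, 0.0) for k in covariate_keys])
        lin = build_covariate_matrix(pats, covariate_keys) @ theta
    else:
        lin = np.zeros(len(pats))
    return CategoricalVPCDesign(
        dv_observed=dv, visit_index=np.arange(1, n_visits + 1), lin_cov=lin
    )


def vpc_categorical(
    params: ResponseParams,
    design: CategoricalVPCDesign | CohortTable,
    n_sim: int = 500,
    rng: np.random.Generator | None = None,
    covariate_keys: Sequence[str] = (),
) -> VPCResult:
    """Visual predictive check of per-visit response-category proportions."""
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2")
    if isinstance(design, CohortTable):
        design = categorical_vpc_design(design, params, covariate_keys)
    rng = rng if rng is not None else np.random.default_rng()
    n, v = design.n_subjects, design.n_visits
    mask = design.dv_observed >= 0  # simulate on the observed visit pattern

    # all replicates at once: (n_sim * n, v)
    lin = np.tile(design.lin_cov, n_sim)
    dv_sim = _simulate_dv_matrix(params, n_sim * n, v, rng, lin).reshape(n_sim, n, v)

    rows = []
    for j in range(v):
        msk = mask[:, j]
        denom = msk.sum()
        for m in (0, 1, 2):
            obs = float(np.mean(design.dv_observed[msk, j] == m)) if denom else np.nan
            sim_prop = (
                np.mean(dv_sim[:, msk, j] == m, axis=1) if denom
                else np.full(n_sim, np.nan)
            )
            lo, med, hi = np.percentile(sim_prop, _PCTL)
            rows.append(
                {"stratum": f"category_{m}", "x": int(design.visit_index[j]),
                 "observed": obs, "p2.5": lo, "p50": med, "p97.5": hi}
            )
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim, kind="categorical")


# ---------------------------------------------------------------------------
# survival VPC
# ---------------------------------------------------------------------------

def survival_vpc_design(
    cohort: CohortTable,
    metastasis_rate: float | None = None,
    max_follow_days: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-subject design frame for the KM VPC.

    ``max_follow_days`` is each subject's potential follow-up (the censoring
    scheme used when re-simulating); when omitted it is taken as the observed
    time for censored subjects and the cohort's maximum observed time for
    subjects who died — an approximation appropriate for administrative
    censoring.  ``metastasis_rate`` (per day) re-simulates the metastasis
    process; if None, each subject's observed metastasis time is reused.
    """
    df = survival_frame(cohort, event_type="death")
    if max_follow_days is None:
        fallback = float(df["time_days"].max())
        df["max_follow_days"] = np.where(df["observed"], fallback, df["time_days"])
    else:
        df["max_follow_days"] = max_follow_days
    df["metastasis_rate"] = np.nan if metastasis_rate is None else metastasis_rate
    return df


def _km_on_grid(times, observed, grid) -> np.ndarray:
    curve = kaplan_meier(times, observed)
    return np.asarray(km_at(curve, grid))


def vpc_survival(
    params: HazardParams,
    design: pd.DataFrame,
    n_sim: int = 500,
    time_grid: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    stratify_by: str | None = None,
) -> VPCResult:
    """Kaplan-Meier visual predictive check, optionally stratified.

    ``stratify_by`` in {None, "metastasis", "stage3", "linitis"}.  For the
    metastasis stratification, simulated curves use each replicate's simulated
    metastasis status while the observed curve uses the recorded one.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be at least 2")
    rng = rng if rng is not None else np.random.default_rng()
    if time_grid is None:
        time_grid = np.linspace(0.0, float(design["time_days"].max()), 25)
    time_grid = np.asarray(time_grid, dtype=float)

    n = len(design)
    stage3 = design["stage3"].to_numpy(dtype=bool)
    linitis = design["linitis"].to_numpy(dtype=bool)
    follow = design["max_follow_days"].to_numpy(dtype=float)
    obs_t = design["time_days"].to_numpy(dtype=float)
    obs_d = design["observed"].to_numpy(dtype=bool)
    obs_tmet = design["t_met"].to_numpy(dtype=float) if "t_met" in design else np.full(n, np.nan)
    met_rate = design["metastasis_rate"].iloc[0] if "metastasis_rate" in design else np.nan

    def strata_masks(t_met_eff, t_event):
        if stratify_by is None:
            return {"all": np.ones(n, dtype=bool)}
        if stratify_by == "stage3":
            return {"stage3": stage3, "stage_lt3": ~stage3}
        if stratify_by == "linitis":
            return {"linitis": linitis, "no_linitis": ~linitis}
        if stratify_by == "metastasis":
            has = np.isfinite(t_met_eff) & (t_met_eff <= t_event)
            return {"metastasis": has, "no_metastasis": ~has}
        raise ValueError(f"unknown stratification {stratify_by!r}")

    sim_curves: dict[str, list[np.ndarray]] = {}
    for _ in range(n_sim):
        if np.isfinite(met_rate):
            t_met = rng.exponential(1.0 / met_rate, size=n)
        else:
            t_met = obs_tmet
        t_sim, d_sim = simulate_event_times_constant(
            params, stage3, linitis, t_met, follow, rng
        )
        for name, msk in strata_masks(t_met, t_sim).items():
            if msk.sum() == 0:
                continue
            sim_curves.setdefault(name, []).append(
                _km_on_grid(t_sim[msk], d_sim[msk], time_grid)
            )

    rows = []
    obs_masks = strata_masks(obs_tmet, obs_t)
    for name, curves in sim_curves.items():
        arr = np.vstack(curves)
        lo, med, hi = np.percentile(arr, _PCTL, axis=0)
        omask = obs_masks.get(name, np.zeros(n, dtype=bool))
        obs_curve = (
            _km_on_grid(obs_t[omask], obs_d[omask], time_grid)
            if omask.sum() else np.full(time_grid.size, np.nan)
        )
        for i, t in enumerate(time_grid):
            rows.append(
                {"stratum": name, "x": float(t), "observed": obs_curve[i],
                 "p2.5": lo[i], "p50": med[i], "p97.5": hi[i]}
            )
    return VPCResult(table=pd.DataFrame(rows), n_sim=n_sim, kind="survival")


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    percentiles: pd.DataFrame     # rows = parameters; columns p2.5/p50/p97.5
    samples: pd.DataFrame         # one row per converged replicate
    n_boot: int
    n_converged: int
    unreliable: bool

    def to_csv(self, path) -> None:
        out = self.percentiles.reset_index(names="parameter")
        out["n_converged"] = self.n_converged
        out.to_csv(path, index=False)


def resample_cohort(cohort: CohortTable, rng: np.random.Generator) -> CohortTable:
    """Subject-level resample with replacement; duplicates get fresh ids."""
    ids = cohort.patients["patient_id"].to_numpy()
    pick_pos = rng.integers(0, ids.size, size=ids.size)
    picked = ids[pick_pos]
    new_ids = np.array([f"B{i:05d}" for i in range(ids.size)])

    pats = cohort.patients.iloc[pick_pos].reset_index(drop=True)
    pats["patient_id"] = new_ids

    def gather(table: pd.DataFrame) -> pd.DataFrame:
        if not len(table):
            return table.iloc[:0]
        groups = table.groupby("patient_id", sort=False).indices
        empty = np.empty(0, dtype=np.intp)
        blocks = [groups.get(pid, empty) for pid in picked]
        counts = [b.size for b in blocks]
        rows = np.concatenate(blocks) if blocks else empty
        out = table.iloc[rows].reset_index(drop=True)
        out["patient_id"] = np.repeat(new_ids, counts)
        return out

    return CohortTable(pats, gather(cohort.visits), gather(cohort.events))


def bootstrap(
    cohort: CohortTable,
    fit: Callable[[CohortTable], Mapping[str, float]],
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Nonparametric (subject-resampling) bootstrap of a fit closure.

    ``fit(cohort)`` returns a mapping of parameter name -> estimate; it may
    include a boolean ``"converged"`` entry (replicates with False are
    dropped).  The result is flagged unreliable when more than half of the
    replicates fail.
    """
    if cohort.n_patients < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    rng = rng if rng is not None else np.random.default_rng()
    rows = []
    n_failed = 0
    for _ in range(n_boot):
        boot = resample_cohort(cohort, rng)
        try:
            est = dict(fit(boot))
        except Exception:
            n_failed += 1
            continue
        if not est.pop("converged", True):
            n_failed += 1
            continue
        rows.append(est)
    samples = pd.DataFrame(rows)
    n_conv = len(samples)
    if n_conv == 0:
        raise RuntimeError("all bootstrap replicates failed")
    pct = samples.quantile([0.025, 0.5, 0.975]).T
    pct.columns = ["p2.5", "p50", "p97.5"]
    return BootstrapResult(
        percentiles=pct, samples=samples, n_boot=n_boot, n_converged=n_conv,
        unreliable=bool(n_conv < 0.5 * n_boot),
    )
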