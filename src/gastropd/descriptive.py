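"""Descriptive analyses: cohort summaries and clinical-pathologic concordance.

The concordance analysis quantifies how well pretreatment clinical staging
(EUS/CT-based cT, cN) predicts post-surgery pathologic staging (ypT, ypN)
with Spearman rank correlations, and compares the final clinical response
category with a pathologic response category obtained by applying the same
downstage / no-change / upstage rule to the clinical-to-pathologic stage
change.  Missing pathology (non-operated patients) is handled by
pairwise-complete deletion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, derive_pcr

__all__ = ["spearman", "staging_concordance", "SummaryTable", "summarize_cohort",
           "pathologic_response_category"]


def spearman(x, y) -> float:
    """Spearman rank correlation (Pearson on midranks), pairwise-complete.

    Returns ``nan`` when either vector is constant or fewer than 3 complete
    pairs remain.
    """
    x = pd.to_numeric(pd.Series(list(x)), errors="coerce")
    y = pd.to_numeric(pd.Series(list(y)), errors="coerce")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    ok = x.notna() & y.notna()
    x, y = x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float)
    if x.size < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def pathologic_response_category(ct, cn, ypt, ypn) -> int | None:
    """Down/no-change/up categorisation of the clinical-to-pathologic stage change.

    Any upstaging in T or N -> 2; downstaging in either without upstaging in
    the other -> 0; otherwise 1.  ``cn``/``ypn`` are compared on their ordinal
    ranks (a positive clinical N is rank 1 when recorded as a boolean).
    """
    deltas = []
    if not (pd.isna(ct) or pd.isna(ypt)):
        deltas.append(np.sign(int(ypt) - int(ct)))
    if not (pd.isna(cn) or pd.isna(ypn)):
        deltas.append(np.sign(int(ypn) - int(cn)))
    if not deltas:
        return None
    if any(d > 0 for d in deltas):
        return 2
    if any(d < 0 for d in deltas):
        return 0
    return 1


def staging_concordance(cohort: CohortTable) -> dict[str, float]:
    """Spearman correlations between clinical and pathologic staging/response.

    * ``rho_T``: baseline clinical T rank vs pathologic ypT rank.
    * ``rho_N``: clinical nodal status (cN+, rank 0/1) vs ypN rank.
    * ``rho_response``: final observed clinical response category vs the
      pathologic response category from :func:`pathologic_response_category`.
    """
    pats = cohort.patients.set_index("patient_id")
    v1 = cohort.visits[cohort.visits["visit_index"] == 1].set_index("patient_id")
    ct = v1["clinical_t"].reindex(pats.index)
    cn = pats["ct_n_positive"].map({True: 1, False: 0})
    ypt, ypn = pats["ypt"], pats["ypn"]

    pairs_t = pd.DataFrame({"x": ct, "y": ypt}).dropna()
    pairs_n = pd.DataFrame({"x": cn, "y": ypn}).dropna()
    if pairs_t.empty and pairs_n.empty:
        raise ValueError("no patients with both clinical and pathologic staging")

    final_dv = (
        cohort.visits.dropna(subset=["response_dv"])
        .groupby("patient_id")["response_dv"].last()
        .reindex(pats.index)
    )
    path_cat = pd.Series(
        [
            pathologic_response_category(ct.get(pid), cn.get(pid),
                                         ypt.get(pid), ypn.get(pid))
            for pid in pats.index
        ],
        index=pats.index, dtype="object",
    )
    return {
        "rho_T": spearman(pairs_t["x"], pairs_t["y"]),
        "rho_N": spearman(pairs_n["x"], pairs_n["y"]),
        "rho_response": spearman(final_dv, path_cat),
    }


@dataclass
class SummaryTable:
    """Cohort characteristics: category counts/percentages and scalar stats."""

    blocks: dict[str, dict[str, tuple[int, float]]]  # block -> level -> (n, %)
    scalars: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"block": b, "level": lvl, "count": n, "percent": pct}
            for b, levels in self.blocks.items()
            for lvl, (n, pct) in levels.items()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        scal = pd.DataFrame(
            [{"block": "scalar", "level": k, "count": np.nan, "percent": v}
             for k, v in self.scalars.items()]
        )
        pd.concat([frame, scal], ignore_index=True).to_csv(path, index=False)


_T_LABELS = {0: "T0", 1: "T1", 2: "T2", 3: "T3", 4: "T4a", 5: "T4b"}
_N_LABELS = {0: "N0", 1: "N1", 2: "N2", 3: "N3a", 4: "N3b"}


def summarize_cohort(cohort: CohortTable) -> SummaryTable:
    """Counts and percentages per characteristic block, plus age and pCR."""
    pats = cohort.patients
    if len(pats) == 0:
        raise ValueError("empty cohort")
    n = len(pats)

    def block(series, labels=None, denom=None):
        s = series.dropna()
        if labels:
            s = s.map(labels)
        counts = s.value_counts()
        d = denom if denom is not None else counts.sum()
        return {
            str(lvl): (int(c), 100.0 * c / d if d else float("nan"))
            for lvl, c in counts.items()
        }

    v1 = cohort.visits[cohort.visits["visit_index"] == 1].set_index("patient_id")
    ct = v1["clinical_t"].reindex(pats["patient_id"]).reset_index(drop=True)

    blocks = {
        "sex": block(pats["sex"]),
        "ecog": block(pats["ecog"]),
        "tumor_site": block(pats["tumor_site"]),
        "location": block(pats["location"]),
        "clinical_t": block(ct, _T_LABELS),
        "clinical_n": block(pats["ct_n_positive"].map({True: "cN+", False: "cN0"})),
        "ctnm_stage": block(pats["ctnm_stage"].map({1: "Ib", 2: "II", 3: "III"})),
        "grade": block(pats["grade"]),
        "linitis": block(pats["linitis"].map({True: "yes", False: "no"})),
        "lauren": block(pats["lauren"]),
        "treatment": block(pats["treatment"]),
        "ypt": block(pats["ypt"], {k: "yp" + v for k, v in _T_LABELS.items()}),
        "ypn": block(pats["ypn"], {k: "yp" + v for k, v in _N_LABELS.items()}),
    }
    pcr_flags = [derive_pcr(row) for _, row in pats.iterrows()]
    n_path = sum(f is not None for f in pcr_flags)
    n_pcr = sum(bool(f) for f in pcr_flags if f is not None)
    ages = pats["age_years"].dropna().astype(float)
    scalars = {
        "n_patients": float(n),
        "age_median": float(ages.median()) if len(ages) else float("nan"),
        "age_min": float(ages.min()) if len(ages) else float("nan"),
        "age_max": float(ages.max()) if len(ages) else float("nan"),
        "pcr_count": float(n_pcr),
        "pcr_percent": 100.0 * n_pcr / n_path if n_path else float("nan"),
    }
    return SummaryTable(blocks=blocks, scalars=scalars)
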