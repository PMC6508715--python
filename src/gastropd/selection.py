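"""Likelihood-ratio covariate screening on the -2LL (OFV) scale.

For nested models differing in one parameter, OFV drops of 3.86 / 6.63 /
7.88 / 11.87 are treated as significant at the 5 / 1 / 0.5 / 0.1 % levels.
This published decision ladder is applied verbatim by default (its 0.1 %
entry, 11.87, is slightly more conservative than the exact chi-square-1
quantile 10.828); exact chi-square quantiles are available as an option and
are always used for df > 1 or off-ladder alpha levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd
from scipy.stats import chi2

__all__ = ["OFV_LADDER_DF1", "LRTResult", "lrt", "ScreenTrace", "forward_covariate_screen"]

#: published OFV-difference thresholds for one degree of freedom
OFV_LADDER_DF1 = {0.05: 3.86, 0.01: 6.63, 0.005: 7.88, 0.001: 11.87}

_NEST_TOL = 1e-6


@dataclass
class LRTResult:
    delta_ofv: float
    df: int
    alpha: float
    threshold: float
    significant: bool


def lrt(
    ofv_reduced: float,
    ofv_full: float,
    df: int = 1,
    alpha: float = 0.05,
    use_exact_quantiles: bool = False,
) -> LRTResult:
    """Likelihood-ratio test between nested fits on the OFV (-2LL) scale."""
    if df < 1:
        raise ValueError("df must be >= 1")
    delta = ofv_reduced - ofv_full
    if delta < -_NEST_TOL:
        raise ValueError(
            f"ofv_reduced < ofv_full by {-delta:.3g}: models do not appear nested "
            "(or the full fit did not converge)"
        )
    delta = max(delta, 0.0)
    if df == 1 and alpha in OFV_LADDER_DF1 and not use_exact_quantiles:
        threshold = OFV_LADDER_DF1[alpha]
    else:
        threshold = float(chi2.ppf(1.0 - alpha, df))
    return LRTResult(
        delta_ofv=float(delta), df=df, alpha=alpha, threshold=threshold,
        # boundary counts as significant; tolerance absorbs float round-off
        significant=bool(delta >= threshold - 1e-9),
    )


@dataclass
class ScreenTrace:
    """Round-by-round record of a greedy forward covariate screen."""

    selected: list[str]
    rounds: list[dict] = field(default_factory=list)
    final_fit: object | None = None
    base_ofv: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rounds,
            columns=["round", "candidate", "ofv", "delta_ofv", "threshold",
                     "decision"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def forward_covariate_screen(
    fit: Callable[[tuple[str, ...]], object],
    candidates: Sequence[str],
    alpha_add: float = 0.05,
    use_exact_quantiles: bool = False,
) -> ScreenTrace:
    """Greedy forward selection driven by a fit closure.

    ``fit(selected_keys)`` must return an object exposing ``ofv`` (float) and
    ``converged`` (bool).  Each round refits every remaining single addition;
    the largest significant OFV drop wins.  Selection stops when no addition
    is significant at ``alpha_add``.  A failing or non-convergent inner fit is
    recorded and that candidate is skipped for the round.
    """
    remaining = list(candidates)
    selected: list[str] = []
    base = fit(tuple(selected))
    if not getattr(base, "converged", True):
        raise RuntimeError("base model fit did not converge")
    trace = ScreenTrace(selected=selected, base_ofv=float(base.ofv), final_fit=base)
    base_ofv = float(base.ofv)
    round_no = 0
    while remaining:
        round_no += 1
        results: dict[str, tuple[float, object]] = {}
        for cand in remaining:
            try:
                res = fit(tuple(selected + [cand]))
            except Exception as exc:  # inner fit failure: skip this round
                trace.rounds.append(
                    {"round": round_no, "candidate": cand, "ofv": float("nan"),
                     "delta_ofv": float("nan"), "threshold": float("nan"),
                     "decision": f"fit failed: {exc}"}
                )
                continue
            if not getattr(res, "converged", True):
                trace.rounds.append(
                    {"round": round_no, "candidate": cand, "ofv": float(res.ofv),
                     "delta_ofv": float("nan"), "threshold": float("nan"),
                     "decision": "not converged"}
                )
                continue
            test = lrt(base_ofv, float(res.ofv), df=1, alpha=alpha_add,
                       use_exact_quantiles=use_exact_quantiles)
            trace.rounds.append(
                {"round": round_no, "candidate": cand, "ofv": float(res.ofv),
                 "delta_ofv": test.delta_ofv, "threshold": test.threshold,
                 "decision": "significant" if test.significant else "not significant"}
            )
            if test.significant:
                results[cand] = (test.delta_ofv, res)
        if not results:
            break
        winner = max(results, key=lambda c: results[c][0])
        selected.append(winner)
        remaining.remove(winner)
        base_ofv = float(results[winner][1].ofv)
        trace.final_fit = results[winner][1]
        if alpha_add in OFV_LADDER_DF1 and not use_exact_quantiles:
            thr = OFV_LADDER_DF1[alpha_add]
        else:
            thr = float(chi2.ppf(1.0 - alpha_add, 1))
        trace.rounds.append(
            {"round": round_no, "candidate": winner, "ofv": base_ofv,
             "delta_ofv": results[winner][0], "threshold": thr,
             "decision": "added"}
        )
    return trace
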