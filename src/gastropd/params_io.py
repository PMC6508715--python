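"""Flat key-value (YAML) round-tripping of model parameter sets."""

from __future__ import annotations

from pathlib import Path

import yaml

from .response import ResponseParams
from .survival import HazardParams

__all__ = ["write_response_params", "read_response_params",
           "write_hazard_params", "read_hazard_params"]


def write_response_params(params: ResponseParams, path) -> None:
    d = {
        "beta1": float(params.beta[0]),
        "beta2": float(params.beta[1]),
        "theta_pr": float(params.theta_markov["PR"]),
        "theta_sd": float(params.theta_markov["SD"]),
        "theta_dp": float(params.theta_markov["DP"]),
        "omega2": float(params.omega2),
        "markov_sign": float(params.markov_sign),
    }
    for key, val in params.theta_cov.items():
        d[f"theta_{key.lower()}"] = float(val)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_response_params(path) -> ResponseParams:
    d = yaml.safe_load(Path(path).read_text())
    known = {"beta1", "beta2", "theta_pr", "theta_sd", "theta_dp", "omega2",
             "markov_sign"}
    theta_cov = {
        k.removeprefix("theta_").upper(): float(v)
        for k, v in d.items()
        if k.startswith("theta_") and k not in known
    }
    return ResponseParams(
        beta=(float(d["beta1"]), float(d["beta2"])),
        theta_markov={"PR": float(d["theta_pr"]), "SD": float(d["theta_sd"]),
                      "DP": float(d["theta_dp"])},
        theta_cov=theta_cov,
        omega2=float(d.get("omega2", 1.0)),
        markov_sign=float(d.get("markov_sign", -1.0)),
    )


def write_hazard_params(params: HazardParams, path) -> None:
    d = {
        "family": params.family,
        "lambda0": float(params.lambda0),
        "delta_stage": float(params.delta_stage),
        "delta_linitis": float(params.delta_linitis),
        "beta_met": float(params.beta_met),
        "time_unit_days": float(params.time_unit_days),
    }
    if params.shape is not None:
        d["shape"] = float(params.shape)
    for key, val in params.delta_extra.items():
        d[f"delta_{key}"] = float(val)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def read_hazard_params(path) -> HazardParams:
    d = yaml.safe_load(Path(path).read_text())
    known = {"family", "lambda0", "delta_stage", "delta_linitis", "beta_met",
             "time_unit_days", "shape"}
    extra = {
        k.removeprefix("delta_"): float(v)
        for k, v in d.items()
        if k.startswith("delta_") and k not in known
    }
    return HazardParams(
        family=d.get("family", "constant"),
        lambda0=float(d["lambda0"]),
        shape=float(d["shape"]) if "shape" in d else None,
        delta_stage=float(d.get("delta_stage", 0.0)),
        delta_linitis=float(d.get("delta_linitis", 0.0)),
        beta_met=float(d.get("beta_met", 0.0)),
        delta_extra=extra,
        time_unit_days=float(d.get("time_unit_days", 1.0)),
    )
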