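"""Configuration files (YAML, with JSON equivalence) for priors and targets.

A config file may contain any of the top-level sections ``np_prior``,
``parametric_prior``, ``error_model``, ``targets`` and ``template``;
omitted sections fall back to the packaged daptomycin defaults.  Example::

    np_prior:
      n_support: 1000
      seed: 7
      moments:
        v1_std: {mean: 6.90, cv: 0.394}
        ks:     {mean: 0.050, cv: 0.896}
        ki:     {mean: 0.060, cv: 0.832}
        kcp:    {mean: 0.693, cv: 1.180}
        kpc:    {mean: 0.667, cv: 0.977}
    parametric_prior:
      tv_cl: 0.759
      tv_v1: 6.90
      tv_q: 4.78
      tv_v2: 7.17
      clcr_form: linear     # declared explicitly: linear or power
      theta_clcr: 0.4545
      theta_sex_male: 1.0
    error_model: {c0: 0.5, c1: 0.1, lloq: 2.0}
    targets: {auc_target: 666.0, cmin_limit: 24.3}
    template: {interval_h: 24.0, infusion_duration_h: 0.5}

The nonparametric prior may alternatively give an explicit support table::

    np_prior:
      support: [[6.9, 0.05, 0.06, 0.693, 0.667], ...]
      weights: [0.5, ...]
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .dosing import ExposureTargets
from .pk import DosingRegimen, InvalidParameterError, PARAM_NAMES
from .priors import (
    AssayErrorModel,
    NonparametricPrior,
    ParamMoments,
    ParametricPrior,
    build_np_prior,
)

__all__ = [
    "load_config",
    "np_prior_from_config",
    "parametric_prior_from_config",
    "error_model_from_config",
    "targets_from_config",
    "template_regimen_from_config",
]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise InvalidParameterError("config root must be a mapping")
    return data


def np_prior_from_config(cfg: dict, default_seed: int = 2022) -> NonparametricPrior:
    section = cfg.get("np_prior", {})
    if "support" in section:
        support = np.asarray(section["support"], dtype=float)
        weights = section.get("weights")
        if weights is None:
            weights = np.full(support.shape[0], 1.0 / support.shape[0])
        return NonparametricPrior(support=support, weights=np.asarray(weights, float))
    if "moments" in section:
        raw = section["moments"]
        moments = ParamMoments(
            means={k: float(raw[k]["mean"]) for k in PARAM_NAMES},
            cvs={k: float(raw[k]["cv"]) for k in PARAM_NAMES},
        )
    else:
        moments = ParamMoments.daptomycin_bji()
    return build_np_prior(
        moments,
        n_support=int(section.get("n_support", 1000)),
        seed=int(section.get("seed", default_seed)),
    )


def parametric_prior_from_config(cfg: dict) -> ParametricPrior:
    section = dict(cfg.get("parametric_prior", {}))
    if not section:
        return ParametricPrior.from_micro_moments(ParamMoments.daptomycin_bji())
    if not {"tv_cl", "tv_v1", "tv_q", "tv_v2"} <= section.keys():
        return ParametricPrior.from_micro_moments(ParamMoments.daptomycin_bji(), **section)
    return ParametricPrior(**section)


def error_model_from_config(cfg: dict) -> AssayErrorModel:
    return AssayErrorModel(**cfg.get("error_model", {}))


def targets_from_config(cfg: dict) -> ExposureTargets:
    return ExposureTargets(**cfg.get("targets", {}))


def template_regimen_from_config(cfg: dict) -> DosingRegimen:
    """Template schedule for dose optimization (dose amount is nominal:
    only the interval and infusion duration matter for sensitivities)."""
    section = cfg.get("template", {})
    interval = float(section.get("interval_h", 24.0))
    duration = float(section.get("infusion_duration_h", 0.5))
    return DosingRegimen.multiple_doses(1.0, n_doses=1, interval_h=interval,
                                        infusion_duration_h=duration)
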