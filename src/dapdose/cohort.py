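"""Virtual TDM cohorts emulating a sparse daptomycin monitoring design.

Each virtual patient gets covariates drawn from the monitored bone-and-
joint-infection population (weight 76 +/- 18 kg, CLcr 103 +/- 56 mL/min,
42.5% female, age 62 +/- 17 y, truncated to plausible ranges), true PK
parameters sampled from the discrete population prior, a weight-based
q24h dosing regimen (7.6 +/- 1.3 mg/kg/day), and a three-sample TDM
profile on one occasion: pre-dose trough, ~30 min after administration,
and 5-6 h post-dose.  Observations carry polynomial assay noise and are
left-censored below the 2 mg/L LLOQ.  The generating truth is retained
for recovery testing.

Datasets are exchanged as NONMEM-style event-record tables (CSV):

====  =======================================================
col   meaning
====  =======================================================
ID    patient identifier
TIME  hours since first dose
EVID  1 = dose event, 0 = observation
AMT   dose amount, mg (dose rows; "." otherwise)
RATE  infusion rate, mg/h (dose rows)
II    dosing interval, h (dose rows)
DV    measured concentration, mg/L (observation rows)
MDV   1 = DV missing/not usable (dose rows and censored rows)
BLQ   1 = observation below the LLOQ (DV withheld, ".")
WT    body weight, kg
CLCR  creatinine clearance, mL/min
SEX   0 = female, 1 = male
AGE   years ("." if unknown)
====  =======================================================

Missing fields are written as ".".  Round-tripping a cohort through
write/read preserves times, doses, covariates and uncensored values
exactly; censored rows keep only the flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bayes import ObservationSet
from .pk import (
    Covariates,
    DoseEvent,
    DosingRegimen,
    ExposureMetrics,
    InvalidParameterError,
    PKMicroParams,
    predict_concentrations,
    resolve_parameters,
    steady_state_metrics,
)
from .priors import AssayErrorModel, NonparametricPrior

__all__ = [
    "CohortConfig",
    "VirtualPatient",
    "PatientRecord",
    "generate_cohort",
    "write_dataset",
    "read_dataset",
    "cohort_truth",
]

DATASET_COLUMNS = [
    "ID", "TIME", "EVID", "AMT", "RATE", "II", "DV", "MDV", "BLQ",
    "WT", "CLCR", "SEX", "AGE",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the virtual cohort.

    Defaults reproduce the monitored population's covariate moments, dosing
    practice and sampling times; ``peak_after_infusion_end`` switches the
    "30 min after administration" sample from 30 min after infusion start
    (default) to 30 min after infusion end.
    """

    n_patients: int
    seed: int
    weight_mean: float = 76.0
    weight_sd: float = 18.0
    weight_min: float = 30.0
    clcr_mean: float = 103.0
    clcr_sd: float = 56.0
    clcr_min: float = 10.0
    frac_female: float = 0.425
    age_mean: float = 62.0
    age_sd: float = 17.0
    age_min: float = 18.0
    age_max: float = 100.0
    dose_mg_kg_mean: float = 7.6
    dose_mg_kg_sd: float = 1.3
    interval_h: float = 24.0
    infusion_duration_h: float = 0.5
    sampling_dose_index: int = 5
    trough_lead_h: float = 1.0 / 12.0  # 5 min before the monitored dose
    peak_offset_h: float = 0.5
    peak_after_infusion_end: bool = False
    late_window_h: tuple[float, float] = (5.0, 6.0)
    jitter_h: float = 0.25
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidParameterError("n_patients must be >= 1")
        if not 0.0 <= self.frac_female <= 1.0:
            raise InvalidParameterError("frac_female must be in [0, 1]")
        for name in ("weight_sd", "clcr_sd", "age_sd", "dose_mg_kg_sd", "jitter_h"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.age_min >= self.age_max:
            raise InvalidParameterError("age bounds are impossible")
        if self.sampling_dose_index < 0:
            raise InvalidParameterError("sampling_dose_index must be >= 0")


@dataclass(frozen=True)
class VirtualPatient:
    """One simulated patient with generating truth attached."""

    id: int
    covariates: Covariates
    true_params: PKMicroParams
    regimen: DosingRegimen
    observations: ObservationSet
    true_exposure: ExposureMetrics


@dataclass(frozen=True)
class PatientRecord:
    """A patient as read back from a dataset (no truth)."""

    id: int
    covariates: Covariates
    regimen: DosingRegimen
    observations: ObservationSet


def _trunc_normal(rng, mean, sd, low=-math.inf, high=math.inf, max_tries=10000) -> float:
    if not (low < high) or (mean < low - 10 * sd) or (mean > high + 10 * sd):
        raise InvalidParameterError(
            f"impossible truncation bounds ({low}, {high}) for mean {mean}, sd {sd}"
        )
    if sd == 0:
        if low < mean < high:
            return mean
        raise InvalidParameterError("degenerate draw outside truncation bounds")
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if low < x < high:
            return x
    raise InvalidParameterError("truncated sampling failed; bounds too tight")


def generate_cohort(
    cfg: CohortConfig,
    prior: NonparametricPrior,
    error_model: AssayErrorModel | None = None,
) -> list[VirtualPatient]:
    """Simulate a cohort; reproducible under ``cfg.seed``."""
    e = error_model if error_model is not None else AssayErrorModel()
    rng = np.random.default_rng(cfg.seed)
    patients = []
    for pid in range(1, cfg.n_patients + 1):
        wt = _trunc_normal(rng, cfg.weight_mean, cfg.weight_sd, low=cfg.weight_min)
        clcr = _trunc_normal(rng, cfg.clcr_mean, cfg.clcr_sd, low=cfg.clcr_min)
        sex = "F" if rng.random() < cfg.frac_female else "M"
        age = _trunc_normal(rng, cfg.age_mean, cfg.age_sd, low=cfg.age_min, high=cfg.age_max)
        cov = Covariates(weight_kg=wt, clcr_ml_min=clcr, sex=sex, age_years=age)

        j = rng.choice(prior.n_support, p=prior.weights)
        true_params = prior.point(j)

        mg_kg = max(_trunc_normal(rng, cfg.dose_mg_kg_mean, cfg.dose_mg_kg_sd, low=0.5), 0.5)
        dose_mg = float(round(mg_kg * wt))
        regimen = DosingRegimen.multiple_doses(
            dose_mg,
            n_doses=cfg.sampling_dose_index + 1,
            interval_h=cfg.interval_h,
            infusion_duration_h=cfg.infusion_duration_h,
        )

        occ = cfg.sampling_dose_index * cfg.interval_h
        jit = (lambda: rng.uniform(-cfg.jitter_h, cfg.jitter_h)) if cfg.jitter_h > 0 else (lambda: 0.0)
        t_trough = occ - cfg.trough_lead_h + jit()
        t_trough = min(max(t_trough, occ - cfg.interval_h * 0.5), occ - 0.01)
        peak_base = occ + cfg.peak_offset_h + (
            cfg.infusion_duration_h if cfg.peak_after_infusion_end else 0.0
        )
        t_peak = max(peak_base + jit(), occ + cfg.infusion_duration_h + 0.01)
        t_late = occ + rng.uniform(*cfg.late_window_h)
        times = np.array(sorted([t_trough, t_peak, t_late]))

        resolved = resolve_parameters(true_params, cov)
        true_conc = predict_concentrations(resolved, regimen, times)
        if cfg.noise:
            noisy = true_conc + rng.standard_normal(times.size) * e.sd(true_conc)
            noisy = np.clip(noisy, 0.0, None)
        else:
            noisy = true_conc.copy()
        blq = noisy < e.lloq
        obs = ObservationSet(
            times_h=times,
            conc_mg_l=noisy,
            below_lloq=blq,
            covariates=cov,
            regimen=regimen,
        )
        patients.append(
            VirtualPatient(
                id=pid,
                covariates=cov,
                true_params=true_params,
                regimen=regimen,
                observations=obs,
                true_exposure=steady_state_metrics(resolved, regimen),
            )
        )
    return patients


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def _sex_code(sex: str) -> int:
    return 0 if sex == "F" else 1


def write_dataset(cohort: Sequence[VirtualPatient | PatientRecord]) -> pd.DataFrame:
    """Event-record table for a cohort; see module docstring for the layout."""
    rows = []
    for p in cohort:
        cov = p.covariates
        base = {
            "ID": p.id,
            "WT": cov.weight_kg,
            "CLCR": cov.clcr_ml_min,
            "SEX": _sex_code(cov.sex),
            "AGE": cov.age_years if cov.age_years is not None else None,
        }
        for ev in p.regimen.dose_events:
            rows.append(
                base
                | {
                    "TIME": ev.start_time_h,
                    "EVID": 1,
                    "AMT": ev.dose_mg,
                    "RATE": ev.rate_mg_h,
                    "II": p.regimen.interval_h,
                    "DV": None,
                    "MDV": 1,
                    "BLQ": 0,
                }
            )
        obs = p.observations
        for t, c, b in zip(obs.times_h, obs.conc_mg_l, obs.below_lloq):
            rows.append(
                base
                | {
                    "TIME": float(t),
                    "EVID": 0,
                    "AMT": None,
                    "RATE": None,
                    "II": None,
                    "DV": None if b else float(c),
                    "MDV": 1 if b else 0,
                    "BLQ": int(b),
                }
            )
    df = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable").reset_index(drop=True)


def write_dataset_csv(cohort, path: str | Path) -> None:
    df = write_dataset(cohort)
    df.to_csv(path, index=False, na_rep=".")


def read_dataset(source: str | Path | pd.DataFrame) -> list[PatientRecord]:
    """Parse an event-record table back into per-patient records.

    Censored observations come back with concentration 0 and the BLQ flag
    set; malformed rows raise with their row number.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, na_values=["."])
    missing = [c for c in DATASET_COLUMNS if c not in df.columns and c != "AGE"]
    if missing:
        raise InvalidParameterError(f"dataset is missing columns: {missing}")
    records = []
    for pid, grp in df.groupby("ID", sort=True):
        grp = grp.sort_values(["TIME", "EVID"], kind="stable")
        first = grp.iloc[0]
        age = None
        if "AGE" in grp.columns and pd.notna(first["AGE"]):
            age = float(first["AGE"])
        cov = Covariates(
            weight_kg=float(first["WT"]),
            clcr_ml_min=float(first["CLCR"]),
            sex="F" if int(first["SEX"]) == 0 else "M",
            age_years=age,
        )
        doses = grp[grp["EVID"] == 1]
        if doses.empty:
            raise InvalidParameterError(f"patient {pid}: no dose events")
        events = []
        interval = None
        for idx, row in doses.iterrows():
            try:
                amt = float(row["AMT"])
                rate = float(row["RATE"])
                interval = float(row["II"]) if pd.notna(row["II"]) else interval
                events.append(DoseEvent(float(row["TIME"]), amt, amt / rate))
            except (TypeError, ValueError) as exc:
                raise InvalidParameterError(f"malformed dose row {idx}: {exc}")
        if interval is None:
            raise InvalidParameterError(f"patient {pid}: no dosing interval (II) recorded")
        regimen = DosingRegimen(tuple(events), interval)
        obs_rows = grp[grp["EVID"] == 0]
        times, conc, blq = [], [], []
        for idx, row in obs_rows.iterrows():
            b = bool(int(row["BLQ"])) if pd.notna(row["BLQ"]) else False
            dv = row["DV"]
            if not b and pd.isna(dv):
                raise InvalidParameterError(f"malformed observation row {idx}: DV missing")
            times.append(float(row["TIME"]))
            conc.append(0.0 if b else float(dv))
            blq.append(b)
        obs = ObservationSet(
            times_h=np.array(times),
            conc_mg_l=np.array(conc),
            below_lloq=np.array(blq, dtype=bool),
            covariates=cov,
            regimen=regimen,
        )
        records.append(PatientRecord(id=int(pid), covariates=cov, regimen=regimen, observations=obs))
    return records


def cohort_truth(cohort: Sequence[VirtualPatient]) -> dict:
    """JSON-serializable sidecar with each patient's generating truth."""
    out = {}
    for p in cohort:
        m = p.true_exposure
        out[str(p.id)] = {
            "params": dict(zip(("v1_std", "ks", "ki", "kcp", "kpc"), p.true_params.as_array().tolist())),
            "exposure": {
                "auc24_ss": m.auc24_ss,
                "cmin_ss": m.cmin_ss,
                "cmax_ss": m.cmax_ss,
                "t_half_terminal": m.t_half_terminal,
                "cl": m.cl,
            },
        }
    return out
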