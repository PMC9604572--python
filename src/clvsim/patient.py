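"""Synthetic surgical-patient hemodynamics and the closed-loop case runner.

The patient stand-in has three parts:

* **PK/PD** — one-compartment infusion pharmacokinetics for norepinephrine
  (distribution volume ``vd``, first-order elimination ``k_elim``; plasma
  half-life a few minutes) with a first-order effect-site compartment
  (``ke0``), driving a sigmoid Emax (Hill) pressor effect on SAP.
* **Baseline process** — an Ornstein–Uhlenbeck mean-reverting fluctuation of
  the unsupported (anesthetized) SAP around ``sap_baseline``, plus scheduled
  hypotensive disturbance events (step or ramp) emulating fluid shifts and
  vascular compression during abdominal surgery.
* **Measurement** — additive Gaussian noise on the monitored SAP, a linear
  SAP→MAP surrogate, and random signal-dropout (invalid) flags.

Three clocks are used: a 1-s internal integration step, the controller cycle
(``dt_control``, default 10 s) and the 20-s recording grid the monitor
reports on.  No claim is made that this synthetic model reproduces any
clinical cohort beyond qualitative behavior.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .controller import ControllerState, controller_step
from .core_io import CaseTimeSeries, ControllerConfig

__all__ = [
    "DT_SIM",
    "PatientParams",
    "DisturbanceEvent",
    "SimResult",
    "pk_step",
    "pd_effect",
    "baseline_step",
    "disturbance_offset",
    "simulate_case",
    "run_case",
    "make_cohort",
    "COHORT_RANGES",
]

#: Internal integration step of the simulator (s).
DT_SIM = 1.0


class PatientParams(BaseModel):
    """Synthetic patient parameters (pharmacology-plausible defaults, not clinical data)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    sap_baseline: float = Field(112.0, gt=0.0, description="unsupported anesthetized SAP, mmHg")
    emax: float = Field(65.0, gt=0.0, description="maximal pressor effect on SAP, mmHg")
    ec50: float = Field(10.0, gt=0.0, description="effect-site conc. at half effect, ng/mL")
    gamma: float = Field(1.5, ge=1.0, description="Hill slope")
    vd: float = Field(10.0, gt=0.0, description="distribution volume, L")
    k_elim: float = Field(math.log(2) / 2.5, gt=0.0, description="elimination, 1/min (t1/2 2.5 min)")
    ke0: float = Field(2.0, gt=0.0, description="effect-site equilibration, 1/min")
    sigma_noise: float = Field(2.0, ge=0.0, description="SAP measurement noise SD, mmHg")
    ou_tau: float = Field(300.0, gt=0.0, description="baseline fluctuation time constant, s")
    ou_sigma: float = Field(5.0, ge=0.0, description="baseline fluctuation stationary SD, mmHg")
    map_slope: float = Field(0.65, gt=0.0, description="MAP ≈ slope·SAP + intercept")
    map_intercept: float = Field(10.0, description="mmHg")
    p_dropout: float = Field(0.02, ge=0.0, lt=1.0, description="P(invalid signal) per sample")


class DisturbanceEvent(BaseModel):
    """A scheduled hypotensive (or hypertensive) insult on the baseline SAP."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    t_on: float = Field(ge=0.0, description="onset, s")
    duration: float = Field(gt=0.0, description="s")
    magnitude: float = Field(description="mmHg; negative = hypotensive")
    shape: Literal["step", "ramp"] = "step"


def pk_step(
    cp: float, ce: float, rate: float, dt: float, p: PatientParams
) -> tuple[float, float]:
    """One Euler step of plasma (cp) and effect-site (ce) concentration, ng/mL.

    ``rate`` is in µg/min; with ``vd`` in L the steady state under constant
    infusion is ``cp* = rate / (vd · k_elim)`` (µg/L ≡ ng/mL).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    # µg/min → ng/s into vd mL: rate·1000/(vd·1000)/60 = rate/(vd·60) ng/mL/s
    cp_new = cp + dt * (rate / (p.vd * 60.0) - (p.k_elim / 60.0) * cp)
    ce_new = ce + dt * (p.ke0 / 60.0) * (cp - ce)
    return max(cp_new, 0.0), max(ce_new, 0.0)


def pd_effect(ce: float, p: PatientParams) -> float:
    """Sigmoid Emax pressor effect on SAP (mmHg) at effect-site concentration ce."""
    if ce <= 0:
        return 0.0
    cg = ce**p.gamma
    return p.emax * (cg / (p.ec50**p.gamma + cg))


def baseline_step(b: float, dt: float, p: PatientParams, noise_draw: float = 0.0) -> float:
    """Exact-discretization Ornstein–Uhlenbeck update of the baseline SAP.

    Deterministic part decays toward ``sap_baseline`` with factor
    ``exp(−dt/ou_tau)``; the noise increment has the exact transition variance
    ``ou_sigma²·(1 − exp(−2·dt/ou_tau))`` so the stationary SD is ``ou_sigma``
    for any step size.  ``noise_draw`` is a standard-normal deviate.
    """
    a = math.exp(-dt / p.ou_tau)
    return p.sap_baseline + (b - p.sap_baseline) * a + p.ou_sigma * math.sqrt(
        1.0 - a * a
    ) * noise_draw


def disturbance_offset(t: float, events: Sequence[DisturbanceEvent]) -> float:
    """Summed baseline offset (mmHg) of all events active at time t.

    A ``step`` applies its full magnitude throughout [t_on, t_on+duration); a
    ``ramp`` interpolates linearly from 0 at onset to the full magnitude at
    the event end.  Overlapping events add.
    """
    total = 0.0
    for ev in events:
        x = t - ev.t_on
        if 0.0 <= x < ev.duration:
            if ev.shape == "step":
                total += ev.magnitude
            else:
                total += ev.magnitude * x / ev.duration
    return total


@dataclass
class SimResult:
    """A simulated case plus the controller-side command record."""

    series: CaseTimeSeries
    final_state: ControllerState
    command_t: np.ndarray
    command_rate: np.ndarray
    true_sap: np.ndarray = field(repr=False, default=None)  # on recording grid

    @property
    def rate_changes_per_min(self) -> float:
        """Commanded-rate modifications per minute, counted at the controller cycle."""
        duration_min = self.series.duration_s / 60.0
        return self.final_state.n_rate_changes / duration_min


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def run_case(
    p: PatientParams,
    events: Sequence[DisturbanceEvent],
    cfg: ControllerConfig,
    duration: float,
    seed=0,
    case_id: str = "case",
    dt_record: float = 20.0,
    open_loop: bool = False,
) -> SimResult:
    """Closed-loop simulation of one case; returns series + command record.

    The plant integrates on a 1-s step; the controller runs every
    ``cfg.dt_control`` on the noisy measured SAP; the output series is emitted
    on the ``dt_record`` grid (t = 0 … duration inclusive).  Fully
    reproducible for a fixed seed.  ``open_loop=True`` keeps the pump at zero
    throughout (reference run for efficacy comparisons).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_ctrl = int(round(cfg.dt_control / DT_SIM))
    n_rec = int(round(dt_record / DT_SIM))
    if abs(n_ctrl * DT_SIM - cfg.dt_control) > 1e-9 or n_ctrl < 1:
        raise ValueError("dt_control must be a positive multiple of the 1-s internal step")
    if abs(n_rec * DT_SIM - dt_record) > 1e-9 or n_rec < 1:
        raise ValueError("dt_record must be a positive multiple of the 1-s internal step")

    rng = _as_rng(seed)
    n_steps = int(round(duration / DT_SIM))
    b = p.sap_baseline
    cp = ce = 0.0
    rate = 0.0
    state = ControllerState()
    rec: list[tuple] = []
    cmd_t: list[float] = []
    cmd_rate: list[float] = []

    for i in range(n_steps + 1):
        t = i * DT_SIM
        true_sap = b + disturbance_offset(t, events) + pd_effect(ce, p)
        is_ctrl = i % n_ctrl == 0
        is_rec = i % n_rec == 0
        if is_ctrl or is_rec:
            meas = max(true_sap + p.sigma_noise * rng.standard_normal(), 1.0)
            valid = rng.random() >= p.p_dropout
        if is_ctrl and not open_loop:
            state, rate = controller_step(state, cfg, meas, valid, t=t)
            cmd_t.append(t)
            cmd_rate.append(rate)
        if is_rec:
            # linear MAP surrogate, capped so MAP < SAP holds even in deep hypotension
            map_mmhg = min(p.map_slope * meas + p.map_intercept, 0.95 * meas)
            rec.append((t, meas, map_mmhg, rate, rate > 0, valid, true_sap))
        if i < n_steps:
            cp, ce = pk_step(cp, ce, rate, DT_SIM, p)
            b = baseline_step(b, DT_SIM, p, rng.standard_normal())

    arr = np.array(rec, dtype=float)
    series = CaseTimeSeries(
        t=arr[:, 0],
        sap=arr[:, 1],
        map=arr[:, 2],
        rate=arr[:, 3],
        pump_active=arr[:, 4].astype(bool),
        valid=arr[:, 5].astype(bool),
        case_id=case_id,
        dt_record=dt_record,
    )
    return SimResult(
        series=series,
        final_state=state,
        command_t=np.array(cmd_t),
        command_rate=np.array(cmd_rate),
        true_sap=arr[:, 6],
    )


def simulate_case(
    p: PatientParams,
    events: Sequence[DisturbanceEvent],
    cfg: ControllerConfig,
    duration: float,
    seed=0,
    case_id: str = "case",
) -> CaseTimeSeries:
    """Convenience wrapper around :func:`run_case` returning only the series."""
    return run_case(p, events, cfg, duration, seed=seed, case_id=case_id).series


#: Inter-patient sampling ranges used by :func:`make_cohort`.
#: Preoperative SAP is centered at 130 mmHg (the cohort it emulates had a
#: median preoperative SAP of 130); the anesthetized unsupported baseline is
#: that value scaled by a depression factor.
COHORT_RANGES = {
    "preop_sap": ("normal", 130.0, 6.0, 110.0, 160.0),  # mean, sd, clip lo/hi
    "anesthesia_factor": ("uniform", 0.85, 0.93),
    "emax": ("normal", 65.0, 8.0, 50.0, 85.0),
    "ec50": ("lognormal", math.log(10.0), 0.25),
    "gamma": ("uniform", 1.2, 1.8),
    "vd": ("lognormal", math.log(10.0), 0.2),
    "half_life_min": ("uniform", 2.0, 3.0),
    "ke0": ("uniform", 1.5, 2.5),
    "sigma_noise": ("uniform", 1.5, 3.0),
    "ou_tau": ("uniform", 200.0, 400.0),
    "ou_sigma": ("uniform", 3.0, 7.0),
    "map_slope": ("uniform", 0.60, 0.70),
    "map_intercept": ("uniform", 5.0, 15.0),
    "p_dropout": ("uniform", 0.005, 0.03),
    "disturbance_magnitude": ("uniform", -25.0, -8.0),
    "disturbance_duration": ("uniform", 600.0, 1500.0),
}


def make_cohort(
    n: int,
    seed=0,
    duration: float = 14400.0,
    disturbance_rate_per_h: float = 2.0,
) -> list[tuple[PatientParams, list[DisturbanceEvent]]]:
    """Draw ``n`` synthetic patients with Poisson-scheduled hypotensive insults.

    Parameter ranges are listed in :data:`COHORT_RANGES`.  Disturbances are
    mostly ramps (gradual fluid shifts) with occasional steps (abrupt
    compression); their onset times follow a homogeneous Poisson process with
    the given hourly intensity over the case duration.  Reproducible per seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    cohort = []
    for _ in range(n):
        r = COHORT_RANGES
        preop = float(np.clip(rng.normal(r["preop_sap"][1], r["preop_sap"][2]),
                              r["preop_sap"][3], r["preop_sap"][4]))
        factor = rng.uniform(*r["anesthesia_factor"][1:])
        params = PatientParams(
            sap_baseline=preop * factor,
            emax=float(np.clip(rng.normal(r["emax"][1], r["emax"][2]),
                               r["emax"][3], r["emax"][4])),
            ec50=float(rng.lognormal(*r["ec50"][1:])),
            gamma=rng.uniform(*r["gamma"][1:]),
            vd=float(rng.lognormal(*r["vd"][1:])),
            k_elim=math.log(2) / rng.uniform(*r["half_life_min"][1:]),
            ke0=rng.uniform(*r["ke0"][1:]),
            sigma_noise=rng.uniform(*r["sigma_noise"][1:]),
            ou_tau=rng.uniform(*r["ou_tau"][1:]),
            ou_sigma=rng.uniform(*r["ou_sigma"][1:]),
            map_slope=rng.uniform(*r["map_slope"][1:]),
            map_intercept=rng.uniform(*r["map_intercept"][1:]),
            p_dropout=rng.uniform(*r["p_dropout"][1:]),
        )
        n_ev = rng.poisson(disturbance_rate_per_h * duration / 3600.0)
        events = []
        for _ in range(n_ev):
            events.append(
                DisturbanceEvent(
                    t_on=float(rng.uniform(0.0, duration)),
                    duration=float(rng.uniform(*r["disturbance_duration"][1:])),
                    magnitude=float(rng.uniform(*r["disturbance_magnitude"][1:])),
                    shape="ramp" if rng.random() < 0.7 else "step",
                )
            )
        events.sort(key=lambda ev: ev.t_on)
        cohort.append((params, events))
    return cohort
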