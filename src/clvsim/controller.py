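"""Discrete-time PID + rules-based norepinephrine controller.

The control law is an incremental (velocity-form) PID on the SAP error
``e = target − sap``::

    Δu_k = kp·(e_k − e_{k−1}) + ki·e_k·dt + kd·(e_k − 2·e_{k−1} + e_{k−2})/dt

The commanded infusion rate is ``u_k = u_{k−1} + Δu_k`` after the rules-based
safety layer: per-cycle rate-of-change limits, an absolute rate ceiling, a
zero floor, and a hold-last-rate policy on invalid signal.  Because the
integrator lives implicitly in the commanded rate, clamping the rate is
itself anti-windup — no separate integrator reset is needed.

Above-band pressures drive the same law with negative error; the rate decays
toward zero rather than entering a distinct "off" state, so pump-inactive
time emerges as ``rate == 0``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core_io import ControllerConfig

__all__ = ["ControllerState", "pid_increment", "apply_rules", "controller_step", "replay"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControllerState:
    """Error history and last command of the velocity-form PID.

    A fresh state (all zeros) corresponds to a controller started with the
    pump idle and no accumulated error.
    """

    e_prev: float = 0.0
    e_prev2: float = 0.0
    rate_prev: float = 0.0
    t_last_valid: float | None = None
    n_rate_changes: int = 0


def pid_increment(state: ControllerState, cfg: ControllerConfig, sap: float) -> float:
    """Raw velocity-form PID increment Δu (µg/min); limits applied downstream."""
    if sap <= 0:
        raise ValueError(f"sap must be positive, got {sap}")
    e = cfg.band.target - sap
    du = cfg.kp * (e - state.e_prev) + cfg.ki * e * cfg.dt_control
    if cfg.kd:
        du += cfg.kd * (e - 2.0 * state.e_prev + state.e_prev2) / cfg.dt_control
    return du


def apply_rules(
    delta: float, state: ControllerState, cfg: ControllerConfig, valid: bool
) -> float:
    """Safety layer: hold-on-invalid, per-cycle step limits, [0, rate_max] clamp."""
    if not valid and cfg.hold_on_invalid:
        return state.rate_prev
    delta = min(max(delta, -cfg.step_down_max), cfg.step_up_max)
    return min(max(state.rate_prev + delta, 0.0), cfg.rate_max)


def controller_step(
    state: ControllerState,
    cfg: ControllerConfig,
    sap: float,
    valid: bool = True,
    t: float = 0.0,
) -> tuple[ControllerState, float]:
    """One controller cycle: PID increment, safety rules, state bookkeeping.

    Error history advances only on valid samples (it is frozen, together with
    the rate, while the signal is flagged invalid and ``hold_on_invalid`` is
    set).  ``n_rate_changes`` counts cycles whose applied rate moved by more
    than ``rate_epsilon`` — the commanded-rate "modification" counter.
    """
    if valid or not cfg.hold_on_invalid:
        du = pid_increment(state, cfg, sap)
    else:
        du = 0.0
    rate = apply_rules(du, state, cfg, valid)
    changed = abs(rate - state.rate_prev) > cfg.rate_epsilon
    if logger.isEnabledFor(logging.DEBUG):
        logger.debug(
            "t=%.0fs sap=%.1f valid=%d du=%+.3f rate %.3f -> %.3f",
            t, sap, valid, du, state.rate_prev, rate,
        )
    if valid:
        e = cfg.band.target - sap
        new = ControllerState(
            e_prev=e,
            e_prev2=state.e_prev,
            rate_prev=rate,
            t_last_valid=t,
            n_rate_changes=state.n_rate_changes + int(changed),
        )
    else:
        new = replace(
            state, rate_prev=rate, n_rate_changes=state.n_rate_changes + int(changed)
        )
    return new, rate


def replay(
    sap: Sequence[float],
    valid: Sequence[bool] | None,
    cfg: ControllerConfig,
    state: ControllerState | None = None,
) -> tuple[np.ndarray, ControllerState]:
    """Batch-run the controller over a recorded SAP trace.

    One controller cycle per sample; the caller chooses ``cfg.dt_control`` to
    match the trace's sampling period.  Returns the commanded rate per sample
    and the final state.
    """
    sap = np.asarray(sap, dtype=float)
    if valid is None:
        valid = np.ones(len(sap), dtype=bool)
    state = state or ControllerState()
    rates = np.empty(len(sap))
    for i, (s, v) in enumerate(zip(sap, np.asarray(valid, dtype=bool))):
        state, rates[i] = controller_step(state, cfg, float(s), bool(v), t=i * cfg.dt_control)
    return rates, state
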