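"""Synaptic plasticity rules and dopamine-factor kinetics.

The dopaminergic plasticity rule (DPR) changes each KC->MBON weight by

    dW[i, j] = (1 / tau) * delta[j] * (k[i] + W[i, j] - w_rest)

where ``delta`` is the per-MBON *dopaminergic factor* (signed net dopamine
effect of the DANs converging on that MBON) and ``w_rest`` the resting
weight.  Depending on the sign of ``delta`` and whether the KC is active
this produces four effects: depression (delta < 0, KC active), potentiation
(delta > 0, KC active), recovery towards rest (delta < 0, KC silent) and
saturation away from rest (delta > 0, KC silent).  Weights are clamped at 0.

The reward-prediction-error (RPE) alternative replaces the update term with
``k[i] * (delta[j] - m[j] + w_rest)``: learning is gated by KC activity and
driven by the mismatch between dopamine and the MBON's own output.

:class:`DopamineKinetics` resolves ``delta`` in time as the difference of a
potentiation and a depression component with distinct gain pathways
(abstracting the two dopamine-receptor channels).  With ``tau_short = 1``
and ``tau_long = inf`` the kinetics collapse to the static factor
``delta = d @ W_d2km`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

from .circuit import CircuitParameters

__all__ = [
    "dopaminergic_factor_static",
    "dpr_update",
    "rpe_update",
    "get_rule",
    "validate_time_constants",
    "DopamineKinetics",
    "kinetics_step",
]


def dopaminergic_factor_static(d: np.ndarray, W_d2km: np.ndarray) -> np.ndarray:
    """Instantaneous per-MBON dopaminergic factor ``delta = d @ W_d2km``."""
    return np.asarray(d, dtype=float) @ np.asarray(W_d2km, dtype=float)


def dpr_update(
    W_k2m: np.ndarray,
    k: np.ndarray,
    delta: np.ndarray,
    m: np.ndarray = None,
    params: CircuitParameters = None,
    *,
    tau: float = None,
    w_rest: float = None,
) -> np.ndarray:
    """Dopaminergic plasticity rule; ``m`` is accepted but unused.

    ``delta`` broadcasts over columns (MBONs), ``k`` over rows (KCs); the
    result is clamped element-wise at zero.
    """
    tau = params.tau if tau is None else tau
    w_rest = params.w_rest if w_rest is None else w_rest
    W = np.asarray(W_k2m, dtype=float)
    dW = np.asarray(delta)[None, :] * (np.asarray(k)[:, None] + W - w_rest) / tau
    return np.maximum(W + dW, 0.0)


def rpe_update(
    W_k2m: np.ndarray,
    k: np.ndarray,
    delta: np.ndarray,
    m: np.ndarray,
    params: CircuitParameters = None,
    *,
    tau: float = None,
    w_rest: float = None,
) -> np.ndarray:
    """Reward-prediction-error rule, a drop-in replacement for the DPR.

    The same non-negativity clamp is applied so the two rules differ only in
    their update term.
    """
    tau = params.tau if tau is None else tau
    w_rest = params.w_rest if w_rest is None else w_rest
    W = np.asarray(W_k2m, dtype=float)
    dW = np.asarray(k)[:, None] * (np.asarray(delta) - np.asarray(m) + w_rest)[None, :] / tau
    return np.maximum(W + dW, 0.0)


def get_rule(name: str):
    """Look a plasticity rule up by its config name (``"dpr"`` | ``"rpe"``)."""
    try:
        return {"dpr": dpr_update, "rpe": rpe_update}[name]
    except KeyError:
        raise ValueError(f"unknown plasticity rule {name!r}; expected 'dpr' or 'rpe'") from None


def validate_time_constants(tau_short: float, tau_long: float) -> None:
    """Enforce ``0 < 1/tau_short + 1/tau_long <= 2``.

    ``tau_long = inf`` is the sentinel for a vanishing long-channel rate.
    The bound is exactly the stability condition of the discrete kinetics
    update.
    """
    rate = 1.0 / tau_short + (0.0 if math.isinf(tau_long) else 1.0 / tau_long)
    if not (0.0 < rate <= 2.0):
        raise ValueError(
            f"time constants violate 0 < 1/tau_short + 1/tau_long <= 2 "
            f"(got 1/{tau_short} + 1/{tau_long} = {rate:g})"
        )


def _split_by_sign(W: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Split into the non-negative part and the magnitude of the negative part."""
    W = np.asarray(W, dtype=float)
    return np.maximum(W, 0.0), np.maximum(-W, 0.0)


@dataclass
class DopamineKinetics:
    """Time-resolved depression/potentiation components of the dopamine factor.

    The dopaminergic-effect matrix is split by sign: the positive channel
    (potentiation/saturation effects) and the magnitude of the negative
    channel (depression/recovery).  The depression component ``D_dep`` is
    driven by the negative channel at the short-time-constant rate and by
    the positive channel at the long rate; ``D_pot`` is the mirror image.
    Both components retain ``(1 - 1/tau_short - 1/tau_long)`` of their value
    per step, so with ``tau_short = 1`` and ``tau_long = inf`` they carry no
    memory at all and ``delta = D_pot - D_dep`` reduces to the static
    factor, while with long constants they decay smoothly and stay
    non-negative under non-negative input.
    """

    W_d2km: np.ndarray
    tau_short: float = 1.0
    tau_long: float = math.inf
    D_dep: np.ndarray = field(default=None)
    D_pot: np.ndarray = field(default=None)
    W_pos: np.ndarray = field(init=False)
    W_neg: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        validate_time_constants(self.tau_short, self.tau_long)
        self.W_d2km = np.asarray(self.W_d2km, dtype=float)
        self.W_pos, self.W_neg = _split_by_sign(self.W_d2km)
        n_mbon = self.W_d2km.shape[1]
        if self.D_dep is None:
            self.D_dep = np.zeros(n_mbon)
        if self.D_pot is None:
            self.D_pot = np.zeros(n_mbon)

    @property
    def delta(self) -> np.ndarray:
        return self.D_pot - self.D_dep


def kinetics_step(kin: DopamineKinetics, d: np.ndarray) -> DopamineKinetics:
    """Advance the dopamine components by one Euler step; returns a new object."""
    d = np.asarray(d, dtype=float)
    r_short = 1.0 / kin.tau_short
    r_long = 0.0 if math.isinf(kin.tau_long) else 1.0 / kin.tau_long
    retain = 1.0 - r_short - r_long
    gain_dep = r_long * (d @ kin.W_pos) + r_short * (d @ kin.W_neg)
    gain_pot = r_short * (d @ kin.W_pos) + r_long * (d @ kin.W_neg)
    return DopamineKinetics(
        W_d2km=kin.W_d2km,
        tau_short=kin.tau_short,
        tau_long=kin.tau_long,
        D_dep=retain * kin.D_dep + gain_dep,
        D_pot=retain * kin.D_pot + gain_pot,
    )
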