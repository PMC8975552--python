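"""Second-messenger account of forward and backward (relief) conditioning.

At high temporal resolution the signed dopaminergic factor is resolved into
two receptor channels with different kinetics.  In a depressing terminal the
depression component D_dep responds to dopamine quickly (high peak, fast
decay) while the potentiation component D_pot responds at half the rate
(lower peak, slower decay); a potentiating terminal is the mirror image.
After a dopamine pulse D_dep therefore drops below D_pot, so the net factor
delta = D_pot - D_dep changes sign from negative (during/just after the US)
to positive (about a second later).  Pairing the odour with the US
(forward, delta_s >= 0) hence depresses the synapse, while delivering the US
shortly *before* the odour (backward, delta_s < 0) potentiates it -- the
relief-learning sign flip.

The presynaptic ER-Ca2+ and cAMP proxies are linear read-outs of the two
components, the KC activity and the synaptic weight:

    ER-Ca2+ = -D_pot (k - w_rest) - (D_pot - D_dep) W
    cAMP    =  D_dep (k - w_rest)

and the mean weight change over a pairing, mean(-ER-Ca2+ - cAMP), equals the
time-average of the dopaminergic plasticity rule's update term
delta * (k + W - w_rest).

The simulated motif is a single susceptible-memory synapse: one KC, one
depressing DAN terminal and one MBON that inhibits the DAN.  With
``tau_short = 1`` and ``tau_long = inf`` both channels become memoryless and
the per-sample factor collapses to the static ``delta = d * w`` of the
low-resolution model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .plasticity import validate_time_constants

__all__ = [
    "PairingProtocol",
    "SecondMessengerTrace",
    "er_camp_levels",
    "run_pairing",
    "mean_weight_change",
    "sweep_delta_s",
]


@dataclass(frozen=True)
class PairingProtocol:
    """Timing of one CS/US pairing at high sampling rate.

    ``delta_s`` is US start minus CS start in seconds (negative = backward).
    ``tau_short`` (samples) sets the fast receptor channel; the slow channel
    runs at half its rate.  ``tau_long`` enters the stability constraint and
    the collapse limit (``tau_short=1, tau_long=inf`` recovers the static
    dopaminergic factor).
    """

    delta_s: float = 0.0
    cs_duration: float = 0.5
    us_duration: float = 0.6
    sampling_hz: float = 100.0
    tau_short: float = 60.0
    tau_long: float = 1e4
    total_duration: Optional[float] = None  # auto: stimuli + kinetics tail
    w_rest: float = 1.0
    # susceptible-motif weights: US->DAN drive, MBON-|DAN inhibition, DAN bias,
    # and the (depressing, hence negative) dopaminergic effect on the synapse
    w_us2d: float = 2.0
    w_m2d: float = -0.3
    b_d: float = -0.5
    w_d2km: float = -1.0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0 or self.cs_duration <= 0 or self.us_duration <= 0:
            raise ValueError("sampling rate and stimulus durations must be positive")
        validate_time_constants(self.tau_short, self.tau_long)

    @property
    def learning_tau(self) -> float:
        """Weight-update time constant: one second's worth of samples."""
        return self.sampling_hz


@dataclass
class SecondMessengerTrace:
    """Sampled traces of one pairing (all arrays share the time axis)."""

    time: np.ndarray  # seconds, CS onset at 0
    k: np.ndarray  # KC activity
    d: np.ndarray  # DAN activity
    D_dep: np.ndarray
    D_pot: np.ndarray
    er_ca: np.ndarray
    camp: np.ndarray
    W: np.ndarray  # synaptic weight
    protocol: PairingProtocol

    def __len__(self) -> int:
        return self.time.size


def er_camp_levels(D_dep, D_pot, k, W, w_rest: float = 1.0):
    """ER-Ca2+ and cAMP proxies (proportionality constants set to 1)."""
    D_dep = np.asarray(D_dep, dtype=float)
    D_pot = np.asarray(D_pot, dtype=float)
    k = np.asarray(k, dtype=float)
    W = np.asarray(W, dtype=float)
    er_ca = -D_pot * (k - w_rest) - (D_pot - D_dep) * W
    camp = D_dep * (k - w_rest)
    return er_ca, camp


def run_pairing(protocol: PairingProtocol) -> SecondMessengerTrace:
    """Simulate one CS/US pairing in the susceptible-memory motif.

    Per sample: the CS pulse drives the KC (k = 1), the US pulse drives the
    DAN through ``w_us2d`` against the MBON's inhibition, the two receptor
    channels low-pass filter the dopamine signal (fast rate ``1/tau_short``,
    slow rate half of it), and the dopaminergic plasticity rule moves the
    weight.  The trace is padded after the stimuli until the kinetics have
    decayed below 1e-6 of their peak.
    """
    p = protocol
    dt = 1.0 / p.sampling_hz
    cs_start = 0.0
    us_start = p.delta_s
    t0 = min(cs_start, us_start) - 2 * dt
    stim_end = max(cs_start + p.cs_duration, us_start + p.us_duration)

    alpha_fast = 1.0 / p.tau_short
    # slow receptor channel: half the fast rate ("full update" twice as long)
    alpha_slow = 1.0 / (2.0 * p.tau_short - 1.0)
    # the slow channel's contribution vanishes when the kinetics collapse
    # (tau_short = 1), leaving the static per-sample factor
    gain_slow = 1.0 - alpha_fast
    w_pos = max(p.w_d2km, 0.0)
    w_neg = max(-p.w_d2km, 0.0)

    if p.total_duration is not None:
        hard_end = t0 + p.total_duration
    else:
        # analytic bound on the slower channel's 1e-6 decay tail
        tail = -math.log(1e-6) / min(alpha_fast, alpha_slow) * dt
        hard_end = stim_end + tail

    time, k_tr, d_tr, dep_tr, pot_tr, w_tr = [], [], [], [], [], []
    fast_dep = slow_dep = fast_pot = slow_pot = 0.0
    W = p.w_rest
    peak = 0.0
    t = t0
    while t < hard_end:
        k = 1.0 if cs_start <= t < cs_start + p.cs_duration else 0.0
        u = 1.0 if us_start <= t < us_start + p.us_duration else 0.0
        m = max(0.0, k * W)  # susceptible MBON: KC drive through the synapse
        d = max(0.0, p.w_us2d * u + p.w_m2d * m + p.b_d)

        x_dep = d * w_neg  # depression-channel dopamine
        x_pot = d * w_pos  # potentiation-channel dopamine
        fast_dep += alpha_fast * (x_dep - fast_dep)
        slow_dep += alpha_slow * (x_pot - slow_dep)
        fast_pot += alpha_fast * (x_pot - fast_pot)
        slow_pot += alpha_slow * (x_dep - slow_pot)
        D_dep = fast_dep + gain_slow * slow_dep
        D_pot = fast_pot + gain_slow * slow_pot

        delta = D_pot - D_dep
        W = max(0.0, W + delta * (k + W - p.w_rest) / p.learning_tau)

        time.append(t)
        k_tr.append(k)
        d_tr.append(d)
        dep_tr.append(D_dep)
        pot_tr.append(D_pot)
        w_tr.append(W)
        peak = max(peak, D_dep, D_pot)
        if p.total_duration is None and t >= stim_end and peak > 0:
            if max(D_dep, D_pot) < 1e-6 * peak:
                break
        t += dt

    time = np.array(time)
    k_arr = np.array(k_tr)
    dep = np.array(dep_tr)
    pot = np.array(pot_tr)
    w_arr = np.array(w_tr)
    er_ca, camp = er_camp_levels(dep, pot, k_arr, w_arr, p.w_rest)
    return SecondMessengerTrace(
        time=time, k=k_arr, d=np.array(d_tr), D_dep=dep, D_pot=pot,
        er_ca=er_ca, camp=camp, W=w_arr, protocol=protocol,
    )


def mean_weight_change(trace: SecondMessengerTrace) -> float:
    """Mean synaptic change of a pairing from the messenger levels.

    Computes ``mean(-ER-Ca2+ - cAMP)`` over the trace; unnormalised (a
    sweep normalises across its own grid).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    return float(np.mean(-trace.er_ca - trace.camp))


def sweep_delta_s(
    ds_min: float = -5.0,
    ds_max: float = 5.0,
    ds_step: float = 0.5,
    normalise: bool = True,
    **protocol_kwargs,
) -> pd.DataFrame:
    """Mean weight change over a grid of CS/US onset offsets.

    Returns a table (delta_s, mean_change); with ``normalise=True`` the
    changes are scaled by the maximum absolute value over the grid, so the
    curve reports sign and relative size only.
    """
    grid = np.arange(ds_min, ds_max + 0.5 * ds_step, ds_step)
    changes = []
    for ds in grid:
        trace = run_pairing(PairingProtocol(delta_s=float(ds), **protocol_kwargs))
        changes.append(mean_weight_change(trace))
    changes = np.array(changes)
    if normalise:
        scale = np.abs(changes).max()
        if scale > 0:
            changes = changes / scale
    return pd.DataFrame({"delta_s": grid, "mean_change": changes})
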