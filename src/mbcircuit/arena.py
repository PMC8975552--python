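"""Agent-based simulation of freely moving flies in a two-odour arena.

Flies move on an unbounded plane carrying a full circuit instance as their
brain.  Two odour sources sit at -0.6 m and +0.6 m on the real axis; odour
intensity at a position is the univariate Gaussian density evaluated at the
Euclidean distance from the source (sigma = 0.3 m), and an odour is *smelt*
when its density exceeds the detection threshold theta_CS = 0.2, i.e. within
roughly 0.58 m of the source.  Reinforcement is delivered only inside the
smaller rho_US = 0.3 m radius and only during the training phase.

Each repeat of the experiment lasts 100 s at 1 Hz: 20 s pre-training, 30 s
training, 50 s post-training.  Positions are reset to the centre between the
10 repeats but brains (and therefore long-term memories) persist.  Behaviour
is summarised by the normalised cumulative odour exposure and the preference
index PI = (C_A - C_B) / (C_A + C_B).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .circuit import (
    CircuitParameters,
    CircuitState,
    ODOUR_A,
    ODOUR_AB,
    ODOUR_B,
    ODOUR_NONE,
    US_NONE,
    US_SHOCK,
    US_SUGAR,
    default_parameters,
)
from .plasticity import get_rule

__all__ = [
    "ArenaParameters",
    "FlyState",
    "BehaviourLog",
    "TRAINING_CONDITIONS",
    "odour_density",
    "odour_stimulus",
    "detection_radius",
    "reinforcement_at",
    "closeness_posterior",
    "attraction_force",
    "velocity_update",
    "run_arena_experiment",
    "cumulative_exposure",
    "preference_index",
    "filter_both_odour_visitors",
]

TRAINING_CONDITIONS = ("shock_a", "shock_b", "shock_ab", "sugar_a", "sugar_b", "sugar_ab")

# MBON roles for the behavioural readout (indices into the MBON vector)
_ATTRACTION = (0, 2, 4)  # s_at, r_at, m_at
_AVOIDANCE = (1, 3, 5)  # s_av, r_av, m_av


@dataclass
class ArenaParameters:
    """Geometry, timeline and population size of the arena experiment."""

    mu_A: complex = -0.6 + 0.0j
    mu_B: complex = 0.6 + 0.0j
    sigma_A: float = 0.3
    sigma_B: float = 0.3
    theta_CS: float = 0.2  # odour-detection threshold on density
    rho_US: float = 0.3  # reinforcement radius (m)
    step_speed: float = 0.05  # normalised step size (m/s)
    motion_noise_sigma: float = 0.1  # per-axis velocity noise
    n_flies: int = 100
    n_repeats: int = 10
    pre_steps: int = 20
    train_steps: int = 30
    post_steps: int = 50

    @property
    def total_steps(self) -> int:
        return self.pre_steps + self.train_steps + self.post_steps

    def phase_of(self, step: int) -> str:
        if step < self.pre_steps:
            return "pre"
        if step < self.pre_steps + self.train_steps:
            return "train"
        return "post"

    def validate(self) -> "ArenaParameters":
        if self.sigma_A <= 0 or self.sigma_B <= 0:
            raise ValueError("odour spreads must be positive")
        peak = norm.pdf(0.0, scale=min(self.sigma_A, self.sigma_B))
        if not (0 < self.theta_CS < peak):
            raise ValueError("theta_CS must lie within (0, peak density)")
        if self.rho_US >= detection_radius(self):
            raise ValueError("rho_US must be smaller than the detection radius")
        return self


@dataclass
class FlyState:
    """Position, velocity and brain of one simulated fly."""

    position: complex
    velocity: complex
    brain: CircuitState


@dataclass
class BehaviourLog:
    """Trajectories and stimuli for all flies, repeats and steps.

    ``positions`` has shape (n_repeats, n_flies, n_steps) of complex
    coordinates; ``detect_A``/``detect_B`` are boolean detection masks of
    the same shape, and ``us`` records delivered reinforcement.
    """

    arena: ArenaParameters
    positions: np.ndarray
    detect_A: np.ndarray
    detect_B: np.ndarray
    us: np.ndarray
    condition: str

    def phase_slice(self, phase: str) -> slice:
        a = self.arena
        return {
            "pre": slice(0, a.pre_steps),
            "train": slice(a.pre_steps, a.pre_steps + a.train_steps),
            "post": slice(a.pre_steps + a.train_steps, a.total_steps),
        }[phase]

    def to_frame(self) -> pd.DataFrame:
        reps, flies, steps = self.positions.shape
        r, f, s = np.meshgrid(np.arange(reps), np.arange(flies),
                              np.arange(steps), indexing="ij")
        return pd.DataFrame({
            "repeat": r.ravel(), "fly": f.ravel(), "step": s.ravel(),
            "x": self.positions.real.ravel(), "y": self.positions.imag.ravel(),
            "detect_A": self.detect_A.ravel(), "detect_B": self.detect_B.ravel(),
            "us": self.us.ravel(),
        })


def odour_density(position: complex, mu: complex, sigma: float) -> float:
    """Univariate Gaussian density evaluated at the distance from the source."""
    return float(norm.pdf(abs(position - mu), scale=sigma))


def detection_radius(arena: Optional[ArenaParameters] = None) -> float:
    """Distance at which the odour density falls to the detection threshold.

    Solves ``pdf(r; sigma) = theta_CS`` for r; about 0.58 m under defaults.
    """
    arena = arena or ArenaParameters()
    sigma, theta = arena.sigma_A, arena.theta_CS
    return brentq(lambda r: norm.pdf(r, scale=sigma) - theta, 0.0, 10.0 * sigma)


def odour_stimulus(position: complex, arena: ArenaParameters) -> np.ndarray:
    """Binary PN odour code at a position (detection, not intensity)."""
    in_A = odour_density(position, arena.mu_A, arena.sigma_A) > arena.theta_CS
    in_B = odour_density(position, arena.mu_B, arena.sigma_B) > arena.theta_CS
    if in_A and in_B:
        return ODOUR_AB
    if in_A:
        return ODOUR_A
    if in_B:
        return ODOUR_B
    return ODOUR_NONE


def reinforcement_at(
    position: complex,
    arena: ArenaParameters,
    phase: str,
    condition: str,
) -> np.ndarray:
    """US code at a position: delivered only in training, inside rho_US."""
    if phase != "train":
        return US_NONE
    if condition not in TRAINING_CONDITIONS:
        raise ValueError(f"unknown training condition {condition!r}")
    us_kind, targets = condition.split("_")
    us = US_SUGAR if us_kind == "sugar" else US_SHOCK
    near_A = abs(position - arena.mu_A) < arena.rho_US
    near_B = abs(position - arena.mu_B) < arena.rho_US
    hit = (("a" in targets) and near_A) or (("b" in targets) and near_B)
    return us if hit else US_NONE


def closeness_posterior(position: complex, arena: ArenaParameters) -> Tuple[float, float]:
    """Posterior probability of being closer to source A vs B (equal priors)."""
    n_A = odour_density(position, arena.mu_A, arena.sigma_A)
    n_B = odour_density(position, arena.mu_B, arena.sigma_B)
    total = n_A + n_B
    if total == 0.0:
        return 0.5, 0.5
    return n_A / total, 1.0 - n_A / total


def attraction_force(m: np.ndarray, position: complex, arena: ArenaParameters) -> complex:
    """Net drive toward/away from the odour sources given the MBON vector.

    For each odour the mean of the three attraction MBONs minus the mean of
    the three avoidance MBONs scales the unit vector toward that source; the
    two odours are combined weighted by the closeness posterior.  At exactly
    a source position the unit vector is undefined and that odour
    contributes no force.
    """
    m = np.asarray(m, dtype=float)
    att = m[list(_ATTRACTION)].mean()
    av = m[list(_AVOIDANCE)].mean()
    p_A, p_B = closeness_posterior(position, arena)
    force = 0.0 + 0.0j
    for prob, mu in ((p_A, arena.mu_A), (p_B, arena.mu_B)):
        displacement = mu - position
        dist = abs(displacement)
        if dist == 0.0:
            continue
        force += prob * (att - av) * displacement / dist
    return force


def velocity_update(
    fly: FlyState,
    force: complex,
    arena: ArenaParameters,
    rng: np.random.Generator,
) -> None:
    """Add force and Gaussian noise to the velocity, renormalise, and move.

    The updated velocity keeps its direction but its magnitude is replaced
    by ``step_speed``; a zero pre-normalisation velocity redraws the noise.
    """
    while True:
        ex, ey = rng.normal(0.0, arena.motion_noise_sigma, 2)
        v = fly.velocity + force + complex(ex, ey)
        if abs(v) > 0.0:
            break
    fly.velocity = arena.step_speed * v / abs(v)
    fly.position = fly.position + fly.velocity


def _wta_batch(drive: np.ndarray, fraction: float) -> np.ndarray:
    """Row-wise winner-take-all keeping the top fraction (stable ties)."""
    import math as _math
    n_keep = _math.ceil(fraction * drive.shape[1])
    order = np.argsort(-drive, axis=1, kind="stable")
    out = np.zeros_like(drive)
    rows = np.arange(drive.shape[0])[:, None]
    keep = order[:, :n_keep]
    out[rows, keep] = drive[rows, keep]
    return np.maximum(out, 0.0)


def brain_step_batch(
    cs: np.ndarray,
    us: np.ndarray,
    d: np.ndarray,
    m: np.ndarray,
    W: np.ndarray,
    params: CircuitParameters,
    rule: str,
    rng: np.random.Generator,
    repeats: int = 4,
):
    """One four-repeat circuit update for a whole fly population at once.

    ``cs``/``us`` are (n, 2) stimulus codes, ``d``/``m`` (n, n_dan/n_mbon)
    activities and ``W`` (n, n_kc, n_mbon) per-fly plastic weights.  The
    arithmetic is identical to :func:`mbcircuit.circuit.forward_step`
    applied fly by fly; only the noise draws are batched.
    """
    n = cs.shape[0]
    drive = cs @ params.W_p2k + rng.normal(0.0, params.eta_scale, (n, params.n_kc))
    k = _wta_batch(drive, params.wta_fraction)
    cap = params.activation_cap
    lam = 1.0 - 1.0 / params.tau
    for _ in range(repeats):
        drive_d = us @ params.W_u2d + m @ params.W_m2d + params.b_d
        drive_m = np.einsum("fk,fkj->fj", k, W) + m @ params.W_m2m + params.b_m
        if params.integration == "literal":
            d = np.clip(drive_d / params.tau, 0.0, cap)
            m = np.clip(drive_m / params.tau, 0.0, cap)
        else:
            d = np.clip(lam * d + drive_d / params.tau, 0.0, cap)
            m = np.clip(lam * m + drive_m / params.tau, 0.0, cap)
        delta = d @ params.W_d2km
        if rule == "dpr":
            dW = delta[:, None, :] * (k[:, :, None] + W - params.w_rest) / params.tau
        elif rule == "rpe":
            dW = k[:, :, None] * (delta - m + params.w_rest)[:, None, :] / params.tau
        else:
            raise ValueError(f"unknown plasticity rule {rule!r}")
        W = np.maximum(W + dW, 0.0)
    return k, d, m, W


def run_arena_experiment(
    arena: Optional[ArenaParameters] = None,
    params: Optional[CircuitParameters] = None,
    rule: str = "dpr",
    seed: int = 0,
    condition: str = "shock_a",
) -> BehaviourLog:
    """Simulate the full population through all repeats of one condition.

    Per step: every fly senses the odour at its position, runs one
    four-repeat brain update with the reinforcement appropriate to the
    phase, converts its MBON vector to a force, then moves.  Between
    repeats positions and velocities are reset to the centre but brains
    persist, so long-term memory accumulates across repeats.  The whole
    population is advanced with batched array arithmetic.
    """
    arena = (arena or ArenaParameters()).validate()
    params = (params or default_parameters()).validate()
    if condition not in TRAINING_CONDITIONS:
        raise ValueError(f"unknown training condition {condition!r}")
    get_rule(rule)  # validate the name early
    rng = np.random.default_rng(seed)

    F = arena.n_flies
    us_kind, targets = condition.split("_")
    us_code = US_SUGAR if us_kind == "sugar" else US_SHOCK

    d = np.zeros((F, params.n_dan))
    m = np.zeros((F, params.n_mbon))
    W = np.full((F, params.n_kc, params.n_mbon), params.w_rest)

    shape = (arena.n_repeats, F, arena.total_steps)
    positions = np.zeros(shape, dtype=complex)
    detect_A = np.zeros(shape, dtype=bool)
    detect_B = np.zeros(shape, dtype=bool)
    us_log = np.zeros(shape, dtype=bool)

    for rep in range(arena.n_repeats):
        pos = np.zeros(F, dtype=complex)
        vel = np.zeros(F, dtype=complex)
        for step in range(arena.total_steps):
            phase = arena.phase_of(step)
            dist_A = np.abs(pos - arena.mu_A)
            dist_B = np.abs(pos - arena.mu_B)
            dens_A = norm.pdf(dist_A, scale=arena.sigma_A)
            dens_B = norm.pdf(dist_B, scale=arena.sigma_B)
            in_A = dens_A > arena.theta_CS
            in_B = dens_B > arena.theta_CS
            cs = np.column_stack([in_A, in_B]).astype(float)
            us = np.zeros((F, 2))
            if phase == "train":
                hit = np.zeros(F, dtype=bool)
                if "a" in targets:
                    hit |= dist_A < arena.rho_US
                if "b" in targets:
                    hit |= dist_B < arena.rho_US
                us[hit] = us_code

            _, d, m, W = brain_step_batch(cs, us, d, m, W, params, rule, rng)

            att = m[:, list(_ATTRACTION)].mean(axis=1)
            av = m[:, list(_AVOIDANCE)].mean(axis=1)
            total = dens_A + dens_B
            p_A = np.where(total > 0, dens_A / np.where(total > 0, total, 1.0), 0.5)
            force = np.zeros(F, dtype=complex)
            for prob, mu, dist in ((p_A, arena.mu_A, dist_A),
                                   (1.0 - p_A, arena.mu_B, dist_B)):
                ok = dist > 0
                force[ok] += (prob[ok] * (att[ok] - av[ok])
                              * (mu - pos[ok]) / dist[ok])

            positions[rep, :, step] = pos
            detect_A[rep, :, step] = in_A
            detect_B[rep, :, step] = in_B
            us_log[rep, :, step] = us.any(axis=1)

            noise = rng.normal(0.0, arena.motion_noise_sigma, (F, 2))
            v = vel + force + noise[:, 0] + 1j * noise[:, 1]
            stuck = np.abs(v) == 0.0
            while stuck.any():
                extra = rng.normal(0.0, arena.motion_noise_sigma, (int(stuck.sum()), 2))
                v[stuck] = vel[stuck] + force[stuck] + extra[:, 0] + 1j * extra[:, 1]
                stuck = np.abs(v) == 0.0
            vel = arena.step_speed * v / np.abs(v)
            pos = pos + vel

    return BehaviourLog(arena=arena, positions=positions, detect_A=detect_A,
                        detect_B=detect_B, us=us_log, condition=condition)


def cumulative_exposure(
    log: BehaviourLog,
    odour: str,
    phase: str,
    up_to_repeat: Optional[int] = None,
) -> np.ndarray:
    """Normalised cumulative exposure per fly (summed over repeats 1..R).

    Each repeat contributes the fraction of that phase's steps during which
    the odour was detected; values therefore range from 0 to R.
    """
    mask = {"A": log.detect_A, "B": log.detect_B}[odour]
    sl = log.phase_slice(phase)
    n_steps = sl.stop - sl.start
    R = log.arena.n_repeats if up_to_repeat is None else up_to_repeat
    return mask[:R, :, sl].sum(axis=(0, 2)) / n_steps


def preference_index(C_A, C_B):
    """PI = (C_A - C_B) / (C_A + C_B); NaN where the fly saw neither odour."""
    C_A = np.asarray(C_A, dtype=float)
    C_B = np.asarray(C_B, dtype=float)
    total = C_A + C_B
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(total > 0, (C_A - C_B) / np.where(total > 0, total, 1.0), np.nan)
    return pi if pi.shape else float(pi)


def filter_both_odour_visitors(log: BehaviourLog) -> np.ndarray:
    """Indices of flies that detected each odour for at least one step."""
    saw_A = log.detect_A.any(axis=(0, 2))
    saw_B = log.detect_B.any(axis=(0, 2))
    return np.nonzero(saw_A & saw_B)[0]


def exposure_summary(log: BehaviourLog) -> pd.DataFrame:
    """Per-repeat, per-phase exposure and PI over the both-odour visitors."""
    keep = filter_both_odour_visitors(log)
    rows = []
    for rep in range(1, log.arena.n_repeats + 1):
        for phase in ("pre", "train", "post"):
            c_A = cumulative_exposure(log, "A", phase, rep)[keep]
            c_B = cumulative_exposure(log, "B", phase, rep)[keep]
            pi = preference_index(c_A, c_B)
            rows.append({
                "repeat": rep, "phase": phase,
                "C_A_median": float(np.median(c_A)),
                "C_B_median": float(np.median(c_B)),
                "PI_median": float(np.nanmedian(pi)) if np.isfinite(pi).any() else np.nan,
                "n_flies": int(keep.size),
            })
    return pd.DataFrame(rows)
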