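"""Core of the twelve-neuron mushroom-body memory circuit.

The model is a discrete-time rate network of the *Drosophila* mushroom body:
two projection neurons (PNs) carry odour identity to ten Kenyon cells (KCs),
whose sparse code drives six mushroom-body output neurons (MBONs) through a
plastic weight matrix.  Six dopaminergic neurons (DANs) receive reinforcement
and MBON feedback and gate the plasticity of the KC->MBON synapses.  For each
valence (attraction ``at`` / avoidance ``av``) the six output-side neurons
fall into stereotyped roles:

==========  =====================================================
``d_*``     discharging DAN -- erases the susceptible memory
``c_*``     charging DAN -- builds short- and long-term memories
``f_*``     forgetting DAN -- depresses the opposing long-term memory
``s_*``     susceptible MBON -- rapidly erasable memory
``r_*``     restrained MBON -- opponent-inhibited short-term memory
``m_*``     long-term-memory MBON -- self-sustaining memory
==========  =====================================================

All fixed connectivity lives in :class:`CircuitParameters`; the only plastic
quantity is the KC->MBON matrix carried by :class:`CircuitState`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Tuple

import numpy as np
import yaml

__all__ = [
    "DAN_LABELS",
    "MBON_LABELS",
    "ODOUR_A",
    "ODOUR_B",
    "ODOUR_AB",
    "ODOUR_NONE",
    "US_SUGAR",
    "US_SHOCK",
    "US_NONE",
    "StimulusFrame",
    "CircuitParameters",
    "CircuitState",
    "default_parameters",
    "bounded_relu",
    "wta_fraction_filter",
    "kc_response",
    "neuron_step",
    "forward_step",
]

DAN_LABELS: Tuple[str, ...] = ("d_at", "d_av", "c_at", "c_av", "f_at", "f_av")
MBON_LABELS: Tuple[str, ...] = ("s_at", "s_av", "r_at", "r_av", "m_at", "m_av")

# PN odour codes and US codes (first US channel = reward, second = punishment).
ODOUR_A = np.array([1.0, 0.0])
ODOUR_B = np.array([0.0, 1.0])
ODOUR_AB = np.array([1.0, 1.0])
ODOUR_NONE = np.array([0.0, 0.0])
US_SUGAR = np.array([1.0, 0.0])
US_SHOCK = np.array([0.0, 1.0])
US_NONE = np.array([0.0, 0.0])


@dataclass(frozen=True)
class StimulusFrame:
    """One time-step of input: a binary odour code and a binary US code."""

    cs: np.ndarray
    us: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "cs", np.asarray(self.cs, dtype=float))
        object.__setattr__(self, "us", np.asarray(self.us, dtype=float))
        if not np.isin(self.cs, (0.0, 1.0)).all() or not np.isin(self.us, (0.0, 1.0)).all():
            raise ValueError("stimulus entries must be 0 or 1")


BLANK_FRAME = StimulusFrame(cs=ODOUR_NONE, us=US_NONE)


@dataclass
class CircuitParameters:
    """Fixed weights, biases and constants of the circuit.

    The defaults (see :func:`default_parameters`) are hand-set, not fitted:
    the sign pattern encodes the known microcircuits (susceptible, restrained,
    reciprocal short-term, long-term, reciprocal long-term and memory
    assimilation) and magnitudes set their relative strength.
    """

    n_pn: int = 2
    n_kc: int = 10
    n_dan: int = 6
    n_mbon: int = 6
    W_p2k: np.ndarray = field(default=None)  # PN -> KC efficacies
    W_u2d: np.ndarray = field(default=None)  # US -> DAN efficacies
    W_m2d: np.ndarray = field(default=None)  # MBON -> DAN feedback (signed)
    W_m2m: np.ndarray = field(default=None)  # MBON -> MBON inhibition (signed)
    W_d2km: np.ndarray = field(default=None)  # DAN -> per-MBON dopaminergic effect
    b_d: np.ndarray = field(default=None)  # DAN bias
    b_m: np.ndarray = field(default=None)  # MBON bias
    tau: float = 3.0  # integration time constant (time-steps)
    w_rest: float = 1.0  # resting KC->MBON weight
    eta_scale: float = 1e-3  # KC input-noise standard deviation
    wta_fraction: float = 0.5  # fraction of KCs kept active
    activation_cap: float = 2.0  # upper bound of the activation function
    integration: str = "literal"  # "literal" | "leaky"
    dan_labels: Tuple[str, ...] = DAN_LABELS
    mbon_labels: Tuple[str, ...] = MBON_LABELS

    def __post_init__(self) -> None:
        for name in ("W_p2k", "W_u2d", "W_m2d", "W_m2m", "W_d2km", "b_d", "b_m"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, np.asarray(value, dtype=float))

    def validate(self) -> "CircuitParameters":
        """Check shape consistency and parameter ranges; return self."""
        shapes = {
            "W_p2k": (self.n_pn, self.n_kc),
            "W_u2d": (2, self.n_dan),
            "W_m2d": (self.n_mbon, self.n_dan),
            "W_m2m": (self.n_mbon, self.n_mbon),
            "W_d2km": (self.n_dan, self.n_mbon),
            "b_d": (self.n_dan,),
            "b_m": (self.n_mbon,),
        }
        for name, shape in shapes.items():
            value = getattr(self, name)
            if value is None or value.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
        if not (self.w_rest > 0 and self.tau >= 1):
            raise ValueError("require w_rest > 0 and tau >= 1")
        if not (0 < self.wta_fraction <= 1):
            raise ValueError("require 0 < wta_fraction <= 1")
        if not self.activation_cap > 0:
            raise ValueError("require activation_cap > 0")
        if self.integration not in ("literal", "leaky"):
            raise ValueError("integration must be 'literal' or 'leaky'")
        return self

    def dan_index(self, label: str) -> int:
        return self.dan_labels.index(label)

    def mbon_index(self, label: str) -> int:
        return self.mbon_labels.index(label)

    # -- plain-text config round-trip -------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if isinstance(value, np.ndarray):
                value = value.tolist()
            elif isinstance(value, tuple):
                value = list(value)
            out[f.name] = value
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "CircuitParameters":
        kwargs = dict(data)
        for key in ("dan_labels", "mbon_labels"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CircuitParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CircuitState:
    """Activities and plastic weights at one time-step."""

    p: np.ndarray  # PN activity (odour code)
    k: np.ndarray  # KC activity (sparse, non-negative)
    d: np.ndarray  # DAN activity in [0, cap]
    m: np.ndarray  # MBON activity in [0, cap]
    W_k2m: np.ndarray  # plastic KC -> MBON weights (non-negative)
    t: int = 0

    @classmethod
    def initial(cls, params: CircuitParameters) -> "CircuitState":
        """Resting state: all activities zero, every weight at ``w_rest``."""
        return cls(
            p=np.zeros(params.n_pn),
            k=np.zeros(params.n_kc),
            d=np.zeros(params.n_dan),
            m=np.zeros(params.n_mbon),
            W_k2m=np.full((params.n_kc, params.n_mbon), params.w_rest),
            t=0,
        )

    def memory_strength(self, params: CircuitParameters) -> np.ndarray:
        """Stored memory per synapse: deviation of the weight from rest."""
        return np.abs(self.W_k2m - params.w_rest)

    def copy(self) -> "CircuitState":
        return CircuitState(
            p=self.p.copy(), k=self.k.copy(), d=self.d.copy(),
            m=self.m.copy(), W_k2m=self.W_k2m.copy(), t=self.t,
        )


def default_parameters() -> CircuitParameters:
    """The hand-set parameter matrices used throughout all experiments.

    Odour coding: KCs 0-3 respond only to odour A, KCs 7-9 only to odour B
    and KCs 4-6 to either, giving the two odours an overlapping sparse code.
    Reward excites the attraction-side discharging and charging DANs, shock
    the avoidance-side ones.  The MBON->DAN / MBON->MBON matrices and the
    dopaminergic-effect matrix encode the microcircuit topology (e.g. the
    susceptible MBON inhibits its discharging DAN; the charging DAN
    potentiates its long-term-memory MBON while depressing the opposing
    restrained MBON; the forgetting DAN depresses the opposing long-term
    memory and its own side's restrained MBON).
    """
    W_p2k = np.array([
        [0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8],
    ])
    # columns follow DAN_LABELS: d_at, d_av, c_at, c_av, f_at, f_av
    W_u2d = np.array([
        [2.0, 0.0, 2.0, 0.0, 0.0, 0.0],  # sugar
        [0.0, 2.0, 0.0, 2.0, 0.0, 0.0],  # shock
    ])
    # rows follow MBON_LABELS: s_at, s_av, r_at, r_av, m_at, m_av
    W_m2d = np.array([
        [0.0, -0.3, 0.0, 0.0, 0.0, 0.0],  # s_at -| d_av
        [-0.3, 0.0, 0.0, 0.0, 0.0, 0.0],  # s_av -| d_at
        [0.0, 0.0, 0.5, 0.0, 0.0, 0.0],   # r_at -> c_at
        [0.0, 0.0, 0.0, 0.5, 0.0, 0.0],   # r_av -> c_av
        [0.0, 0.0, 0.3, 0.0, 0.5, 0.0],   # m_at -> c_at, f_at
        [0.0, 0.0, 0.0, 0.3, 0.0, 0.5],   # m_av -> c_av, f_av
    ])
    W_m2m = np.array([
        [0.0, 0.0, 0.0, -1.0, 0.0, 0.0],  # s_at -| r_av
        [0.0, 0.0, -1.0, 0.0, 0.0, 0.0],  # s_av -| r_at
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    ])
    b_d = np.array([-0.5, -0.5, -0.15, -0.15, -0.15, -0.15])
    b_m = np.array([-2.0, -2.0, -0.5, -0.5, -0.5, -0.5])
    # rows: DANs; columns: target MBONs (negative = depression of KC input)
    W_d2km = np.array([
        [0.0, -1.0, 0.0, 0.0, 0.0, 0.0],    # d_at depresses s_av
        [-1.0, 0.0, 0.0, 0.0, 0.0, 0.0],    # d_av depresses s_at
        [0.0, 0.0, 0.0, -1.0, 0.3, 0.0],    # c_at: -| r_av, -> m_at
        [0.0, 0.0, -1.0, 0.0, 0.0, 0.3],    # c_av: -| r_at, -> m_av
        [0.0, 0.0, -0.3, 0.0, 0.0, -1.0],   # f_at: -| r_at, -| m_av
        [0.0, 0.0, 0.0, -0.3, -1.0, 0.0],   # f_av: -| r_av, -| m_at
    ])
    return CircuitParameters(
        W_p2k=W_p2k, W_u2d=W_u2d, W_m2d=W_m2d, W_m2m=W_m2m,
        W_d2km=W_d2km, b_d=b_d, b_m=b_m,
    ).validate()


def bounded_relu(x, cap: float = 2.0):
    """Rectified-linear activation clipped to ``[0, cap]`` (element-wise)."""
    return np.clip(x, 0.0, cap)


def wta_fraction_filter(x: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Keep the ``ceil(fraction * n)`` largest entries, zero the rest.

    Retained entries keep their input value (the filter does not binarise).
    Ties are broken in favour of the lowest index via a stable sort.
    """
    x = np.asarray(x, dtype=float)
    n_keep = math.ceil(fraction * x.size)
    # stable sort of -x: equal values keep ascending index order
    order = np.argsort(-x, kind="stable")
    out = np.zeros_like(x)
    keep = order[:n_keep]
    out[keep] = x[keep]
    return out


def kc_response(
    stim: StimulusFrame,
    params: CircuitParameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sparse KC code for one time-step.

    The PN odour code drives the KCs through ``W_p2k``; independent Gaussian
    noise (scale ``eta_scale``) breaks ties, and the winner-take-all filter
    keeps the strongest half active.  Negative (noise-only) survivors are
    clamped to zero so the KC vector is always non-negative.
    """
    drive = stim.cs @ params.W_p2k + rng.normal(0.0, params.eta_scale, params.n_kc)
    return np.maximum(wta_fraction_filter(drive, params.wta_fraction), 0.0)


def neuron_step(
    state: CircuitState,
    stim: StimulusFrame,
    params: CircuitParameters,
) -> Tuple[np.ndarray, np.ndarray]:
    """One synchronous update of DAN and MBON activities.

    Both populations are driven from the *previous* step's MBON vector.
    With ``integration="literal"`` the update is memoryless,
    ``x_new = relu(drive / tau)``; with ``"leaky"`` it is the standard leaky
    integrator ``x_new = relu((1 - 1/tau) x + drive / tau)``.
    """
    if state.W_k2m.shape != (params.n_kc, params.n_mbon):
        raise ValueError("state/parameter shape mismatch")
    drive_d = stim.us @ params.W_u2d + state.m @ params.W_m2d + params.b_d
    drive_m = state.k @ state.W_k2m + state.m @ params.W_m2m + params.b_m
    if params.integration == "literal":
        d_new = drive_d / params.tau
        m_new = drive_m / params.tau
    else:
        lam = 1.0 - 1.0 / params.tau
        d_new = lam * state.d + drive_d / params.tau
        m_new = lam * state.m + drive_m / params.tau
    cap = params.activation_cap
    return bounded_relu(d_new, cap), bounded_relu(m_new, cap)


#: Plasticity-rule contract: (W_k2m, k, delta, m, params) -> new W_k2m.
PlasticityRule = Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray, CircuitParameters], np.ndarray]

#: Activity clamp for interventions: {("dan"|"mbon", index): value}.
Clamp = Mapping[Tuple[str, int], float]


def forward_step(
    state: CircuitState,
    stim: StimulusFrame,
    params: CircuitParameters,
    rule: PlasticityRule,
    rng: np.random.Generator,
    repeats: int = 4,
    clamp: Optional[Clamp] = None,
) -> CircuitState:
    """Advance the circuit by one time-step.

    The KC code (and its noise) is drawn once per time-step; the neuron
    update, dopaminergic factor and weight update are then iterated
    ``repeats`` times (default 4) to smooth out the order dependence between
    the value and the weight update.  ``clamp`` optionally pins named
    neurons' activity after each neuron update and before plasticity,
    emulating silencing/activation interventions.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    k = kc_response(stim, params, rng)
    work = state.copy()
    work.p = stim.cs.copy()
    work.k = k
    for _ in range(repeats):
        d_new, m_new = neuron_step(work, stim, params)
        if clamp:
            for (kind, idx), value in clamp.items():
                if kind == "dan":
                    d_new[idx] = value
                elif kind == "mbon":
                    m_new[idx] = value
                else:
                    raise ValueError(f"unknown clamp kind {kind!r}")
        work.d, work.m = d_new, m_new
        delta = work.d @ params.W_d2km
        work.W_k2m = rule(work.W_k2m, k, delta, work.m, params)
    work.t = state.t + 1
    return work
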