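"""Trial schedulers and experiment runner for the conditioning paradigms.

An experiment is one initialisation time-step followed by 24 three-step
trials (73 time-steps in total).  Within each trial the first step carries
no odour and the odour is presented on steps 2 and 3; shock may be placed
on step 1 (unpaired with odour) or step 3 (paired).  Trials alternate
odours, odour A on even trials (0-indexed) and odour B on odd trials.

The default aversive paradigm is: 2 pre-training trials, 10 acquisition
trials (shock paired with odour B), 2 resting trials and 10 forgetting
trials whose condition is ``extinction`` (no shock), ``unpaired`` (shock on
step 1 of A-trials) or ``reversal`` (shock paired with odour A).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit import (
    BLANK_FRAME,
    CircuitParameters,
    CircuitState,
    ODOUR_A,
    ODOUR_B,
    ODOUR_NONE,
    StimulusFrame,
    US_NONE,
    US_SHOCK,
    US_SUGAR,
    default_parameters,
    forward_step,
)
from .plasticity import get_rule

__all__ = [
    "TrialSpec",
    "ExperimentLog",
    "build_aversive_paradigm",
    "build_unpaired_conditioning_paradigm",
    "run_experiment",
    "extract_trial_summaries",
]

STEPS_PER_TRIAL = 3
FORGETTING_CONDITIONS = ("extinction", "unpaired", "reversal")

_ODOUR_CODES = {"A": ODOUR_A, "B": ODOUR_B, "none": ODOUR_NONE}
_US_CODES = {"shock": US_SHOCK, "sugar": US_SUGAR, None: US_NONE}


@dataclass(frozen=True)
class TrialSpec:
    """One three-step trial: which odour, where the US falls, and its phase."""

    odour: str  # "A" | "B" | "none"
    us_step: Optional[int] = None  # 1 (unpaired) or 3 (paired); None = no US
    phase: str = "pre_training"
    us: str = "shock"

    def __post_init__(self) -> None:
        if self.odour not in _ODOUR_CODES:
            raise ValueError(f"unknown odour {self.odour!r}")
        if self.us_step not in (None, 1, 3):
            raise ValueError("us_step must be None, 1 (unpaired) or 3 (paired)")

    def frames(self) -> List[StimulusFrame]:
        """The trial's three stimulus frames (odour on steps 2 and 3 only)."""
        cs = _ODOUR_CODES[self.odour]
        us = _US_CODES[self.us] if self.us_step is not None else US_NONE
        out = []
        for step in (1, 2, 3):
            out.append(StimulusFrame(
                cs=cs if step >= 2 else ODOUR_NONE,
                us=us if step == self.us_step else US_NONE,
            ))
        return out


def _alternating_odours(n: int, start_trial: int) -> List[str]:
    return ["A" if (start_trial + i) % 2 == 0 else "B" for i in range(n)]


def build_aversive_paradigm(forgetting: str = "extinction") -> List[TrialSpec]:
    """The 24-trial aversive conditioning schedule.

    Trials alternate A (even) / B (odd).  Acquisition pairs shock with
    odour B (US on in-trial step 3); the forgetting phase re-pairs shock
    with odour A (``reversal``), delivers it on the odour-free step 1 of
    A-trials (``unpaired``), or omits it (``extinction``).
    """
    if forgetting not in FORGETTING_CONDITIONS:
        raise ValueError(f"unknown forgetting condition {forgetting!r}")
    trials: List[TrialSpec] = []
    for i, odour in enumerate(_alternating_odours(2, 0)):
        trials.append(TrialSpec(odour=odour, phase="pre_training"))
    for i, odour in enumerate(_alternating_odours(10, 2)):
        us_step = 3 if odour == "B" else None
        trials.append(TrialSpec(odour=odour, us_step=us_step, phase="acquisition"))
    for odour in _alternating_odours(2, 12):
        trials.append(TrialSpec(odour=odour, phase="resting"))
    for odour in _alternating_odours(10, 14):
        if forgetting == "extinction":
            us_step = None
        elif forgetting == "unpaired":
            us_step = 1 if odour == "A" else None
        else:  # reversal
            us_step = 3 if odour == "A" else None
        trials.append(TrialSpec(odour=odour, us_step=us_step, phase=forgetting))
    return trials


def build_unpaired_conditioning_paradigm() -> List[TrialSpec]:
    """Classic unpaired conditioning: shock and odour A strictly alternate.

    Acquisition presents odour A alone on even trials and shock alone (odour
    B omitted) on odd trials; the test phase then alternates A and B with no
    US.
    """
    trials: List[TrialSpec] = []
    for odour in _alternating_odours(2, 0):
        trials.append(TrialSpec(odour=odour, phase="pre_training"))
    for i in range(10):
        if i % 2 == 0:
            trials.append(TrialSpec(odour="A", phase="acquisition"))
        else:
            trials.append(TrialSpec(odour="none", us_step=3, phase="acquisition"))
    for odour in _alternating_odours(2, 12):
        trials.append(TrialSpec(odour=odour, phase="resting"))
    for odour in _alternating_odours(10, 14):
        trials.append(TrialSpec(odour=odour, phase="test"))
    return trials


@dataclass
class ExperimentLog:
    """Per-time-step record of stimuli, activities and weights.

    Arrays are indexed by time-step (0 = initialisation).  ``meta`` holds
    one row per time-step with trial index, in-trial step (0 for the
    initialisation step), phase and odour.
    """

    meta: pd.DataFrame
    d: np.ndarray  # (T, n_dan)
    m: np.ndarray  # (T, n_mbon)
    W_k2m: np.ndarray  # (T, n_kc, n_mbon)
    params: CircuitParameters

    def __len__(self) -> int:
        return len(self.meta)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format activity table: (time_step, neuron, value)."""
        rows = []
        labels = list(self.params.dan_labels) + list(self.params.mbon_labels)
        values = np.concatenate([self.d, self.m], axis=1)
        for t in range(len(self)):
            for j, label in enumerate(labels):
                rows.append((t, label, values[t, j]))
        return pd.DataFrame(rows, columns=["time_step", "neuron", "value"])

    def weights_tidy(self) -> pd.DataFrame:
        """Long-format weight table: (time_step, kc, mbon, weight)."""
        T, n_kc, n_mbon = self.W_k2m.shape
        t_idx, kc_idx, mb_idx = np.meshgrid(
            np.arange(T), np.arange(n_kc), np.arange(n_mbon), indexing="ij")
        return pd.DataFrame({
            "time_step": t_idx.ravel(),
            "kc": kc_idx.ravel(),
            "mbon": [self.params.mbon_labels[j] for j in mb_idx.ravel()],
            "weight": self.W_k2m.ravel(),
        })


def _resolve_clamp(
    intervention: Optional[Mapping],
    phase: str,
    params: CircuitParameters,
) -> Optional[dict]:
    """Translate an intervention spec into a per-step activity clamp.

    ``intervention`` maps neuron label -> (mode, phases); mode is
    ``"silence"`` (clamp to 0) or ``"activate"`` (clamp to the activation
    cap); phases is a collection of phase names or ``"all"``.
    """
    if not intervention:
        return None
    clamp = {}
    for label, (mode, phases) in intervention.items():
        if phases != "all" and phase not in phases:
            continue
        value = 0.0 if mode == "silence" else params.activation_cap
        if mode not in ("silence", "activate"):
            raise ValueError(f"unknown intervention mode {mode!r}")
        if label in params.dan_labels:
            clamp[("dan", params.dan_index(label))] = value
        elif label in params.mbon_labels:
            clamp[("mbon", params.mbon_index(label))] = value
        else:
            raise ValueError(f"unknown neuron label {label!r}")
    return clamp or None


def run_experiment(
    schedule: Sequence[TrialSpec],
    params: Optional[CircuitParameters] = None,
    rule: str = "dpr",
    seed: int = 0,
    intervention: Optional[Mapping] = None,
    repeats: int = 4,
) -> ExperimentLog:
    """Run a trial schedule from the resting state and log every time-step.

    The state is initialised with every KC->MBON weight at rest and a blank
    (no odour, no US) initialisation step at t = 0; each scheduled time-step
    then applies the four-repeat forward update with the selected plasticity
    rule (``"dpr"`` or ``"rpe"``).
    """
    params = (params or default_parameters()).validate()
    rule_fn = get_rule(rule)
    rng = np.random.default_rng(seed)

    frames: List[Tuple[int, int, str, str, StimulusFrame]] = []
    frames.append((-1, 0, "init", "none", BLANK_FRAME))
    for trial_idx, trial in enumerate(schedule):
        for step, frame in enumerate(trial.frames(), start=1):
            frames.append((trial_idx, step, trial.phase, trial.odour, frame))

    state = CircuitState.initial(params)
    meta_rows = []
    d_hist, m_hist, W_hist = [], [], []
    for trial_idx, step, phase, odour, frame in frames:
        if phase != "init":
            clamp = _resolve_clamp(intervention, phase, params)
            state = forward_step(state, frame, params, rule_fn, rng,
                                 repeats=repeats, clamp=clamp)
        meta_rows.append({
            "time_step": len(meta_rows),
            "trial": trial_idx,
            "in_trial_step": step,
            "phase": phase,
            "odour": odour,
            "us_on": bool(frame.us.any()),
        })
        d_hist.append(state.d.copy())
        m_hist.append(state.m.copy())
        W_hist.append(state.W_k2m.copy())

    return ExperimentLog(
        meta=pd.DataFrame(meta_rows),
        d=np.array(d_hist),
        m=np.array(m_hist),
        W_k2m=np.array(W_hist),
        params=params,
    )


def extract_trial_summaries(log: ExperimentLog) -> pd.DataFrame:
    """Per-trial off-/on-shock responses for every neuron.

    The off-shock value is the response at in-trial step 2 (odour only) and
    the on-shock value the response at step 3 (where a paired US falls, if
    delivered).  Returns a long table with columns
    (trial, phase, odour, neuron, step_kind, value).
    """
    meta = log.meta
    labels = list(log.params.dan_labels) + list(log.params.mbon_labels)
    values = np.concatenate([log.d, log.m], axis=1)
    rows = []
    for trial in sorted(meta.loc[meta.trial >= 0, "trial"].unique()):
        sub = meta[meta.trial == trial]
        if set(sub.in_trial_step) != {1, 2, 3}:
            raise ValueError("log is not from a 3-step-per-trial schedule")
        idx_off = sub.loc[sub.in_trial_step == 2, "time_step"].iloc[0]
        idx_on = sub.loc[sub.in_trial_step == 3, "time_step"].iloc[0]
        phase = sub.phase.iloc[0]
        odour = sub.odour.iloc[0]
        for kind, idx in (("off", idx_off), ("on", idx_on)):
            for j, label in enumerate(labels):
                rows.append((trial, phase, odour, label, kind, values[idx, j]))
    return pd.DataFrame(
        rows, columns=["trial", "phase", "odour", "neuron", "step_kind", "value"])
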