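"""Imaging-trace summaries, synthetic fixtures, and the intervention screen.

Calcium-imaging trials are 100 samples at 5 Hz (20 s): odour on between
samples 25 and 50, shock (when delivered) at sample 45.  The off-shock value
of a trial averages samples 28-42 (15 per fly, odour before any shock) and
the on-shock value samples 44-48 (5 per fly, the window in which shock
delivery could have occurred).

The intervention screen runs the conditioning protocol once as a control and
once with a neuron silenced or activated during given phases, reads out an
odour preference from the test-phase MBON responses, and correlates the
model's preference changes with experimentally reported ones across the
screen's rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .circuit import CircuitParameters, default_parameters
from .paradigms import (
    TrialSpec,
    build_aversive_paradigm,
    run_experiment,
)

__all__ = [
    "TRACE_LENGTH",
    "TRACE_HZ",
    "OFF_WINDOW",
    "ON_WINDOW",
    "TraceSummary",
    "summarise_imaging_traces",
    "generate_synthetic_traces",
    "InterventionSpec",
    "model_preference_from_mbons",
    "conditioning_preference",
    "run_intervention_screen",
]

TRACE_LENGTH = 100  # samples per trial
TRACE_HZ = 5.0
OFF_WINDOW = (28, 42)  # inclusive sample range before shock onset
ON_WINDOW = (44, 48)  # inclusive sample range around shock delivery

# behavioural read-out roles of the MBON vector
_ATTRACTION = (0, 2, 4)  # s_at, r_at, m_at
_AVOIDANCE = (1, 3, 5)  # s_av, r_av, m_av


@dataclass(frozen=True)
class TraceSummary:
    """Off-/on-shock mean and spread over the pooled per-fly windows."""

    off_mean: float
    off_sd: float
    on_mean: float
    on_sd: float
    n_flies: int


def _window_matrix(traces: pd.DataFrame, window: Tuple[int, int]) -> np.ndarray:
    lo, hi = window
    sub = traces[(traces["sample"] >= lo) & (traces["sample"] <= hi)]
    mat = sub.pivot_table(index="fly", columns="sample", values="value")
    return mat.to_numpy()


def summarise_imaging_traces(traces: pd.DataFrame) -> TraceSummary:
    """Off-/on-shock summary of one neuron/trial's traces across flies.

    ``traces`` is long-format with columns (fly, sample, value) — and
    optionally neuron/trial identifiers, which must be unique.  Every fly
    must contribute the full 100-sample trace.
    """
    for col in ("fly", "sample", "value"):
        if col not in traces.columns:
            raise ValueError(f"missing column {col!r}")
    for col in ("neuron", "trial"):
        if col in traces.columns and traces[col].nunique() > 1:
            raise ValueError(f"traces mix more than one {col}")
    counts = traces.groupby("fly")["sample"].nunique()
    if not (counts == TRACE_LENGTH).all():
        raise ValueError(f"each fly must have exactly {TRACE_LENGTH} samples")
    off = _window_matrix(traces, OFF_WINDOW)
    on = _window_matrix(traces, ON_WINDOW)
    return TraceSummary(
        off_mean=float(off.mean()), off_sd=float(off.std()),
        on_mean=float(on.mean()), on_sd=float(on.std()),
        n_flies=int(counts.size),
    )


def generate_synthetic_traces(
    spec: Mapping[str, Tuple[float, float]],
    noise_sd: float = 0.0,
    n_flies: int = 8,
    seed: int = 0,
    baseline: float = 0.0,
) -> pd.DataFrame:
    """Synthetic imaging-style traces with known window means.

    ``spec`` maps neuron name -> (off_mean, on_mean).  Each fly's trace is a
    flat baseline with the odour window raised to the off-shock level and
    the on-shock window to the on-shock level, plus Gaussian noise.  Purely
    a test fixture emulating the documented trace geometry.
    """
    rng = np.random.default_rng(seed)
    frames = []
    samples = np.arange(TRACE_LENGTH)
    odour_on = (samples >= 25) & (samples < 50)
    on_shock = (samples >= ON_WINDOW[0]) & (samples <= ON_WINDOW[1])
    for neuron, (off_mean, on_mean) in spec.items():
        for fly in range(n_flies):
            values = np.full(TRACE_LENGTH, baseline)
            values[odour_on] = off_mean
            values[on_shock] = on_mean
            values = values + rng.normal(0.0, noise_sd, TRACE_LENGTH)
            frames.append(pd.DataFrame({
                "neuron": neuron, "fly": fly, "trial": 0,
                "sample": samples, "value": values,
            }))
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class InterventionSpec:
    """One screen experiment: which neurons to clamp, when, and the outcome."""

    neurons: Tuple[str, ...]
    mode: str  # "silence" | "activate"
    phases: Tuple[str, ...] = ("acquisition",)
    us: str = "shock"
    delta_f_exp: Optional[float] = None

    def to_intervention(self) -> dict:
        phases = "all" if "all" in self.phases else tuple(self.phases)
        return {name: (self.mode, phases) for name in self.neurons}


def model_preference_from_mbons(m_A: np.ndarray, m_B: np.ndarray) -> float:
    """Preference index from test-phase MBON responses to each odour.

    Each odour's score is the mean attraction-MBON response minus the mean
    avoidance-MBON response; PI = (score_A - score_B) / (|score_A| +
    |score_B|), 0 when both scores vanish.
    """
    m_A = np.asarray(m_A, dtype=float)
    m_B = np.asarray(m_B, dtype=float)
    s_A = m_A[list(_ATTRACTION)].mean() - m_A[list(_AVOIDANCE)].mean()
    s_B = m_B[list(_ATTRACTION)].mean() - m_B[list(_AVOIDANCE)].mean()
    denom = abs(s_A) + abs(s_B)
    if denom == 0.0:
        return 0.0
    return (s_A - s_B) / denom


def _test_phase_responses(log, phase: str) -> Tuple[np.ndarray, np.ndarray]:
    """Mean MBON vector at the odour-only (off) steps of a phase, per odour."""
    meta = log.meta
    out = {}
    for odour in ("A", "B"):
        idx = meta[(meta.phase == phase) & (meta.odour == odour)
                   & (meta.in_trial_step == 2)]["time_step"].to_numpy()
        if idx.size == 0:
            raise ValueError(f"no odour-{odour} steps in phase {phase!r}")
        out[odour] = log.m[idx].mean(axis=0)
    return out["A"], out["B"]


def conditioning_preference(
    params: Optional[CircuitParameters] = None,
    us: str = "shock",
    rule: str = "dpr",
    seed: int = 0,
    intervention: Optional[dict] = None,
) -> float:
    """Preference index after conditioning odour B with the given US.

    Runs the standard schedule (acquisition pairs the US with odour B, the
    forgetting phase is extinction, used as the test) and reads the PI from
    the extinction-phase responses.  Positive PI means preferring odour A.
    """
    schedule = [
        TrialSpec(odour=t.odour, us_step=t.us_step, phase=t.phase, us=us)
        for t in build_aversive_paradigm("extinction")
    ]
    log = run_experiment(schedule, params=params, rule=rule, seed=seed,
                         intervention=intervention)
    m_A, m_B = _test_phase_responses(log, "extinction")
    return model_preference_from_mbons(m_A, m_B)


def run_intervention_screen(
    screen: pd.DataFrame,
    params: Optional[CircuitParameters] = None,
    rule: str = "dpr",
    seed: int = 0,
) -> Tuple[pd.DataFrame, Optional[float]]:
    """Run every screen row and correlate model vs experimental effects.

    ``screen`` columns: neurons (``"+"``-separated labels), mode, phases
    (``"+"``-separated), us, delta_f_exp.  For each row the model's
    preference change is PI(intervention) - PI(control).  Returns the
    per-row results and the Pearson r across rows (None when undefined,
    e.g. zero variance or fewer than two usable rows).
    """
    params = params or default_parameters()
    results = []
    controls: dict = {}
    for _, row in screen.iterrows():
        if pd.isna(row.get("delta_f_exp")):
            warnings.warn(f"row {row.to_dict()} has no experimental value; skipped")
            continue
        spec = InterventionSpec(
            neurons=tuple(str(row["neurons"]).split("+")),
            mode=str(row["mode"]),
            phases=tuple(str(row["phases"]).split("+")),
            us=str(row["us"]),
            delta_f_exp=float(row["delta_f_exp"]),
        )
        if spec.us not in controls:
            controls[spec.us] = conditioning_preference(
                params, us=spec.us, rule=rule, seed=seed)
        pi_int = conditioning_preference(
            params, us=spec.us, rule=rule, seed=seed,
            intervention=spec.to_intervention())
        results.append({
            "neurons": "+".join(spec.neurons), "mode": spec.mode,
            "phases": "+".join(spec.phases), "us": spec.us,
            "delta_f_model": pi_int - controls[spec.us],
            "delta_f_exp": spec.delta_f_exp,
        })
    table = pd.DataFrame(results)
    r: Optional[float] = None
    if len(table) >= 2:
        x = table["delta_f_model"].to_numpy()
        y = table["delta_f_exp"].to_numpy()
        if np.std(x) > 0 and np.std(y) > 0:
            r = float(pearsonr(x, y).statistic)
        else:
            warnings.warn("screen has zero variance; correlation undefined")
    return table, r
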