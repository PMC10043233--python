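"""Pseudo-online scoring: per-repetition outcomes, the metric suite, and
leave-one-out trial cross-validation.

Metrics (all computed per repetition, then aggregated):

* ``NOFP``   -- % of repetitions with zero false positives;
* ``TP``     -- % of repetitions with at least one stop command inside
  ``[laser, stop_cue]`` (under close-loop latch semantics, only repetitions
  that survived the walking phase are eligible);
* ``NOFP/TP``-- % of repetitions with zero FP *and* a TP;
* ``FP/min`` -- 60 x (total FP) / (total walking time).  The denominator is
  the labeled walking (class-1) time summed over scored repetitions, not
  wall-clock session time -- discarded and stopped periods do not dilute the
  rate.  A wall-clock denominator is available for sensitivity checks.
* ``SuFP``   -- mean time from walking-phase start to the first FP, over
  repetitions that contain one (close-loop survival time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cnn
from .cascade import run_stream, train_cascade
from .core import EventLog
from .preprocessing import BandStack, CLASS1_WINDOW_S, CLASS2_PRE_S


@dataclass
class RepetitionOutcome:
    rep_id: int
    n_fp: int
    has_tp: bool | None          # None = undefined (latched FP ended the rep)
    sufp_s: float | None         # time from walk start to first FP
    walk_duration_s: float
    eligible_for_tp: bool


@dataclass
class MetricsReport:
    nofp_tp_pct: float
    nofp_pct: float
    tp_pct: float | None         # None when no repetition was eligible
    fp_per_min: float
    sufp_mean_s: float | None
    n_reps: int
    outcomes: list[RepetitionOutcome] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "nofp_tp_pct": self.nofp_tp_pct,
            "nofp_pct": self.nofp_pct,
            "tp_pct": self.tp_pct,
            "fp_per_min": self.fp_per_min,
            "sufp_mean_s": self.sufp_mean_s,
            "n_reps": self.n_reps,
        }


def _subtract_windows(a0: float, a1: float,
                      windows: list[tuple[float, float]]) -> float:
    """Length of [a0, a1] after removing its overlap with ``windows``."""
    length = max(0.0, a1 - a0)
    for w0, w1 in windows:
        length -= max(0.0, min(a1, w1) - max(a0, w0))
    return max(0.0, length)


def score_repetition(command_times_s: np.ndarray, laser_s: float, stop_s: float,
                     span_start_s: float, trial_start_s: float,
                     discard_windows_s: list[tuple[float, float]] | None = None,
                     latch: bool = False, rep_id: int = -1) -> RepetitionOutcome:
    """Assign one repetition's commands to FP/TP windows.

    The walking (class-1) window is ``[laser - 8, laser - 0.2]`` clipped to
    the trial start; the TP window is ``[laser, stop_cue]``.  Commands inside
    the repetition's span but in neither window (e.g. inside a discard
    window or the 0.2-s transition) are counted as FP with a warning -- the
    conservative reading for a closed loop.  Under ``latch`` only the first
    command exists; a latched FP leaves ``has_tp`` undefined.
    """
    discard_windows_s = discard_windows_s or []
    walk0 = max(laser_s + CLASS1_WINDOW_S[0], trial_start_s, span_start_s)
    walk1 = laser_s + CLASS2_PRE_S
    walk_duration = _subtract_windows(walk0, walk1, discard_windows_s)

    cmds = np.sort(np.asarray(command_times_s, dtype=float))
    cmds = cmds[(cmds >= span_start_s) & (cmds <= stop_s)]
    if latch:
        cmds = cmds[:1]

    n_fp, first_fp, has_tp, n_outside = 0, None, False, 0
    for t in cmds:
        if walk0 <= t <= walk1:
            is_fp = True
        elif laser_s <= t <= stop_s:
            has_tp = True
            is_fp = False
        else:
            n_outside += 1
            is_fp = True
        if is_fp:
            n_fp += 1
            if first_fp is None:
                # SuFP measures survival of the walking phase; clamp commands
                # that arrived before the walk window opened
                first_fp = max(0.0, t - walk0)
    if n_outside:
        warnings.warn(
            f"{n_outside} command(s) of repetition {rep_id} fall outside the "
            "walk and laser windows; counted as FP", stacklevel=2)
    if latch and n_fp > 0:
        has_tp = None  # the repetition ended before the laser phase
    return RepetitionOutcome(
        rep_id=rep_id,
        n_fp=n_fp,
        has_tp=has_tp,
        sufp_s=first_fp,
        walk_duration_s=walk_duration,
        eligible_for_tp=not (latch and n_fp > 0),
    )


def aggregate(outcomes: list[RepetitionOutcome],
              denominator: str = "walk",
              total_time_s: float | None = None) -> MetricsReport:
    """Aggregate repetition outcomes into the metric suite.

    ``denominator`` selects the FP/min normalization: ``"walk"`` (labeled
    walking time; the default) or ``"wallclock"`` (``total_time_s``).
    """
    if not outcomes:
        raise ValueError("aggregate needs at least one repetition outcome")
    n = len(outcomes)
    n_clean = sum(1 for o in outcomes if o.n_fp == 0)
    n_clean_tp = sum(1 for o in outcomes if o.n_fp == 0 and o.has_tp)
    eligible = [o for o in outcomes if o.eligible_for_tp]
    tp_pct = (100.0 * sum(1 for o in eligible if o.has_tp) / len(eligible)
              if eligible else None)
    total_fp = sum(o.n_fp for o in outcomes)
    if denominator == "walk":
        denom_s = sum(o.walk_duration_s for o in outcomes)
    elif denominator == "wallclock":
        if total_time_s is None:
            raise ValueError("wallclock denominator needs total_time_s")
        denom_s = total_time_s
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    fp_per_min = 60.0 * total_fp / denom_s if denom_s > 0 else float("nan")
    sufp = [o.sufp_s for o in outcomes if o.sufp_s is not None]
    return MetricsReport(
        nofp_tp_pct=100.0 * n_clean_tp / n,
        nofp_pct=100.0 * n_clean / n,
        tp_pct=tp_pct,
        fp_per_min=fp_per_min,
        sufp_mean_s=float(np.mean(sufp)) if sufp else None,
        n_reps=n,
        outcomes=list(outcomes),
    )


def score_timeline(timeline: pd.DataFrame, events: EventLog, fs: float,
                   trial: int, latch: bool = False) -> list[RepetitionOutcome]:
    """Score every repetition of ``trial`` against a command timeline."""
    cmd_times = timeline.loc[timeline["command"], "t_end_s"].to_numpy()
    trial_start = events.trial_bounds[trial][0] / fs
    discard_s = [(s / fs, e / fs) for s, e in events.discard_windows]
    outcomes = []
    prev_stop = trial_start
    for rep in events.repetitions_in_trial(trial):
        laser = events.laser_onsets[rep] / fs
        stop = events.stop_cues[rep] / fs if events.stop_cues[rep] >= 0 else laser + 2.0
        outcomes.append(score_repetition(
            cmd_times, laser, stop, span_start_s=prev_stop,
            trial_start_s=trial_start, discard_windows_s=discard_s,
            latch=latch, rep_id=int(rep)))
        prev_stop = stop
    return outcomes


def evaluate_trial(nn1, nn2, stack: BandStack, events: EventLog, trial: int,
                   latch: bool = False) -> MetricsReport:
    """Replay one trial through the cascade and aggregate its repetitions."""
    timeline = run_stream(nn1, nn2, stack, events, latch=latch, trial=trial)
    return aggregate(score_timeline(timeline, events, stack.fs, trial, latch=latch))


def macro_average(reports: list[MetricsReport]) -> MetricsReport:
    """Equal-weight average over folds (each fold one report)."""
    def _mean(vals):
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else None

    return MetricsReport(
        nofp_tp_pct=_mean([r.nofp_tp_pct for r in reports]),
        nofp_pct=_mean([r.nofp_pct for r in reports]),
        tp_pct=_mean([r.tp_pct for r in reports]),
        fp_per_min=_mean([r.fp_per_min for r in reports]),
        sufp_mean_s=_mean([r.sufp_mean_s for r in reports]),
        n_reps=sum(r.n_reps for r in reports),
        outcomes=[o for r in reports for o in r.outcomes],
    )


def loo_cv(stack: BandStack, events: EventLog,
           train_spec: cnn.TrainSpec | None = None,
           netspec: cnn.NetSpec | None = None,
           seed: int = 0, latch: bool = False,
           trials: list[int] | None = None) -> tuple[MetricsReport, list[MetricsReport]]:
    """Leave-one-trial-out cross-validation of the full cascade.

    Each fold trains NN1+NN2 (harvest included) on N-1 trials and replays the
    held-out trial pseudo-online.  Folds whose harvest is degenerate are
    skipped with a warning.  Returns (macro-averaged report, per-fold list).
    """
    from .cascade import CascadeDegeneracyError

    trials = list(range(len(events.trial_bounds))) if trials is None else list(trials)
    if len(trials) < 2:
        raise ValueError("leave-one-out needs at least 2 trials")
    fold_reports = []
    for k, test_trial in enumerate(trials):
        train_trials = [t for t in trials if t != test_trial]
        try:
            nn1, nn2 = train_cascade(
                stack, events, train_trials, train_spec, netspec, seed=seed + 1000 * k)
        except CascadeDegeneracyError as err:
            warnings.warn(f"fold {k} (test trial {test_trial}) skipped: {err}",
                          stacklevel=2)
            continue
        fold_reports.append(evaluate_trial(nn1, nn2, stack, events, test_trial, latch))
    if not fold_reports:
        raise RuntimeError("every cross-validation fold was degenerate")
    return macro_average(fold_reports), fold_reports
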