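"""Two-stage cascade: stop detector (NN1) plus false-stop veto (NN2).

NN1 is trained on the laser-locked 4+4 epochs per repetition.  It is then
replayed over the wide walk/stop windows of the same training trials; the
epochs it wrongly calls "stop" (false positives) and those it correctly
calls "stop" (true positives) form, after balancing, the two classes of
NN2.  At inference an epoch must pass both networks to count as a stop
output, and a stop *command* is only issued when at least 3 of the last 5
outputs are stops (equivalently: the mode of the last five outputs).
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cnn
from .core import EventLog
from .preprocessing import (
    BandStack,
    EpochSet,
    LABEL_STOP,
    LABEL_WALK,
    extract_epochs,
    label_epochs,
)

BUFFER_LEN = 5
COMMAND_VOTES = 3
_PREDICT_BATCH = 256


class CascadeDegeneracyError(RuntimeError):
    """NN1 produced no false (or no true) stop detections on the training
    trials, so NN2 has nothing to learn from.  Usually means NN1 is either
    perfect or broken on this data; retrain NN1 or enlarge the training set."""


# ---------------------------------------------------------------------------
# NN1 dataset + harvest
# ---------------------------------------------------------------------------

def _reps_of_trials(events: EventLog, trials) -> np.ndarray:
    return np.concatenate([events.repetitions_in_trial(t) for t in trials]) \
        if len(trials) else np.empty(0, dtype=np.int64)


def build_nn1_dataset(stack: BandStack, events: EventLog,
                      trials: list[int] | None = None,
                      rep_ids: list[int] | None = None) -> EpochSet:
    """Laser-locked 4 walk + 4 stop epochs per repetition.

    ``trials`` and/or ``rep_ids`` restrict which repetitions contribute
    (both given = intersection)."""
    grid = extract_epochs(stack)
    labeled = label_epochs(grid, events, mode="nn1_train")
    mask = np.ones(len(labeled), dtype=bool)
    if trials is not None:
        keep = set(int(r) for r in _reps_of_trials(events, trials))
        mask &= np.isin(labeled.rep_ids, list(keep))
    if rep_ids is not None:
        mask &= np.isin(labeled.rep_ids, list(map(int, rep_ids)))
    return labeled.subset(mask)


@dataclass
class HarvestSet:
    """Stop-classified epochs from NN1's prediction pass, split by truth."""

    epochs: EpochSet          # the wide-window labeled epochs that were predicted
    false_idx: np.ndarray     # indices into epochs: truly walk, NN1 said stop
    true_idx: np.ndarray      # indices into epochs: truly stop, NN1 said stop

    @property
    def counts(self) -> tuple[int, int]:
        return len(self.false_idx), len(self.true_idx)

    def tensors_and_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """NN2 training data: false stops are class 1 (walk), true stops 2."""
        idx = np.concatenate([self.false_idx, self.true_idx])
        y = np.concatenate([
            np.full(len(self.false_idx), LABEL_WALK),
            np.full(len(self.true_idx), LABEL_STOP),
        ])
        return self.epochs.tensor(idx), y


def predict_epochset(model, epochs: EpochSet,
                     indices: np.ndarray | None = None) -> np.ndarray:
    """Batched class prediction over an EpochSet (1 walk / 2 stop)."""
    idx = np.arange(len(epochs)) if indices is None else np.asarray(indices)
    out = np.empty(len(idx), dtype=np.int64)
    for i in range(0, len(idx), _PREDICT_BATCH):
        sl = idx[i : i + _PREDICT_BATCH]
        out[i : i + len(sl)] = model.predict_classes(epochs.tensor(sl))
    return out


def nn1_prediction_pass(nn1, stack: BandStack, events: EventLog,
                        trials: list[int] | None = None,
                        rep_ids: list[int] | None = None,
                        allow_degenerate: bool = False) -> HarvestSet:
    """Replay NN1 over the wide-window labeled epochs of the training trials
    and harvest its stop detections, split into false and true stops."""
    grid = extract_epochs(stack)
    wide = label_epochs(grid, events, mode="wide")
    mask = wide.labels > 0
    if trials is not None:
        keep = set(int(r) for r in _reps_of_trials(events, trials))
        mask &= np.isin(wide.rep_ids, list(keep))
    if rep_ids is not None:
        mask &= np.isin(wide.rep_ids, list(map(int, rep_ids)))
    wide = wide.subset(mask)
    pred = predict_epochset(nn1, wide)
    stop_mask = pred == LABEL_STOP
    false_idx = np.where(stop_mask & (wide.labels == LABEL_WALK))[0]
    true_idx = np.where(stop_mask & (wide.labels == LABEL_STOP))[0]
    if (len(false_idx) == 0 or len(true_idx) == 0) and not allow_degenerate:
        raise CascadeDegeneracyError(
            f"harvest degenerate: {len(false_idx)} false stops, "
            f"{len(true_idx)} true stops"
        )
    return HarvestSet(wide, false_idx, true_idx)


def balance_harvest(h: HarvestSet, seed: int = 0) -> HarvestSet:
    """Randomly undersample the majority class to the minority count."""
    nf, nt = h.counts
    if nf == 0 or nt == 0:
        raise CascadeDegeneracyError("cannot balance an empty harvest class")
    rng = np.random.default_rng(seed)
    m = min(nf, nt)
    false_idx = h.false_idx if nf == m else np.sort(
        rng.choice(h.false_idx, size=m, replace=False))
    true_idx = h.true_idx if nt == m else np.sort(
        rng.choice(h.true_idx, size=m, replace=False))
    return HarvestSet(h.epochs, false_idx, true_idx)


def train_nn2(h: HarvestSet, train_spec: cnn.TrainSpec,
              netspec: cnn.NetSpec | None = None,
              provenance: dict | None = None) -> cnn.TrainedModel:
    """Train the veto network on a balanced harvest (same architecture and
    training parameters as NN1)."""
    nf, nt = h.counts
    if nf != nt:
        raise ValueError("harvest must be balanced before NN2 training")
    x, y = h.tensors_and_labels()
    if len(y) < 2 * train_spec.batch_size and train_spec.batch_size > len(y):
        warnings.warn(
            f"harvest ({len(y)} epochs) smaller than batch size "
            f"{train_spec.batch_size}; shrinking batch to dataset size",
            stacklevel=2,
        )
        train_spec = replace(train_spec, batch_size=len(y))
    net = cnn.build_network(netspec or cnn.NetSpec(
        n_bands=h.epochs.stack.data.shape[0],
        n_channels=h.epochs.stack.data.shape[1],
        temporal=h.epochs.epoch_len,
    ), seed=train_spec.seed)
    prov = {"role": "NN2", "harvest_counts": (nf, nt), **(provenance or {})}
    return cnn.train(net, x, y, train_spec, provenance=prov)


# ---------------------------------------------------------------------------
# cascaded inference
# ---------------------------------------------------------------------------

@dataclass
class DecisionBuffer:
    """Sliding window of the last 5 cascade outputs; command = >=3 stops."""

    window: deque = field(default_factory=lambda: deque(maxlen=BUFFER_LEN))

    def push(self, output: int) -> bool:
        """Append a walk(1)/stop(2) output; True when a stop command fires."""
        self.window.append(output)
        return self.command

    @property
    def command(self) -> bool:
        return (len(self.window) == BUFFER_LEN
                and sum(1 for o in self.window if o == LABEL_STOP) >= COMMAND_VOTES)

    def reset(self) -> None:
        self.window.clear()


def cascade_step(nn1, nn2, epoch_tensor: np.ndarray,
                 buffer: DecisionBuffer) -> tuple[int, bool]:
    """One causal step: NN1 gates NN2; the buffer votes on the command.

    Returns (current_output, command); the buffer is updated in place.
    NN2 is only consulted when NN1 says stop, and its "false stop" verdict
    rewrites the output to walk.
    """
    out1 = int(nn1.predict_classes(epoch_tensor[None] if epoch_tensor.ndim == 3
                                   else epoch_tensor)[0])
    if out1 == LABEL_WALK:
        out = LABEL_WALK
    else:
        out = int(nn2.predict_classes(epoch_tensor[None] if epoch_tensor.ndim == 3
                                      else epoch_tensor)[0])
    command = buffer.push(out)
    return out, command


def run_stream(nn1, nn2, stack: BandStack, events: EventLog,
               latch: bool = False, trial: int | None = None) -> pd.DataFrame:
    """Pseudo-online replay of the cascade over a preprocessed stream.

    Epochs are cut on the 0.1-s grid; each is classified by NN1 and, when
    NN1 says stop, by NN2.  With ``latch=True`` (close-loop semantics) the
    first stop command ends the repetition: further outputs are suppressed
    until the repetition's stop cue has passed and the buffer restarts at
    the next repetition.  ``trial`` restricts the replay to one trial.

    Returns a timeline frame with one row per epoch: t_start_s, t_end_s,
    nn1 (1/2), nn2 (0 = not consulted), final (1/2), command (bool).
    """
    fs = stack.fs
    grid = extract_epochs(stack)
    starts = grid.starts
    if trial is not None:
        s, e = events.trial_bounds[trial]
        keep = (starts >= s) & (starts + grid.epoch_len <= e)
        grid = grid.subset(keep)
        starts = grid.starts

    # classifier outputs do not depend on the command history, so they can be
    # computed in batch; the command/latch semantics are applied sequentially
    nn1_out = predict_epochset(nn1, grid)
    nn2_out = np.zeros(len(grid), dtype=np.int64)
    stop_idx = np.where(nn1_out == LABEL_STOP)[0]
    if len(stop_idx):
        nn2_out[stop_idx] = predict_epochset(nn2, grid, stop_idx)
    final = np.where(nn1_out == LABEL_WALK, LABEL_WALK,
                     np.where(nn2_out == LABEL_STOP, LABEL_STOP, LABEL_WALK))

    # repetition spans for latch semantics: a repetition "ends" at its stop
    # cue; after a latched command we stay silent until the span ends, then
    # clear the buffer (the walking period restarts)
    stops = np.sort(events.stop_cues[events.stop_cues >= 0])
    trial_starts = {s for s, _ in events.trial_bounds}

    buffer = DecisionBuffer()
    commands = np.zeros(len(grid), dtype=bool)
    latched_until: int | None = None
    for i, s0 in enumerate(starts):
        if int(s0) in trial_starts:
            buffer.reset()
        if latched_until is not None:
            if s0 < latched_until:
                continue
            buffer.reset()
            latched_until = None
        cmd = buffer.push(int(final[i]))
        if cmd:
            commands[i] = True
            if latch:
                nxt = stops[stops >= s0 + grid.epoch_len]
                latched_until = int(nxt[0]) if len(nxt) else int(starts[-1]) + 1
    return pd.DataFrame({
        "t_start_s": starts / fs,
        "t_end_s": (starts + grid.epoch_len) / fs,
        "nn1": nn1_out,
        "nn2": nn2_out,
        "final": final,
        "command": commands,
    })


# ---------------------------------------------------------------------------
# end-to-end training of a cascade pair
# ---------------------------------------------------------------------------

def train_cascade(stack: BandStack, events: EventLog, trials: list[int],
                  train_spec: cnn.TrainSpec | None = None,
                  netspec: cnn.NetSpec | None = None,
                  seed: int = 0) -> tuple[cnn.TrainedModel, cnn.TrainedModel]:
    """Train NN1 then harvest + balance + train NN2 on the given trials.

    The harvest pass uses only the training trials (no test leakage); the
    repetition ids used are recorded in each model's provenance.
    """
    train_spec = train_spec or cnn.TrainSpec()
    netspec = netspec or cnn.NetSpec(
        n_bands=stack.data.shape[0], n_channels=stack.data.shape[1])
    nn1_set = build_nn1_dataset(stack, events, trials)
    if len(nn1_set) == 0:
        raise cnn.TrainingError("no usable repetitions in the training trials")
    reps_used = sorted(set(int(r) for r in nn1_set.rep_ids))
    spec1 = replace(train_spec, seed=seed)
    nn1 = cnn.train(
        cnn.build_network(netspec, seed=seed),
        nn1_set.tensor(), nn1_set.labels, spec1,
        provenance={"role": "NN1", "trials": list(map(int, trials)), "reps": reps_used},
    )
    harvest = nn1_prediction_pass(nn1, stack, events, trials)
    balanced = balance_harvest(harvest, seed=seed + 1)
    nn2 = train_nn2(
        balanced, replace(train_spec, seed=seed + 2), netspec,
        provenance={"trials": list(map(int, trials)), "reps": reps_used},
    )
    return nn1, nn2
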