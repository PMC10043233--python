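"""Transfer learning for small subject datasets (TL + FT).

A generic cascade pair is pre-trained on the pooled training data of other
subjects plus the target subject's first 20 training repetitions, then both
networks are fine-tuned on those same 20 repetitions (all layers trainable,
lower learning rate).  The comparison baseline is a cascade trained on the
20 target repetitions alone.  Target test trials never enter any training
stage; the repetition provenance stored in each model makes that auditable.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import cnn
from .cascade import (
    CascadeDegeneracyError,
    balance_harvest,
    build_nn1_dataset,
    nn1_prediction_pass,
    train_nn2,
)
from .core import EventLog
from .preprocessing import BandStack, LABEL_STOP, LABEL_WALK


@dataclass
class Session:
    """A preprocessed session: band stack + events (one subject, one setup)."""

    stack: BandStack
    events: EventLog
    name: str = ""


@dataclass
class TLPlan:
    """What goes into pre-training and fine-tuning.

    ``target_train_trials`` are the target trials whose first
    ``n_target_reps`` repetitions may be used; everything else of the target
    is test data and is never touched.
    """

    sources: list[Session]
    target: Session
    target_train_trials: list[int]
    n_target_reps: int = 20
    ft_spec: cnn.TrainSpec = field(default_factory=lambda: cnn.TrainSpec(
        learning_rate=0.001, max_epochs=50))

    def target_rep_ids(self) -> list[int]:
        reps = np.concatenate([
            self.target.events.repetitions_in_trial(t)
            for t in self.target_train_trials
        ])
        reps = np.sort(reps)
        return [int(r) for r in reps[: self.n_target_reps]]


def _default_ft_spec() -> cnn.TrainSpec:
    return cnn.TrainSpec(learning_rate=0.001, max_epochs=50)


def _pooled_nn1_data(plan: TLPlan) -> tuple[np.ndarray, np.ndarray, dict]:
    xs, ys = [], []
    prov_reps = {}
    for s in plan.sources:
        ds = build_nn1_dataset(s.stack, s.events)
        xs.append(ds.tensor())
        ys.append(ds.labels)
        prov_reps[s.name or f"source{len(prov_reps)}"] = sorted(
            set(int(r) for r in ds.rep_ids))
    reps = plan.target_rep_ids()
    ds = build_nn1_dataset(plan.target.stack, plan.target.events, rep_ids=reps)
    xs.append(ds.tensor())
    ys.append(ds.labels)
    prov_reps["target"] = sorted(set(int(r) for r in ds.rep_ids))
    return np.concatenate(xs), np.concatenate(ys), prov_reps


def _pooled_harvest(nn1, plan: TLPlan, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Harvest false/true stops across all pooled sessions, then balance."""
    xf, xt = [], []
    for s in plan.sources + [plan.target]:
        rep_ids = plan.target_rep_ids() if s is plan.target else None
        h = nn1_prediction_pass(nn1, s.stack, s.events, rep_ids=rep_ids,
                                allow_degenerate=True)
        if len(h.false_idx):
            xf.append(h.epochs.tensor(h.false_idx))
        if len(h.true_idx):
            xt.append(h.epochs.tensor(h.true_idx))
    if not xf or not xt:
        raise CascadeDegeneracyError("pooled harvest has an empty class")
    xf = np.concatenate(xf)
    xt = np.concatenate(xt)
    rng = np.random.default_rng(seed)
    m = min(len(xf), len(xt))
    if len(xf) > m:
        xf = xf[np.sort(rng.choice(len(xf), size=m, replace=False))]
    if len(xt) > m:
        xt = xt[np.sort(rng.choice(len(xt), size=m, replace=False))]
    x = np.concatenate([xf, xt])
    y = np.concatenate([np.full(m, LABEL_WALK), np.full(m, LABEL_STOP)])
    return x, y


def pretrain_pooled(plan: TLPlan, train_spec: cnn.TrainSpec | None = None,
                    netspec: cnn.NetSpec | None = None,
                    seed: int = 0) -> tuple[cnn.TrainedModel, cnn.TrainedModel]:
    """Train the generic (pooled) cascade pair.

    NN1 sees the laser-locked epochs of every source session plus the
    target's first ``n_target_reps``; the harvest pass and NN2 training run
    over the same pooled material.
    """
    train_spec = train_spec or cnn.TrainSpec()
    st = plan.target.stack
    netspec = netspec or cnn.NetSpec(n_bands=st.data.shape[0],
                                     n_channels=st.data.shape[1])
    for s in plan.sources:
        if s.stack.data.shape[:2] != st.data.shape[:2]:
            raise ValueError(
                f"channel layout of session {s.name!r} differs from the target")
    x, y, prov_reps = _pooled_nn1_data(plan)
    nn1 = cnn.train(
        cnn.build_network(netspec, seed=seed), x, y,
        replace(train_spec, seed=seed),
        provenance={"role": "NN1", "stage": "pooled", "reps": prov_reps},
    )
    hx, hy = _pooled_harvest(nn1, plan, seed=seed + 1)
    spec2 = replace(train_spec, seed=seed + 2)
    if len(hy) < spec2.batch_size:
        spec2 = replace(spec2, batch_size=len(hy))
    nn2 = cnn.train(
        cnn.build_network(netspec, seed=seed + 2), hx, hy, spec2,
        provenance={"role": "NN2", "stage": "pooled", "reps": prov_reps},
    )
    return nn1, nn2


def fine_tune(models: tuple[cnn.TrainedModel, cnn.TrainedModel], plan: TLPlan,
              ft_spec: cnn.TrainSpec | None = None,
              seed: int = 100) -> tuple[cnn.TrainedModel, cnn.TrainedModel]:
    """Fine-tune the pooled pair on the target's 20 repetitions.

    All layers stay trainable; NN1 is re-trained on the target-only
    laser-locked epochs, then NN2's harvest is re-run with the fine-tuned
    NN1 on the target repetitions only.  A degenerate re-harvest falls back
    to the pooled NN2 with a warning.
    """
    nn1_pre, nn2_pre = models
    ft_spec = ft_spec or plan.ft_spec or _default_ft_spec()
    reps = plan.target_rep_ids()
    ds = build_nn1_dataset(plan.target.stack, plan.target.events, rep_ids=reps)
    net1 = copy.deepcopy(nn1_pre.net)
    nn1_ft = cnn.train(
        net1, ds.tensor(), ds.labels, replace(ft_spec, seed=seed),
        provenance={"role": "NN1", "stage": "fine-tuned", "reps": reps},
    )
    try:
        h = nn1_prediction_pass(nn1_ft, plan.target.stack, plan.target.events,
                                rep_ids=reps)
        h = balance_harvest(h, seed=seed + 1)
        x, y = h.tensors_and_labels()
        spec2 = replace(ft_spec, seed=seed + 2)
        if len(y) < spec2.batch_size:
            spec2 = replace(spec2, batch_size=len(y))
        net2 = copy.deepcopy(nn2_pre.net)
        nn2_ft = cnn.train(
            net2, x, y, spec2,
            provenance={"role": "NN2", "stage": "fine-tuned", "reps": reps},
        )
    except CascadeDegeneracyError as err:
        warnings.warn(f"fine-tuning harvest degenerate ({err}); "
                      "keeping the pooled NN2", stacklevel=2)
        nn2_ft = nn2_pre
    return nn1_ft, nn2_ft


def subject_only_cascade(target: Session, rep_ids: list[int],
                         train_spec: cnn.TrainSpec | None = None,
                         netspec: cnn.NetSpec | None = None,
                         seed: int = 0) -> tuple[cnn.TrainedModel, cnn.TrainedModel]:
    """Baseline: cascade trained on the target's few repetitions alone."""
    train_spec = train_spec or cnn.TrainSpec()
    st = target.stack
    netspec = netspec or cnn.NetSpec(n_bands=st.data.shape[0],
                                     n_channels=st.data.shape[1])
    ds = build_nn1_dataset(st, target.events, rep_ids=rep_ids)
    nn1 = cnn.train(
        cnn.build_network(netspec, seed=seed), ds.tensor(), ds.labels,
        replace(train_spec, seed=seed),
        provenance={"role": "NN1", "stage": "subject-only", "reps": list(rep_ids)},
    )
    h = balance_harvest(
        nn1_prediction_pass(nn1, st, target.events, rep_ids=rep_ids),
        seed=seed + 1)
    nn2 = train_nn2(h, replace(train_spec, seed=seed + 2), netspec,
                    provenance={"stage": "subject-only", "reps": list(rep_ids)})
    return nn1, nn2
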