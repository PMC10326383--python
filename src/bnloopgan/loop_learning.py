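"""Multiple-loop learning: critic-ranked incremental classifier training.

Each loop assembles a class-balanced batch (carryover from the previous
loop topped up by a random draw from the database), generates
class-conditioned fake samples, and scores every real sample by the
Euclidean distance between its critic patch map and the centroid of the
fake patch maps of its class.  Samples close to the generator's learned
distribution are considered easier to learn and are ranked first.  Per
class, the top half of the ranking trains the classifier, ranks from
half to three-quarters carry over to the next loop, and the bottom
quarter returns to the database.  The loop repeats until the validation
accuracy stops improving or a loop budget is exhausted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from . import evaluation, gan_core
from .gan_core import GanBundle, Network
from .nn import Adam, autodiff as ad
from .nn.autodiff import Tensor

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankEntry:
    sample_id: str
    label: int
    score: float


@dataclass
class RankingTable:
    """Per-sample contribution scores, ascending within each class.

    Smaller score = closer to the generator's learned distribution =
    easier to learn; ties are broken by sample id for stability.
    """

    entries: list[RankEntry]

    def __post_init__(self):
        for e in self.entries:
            if not (np.isfinite(e.score) and e.score >= 0):
                raise ValueError(f"invalid score for {e.sample_id}")
        self.entries = sorted(self.entries,
                              key=lambda e: (e.label, e.score, e.sample_id))

    def per_class(self, label: int) -> list[RankEntry]:
        return [e for e in self.entries if e.label == label]


@dataclass
class LoopConfig:
    """Free parameters of the loop (batch size, budgets, convergence)."""

    batch_per_class: int = 8
    classifier_epochs: int = 10
    classifier_lr: float = 1e-3
    patience: int = 3
    min_delta: float = 1e-3
    max_loops: int = 10
    n_fakes_per_class: int = 8
    refresh_gan: bool = False
    rank_easiest_first: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_per_class < 4:
            raise ValueError("batch_per_class must be >= 4 so ranking "
                             "quarters are non-empty")
        if self.patience < 1 or self.max_loops < 1:
            raise ValueError("patience and max_loops must be >= 1")


@dataclass
class LoopState:
    """Disjoint sample pools; their union is the whole training set."""

    loop_index: int = 0
    database: list[str] = field(default_factory=list)
    carryover: list[str] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)

    def pools(self) -> dict[str, list[str]]:
        return {"database": self.database, "carryover": self.carryover,
                "selected": self.selected}

    def check_conservation(self, all_ids: set[str]):
        combined = self.database + self.carryover + self.selected
        if len(combined) != len(set(combined)):
            raise RuntimeError("sample pools overlap")
        if set(combined) != all_ids:
            raise RuntimeError("sample pools do not cover the training set")


def _sample_arrays(samples) -> tuple[np.ndarray, np.ndarray, list[str]]:
    x = np.stack([s.tensor.transpose(2, 0, 1) for s in samples])
    y = np.array([s.label for s in samples], dtype=int)
    ids = [s.sample_id for s in samples]
    return x, y, ids


def contribution_ranking(critic: Network, real_batch,
                         fake_batch: tuple[np.ndarray, np.ndarray],
                         conditional: bool = True,
                         easiest_first: bool = True) -> RankingTable:
    """Distance of each real sample to its class's fake patch-map centroid.

    score(r) = || vec(D(r)) - mean_f vec(D(f)) ||_2 over fakes f of r's
    class.  With ``easiest_first`` (default) smaller distances rank
    first; the opposite direction is available for ablation.
    """
    x, y, ids = _sample_arrays(real_batch)
    fx, fy = np.asarray(fake_batch[0], dtype=float), np.asarray(fake_batch[1])
    critic.eval()
    real_maps = _patch_maps(critic, x, y, conditional)
    fake_maps = _patch_maps(critic, fx, fy, conditional)
    critic.train()
    entries = []
    for label in sorted(set(y.tolist())):
        f_sel = fake_maps[fy == label]
        if f_sel.shape[0] == 0:
            raise ValueError(f"no fake samples for class {label}")
        centroid = f_sel.mean(axis=0)
        for i in np.flatnonzero(y == label):
            d = float(np.linalg.norm(real_maps[i] - centroid))
            entries.append(RankEntry(ids[i], int(label),
                                     d if easiest_first else -d))
    if not easiest_first:
        offset = max((-e.score for e in entries), default=0.0)
        entries = [RankEntry(e.sample_id, e.label, e.score + offset)
                   for e in entries]
    return RankingTable(entries)


def _patch_maps(critic: Network, x: np.ndarray, y: np.ndarray,
                conditional: bool) -> np.ndarray:
    xt = Tensor(x)
    if conditional:
        xt = gan_core.condition_inputs(xt, y)
    maps = critic(xt).data
    return maps.reshape(maps.shape[0], -1)


def partition_ranked(table: RankingTable
                     ) -> tuple[list[str], list[str], list[str]]:
    """Split each class's ranking into train / carryover / returned ids.

    Per class of size m: train = ranks 1..ceil(m/2), carryover =
    ceil(m/2)+1..ceil(3m/4), returned = the rest.  Ceilings make the
    counts reproducible for any m.
    """
    train, carry, returned = [], [], []
    labels = sorted({e.label for e in table.entries})
    for label in labels:
        entries = table.per_class(label)
        m = len(entries)
        if m < 4:
            raise ValueError(f"class {label} has only {m} ranked samples; "
                             "need at least 4")
        c_train = math.ceil(m / 2)
        c_carry = math.ceil(3 * m / 4)
        train.extend(e.sample_id for e in entries[:c_train])
        carry.extend(e.sample_id for e in entries[c_train:c_carry])
        returned.extend(e.sample_id for e in entries[c_carry:])
    return train, carry, returned


def assemble_loop_batch(state: LoopState, config: LoopConfig,
                        rng: np.random.Generator,
                        labels_by_id: dict[str, int]) -> LoopState:
    """Fill ``selected`` to the per-class batch size.

    Carryover moves into the batch wholesale; the remainder is a seeded
    uniform draw (without replacement) from the database, per class, so
    the batch stays balanced (x = y).
    """
    selected = list(state.carryover)
    state.carryover = []
    for label in (0, 1):
        have = sum(1 for sid in selected if labels_by_id[sid] == label)
        need = config.batch_per_class - have
        if need < 0:
            raise RuntimeError("carryover exceeds the loop batch size")
        pool = [sid for sid in state.database if labels_by_id[sid] == label]
        if len(pool) < need:
            raise ValueError(
                f"database holds {len(pool)} class-{label} samples but "
                f"{need} are needed; use a smaller batch_per_class")
        draw = [pool[i] for i in rng.choice(len(pool), size=need, replace=False)]
        selected.extend(draw)
        drawn = set(draw)
        state.database = [sid for sid in state.database if sid not in drawn]
    state.selected = selected
    return state


@dataclass
class MultiloopResult:
    classifier: Network
    history: list[dict]
    converged: bool
    ledger: list[dict]

    @property
    def final_accuracy(self) -> float:
        return self.history[-1]["acc"] if self.history else float("nan")


def classifier_scores(classifier: Network, x: np.ndarray) -> np.ndarray:
    """Logits for an NCHW batch (eval mode; prediction is logit > 0)."""
    classifier.eval()
    logits = gan_core.classifier_logit(classifier(Tensor(x))).data
    classifier.train()
    return logits


def _train_classifier(classifier: Network, opt: Adam, x: np.ndarray,
                      y: np.ndarray, epochs: int, rng: np.random.Generator):
    for _ in range(epochs):
        idx = rng.permutation(x.shape[0])
        logits = gan_core.classifier_logit(classifier(Tensor(x[idx])))
        loss = gan_core.classifier_loss(logits, y[idx])
        if not np.isfinite(loss.data):
            raise RuntimeError("non-finite classifier loss")
        opt.step(ad.grad(loss, classifier.parameters()))


def run_multiloop(dataset, gan: GanBundle, classifier: Network,
                  config: LoopConfig, val_dataset) -> MultiloopResult:
    """Algorithm: rank, select, train, re-pool, until convergence.

    ``dataset`` is the training pool of multi-modal samples; held-out
    ``val_dataset`` drives the convergence check (no improvement greater
    than ``min_delta`` for ``patience`` consecutive loops).  Trained-on
    and bottom-quarter samples return to the database after each loop;
    carryover is held for the next batch.  Returns the classifier, the
    per-loop accuracy history, and a pool-transition ledger.
    """
    samples_by_id = {s.sample_id: s for s in dataset}
    labels_by_id = {sid: s.label for sid, s in samples_by_id.items()}
    all_ids = set(samples_by_id)
    vx, vy, _ = _sample_arrays(val_dataset)

    rng = np.random.default_rng(config.seed)
    opt = Adam(classifier.parameters(), lr=config.classifier_lr,
               betas=(0.9, 0.999))
    state = LoopState(database=sorted(all_ids))
    ledger: list[dict] = []
    best_acc, stall = -np.inf, 0
    converged = False

    while state.loop_index < config.max_loops:
        assemble_loop_batch(state, config, rng, labels_by_id)
        state.check_conservation(all_ids)

        fake_labels = np.repeat([0, 1], config.n_fakes_per_class)
        fakes = gan.sample(fake_labels, rng)
        selected_samples = [samples_by_id[sid] for sid in state.selected]
        table = contribution_ranking(
            gan.critic, selected_samples, (fakes, fake_labels),
            conditional=gan.config.conditional,
            easiest_first=config.rank_easiest_first)
        train_ids, carry_ids, returned_ids = partition_ranked(table)

        tx, ty, _ = _sample_arrays([samples_by_id[sid] for sid in train_ids])
        _train_classifier(classifier, opt, tx, ty, config.classifier_epochs, rng)

        if config.refresh_gan:
            gan_core.gan_refresh_steps(gan, tx, ty, steps=1, rng=rng)

        preds = (classifier_scores(classifier, vx) > 0).astype(int)
        c = evaluation.confusion(vy, preds)
        acc = (c.tp + c.tn) / (c.tp + c.tn + c.fp + c.fn)
        sen = c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")
        spe = c.tn / (c.fp + c.tn) if c.fp + c.tn else float("nan")
        state.history.append({"loop": state.loop_index,
                              "n_selected": len(state.selected),
                              "acc": acc, "sen": sen, "spe": spe})
        ledger.append({"loop": state.loop_index,
                       "selected": list(state.selected),
                       "trained": train_ids, "carryover": carry_ids,
                       "returned": returned_ids})
        logger.info("loop %d: acc=%.3f sen=%.3f spe=%.3f",
                    state.loop_index, acc, sen, spe)

        # re-pool: trained-on and bottom-quarter samples go back to the
        # database; carryover is held for the next loop's batch
        state.database = sorted(state.database + train_ids + returned_ids)
        state.carryover = carry_ids
        state.selected = []
        state.loop_index += 1
        state.check_conservation(all_ids)

        if acc > best_acc + config.min_delta:
            best_acc, stall = acc, 0
        else:
            stall += 1
            if stall >= config.patience:
                converged = True
                break

    if not converged:
        logger.warning("loop budget exhausted before convergence "
                       "(best validation accuracy %.3f)", best_acc)
    return MultiloopResult(classifier, state.history, converged, ledger)
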