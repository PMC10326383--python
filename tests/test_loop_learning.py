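import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bnloopgan import nn
from bnloopgan.gan_core import Network, build_classifier
from bnloopgan.loop_learning import (LoopConfig, LoopState, RankEntry,
                                     RankingTable, assemble_loop_batch,
                                     contribution_ranking, partition_ranked,
                                     run_multiloop)
from bnloopgan.network_construction import ConnectivityMatrix, MultiModalSample
from bnloopgan.nn import autodiff as ad
from bnloopgan.nn.autodiff import Tensor


def _sample(sid, label, matrix):
    c = ConnectivityMatrix(sid, "structural", matrix)
    return MultiModalSample(sid, [c], label)


def _rand_sample(sid, label, r, rng):
    m = rng.uniform(0, 1, size=(r, r))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return _sample(sid, label, m)


class _ZeroCritic(nn.Module):
    def forward(self, x):
        return Tensor(np.zeros((x.shape[0], 1, 2, 2)))


class _LinearCritic(nn.Module):
    """Patch map = W @ vec(x), a fixed known linear map for hand oracles."""

    def __init__(self, w):
        super().__init__()
        self.w = w  # (4, d)

    def forward(self, x):
        flat = ad.reshape(x, (x.shape[0], self.w.shape[1], 1))
        out = ad.matmul(Tensor(self.w), flat)
        return ad.reshape(out, (x.shape[0], 1, 2, 2))


class TestContributionRanking:
    def test_zero_critic_gives_zero_scores_in_stable_id_order(self, rng):
        reals = [_rand_sample(f"s{i}", i % 2, 4, rng) for i in range(6)]
        fakes = (rng.uniform(size=(4, 1, 4, 4)), np.array([0, 0, 1, 1]))
        table = contribution_ranking(_ZeroCritic(), reals, fakes,
                                     conditional=False)
        assert all(e.score == 0.0 for e in table.entries)
        for label in (0, 1):
            ids = [e.sample_id for e in table.per_class(label)]
            assert ids == sorted(ids)

    def test_real_identical_to_single_fake_ranks_first(self, rng):
        w = rng.normal(size=(4, 16))
        critic = _LinearCritic(w)
        target = rng.uniform(size=(4, 4))
        target = (target + target.T) / 2
        np.fill_diagonal(target, 0)
        reals = [_sample("match", 0, target),
                 _rand_sample("other1", 0, 4, rng),
                 _rand_sample("other2", 0, 4, rng),
                 _rand_sample("hc", 1, 4, rng)]
        fakes = (np.stack([target[None], rng.uniform(size=(1, 4, 4))]),
                 np.array([0, 1]))
        table = contribution_ranking(critic, reals, fakes, conditional=False)
        top = table.per_class(0)[0]
        assert top.sample_id == "match#s0"
        assert top.score == pytest.approx(0.0, abs=1e-12)

    def test_scores_match_hand_computed_euclidean_distances(self, rng):
        w = rng.normal(size=(4, 9))
        critic = _LinearCritic(w)
        reals = [_rand_sample(f"s{i}", 0, 3, rng) for i in range(3)]
        fake_x = rng.uniform(size=(2, 1, 3, 3))
        table = contribution_ranking(critic, reals, (fake_x, np.zeros(2)),
                                     conditional=False)
        centroid = np.mean([w @ fake_x[k].ravel() for k in range(2)], axis=0)
        expect = {s.sample_id: np.linalg.norm(w @ s.tensor.ravel() - centroid)
                  for s in reals}
        for e in table.entries:
            assert e.score == pytest.approx(expect[e.sample_id], abs=1e-10)

    def test_missing_fake_class_rejected(self, rng):
        reals = [_rand_sample(f"s{i}", i % 2, 4, rng) for i in range(4)]
        fakes = (rng.uniform(size=(2, 1, 4, 4)), np.zeros(2))
        with pytest.raises(ValueError, match="class 1"):
            contribution_ranking(_ZeroCritic(), reals, fakes, conditional=False)

    def test_ranking_is_permutation_equivariant(self, rng):
        w = rng.normal(size=(4, 16))
        critic = _LinearCritic(w)
        reals = [_rand_sample(f"s{i}", i % 2, 4, rng) for i in range(8)]
        fakes = (rng.uniform(size=(4, 1, 4, 4)), np.array([0, 1, 0, 1]))
        t1 = contribution_ranking(critic, reals, fakes, conditional=False)
        t2 = contribution_ranking(critic, reals[::-1], fakes,
                                  conditional=False)
        assert [e.sample_id for e in t1.entries] == \
               [e.sample_id for e in t2.entries]


def _table(m_per_class):
    entries = [RankEntry(f"{lab}-{i:02d}", lab, float(i))
               for lab in (0, 1) for i in range(m_per_class)]
    return RankingTable(entries)


class TestPartitionRanked:
    def test_eight_per_class_splits_into_exact_quarters(self):
        train, carry, returned = partition_ranked(_table(8))
        assert (len(train), len(carry), len(returned)) == (8, 4, 4)
        # top half trains, per class
        assert sorted(train) == [f"{lab}-{i:02d}" for lab in (0, 1)
                                 for i in range(4)]

    def test_seven_per_class_follows_ceiling_rule(self):
        train, carry, returned = partition_ranked(_table(7))
        assert (len(train), len(carry), len(returned)) == (8, 4, 2)
        for lab in (0, 1):
            assert sum(s.startswith(f"{lab}-") for s in train) == 4
            assert sum(s.startswith(f"{lab}-") for s in carry) == 2
            assert sum(s.startswith(f"{lab}-") for s in returned) == 1

    @given(st.integers(min_value=4, max_value=50))
    def test_three_way_partition_property(self, m):
        train, carry, returned = partition_ranked(_table(m))
        union = train + carry + returned
        assert len(union) == len(set(union)) == 2 * m
        for lab in (0, 1):
            assert sum(s.startswith(f"{lab}-") for s in train) == math.ceil(m / 2)

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            partition_ranked(_table(3))


class TestAssembleLoopBatch:
    def _labels(self, n_per_class):
        ids = {}
        for lab in (0, 1):
            for i in range(n_per_class):
                ids[f"{lab}-{i:02d}"] = lab
        return ids

    def test_first_loop_is_fully_random_balanced_draw(self, rng):
        labels = self._labels(10)
        state = LoopState(database=sorted(labels))
        cfg = LoopConfig(batch_per_class=6)
        assemble_loop_batch(state, cfg, rng, labels)
        assert len(state.selected) == 12
        assert sum(labels[s] for s in state.selected) == 6
        assert len(state.database) == 8

    def test_carryover_is_topped_up_from_database(self, rng):
        labels = self._labels(10)
        carry = ["0-00", "0-01", "1-00", "1-01"]
        state = LoopState(database=sorted(set(labels) - set(carry)),
                          carryover=carry)
        cfg = LoopConfig(batch_per_class=8)
        assemble_loop_batch(state, cfg, rng, labels)
        assert set(carry) <= set(state.selected)
        for lab in (0, 1):
            assert sum(labels[s] == lab for s in state.selected) == 8

    def test_insufficient_database_suggests_smaller_batch(self, rng):
        labels = self._labels(4)
        state = LoopState(database=sorted(labels))
        with pytest.raises(ValueError, match="smaller batch"):
            assemble_loop_batch(state, LoopConfig(batch_per_class=5), rng,
                                labels)


@pytest.fixture(scope="module")
def loop_result(desk_gan, desk_dataset):
    rng = np.random.default_rng(4)
    classifier = Network(build_classifier(2, image_size=40, width=0.25), rng)
    cfg = LoopConfig(batch_per_class=8, classifier_epochs=5,
                     max_loops=5, patience=5, seed=2)
    return run_multiloop(desk_dataset[:32], desk_gan, classifier, cfg,
                         desk_dataset[32:])


class TestRunMultiloop:

    def test_history_and_ledger_cover_each_loop(self, loop_result):
        assert len(loop_result.history) == len(loop_result.ledger) == 5

    def test_pool_ledger_partitions_every_selected_batch(self, loop_result):
        for rec in loop_result.ledger:
            routed = rec["trained"] + rec["carryover"] + rec["returned"]
            assert sorted(routed) == sorted(rec["selected"])
            assert len(set(routed)) == len(routed)

    def test_every_batch_is_class_balanced(self, loop_result, desk_dataset):
        labels = {s.sample_id: s.label for s in desk_dataset}
        for rec in loop_result.ledger:
            n_ab = sum(labels[s] for s in rec["selected"])
            assert n_ab * 2 == len(rec["selected"])

    def test_carryover_feeds_the_next_loop(self, loop_result):
        for prev, nxt in zip(loop_result.ledger, loop_result.ledger[1:]):
            assert set(prev["carryover"]) <= set(nxt["selected"])

    def test_single_loop_budget_gives_single_round(self, desk_gan,
                                                   desk_dataset):
        classifier = Network(build_classifier(2, image_size=40, width=0.25),
                             np.random.default_rng(0))
        cfg = LoopConfig(batch_per_class=4, classifier_epochs=1, max_loops=1,
                         seed=0)
        res = run_multiloop(desk_dataset[:16], desk_gan, classifier, cfg,
                            desk_dataset[16:24])
        assert len(res.history) == 1
        assert not res.converged
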