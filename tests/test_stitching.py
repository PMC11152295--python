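"""Enumeration strategies, least-squares stitches, and space training."""
import numpy as np
import pytest

from octstitch import nn
from octstitch.architecture import build_medvit
from octstitch.specs import ConfigurationError
from octstitch.stitching import (Anchor, StitchTrainConfig,
                                 build_space, enumerate_paired,
                                 enumerate_unpaired,
                                 init_stitch_least_squares, train_stitched,
                                 uniform_config_draws)
from octstitch.training import OCTDataset, PretrainConfig, pretrain


def brute_force_unpaired(len_a, len_b):
    """Bucket construction written out directly."""
    out = []
    for n in range(1, len_a + 1):
        bucket = [j for j in range(1, len_b + 1)
                  if (j - 1) * len_a // len_b == n - 1]
        for j in bucket:
            if j + 1 <= len_b:
                out.append((n, j + 1))
    return sorted(out)


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,expected", [
    (3, [(1, 2), (2, 3)]),
    (1, []),
    (4, [(1, 2), (2, 3), (3, 4)]),
])
def test_paired_enumeration_sliding_window(length, expected):
    assert enumerate_paired(length, length) == expected
    assert len(enumerate_paired(length, length)) == length - 1


def test_paired_requires_equal_lengths():
    with pytest.raises(ConfigurationError, match="unpaired"):
        enumerate_paired(3, 4)


def test_unpaired_five_to_ten_buckets_of_two():
    cands = enumerate_unpaired(5, 10)
    per_front = {}
    for n, m in cands:
        per_front.setdefault(n, []).append(m)
    # each front block covers two back positions; the last loses one to m<=10
    assert {n: len(ms) for n, ms in per_front.items()} == \
        {1: 2, 2: 2, 3: 2, 4: 2, 5: 1}
    assert sorted(cands) == brute_force_unpaired(5, 10)


def test_unpaired_two_to_five_bucket_sizes():
    cands = enumerate_unpaired(2, 5)
    assert sorted(cands) == brute_force_unpaired(2, 5)
    sizes = {}
    for j in range(1, 6):
        sizes.setdefault((j - 1) * 2 // 5 + 1, 0)
        sizes[(j - 1) * 2 // 5 + 1] += 1
    assert sizes == {1: 3, 2: 2}


@pytest.mark.parametrize("la,lb", [(3, 7), (4, 9), (2, 3), (6, 13)])
def test_unpaired_matches_brute_force_bucket_oracle(la, lb):
    assert sorted(enumerate_unpaired(la, lb)) == brute_force_unpaired(la, lb)


def test_equal_length_bucket_rule_degenerates_to_paired():
    for L in (3, 5, 8):
        assert brute_force_unpaired(L, L) == enumerate_paired(L, L)


def test_unpaired_requires_strictly_shallower_front():
    with pytest.raises(ConfigurationError, match="len_a < len_b"):
        enumerate_unpaired(5, 5)


# ---------------------------------------------------------------------------
# Space building and pruning
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def full_anchors():
    return (Anchor(0, build_medvit("micro", seed=0), "micro"),
            Anchor(1, build_medvit("tiny", seed=1), "tiny"))


def test_micro_tiny_space_stagewise_counts(full_anchors):
    space = build_space(*full_anchors, prune=False)
    per_stage = {}
    for cfg in space.configs:
        per_stage[cfg.stage] = per_stage.get(cfg.stage, 0) + 1
    assert per_stage == {1: 2, 2: 3, 3: 9, 4: 2}
    assert len(space) == 16
    assert [c.config_id for c in space.configs] == list(range(16))


def test_pruning_keeps_even_original_indexes(full_anchors):
    raw = build_space(*full_anchors, prune=False)
    pruned = build_space(*full_anchors, prune=True)
    assert len(pruned) == int(np.ceil(len(raw) / 2))
    assert [c.raw_index for c in pruned.configs] == list(range(0, 16, 2))
    assert [c.config_id for c in pruned.configs] == list(range(8))
    # survivors carry the same (n, m) as the raw candidates they came from
    raw_pairs = {c.raw_index: (c.cut_index, c.entry_index)
                 for c in raw.configs}
    for c in pruned.configs:
        assert raw_pairs[c.raw_index] == (c.cut_index, c.entry_index)


def test_eight_candidate_pruning_survivor_indexes():
    kept = [i for i in range(8) if i % 2 == 0]
    assert kept == [0, 2, 4, 6]
    reindexed = list(range(len(kept)))
    assert reindexed == [0, 1, 2, 3]


def test_same_stage_restriction(full_anchors):
    space = build_space(*full_anchors, prune=False)
    front, back = full_anchors
    for cfg in space.configs:
        assert front.model.block_infos[cfg.cut_index - 1].stage == cfg.stage
        assert back.model.block_infos[cfg.entry_index - 1].stage == cfg.stage
        assert back.model.block_infos[cfg.entry_index - 2].stage == cfg.stage


# ---------------------------------------------------------------------------
# Least-squares initialization
# ---------------------------------------------------------------------------

def test_self_stitch_identity_recovery():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(200, 12))
    layer = init_stitch_least_squares(A, A)
    W = layer.conv.weight.data.reshape(12, 12)
    np.testing.assert_allclose(W, np.eye(12), atol=1e-6)
    np.testing.assert_allclose(layer.conv.bias.data, 0.0, atol=1e-6)


def test_planted_solution_recovery():
    rng = np.random.default_rng(1)
    d = 10
    A = rng.normal(size=(10 * d, d))
    W0 = rng.normal(size=(d, d))
    b0 = rng.normal(size=d)
    B = A @ W0 + b0
    layer = init_stitch_least_squares(A, B)
    np.testing.assert_allclose(layer.conv.weight.data.reshape(d, d),
                               W0.T, atol=1e-5)
    np.testing.assert_allclose(layer.conv.bias.data, b0, atol=1e-5)


def test_residual_equals_normal_equations_solution():
    rng = np.random.default_rng(2)
    A = rng.normal(size=(300, 8))
    B = rng.normal(size=(300, 6))
    layer = init_stitch_least_squares(A, B)
    W = layer.conv.weight.data.reshape(6, 8).astype(np.float64)
    b = layer.conv.bias.data.astype(np.float64)
    res = np.linalg.norm(A @ W.T + b - B)
    A1 = np.hstack([A, np.ones((300, 1))])
    sol = np.linalg.solve(A1.T @ A1, A1.T @ B)
    res_ne = np.linalg.norm(A1 @ sol - B)
    assert res == pytest.approx(res_ne, rel=1e-6)


def test_least_squares_optimality_under_perturbation():
    rng = np.random.default_rng(3)
    A = rng.normal(size=(150, 6))
    B = rng.normal(size=(150, 4))
    layer = init_stitch_least_squares(A, B)
    W = layer.conv.weight.data.reshape(4, 6).astype(np.float64)
    b = layer.conv.bias.data.astype(np.float64)
    base = np.linalg.norm(A @ W.T + b - B)
    for _ in range(100):
        dW = rng.normal(size=W.shape) * 1e-2
        db = rng.normal(size=b.shape) * 1e-2
        perturbed = np.linalg.norm(A @ (W + dW).T + (b + db) - B)
        assert perturbed >= base - 1e-9


def test_rank_deficiency_warns_and_token_mismatch_errors():
    A = np.zeros((50, 4))
    A[:, 0] = np.arange(50)
    with pytest.warns(RuntimeWarning, match="rank"):
        init_stitch_least_squares(A, np.random.default_rng(0).normal(
            size=(50, 3)))
    with pytest.raises(ValueError, match="token count"):
        init_stitch_least_squares(np.zeros((10, 4)), np.zeros((12, 4)))


# ---------------------------------------------------------------------------
# Stitched execution
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def identical_reduced_anchors():
    return (Anchor(0, build_medvit("reduced-micro", seed=3), "a"),
            Anchor(1, build_medvit("reduced-micro", seed=3), "b"))


def test_self_stitch_equivalence_at_every_cut(identical_reduced_anchors):
    """Identity-initialized stitches between two copies of one model must
    reproduce the unstitched outputs at every enumerated cut."""
    front, back = identical_reduced_anchors
    space = build_space(front, back, prune=False)
    front.model.eval()
    back.model.eval()
    x = np.random.default_rng(0).random((2, 3, 32, 32)).astype(np.float32)
    with nn.no_grad():
        ref = back.model(x).data
    assert len(space) > 0
    for cfg in space.configs:
        assert cfg.entry_index == cfg.cut_index + 1   # paired windows
        cfg.stitch.set_identity()
        with nn.no_grad():
            out = space(x, cfg.config_id).data
        np.testing.assert_allclose(out, ref, atol=1e-5)


def test_every_config_in_reduced_space_is_runnable():
    front = Anchor(0, build_medvit("reduced-micro", seed=0), "rm")
    back = Anchor(1, build_medvit("reduced-tiny", seed=1), "rt")
    for prune in (False, True):
        space = build_space(front, back, prune=prune)
        rng = np.random.default_rng(0)
        space.initialize_stitches(
            rng.random((16, 32, 32)).astype(np.float32), batch_size=16)
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        front.model.eval(), back.model.eval()
        for cfg in space.configs:
            with nn.no_grad():
                out = space(x, cfg.config_id)
            assert out.shape == (2, 3)


def test_uninitialized_stitch_raises(identical_reduced_anchors):
    space = build_space(*identical_reduced_anchors, prune=False)
    x = np.zeros((1, 3, 32, 32), dtype=np.float32)
    with pytest.raises(ConfigurationError, match="not initialized"):
        space(x, 0)


def test_stitched_parameter_accounting():
    """Assembled-network count equals front prefix + stitch + back suffix
    summed module by module in the test itself."""
    front = Anchor(0, build_medvit("reduced-micro", seed=0), "rm")
    back = Anchor(1, build_medvit("reduced-tiny", seed=1), "rt")
    space = build_space(front, back, prune=True)
    fm, bm = front.model, back.model
    for cfg in space.configs:
        n, m = cfg.cut_index, cfg.entry_index
        expected = sum(p.data.size for p in fm.stem.parameters())
        fstage = fm.block_infos[n - 1].stage
        for si in range(fstage):
            expected += sum(p.data.size for p in fm.embeds[si].parameters())
        for blk in fm.blocks[:n]:
            expected += sum(p.data.size for p in blk.parameters())
        expected += (cfg.stitch.in_channels + 1) * cfg.stitch.out_channels
        bstage = bm.block_infos[m - 1].stage
        for blk in bm.blocks[m - 1:]:
            expected += sum(p.data.size for p in blk.parameters())
        for si in range(bstage, 4):
            expected += sum(p.data.size for p in bm.embeds[si].parameters())
        expected += sum(p.data.size for p in bm.head_norm.parameters())
        expected += sum(p.data.size for p in bm.head.parameters())
        assert space.stitched_parameter_count(cfg.config_id) == expected


def test_manifest_lists_every_config():
    front = Anchor(0, build_medvit("reduced-micro", seed=0), "rm")
    back = Anchor(1, build_medvit("reduced-tiny", seed=1), "rt")
    space = build_space(front, back, prune=True)
    mf = space.manifest()
    assert list(mf["config_id"]) == list(range(len(space)))
    assert {"stage", "cut_index", "entry_index", "stitch_in", "stitch_out",
            "params", "params_millions"} <= set(mf.columns)


# ---------------------------------------------------------------------------
# Random-path training
# ---------------------------------------------------------------------------

def test_uniform_config_selection_fractions():
    rng = np.random.default_rng(123)
    draws = uniform_config_draws(5, 10_000, rng)
    fractions = np.bincount(draws, minlength=5) / 10_000
    np.testing.assert_allclose(fractions, 0.2, atol=0.01)


def _toy_space(dataset, seed=0):
    pc = PretrainConfig.toy(seed=seed, epochs=1)
    f = pretrain("reduced-micro", dataset, pc)
    b = pretrain("reduced-tiny", dataset, pc)
    space = build_space(Anchor(0, f.model), Anchor(1, b.model), prune=True)
    space.initialize_stitches(dataset.images[:64], batch_size=64)
    return space


def test_training_is_bitwise_reproducible(toy_dataset_32):
    weights = []
    for _ in range(2):
        space = _toy_space(toy_dataset_32, seed=4)
        train_stitched(space, toy_dataset_32,
                       StitchTrainConfig.toy(seed=4, iterations=8))
        weights.append([s.conv.weight.data.copy() for s in space.stitches])
    for a, b in zip(*weights):
        np.testing.assert_array_equal(a, b)


def test_single_config_space_trains_monotonically(toy_dataset_32):
    from octstitch.training import prepare_batch

    space = _toy_space(toy_dataset_32, seed=1)
    space.configs = space.configs[:1]
    space.stitches = space.stitches[:1]
    single = OCTDataset(toy_dataset_32.images[:32],
                        toy_dataset_32.labels[:32],
                        class_names=toy_dataset_32.class_names)
    xb = prepare_batch(single.images)
    losses = []
    for _ in range(50):
        log = train_stitched(space, single,
                             StitchTrainConfig(iterations=1, lr=1e-4,
                                               batch_size=32, seed=0))
        assert log[0]["config_id"] == 0
        losses.append(log[0]["loss"])
    # full-batch steps at a small rate: the fixed-batch loss decreases
    assert losses[-1] < losses[0]
    increases = np.diff(losses)
    assert (increases > 1e-3).sum() <= 2


def test_empty_space_and_off_path_parameters(toy_dataset_32):
    space = _toy_space(toy_dataset_32, seed=2)
    before = {cid: s.conv.weight.data.copy()
              for cid, s in enumerate(space.stitches)}
    log = train_stitched(space, toy_dataset_32,
                         StitchTrainConfig.toy(seed=0, iterations=3))
    touched = {row["config_id"] for row in log}
    for cid, s in enumerate(space.stitches):
        moved = not np.array_equal(before[cid], s.conv.weight.data)
        assert moved == (cid in touched)
    space.configs = []
    space.stitches = []
    with pytest.raises(ConfigurationError, match="empty"):
        train_stitched(space, toy_dataset_32, StitchTrainConfig.toy())


def test_freeze_anchors_only_updates_stitches(toy_dataset_32):
    space = _toy_space(toy_dataset_32, seed=3)
    anchor_before = space.front_model.state_dict()
    train_stitched(space, toy_dataset_32,
                   StitchTrainConfig.toy(seed=0, iterations=4,
                                         freeze_anchors=True))
    after = space.front_model.state_dict()
    for k in anchor_before:
        if not k.startswith("running_") and "running_" not in k:
            np.testing.assert_array_equal(anchor_before[k], after[k])
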