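import numpy as np
import pytest

from pentrack.io import TrajectorySet
from pentrack.postprocess import (
    AFLinkModel,
    _cut_pairs,
    _pair_vector,
    aflink_associate,
    aflink_features,
    aflink_train,
    gsi_correct,
    gsi_smooth,
)
from pentrack.simulate import SimConfig, simulate_pen
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler


def _linear_track(frames, vx=2.0, vy=0.5, x0=100.0, y0=50.0, w=20.0, h=14.0):
    return {
        f: (x0 + vx * f - w / 2, y0 + vy * f - h / 2, w, h) for f in frames
    }


def _centers(traj):
    return {f: (b[0] + b[2] / 2, b[1] + b[3] / 2) for f, b in traj.items()}


# ---------------------------------------------------------------------------
# GSI
# ---------------------------------------------------------------------------

def test_gsi_fills_gap_on_linear_track():
    frames = list(range(1, 51)) + list(range(61, 101))
    traj = _linear_track(frames)
    out = gsi_smooth(traj, length_scale=10.0, max_gap=30)
    truth = _centers(_linear_track(range(1, 101)))
    got = _centers(out)
    assert set(out) == set(range(1, 101))
    gap_err = [np.hypot(got[f][0] - truth[f][0], got[f][1] - truth[f][1]) for f in range(51, 61)]
    assert np.sqrt(np.mean(np.square(gap_err))) < 1.0


def test_gsi_near_identity_on_clean_track():
    traj = _linear_track(range(40))
    out = gsi_smooth(traj, length_scale=5.0)
    err = [
        np.hypot(a[0] - b[0], a[1] - b[1])
        for a, b in zip(_centers(traj).values(), _centers(out).values())
    ]
    assert np.sqrt(np.mean(np.square(err))) < 0.1


def test_gsi_respects_max_gap():
    frames = list(range(10)) + list(range(30, 40))
    out = gsi_smooth(_linear_track(frames), max_gap=5)
    assert set(out) == set(frames)  # the 20-frame hole stays open


def test_gsi_idempotent_within_tolerance():
    frames = list(range(0, 60, 1))
    rng = np.random.default_rng(1)
    traj = {
        f: (100 + 2 * f + rng.normal(0, 1.0), 50 + rng.normal(0, 1.0), 20.0, 14.0)
        for f in frames
    }
    once = gsi_smooth(traj, length_scale=10.0)
    twice = gsi_smooth(once, length_scale=10.0)
    deltas = [
        np.hypot(a[0] - b[0], a[1] - b[1])
        for a, b in zip(_centers(once).values(), _centers(twice).values())
    ]
    assert max(deltas) < 0.1


def test_gsi_single_point_unchanged():
    traj = {5: (0.0, 0.0, 10.0, 10.0)}
    assert gsi_smooth(traj) == traj


def test_gsi_correct_preserves_ids(noisy_scenario):
    ts = TrajectorySet(fps=25)
    for f in range(0, 100):
        if not 40 <= f < 50:
            ts.add(1, f, (f * 2.0, 0.0, 20.0, 14.0))
            ts.add(2, f, (f * 2.0, 300.0, 20.0, 14.0))
    out = gsi_correct(ts, max_gap=30)
    assert out.ids == ts.ids
    assert set(out.frames_of(1)) == set(range(100))


# ---------------------------------------------------------------------------
# tracklet linking
# ---------------------------------------------------------------------------

def test_aflink_features_padding_and_shape():
    left = _linear_track(range(10))
    right = _linear_track(range(12, 30))
    tail, head, deltas = aflink_features(left, right)
    assert tail.shape == (30, 3) and head.shape == (30, 3)
    assert int((tail == 0).all(axis=1).sum()) == 20  # 10-frame track -> 20 zero rows
    assert int((head == 0).all(axis=1).sum()) == 12
    assert deltas[0] == 3  # frame gap 12 - 9


def test_aflink_features_takes_nearest_30():
    left = _linear_track(range(100))
    right = _linear_track(range(101, 200))
    tail, head, deltas = aflink_features(left, right)
    assert not (tail == 0).all(axis=1).any()
    assert tail[-1, 0] == 99 and tail[0, 0] == 70  # nearest 30 frames of the tail
    assert head[0, 0] == 101 and head[-1, 0] == 130
    assert deltas[0] == 2


def test_aflink_features_contiguous_split_deltas():
    track = _linear_track(range(100), vx=3.0, vy=-1.0)
    left = {f: track[f] for f in range(50)}
    right = {f: track[f] for f in range(50, 100)}
    _, _, deltas = aflink_features(left, right)
    assert deltas[0] == 1
    assert deltas[1] == pytest.approx(3.0)
    assert deltas[2] == pytest.approx(-1.0)


def test_aflink_features_rejects_overlap():
    a = _linear_track(range(10))
    b = _linear_track(range(5, 15))
    with pytest.raises(ValueError, match="overlap"):
        aflink_features(a, b)


@pytest.fixture(scope="module")
def link_model():
    scenarios = [simulate_pen(SimConfig(seed=s, duration=90.0)) for s in (20, 21)]
    return aflink_train(scenarios, seed=5, pairs_per_id=25), scenarios


def test_aflink_training_reaches_heldout_accuracy(link_model):
    model, _ = link_model
    assert model.heldout_accuracy >= 0.9


def test_aflink_training_deterministic():
    scenarios = [simulate_pen(SimConfig(seed=30, duration=90.0))]
    a = aflink_train(scenarios, seed=9, pairs_per_id=10)
    b = aflink_train(scenarios, seed=9, pairs_per_id=10)
    assert np.allclose(a.classifier.coefs_[0], b.classifier.coefs_[0])


def test_aflink_permuted_labels_score_at_chance():
    rng = np.random.default_rng(3)
    scenarios = [simulate_pen(SimConfig(seed=s, duration=120.0)) for s in (40, 41)]
    X, y = [], []
    for sc in scenarios:
        pos, neg = _cut_pairs(sc, rng, 60)
        for left, right in pos:
            X.append(_pair_vector(*aflink_features(left, right)))
            y.append(1)
        for left, right in neg:
            X.append(_pair_vector(*aflink_features(left, right)))
            y.append(0)
    X, y = np.asarray(X), np.asarray(y)
    y = rng.permutation(y)  # destroy the signal
    n_hold = len(X) // 4
    scaler = StandardScaler().fit(X[n_hold:])
    clf = MLPClassifier(hidden_layer_sizes=(32, 16), max_iter=500, random_state=0, solver="lbfgs")
    clf.fit(scaler.transform(X[n_hold:]), y[n_hold:])
    acc = clf.score(scaler.transform(X[:n_hold]), y[:n_hold])
    assert abs(acc - 0.5) <= 0.07


def test_aflink_training_needs_enough_pairs():
    tiny = simulate_pen(SimConfig(seed=1, duration=2.0))
    with pytest.raises(ValueError, match="too few"):
        aflink_train([tiny], seed=0, pairs_per_id=0)


def test_aflink_merges_forced_fragmentation(link_model):
    model, scenarios = link_model
    sc = scenarios[0]
    # split ground-truth id 1 into two fragments with a 5-frame gap
    frag = TrajectorySet(fps=sc.config.fps)
    for tid in sc.gt.ids:
        for f, b in sc.gt.trajectory(tid).items():
            if tid == 1 and f >= 800:
                frag.add(90, f, b)  # second fragment under a fresh id
            elif tid == 1 and f >= 795:
                continue
            else:
                frag.add(tid, f, b)
    linked = aflink_associate(frag, model)
    assert len(linked) <= len(frag)
    assert 1 in linked.ids and 90 not in linked.ids
    assert set(linked.frames_of(1)) == set(
        f for f in sc.gt.frames_of(1) if not 795 <= f < 800
    )


def test_aflink_gap_constraint_blocks_links(link_model):
    model, scenarios = link_model
    sc = scenarios[0]
    frag = TrajectorySet(fps=sc.config.fps)
    for f, b in sc.gt.trajectory(1).items():
        if f < 500:
            frag.add(1, f, b)
        elif f >= 600:
            frag.add(2, f, b)
    linked = aflink_associate(frag, model, max_gap=30)
    assert linked.ids == [1, 2]  # 100-frame gap exceeds the constraint


def test_aflink_empty_and_id_count_invariant(link_model):
    model, _ = link_model
    empty = TrajectorySet()
    assert len(aflink_associate(empty, model)) == 0


def test_aflink_model_round_trip(tmp_path, link_model):
    model, _ = link_model
    p = tmp_path / "model.pkl"
    model.save(str(p))
    back = AFLinkModel.load(str(p))
    assert back.heldout_accuracy == model.heldout_accuracy
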