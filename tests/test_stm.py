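"""Unit and property tests for the topological-map core."""

import numpy as np
import pytest

from stmalign import stm


def line_map(prototypes, sigma_r=1.0, sigma_t=1.5):
    """A degenerate 1-D map laid out along the x axis of the grid."""
    protos = np.asarray(prototypes, dtype=float).reshape(len(prototypes), -1)
    grid = np.stack(
        [np.arange(len(protos)), np.zeros(len(protos))], axis=1
    )
    return stm.TopologicalMap(
        prototypes=protos,
        grid_positions=grid,
        sigma_r=sigma_r,
        sigma_t=sigma_t,
        modality_tag="visual",
    )


# -- independent brute-force oracles ----------------------------------------

def brute_winner(pattern, tm):
    best, best_d = 0, np.inf
    for j in range(tm.n_nodes):
        d = np.sqrt(np.sum((tm.prototypes[j] - pattern) ** 2))
        if d < best_d:
            best, best_d = j, d
    return best


def brute_weights(winner, anchor, tm):
    out = np.zeros(tm.n_nodes)
    for j in range(tm.n_nodes):
        d2 = np.sum((tm.grid_positions[j] - tm.grid_positions[winner]) ** 2)
        w = np.exp(-d2 / (2 * tm.sigma_r**2))
        if anchor is not None:
            a2 = np.sum((tm.grid_positions[j] - anchor) ** 2)
            w *= np.exp(-a2 / (2 * tm.sigma_t**2))
        out[j] = w
    return out


def brute_loss(patterns, anchors, tm):
    total = 0.0
    for i, x in enumerate(patterns):
        wi = brute_winner(x, tm)
        phi = brute_weights(wi, None if anchors is None else anchors[i], tm)
        for j in range(tm.n_nodes):
            total += phi[j] * np.sum((x - tm.prototypes[j]) ** 2)
    return 0.5 * total


def brute_forward_point(pattern, tm):
    wi = brute_winner(pattern, tm)
    num, den = np.zeros(2), 0.0
    for j in range(tm.n_nodes):
        d2 = np.sum((tm.grid_positions[j] - tm.grid_positions[wi]) ** 2)
        a = np.exp(-d2 / (2 * tm.sigma_r**2))
        if a < stm.ACTIVATION_FLOOR:
            a = 0.0
        num += a * tm.grid_positions[j]
        den += a
    return num / den


# -- winner selection --------------------------------------------------------

def test_winner_exact_prototype_match(rng):
    tm = stm.new_map(4, 6, rng)
    assert stm.find_winner(tm.prototypes[7], tm) == 7


@pytest.mark.parametrize(
    "prototypes,pattern,expected",
    [([0.0, 1.0, 2.0], 1.4, 1), ([0.0, 2.0], 1.0, 0)],
)
def test_winner_1d_scan_and_tiebreak(prototypes, pattern, expected):
    tm = line_map(prototypes)
    assert stm.find_winner(np.array([pattern]), tm) == expected


def test_winner_rejects_bad_patterns(rng):
    tm = stm.new_map(3, 4, rng)
    with pytest.raises(ValueError):
        stm.find_winner(np.zeros(5), tm)
    with pytest.raises(ValueError):
        stm.find_winner(np.array([np.nan, 0, 0, 0]), tm)


# -- neighborhood weights ----------------------------------------------------

def test_weights_anchor_at_winner_gives_unit_weight(rng):
    tm = stm.new_map(4, 3, rng, sigma_r=1.2)
    phi = stm.neighborhood_weights(5, tm.grid_positions[5], tm)
    assert phi[5] == pytest.approx(1.0)
    assert np.all(phi > 0) and np.all(phi <= 1)


def test_weights_wide_anchor_reduces_to_unsupervised(rng):
    tm = stm.new_map(4, 3, rng, sigma_r=1.2, sigma_t=1e9)
    anchored = stm.neighborhood_weights(3, np.array([0.0, 0.0]), tm)
    free = stm.neighborhood_weights(3, None, tm)
    np.testing.assert_allclose(anchored, free, atol=1e-12)


def test_weights_1d_grid_values():
    tm = line_map([0.0, 1.0, 2.0], sigma_r=1.0)
    phi = stm.neighborhood_weights(0, None, tm)
    np.testing.assert_allclose(
        phi, [1.0, np.exp(-0.5), np.exp(-2.0)], rtol=1e-12
    )


def test_weights_reject_bad_sigma(rng):
    with pytest.raises(ValueError):
        stm.new_map(3, 2, rng, sigma_r=-1.0)


# -- loss --------------------------------------------------------------------

def test_loss_zero_for_perfectly_quantized_data():
    tm = line_map([0.25, 0.25, 0.25])
    patterns = np.full((6, 1), 0.25)
    assert stm.stm_loss(patterns, None, tm) == pytest.approx(0.0, abs=1e-15)


def test_loss_rejects_empty():
    tm = line_map([0.0, 1.0])
    with pytest.raises(ValueError):
        stm.stm_loss(np.empty((0, 1)), None, tm)


def test_loss_quadratic_in_residuals(rng):
    # single node: phi == 1 regardless of the pattern, so scaling the
    # residuals by 2 must scale the loss by 4 exactly
    tm = stm.TopologicalMap(
        prototypes=np.array([[0.5, 0.5]]),
        grid_positions=np.array([[0.0, 0.0]]),
        sigma_r=1.0,
        sigma_t=1.0,
    )
    r = rng.normal(size=(10, 2))
    l1 = stm.stm_loss(tm.prototypes[0] + r, None, tm)
    l2 = stm.stm_loss(tm.prototypes[0] + 2 * r, None, tm)
    assert l2 == pytest.approx(4 * l1, rel=1e-10)


# -- oracle equivalence (acceptance-grade battery lives in test_acceptance) --

def test_core_operations_match_bruteforce(rng):
    for _ in range(25):
        g = int(rng.integers(2, 5))
        d = int(rng.integers(1, 6))
        tm = stm.new_map(g, d, rng, sigma_r=float(rng.uniform(0.3, 2.0)))
        x = rng.normal(size=d)
        assert stm.find_winner(x, tm) == brute_winner(x, tm)
        anchor = rng.uniform(0, g - 1, size=2)
        np.testing.assert_allclose(
            stm.neighborhood_weights(0, anchor, tm),
            brute_weights(0, anchor, tm),
            atol=1e-12,
        )
        pats = rng.normal(size=(5, d))
        anchors = rng.uniform(0, g - 1, size=(5, 2))
        assert stm.stm_loss(pats, anchors, tm) == pytest.approx(
            brute_loss(pats, anchors, tm), rel=1e-10
        )
        np.testing.assert_allclose(
            stm.forward_map(x, tm).point, brute_forward_point(x, tm),
            atol=1e-12,
        )


# -- updates -----------------------------------------------------------------

def test_update_eta_zero_is_identity(rng):
    tm = stm.new_map(3, 4, rng)
    out = stm.update_map(tm, rng.normal(size=(5, 4)), None, np.ones(5), 0.0)
    assert np.array_equal(out.prototypes, tm.prototypes)


def test_update_full_step_moves_winner_onto_pattern(rng):
    tm = stm.new_map(3, 4, rng, sigma_r=0.5)
    x = tm.prototypes[4] + 0.05
    out = stm.update_map(tm, x[None, :], None, np.ones(1), 1.0)
    np.testing.assert_allclose(out.prototypes[4], x, atol=1e-12)


def test_update_zero_weights_is_identity(rng):
    tm = stm.new_map(3, 4, rng)
    out = stm.update_map(tm, rng.normal(size=(5, 4)), None, np.zeros(5), 0.5)
    assert np.array_equal(out.prototypes, tm.prototypes)


def test_update_rejects_invalid_inputs(rng):
    tm = stm.new_map(3, 2, rng)
    pats = rng.normal(size=(2, 2))
    with pytest.raises(ValueError):
        stm.update_map(tm, pats, None, np.ones(2), -0.1)
    with pytest.raises(ValueError):
        stm.update_map(tm, pats, None, np.array([0.5, 1.5]), 0.1)


# -- forward / inverse mapping ----------------------------------------------

def test_forward_point_collapses_to_winner_at_small_sigma(rng):
    tm = stm.new_map(6, 8, rng, sigma_r=0.15)
    j = stm.find_winner(tm.prototypes[21], tm)
    res = stm.forward_map(tm.prototypes[21], tm)
    assert j == 21
    assert np.linalg.norm(res.point - tm.grid_positions[21]) < 0.05
    assert res.activation.max() == pytest.approx(1.0)
    assert int(np.argmax(res.activation)) == 21


def test_inverse_on_node_returns_prototype(rng):
    tm = stm.new_map(5, 7, rng, sigma_r=0.15)
    for j in (0, 7, 24):
        pat = stm.inverse_map(tm.grid_positions[j], tm)
        np.testing.assert_allclose(pat, tm.prototypes[j], rtol=1e-3)


def test_inverse_midpoint_blends_two_prototypes():
    tm = line_map([[0.0, 1.0], [2.0, 5.0], [10.0, -3.0]], sigma_r=0.15)
    pat = stm.inverse_map(np.array([0.5, 0.0]), tm)
    np.testing.assert_allclose(
        pat, 0.5 * (tm.prototypes[0] + tm.prototypes[1]), rtol=1e-3
    )


def test_forward_inverse_roundtrip_all_nodes(rng):
    # well-separated prototypes: every node re-enacts to a pattern that
    # forward-maps back to itself
    g = 6
    tm = stm.new_map(g, 10, rng, sigma_r=0.4)
    tm.prototypes[:] = 5.0 * rng.normal(size=tm.prototypes.shape)
    for j in range(g * g):
        pat = stm.inverse_map(tm.grid_positions[j], tm)
        assert stm.find_winner(pat, tm) == j


def test_inverse_rejects_out_of_bounds(rng):
    tm = stm.new_map(4, 3, rng)
    with pytest.raises(ValueError):
        stm.inverse_map(np.array([5.0, 0.0]), tm)


def test_batch_forward_matches_single(rng):
    tm = stm.new_map(5, 6, rng, sigma_r=0.9)
    pats = rng.normal(size=(20, 6))
    points, winners = stm.forward_map_batch(pats, tm)
    for i in range(20):
        single = stm.forward_map(pats[i], tm)
        assert winners[i] == single.winner
        np.testing.assert_allclose(points[i], single.point, atol=1e-12)


# -- training behaviour ------------------------------------------------------

def quantization_error(tm, pats):
    _, winners = stm.forward_map_batch(pats, tm)
    return float(
        np.mean(np.linalg.norm(pats - tm.prototypes[winners], axis=1))
    )


def test_unsupervised_som_reduces_quantization_error(rng):
    pats = rng.uniform(size=(500, 2))
    tm = stm.new_map(6, 2, rng)
    # small random init away from the data bulk, so the error starts
    # well above the K-prototype quantization floor
    tm.prototypes[:] = 0.05 * rng.uniform(size=tm.prototypes.shape)
    e0 = quantization_error(tm, pats)
    epochs = 30
    for epoch in range(epochs):
        sig = stm.anneal_sigma_r(epoch, epochs, 3.0, 0.8)
        tm = stm.update_map(
            tm.with_sigma_r(sig), pats, None, np.ones(500), 0.5
        )
    assert quantization_error(tm, pats) < 0.5 * e0


def make_anchored_fixture(rng, n=200, n_classes=5, dim=8, g=6):
    """Patterns in well-separated class blobs; each class is assigned a
    fixed anchor position in the internal space."""
    centers = rng.uniform(0, 1, size=(n_classes, dim))
    anchor_pos = np.array(
        [[0.0, 0.0], [0.0, 5.0], [5.0, 0.0], [5.0, 5.0], [2.5, 2.5]]
    )[:n_classes]
    labels = rng.integers(0, n_classes, size=n)
    pats = centers[labels] + 0.03 * rng.normal(size=(n, dim))
    anchors = anchor_pos[labels]
    return pats, anchors, labels


def train_stm(tm, pats, anchors, epochs=30, eta=0.5):
    for epoch in range(epochs):
        sig = stm.anneal_sigma_r(epoch, epochs, tm.grid_size / 2.0, 0.8)
        tm = stm.update_map(
            tm.with_sigma_r(sig), pats, anchors, np.ones(len(pats)), eta
        )
    return tm


def test_anchoring_pulls_winners_to_anchors(rng):
    pats, anchors, _ = make_anchored_fixture(rng)
    tm = train_stm(stm.new_map(6, 8, rng), pats, anchors)
    _, winners = stm.forward_map_batch(pats, tm)
    d = np.linalg.norm(tm.grid_positions[winners] - anchors, axis=1)
    assert np.mean(d <= 1.5) >= 0.9


def test_scaler_roundtrip_and_bounds(rng):
    sc = stm.RunningScaler(3)
    data = rng.normal(2.0, 5.0, size=(100, 3))
    sc.update(data)
    z = sc.transform(data)
    assert z.min() >= 0.0 and z.max() <= 1.0
    np.testing.assert_allclose(sc.inverse_transform(z), data, rtol=1e-10)


def test_map_save_load_roundtrip(tmp_path, rng):
    tm = stm.new_map(4, 5, rng, modality_tag="touch")
    stm.save_map(tm, tmp_path / "m.npz", epoch=7)
    back = stm.load_map(tmp_path / "m.npz")
    np.testing.assert_array_equal(back.prototypes, tm.prototypes)
    assert back.modality_tag == "touch"
    assert back.sigma_r == tm.sigma_r
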