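import numpy as np
import pytest

from difflux.tfbs import (TFBSResult, TFBSSignalMatrix, average_signal_profile,
                          binding_heatmap_table, read_signal_track,
                          tfbs_overrepresentation, write_signal_track)


def constant_matrix(n_genes=10, n_bins=4, values=None):
    universe = [f"g{i}" for i in range(n_genes)]
    positions = np.linspace(-1000, 1000, n_bins, endpoint=False)
    if values is None:
        values = np.ones(n_genes)
    track = np.tile(np.asarray(values, dtype=float)[:, None], (1, n_bins))
    return TFBSSignalMatrix(universe, positions, {"TF": track})


def test_average_profile_is_per_bin_mean():
    m = constant_matrix(values=[1.0, 3.0] + [5.0] * 8)
    profile = average_signal_profile(m, "TF", ["g0", "g1"])
    assert profile == pytest.approx([2.0] * 4)


def test_single_gene_profile_is_its_row():
    m = constant_matrix(values=np.arange(10, dtype=float))
    assert average_signal_profile(m, "TF", ["g3"]) == pytest.approx([3.0] * 4)


def test_universe_profile_equals_universe_mean():
    m = constant_matrix(values=np.arange(10, dtype=float))
    assert average_signal_profile(m, "TF", m.universe) == pytest.approx(
        m.tracks["TF"].mean(axis=0))


def test_unknown_gene_named_in_error():
    m = constant_matrix()
    with pytest.raises(ValueError, match="ghost"):
        average_signal_profile(m, "TF", ["ghost"])


def test_identical_signal_gives_p_one():
    m = constant_matrix(n_genes=20)
    (res,) = tfbs_overrepresentation(m, ["g0", "g1", "g2"], B=99, seed=1)
    assert res.p_empirical == 1.0


def test_top_k_list_achieves_minimal_p():
    rng = np.random.default_rng(3)
    n = 50
    sums = np.arange(1.0, n + 1.0)  # strictly increasing, ties impossible
    rng.shuffle(sums)
    universe = [f"g{i}" for i in range(n)]
    track = np.tile(sums[:, None] / 4.0, (1, 4))
    m = TFBSSignalMatrix(universe, np.arange(4.0), {"TF": track})
    top5 = [universe[i] for i in np.argsort(sums)[-5:]]
    (res,) = tfbs_overrepresentation(m, top5, B=999, seed=11)
    assert res.p_empirical == pytest.approx(1 / 1000)
    assert res.p_bonferroni == pytest.approx(1 / 1000)  # single track


def test_determinism_and_seed_sensitivity():
    rng = np.random.default_rng(8)
    track = rng.lognormal(size=(30, 5))
    m = TFBSSignalMatrix([f"g{i}" for i in range(30)], np.arange(5.0),
                         {"TF": track.copy()})
    lst = ["g0", "g5", "g7"]
    a = tfbs_overrepresentation(m, lst, B=199, seed=4)[0].p_empirical
    b = tfbs_overrepresentation(m, lst, B=199, seed=4)[0].p_empirical
    assert a == b


def test_constant_shift_leaves_p_unchanged():
    rng = np.random.default_rng(9)
    track = rng.lognormal(size=(40, 6))
    universe = [f"g{i}" for i in range(40)]
    lst = universe[:4]
    m1 = TFBSSignalMatrix(universe, np.arange(6.0), {"TF": track.copy()})
    m2 = TFBSSignalMatrix(universe, np.arange(6.0), {"TF": track + 7.5})
    p1 = tfbs_overrepresentation(m1, lst, B=299, seed=2)[0].p_empirical
    p2 = tfbs_overrepresentation(m2, lst, B=299, seed=2)[0].p_empirical
    assert p1 == p2


def test_bonferroni_scales_with_track_count():
    rng = np.random.default_rng(10)
    universe = [f"g{i}" for i in range(30)]
    tracks = {f"TF{j}": rng.lognormal(size=(30, 4)) for j in range(3)}
    m = TFBSSignalMatrix(universe, np.arange(4.0), tracks)
    for res in tfbs_overrepresentation(m, universe[:3], B=99, seed=0):
        assert res.p_bonferroni == min(1.0, res.p_empirical * 3)


@pytest.mark.parametrize("call,match", [
    (dict(gene_list=["g0"], B=10), "at least 2"),
    (dict(gene_list=["g0", "g1"], B=0), "B must be"),
    (dict(gene_list=["g0", "g0"], B=10), "duplicates"),
    (dict(gene_list=["g0", "nope"], B=10), "not in universe"),
])
def test_overrepresentation_input_validation(call, match):
    m = constant_matrix()
    with pytest.raises(ValueError, match=match):
        tfbs_overrepresentation(m, call["gene_list"], B=call["B"], seed=0)


def test_list_must_be_smaller_than_universe():
    m = constant_matrix(n_genes=3)
    with pytest.raises(ValueError, match="strictly larger"):
        tfbs_overrepresentation(m, m.universe, B=10, seed=0)


def test_fixed_background_mode_is_deterministic():
    rng = np.random.default_rng(12)
    m = TFBSSignalMatrix([f"g{i}" for i in range(100)], np.arange(4.0),
                         {"TF": rng.lognormal(size=(100, 4))})
    kw = dict(B=99, seed=5, background="fixed", n_background=50)
    a = tfbs_overrepresentation(m, m.universe[:5], **kw)[0]
    b = tfbs_overrepresentation(m, m.universe[:5], **kw)[0]
    assert a.p_empirical == b.p_empirical


def fake_result(tf, stat, p_bonf):
    return TFBSResult(tf, 5, stat, 1.0, p_bonf, p_bonf, 999, 0)


def test_heatmap_single_significant_tf_scales_to_one():
    table = binding_heatmap_table([fake_result("A", 2.0, 0.001)])
    assert table.set_index("tf").loc["A", "normalized_signal"] == 1.0


def test_heatmap_nonsignificant_assigned_zero():
    table = binding_heatmap_table([fake_result("A", 2.0, 0.2),
                                   fake_result("B", 9.0, 0.9)])
    assert (table["normalized_signal"] == 0.0).all()


def test_heatmap_max_scaling_between_significant_tfs():
    table = binding_heatmap_table([fake_result("A", 2.0, 0.001),
                                   fake_result("B", 4.0, 0.001)]).set_index("tf")
    assert table.loc["A", "normalized_signal"] == 0.5
    assert table.loc["B", "normalized_signal"] == 1.0


def test_signal_track_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(2)
    genes = [f"g{i}" for i in range(6)]
    positions = np.linspace(-1000, 1000, 8, endpoint=False)
    mat = rng.lognormal(size=(6, 8))
    path = write_signal_track(tmp_path / "TF.tsv", genes, positions, mat)
    g2, p2, m2 = read_signal_track(path)
    assert g2 == genes
    assert p2 == pytest.approx(positions)
    assert m2 == pytest.approx(mat, rel=1e-12)
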