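import math

import numpy as np
import pytest

from difflux.expression import reaction_fold_changes
from difflux.gpr import gpr_genes
from difflux.synthetic import (SyntheticSpec, make_expression, make_tfbs_signal,
                               make_toy_model)


def test_model_structure_counts():
    model = make_toy_model(SyntheticSpec(n_pathways=2, reactions_per_pathway=3, seed=0))
    internal = [r for r in model.reactions if r.subsystem != "exchange"]
    exchanges = [r for r in model.reactions if r.subsystem == "exchange"]
    assert len(internal) == 6
    assert {r.subsystem for r in internal} == {"pathway_00", "pathway_01"}
    # per pathway: uptake + secretion + feed/leak pair per intermediate
    assert len(exchanges) == 2 * (2 + 2 * 2)
    assert all(r.gpr is not None for r in internal)
    assert all(r.gpr is None for r in exchanges)


def test_same_seed_reproduces_model_exactly():
    spec = SyntheticSpec(seed=42)
    a, b = make_toy_model(spec), make_toy_model(spec)
    assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
    for ra, rb in zip(a.reactions, b.reactions):
        assert ra.stoichiometry == rb.stoichiometry
        assert (ra.lower_bound, ra.upper_bound) == (rb.lower_bound, rb.upper_bound)
        assert ra.enzyme == rb.enzyme


def test_enzyme_layer_annotates_every_internal_reaction():
    model = make_toy_model(SyntheticSpec(n_pathways=2, reactions_per_pathway=2,
                                         enzyme_layer=True, seed=1))
    for r in model.reactions:
        if r.subsystem != "exchange":
            assert r.enzyme is not None
            assert 1.0 <= r.enzyme.kcat <= 100.0
            assert 10.0 <= r.enzyme.mw <= 100.0
    assert model.enzyme_pool is not None and model.enzyme_pool > 0


def test_gene_count_within_configured_range():
    model = make_toy_model(SyntheticSpec(n_pathways=4, reactions_per_pathway=4,
                                         genes_per_reaction=(2, 3), seed=3))
    for r in model.reactions:
        if r.gpr is not None:
            assert 2 <= len(gpr_genes(r.gpr)) <= 3


def test_planted_effect_without_noise_is_exact():
    spec = SyntheticSpec(n_pathways=3, reactions_per_pathway=2,
                         planted_effects={"pathway_01": 3.0},
                         noise_sd=0.0, nan_fraction=0.0, seed=7)
    model = make_toy_model(spec)
    expr = make_expression(model, spec)
    rfc = reaction_fold_changes(model, expr)
    for rxn in model.reactions:
        if rxn.subsystem == "pathway_01":
            assert rfc.values[rxn.id] == pytest.approx(8.0)
        elif rxn.subsystem != "exchange":
            assert rfc.values[rxn.id] == pytest.approx(1.0)


def test_no_effects_no_noise_gives_unit_fold_changes():
    spec = SyntheticSpec(n_pathways=2, reactions_per_pathway=2,
                         noise_sd=0.0, nan_fraction=0.0, seed=9)
    expr = make_expression(make_toy_model(spec), spec)
    assert all(v == pytest.approx(1.0) for v in expr.entries.values())


def test_nan_fraction_drops_exact_count():
    spec = SyntheticSpec(n_pathways=8, reactions_per_pathway=4,
                         genes_per_reaction=(1, 1), nan_fraction=0.25, seed=11)
    model = make_toy_model(spec)
    expr = make_expression(model, spec)
    assert len(model.genes) == 32
    assert len(expr) == 32 - 8  # floor(0.25 * 32) genes missing


def test_planted_pathway_never_fully_silenced():
    for seed in range(30):
        spec = SyntheticSpec(n_pathways=2, reactions_per_pathway=2,
                             genes_per_reaction=(1, 1),
                             planted_effects={"pathway_00": 3.0},
                             nan_fraction=0.5, seed=seed)
        model = make_toy_model(spec)
        expr = make_expression(model, spec)
        planted_genes = [g for g in model.genes if g.startswith("pathway_00")]
        assert any(expr.get(g) is not None for g in planted_genes)


def test_expression_deterministic_given_seed():
    spec = SyntheticSpec(seed=5)
    model = make_toy_model(spec)
    assert make_expression(model, spec).entries == make_expression(model, spec).entries


@pytest.mark.parametrize("bad", [
    dict(n_pathways=0),
    dict(nan_fraction=1.0),
    dict(genes_per_reaction=(0, 2)),
    dict(noise_sd=-0.1),
    dict(planted_effects={"nope": 1.0}),
])
def test_invalid_specs_rejected(bad):
    with pytest.raises(ValueError):
        spec = SyntheticSpec(**bad)
        make_toy_model(spec)


def test_tfbs_signal_shapes_and_determinism():
    m1, enriched1 = make_tfbs_signal(100, 20, 10, 5.0, seed=3)
    m2, enriched2 = make_tfbs_signal(100, 20, 10, 5.0, seed=3)
    assert enriched1 == enriched2
    assert set(m1.tracks) == {"TF_planted", "TF_null"}
    assert m1.tracks["TF_planted"].shape == (100, 20)
    assert np.array_equal(m1.tracks["TF_planted"], m2.tracks["TF_planted"])
    assert m1.positions[0] == -1000.0 and m1.positions[-1] < 1000.0


def test_tfbs_multiplier_one_leaves_tracks_exchangeable():
    m, enriched = make_tfbs_signal(200, 10, 20, 1.0, seed=4)
    # no planted effect: both tracks drawn from the same law; their per-gene
    # sums should have indistinguishable means at this sample size
    s1 = m.tracks["TF_planted"].sum(axis=1)
    s2 = m.tracks["TF_null"].sum(axis=1)
    assert abs(s1.mean() - s2.mean()) < 0.2 * s1.mean()


@pytest.mark.parametrize("args", [(1, 5, 0, 1.0), (10, 5, 10, 1.0), (10, 5, 2, 0.5)])
def test_tfbs_signal_validation(args):
    with pytest.raises(ValueError):
        make_tfbs_signal(*args, seed=0)
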