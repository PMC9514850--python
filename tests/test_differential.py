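import math

import numpy as np
import pytest

from difflux.differential import (ClassificationConfig, ReactionDelta, build_deltas,
                                  classify_reactions, flux_fold_change,
                                  pathway_flux_change)
from oracles import percentile_closest_ranks


@pytest.mark.parametrize("cond,base,ffc,log2", [
    (0.0, 0.0, 1.0, 0.0),
    (3.0, 1.0, 2.0, 1.0),
    (1.0, 3.0, 0.5, -1.0),
    (7.0, 7.0, 1.0, 0.0),
])
def test_flux_fold_change_arithmetic(cond, base, ffc, log2):
    f, l, valid = flux_fold_change(cond, base)
    assert valid
    assert f == ffc
    assert l == pytest.approx(log2, abs=1e-12)


@pytest.mark.parametrize("cond,base", [(-2.0, 0.0), (0.0, -1.5), (-1.0, 0.0)])
def test_corrected_term_at_or_below_zero_is_invalid(cond, base):
    f, l, valid = flux_fold_change(cond, base)
    assert not valid
    assert math.isnan(f) and math.isnan(l)


def test_non_finite_inputs_rejected():
    with pytest.raises(ValueError):
        flux_fold_change(float("inf"), 0.0)


def make_deltas(log2_values):
    out = []
    for i, v in enumerate(log2_values):
        # realise the target log2 through actual max-flux pairs: b = 0
        out.append(ReactionDelta(f"r{i}", 2.0 ** v - 1.0, 0.0, 2.0 ** v, v))
    return out


def test_all_zero_distribution_labels_nothing():
    deltas = classify_reactions(make_deltas([0.0] * 100))
    assert all(d.label == "unchanged" for d in deltas)


def test_single_outlier_up_is_the_only_up_label():
    values = [0.0] * 99 + [2.0]
    deltas = classify_reactions(make_deltas(values))
    p95 = percentile_closest_ranks(values, 95)
    assert 2.0 > max(p95, 1.0)  # oracle confirms the dual criterion
    labels = [d.label for d in deltas]
    assert labels.count("up") == 1 and deltas[-1].label == "up"
    assert labels.count("down") == 0


def test_single_outlier_down_is_the_only_down_label():
    values = [0.0] * 99 + [-0.5]
    deltas = classify_reactions(make_deltas(values))
    p5 = percentile_closest_ranks(values, 5)
    assert -0.5 < min(p5, -0.1)
    labels = [d.label for d in deltas]
    assert labels.count("down") == 1 and deltas[-1].label == "down"


def test_classification_uses_strict_percentile_and_threshold(rng):
    """Labels match the brute-force dual rule on random vectors."""
    values = rng.normal(0, 1.2, size=60)
    deltas = classify_reactions(make_deltas(values))
    p95 = percentile_closest_ranks(values, 95)
    p5 = percentile_closest_ranks(values, 5)
    for d, v in zip(deltas, values):
        expected = ("up" if (v > 1.0 and v > p95)
                    else "down" if (v < -0.1 and v < p5) else "unchanged")
        assert d.label == expected


def test_classification_invariant_to_ordering(rng):
    values = list(rng.normal(0, 1.5, size=40))
    direct = {d.reaction_id: d.label for d in classify_reactions(make_deltas(values))}
    shuffled = make_deltas(values)
    rng.shuffle(shuffled)
    assert {d.reaction_id: d.label for d in classify_reactions(shuffled)} == direct


def test_invalid_deltas_excluded_and_never_labelled():
    deltas = make_deltas([0.0] * 50 + [2.0])
    bad = ReactionDelta("bad", -5.0, 0.0, math.nan, math.nan, "invalid")
    out = classify_reactions(deltas + [bad])
    assert out[-1].label == "invalid"
    assert sum(d.label == "up" for d in out) == 1


def test_fewer_than_two_valid_deltas_is_an_error():
    with pytest.raises(ValueError, match="valid deltas"):
        classify_reactions(make_deltas([1.0]))


def test_at_most_five_percent_labelled_each_way(rng):
    n = 200
    for _ in range(20):
        deltas = classify_reactions(make_deltas(rng.normal(0, 2, size=n)))
        labels = [d.label for d in deltas]
        cap = math.ceil(0.05 * n)
        assert labels.count("up") <= cap
        assert labels.count("down") <= cap


def test_build_deltas_requires_matching_reactions():
    with pytest.raises(ValueError, match="different reactions"):
        build_deltas({"a": 1.0}, {"b": 1.0})


def test_pathway_mean_aggregation():
    deltas = [ReactionDelta(f"r{i}", 0, 0, 1.0, v) for i, v in enumerate([1.0, 2.0, 3.0])]
    out = pathway_flux_change(deltas, {f"r{i}": "p" for i in range(3)})
    assert len(out) == 1
    assert out[0].aggregate_log2_ffc == 2.0


@pytest.mark.parametrize("aggregator,expected", [("mean", 2.0), ("median", 2.0), ("sum", 6.0)])
def test_pathway_aggregators(aggregator, expected):
    deltas = [ReactionDelta(f"r{i}", 0, 0, 1.0, v) for i, v in enumerate([1.0, 2.0, 3.0])]
    out = pathway_flux_change(deltas, {f"r{i}": "p" for i in range(3)}, aggregator)
    assert out[0].aggregate_log2_ffc == expected


def test_all_invalid_pathway_is_omitted(caplog):
    deltas = [ReactionDelta("r0", -5, 0, math.nan, math.nan, "invalid"),
              ReactionDelta("r1", 0, 0, 1.0, 0.0)]
    out = pathway_flux_change(deltas, {"r0": "dead", "r1": "alive"})
    assert [p.subsystem for p in out] == ["alive"]


def test_two_pathways_aggregate_independently():
    deltas = [ReactionDelta(f"a{i}", 0, 0, 1.0, 0.0) for i in range(2)]
    deltas += [ReactionDelta(f"b{i}", 0, 0, 8.0, 3.0) for i in range(2)]
    subsystems = {"a0": "p1", "a1": "p1", "b0": "p2", "b1": "p2"}
    out = {p.subsystem: p.aggregate_log2_ffc for p in pathway_flux_change(deltas, subsystems)}
    assert out == {"p1": 0.0, "p2": 3.0}


def test_empty_subsystem_map_is_an_error():
    with pytest.raises(ValueError, match="empty subsystem map"):
        pathway_flux_change([ReactionDelta("r", 0, 0, 1.0, 0.0)], {})
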