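import math

import numpy as np
import pytest

from codonecon import (
    NITROGEN,
    SKParams,
    build_features,
    codon_probability,
    count_codons,
    fit,
    fit_genes,
    select_model,
)
from codonecon.simulate import SimulationSpec, simulate_genome
from codonecon.skmodel import CodonFeatures, _probabilities


def two_codon_features(costs=(10.0, 13.0), effs=(1.0, 1.0)):
    """A minimal synthetic feature set: one family of two codons."""
    return CodonFeatures(
        codons=("AAA", "AAG"),
        n_gc=np.array([0.0, 1.0]),
        cost=np.array(costs),
        eff=np.array(effs),
        family_index=np.array([0, 0]),
        family_slices=((0, 1),),
    )


def test_null_parameters_give_uniform_family_probabilities(code, features):
    params = SKParams(0.0, 0.0, 0.0)
    for c in code.families["A"]:
        assert codon_probability(c, params, features, code) == pytest.approx(0.25)
    assert codon_probability("AUG", params, features, code) == 1.0  # singleton


def test_two_codon_softmax_hand_value():
    feats = two_codon_features()
    probs = _probabilities(np.array([0.0, -0.1, 0.0]), feats)
    # P(cost-10) = e^{-1.0} / (e^{-1.0} + e^{-1.3}) = 1 / (1 + e^{-0.3})
    assert probs[0] == pytest.approx(1.0 / (1.0 + math.exp(-0.3)))
    assert probs.sum() == pytest.approx(1.0)


def test_probabilities_normalize_within_families(features):
    rng = np.random.default_rng(0)
    for _ in range(5):
        theta = rng.uniform(-2, 2, size=3)
        probs = _probabilities(theta, features)
        for members in features.family_slices:
            assert probs[list(members)].sum() == pytest.approx(1.0)


def test_shift_invariance_of_cost_feature(features):
    """Adding a constant to every codon's cost leaves the likelihood surface
    unchanged (within-family softmax shift invariance)."""
    shifted = CodonFeatures(
        codons=features.codons,
        n_gc=features.n_gc,
        cost=features.cost + 7.5,
        eff=features.eff,
        family_index=features.family_index,
        family_slices=features.family_slices,
    )
    theta = np.array([0.3, -0.12, 0.2])
    assert np.allclose(
        _probabilities(theta, features), _probabilities(theta, shifted)
    )


def test_count_codons(code):
    assert {
        c: n for c, n in count_codons(["ATGGCAGCCTAA"], code).items() if n
    } == {"AUG": 1, "GCA": 1, "GCC": 1}
    zero = count_codons([], code)
    assert sum(zero.values()) == 0
    doubled = count_codons(["ATGGCAGCCTAA"] * 2, code)
    assert doubled["GCA"] == 2


def test_fit_refuses_empty_counts(code, features):
    with pytest.raises(ValueError):
        fit(count_codons([], code), features)


def test_fit_on_uniform_counts_is_null(code, features):
    counts = {c: 10 for c in code.sense_codons}
    res = fit(counts, features, seed=0)
    assert abs(res.params.GCb) < 1e-3
    assert abs(res.params.Sc) < 1e-3
    assert abs(res.params.St) < 1e-3
    assert res.fit_r2 == pytest.approx(1.0, abs=1e-6)


def test_fit_r2_is_one_on_expected_counts(code, s2_features):
    theta = np.array([0.4, -0.08, 0.10])
    probs = _probabilities(theta, s2_features)
    counts = {c: 1000 * probs[i] for i, c in enumerate(s2_features.codons)}
    res = fit(counts, s2_features, seed=0)
    assert res.fit_r2 == pytest.approx(1.0, abs=1e-9)
    assert res.params.GCb == pytest.approx(0.4, abs=1e-4)
    assert res.params.Sc == pytest.approx(-0.08, abs=1e-4)
    assert res.params.St == pytest.approx(0.10, abs=1e-4)


def test_gcb_only_fit_sign_matches_skew(code, features):
    counts = {c: (50 if sum(b in "GC" for b in c) >= 2 else 5)
              for c in code.sense_codons}
    res = fit(counts, features, spec={"GCb"}, seed=0)
    assert res.params.GCb > 0
    assert res.params.Sc == 0.0 and res.params.St == 0.0
    assert res.included == frozenset({"GCb"})
    assert res.aic == pytest.approx(2 - 2 * res.loglik)


def test_loglik_at_optimum_beats_null(code, s2_features):
    spec = SimulationSpec(n_genes=30, codons_per_gene=100,
                          params=SKParams(0.3, -0.1, 0.2), seed=5)
    from codonecon import standard_code

    recs, _ = simulate_genome(spec, s2_features, code)
    counts = count_codons([r.seq for r in recs], code)
    res = fit(counts, s2_features, seed=1)
    from codonecon.skmodel import _counts_array, _loglik

    null = _loglik(np.zeros(3), _counts_array(counts, s2_features), s2_features)
    assert res.loglik >= null


def test_parameter_recovery_single_replicate(code, s2_features):
    truth = SKParams(0.4, -0.08, 0.10)
    spec = SimulationSpec(n_genes=500, codons_per_gene=300, params=truth,
                          inventory_kind="strategy2", seed=11)
    recs, _ = simulate_genome(spec, s2_features, code)
    counts = count_codons([r.seq for r in recs], code)
    res = fit(counts, s2_features, seed=11)
    assert res.params.GCb == pytest.approx(truth.GCb, abs=0.03)
    assert res.params.Sc == pytest.approx(truth.Sc, abs=0.03)
    assert res.params.St == pytest.approx(truth.St, abs=0.06)


def test_select_model_prefers_simpler_when_signal_absent(code, s2_features):
    spec = SimulationSpec(n_genes=400, codons_per_gene=300,
                          params=SKParams(0.5, 0.0, 0.0),
                          inventory_kind="strategy2", seed=2)
    recs, _ = simulate_genome(spec, s2_features, code)
    counts = count_codons([r.seq for r in recs], code)
    best = select_model(counts, s2_features, seed=2)
    assert "GCb" in best.included
    assert len(best.included) < 3  # at least one of Sc/St excluded


def test_select_model_runs_on_tiny_counts(code, features):
    counts = count_codons(["ATGGCAGCCGCAGCGGCUTAA"], code)
    best = select_model(counts, features, seed=0)
    assert best.n_codons > 0


def test_fit_genes_signs_and_degenerate_flag(code, s2_features):
    spec = SimulationSpec(n_genes=3, codons_per_gene=2000,
                          params=SKParams(0.4, -0.3, 0.4),
                          inventory_kind="strategy2", seed=7)
    recs, _ = simulate_genome(spec, s2_features, code)
    genome_fit = fit(count_codons([r.seq for r in recs], code), s2_features, seed=0)
    seqs = [r.seq for r in recs] + ["ATG" + "ATG" * 11 + "TAA", recs[0].seq]
    ids = [r.id for r in recs] + ["met_only", "dup_of_first"]
    df = fit_genes(seqs, genome_fit, s2_features, code, ids=ids, seed=3)
    by_id = df.set_index("gene")
    assert not by_id.loc["met_only", "estimable"]
    for r in recs:
        assert by_id.loc[r.id, "Sc"] < 0
        assert by_id.loc[r.id, "St"] > 0
    assert by_id.loc["dup_of_first", "Sc"] == by_id.loc[recs[0].id, "Sc"]
    assert by_id.loc["dup_of_first", "St"] == by_id.loc[recs[0].id, "St"]
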