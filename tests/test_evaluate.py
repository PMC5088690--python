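"""Mixed-model solving and validation metric tests."""

import numpy as np
import pandas as pd
import pytest

import apydim as ad
from apydim.apycore import apy_inverse, regular_inverse, select_core
from apydim.evaluate import (
    ConvergenceError,
    EvaluationConfig,
    EvaluationResult,
    accuracy_vs_tbv,
    adjust_phenotypes,
    compare_inverses,
    gblup,
    predictive_ability,
    progeny_mean_dependent,
    single_step_gblup,
    solve_mme,
    truncate_records,
    validation_animals,
    validation_r2,
)
from conftest import random_spd


def _phen(animals, values, gens):
    return pd.DataFrame(
        {"animal": animals, "value": values, "generation": gens, "fixed_effect": gens}
    )


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------


def test_truncation_keeps_records_at_or_before_cutoff():
    phen = _phen([1, 2, 3, 4, 5], [0.0] * 5, [1, 2, 3, 4, 5])
    assert len(truncate_records(phen, 5)) == 5
    assert truncate_records(phen, 4)["generation"].max() == 4
    with pytest.raises(ValueError, match="removes every record"):
        truncate_records(phen, 0)


def test_validation_set_and_empty_warning():
    phen = _phen([1, 2, 3], [0.0] * 3, [1, 2, 3])
    val = validation_animals(phen, np.array([2, 3]), cutoff=2)
    assert np.array_equal(val, [3])
    with pytest.warns(UserWarning, match="empty"):
        validation_animals(phen, np.array([1, 2]), cutoff=3)


def test_config_validation():
    with pytest.raises(ValueError):
        EvaluationConfig(variance_ratio=0.0)
    with pytest.raises(ValueError):
        EvaluationConfig(mode="bayesB")
    assert EvaluationConfig.lambda_from_h2(0.5) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# MME solving
# ---------------------------------------------------------------------------


def test_mme_hand_solved_two_animal_system():
    """Two animals, G = I, λ = 1, intercept only, y = (1, -1):
    the 3x3 system gives intercept 0 and GEBV (0.5, -0.5)."""
    b, u, info = solve_mme(
        y=np.array([1.0, -1.0]),
        X=np.ones((2, 1)),
        record_animal=np.array([0, 1]),
        ginv=np.eye(2),
        n_animals=2,
        variance_ratio=1.0,
    )
    assert b[0] == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(u, [0.5, -0.5])


def test_constant_phenotypes_give_zero_gebv():
    phen = _phen([1, 2, 3], [2.5, 2.5, 2.5], [1, 1, 1])
    res = gblup(phen, np.array([1, 2, 3]), np.eye(3), EvaluationConfig(variance_ratio=2.0))
    assert np.allclose(res.gebv.to_numpy(), 0.0, atol=1e-12)
    assert res.fixed_effect_estimates[1] == pytest.approx(2.5)


def test_cg_matches_direct_solve():
    rng = np.random.default_rng(20)
    n = 40
    g = random_spd(n, rng) / n
    ginv = regular_inverse(g)
    y = rng.standard_normal(n)
    X = np.ones((n, 1))
    rec = np.arange(n)
    b_d, u_d, _ = solve_mme(y, X, rec, ginv, n, 1.7, solver="direct")
    b_c, u_c, info = solve_mme(y, X, rec, ginv, n, 1.7, solver="cg", tolerance=1e-12)
    assert info["solver"] == "cg" and info["n_iterations"] > 0
    assert np.allclose(b_d, b_c, atol=1e-8)
    assert np.allclose(u_d, u_c, atol=1e-8)


def test_cg_with_apy_operator_matches_dense(tiny_rels, tiny_pop):
    ids = tiny_pop.genotyped_ids
    part = select_core(ids, 60, seed=5)
    apy = apy_inverse(tiny_rels.grm_blended, part)
    cfg_d = EvaluationConfig(variance_ratio=7 / 3, truncation_cutoff=3, solver="direct")
    cfg_c = EvaluationConfig(
        variance_ratio=7 / 3, truncation_cutoff=3, solver="cg", tolerance=1e-12
    )
    res_d = gblup(tiny_pop.phenotypes, ids, apy, cfg_d)
    res_c = gblup(tiny_pop.phenotypes, ids, apy, cfg_c)
    assert np.allclose(res_d.gebv.to_numpy(), res_c.gebv.to_numpy(), atol=1e-6)


def test_cg_nonconvergence_raises_with_history():
    rng = np.random.default_rng(21)
    n = 30
    g = random_spd(n, rng) / n
    with pytest.raises(ConvergenceError) as exc:
        solve_mme(
            rng.standard_normal(n), np.ones((n, 1)), np.arange(n),
            regular_inverse(g), n, 1.0, solver="cg", tolerance=1e-14, max_iterations=2,
        )
    assert len(exc.value.residual_history) > 0


def test_mme_rejects_bad_lambda():
    with pytest.raises(ValueError):
        solve_mme(np.ones(2), np.ones((2, 1)), np.arange(2), np.eye(2), 2, 0.0)


# ---------------------------------------------------------------------------
# single-step
# ---------------------------------------------------------------------------


def test_single_step_equals_gblup_when_all_animals_genotyped():
    """With every pedigree animal genotyped, A22 = A and H⁻¹ reduces to
    G⁻¹, so single-step and genotyped-only GBLUP coincide."""
    pop = ad.simulate_population(
        ad.SimConfig(ne=15, genome_length=1.0, n_chrom=2, n_snp=200, n_qtl=30,
                     n_generations=2, n_per_generation=80,
                     genotyped_generations=(1, 2), heritability=0.4, seed=77)
    )
    rels = ad.build_relationships(pop.genotypes, pop.genotyped_ids, pop.pedigree, 0.95)
    ginv = regular_inverse(rels.grm_blended)
    cfg = EvaluationConfig(variance_ratio=1.5, truncation_cutoff=1)
    res_g = gblup(pop.phenotypes, pop.genotyped_ids, ginv, cfg)
    res_ss = single_step_gblup(pop.phenotypes, pop.pedigree, pop.genotyped_ids, ginv, cfg)
    assert np.allclose(
        res_ss.gebv[pop.genotyped_ids].to_numpy(), res_g.gebv.to_numpy(), atol=1e-6
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _series(vals, ids=None):
    ids = ids if ids is not None else np.arange(1, len(vals) + 1)
    return pd.Series(np.asarray(vals, dtype=float), index=ids)


def test_predictive_ability_limits():
    ids = [1, 2, 3]
    g = _series([0.1, 0.5, -0.2])
    assert predictive_ability(g, g, ids) == pytest.approx(1.0)
    assert predictive_ability(_series([1, 2, 3]), _series([3, 2, 1]), ids) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="zero variance"):
        predictive_ability(_series([1, 1, 1]), g, ids)
    with pytest.raises(ValueError, match="at least 3"):
        predictive_ability(g, g, [1, 2])
    with pytest.raises(ValueError, match="missing"):
        predictive_ability(g, g, [1, 2, 9])


def test_correlation_invariant_to_affine_rescaling():
    rng = np.random.default_rng(22)
    ids = np.arange(1, 51)
    a = _series(rng.standard_normal(50), ids)
    b = _series(rng.standard_normal(50), ids)
    r1 = predictive_ability(a, b, ids)
    r2 = predictive_ability(3.0 * a + 7.0, b, ids)
    assert r1 == pytest.approx(r2)


def test_validation_r2_identities():
    rng = np.random.default_rng(23)
    ids = np.arange(1, 201)
    g = _series(rng.standard_normal(200), ids)
    dep = _series(2.0 * g.to_numpy() + 1.0, ids)
    assert validation_r2(dep, g, ids) == pytest.approx(1.0)
    noise = _series(rng.standard_normal(200), ids)
    r2 = validation_r2(noise, g, ids)
    assert r2 == pytest.approx(0.0, abs=0.05)
    # R² equals the squared Pearson correlation in simple regression
    assert r2 == pytest.approx(predictive_ability(noise, g, ids) ** 2)


def test_compare_inverses_full_core_and_permutation_null():
    rng = np.random.default_rng(24)
    ids = np.arange(1, 401)
    v = rng.standard_normal(400)
    ra = EvaluationResult(_series(v, ids), {}, True)
    rb = EvaluationResult(_series(v, ids), {}, True)
    assert compare_inverses(ra, rb, ids) == pytest.approx(1.0)
    rp = EvaluationResult(_series(rng.permutation(v), ids), {}, True)
    assert abs(compare_inverses(ra, rp, ids)) < 0.15
    with pytest.raises(ValueError, match="missing"):
        compare_inverses(ra, EvaluationResult(_series(v[:10], ids[:10]), {}, True), ids)


def test_accuracy_vs_tbv_sign():
    ids = [1, 2, 3, 4]
    t = _series([1.0, -0.5, 0.2, 2.0], ids)
    assert accuracy_vs_tbv(t, t, ids) == pytest.approx(1.0)
    assert accuracy_vs_tbv(-t, t, ids) == pytest.approx(-1.0)


def test_adjust_phenotypes_subtracts_class_estimates():
    phen = _phen([1, 2], [5.0, 7.0], [1, 2])
    adj = adjust_phenotypes(phen, {1: 4.0, 2: 4.0})
    assert np.allclose(adj.to_numpy(), [1.0, 3.0])
    with pytest.raises(ValueError, match="no fixed-effect estimate"):
        adjust_phenotypes(phen, {1: 4.0})


def test_progeny_means_track_parent_tbv(tiny_pop):
    phen = tiny_pop.phenotypes
    tbv = pd.Series(tiny_pop.tbv, index=tiny_pop.pedigree["animal"].to_numpy())
    gen_means = phen.groupby("fixed_effect")["value"].mean().to_dict()
    adj = adjust_phenotypes(phen, gen_means)
    parents = np.unique(
        tiny_pop.pedigree.loc[tiny_pop.pedigree["sire"] > 0, ["sire", "dam"]].to_numpy()
    )
    dep = progeny_mean_dependent(tiny_pop.pedigree, adj, tbv, parents, min_progeny=3)
    assert len(dep) >= 10
    ids = dep.index.to_numpy()
    r = np.corrcoef(dep.to_numpy(), tbv[ids].to_numpy())[0, 1]
    assert r > 0.3  # unbiased but noisy realized dependent


def test_accuracy_bracketing_on_simulated_data(tiny_pop, tiny_rels):
    """With h² = 0.3 and modest data, accuracy sits strictly in (0, 1)."""
    cfg = EvaluationConfig(variance_ratio=7 / 3, truncation_cutoff=3)
    res = gblup(tiny_pop.phenotypes, tiny_pop.genotyped_ids, regular_inverse(tiny_rels.grm_blended), cfg)
    val = validation_animals(tiny_pop.phenotypes, tiny_pop.genotyped_ids, 3)
    tbv = pd.Series(tiny_pop.tbv, index=tiny_pop.pedigree["animal"].to_numpy())
    acc = accuracy_vs_tbv(res.gebv, tbv, val)
    assert 0.0 < acc < 1.0
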