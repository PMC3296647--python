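"""Perturbation factors, bootstrap significance, and the propagation study."""

import numpy as np
import pytest
from scipy.stats import kstest, mannwhitneyu

from pathnet.fixtures import INSULIN_DE_GENES, FixtureSpec, make_fixture
from pathnet.model import GeneNetwork, NodeRef, TypedEdge, merge_edge
from pathnet.spia import (
    PerturbationInput,
    SimulationDesign,
    SingularSystemError,
    edge_sign,
    perturbation_factors,
    ppert,
    run_propagation_experiment,
)

from conftest import network_of


def chain_abc():
    return network_of(
        ["A", "B", "C"],
        [("A", "B", True, {"activation"}), ("B", "C", True, {"activation"})],
    )


def random_dag(seed, n=10, p=0.3, p_inhibit=0.25):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n)]
    records = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                t = "inhibition" if rng.random() < p_inhibit else "activation"
                records.append((genes[i], genes[j], True, {t}))
    return network_of(genes, records), genes, rng


def fixed_point_pf(net, delta_e, tol=1e-14, max_iter=500):
    """Independent iterative solution of the PF recurrence."""
    genes = sorted(net.nodes)
    idx = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    beta = np.zeros((n, n))
    for e in net.edges.values():
        sign = edge_sign(e.types)
        beta[idx[e.dst], idx[e.src]] = sign
        if not e.directed:
            beta[idx[e.src], idx[e.dst]] = sign
    n_ds = (beta != 0).sum(axis=0).astype(float)
    norm = np.divide(1.0, n_ds, out=np.zeros(n), where=n_ds > 0)
    delta = np.array([delta_e.get(g, 0.0) for g in genes])
    pf = delta.copy()
    for _ in range(max_iter):
        new = delta + (beta * norm[np.newaxis, :]) @ pf
        if np.max(np.abs(new - pf)) < tol:
            return genes, new
        pf = new
    return genes, pf


def test_chain_worked_example():
    """A->B->C all activating, dE=(1,0,0): PF=(1,1,1), Acc=(0,1,1), tA=2."""
    res = ppert(PerturbationInput(chain_abc(), {"A": 1.0}), n_boot=100, seed=0)
    assert res.pf == pytest.approx({"A": 1.0, "B": 1.0, "C": 1.0})
    assert res.acc == pytest.approx({"A": 0.0, "B": 1.0, "C": 1.0})
    assert res.t_a == pytest.approx(2.0)


def test_no_edges_pf_equals_delta():
    net = network_of(["A", "B"], [])
    genes, pf = perturbation_factors(PerturbationInput(net, {"A": 3.0, "B": -1.0}))
    assert dict(zip(genes, pf)) == pytest.approx({"A": 3.0, "B": -1.0})
    res = ppert(PerturbationInput(net, {"A": 3.0, "B": -1.0}), n_boot=100, seed=0)
    assert res.t_a == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_direct_solve_matches_fixed_point_on_dags(seed):
    net, genes, rng = random_dag(seed)
    delta_e = {g: float(rng.normal(0, 3)) for g in rng.choice(genes, 4, replace=False)}
    solved_genes, pf = perturbation_factors(PerturbationInput(net, delta_e))
    iter_genes, pf_iter = fixed_point_pf(net, delta_e)
    assert solved_genes == iter_genes
    assert np.max(np.abs(pf - pf_iter)) < 1e-10


def test_unit_gain_cycle_raises_and_damping_recovers():
    net = network_of(
        ["A", "B"],
        [("A", "B", True, {"activation"}), ("B", "A", True, {"activation"})],
    )
    with pytest.raises(SingularSystemError, match="damping"):
        perturbation_factors(PerturbationInput(net, {"A": 1.0}))
    _, pf = perturbation_factors(PerturbationInput(net, {"A": 1.0}), damping=0.99)
    assert np.all(np.isfinite(pf))


def test_binding_edges_carry_no_regulatory_weight():
    net = network_of(["A", "B"], [("A", "B", False, {"binding"})])
    genes, pf = perturbation_factors(PerturbationInput(net, {"A": 2.0}))
    assert dict(zip(genes, pf)) == pytest.approx({"A": 2.0, "B": 0.0})


def test_pf_linearity():
    net, genes, rng = random_dag(3)
    delta_e = {g: float(rng.normal(0, 2)) for g in genes[:4]}
    doubled = {g: 2 * v for g, v in delta_e.items()}
    r1 = ppert(PerturbationInput(net, delta_e), n_boot=50, seed=1)
    r2 = ppert(PerturbationInput(net, doubled), n_boot=50, seed=1)
    assert r2.t_a == pytest.approx(2 * r1.t_a)
    for g in net.nodes:
        assert r2.pf[g] == pytest.approx(2 * r1.pf[g])


def test_sign_symmetry_negated_fold_changes():
    net, genes, rng = random_dag(4)
    delta_e = {g: float(abs(rng.normal(5, 2))) for g in genes[:5]}
    negated = {g: -v for g, v in delta_e.items()}
    r_pos = ppert(PerturbationInput(net, delta_e), n_boot=500, seed=9)
    r_neg = ppert(PerturbationInput(net, negated), n_boot=500, seed=9)
    assert r_neg.t_a == pytest.approx(-r_pos.t_a)
    assert r_neg.p_pert == pytest.approx(r_pos.p_pert)


def test_zero_delta_gives_p_one():
    net = chain_abc()
    res = ppert(PerturbationInput(net, {}), n_boot=100, seed=0)
    assert res.t_a == 0.0 and res.p_pert == 1.0


def test_ppert_deterministic_given_seed():
    net, genes, rng = random_dag(6)
    delta_e = {g: 4.0 for g in genes[:3]}
    p1 = ppert(PerturbationInput(net, delta_e), n_boot=300, seed=42).p_pert
    p2 = ppert(PerturbationInput(net, delta_e), n_boot=300, seed=42).p_pert
    assert p1 == p2


def test_ppert_null_uniformity():
    """Under random DE-gene placement, pPERT is approximately U(0,1)
    (KS statistic below the 1% critical value at 500 replicates)."""
    net, genes, _ = random_dag(11, n=40, p=0.08)
    rng = np.random.default_rng(11)
    ps = []
    for _ in range(500):
        de = rng.choice(genes, size=8, replace=False)
        delta_e = {g: float(rng.normal(5, 2)) for g in de}
        ps.append(
            ppert(PerturbationInput(net, delta_e), n_boot=199, seed=int(rng.integers(2**31))).p_pert
        )
    ks = kstest(ps, "uniform").statistic
    assert ks < 1.628 / np.sqrt(500)  # 1% critical value, large-sample form


def test_fold_change_moment_check():
    """dE_i ~ N(mu_FC, sd=2): sample variance over 10,000 draws within 10%."""
    rng = np.random.default_rng(0)
    draws = rng.normal(4.0, 2.0, size=10_000)
    assert abs(np.var(draws) - 4.0) / 4.0 < 0.10


def test_sigma_zero_gives_exact_mu():
    fx = make_fixture(FixtureSpec("insulin_fragment", {"n_background": 6}))
    design = SimulationDesign(
        de_genes=INSULIN_DE_GENES, sigma_fc=0.0, n_reps=1, n_boot=50, seed=3
    )
    table, _ = run_propagation_experiment(design, fx.topology)
    assert len(table) == 2  # one rep, two variants
    assert set(table["variant"]) == {"propagated", "non_propagated"}


def test_propagated_variant_dominates():
    """On the insulin fragment the propagated variant's pPERT distribution is
    stochastically smaller (the cascade is reconnected through PIP3/cAMP)."""
    fx = make_fixture(FixtureSpec("insulin_fragment", {"n_background": 30}))
    design = SimulationDesign(de_genes=INSULIN_DE_GENES, n_reps=300, n_boot=300, seed=7)
    table, summary = run_propagation_experiment(design, fx.topology)
    med = summary.set_index("variant")["median"]
    assert med["propagated"] < med["non_propagated"]
    p_prop = table.loc[table.variant == "propagated", "p_pert"]
    p_non = table.loc[table.variant == "non_propagated", "p_pert"]
    assert mannwhitneyu(p_prop, p_non, alternative="less").pvalue < 0.01


def test_experiment_deterministic_given_seed():
    fx = make_fixture(FixtureSpec("insulin_fragment", {"n_background": 6}))
    design = SimulationDesign(de_genes=INSULIN_DE_GENES, n_reps=5, n_boot=50, seed=21)
    t1, _ = run_propagation_experiment(design, fx.topology)
    t2, _ = run_propagation_experiment(design, fx.topology)
    assert t1.equals(t2)
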