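"""Hierarchical AMOVA: distance identities, coefficients, permutations."""
import itertools

import numpy as np
import pytest
from scipy.stats import kstest

from conftest import brute_force_ss, make_matrix
from ecotype.amova import (
    amova_nested,
    pairwise_region_amova,
    permutation_test,
    phi_from_components,
    squared_distance_matrix,
)
from ecotype.diversity import encode_genotypes
from ecotype.errors import ConfigError


def test_squared_distance_coding_arithmetic():
    """AA vs BB at one marker gives d2=2, AA vs AB gives 0.5 under the
    (1,0)/(0,1) encoding; identical rows give 0."""
    m = make_matrix(
        {"s1": ["AA"], "s2": ["BB"], "s3": ["AB"], "s4": ["AA"]},
        {"s1": "a", "s2": "a", "s3": "a", "s4": "a"},
    )
    d2 = squared_distance_matrix(encode_genotypes(m))
    assert d2[0, 1] == pytest.approx(2.0)
    assert d2[0, 2] == pytest.approx(0.5)
    assert d2[0, 3] == pytest.approx(0.0)
    assert np.allclose(d2, d2.T)
    assert np.allclose(np.diag(d2), 0.0)


def test_two_accession_fixed_difference_hand_example():
    """Two accessions of two individuals, one all AA and one all BB at a
    single marker: SS_AP=2, SS_WP=0, WP=0, AP=1, Phi_PT=1."""
    m = make_matrix(
        {"s1": ["AA"], "s2": ["AA"], "s3": ["BB"], "s4": ["BB"]},
        {"s1": "a1", "s2": "a1", "s3": "a2", "s4": "a2"},
    )
    res = amova_nested(encode_genotypes(m), m.accessions)
    assert res.ss["AP"] == pytest.approx(2.0, abs=1e-12)
    assert res.ss["WP"] == pytest.approx(0.0, abs=1e-12)
    assert res.components["WP"] == pytest.approx(0.0, abs=1e-12)
    assert res.components["AP"] == pytest.approx(1.0, abs=1e-12)
    assert res.phi["Phi_PT"] == pytest.approx(1.0, abs=1e-12)


def test_all_identical_individuals_is_degenerate_zero():
    m = make_matrix(
        {f"s{i}": ["AA", "AB"] for i in range(6)},
        {f"s{i}": f"a{i % 2}" for i in range(6)},
    )
    res = amova_nested(encode_genotypes(m), m.accessions)
    assert res.degenerate
    assert res.phi["Phi_PT"] == 0.0


def test_phi_from_components_ratio_arithmetic():
    """Printed-scale variance components (85, 247, 713) give
    Phi_RT=0.081, Phi_PR=0.257, Phi_PT=0.318 to 3 decimals."""
    phi_rt, phi_pr, phi_pt = phi_from_components(85, 247, 713)
    assert round(phi_pt, 3) == 0.318
    assert round(phi_rt, 3) == 0.081
    assert round(phi_pr, 3) == 0.257
    assert phi_from_components(0, 0, 5.0) == (0.0, 0.0, 0.0)


@pytest.mark.parametrize("n_acc,n_reg,seed", [(4, None, 1), (6, 2, 2),
                                              (9, 3, 3), (5, None, 4)])
def test_matches_brute_force_decomposition(n_acc, n_reg, seed):
    """SS by the distance route equals the direct group-mean sums of
    squares on random unbalanced instances with N <= 30 (1e-9)."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(2, 6, size=n_acc)
    n = int(sizes.sum())
    assert n <= 30
    acc = np.repeat([f"a{i}" for i in range(n_acc)], sizes)
    reg = None
    if n_reg:
        acc_to_reg = {f"a{i}": f"r{i % n_reg}" for i in range(n_acc)}
        reg = np.array([acc_to_reg[a] for a in acc])
    x = rng.choice([0.0, 0.5, 1.0], size=(n, 24))
    res = amova_nested(x, acc, reg)
    oracle = brute_force_ss(x, acc, reg)
    for key, val in oracle.items():
        assert res.ss[key] == pytest.approx(val, abs=1e-9)


def test_balanced_design_coefficients_closed_form():
    """R regions x a accessions x n individuals recover n1=n, n2=n,
    n3=a*n exactly; the two-level coefficient equals n."""
    r_regions, a_acc, n_ind = 3, 4, 5
    acc = np.repeat([f"a{i}" for i in range(r_regions * a_acc)], n_ind)
    reg = np.repeat([f"r{i}" for i in range(r_regions)], a_acc * n_ind)
    rng = np.random.default_rng(0)
    x = rng.random((len(acc), 10))
    res = amova_nested(x, acc, reg)
    assert res.coefficients["n1"] == pytest.approx(n_ind, abs=1e-12)
    assert res.coefficients["n2"] == pytest.approx(n_ind, abs=1e-12)
    assert res.coefficients["n3"] == pytest.approx(a_acc * n_ind, abs=1e-12)
    res2 = amova_nested(x, acc)
    assert res2.coefficients["n0"] == pytest.approx(n_ind, abs=1e-12)


def test_row_order_invariance():
    rng = np.random.default_rng(7)
    x = rng.choice([0.0, 0.5, 1.0], size=(18, 12))
    acc = np.repeat(["a", "b", "c"], 6)
    reg = np.repeat(["r1", "r1", "r2"], 6)
    res = amova_nested(x, acc, reg)
    order = rng.permutation(18)
    res2 = amova_nested(x[order], acc[order], reg[order])
    for key in res.phi:
        assert res.phi[key] == pytest.approx(res2.phi[key], abs=1e-10)


def test_accession_spanning_regions_rejected():
    x = np.zeros((4, 2))
    with pytest.raises(ConfigError):
        amova_nested(x, ["a", "a", "b", "b"], ["r1", "r2", "r2", "r2"])


def test_permutation_counting_rule_matches_exhaustive_enumeration():
    """At n=4 (two fixed-difference accessions of two) a random label
    shuffle recreates the observed partition with probability 1/3, so the
    >=-counting estimate converges to 1/3, as exhaustive enumeration of
    all 24 relabellings shows."""
    m = make_matrix(
        {"s1": ["AA"], "s2": ["AA"], "s3": ["BB"], "s4": ["BB"]},
        {"s1": "a1", "s2": "a1", "s3": "a2", "s4": "a2"},
    )
    enc = encode_genotypes(m).to_numpy()
    labels = np.array(["a1", "a1", "a2", "a2"])
    d2 = squared_distance_matrix(enc)

    def phi_of(lab):
        return amova_nested(enc, lab).phi["Phi_PT"]

    observed = phi_of(labels)
    hits = sum(
        phi_of(np.array(perm)) >= observed - 1e-12
        for perm in itertools.permutations(labels)
    )
    assert hits / 24 == pytest.approx(1 / 3)
    p = permutation_test(enc, labels, statistic="Phi_PT", n_perm=999, seed=5)
    assert p == pytest.approx(1 / 3, abs=0.06)


def test_permutation_floor_for_well_separated_groups():
    """With 2 accessions of 8 and a fixed difference, recreating the
    observed partition by chance is ~2/12870, so the P value hits the
    1/(n_perm+1) floor."""
    calls = {f"s{i}": ["AA", "AA"] for i in range(8)}
    calls.update({f"t{i}": ["BB", "BB"] for i in range(8)})
    acc = {f"s{i}": "a1" for i in range(8)}
    acc.update({f"t{i}": "a2" for i in range(8)})
    m = make_matrix(calls, acc)
    p = permutation_test(
        encode_genotypes(m), m.accessions, statistic="Phi_PT",
        n_perm=999, seed=11,
    )
    assert p == pytest.approx(1 / 1000)


def test_permutation_p_uniform_under_null():
    """Label-shuffled data give permutation P values uniform on their
    grid (KS not rejected at alpha=0.01 over 100 null replicates)."""
    rng = np.random.default_rng(123)
    pvals = []
    for _ in range(100):
        x = rng.choice([0.0, 0.5, 1.0], size=(16, 30))
        acc = rng.permutation(np.repeat(["a", "b", "c", "d"], 4))
        pvals.append(
            permutation_test(x, acc, statistic="Phi_PT", n_perm=99,
                             seed=int(rng.integers(2**31 - 1)))
        )
    stat = kstest(pvals, "uniform").statistic
    assert stat < 1.63 / np.sqrt(len(pvals))


def test_pairwise_region_consistency():
    """Pairwise-region analysis equals the two-level analysis restricted
    to the pair with regions as the populations (1 df between)."""
    rng = np.random.default_rng(9)
    x = rng.choice([0.0, 0.5, 1.0], size=(24, 16))
    reg = np.repeat(["north", "south", "east"], 8)
    res = pairwise_region_amova(x, reg, ("north", "south"))
    assert res.df["AP"] == 1
    mask = reg != "east"
    direct = amova_nested(x[mask], reg[mask])
    assert res.phi["Phi_PT"] == pytest.approx(direct.phi["Phi_PT"], abs=1e-12)
    # identical regions: duplicate one region's rows under two labels
    dup = np.vstack([x[:8], x[:8]])
    lab = np.array(["r1"] * 8 + ["r2"] * 8)
    res0 = pairwise_region_amova(dup, lab, ("r1", "r2"))
    assert abs(res0.phi["Phi_PT"]) < 0.05
    # disjoint fixed difference: maximal differentiation
    fixed = np.vstack([np.tile([1.0, 0.0], (6, 4)), np.tile([0.0, 1.0], (6, 4))])
    lab2 = np.array(["r1"] * 6 + ["r2"] * 6)
    res1 = pairwise_region_amova(fixed, lab2, ("r1", "r2"))
    assert res1.phi["Phi_PT"] == pytest.approx(1.0, abs=1e-12)
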