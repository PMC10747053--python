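"""Distances, neighbor-joining, PCA and admixture ancestry estimation."""

import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from sojapop import structure
from sojapop.errors import SojapopError
from sojapop.genotypes import MISSING
from sojapop.structure import (admixture_fit, choose_K, group_mean_distance,
                               match_labels, nj_tree, pca, pdistance)
from tests.conftest import make_gm

GROUP_CODE = {"SR": 0, "CR": 1, "NER": 2}


# ---------------------------------------------------------------- distances

def test_pdistance_trivial_cases():
    gm = make_gm([[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 2]])
    d = pdistance(gm)
    assert d["S0", "S1"] == 0.0
    # S0 vs S2 differ by 2,0,2,2 dosage units over 4 sites -> 6/8
    assert d["S0", "S2"] == pytest.approx(6 / 8)


def test_pdistance_maximal_for_opposite_homozygotes():
    gm = make_gm([[0, 0, 0], [2, 2, 2]])
    assert pdistance(gm)["S0", "S1"] == 1.0


def test_pdistance_matches_brute_force_with_missing():
    rng = np.random.default_rng(1)
    dosage = rng.integers(0, 3, (5, 30)).astype(np.int8)
    dosage[rng.random(dosage.shape) < 0.2] = MISSING
    gm = make_gm(dosage)
    d = pdistance(gm)
    for i, j in itertools.combinations(range(5), 2):
        num = den = 0
        for k in range(30):
            a, b = dosage[i, k], dosage[j, k]
            if a != MISSING and b != MISSING:
                num += abs(int(a) - int(b))
                den += 1
        assert d[i, j] == pytest.approx(num / (2 * den))


def test_pdistance_satisfies_triangle_inequality():
    rng = np.random.default_rng(2)
    gm = make_gm(rng.integers(0, 3, (8, 100)).astype(np.int8))
    d = pdistance(gm).data
    for i, j, k in itertools.permutations(range(8), 3):
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_pdistance_errors_on_disjoint_missingness():
    dosage = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
    with pytest.raises(SojapopError, match="share no genotyped sites"):
        pdistance(make_gm(dosage))


def test_group_mean_distance_hand_cases():
    d = DistanceMatrix(np.array([[0.0, 0.2], [0.2, 0.0]]), ids=["a", "b"])
    got = group_mean_distance(d, {"a": "L1", "b": "L2"})
    assert got["L1", "L2"] == pytest.approx(0.2)

    rng = np.random.default_rng(0)
    raw = rng.random((6, 6))
    raw = (raw + raw.T) / 2
    np.fill_diagonal(raw, 0)
    d6 = DistanceMatrix(raw, ids=[f"s{i}" for i in range(6)])
    grouping = {f"s{i}": f"L{i // 2}" for i in range(6)}
    got = group_mean_distance(d6, grouping)
    for la, lb in itertools.combinations(range(3), 2):
        pairs = [raw[i, j] for i in (2 * la, 2 * la + 1)
                 for j in (2 * lb, 2 * lb + 1)]
        assert got[f"L{la}", f"L{lb}"] == pytest.approx(np.mean(pairs))


# ---------------------------------------------------------------- NJ

def _random_additive_tree(rng, n_taxa):
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)),
                          children=[nodes.pop(j), nodes.pop(i)])
        nodes.append(parent)
    return TreeNode(children=nodes)


def test_nj_recovers_known_four_taxon_tree():
    # additive metric from ((A:2,B:3):1,(C:4,D:5)): classic worked example
    dm = DistanceMatrix(np.array([
        [0, 5, 7, 8],
        [5, 0, 8, 9],
        [7, 8, 0, 9],
        [8, 9, 9, 0]], dtype=float), ids=list("ABCD"))
    tree = nj_tree(dm)
    got = tree.tip_tip_distances(list("ABCD"))
    np.testing.assert_allclose(got.data, dm.data, atol=1e-9)
    # AB form a cherry
    parent_names = {t.name: {s.name for s in t.parent.children if s.is_tip()}
                    for t in tree.tips()}
    assert parent_names["A"] == {"A", "B"} or parent_names["C"] == {"C", "D"}


def test_nj_three_taxa_closed_form():
    dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
                        ids=list("ABC"))
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_round_trips_random_additive_metrics():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        src = _random_additive_tree(rng, n)
        names = sorted(t.name for t in src.tips())
        dm_src = src.tip_tip_distances(names)
        rebuilt = nj_tree(DistanceMatrix(dm_src.data, ids=names))
        got = rebuilt.tip_tip_distances(names)
        np.testing.assert_allclose(got.data, dm_src.data, atol=1e-8)


def test_nj_refuses_nonfinite_and_tiny_inputs():
    bad = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0.0]])
    dm = DistanceMatrix(np.array([[0, 1], [1, 0.0]]), ids=["a", "b"])
    with pytest.raises(SojapopError):
        nj_tree(dm)
    with pytest.raises(Exception):
        nj_tree(DistanceMatrix(bad, ids=list("abc")))


def test_nj_separates_simulated_groups(small_sim):
    tree = nj_tree(pdistance(small_sim.genotypes))
    truth = small_sim.truth.group_assignments
    # on the midpoint-rooted tree, some clade should isolate each group
    rooted = tree.root_at_midpoint()
    for grp in ("SR", "CR", "NER"):
        members = {s for s, g in truth.items() if g == grp}
        found = any({t.name for t in node.tips()} == members
                    for node in rooted.non_tips(include_self=True))
        assert found, f"group {grp} is not monophyletic"


# ---------------------------------------------------------------- PCA

def test_pca_eigenvalues_sorted_nonnegative(small_sim):
    _, ev = pca(small_sim.genotypes)
    assert (ev >= -1e-9).all()
    assert (np.diff(ev) <= 1e-9).all()


def test_pca_separates_groups(small_sim):
    from sklearn.cluster import KMeans

    scores, _ = pca(small_sim.genotypes)
    labels = KMeans(3, n_init=10, random_state=0).fit_predict(scores[:, :2])
    truth = np.array([GROUP_CODE[small_sim.truth.group_assignments[s]]
                      for s in small_sim.genotypes.samples])
    assert match_labels(labels, truth) >= 0.95


def test_pca_direction_stable_under_sample_duplication(small_sim):
    gm = small_sim.genotypes
    idx = np.arange(gm.n_samples)
    dup = gm.take_samples(np.concatenate([idx, idx]))
    dup.samples = [f"{s}_{i}" for i, s in enumerate(dup.samples)]
    s1, _ = pca(gm, n_components=1)
    s2, _ = pca(dup, n_components=1)
    r = np.corrcoef(np.tile(s1[:, 0], 2), s2[:, 0])[0, 1]
    assert abs(r) > 0.99


# ---------------------------------------------------------------- admixture

def test_admixture_k1_is_closed_form(small_sim):
    gm = small_sim.genotypes.take_sites(np.arange(300))
    fit = admixture_fit(gm, K=1, seed=0)
    assert np.allclose(fit.Q, 1.0)
    ref, alt = gm.allele_counts()
    freq = alt / (ref + alt)
    np.testing.assert_allclose(fit.P[0], freq, atol=1e-6)
    eps = 1e-12
    ll = np.sum(alt * np.log(np.clip(freq, eps, None))
                + ref * np.log(np.clip(1 - freq, eps, None)))
    assert fit.loglik == pytest.approx(ll, rel=1e-6)


def test_admixture_loglik_monotone_and_q_simplex(small_sim):
    gm = small_sim.genotypes.take_sites(np.arange(500))
    for seed in (0, 1, 2):
        fit = admixture_fit(gm, K=3, seed=seed, max_iter=300, tol=1e-5)
        diffs = np.diff(fit.loglik_path)
        assert (diffs >= -1e-6 * np.abs(fit.loglik)).all()
        np.testing.assert_allclose(fit.Q.sum(axis=1), 1.0, atol=1e-8)
        assert fit.P.min() >= 0 and fit.P.max() <= 1


def test_admixture_recovers_three_groups(small_sim):
    from sojapop.vcfio import ld_prune

    pruned = ld_prune(small_sim.genotypes)
    fit = admixture_fit(pruned, K=3, seed=0)
    truth = np.array([GROUP_CODE[small_sim.truth.group_assignments[s]]
                      for s in pruned.samples])
    assert fit.Q.max(axis=1).mean() >= 0.9
    assert match_labels(fit.Q.argmax(axis=1), truth) >= 0.95


def test_choose_k_folds_partition_observed_entries(small_sim):
    # masking CV must split observed entries into disjoint folds of ~equal size
    gm = small_sim.genotypes.take_sites(np.arange(200))
    d = gm.dosage
    obs = np.argwhere(d != MISSING)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(obs))
    fold_of = np.empty(len(obs), dtype=int)
    fold_of[perm] = np.arange(len(obs)) % 5
    sizes = np.bincount(fold_of, minlength=5)
    assert sizes.sum() == len(obs)
    assert sizes.max() - sizes.min() <= 1
    # and the implementation runs end to end returning one error per K
    errors = choose_K(gm, K_range=(2, 3), folds=3, seed=0, max_iter=50, tol=1e-3)
    assert set(errors) == {2, 3}
    assert all(np.isfinite(v) for v in errors.values())


def test_admixture_refuses_k_above_n(small_sim):
    with pytest.raises(SojapopError):
        admixture_fit(small_sim.genotypes, K=1000, seed=0)
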