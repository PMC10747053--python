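"""Windowed diversity, Weir-Cockerham F_ST and the joint scan table."""

import numpy as np
import pytest

from sojapop import popstats
from sojapop.errors import SojapopError
from sojapop.genotypes import MISSING
from sojapop.popstats import ScanParams, scan_pair, site_wc_components, window_pi
from tests.conftest import make_gm


def test_site_pi_hand_example():
    # 2 diploids genotyped 0/0 and 1/1: c_ref = c_alt = 2, n = 4
    gm = make_gm([[0], [2]], chrom_length=1000)
    params = ScanParams(window_bp=1000, step_bp=1000, min_snps_per_window=1)
    out = window_pi(gm, ["S0", "S1"], params)
    assert out["pi"].iloc[0] == pytest.approx((8 / 12) / 1000)


def test_monomorphic_window_has_zero_pi():
    gm = make_gm([[0, 0], [0, 0], [0, 0]], chrom_length=1000)
    params = ScanParams(window_bp=1000, step_bp=1000, min_snps_per_window=1)
    with pytest.warns(UserWarning):
        out = window_pi(gm, ["S0", "S1", "S2"], params)
    assert (out["pi"] == 0).all()


def test_fixed_difference_gives_site_fst_one():
    gm = make_gm([[0], [0], [2], [2]], chrom_length=100)
    a, b, c = site_wc_components(gm, np.array([0, 1]), np.array([2, 3]))
    assert a[0] / (a[0] + b[0] + c[0]) == pytest.approx(1.0)


def test_panmictic_groups_have_near_zero_fst():
    rng = np.random.default_rng(0)
    p = rng.uniform(0.1, 0.9, 10_000)
    dosage = rng.binomial(2, p, size=(40, 10_000)).astype(np.int8)
    gm = make_gm(dosage, chrom_length=10_000_000,
                 positions=np.sort(rng.choice(10_000_000, 10_000, replace=False)) + 1)
    ga = [f"S{i}" for i in range(20)]
    gb = [f"S{i}" for i in range(20, 40)]
    fst = popstats.global_fst(gm, ga, gb)
    assert abs(fst) < 0.02


def test_windowed_fst_matches_scalar_oracle():
    """Vectorized ratio-of-sums equals an independent per-site scalar
    evaluation of the W&C formulas, to 1e-12."""
    rng = np.random.default_rng(4)
    dosage = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
    dosage[rng.random(dosage.shape) < 0.1] = MISSING
    gm = make_gm(dosage, chrom_length=5000, positions=rng.choice(
        np.arange(1, 5001), 40, replace=False))
    gm = gm.take_sites(np.argsort(gm.sites["pos"].to_numpy()))
    idx_a, idx_b = np.arange(6), np.arange(6, 12)
    a, b, c = site_wc_components(gm, idx_a, idx_b)

    def scalar(j):
        comps = []
        for idx in (idx_a, idx_b):
            g = [int(gm.dosage[i, j]) for i in idx if gm.dosage[i, j] != MISSING]
            if not g:
                return 0.0, 0.0, 0.0
            ni = len(g)
            comps.append((ni, sum(g) / (2 * ni), sum(1 for x in g if x == 1) / ni))
        (n1, p1, h1), (n2, p2, h2) = comps
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            return 0.0, 0.0, 0.0
        nc = (2 * nbar - (n1 ** 2 + n2 ** 2) / (2 * nbar))
        if nc <= 0:
            return 0.0, 0.0, 0.0
        pbar = (n1 * p1 + n2 * p2) / (2 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2 * nbar)
        aa = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        bb = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                    - (2 * nbar - 1) / (4 * nbar) * hbar)
        return aa, bb, hbar / 2

    for j in range(gm.n_sites):
        sa, sb, sc = scalar(j)
        assert a[j] == pytest.approx(sa, abs=1e-12)
        assert b[j] == pytest.approx(sb, abs=1e-12)
        assert c[j] == pytest.approx(sc, abs=1e-12)


def test_scan_pair_symmetries(small_sim, group_samples):
    gm = small_sim.genotypes
    ab = scan_pair(gm, group_samples["SR"], group_samples["CR"])
    ba = scan_pair(gm, group_samples["CR"], group_samples["SR"])
    np.testing.assert_allclose(ab["fst"], ba["fst"], rtol=1e-12)
    np.testing.assert_allclose(ab["log_pi_ratio"], -ba["log_pi_ratio"],
                               rtol=1e-9, atol=1e-12)
    # pi invariant under permutation of samples within a group
    pa = window_pi(gm, group_samples["SR"])
    pb = window_pi(gm, list(group_samples["SR"])[::-1])
    np.testing.assert_allclose(pa["pi"], pb["pi"], rtol=1e-12)


def test_fst_invariant_to_sample_order_and_allele_swap(small_sim, group_samples):
    gm = small_sim.genotypes
    f1 = popstats.global_fst(gm, group_samples["SR"], group_samples["NER"])
    f2 = popstats.global_fst(gm, group_samples["SR"][::-1], group_samples["NER"][::-1])
    swapped = gm.take_sites(np.arange(gm.n_sites))
    d = swapped.dosage
    d[d != MISSING] = 2 - d[d != MISSING]
    f3 = popstats.global_fst(swapped, group_samples["SR"], group_samples["NER"])
    assert f1 == pytest.approx(f2, rel=1e-12)
    assert f1 == pytest.approx(f3, rel=1e-9)


def test_window_grid_covers_chromosomes():
    grid = popstats.window_grid({"c1": 1_050_000}, ScanParams())
    assert list(grid["start"]) == [0, 100_000, 200_000, 300_000, 400_000,
                                   500_000, 600_000, 700_000, 800_000,
                                   900_000, 1_000_000]
    assert grid["end"].iloc[0] == 500_000
    assert grid["end"].iloc[-1] == 1_050_000  # truncated last window


def test_scan_pair_flags_sparse_windows(small_sim, group_samples):
    params = ScanParams(min_snps_per_window=10_000)  # nothing can satisfy this
    out = scan_pair(small_sim.genotypes, group_samples["SR"],
                    group_samples["CR"], params)
    assert out["excluded"].all()


def test_identical_groups_refused(small_sim, group_samples):
    with pytest.raises(SojapopError):
        popstats.window_fst(small_sim.genotypes, group_samples["SR"],
                            group_samples["SR"])


def test_invalid_scan_params():
    with pytest.raises(SojapopError):
        ScanParams(window_bp=100, step_bp=200)
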