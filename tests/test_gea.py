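"""Genotype-environment association, BH adjustment, SALs and gene lookup."""

import numpy as np
import pandas as pd
import pytest

from sojapop import gea
from sojapop.errors import SojapopError
from tests.conftest import make_gm


# ---------------------------------------------------------------- FDR

def test_bh_hand_example():
    q = gea.fdr_adjust([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])


@pytest.mark.parametrize("p,expected", [
    ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ([0.2], [0.2]),
    ([], []),
])
def test_bh_degenerate_inputs(p, expected):
    np.testing.assert_allclose(gea.fdr_adjust(p), expected)


def test_bh_q_bounded_and_monotone():
    rng = np.random.default_rng(0)
    p = rng.random(500)
    q = gea.fdr_adjust(p)
    assert ((q >= p - 1e-12) & (q <= 1.0)).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_rejects_invalid_pvalues():
    with pytest.raises(SojapopError):
        gea.fdr_adjust([0.5, 1.5])


# ---------------------------------------------------------------- SALs

def _results(positions, qs, chrom="c1"):
    return pd.DataFrame({
        "chrom": chrom, "pos": positions, "env_name": "temp",
        "beta": 0.0, "z": 0.0, "p_raw": qs, "q": qs, "flag": "",
    })


def test_snps_150kb_apart_merge_into_one_sal():
    sals = gea.build_sals(_results([500_000, 650_000], [0.01, 0.02]),
                          {"c1": 2_000_000})
    assert len(sals) == 1
    assert sals.iloc[0]["start"] == 400_000
    assert sals.iloc[0]["end"] == 750_000
    assert sals.iloc[0]["n_snps"] == 2
    assert sals.iloc[0]["peak_pos"] == 500_000


def test_snps_250kb_apart_stay_separate_sals():
    sals = gea.build_sals(_results([500_000, 750_000], [0.01, 0.02]),
                          {"c1": 2_000_000})
    assert len(sals) == 2


def test_sal_intervals_clipped_to_chromosome():
    sals = gea.build_sals(_results([50_000, 1_980_000], [0.01, 0.02]),
                          {"c1": 2_000_000})
    assert sals.iloc[0]["start"] == 0
    assert sals.iloc[-1]["end"] == 2_000_000


def test_sal_count_monotone_in_flank():
    rng = np.random.default_rng(1)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), 40, replace=False))
    res = _results(pos, np.full(40, 0.01))
    lengths = {"c1": 10_000_000}
    counts = [len(gea.build_sals(res, lengths, flank=f))
              for f in (10_000, 50_000, 100_000, 500_000)]
    assert counts == sorted(counts, reverse=True)


def test_sals_merge_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    lengths = {"c1": 1_000_000}
    for _ in range(200):
        n = int(rng.integers(1, 10))
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), n, replace=False))
        sals = gea.build_sals(_results(pos, np.full(n, 0.01)), lengths,
                              flank=30_000)
        covered = set()
        for p in pos:
            covered.update(range(max(0, p - 30_000), min(1_000_000, p + 30_000)))
        got = set()
        for r in sals.itertuples():
            block = set(range(int(r.start), int(r.end)))
            assert not block & got
            got |= block
        assert got == covered


# ---------------------------------------------------------------- genes

GFF = """##gff-version 3
c1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g_inside
c1\tsrc\tgene\t3000\t3500\t.\t-\t.\tID=g_touching_end
c1\tsrc\tmRNA\t1001\t2000\t.\t+\t.\tID=m1;Parent=g_inside
c2\tsrc\tgene\t10\t20\t.\t+\t.\tID=g_other_contig
"""


def test_gff_genes_use_half_open_overlap(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF)
    genes = gea.read_gff3_genes(path)
    assert list(genes["gene_id"]) == ["g_inside", "g_touching_end", "g_other_contig"]
    assert genes.iloc[0]["start"] == 1000 and genes.iloc[0]["end"] == 2000

    sals = pd.DataFrame([
        {"chrom": "c1", "start": 500, "end": 2999, "n_snps": 1,
         "peak_pos": 1500, "peak_q": 0.01, "env_name": "temp"},
    ])
    hits = gea.genes_in_sals(sals, genes)
    # g_inside overlaps; g_touching_end starts exactly at the SAL end (2999
    # in 0-based is its start index 2999) and must be excluded
    assert list(hits["gene_id"]) == ["g_inside"]


def test_genes_in_sals_brute_force_oracle(tmp_path):
    rng = np.random.default_rng(4)
    genes = pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(5)],
        "chrom": "c1",
        "start": rng.integers(0, 900, 5),
        "homolog": "",
    })
    genes["end"] = genes["start"] + rng.integers(10, 200, 5)
    sals = pd.DataFrame([
        {"chrom": "c1", "start": 100, "end": 400, "n_snps": 1,
         "peak_pos": 200, "peak_q": 0.01, "env_name": "t"},
        {"chrom": "c1", "start": 600, "end": 800, "n_snps": 1,
         "peak_pos": 700, "peak_q": 0.01, "env_name": "t"},
    ])
    hits = gea.genes_in_sals(sals, genes)
    expected = {(i, g.gene_id) for i, s in sals.iterrows()
                for g in genes.itertuples()
                if g.start < s["end"] and g.end > s["start"]}
    got = set(zip(hits["sal_index"], hits["gene_id"]))
    assert got == expected


def test_genes_in_sals_warns_on_unknown_contig():
    sals = pd.DataFrame([{"chrom": "cX", "start": 0, "end": 10, "n_snps": 1,
                          "peak_pos": 5, "peak_q": 0.01, "env_name": "t"}])
    genes = pd.DataFrame({"gene_id": ["g"], "chrom": ["c1"], "start": [0],
                          "end": [5], "homolog": [""]})
    with pytest.warns(UserWarning):
        hits = gea.genes_in_sals(sals, genes)
    assert hits.empty


# ---------------------------------------------------------------- associate

def test_associate_validates_inputs(small_sim):
    gm = small_sim.genotypes.take_sites(np.arange(50))
    with pytest.raises(SojapopError):
        gea.associate(gm, np.ones(gm.n_samples))        # constant env
    with pytest.raises(SojapopError):
        gea.associate(gm, np.arange(5))                 # wrong length
    rng = np.random.default_rng(0)
    with pytest.warns(UserWarning):
        gea.associate(gm, rng.normal(size=gm.n_samples), n_latent=0)


def test_associate_lambda_near_one_with_structure_factors(small_sim):
    """With n_latent = n_groups - 1 the inflation factor on null SNPs sits
    near 1 (structure absorbed); without factors it is far larger."""
    from sojapop import structure

    gm = small_sim.genotypes.take_sites(
        np.flatnonzero(small_sim.genotypes.maf() >= 0.05))
    env = (small_sim.metadata.merge(small_sim.environment, on="location")
           .set_index("sample").loc[gm.samples, "annual_mean_temp"]
           .to_numpy(float))
    fac, _ = structure.pca(gm, n_components=2)
    adj = gea.associate(gm, env, n_latent=2, factors=fac[:, :2])
    assert 0.8 <= adj.attrs["lambda_gc"] <= 1.2
    with pytest.warns(UserWarning):
        raw = gea.associate(gm, env, n_latent=0)
    assert raw.attrs["lambda_gc"] > 2 * adj.attrs["lambda_gc"]


def test_associate_null_is_calibrated(small_sim):
    from sojapop import structure

    gm = small_sim.genotypes.take_sites(
        np.flatnonzero(small_sim.genotypes.maf() >= 0.05))
    env = (small_sim.metadata.merge(small_sim.environment, on="location")
           .set_index("sample").loc[gm.samples, "annual_mean_temp"]
           .to_numpy(float))
    fac, _ = structure.pca(gm, n_components=2)
    bad = 0
    for i in range(20):
        rng = np.random.default_rng(i)
        r = gea.associate(gm, rng.permutation(env), n_latent=2,
                          factors=fac[:, :2])
        bad += int((r["q"] < 0.05).any())
    assert bad <= 2
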