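"""Genetic distances, neighbor-joining, PCA and admixture-style ancestry.

Distances are allele-sharing p-distances on dosages: d(i, j) is the mean of
|g_i - g_j| / 2 over sites non-missing in both samples, a simple
model-free metric in [0, 1].  The neighbor-joining tree is built with the
Saitou–Nei agglomeration (scikit-bio's implementation; negative branch
lengths clamped to zero).  Ancestry is estimated by maximizing the binomial
admixture likelihood

    sum_il [ g_il ln(sum_k q_ik p_kl) + (2 - g_il) ln(1 - sum_k q_ik p_kl) ]

with plain EM block updates over the simplex rows of Q and frequencies P —
the same likelihood ADMIXTURE optimizes, without its quasi-Newton
acceleration, which is unnecessary at desk scale.  The number of ancestral
populations K is chosen by masked-entry cross-validation: genotype entries
are hidden fold by fold and predicted as 2 * sum_k q_ik p_kl.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from sojapop.errors import SojapopError
from sojapop.genotypes import MISSING, GenotypeMatrix


# ---------------------------------------------------------------- distances

def pdistance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise allele-sharing p-distance over shared non-missing sites."""
    if gm.n_samples < 2:
        raise SojapopError("pdistance needs >= 2 samples")
    d = gm.dosage
    obs = (d != MISSING).astype(np.float64)
    g0 = ((d == 0) & (d != MISSING)).astype(np.float64)
    g1 = (d == 1).astype(np.float64)
    g2 = (d == 2).astype(np.float64)
    shared = obs @ obs.T
    diff1 = g0 @ g1.T + g1 @ g0.T + g1 @ g2.T + g2 @ g1.T
    diff2 = g0 @ g2.T + g2 @ g0.T
    if (shared == 0).any():
        i, j = np.argwhere(shared == 0)[0]
        raise SojapopError(
            f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share no genotyped sites"
        )
    dist = (diff1 + 2.0 * diff2) / (2.0 * shared)
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(dist, ids=list(gm.samples))


def group_mean_distance(d: DistanceMatrix, grouping: dict) -> DistanceMatrix:
    """Collapse a sample distance matrix to mean cross-group distances.

    ``grouping`` maps every sample id to a location (or group) label; the
    collapsed entry for two labels is the mean of d(i, j) over cross-label
    sample pairs, with a zero diagonal.
    """
    labels = list(d.ids)
    missing = [s for s in labels if s not in grouping]
    if missing:
        raise SojapopError(f"samples without a location assignment: {missing[:5]}")
    locs = sorted(set(grouping[s] for s in labels))
    members = {loc: [i for i, s in enumerate(labels) if grouping[s] == loc]
               for loc in locs}
    for loc, mem in members.items():
        if not mem:
            raise SojapopError(f"location {loc!r} has no samples")
    raw = d.data
    out = np.zeros((len(locs), len(locs)))
    for a, b in itertools.combinations(range(len(locs)), 2):
        block = raw[np.ix_(members[locs[a]], members[locs[b]])]
        out[a, b] = out[b, a] = block.mean()
    return DistanceMatrix(out, ids=locs)


# ---------------------------------------------------------------- NJ tree

def nj_tree(d: DistanceMatrix):
    """Neighbor-joining tree (Saitou–Nei, Studier–Keppler Q-criterion).

    Returns a ``skbio.TreeNode``; negative branch lengths are clamped to 0.
    Use ``str(tree)`` or ``tree.write`` for newick output.
    """
    if len(d.ids) < 3:
        raise SojapopError("nj_tree needs >= 3 labels")
    if not np.isfinite(d.data).all():
        raise SojapopError("distance matrix contains non-finite values")
    return _skbio_nj(d, neg_as_zero=True)


# ---------------------------------------------------------------- PCA

def pca(gm: GenotypeMatrix, n_components: int = 10):
    """Genotype PCA with per-site mean imputation and sqrt(p(1-p)) scaling.

    Returns ``(scores, eigenvalues)``: sample scores for the top components
    (columns ordered by decreasing eigenvalue) and all eigenvalues of the
    sample covariance of the standardized matrix.  All-missing and
    monomorphic sites are dropped (warning for all-missing).
    """
    if gm.n_samples < 2 or gm.n_sites < 2:
        raise SojapopError("pca needs >= 2 samples and >= 2 sites")
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    all_missing = np.all(np.isnan(d), axis=0)
    if all_missing.any():
        warnings.warn(f"{all_missing.sum()} all-missing sites dropped before PCA")
    mean = np.nanmean(np.where(all_missing, 0.0, d), axis=0)
    mean[all_missing] = 0.0
    inds = np.where(np.isnan(d))
    d[inds] = mean[inds[1]]
    p = mean / 2.0
    keep = ~all_missing & (p > 0.0) & (p < 1.0)
    x = (d[:, keep] - mean[keep]) / np.sqrt(p[keep] * (1.0 - p[keep]))
    u, s, _ = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
    eigvals = s ** 2 / x.shape[1]
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    return scores, eigvals


# ---------------------------------------------------------------- admixture

@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                 # samples x K, rows on the simplex
    P: np.ndarray                 # K x sites allele frequencies
    loglik: float
    loglik_path: list = field(repr=False, default_factory=list)
    cv_error: float | None = None
    seed: int | None = None


def _admixture_loglik(g, miss, F):
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = g * np.log(F) + (2.0 - g) * np.log1p(-F)
    ll[miss] = 0.0
    return float(ll.sum())


def admixture_fit(gm_or_dosage, K: int, seed: int = 0, max_iter: int = 2000,
                  tol: float = 1e-6) -> AdmixtureFit:
    """EM fit of the binomial admixture model; loglik never decreases.

    Accepts a :class:`GenotypeMatrix` (ideally LD-pruned) or a raw dosage
    array with ``-1`` for missing.  K = 1 reduces to per-site allele
    frequencies and the closed-form binomial log-likelihood.
    """
    d = gm_or_dosage.dosage if isinstance(gm_or_dosage, GenotypeMatrix) else np.asarray(gm_or_dosage)
    n, m = d.shape
    if K < 1:
        raise SojapopError("K must be >= 1")
    if K > n:
        raise SojapopError(f"K={K} exceeds the number of samples ({n})")
    miss = d == MISSING
    g = np.where(miss, 0, d).astype(np.float64)
    g2 = np.where(miss, 0.0, 2.0)              # per-entry total allele count
    n_obs = (~miss).sum(axis=1).astype(float)  # sites observed per sample
    if (n_obs == 0).any():
        raise SojapopError("a sample has no observed genotypes")

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    freq = np.where((~miss).sum(axis=0) > 0,
                    g.sum(axis=0) / np.maximum(g2.sum(axis=0), 1e-12), 0.5)
    P = np.clip(freq[None, :] + rng.uniform(-0.1, 0.1, (K, m)), 0.05, 0.95)

    eps = 1e-12
    ll_old = -np.inf
    path = []
    for _ in range(max_iter):
        F = np.clip(Q @ P, eps, 1.0 - eps)
        ll = _admixture_loglik(g, miss, F)
        path.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) < tol:
            break
        ll_old = ll
        W1 = np.where(miss, 0.0, g / F)
        W0 = np.where(miss, 0.0, (g2 - g) / (1.0 - F))
        SA = (W1 @ P.T) * Q                   # n x K: sum_l a_ikl
        SB = (W0 @ (1.0 - P).T) * Q           # n x K: sum_l b_ikl
        Q = (SA + SB) / (2.0 * n_obs)[:, None]
        Q = np.clip(Q, eps, None)
        Q /= Q.sum(axis=1, keepdims=True)
        Pnum = P * (Q.T @ W1)                 # K x m: sum_i a_ikl
        Pden = Pnum + (1.0 - P) * (Q.T @ W0)
        P = np.clip(Pnum / np.maximum(Pden, eps), eps, 1.0 - eps)
    F = np.clip(Q @ P, eps, 1.0 - eps)
    final = _admixture_loglik(g, miss, F)
    if not path or final > path[-1]:
        path.append(final)
    return AdmixtureFit(K=K, Q=Q, P=P, loglik=path[-1], loglik_path=path, seed=seed)


def choose_K(gm_or_dosage, K_range=range(2, 11), folds: int = 5, seed: int = 0,
             metric: str = "mse", max_iter: int = 500, tol: float = 1e-4) -> dict:
    """Masked-entry cross-validated error per K.

    Non-missing genotype entries are partitioned into ``folds`` disjoint
    folds; each fold is masked in turn, the model refit, and the masked
    dosages predicted as 2 * sum_k q_ik p_kl.  ``metric`` is ``"mse"``
    (default) or ``"deviance"`` (mean binomial deviance).
    """
    d = gm_or_dosage.dosage if isinstance(gm_or_dosage, GenotypeMatrix) else np.asarray(gm_or_dosage)
    obs = np.argwhere(d != MISSING)
    if len(obs) < folds:
        raise SojapopError("not enough observed genotypes to build the CV folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(obs))
    fold_of = np.empty(len(obs), dtype=int)
    fold_of[perm] = np.arange(len(obs)) % folds
    errors = {}
    for K in K_range:
        fold_err = []
        for f in range(folds):
            mask = obs[fold_of == f]
            if len(mask) == 0:
                raise SojapopError(f"fold {f} masks zero entries")
            dm = d.copy()
            dm[mask[:, 0], mask[:, 1]] = MISSING
            fit = admixture_fit(dm, K, seed=seed * 1000 + K * 10 + f,
                                max_iter=max_iter, tol=tol)
            pred = 2.0 * (fit.Q @ fit.P)[mask[:, 0], mask[:, 1]]
            truth = d[mask[:, 0], mask[:, 1]].astype(float)
            if metric == "mse":
                fold_err.append(float(np.mean((pred - truth) ** 2)))
            elif metric == "deviance":
                fhat = np.clip(pred / 2.0, 1e-9, 1.0 - 1e-9)
                dev = -2.0 * (truth * np.log(fhat) + (2.0 - truth) * np.log1p(-fhat))
                fold_err.append(float(np.mean(dev)))
            else:
                raise SojapopError(f"unknown CV metric {metric!r}")
        errors[int(K)] = float(np.mean(fold_err))
    return errors


def match_labels(assigned: np.ndarray, truth: np.ndarray) -> float:
    """Best label-permutation agreement between two integer label vectors."""
    ks = sorted(set(assigned) | set(truth))
    best = 0.0
    for perm in itertools.permutations(ks):
        relab = np.array([perm[k] for k in assigned])
        best = max(best, float(np.mean(relab == truth)))
    return best


def write_q_matrix(fit: AdmixtureFit, samples, path, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"# sojapop admixture K={fit.K} seed={fit.seed} "
                 f"loglik={fit.loglik:.6f} {header_extra}\n")
        df = pd.DataFrame(fit.Q, columns=[f"Q{k + 1}" for k in range(fit.K)])
        df.insert(0, "sample", list(samples))
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")
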