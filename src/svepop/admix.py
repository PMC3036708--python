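"""Maximum-likelihood admixture decomposition and the Evanno delta-K
cluster-number statistic.

The model is the classic admixture likelihood: each of an individual's
two allele copies at a locus originates from cluster k with probability
q_ik and is the A1 allele with probability f_kl. Q and F are estimated
jointly by EM (the frappe/ADMIXTURE likelihood, fit by EM rather than
quasi-Newton); the likelihood is multimodal for K >= 2, so several random
restarts are run and the best kept. Cluster labels are identifiable only
up to permutation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix

_F_EPS = 1e-6  # cluster frequencies clipped away from {0,1} to keep log finite


@dataclass
class AdmixtureResult:
    Q: np.ndarray  # (n, K), rows sum to 1
    F_alleles: np.ndarray  # (K, L)
    loglik_trace: list[float]
    K: int
    seed: int

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


@dataclass
class EvannoResult:
    table: "np.ndarray"  # structured rows (K, mean_loglik, sd_loglik, delta_k)
    best_k: int


def _loglik_from_pi(g, miss, pi) -> float:
    ll = g * np.log(pi) + (2 - g) * np.log1p(-pi)
    ll = np.where(miss, 0.0, ll + np.where(g == 1, np.log(2.0), 0.0))
    return float(ll.sum())


def _admixture_loglik(g, miss, Q, F) -> float:
    # P(g copies of A1) = C(2,g) pi^g (1-pi)^(2-g), pi = Q @ F
    pi = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    return _loglik_from_pi(g, miss, pi)


def _em_once(g, miss, K, rng, tol, max_iter):
    n, L = g.shape
    gz = np.where(miss, 0, g).astype(float)
    two_minus = np.where(miss, 0, 2 - g).astype(float)
    n_called = 2.0 * (~miss).sum(axis=1)

    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.05, 0.95, size=(K, L)), _F_EPS, 1 - _F_EPS)

    pi = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    trace = [_loglik_from_pi(g, miss, pi)]
    for _ in range(max_iter):
        # expected haplotype-origin counts:
        # a_ik = sum_l g_il * q_ik f_kl / pi_il ; b_ik likewise for the
        # non-A1 copies; per-locus sums for F use the same responsibilities
        r1 = gz / pi  # (n, L)
        r0 = two_minus / (1.0 - pi)
        A = Q * (r1 @ F.T)  # (n, K): sum over loci of A1-copy responsibilities
        B = Q * (r0 @ (1.0 - F).T)
        Q_new = (A + B) / n_called[:, None]
        # F update: expected A1 vs non-A1 copies attributed to cluster k
        FA = F * (Q.T @ r1)  # (K, L)
        FB = (1.0 - F) * (Q.T @ r0)
        F = np.clip(FA / np.clip(FA + FB, 1e-300, None), _F_EPS, 1 - _F_EPS)
        Q = np.clip(Q_new, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)
        pi = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        ll = _loglik_from_pi(g, miss, pi)
        trace.append(ll)
        if ll - trace[-2] < tol and ll >= trace[-2] - 1e-6:
            break
    return Q, F, trace


def admixture_em(
    G: GenotypeMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 3,
) -> AdmixtureResult:
    """Fit the K-cluster admixture model by EM with random restarts.

    Missing genotypes are skipped in the likelihood. K = 1 reduces to the
    sample allele frequencies in closed form. Returns the restart with the
    best final log-likelihood; deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_samples:
        raise ValueError("K exceeds the number of samples")
    g = G.dosage.astype(np.int64)
    miss = G.dosage == MISSING

    if K == 1:
        p = G.allele_freq()
        p = np.clip(np.nan_to_num(p, nan=0.5), _F_EPS, 1 - _F_EPS)
        Q = np.ones((G.n_samples, 1))
        F = p[None, :]
        return AdmixtureResult(
            Q=Q, F_alleles=F, loglik_trace=[_admixture_loglik(g, miss, Q, F)],
            K=1, seed=seed,
        )

    best = None
    ss = np.random.SeedSequence([seed, K])
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        Q, F, trace = _em_once(g, miss, K, rng, tol, max_iter)
        if best is None or trace[-1] > best[2][-1]:
            best = (Q, F, trace)
    Q, F, trace = best
    return AdmixtureResult(Q=Q, F_alleles=F, loglik_trace=trace, K=K, seed=seed)


def align_clusters(Q_est: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute estimated cluster columns to best match a reference Q.

    Returns the column-permuted copy of ``Q_est`` minimizing mean absolute
    error; resolves label switching before any Q comparison.
    """
    K = Q_est.shape[1]
    best_perm, best_err = None, np.inf
    for perm in itertools.permutations(range(K)):
        err = np.abs(Q_est[:, perm] - Q_true).mean()
        if err < best_err:
            best_err, best_perm = err, perm
    return Q_est[:, best_perm]


def evanno_delta_k(logliks: dict[int, list[float]]) -> EvannoResult:
    """Evanno second-difference statistic over replicate run likelihoods.

    logliks maps K to the final log-likelihoods of replicate runs. For
    interior K (with K-1 and K+1 present):
    delta_K = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)).
    Requires >= 3 consecutive K and >= 2 replicates at each K; sd must be
    positive wherever delta_K is computed.
    """
    ks = sorted(logliks)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    means, sds = {}, {}
    for k in ks:
        reps = np.asarray(logliks[k], dtype=float)
        if len(reps) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates")
        means[k] = reps.mean()
        sds[k] = reps.std(ddof=1)
    rows = []
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            rows.append((k, means[k], sds[k], np.nan))
            continue
        if sds[k] == 0:
            raise ValueError(f"K={k}: zero replicate sd; delta_K undefined")
        l2 = abs(means[k + 1] - 2 * means[k] + means[k - 1])
        rows.append((k, means[k], sds[k], l2 / sds[k]))
    table = np.array(
        rows, dtype=[("K", int), ("mean_loglik", float), ("sd_loglik", float), ("delta_k", float)]
    )
    interior = table[~np.isnan(table["delta_k"])]
    best_k = int(interior["K"][np.argmax(interior["delta_k"])])
    return EvannoResult(table=table, best_k=best_k)


def write_q_matrix(result: AdmixtureResult, sample_ids, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(sample_ids, result.Q):
            fh.write(str(sid) + " " + " ".join(f"{q:.6f}" for q in row) + "\n")


def read_q_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    return np.array(ids, dtype=object), np.array(rows)
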