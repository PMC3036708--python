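"""Identity-by-state distances, classical MDS, and permutation Mann-Whitney
comparison of IBS-similarity distributions between populations."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genio import MISSING, GenotypeMatrix


@dataclass
class SquareDistanceMatrix:
    """Symmetric pairwise matrix keyed by sample or population ids.

    kind is one of 'ibs_distance', 'km', 'fst'.
    """

    ids: np.ndarray
    values: np.ndarray
    kind: str = "ibs_distance"

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if self.kind in ("ibs_distance", "km") and not np.allclose(
            np.diag(self.values), 0.0
        ):
            raise ValueError("nonzero diagonal")
        if self.kind == "ibs_distance" and (
            self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12
        ):
            raise ValueError("IBS distances outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.ids)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, ids) -> "SquareDistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = np.array([pos[s] for s in ids], dtype=int)
        return SquareDistanceMatrix(
            np.asarray(ids, dtype=object), self.values[np.ix_(idx, idx)], self.kind
        )

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, kind: str = "ibs_distance") -> "SquareDistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.index.to_numpy(dtype=object), df.to_numpy(), kind)


@dataclass
class MdsResult:
    coordinates: np.ndarray  # (n, dims)
    eigenvalues: np.ndarray  # descending, all retained (positive) ones
    variance_explained: np.ndarray  # per retained axis


def ibs_matrix(G: GenotypeMatrix) -> SquareDistanceMatrix:
    """Pairwise IBS distance: 1 minus the mean fraction of shared alleles.

    Per locus the shared fraction between dosages d_i, d_j is
    1 - |d_i - d_j| / 2; the mean runs over loci non-missing in both
    samples (pairwise-complete). A pair with no overlapping loci is an
    error.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = G.dosage
    # indicator decomposition: |d_i - d_j| summed over loci via matmuls
    i0 = (d == 0).astype(np.float64)
    i1 = (d == 1).astype(np.float64)
    i2 = (d == 2).astype(np.float64)
    ok = (i0 + i1 + i2)  # non-missing indicator

    c01 = i0 @ i1.T
    c12 = i1 @ i2.T
    c02 = i0 @ i2.T
    absdiff = (c01 + c01.T) + (c12 + c12.T) + 2.0 * (c02 + c02.T)
    overlap = ok @ ok.T
    if np.any(overlap[~np.eye(G.n_samples, dtype=bool)] == 0):
        i, j = np.argwhere((overlap == 0) & ~np.eye(G.n_samples, dtype=bool))[0]
        raise ValueError(
            f"samples {G.sample_ids[i]!r} and {G.sample_ids[j]!r} share no called loci"
        )
    with np.errstate(invalid="ignore"):
        dist = absdiff / (2.0 * overlap)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # kill float asymmetry
    return SquareDistanceMatrix(G.sample_ids.copy(), dist, kind="ibs_distance")


def classical_mds(D: SquareDistanceMatrix, dims: int = 2) -> MdsResult:
    """Torgerson classical scaling of a distance matrix.

    Double-centers the squared distances, eigendecomposes, and returns
    coordinates scaled by the square roots of the positive eigenvalues.
    variance_explained_k = lambda_k / sum(positive lambdas); negative
    eigenvalues (non-Euclidean input) are excluded from both coordinates
    and the denominator. ``dims`` beyond the positive spectrum truncates
    with a warning.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    n = D.n
    D2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-12 * abs(evals[0]))
    lam = evals[pos]
    vec = evecs[:, pos]
    if dims > len(lam):
        import warnings

        warnings.warn(
            f"requested {dims} dimensions but only {len(lam)} positive eigenvalues; truncating"
        )
        dims = max(len(lam), 1)
    if len(lam) == 0:
        raise ValueError("no positive eigenvalues; degenerate distance matrix")
    coords = vec[:, :dims] * np.sqrt(lam[:dims])
    return MdsResult(
        coordinates=coords,
        eigenvalues=lam,
        variance_explained=lam[:dims] / lam.sum(),
    )


def _mannwhitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for sample x vs y (number of (x, y) pairs with x > y,
    ties counted half)."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _within_group_values(values: np.ndarray, members_a, members_b):
    a = values[np.ix_(members_a, members_a)][np.triu_indices(len(members_a), 1)]
    b = values[np.ix_(members_b, members_b)][np.triu_indices(len(members_b), 1)]
    return a, b


def permutation_mannwhitney(
    D: SquareDistanceMatrix,
    labels: np.ndarray,
    groupA: str,
    groupB: str,
    n_perm: int = 10_000,
    seed: int = 0,
    method: str = "permutation",
) -> tuple[float, float]:
    """Compare within-group IBS-distance distributions of two populations.

    The two samples are the within-group pairwise values of groupA and
    groupB. Because pairwise values sharing an individual are dependent,
    the null is built by shuffling *individual* labels and rebuilding both
    sets. Two-sided empirical p by doubling the smaller tail:
    p = (1 + #{perm tail >= obs tail}) / (n_perm + 1), capped at 1.

    method='exact' enumerates every distinct assignment of individuals to
    the two groups instead (small n only); the identity assignment counts
    in the numerator.
    """
    labels = np.asarray(labels)
    idx_a = np.where(labels == groupA)[0]
    idx_b = np.where(labels == groupB)[0]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each group needs >= 2 individuals for within-group pairs")
    if n_perm < 1 and method == "permutation":
        raise ValueError("n_perm must be >= 1")

    pool = np.concatenate([idx_a, idx_b])
    na = len(idx_a)
    obs_a, obs_b = _within_group_values(D.values, idx_a, idx_b)
    u_obs = _mannwhitney_u(obs_a, obs_b)
    mu = len(obs_a) * len(obs_b) / 2.0  # center of the U distribution

    def tail_stat(u: float) -> float:
        return abs(u - mu)

    if method == "exact":
        count = 0
        total = 0
        for combo in itertools.combinations(range(len(pool)), na):
            sel = np.zeros(len(pool), dtype=bool)
            sel[list(combo)] = True
            a, b = _within_group_values(D.values, pool[sel], pool[~sel])
            if tail_stat(_mannwhitney_u(a, b)) >= tail_stat(u_obs) - 1e-12:
                count += 1
            total += 1
        return u_obs, count / total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        a, b = _within_group_values(D.values, perm[:na], perm[na:])
        if tail_stat(_mannwhitney_u(a, b)) >= tail_stat(u_obs) - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return u_obs, min(1.0, p)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m). ``m`` defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m smaller than the number of p-values")
    return np.minimum(1.0, p * m)
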