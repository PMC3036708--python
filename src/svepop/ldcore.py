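"""Two-locus linkage disequilibrium: EM haplotype-frequency estimation,
D-prime, the index-SNP pair-sampling scheme, windowed decay profiles and
paired population comparisons.

Unphased diploid genotype pairs determine haplotypes except for double
heterozygotes; the EM iterates the expected split of those between the
coupling (AB/ab) and repulsion (Ab/aB) phases until the log-likelihood
stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix


@dataclass
class LdPair:
    locus_a: str
    locus_b: str
    dist_bp: int
    hap_freqs: tuple[float, float, float, float]  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    Dprime: float
    converged: bool
    loglik: float


def _genotype_pair_counts(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    """3x3 table of joint genotype counts over pairwise-complete samples."""
    ok = (da != MISSING) & (db != MISSING)
    a, b = da[ok], db[ok]
    counts = np.zeros((3, 3), dtype=np.int64)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((a == i) & (b == j))
    return counts


def em_haplotype_freqs(
    dosage_a: np.ndarray,
    dosage_b: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[tuple[float, float, float, float], float, bool]:
    """EM estimate of the four two-locus haplotype frequencies.

    Dosages count the A (resp. B) allele at each locus; only double
    heterozygotes are phase-ambiguous. Initialized at linkage
    equilibrium; stops when the log-likelihood gain drops below ``tol``.
    Returns ((p_AB, p_Ab, p_aB, p_ab), final loglik, converged).
    """
    counts = _genotype_pair_counts(np.asarray(dosage_a), np.asarray(dosage_b))
    n = counts.sum()
    if n < 2:
        raise ValueError("need at least 2 pairwise-complete samples")
    pa = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2.0 * n)
    pb = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2.0 * n)
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus in the pairwise-complete subset")

    # Known haplotype counts from unambiguous genotypes (dosage 0/2 at
    # either locus); the double-het cell counts[1,1] is split by EM.
    # haplotypes: AB, Ab, aB, ab; genotype (i copies of A, j copies of B)
    known = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            if c == 0:
                continue
            # each individual contributes 2 haplotypes with determined phase
            n_A, n_B = i, j
            # phase is forced for every non-double-het genotype
            hap_AB = min(n_A, n_B)
            hap_Ab = n_A - hap_AB
            hap_aB = n_B - hap_AB
            hap_ab = 2 - hap_AB - hap_Ab - hap_aB
            known += c * np.array([hap_AB, hap_Ab, hap_aB, hap_ab])
    n_dh = counts[1, 1]

    f = np.array([pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    def loglik(fv: np.ndarray) -> float:
        ll = float(np.dot(known, np.log(np.clip(fv, 1e-300, None))))
        if n_dh:
            coupling = fv[0] * fv[3]
            repulsion = fv[1] * fv[2]
            ll += n_dh * np.log(max(2 * coupling + 2 * repulsion, 1e-300))
        return ll

    prev = loglik(f)
    converged = False
    for _ in range(max_iter):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        tot = coupling + repulsion
        w = coupling / tot if tot > 0 else 0.5
        counts_hat = known + n_dh * np.array([w, 1 - w, 1 - w, w])
        f = counts_hat / (2.0 * n)
        cur = loglik(f)
        if cur < prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        if cur - prev < tol:
            converged = True
            prev = cur
            break
        prev = cur
    return (float(f[0]), float(f[1]), float(f[2]), float(f[3])), float(prev), converged


def dprime(hap_freqs) -> float:
    """Lewontin's D' from four haplotype frequencies (p_AB, p_Ab, p_aB, p_ab).

    D = p_AB - p_A p_B, scaled by its maximum attainable magnitude given
    the allele frequencies; returned in [0, 1].
    """
    f = np.asarray(hap_freqs, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6 or (f < -1e-12).any():
        raise ValueError("invalid haplotype frequencies")
    p_A = f[0] + f[1]
    p_B = f[0] + f[2]
    if p_A <= 0 or p_A >= 1 or p_B <= 0 or p_B >= 1:
        raise ValueError("monomorphic marginal; D' undefined")
    D = f[0] - p_A * p_B
    if D > 0:
        dmax = min(p_A * (1 - p_B), (1 - p_A) * p_B)
        return float(D / dmax)
    if D < 0:
        dmax = -min(p_A * p_B, (1 - p_A) * (1 - p_B))
        return float(D / dmax)
    return 0.0


def ld_pair(G: GenotypeMatrix, ja: int, jb: int, tol: float = 1e-8) -> LdPair:
    """Estimate haplotype frequencies and D' for one locus pair of ``G``."""
    hap, ll, conv = em_haplotype_freqs(G.dosage[:, ja], G.dosage[:, jb], tol=tol)
    p_A = hap[0] + hap[1]
    p_B = hap[0] + hap[2]
    return LdPair(
        locus_a=G.locus_ids[ja],
        locus_b=G.locus_ids[jb],
        dist_bp=int(abs(G.pos_bp[ja] - G.pos_bp[jb])),
        hap_freqs=hap,
        D=float(hap[0] - p_A * p_B),
        Dprime=dprime(hap),
        converged=conv,
        loglik=ll,
    )


def sample_ld_pairs(
    G: GenotypeMatrix, n_index: int, max_dist_bp: int, seed: int = 0
) -> list[tuple[int, int]]:
    """Index-SNP pair sampling: draw ``n_index`` loci uniformly without
    replacement; pair each with every same-chromosome locus at
    0 < distance < ``max_dist_bp``. Duplicate pairs are removed.

    Returns column-index pairs (j, k) with j < k.
    """
    if n_index > G.n_loci:
        raise ValueError("n_index exceeds number of loci")
    rng = np.random.default_rng(seed)
    index = rng.choice(G.n_loci, size=n_index, replace=False)
    pairs: set[tuple[int, int]] = set()
    for j in index:
        same = np.where(
            (G.chrom == G.chrom[j])
            & (np.abs(G.pos_bp - G.pos_bp[j]) > 0)
            & (np.abs(G.pos_bp - G.pos_bp[j]) < max_dist_bp)
        )[0]
        for k in same:
            pairs.add((min(j, k), max(j, k)))
    return sorted(pairs)


def ld_decay_profile(
    pairs: list[LdPair], window_bp: int = 40_000, step_bp: int = 10_000
):
    """Median D' in overlapping distance windows.

    Windows are [s, s + window_bp) for s = 0, step_bp, 2*step_bp, ...; a
    pair contributes to every window containing its distance. Windows
    with no pairs are omitted. Returns a list of (window_start, n, median).
    """
    if not pairs:
        return []
    max_d = max(p.dist_bp for p in pairs)
    out = []
    s = 0
    while s <= max_d:
        members = [p.Dprime for p in pairs if s <= p.dist_bp < s + window_bp]
        if members:
            out.append((s, len(members), float(np.median(members))))
        s += step_bp
    return out


# ---------------------------------------------------------------------------
# Paired comparison of D' between populations
# ---------------------------------------------------------------------------


def _wilcoxon_exact_p(ranks2: np.ndarray, w2: int) -> float:
    """Exact two-sided signed-rank p via DP over doubled midranks.

    ranks2: doubled midranks (integers); w2: doubled observed W+.
    """
    total = ranks2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    dist /= dist.sum()
    cdf_le = dist[: w2 + 1].sum()
    cdf_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


def compare_ld_paired(dprimes_popA, dprimes_popB) -> tuple[float, float]:
    """Wilcoxon signed-rank test of paired D' values from two populations.

    Zero differences are dropped. Exact distribution (DP over midranks,
    ties allowed) when at most 25 non-zero differences remain; otherwise
    the normal approximation with tie correction. Returns (W+, two-sided p).
    """
    a = np.asarray(dprimes_popA, dtype=float)
    b = np.asarray(dprimes_popB, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        import warnings

        warnings.warn("all paired differences are zero")
        return 0.0, 1.0
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        ranks2 = np.round(2 * ranks).astype(int)
        w2 = int(round(2 * w_plus))
        return w_plus, _wilcoxon_exact_p(ranks2, w2)
    mu = n * (n + 1) / 4.0
    # tie correction on the variance
    _, t = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (t**3 - t).sum() / 48.0
    from scipy.stats import norm

    z = (w_plus - mu) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z))))
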