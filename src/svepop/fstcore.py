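"""Weir-Cockerham F_ST, hierarchical F-statistics, permutation inference,
and equal-size downsampling.

The multilocus estimator is the ratio-of-sums theta-hat of Weir &
Cockerham (1984) built from per-locus variance components a (among
populations), b (among individuals within populations) and c (within
individuals), using observed heterozygosity. Negative estimates are
reported as-is: near F_ST = 0 truncation would bias the estimator upward.

The hierarchical decomposition (regions / provinces within regions /
within provinces) is a nested ANOVA on allele indicators; its F_CT, F_SC
and F_ST satisfy (1 - F_ST) = (1 - F_CT)(1 - F_SC) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import MISSING, GenotypeMatrix


@dataclass
class FstResult:
    theta: float
    a_sum: float
    b_sum: float
    c_sum: float
    n_perm: int = 0
    p_perm: float | None = None


@dataclass
class HierFstResult:
    f_ct: float
    f_sc: float
    f_st: float
    p_ct: float | None = None
    p_sc: float | None = None


# ---------------------------------------------------------------------------
# Weir-Cockerham components
# ---------------------------------------------------------------------------


def _group_summaries(dosage: np.ndarray, het: np.ndarray, ok: np.ndarray, member: np.ndarray):
    """Per-population, per-locus (n, sum dosage, n het) via one stacked matmul.

    member: (r, n) 0/1 indicator of population membership.
    Returns n_il, p_il, h_il arrays of shape (r, L) (p, h NaN where n=0).
    """
    stacked = np.concatenate([ok, dosage * ok, het], axis=1)  # (n, 3L)
    res = member @ stacked  # (r, 3L)
    L = dosage.shape[1]
    n_il = res[:, :L]
    sum_d = res[:, L : 2 * L]
    n_het = res[:, 2 * L :]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_il = np.where(n_il > 0, sum_d / (2.0 * n_il), np.nan)
        h_il = np.where(n_il > 0, n_het / n_il, np.nan)
    return n_il, p_il, h_il


def _wc_components(n_il: np.ndarray, p_il: np.ndarray, h_il: np.ndarray):
    """Per-locus Weir-Cockerham variance components for diploids.

    Inputs are (r, L): per-population sample sizes, A1 frequencies and
    observed heterozygote proportions. Loci with fewer than two
    populations sampled, mean sample size <= 1, or monomorphic across all
    populations are returned as NaN and skipped by the caller.
    """
    r_eff = (n_il > 0).sum(axis=0).astype(float)  # populations sampled per locus
    n_sum = n_il.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = n_sum / r_eff
        pbar = np.where(n_il > 0, n_il * np.nan_to_num(p_il), 0.0).sum(axis=0) / n_sum
        hbar = np.where(n_il > 0, n_il * np.nan_to_num(h_il), 0.0).sum(axis=0) / n_sum
        nc = (n_sum - (n_il**2).sum(axis=0) / n_sum) / (r_eff - 1.0)
        dev = np.where(n_il > 0, np.nan_to_num(p_il) - pbar, 0.0)
        s2 = (n_il * dev**2).sum(axis=0) / ((r_eff - 1.0) * nbar)

        term = pbar * (1.0 - pbar) - (r_eff - 1.0) / r_eff * s2
        a = (nbar / nc) * (s2 - (term - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (term - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0

    valid = (r_eff >= 2) & (nbar > 1.0) & (nc > 0)
    poly = (pbar > 0) & (pbar < 1)
    valid &= poly
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def _prepare(G: GenotypeMatrix):
    ok = (G.dosage != MISSING).astype(np.float64)
    dosage = np.where(G.dosage == MISSING, 0, G.dosage).astype(np.float64)
    het = (G.dosage == 1).astype(np.float64)
    return dosage, het, ok


def _membership(labels: np.ndarray) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    pops = list(dict.fromkeys(labels))
    member = np.stack([(labels == p).astype(np.float64) for p in pops])
    return member, pops


def wc_fst(G: GenotypeMatrix, pop_labels) -> FstResult:
    """Multilocus Weir-Cockerham theta-hat over the given populations.

    Loci monomorphic across all populations are skipped. Populations must
    number at least two, each with at least two samples.
    """
    member, pops = _membership(np.asarray(pop_labels))
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    if (member.sum(axis=1) < 2).any():
        raise ValueError("every population needs at least 2 samples")
    dosage, het, ok = _prepare(G)
    n_il, p_il, h_il = _group_summaries(dosage, het, ok, member)
    a, b, c = _wc_components(n_il, p_il, h_il)
    valid = ~np.isnan(a)
    if not valid.any():
        raise ValueError("no usable polymorphic loci")
    a_sum = float(np.nansum(a))
    b_sum = float(np.nansum(b))
    c_sum = float(np.nansum(c))
    theta = a_sum / (a_sum + b_sum + c_sum)
    return FstResult(theta=theta, a_sum=a_sum, b_sum=b_sum, c_sum=c_sum)


def fst_permutation_p(
    G: GenotypeMatrix, pop_labels, n_perm: int = 5000, seed: int = 0
) -> FstResult:
    """Weir-Cockerham theta with a one-sided upper permutation p-value.

    Individuals' population labels are permuted; theta recomputed each
    time; p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(pop_labels)
    member, pops = _membership(labels)
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    if (member.sum(axis=1) < 2).any():
        raise ValueError("every population needs at least 2 samples")
    dosage, het, ok = _prepare(G)
    stacked = np.concatenate([ok, dosage * ok, het], axis=1)

    def theta_for(member_mat: np.ndarray) -> float:
        res = member_mat @ stacked
        L = dosage.shape[1]
        n_il = res[:, :L]
        with np.errstate(invalid="ignore", divide="ignore"):
            p_il = np.where(n_il > 0, res[:, L : 2 * L] / (2.0 * n_il), np.nan)
            h_il = np.where(n_il > 0, res[:, 2 * L :] / n_il, np.nan)
        a, b, c = _wc_components(n_il, p_il, h_il)
        return float(np.nansum(a) / (np.nansum(a) + np.nansum(b) + np.nansum(c)))

    obs = wc_fst(G, labels)
    rng = np.random.default_rng(seed)
    n = G.n_samples
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if theta_for(member[:, perm]) >= obs.theta - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return FstResult(
        theta=obs.theta,
        a_sum=obs.a_sum,
        b_sum=obs.b_sum,
        c_sum=obs.c_sum,
        n_perm=n_perm,
        p_perm=p,
    )


def pairwise_fst_matrix(G: GenotypeMatrix, pop_labels) -> "np.ndarray":
    """Pairwise Weir-Cockerham theta between every pair of populations.

    Returns a SquareDistanceMatrix (kind 'fst'); negative estimates are
    kept (the matrix is a dissimilarity summary, not a metric).
    """
    from .ibsmds import SquareDistanceMatrix

    labels = np.asarray(pop_labels)
    pops = list(dict.fromkeys(labels))
    k = len(pops)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mask = (labels == pops[i]) | (labels == pops[j])
            sub = G.take_samples(np.where(mask)[0])
            res = wc_fst(sub, labels[mask])
            vals[i, j] = vals[j, i] = res.theta
    return SquareDistanceMatrix(np.array(pops, dtype=object), vals, kind="fst")


# ---------------------------------------------------------------------------
# Hierarchical F-statistics
# ---------------------------------------------------------------------------


def _nested_anova_components(
    dosage: np.ndarray, ok: np.ndarray, region_of: np.ndarray, prov_of: np.ndarray
):
    """Variance components (sigma_a, sigma_b, sigma_c) per locus of a
    nested ANOVA on allele indicators: regions / provinces in regions /
    allele copies within provinces (HW-pooled).

    Returns summed components over loci.
    """
    provs = list(dict.fromkeys(prov_of))
    regions = list(dict.fromkeys(region_of))
    pmask = np.stack([(prov_of == p).astype(float) for p in provs])  # (P, n)
    prov_region = []
    for p in provs:
        rg = set(region_of[prov_of == p])
        if len(rg) != 1:
            raise ValueError(f"province {p!r} spans multiple regions")
        prov_region.append(rg.pop())
    prov_region = np.array(prov_region, dtype=object)

    # per-province allele counts (N_gp) and A1-copy sums (Y_gp) per locus
    N_gp = 2.0 * (pmask @ ok)  # (P, L)
    Y_gp = pmask @ (dosage * ok)

    reg_index = {r: i for i, r in enumerate(regions)}
    rmask = np.zeros((len(regions), len(provs)))
    for pi, r in enumerate(prov_region):
        rmask[reg_index[r], pi] = 1.0

    N_g = rmask @ N_gp  # (G, L)
    Y_g = rmask @ Y_gp
    N = N_gp.sum(axis=0)
    Y = Y_gp.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        # sums of squares of the binary allele indicator at the three levels
        prov_term = np.where(N_gp > 0, Y_gp**2 / N_gp, 0.0).sum(axis=0)
        reg_term = np.where(N_g > 0, Y_g**2 / N_g, 0.0).sum(axis=0)
        ss_within_prov = Y - prov_term
        ss_prov_in_reg = prov_term - reg_term
        ss_region = reg_term - Y**2 / N

        P_eff = (N_gp > 0).sum(axis=0).astype(float)
        G_eff = (N_g > 0).sum(axis=0).astype(float)
        df_a = G_eff - 1.0
        df_b = P_eff - G_eff
        df_w = N - P_eff

        # unequal-size coefficients of the expected mean squares
        ng_of_prov = np.take(N_g, _prov_region_idx(rmask), axis=0)  # (P, L)
        ngp2_over_ng = np.where(ng_of_prov > 0, N_gp**2 / ng_of_prov, 0.0).sum(axis=0)
        ngp2_over_n = (N_gp**2).sum(axis=0) / N
        ng2_over_n = (N_g**2).sum(axis=0) / N

        n_prime = np.where(df_b > 0, (N - ngp2_over_ng) / df_b, np.nan)
        n_dprime = np.where(df_a > 0, (ngp2_over_ng - ngp2_over_n) / df_a, np.nan)
        n_tprime = np.where(df_a > 0, (N - ng2_over_n) / df_a, np.nan)

        ms_w = ss_within_prov / df_w
        ms_b = np.where(df_b > 0, ss_prov_in_reg / df_b, np.nan)
        ms_a = ss_region / df_a

        sig_c = ms_w
        sig_b = (ms_b - ms_w) / n_prime
        sig_a = (ms_a - ms_w - n_dprime * sig_b) / n_tprime

    p_all = Y / N
    valid = (p_all > 0) & (p_all < 1) & (df_a > 0) & (df_b > 0) & (df_w > 0)
    valid &= np.isfinite(sig_a) & np.isfinite(sig_b) & np.isfinite(sig_c)
    return (
        float(np.nansum(np.where(valid, sig_a, 0.0))),
        float(np.nansum(np.where(valid, sig_b, 0.0))),
        float(np.nansum(np.where(valid, sig_c, 0.0))),
    )


def _prov_region_idx(rmask: np.ndarray) -> np.ndarray:
    """For each province (column of rmask) the index of its region row."""
    return rmask.argmax(axis=0)


def hierarchical_fst(
    G: GenotypeMatrix,
    region_labels,
    province_labels,
    n_perm: int = 0,
    seed: int = 0,
) -> HierFstResult:
    """Three-level F-statistics: F_CT (among regions), F_SC (among
    provinces within regions), F_ST (provinces vs total).

    Permutation schemes: whole provinces are permuted among regions for
    F_CT; individuals among provinces within their region for F_SC.
    """
    region_labels = np.asarray(region_labels)
    province_labels = np.asarray(province_labels)
    for p in dict.fromkeys(province_labels):
        if len(set(region_labels[province_labels == p])) != 1:
            raise ValueError(f"province {p!r} not nested in a single region")
    if len(set(region_labels)) < 2:
        raise ValueError("need at least 2 regions")

    dosage, het, ok = _prepare(G)

    def fstats(reg: np.ndarray, prov: np.ndarray):
        sa, sb, sc = _nested_anova_components(dosage, ok, reg, prov)
        tot = sa + sb + sc
        f_ct = sa / tot
        f_sc = sb / (sb + sc)
        f_st = (sa + sb) / tot
        return f_ct, f_sc, f_st

    f_ct, f_sc, f_st = fstats(region_labels, province_labels)

    p_ct = p_sc = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        provs = list(dict.fromkeys(province_labels))
        prov_region = {p: region_labels[province_labels == p][0] for p in provs}
        region_values = [prov_region[p] for p in provs]

        # F_CT: permute the province -> region assignment
        count_ct = 0
        for _ in range(n_perm):
            shuffled = rng.permutation(region_values)
            new_region = np.empty_like(region_labels)
            for p, r in zip(provs, shuffled):
                new_region[province_labels == p] = r
            stat = fstats(new_region, province_labels)[0]
            if stat >= f_ct - 1e-15:
                count_ct += 1
        p_ct = (1 + count_ct) / (n_perm + 1)

        # F_SC: permute individuals among provinces within each region
        count_sc = 0
        idx_by_region = {
            r: np.where(region_labels == r)[0] for r in dict.fromkeys(region_labels)
        }
        for _ in range(n_perm):
            new_prov = province_labels.copy()
            for r, idx in idx_by_region.items():
                new_prov[idx] = province_labels[rng.permutation(idx)]
            stat = fstats(region_labels, new_prov)[1]
            if stat >= f_sc - 1e-15:
                count_sc += 1
        p_sc = (1 + count_sc) / (n_perm + 1)

    return HierFstResult(f_ct=f_ct, f_sc=f_sc, f_st=f_st, p_ct=p_ct, p_sc=p_sc)


# ---------------------------------------------------------------------------
# Downsampling
# ---------------------------------------------------------------------------


def downsample(G: GenotypeMatrix, labels, n_per_pop: int, seed: int = 0):
    """Uniform random subset of ``n_per_pop`` samples per population.

    Used before frequency and LD comparisons so that sample size does not
    drive the statistics. Returns (subset GenotypeMatrix, subset labels).
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for pop in dict.fromkeys(labels):
        idx = np.where(labels == pop)[0]
        if len(idx) < n_per_pop:
            raise ValueError(
                f"population {pop!r} has {len(idx)} samples, fewer than {n_per_pop}"
            )
        chosen = rng.choice(idx, size=n_per_pop, replace=False)
        keep.extend(sorted(chosen))
    keep = np.array(keep, dtype=int)
    return G.take_samples(keep), labels[keep]
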