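"""Quality control for merged SNP panels.

Implements the standard battery applied before structure analyses:
per-sample and per-SNP call-rate filters, an exact Hardy-Weinberg test
within populations, a whole-dataset MAF filter, removal of near-duplicate
individuals by IBS, a two-group allele-frequency concordance filter for
batch effects (or case/control leakage), and greedy LD pruning.

Filter order in :func:`apply_qc` is fixed (samples -> SNP call rate ->
HWE per population -> MAF) so that runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix
from .ibsmds import ibs_matrix


@dataclass
class QcThresholds:
    sample_callrate: float = 0.99
    snp_callrate: float = 0.95
    hwe_p: float = 1e-7
    maf: float = 0.05
    dup_ibs_distance: float = 0.05
    concordance_p: float = 1e-10
    case_control_p: float = 0.1

    def __post_init__(self) -> None:
        for name in ("sample_callrate", "snp_callrate", "maf", "dup_ibs_distance"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name}={v} outside (0, 1]")
        for name in ("hwe_p", "concordance_p", "case_control_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} outside (0, 1)")


@dataclass
class QcReport:
    """Record of every removal with its triggering statistic."""

    removed_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason", "statistic"])
    )
    removed_snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["locus_id", "reason", "statistic"])
    )
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_loci_before: int = 0
    n_loci_after: int = 0

    def reconcile(self) -> None:
        assert self.n_samples_before - self.n_samples_after == len(self.removed_samples)
        assert self.n_loci_before - self.n_loci_after == len(self.removed_snps)


# ---------------------------------------------------------------------------
# Exact HWE test
# ---------------------------------------------------------------------------


def _hwe_het_distribution(n_rare: int, n_geno: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count given the minor
    allele count ``n_rare`` in ``n_geno`` diploids.

    Returns (attainable het counts, their probabilities). Uses the standard
    recurrence on the conditional likelihood ratio, normalized at the end.
    """
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) // 2 + hets <= 2 * n_geno - n_rare + hets]  # always true
    # log-probabilities up to a constant: P(h) ∝ n! / (a! h! b!) * 2^h with
    # a=(n_rare-h)/2 rare homs, b=n_geno-a-h common homs
    a = (n_rare - hets) // 2
    b = n_geno - a - hets
    valid = b >= 0
    hets, a, b = hets[valid], a[valid], b[valid]
    from scipy.special import gammaln

    logp = hets * np.log(2.0) - gammaln(a + 1) - gammaln(hets + 1) - gammaln(b + 1)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return hets, p


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic locus.

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, whose probability does not exceed that of the
    observed count (the standard exact HWE test). Monomorphic tables give
    p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    n_rare = min(n_a, n_A)
    if n_rare == 0:
        return 1.0
    hets, probs = _hwe_het_distribution(n_rare, n)
    p_obs = probs[hets == n_Aa][0]
    # 1e-12 relative slack guards against float round-off in the ∝ comparison
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_scan(G: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per locus over all samples of ``G``."""
    out = np.ones(G.n_loci)
    for j in range(G.n_loci):
        col = G.dosage[:, j]
        ok = col != MISSING
        n2 = int(np.sum(col[ok] == 2))
        n1 = int(np.sum(col[ok] == 1))
        n0 = int(np.sum(col[ok] == 0))
        if n0 + n1 + n2 == 0:
            out[j] = 1.0
        else:
            out[j] = hwe_exact_test(n2, n1, n0)
    return out


# ---------------------------------------------------------------------------
# Composite filter
# ---------------------------------------------------------------------------


def apply_qc(
    G: GenotypeMatrix,
    S: pd.DataFrame | None,
    thresholds: QcThresholds,
    populations_for_hwe: dict[str, list] | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the call-rate / HWE / MAF battery and report every removal.

    Order: sample call rate -> SNP call rate -> HWE within each population
    of ``populations_for_hwe`` (name -> sample ids) -> MAF on the whole
    retained dataset.
    """
    report = QcReport(n_samples_before=G.n_samples, n_loci_before=G.n_loci)
    rs: list[tuple[str, str, float]] = []
    rl: list[tuple[str, str, float]] = []

    cr = G.sample_call_rate()
    drop = cr < thresholds.sample_callrate
    for sid, c in zip(G.sample_ids[drop], cr[drop]):
        rs.append((sid, "sample_callrate", float(c)))
    G = G.take_samples(np.where(~drop)[0])
    if G.n_samples == 0:
        raise ValueError("sample call-rate filter removed every sample")

    cr = G.locus_call_rate()
    drop = cr < thresholds.snp_callrate
    for lid, c in zip(G.locus_ids[drop], cr[drop]):
        rl.append((lid, "snp_callrate", float(c)))
    G = G.take_loci(np.where(~drop)[0])

    if populations_for_hwe:
        fail = np.zeros(G.n_loci, dtype=bool)
        stat = np.ones(G.n_loci)
        for pop, ids in populations_for_hwe.items():
            present = [s for s in ids if s in set(G.sample_ids)]
            if not present:
                continue
            sub = G.select_samples(present)
            p = hwe_scan(sub)
            worse = p < stat
            stat[worse] = p[worse]
            fail |= p < thresholds.hwe_p
        for lid, pv in zip(G.locus_ids[fail], stat[fail]):
            rl.append((lid, "hwe", float(pv)))
        G = G.take_loci(np.where(~fail)[0])

    maf = G.minor_allele_freq()
    maf = np.where(np.isnan(maf), 0.0, maf)
    drop = maf < thresholds.maf
    for lid, m in zip(G.locus_ids[drop], maf[drop]):
        rl.append((lid, "maf", float(m)))
    G = G.take_loci(np.where(~drop)[0])

    if G.n_loci == 0:
        raise ValueError("QC removed every locus; thresholds too aggressive")

    report.removed_samples = pd.DataFrame(rs, columns=["sample_id", "reason", "statistic"])
    report.removed_snps = pd.DataFrame(rl, columns=["locus_id", "reason", "statistic"])
    report.n_samples_after = G.n_samples
    report.n_loci_after = G.n_loci
    report.reconcile()
    return G, report


# ---------------------------------------------------------------------------
# Duplicate removal by IBS
# ---------------------------------------------------------------------------


def remove_duplicates_by_ibs(
    G: GenotypeMatrix, dup_ibs_distance: float = 0.05
) -> tuple[list, list[tuple]]:
    """Drop near-duplicate individuals, keeping the best-called of each group.

    Pairs with IBS distance below ``dup_ibs_distance`` are linked; within
    each connected component the sample with the highest call rate is kept
    (ties broken by position in ``G.sample_ids``) and the rest removed.

    Returns (kept sample ids in original order, removed (kept_id, removed_id)
    pairs).
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    D = ibs_matrix(G)
    close = D.values < dup_ibs_distance
    np.fill_diagonal(close, False)

    # union-find over the 'near-duplicate' graph
    parent = list(range(G.n_samples))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in zip(*np.where(np.triu(close, 1))):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    call = G.sample_call_rate()
    comps: dict[int, list[int]] = {}
    for i in range(G.n_samples):
        comps.setdefault(find(i), []).append(i)

    keep_mask = np.ones(G.n_samples, dtype=bool)
    removed_pairs: list[tuple] = []
    for members in comps.values():
        if len(members) == 1:
            continue
        best = max(members, key=lambda i: (call[i], -i))
        for i in members:
            if i != best:
                keep_mask[i] = False
                removed_pairs.append((G.sample_ids[best], G.sample_ids[i]))
    kept = list(G.sample_ids[keep_mask])
    return kept, removed_pairs


# ---------------------------------------------------------------------------
# Two-group allele-frequency concordance filter
# ---------------------------------------------------------------------------


def _allele_counts_by_group(G: GenotypeMatrix, mask: np.ndarray):
    d = G.dosage[mask].astype(np.int64)
    ok = d != MISSING
    a1 = np.where(ok, d, 0).sum(axis=0)
    tot = 2 * ok.sum(axis=0)
    return a1, tot


def two_group_frequency_filter(
    G: GenotypeMatrix, group_labels: np.ndarray, p_threshold: float
) -> list:
    """SNPs whose allele frequencies differ between two groups.

    A 1-df chi-square on the 2x2 allele-count table per SNP; SNPs with
    p < ``p_threshold`` are returned for removal. SNPs monomorphic in both
    groups combined are never removed. Used both for the platform
    concordance filter (threshold 1e-10) and the case/control screen
    (threshold 0.1).
    """
    from .freqdiff import chisq_scan

    scan = chisq_scan(G, group_labels)
    drop = (scan.p < p_threshold) & ~scan.monomorphic
    return list(np.asarray(G.locus_ids)[drop])


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _composite_r2(d: np.ndarray, j: int, k: int) -> float:
    """Squared Pearson correlation of dosages at loci j, k over
    pairwise-complete samples (composite, genotype-level r^2)."""
    a, b = d[:, j], d[:, k]
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_prune(
    G: GenotypeMatrix, window_snps: int = 50, step_snps: int = 5, r2_threshold: float = 0.5
) -> list:
    """Greedy sliding-window LD pruning on composite genotype r^2.

    Within each window of ``window_snps`` position-sorted SNPs, the
    later-positioned SNP of any pair with r^2 above threshold is removed;
    the window then advances by ``step_snps``. Returns retained locus ids.
    """
    if window_snps < 2:
        raise ValueError("window must cover at least 2 SNPs")
    order = np.lexsort((G.pos_bp, G.chrom.astype(str)))
    if not np.array_equal(order, np.arange(G.n_loci)):
        raise ValueError("SNPs must be position-sorted within chromosome")
    d = G.dosage
    removed = np.zeros(G.n_loci, dtype=bool)
    start = 0
    while start < G.n_loci:
        idx = [
            j
            for j in range(start, min(start + window_snps, G.n_loci))
            if not removed[j] and G.chrom[j] == G.chrom[start]
        ]
        for a_pos in range(len(idx)):
            j = idx[a_pos]
            if removed[j]:
                continue
            for b_pos in range(a_pos + 1, len(idx)):
                k = idx[b_pos]
                if removed[k]:
                    continue
                if _composite_r2(d, j, k) > r2_threshold:
                    removed[k] = True
        if start + window_snps >= G.n_loci:
            break
        start += step_snps
    return list(np.asarray(G.locus_ids)[~removed])
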