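"""Per-SNP allele-frequency chi-square scans, the genomic overdispersion
factor lambda, significant-fraction summaries, and genomic annotation of
the most differentiated SNPs.

lambda follows the smallest-90% convention: the ratio of the mean of the
smallest 90% of observed 1-df chi-square statistics to the mean of the
matching chi-square quantiles; 1 means no systematic frequency
difference between the two groups beyond sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix


@dataclass
class ScanResult:
    locus_ids: np.ndarray
    chi2: np.ndarray
    p: np.ndarray
    monomorphic: np.ndarray  # flagged: chi2 forced to 0, p to 1
    lam: float | None = None
    frac_sig: float | None = None

    def to_frame(self, chrom=None, pos_bp=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"locus_id": self.locus_ids, "chi2": self.chi2, "p": self.p,
             "monomorphic": self.monomorphic}
        )
        if chrom is not None:
            df.insert(1, "chrom", chrom)
        if pos_bp is not None:
            df.insert(2, "pos_bp", pos_bp)
        return df


@dataclass
class GeneAnnotation:
    """Gene interval, 1-based inclusive start, half-open end."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp < 0 or self.end_bp < 0:
            raise ValueError("negative coordinate")
        if self.start_bp >= self.end_bp:
            raise ValueError(f"{self.gene_id}: start >= end")


def chisq_scan(G: GenotypeMatrix, two_group_labels) -> ScanResult:
    """1-df allele-count chi-square per SNP between two groups.

    The per-SNP table is alleles (A1/A2) x groups, counted over
    non-missing genotypes, tested without continuity correction. SNPs
    monomorphic across both groups (or with no data in a group) get
    chi2 = 0, p = 1 and a monomorphic/degenerate flag.
    """
    labels = np.asarray(two_group_labels)
    groups = list(dict.fromkeys(labels))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    masks = [labels == g for g in groups]
    if not all(m.any() for m in masks):
        raise ValueError("empty group")

    counts = []
    for m in masks:
        d = G.dosage[m].astype(np.int64)
        ok = d != MISSING
        a1 = np.where(ok, d, 0).sum(axis=0)
        tot = 2 * ok.sum(axis=0)
        counts.append((a1, tot))
    (a1_1, t1), (a1_2, t2) = counts
    a2_1 = t1 - a1_1
    a2_2 = t2 - a1_2

    n = t1 + t2
    row_a1 = a1_1 + a1_2
    degenerate = (t1 == 0) | (t2 == 0) | (row_a1 == 0) | (row_a1 == n)
    with np.errstate(invalid="ignore", divide="ignore"):
        # chi2 for a 2x2 table in closed form: n (ad - bc)^2 / (r1 r2 c1 c2)
        num = n * (a1_1 * a2_2 - a1_2 * a2_1).astype(float) ** 2
        den = row_a1.astype(float) * (n - row_a1) * t1 * t2
        chi2 = np.where(degenerate, 0.0, num / np.where(den > 0, den, 1.0))
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    return ScanResult(
        locus_ids=np.asarray(G.locus_ids),
        chi2=chi2,
        p=p,
        monomorphic=degenerate,
    )


def lambda_overdispersion(chi2_values) -> float:
    """Overdispersion factor of observed vs expected 1-df chi-square.

    Sorts the m observed statistics, keeps the smallest floor(0.9 m),
    pairs rank i with the chi-square(1) quantile at (i - 0.5)/m, and
    returns the ratio of the two means.
    """
    x = np.asarray(chi2_values, dtype=float)
    x = x[np.isfinite(x)]
    m = len(x)
    if m < 10:
        raise ValueError("need at least 10 finite statistics")
    if np.all(x == 0):
        raise ValueError("all statistics zero; lambda undefined")
    x = np.sort(x)
    k = int(np.floor(0.9 * m))
    obs = x[:k]
    expected = stats.chi2.ppf((np.arange(1, k + 1) - 0.5) / m, df=1)
    return float(obs.mean() / expected.mean())


def significant_fraction(p_values, alpha: float) -> float:
    """Fraction of tests with p < alpha."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value vector")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(np.mean(p < alpha))


def qq_coordinates(chi2_values) -> pd.DataFrame:
    """Expected vs observed chi-square(1) quantiles for a QQ plot."""
    x = np.sort(np.asarray(chi2_values, dtype=float))
    m = len(x)
    exp = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, df=1)
    return pd.DataFrame({"expected": exp, "observed": x})


def annotate_top_snps(
    scan: ScanResult,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    genes: list[GeneAnnotation],
    p_cutoff: float,
    max_dist: int = 200_000,
) -> pd.DataFrame:
    """Nearest gene (within ``max_dist`` bp) for every SNP below p_cutoff.

    Distance is the minimal bp gap to the gene interval, 0 if the SNP lies
    inside. Exact ties list both genes; the primary row is the gene with
    the lower start. Genes must be sorted by (chrom, start).
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c, gl in by_chrom.items():
        starts = [g.start_bp for g in gl]
        if starts != sorted(starts):
            raise ValueError(f"gene table not sorted by start on chromosome {c}")

    rows = []
    hits = np.where(scan.p < p_cutoff)[0]
    for i in hits:
        c = chrom[i]
        pos = int(pos_bp[i])
        best: list[tuple[int, GeneAnnotation]] = []
        for g in by_chrom.get(c, []):
            if g.start_bp <= pos < g.end_bp:
                gap = 0
            elif pos < g.start_bp:
                gap = g.start_bp - pos
            else:
                gap = pos - (g.end_bp - 1)
            if gap > max_dist:
                continue
            if not best or gap < best[0][0]:
                best = [(gap, g)]
            elif gap == best[0][0]:
                best.append((gap, g))
        if not best:
            continue
        best.sort(key=lambda t: (t[0], t[1].start_bp))
        for rank, (gap, g) in enumerate(best):
            rows.append(
                {
                    "locus_id": scan.locus_ids[i],
                    "p": scan.p[i],
                    "gene_id": g.gene_id,
                    "distance_bp": gap,
                    "primary": rank == 0,
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "p", "gene_id", "distance_bp", "primary"])


def interval_overlap_count(
    scan: ScanResult,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    intervals: list[tuple[str, int, int]],
    alpha: float,
) -> dict:
    """Are significant SNPs over-represented in a set of genomic intervals?

    intervals are (chrom, start, end) half-open. Returns observed and
    expected counts of significant SNPs inside the intervals and an exact
    binomial tail p-value; 'ld_caveat' flags that adjacent SNPs are
    correlated, so the binomial p is anti-conservative.
    """
    if not intervals:
        raise ValueError("empty interval set")
    inside = np.zeros(len(scan.p), dtype=bool)
    for c, s, e in intervals:
        inside |= (np.asarray(chrom) == c) & (pos_bp >= s) & (pos_bp < e)
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("intervals cover no SNPs")
    frac_sig = significant_fraction(scan.p, alpha)
    observed = int(np.sum(scan.p[inside] < alpha))
    expected = n_inside * frac_sig
    p = float(stats.binom.sf(observed - 1, n_inside, frac_sig)) if frac_sig > 0 else 1.0
    return {
        "observed": observed,
        "expected": expected,
        "n_inside": n_inside,
        "binomial_p": min(1.0, p),
        "ld_caveat": True,
    }
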