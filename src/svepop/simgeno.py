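"""Synthetic SNP panels with hierarchical and clinal structure on a map.

The generator emulates a genome-wide survey of a weakly structured human
population: provinces nested in regions, differentiation produced by the
Balding-Nichols drift model (whose parameter f equals the expected F_ST),
an optional north-south cline, MAF-ascertained loci, platform-specific
missingness, near-duplicate individuals and batch-shifted SNPs. Ground
truth (ancestral and per-province frequencies, cline ancestry, drift
parameters) is returned for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genio import MISSING, GenotypeMatrix, validate_sample_table

#: km per degree of latitude (spherical Earth, IUGG mean radius).
KM_PER_DEG_LAT = 111.195


@dataclass
class Province:
    name: str
    region: str
    lat: float
    lon: float
    n_samples: int


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    f_region / f_province are Balding-Nichols drift coefficients: the
    expected F_ST among regions around the ancestral population, and among
    provinces around their region. clinal_weight mixes province drift
    (weight 1-w) with a latitude-indexed two-gradient cline (weight w).
    """

    n_snps: int = 5000
    provinces: list[Province] = field(default_factory=lambda: default_provinces())
    maf_range: tuple[float, float] = (0.05, 0.5)
    f_region: float = 0.004
    f_province: float = 0.003
    clinal_weight: float = 0.0
    jitter_km: float = 30.0
    missing_rate_by_platform: dict[str, float] = field(
        default_factory=lambda: {"chipA": 0.0}
    )
    n_duplicate_pairs: int = 0
    n_batch_snps: int = 0
    freq_shift: float = 0.2
    case_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5]: {self.maf_range}")
        if self.f_region < 0 or self.f_province < 0:
            raise ValueError("drift parameters must be >= 0")
        if not 0 <= self.clinal_weight <= 1:
            raise ValueError("clinal_weight must be in [0, 1]")
        if self.clinal_weight > 0 and self.f_region == 0:
            raise ValueError(
                "clinal_weight > 0 needs f_region > 0 to separate the two gradients"
            )
        for plat, rate in self.missing_rate_by_platform.items():
            if not 0 <= rate < 1:
                raise ValueError(f"missing rate for {plat!r} outside [0, 1)")
        if not 0 <= self.case_fraction <= 1:
            raise ValueError("case_fraction must be in [0, 1]")
        if self.n_batch_snps and not 0 < self.freq_shift < 1:
            raise ValueError("freq_shift must be in (0, 1)")
        if (self.f_region > 0 or self.f_province > 0) and len(self.provinces) < 2:
            raise ValueError("differentiation > 0 needs at least 2 provinces")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        provinces = [Province(**p) for p in raw.pop("provinces", [])]
        if "maf_range" in raw:
            raw["maf_range"] = tuple(raw["maf_range"])
        return cls(provinces=provinces, **raw)


@dataclass
class TruthRecord:
    """Simulator ground truth for closed-loop recovery tests."""

    ancestral_freq: np.ndarray  # (L,)
    group_freq: pd.DataFrame  # provinces x loci
    true_Q: np.ndarray  # (n, 2) cline ancestry proportions (rows sum to 1)
    true_f: tuple[float, float]  # (f_region, f_province)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw daughter frequencies around ``p`` with drift coefficient ``f``.

    Beta(p(1-f)/f, (1-p)(1-f)/f); f = 0 degenerates to p itself.
    """
    if f == 0:
        return p.copy()
    c = (1.0 - f) / f
    return rng.beta(p * c, (1.0 - p) * c)


def default_provinces() -> list[Province]:
    """A 3-region x 2-province layout spanning a 10-degree latitude band,
    mimicking a south-to-north national sampling design."""
    return [
        Province("P1", "South", 56.0, 14.0, 100),
        Province("P2", "South", 58.0, 13.0, 100),
        Province("P3", "Middle", 59.5, 16.0, 100),
        Province("P4", "Middle", 61.0, 15.0, 100),
        Province("P5", "North", 64.0, 18.0, 100),
        Province("P6", "North", 66.0, 21.0, 100),
    ]


def simulate_panel(config: SimConfig):
    """Generate (GenotypeMatrix, sample table, TruthRecord) under ``config``.

    Region frequencies are Balding-Nichols draws around ancestral
    frequencies with f_region; province frequencies around their region
    with f_province. In clinal mode each sample's expected frequency mixes
    its province frequency with a latitude-weighted blend of two gradient
    frequency vectors. Genotypes are Binomial(2, freq). Deterministic
    given config.seed.
    """
    provinces = config.provinces or default_provinces()
    rng = np.random.default_rng(config.seed)
    L = config.n_snps
    lo, hi = config.maf_range

    p_anc = rng.uniform(lo, hi, size=L)

    regions = []
    for pr in provinces:
        if pr.region not in regions:
            regions.append(pr.region)
    region_freq = {r: _balding_nichols(rng, p_anc, config.f_region) for r in regions}
    prov_freq = {
        pr.name: _balding_nichols(rng, region_freq[pr.region], config.f_province)
        for pr in provinces
    }

    # Two gradient endpoints for the cline, drawn once around the ancestral
    # frequencies with f_region so they differ by about the regional drift.
    grad_south = _balding_nichols(rng, p_anc, config.f_region)
    grad_north = _balding_nichols(rng, p_anc, config.f_region)

    sample_ids, prov_labels, region_labels, lats, lons = [], [], [], [], []
    for pr in provinces:
        for k in range(pr.n_samples):
            sample_ids.append(f"{pr.name}_{k:04d}")
            prov_labels.append(pr.name)
            region_labels.append(pr.region)
    n = len(sample_ids)

    sd_lat = config.jitter_km / KM_PER_DEG_LAT
    i = 0
    for pr in provinces:
        m = pr.n_samples
        jlat = rng.normal(0.0, sd_lat, size=m)
        sd_lon = config.jitter_km / (KM_PER_DEG_LAT * np.cos(np.radians(pr.lat)))
        jlon = rng.normal(0.0, sd_lon, size=m)
        lats.extend(pr.lat + jlat)
        lons.extend(pr.lon + jlon)
        i += m
    lats = np.asarray(lats)
    lons = np.asarray(lons)

    # Cline ancestry: component 1 is an affine map of latitude, so its
    # correlation with latitude is exactly 1.
    lat_span = np.ptp(lats)
    q1 = (lats - lats.min()) / lat_span if lat_span > 0 else np.full(n, 0.5)
    true_Q = np.column_stack([q1, 1.0 - q1])

    w = config.clinal_weight
    freq = np.empty((n, L))
    for j, pr_name in enumerate(prov_labels):
        base = prov_freq[pr_name]
        if w > 0:
            cline = true_Q[j, 0] * grad_north + true_Q[j, 1] * grad_south
            freq[j] = (1.0 - w) * base + w * cline
        else:
            freq[j] = base
    np.clip(freq, 0.0, 1.0, out=freq)

    dosage = rng.binomial(2, freq).astype(np.int8)

    platforms = sorted(config.missing_rate_by_platform)
    platform_per_sample = [platforms[j % len(platforms)] for j in range(n)]

    G = GenotypeMatrix(
        sample_ids=np.array(sample_ids, dtype=object),
        locus_ids=np.array([f"snp{j}" for j in range(L)], dtype=object),
        chrom=np.array(["1"] * L, dtype=object),
        pos_bp=np.arange(1, L + 1, dtype=np.int64) * 10_000,
        alleles=np.array([("A", "B")] * L, dtype=object),
        dosage=dosage,
    )
    S = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "lat": lats,
            "lon": lons,
            "province": prov_labels,
            "region": region_labels,
            "platform": platform_per_sample,
            "status": "unknown",
        }
    )
    validate_sample_table(S)
    truth = TruthRecord(
        ancestral_freq=p_anc,
        group_freq=pd.DataFrame(
            {name: f for name, f in prov_freq.items()}, index=G.locus_ids
        ).T,
        true_Q=true_Q,
        true_f=(config.f_region, config.f_province),
    )
    return G, S, truth


def inject_artifacts(G: GenotypeMatrix, S: pd.DataFrame, config: SimConfig):
    """Overlay technical artifacts on a clean simulated panel.

    Applies per-platform missingness entry-wise, appends near-duplicate
    individuals (copies of random source samples re-subjected to their
    platform's missingness), shifts the allele frequency of n_batch_snps
    on one platform (clipped to [0.01, 0.99]) and assigns null case labels
    at case_fraction. Uses a seed derived from config.seed so the clean
    panel and the artifact overlay are independently reproducible.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    dosage = G.dosage.copy()
    S = S.copy()
    n, L = dosage.shape

    if config.n_duplicate_pairs > n:
        raise ValueError(
            f"{config.n_duplicate_pairs} duplicate pairs exceed {n} samples"
        )

    platforms = sorted(config.missing_rate_by_platform)
    plat_arr = S["platform"].to_numpy()

    # Batch-shifted SNPs: redraw genotypes of one platform from a shifted
    # frequency, emulating cross-chip calling discordance.
    batch_loci = np.array([], dtype=int)
    if config.n_batch_snps > 0:
        if len(platforms) < 2:
            raise ValueError("batch SNPs need at least two platforms")
        batch_loci = rng.choice(L, size=config.n_batch_snps, replace=False)
        target = platforms[0]
        rows = np.where(plat_arr == target)[0]
        base_p = G.allele_freq()[batch_loci]
        shifted = np.clip(base_p + config.freq_shift, 0.01, 0.99)
        dosage[np.ix_(rows, batch_loci)] = rng.binomial(
            2, np.broadcast_to(shifted, (len(rows), len(batch_loci)))
        ).astype(np.int8)

    # Near-duplicates: copy a source sample, then apply missingness
    # independently below.
    dup_rows = []
    if config.n_duplicate_pairs > 0:
        sources = rng.choice(n, size=config.n_duplicate_pairs, replace=False)
        for s_idx in sources:
            dup_rows.append((s_idx, f"{G.sample_ids[s_idx]}_dup"))

    new_dosage = [dosage]
    new_meta = [S]
    for s_idx, new_id in dup_rows:
        new_dosage.append(dosage[s_idx : s_idx + 1].copy())
        row = S.iloc[s_idx].copy()
        row["sample_id"] = new_id
        new_meta.append(row.to_frame().T)
    dosage = np.vstack(new_dosage)
    S = pd.concat(new_meta, ignore_index=True)
    plat_arr = S["platform"].to_numpy()

    for plat, rate in config.missing_rate_by_platform.items():
        if rate <= 0:
            continue
        rows = np.where(plat_arr == plat)[0]
        if len(rows) == 0:
            continue
        mask = rng.random((len(rows), L)) < rate
        block = dosage[rows]
        block[mask] = MISSING
        dosage[rows] = block

    if config.case_fraction > 0:
        status = np.where(
            rng.random(len(S)) < config.case_fraction, "case", "control"
        )
        S["status"] = status

    G_out = GenotypeMatrix(
        sample_ids=S["sample_id"].to_numpy(dtype=object),
        locus_ids=G.locus_ids.copy(),
        chrom=G.chrom.copy(),
        pos_bp=G.pos_bp.copy(),
        alleles=G.alleles.copy(),
        dosage=dosage,
    )
    S = validate_sample_table(S)
    return G_out, S
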