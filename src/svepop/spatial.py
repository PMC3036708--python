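"""Geographic distances, isolation-by-distance testing, individual
inbreeding coefficients, regional rank tests, and grid-circle local
statistics (median inbreeding / ancestry, local genetic-geographic
correlation) over a map of sampled individuals."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import MISSING, GenotypeMatrix
from .ibsmds import SquareDistanceMatrix

#: IUGG mean Earth radius, km.
EARTH_RADIUS_KM = 6371.0088

#: km per degree of latitude on the same sphere.
KM_PER_DEG_LAT = math.pi * EARTH_RADIUS_KM / 180.0


@dataclass
class GridCell:
    lat: float
    lon: float
    n: int
    value: float
    kind: str


def _haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def great_circle_matrix(S: pd.DataFrame) -> SquareDistanceMatrix:
    """Pairwise haversine distances (km) between sample coordinates."""
    lat = pd.to_numeric(S["lat"], errors="coerce").to_numpy(dtype=float)
    lon = pd.to_numeric(S["lon"], errors="coerce").to_numpy(dtype=float)
    bad = np.isnan(lat) | np.isnan(lon)
    if bad.any():
        raise ValueError(
            f"missing coordinates for samples {list(S['sample_id'][bad][:5])}"
        )
    d = _haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return SquareDistanceMatrix(S["sample_id"].to_numpy(dtype=object), d, kind="km")


def mantel_test(
    D_gen: SquareDistanceMatrix,
    D_geo: SquareDistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    method: str = "permutation",
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over upper-triangle entries; the null is
    built by jointly permuting rows and columns of the second matrix.
    One-sided upper p = (1 + #{r_perm >= r}) / (n_perm + 1).
    method='exact' enumerates all n! permutations (small n only), with the
    identity included in the count.
    """
    if not np.array_equal(D_gen.ids, D_geo.ids):
        raise ValueError("matrices must share ids in the same order")
    n = D_gen.n
    if n < 3:
        raise ValueError("need at least 3 objects")
    iu = np.triu_indices(n, k=1)
    x = D_gen.values[iu]
    if np.std(x) == 0 or np.std(D_geo.values[iu]) == 0:
        raise ValueError("constant distance matrix; correlation undefined")

    xc = (x - x.mean()) / x.std()

    def corr(perm: np.ndarray) -> float:
        y = D_geo.values[np.ix_(perm, perm)][iu]
        yc = (y - y.mean()) / y.std()
        return float(np.mean(xc * yc))

    r_obs = corr(np.arange(n))

    if method == "exact":
        count = total = 0
        for perm in itertools.permutations(range(n)):
            if corr(np.array(perm)) >= r_obs - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if corr(rng.permutation(n)) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (n_perm + 1)


def inbreeding_coefficients(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-sample inbreeding coefficient from observed vs expected
    homozygosity relative to the whole sample.

    Per locus the expected homozygosity is 1 - 2 p (1-p) * 2n/(2n-1)
    (small-sample corrected), with p the total-sample frequency and 2n
    the allele count. Per sample, F = (O_hom - E_hom) / (L - E_hom) over
    its non-missing polymorphic loci. Monomorphic loci carry no
    information and are excluded.
    """
    if G.n_samples < 2:
        raise ValueError("need at least 2 samples")
    ok = G.dosage != MISSING
    if (~ok).all(axis=1).any():
        bad = G.sample_ids[(~ok).all(axis=1)]
        raise ValueError(f"samples with all loci missing: {list(bad[:5])}")
    p = G.allele_freq()
    n_alleles = 2.0 * ok.sum(axis=0)
    poly = (p > 0) & (p < 1) & (n_alleles > 2)
    if not poly.any():
        raise ValueError("no polymorphic loci")
    e_hom_locus = 1.0 - 2.0 * p * (1.0 - p) * (n_alleles / (n_alleles - 1.0))
    e_hom_locus = np.where(poly, e_hom_locus, 0.0)

    use = ok & poly[None, :]
    L = use.sum(axis=1).astype(float)
    O_hom = ((G.dosage != 1) & use).sum(axis=1).astype(float)
    E_hom = use @ e_hom_locus
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (O_hom - E_hom) / (L - E_hom)
    return pd.DataFrame(
        {
            "sample_id": G.sample_ids,
            "F": F,
            "O_hom": O_hom,
            "E_hom": E_hom,
            "L": L.astype(int),
        }
    )


def kruskal_wallis_by_region(values, region_labels) -> tuple[float, float]:
    """Kruskal-Wallis rank test of a per-sample statistic across regions."""
    values = np.asarray(values, dtype=float)
    region_labels = np.asarray(region_labels)
    groups = [values[region_labels == r] for r in dict.fromkeys(region_labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 regions")
    if np.all(values == values[0]):  # scipy refuses the all-identical case
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def grid_local_statistic(
    S: pd.DataFrame,
    per_sample_values=None,
    D_gen: SquareDistanceMatrix | None = None,
    D_geo: SquareDistanceMatrix | None = None,
    kind: str = "median_inbreeding",
    radius_km: float = 150.0,
    min_n: int = 20,
    grid_spacing_km: float = 25.0,
) -> list[GridCell]:
    """Local statistics in circles of ``radius_km`` around map grid points.

    A regular latitude/longitude grid at roughly ``grid_spacing_km`` covers
    the sample bounding box. For median kinds ('median_inbreeding',
    'median_ancestry') a cell reports the median of members' values when
    at least ``min_n`` samples fall within the radius. For
    'local_correlation' a cell reports the Pearson correlation between
    genetic and geographic distance over all member pairs (default
    ``min_n`` should be 40 per the plotting convention for that statistic).
    """
    if min_n < 2:
        raise ValueError("min_n must be >= 2")
    lat = pd.to_numeric(S["lat"]).to_numpy(dtype=float)
    lon = pd.to_numeric(S["lon"]).to_numpy(dtype=float)
    if kind in ("median_inbreeding", "median_ancestry"):
        if per_sample_values is None:
            raise ValueError(f"{kind} needs per_sample_values")
        vals = np.asarray(per_sample_values, dtype=float)
        if len(vals) != len(S):
            raise ValueError("per_sample_values length mismatch")
    elif kind == "local_correlation":
        if D_gen is None or D_geo is None:
            raise ValueError("local_correlation needs D_gen and D_geo")
        if not np.array_equal(D_gen.ids, S["sample_id"].to_numpy(dtype=object)):
            raise ValueError("D_gen ids must match the sample table order")
        if not np.array_equal(D_geo.ids, S["sample_id"].to_numpy(dtype=object)):
            raise ValueError("D_geo ids must match the sample table order")
    else:
        raise ValueError(f"unknown kind {kind!r}")

    dlat = grid_spacing_km / KM_PER_DEG_LAT
    mid_lat = np.radians((lat.min() + lat.max()) / 2.0)
    dlon = grid_spacing_km / (KM_PER_DEG_LAT * max(np.cos(mid_lat), 1e-6))
    glats = np.arange(lat.min(), lat.max() + dlat, dlat)
    glons = np.arange(lon.min(), lon.max() + dlon, dlon)
    if len(glats) == 0 or len(glons) == 0:
        raise ValueError("empty grid")

    cells: list[GridCell] = []
    for gla in glats:
        d_all = _haversine_km(gla, glons[:, None], lat[None, :], lon[None, :])
        for gi, glo in enumerate(glons):
            members = np.where(d_all[gi] <= radius_km)[0]
            if len(members) < min_n:
                continue
            if kind == "local_correlation":
                sub_g = D_gen.values[np.ix_(members, members)]
                sub_d = D_geo.values[np.ix_(members, members)]
                iu = np.triu_indices(len(members), k=1)
                x, y = sub_g[iu], sub_d[iu]
                if x.std() == 0 or y.std() == 0:
                    continue
                value = float(np.corrcoef(x, y)[0, 1])
            else:
                value = float(np.median(vals[members]))
            if not np.isfinite(value):
                continue
            cells.append(GridCell(float(gla), float(glo), int(len(members)), value, kind))
    return cells


def grid_cells_to_frame(cells: list[GridCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.lat, c.lon, c.n, c.kind, c.value) for c in cells],
        columns=["lat", "lon", "n", "kind", "value"],
    )
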