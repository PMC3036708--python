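import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from svepop import spatial
from svepop.genio import MISSING
from svepop.ibsmds import SquareDistanceMatrix

from conftest import make_genotypes


def _sample_table(lats, lons, region=None):
    n = len(lats)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "lat": lats,
            "lon": lons,
            "province": ["P"] * n,
            "region": region if region is not None else ["R"] * n,
            "platform": ["x"] * n,
            "status": ["unknown"] * n,
        }
    )


# ---------------------------------------------------------------------------
# great-circle distances
# ---------------------------------------------------------------------------


def test_one_degree_of_longitude_at_equator():
    S = _sample_table([0.0, 0.0], [0.0, 1.0])
    D = spatial.great_circle_matrix(S)
    want = math.pi * 6371.0088 / 180.0
    assert D.values[0, 1] == pytest.approx(want, rel=1e-9)


def test_identical_coordinates_zero(rng):
    S = _sample_table([59.3, 59.3], [18.1, 18.1])
    assert spatial.great_circle_matrix(S).values[0, 1] == 0.0


def test_symmetry_random_coordinates(rng):
    S = _sample_table(rng.uniform(-80, 80, 10), rng.uniform(-170, 170, 10))
    D = spatial.great_circle_matrix(S)
    assert np.allclose(D.values, D.values.T)
    assert np.all(np.diag(D.values) == 0)


def test_missing_coordinates_error():
    S = _sample_table([59.0, np.nan], [18.0, 17.0])
    with pytest.raises(ValueError, match="missing coordinates"):
        spatial.great_circle_matrix(S)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def _random_distance(rng, n, kind="km"):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return SquareDistanceMatrix(
        np.array([f"s{i}" for i in range(n)], dtype=object), m, kind=kind
    )


def test_proportional_matrices_perfect_correlation(rng):
    D1 = _random_distance(rng, 8)
    D2 = SquareDistanceMatrix(D1.ids, 2.0 * D1.values, kind="km")
    r, p = spatial.mantel_test(D1, D2, n_perm=99, seed=0)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100)


def test_exact_enumeration_at_n4(rng):
    D1 = _random_distance(rng, 4)
    D2 = _random_distance(rng, 4)
    r, p = spatial.mantel_test(D1, D2, method="exact")
    iu = np.triu_indices(4, 1)
    x = D1.values[iu]
    count = total = 0
    r_obs = np.corrcoef(x, D2.values[iu])[0, 1]
    for perm in itertools.permutations(range(4)):
        y = D2.values[np.ix_(perm, perm)][iu]
        count += np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12
        total += 1
    assert total == 24
    assert p == pytest.approx(count / 24)
    assert r == pytest.approx(r_obs)


def test_mantel_null_calibration(rng):
    pvals = []
    for rep in range(300):
        D1 = _random_distance(rng, 10)
        D2 = _random_distance(rng, 10)
        _, p = spatial.mantel_test(D1, D2, n_perm=99, seed=rep)
        pvals.append(p)
    d, p_ks = stats.kstest(pvals, "uniform")
    assert p_ks > 0.01


def test_mantel_invariant_to_joint_relabeling(rng):
    D1 = _random_distance(rng, 7)
    D2 = _random_distance(rng, 7)
    r1, _ = spatial.mantel_test(D1, D2, n_perm=9, seed=0)
    perm = rng.permutation(7)
    ids = D1.ids[perm]
    D1p = SquareDistanceMatrix(ids, D1.values[np.ix_(perm, perm)], kind="km")
    D2p = SquareDistanceMatrix(ids, D2.values[np.ix_(perm, perm)], kind="km")
    r2, _ = spatial.mantel_test(D1p, D2p, n_perm=9, seed=0)
    assert r1 == pytest.approx(r2)


def test_constant_matrix_error():
    n = 5
    ids = np.array([f"s{i}" for i in range(n)], dtype=object)
    m = np.ones((n, n)) - np.eye(n)
    D1 = SquareDistanceMatrix(ids, m, kind="km")
    D2 = SquareDistanceMatrix(ids, m * 2, kind="km")
    with pytest.raises(ValueError, match="constant"):
        spatial.mantel_test(D1, D2, n_perm=9)


# ---------------------------------------------------------------------------
# inbreeding
# ---------------------------------------------------------------------------


def test_fully_homozygous_sample_f_is_one(rng):
    dosage = rng.integers(0, 3, (20, 50)).astype(np.int8)
    dosage[0] = np.where(dosage[0] == 1, 2, dosage[0])
    G = make_genotypes(dosage)
    inb = spatial.inbreeding_coefficients(G)
    assert inb.loc[0, "F"] == pytest.approx(1.0)


def test_fully_heterozygous_sample_f_negative(rng):
    dosage = rng.integers(0, 3, (20, 50)).astype(np.int8)
    dosage[0] = 1
    G = make_genotypes(dosage)
    inb = spatial.inbreeding_coefficients(G)
    row = inb.iloc[0]
    assert row["O_hom"] == 0
    assert row["F"] == pytest.approx(-row["E_hom"] / (row["L"] - row["E_hom"]))
    assert row["F"] < 0


def test_hwe_panel_mean_f_near_zero(rng):
    p = rng.uniform(0.1, 0.5, 10_000)
    dosage = rng.binomial(2, p, (500, 10_000)).astype(np.int8)
    inb = spatial.inbreeding_coefficients(make_genotypes(dosage))
    assert abs(inb["F"].mean()) < 0.01


def test_inbreeding_invariant_to_allele_swap(rng):
    dosage = rng.binomial(2, 0.3, (30, 200)).astype(np.int8)
    f1 = spatial.inbreeding_coefficients(make_genotypes(dosage))["F"]
    swap = dosage.copy()
    swap[:, ::2] = 2 - swap[:, ::2]
    f2 = spatial.inbreeding_coefficients(make_genotypes(swap))["F"]
    assert np.allclose(f1, f2)


def _inbred_genotypes(rng, n, L, p, f_self):
    """Genotypes with excess homozygosity: with prob f_self the two allele
    copies are identical by descent (one Bernoulli draw used twice)."""
    one = rng.random((n, L)) < p
    two = np.where(
        rng.random((n, L)) < f_self, one, rng.random((n, L)) < p
    )
    return (one.astype(np.int8) + two.astype(np.int8))


def test_inbred_region_detected_by_kruskal_and_grid(rng):
    p = rng.uniform(0.2, 0.5, 3000)
    n_per = 60
    g_out = rng.binomial(2, p, (2 * n_per, 3000)).astype(np.int8)
    g_inb = _inbred_genotypes(rng, n_per, 3000, p, 0.1)
    G = make_genotypes(np.vstack([g_out, g_inb]))
    regions = np.repeat(["R1", "R2", "R3"], n_per)
    inb = spatial.inbreeding_coefficients(G)
    h, p_kw = spatial.kruskal_wallis_by_region(inb["F"].to_numpy(), regions)
    assert p_kw < 0.01
    # grid: three well-separated clusters; the inbred one shows higher median F
    lats = np.concatenate(
        [
            56.0 + rng.normal(0, 0.1, n_per),
            60.0 + rng.normal(0, 0.1, n_per),
            64.0 + rng.normal(0, 0.1, n_per),
        ]
    )
    lons = np.full(3 * n_per, 15.0) + rng.normal(0, 0.1, 3 * n_per)
    S = _sample_table(lats, lons, region=list(regions))
    cells = spatial.grid_local_statistic(
        S, per_sample_values=inb["F"].to_numpy(), kind="median_inbreeding",
        radius_km=150, min_n=20, grid_spacing_km=50,
    )
    north = [c.value for c in cells if c.lat > 62]
    south = [c.value for c in cells if c.lat < 62]
    assert north and south
    assert min(north) > max(south)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------


def test_kw_identical_values_h_zero():
    h, p = spatial.kruskal_wallis_by_region([1.0] * 10, ["a"] * 5 + ["b"] * 5)
    assert h == 0.0 and p == 1.0


def test_kw_matches_scipy_and_detects_shift(rng):
    a = rng.normal(0, 1, 50)
    b = rng.normal(3, 1, 50)
    h, p = spatial.kruskal_wallis_by_region(
        np.concatenate([a, b]), ["a"] * 50 + ["b"] * 50
    )
    want_h, want_p = stats.kruskal(a, b)
    assert h == pytest.approx(want_h)
    assert p < 1e-6


def test_kw_two_groups_monotone_with_mannwhitney(rng):
    # for 2 groups H is a monotone transform of |U - mu|
    hs, us = [], []
    for rep in range(5):
        a = rng.normal(rep * 0.3, 1, 30)
        b = rng.normal(0, 1, 30)
        h, _ = spatial.kruskal_wallis_by_region(
            np.concatenate([a, b]), ["a"] * 30 + ["b"] * 30
        )
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        hs.append(h)
        us.append(abs(u - 450))
    order_h = np.argsort(hs)
    order_u = np.argsort(us)
    assert np.array_equal(order_h, order_u)


def test_kw_single_group_error():
    with pytest.raises(ValueError):
        spatial.kruskal_wallis_by_region([1, 2, 3], ["a"] * 3)


# ---------------------------------------------------------------------------
# grid statistics
# ---------------------------------------------------------------------------


def test_grid_min_n_enforced(rng):
    # 19 samples in one tight cluster, min_n=20 -> nothing emitted
    S = _sample_table(
        59.0 + rng.normal(0, 0.05, 19), 15.0 + rng.normal(0, 0.05, 19)
    )
    cells = spatial.grid_local_statistic(
        S, per_sample_values=np.ones(19), kind="median_inbreeding",
        radius_km=150, min_n=20,
    )
    assert cells == []
    cells = spatial.grid_local_statistic(
        S, per_sample_values=np.ones(19), kind="median_inbreeding",
        radius_km=150, min_n=19,
    )
    assert all(c.n >= 19 for c in cells)
    assert all(c.value == 1.0 for c in cells)


def test_grid_min_n_property_randomized(rng):
    for rep in range(5):
        n = int(rng.integers(25, 60))
        S = _sample_table(
            58 + rng.normal(0, 1.0, n), 14 + rng.normal(0, 1.5, n)
        )
        min_n = int(rng.integers(2, 25))
        cells = spatial.grid_local_statistic(
            S, per_sample_values=rng.normal(size=n), kind="median_inbreeding",
            radius_km=100, min_n=min_n, grid_spacing_km=60,
        )
        assert all(c.n >= min_n for c in cells)


def test_grid_local_correlation_perfect(rng):
    n = 45
    S = _sample_table(59 + rng.normal(0, 0.3, n), 15 + rng.normal(0, 0.3, n))
    D_geo = spatial.great_circle_matrix(S)
    D_gen = SquareDistanceMatrix(D_geo.ids, D_geo.values / D_geo.values.max(), kind="ibs_distance")
    cells = spatial.grid_local_statistic(
        S, D_gen=D_gen, D_geo=D_geo, kind="local_correlation",
        radius_km=150, min_n=40, grid_spacing_km=50,
    )
    assert cells
    for c in cells:
        assert c.value == pytest.approx(1.0)
        assert c.n >= 40
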