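import numpy as np
import pytest
from scipy import stats

from svepop import fstcore, simgeno
from svepop.genio import MISSING
from svepop.simgeno import Province, SimConfig

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# independent direct-formula oracle (Weir & Cockerham 1984, diploids)
# ---------------------------------------------------------------------------


def wc_theta_oracle(dosage, labels):
    """Scalar re-implementation of the published component formulas,
    evaluated locus by locus with plain Python loops."""
    labels = np.asarray(labels)
    pops = sorted(set(labels), key=list(labels).index)
    r = len(pops)
    A = B = C = 0.0
    for j in range(dosage.shape[1]):
        ns, ps, hs = [], [], []
        for pop in pops:
            col = dosage[labels == pop, j]
            col = col[col != MISSING]
            if len(col) == 0:
                continue
            ns.append(len(col))
            ps.append(col.sum() / (2 * len(col)))
            hs.append(np.mean(col == 1))
        if len(ns) < 2:
            continue
        ns = np.array(ns, float)
        ps = np.array(ps)
        hs = np.array(hs)
        r_l = len(ns)
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (ns.sum() - (ns**2).sum() / ns.sum()) / (r_l - 1)
        pbar = (ns * ps).sum() / ns.sum()
        if pbar in (0.0, 1.0):
            continue
        hbar = (ns * hs).sum() / ns.sum()
        s2 = (ns * (ps - pbar) ** 2).sum() / ((r_l - 1) * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r_l - 1) / r_l * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r_l - 1) / r_l * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A / (A + B + C)


def test_theta_matches_direct_formula_on_toy_table():
    dosage = np.array(
        [
            [0, 2],
            [1, 1],
            [2, 0],
            [1, 2],
            [2, 2],
            [2, 1],
            [1, 2],
            [2, 2],
        ],
        dtype=np.int8,
    )
    labels = np.array(["p1"] * 4 + ["p2"] * 4)
    G = make_genotypes(dosage)
    res = fstcore.wc_fst(G, labels)
    assert res.theta == pytest.approx(wc_theta_oracle(dosage, labels), rel=1e-12)


def test_theta_matches_oracle_with_missing_data(rng):
    dosage = rng.integers(0, 3, (30, 40)).astype(np.int8)
    dosage[rng.random(dosage.shape) < 0.1] = MISSING
    labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
    G = make_genotypes(dosage)
    res = fstcore.wc_fst(G, labels)
    assert res.theta == pytest.approx(wc_theta_oracle(dosage, labels), rel=1e-10)


def test_fixed_difference_gives_theta_one():
    dosage = np.array([[2, 2], [2, 2], [2, 2], [0, 0], [0, 0], [0, 0]], dtype=np.int8)
    labels = np.array(["p1"] * 3 + ["p2"] * 3)
    res = fstcore.wc_fst(make_genotypes(dosage), labels)
    assert res.theta == pytest.approx(1.0)


def test_no_differentiation_theta_near_zero(rng):
    p = rng.uniform(0.1, 0.5, 5000)
    dosage = rng.binomial(2, p, (400, 5000)).astype(np.int8)
    labels = np.array(["a"] * 200 + ["b"] * 200)
    res = fstcore.wc_fst(make_genotypes(dosage), labels)
    assert abs(res.theta) < 0.002


def test_theta_invariant_to_allele_swap(rng):
    dosage = rng.integers(0, 3, (20, 30)).astype(np.int8)
    labels = np.array(["a"] * 10 + ["b"] * 10)
    t1 = fstcore.wc_fst(make_genotypes(dosage), labels).theta
    swap = dosage.copy()
    swap[:, ::2] = 2 - swap[:, ::2]
    t2 = fstcore.wc_fst(make_genotypes(swap), labels).theta
    assert t1 == pytest.approx(t2, rel=1e-12)


def test_single_population_is_error(rng):
    G = make_genotypes(rng.integers(0, 3, (6, 5)).astype(np.int8))
    with pytest.raises(ValueError):
        fstcore.wc_fst(G, np.array(["a"] * 6))


def test_estimator_recovery_across_f_levels():
    # across f in {0.001, 0.005, 0.02}: mean theta within 15% of f
    for f in (0.001, 0.005, 0.02):
        thetas = []
        for seed in range(5):
            cfg = SimConfig(
                n_snps=20_000,
                provinces=[
                    Province("A", "R1", 56.0, 14.0, 200),
                    Province("B", "R2", 60.0, 15.0, 200),
                ],
                f_region=f,
                f_province=0.0,
                seed=seed,
            )
            G, S, _ = simgeno.simulate_panel(cfg)
            thetas.append(fstcore.wc_fst(G, S["province"].to_numpy()).theta)
        assert abs(np.mean(thetas) - f) / f < 0.15, f


# ---------------------------------------------------------------------------
# permutation p
# ---------------------------------------------------------------------------


def test_strong_differentiation_minimal_p(rng):
    p = rng.uniform(0.1, 0.5, 300)
    q = np.clip(p + rng.normal(0, 0.15, 300), 0.01, 0.99)
    d1 = rng.binomial(2, p, (40, 300))
    d2 = rng.binomial(2, q, (40, 300))
    G = make_genotypes(np.vstack([d1, d2]).astype(np.int8))
    labels = np.array(["a"] * 40 + ["b"] * 40)
    res = fstcore.fst_permutation_p(G, labels, n_perm=199, seed=0)
    assert res.p_perm == pytest.approx(1 / 200)


def test_null_permutation_p_uniform(rng):
    pvals = []
    for rep in range(150):
        p = rng.uniform(0.2, 0.5, 120)
        dosage = rng.binomial(2, p, (30, 120)).astype(np.int8)
        labels = np.array(["a"] * 15 + ["b"] * 15)
        res = fstcore.fst_permutation_p(
            make_genotypes(dosage), labels, n_perm=99, seed=rep
        )
        pvals.append(res.p_perm)
    d, p_ks = stats.kstest(pvals, "uniform")
    assert p_ks > 0.01


def test_zero_permutations_is_error(rng):
    G = make_genotypes(rng.integers(0, 3, (8, 10)).astype(np.int8))
    with pytest.raises(ValueError):
        fstcore.fst_permutation_p(G, np.array(["a"] * 4 + ["b"] * 4), n_perm=0)


# ---------------------------------------------------------------------------
# hierarchical F-statistics
# ---------------------------------------------------------------------------


def test_identity_holds_algebraically(rng):
    dosage = rng.integers(0, 3, (60, 80)).astype(np.int8)
    regions = np.repeat(["R1", "R2", "R3"], 20)
    provinces = np.repeat(["p1", "p2", "p3", "p4", "p5", "p6"], 10)
    res = fstcore.hierarchical_fst(make_genotypes(dosage), regions, provinces)
    assert (1 - res.f_st) == pytest.approx((1 - res.f_ct) * (1 - res.f_sc), abs=1e-10)


def test_identical_provinces_within_region_give_fsc_near_zero(rng):
    p = rng.uniform(0.2, 0.5, 3000)
    q = np.clip(p + 0.1, 0, 1)
    d_r1 = rng.binomial(2, p, (100, 3000))
    d_r2 = rng.binomial(2, q, (100, 3000))
    dosage = np.vstack([d_r1, d_r2]).astype(np.int8)
    regions = np.repeat(["R1", "R2"], 100)
    provinces = np.concatenate(
        [np.repeat(["p1", "p2"], 50), np.repeat(["p3", "p4"], 50)]
    )
    res = fstcore.hierarchical_fst(make_genotypes(dosage), regions, provinces)
    assert abs(res.f_sc) < 0.003
    assert res.f_ct > 0.01


def test_hierarchical_recovery_from_simulation():
    f_cts, f_scs = [], []
    for seed in range(8):
        cfg = SimConfig(
            n_snps=20_000,
            provinces=simgeno.default_provinces(),
            f_region=0.004,
            f_province=0.003,
            seed=100 + seed,
        )
        G, S, _ = simgeno.simulate_panel(cfg)
        res = fstcore.hierarchical_fst(
            G, S["region"].to_numpy(), S["province"].to_numpy()
        )
        f_cts.append(res.f_ct)
        f_scs.append(res.f_sc)
    assert abs(np.mean(f_cts) - 0.004) / 0.004 < 0.30
    assert abs(np.mean(f_scs) - 0.003) / 0.003 < 0.30


def test_non_nested_labels_error(rng):
    G = make_genotypes(rng.integers(0, 3, (8, 5)).astype(np.int8))
    regions = np.array(["R1", "R1", "R2", "R2"] * 2)
    provinces = np.array(["p1", "p1", "p1", "p2"] * 2)
    with pytest.raises(ValueError, match="nested"):
        fstcore.hierarchical_fst(G, regions, provinces)


def test_hierarchical_permutation_detects_structure(rng):
    cfg = SimConfig(
        n_snps=3000,
        provinces=simgeno.default_provinces()[:4],
        f_region=0.05,
        f_province=0.0,
        seed=5,
    )
    G, S, _ = simgeno.simulate_panel(cfg)
    res = fstcore.hierarchical_fst(
        G, S["region"].to_numpy(), S["province"].to_numpy(), n_perm=99, seed=0
    )
    assert res.p_sc is not None
    # f_sc truly ~0 here -> permutation p should not be extreme
    assert res.p_sc > 0.01


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


def test_downsample_sizes_and_determinism(rng):
    dosage = rng.integers(0, 3, (280, 10)).astype(np.int8)
    labels = np.array(["a"] * 139 + ["b"] * 141)
    G = make_genotypes(dosage)
    sub1, lab1 = fstcore.downsample(G, labels, 115, seed=4)
    sub2, _ = fstcore.downsample(G, labels, 115, seed=4)
    assert sub1.n_samples == 230
    assert (lab1 == "a").sum() == 115 and (lab1 == "b").sum() == 115
    assert np.array_equal(sub1.sample_ids, sub2.sample_ids)


def test_downsample_full_population_unchanged(rng):
    dosage = rng.integers(0, 3, (20, 5)).astype(np.int8)
    labels = np.array(["a"] * 8 + ["b"] * 12)
    G = make_genotypes(dosage)
    sub, lab = fstcore.downsample(G, labels, 8, seed=0)
    assert set(sub.sample_ids[lab == "a"]) == set(G.sample_ids[:8])


def test_downsample_too_small_population_errors(rng):
    G = make_genotypes(rng.integers(0, 3, (10, 5)).astype(np.int8))
    labels = np.array(["a"] * 3 + ["b"] * 7)
    with pytest.raises(ValueError, match="'a'"):
        fstcore.downsample(G, labels, 5)


def test_pooled_duplicate_populations_theta_near_zero(rng):
    # the duplicated-labels bias is O(1/n), so test at a few hundred samples
    dosage = rng.binomial(2, rng.uniform(0.2, 0.5, 2000), (250, 2000)).astype(np.int8)
    G = make_genotypes(np.vstack([dosage, dosage]),
                       sample_ids=[f"x{i}" for i in range(500)])
    labels = np.array(["a"] * 250 + ["b"] * 250)
    res = fstcore.wc_fst(G, labels)
    assert abs(res.theta) < 0.005
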