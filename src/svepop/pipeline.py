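"""End-to-end orchestration: simulate or ingest a panel, run QC and every
analysis stage, and write a reproducible report bundle.

Stage order: qc -> ibs/mds -> fst (pairwise + hierarchical) -> freq scan
(lambda, significant fractions) -> ld -> spatial (mantel, inbreeding,
grid) -> admixture (+ Evanno) -> barrier. The master seed spawns one
child seed per stage through numpy's SeedSequence, so any stage can be
re-run in isolation from the manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, admix, barrier, fstcore, freqdiff, genio, ibsmds, ldcore
from . import qc as qcmod
from . import simgeno, spatial

logger = logging.getLogger(__name__)

_STAGES = ("qc", "ibs", "fst", "scan", "ld", "spatial", "admix", "barrier")


@dataclass
class RunConfig:
    out_dir: str
    sim: simgeno.SimConfig | None = None
    ped_path: str | None = None
    map_path: str | None = None
    meta_path: str | None = None
    thresholds: qcmod.QcThresholds = field(default_factory=qcmod.QcThresholds)
    n_perm_fst: int = 5000
    n_perm_mw: int = 10_000
    n_perm_mantel: int = 9999
    downsample_n: int = 115
    mds_dims: int = 2
    k_range: tuple[int, int] = (1, 4)
    admix_replicates: int = 3
    ld_n_index: int = 200
    ld_max_dist_bp: int = 500_000
    grid_radius_km: float = 150.0
    grid_min_n: int = 20
    grid_min_n_corr: int = 40
    grid_spacing_km: float = 25.0
    n_barriers: int = 2
    seed: int = 0
    fast: bool = False

    def validate(self) -> None:
        if self.sim is None:
            for p in (self.ped_path, self.map_path, self.meta_path):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input path missing: {p}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            provinces = [simgeno.Province(**p) for p in sim_raw.pop("provinces", [])]
            if "maf_range" in sim_raw:
                sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
            raw["sim"] = simgeno.SimConfig(provinces=provinces, **sim_raw)
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = qcmod.QcThresholds(**raw["thresholds"])
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)


def stage_seeds(master_seed: int, stages=_STAGES) -> dict[str, int]:
    """One reproducible child seed per stage from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(stages))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(stages, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Returns a manifest dict (also written as manifest.json) holding the
    seeds, thresholds and headline statistics of each stage. Deterministic
    stages are bit-identical across reruns with the same config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    fast = config.fast
    n_perm_fst = 200 if fast else config.n_perm_fst
    n_perm_mw = 200 if fast else config.n_perm_mw
    n_perm_mantel = 199 if fast else config.n_perm_mantel

    manifest: dict = {
        "svepop_version": __version__,
        "master_seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": asdict(config.thresholds),
        "fast": fast,
        "stages": {},
    }
    t0 = time.time()

    stage = "input"
    try:
        if config.sim is not None:
            G, S, truth = simgeno.simulate_panel(config.sim)
            G, S = simgeno.inject_artifacts(G, S, config.sim)
            genio.write_ped_map(G, out / "panel")
            genio.write_sample_metadata(S, out / "panel_samples.tsv")
        else:
            G = genio.read_ped_map(config.ped_path, config.map_path)
            S = genio.read_sample_metadata(config.meta_path)
            G, S = genio.align_samples(G, S)

        # ---- qc ----
        stage = "qc"
        kept, dup_pairs = qcmod.remove_duplicates_by_ibs(
            G, config.thresholds.dup_ibs_distance
        )
        G = G.select_samples(kept)
        S = S.set_index("sample_id").loc[kept].reset_index()
        pops_for_hwe = {
            p: list(S.loc[S["province"] == p, "sample_id"])
            for p in S["province"].unique()
        }
        G, report = qcmod.apply_qc(G, S, config.thresholds, pops_for_hwe)
        S = S.set_index("sample_id").loc[list(G.sample_ids)].reset_index()
        status = S["status"].to_numpy()
        if set(status) >= {"case", "control"}:
            drop = qcmod.two_group_frequency_filter(
                G, status, config.thresholds.case_control_p
            )
            keep_loci = [l for l in G.locus_ids if l not in set(drop)]
            G = G.select_loci(keep_loci)
        report.removed_samples.to_csv(out / "qc_removed_samples.tsv", sep="\t", index=False)
        report.removed_snps.to_csv(out / "qc_removed_snps.tsv", sep="\t", index=False)
        manifest["stages"]["qc"] = {
            "n_samples": G.n_samples,
            "n_loci": G.n_loci,
            "duplicate_pairs_removed": len(dup_pairs),
        }

        provinces = S["province"].to_numpy()
        regions = S["region"].to_numpy()

        # ---- ibs / mds ----
        stage = "ibs"
        D_ibs = ibsmds.ibs_matrix(G)
        D_ibs.to_tsv(out / "ibs_distance.tsv")
        mds = ibsmds.classical_mds(D_ibs, dims=config.mds_dims)
        coords = pd.DataFrame(
            mds.coordinates,
            columns=[f"dim{i+1}" for i in range(mds.coordinates.shape[1])],
        )
        coords.insert(0, "sample_id", G.sample_ids)
        coords.to_csv(out / "mds_coordinates.tsv", sep="\t", index=False)
        reg_list = list(dict.fromkeys(regions))
        mw_rows = []
        for i in range(len(reg_list)):
            for j in range(i + 1, len(reg_list)):
                u, p = ibsmds.permutation_mannwhitney(
                    D_ibs, regions, reg_list[i], reg_list[j],
                    n_perm=n_perm_mw, seed=seeds["ibs"] + i * 31 + j,
                )
                mw_rows.append((reg_list[i], reg_list[j], u, p))
        mw = pd.DataFrame(mw_rows, columns=["regionA", "regionB", "U", "p"])
        mw["p_bonferroni"] = ibsmds.bonferroni(mw["p"], len(mw))
        mw.to_csv(out / "ibs_mannwhitney.tsv", sep="\t", index=False)
        manifest["stages"]["ibs"] = {
            "variance_explained": [float(v) for v in mds.variance_explained],
        }

        # ---- fst ----
        stage = "fst"
        fst_all = fstcore.fst_permutation_p(
            G, provinces, n_perm=n_perm_fst, seed=seeds["fst"]
        )
        pw = fstcore.pairwise_fst_matrix(G, provinces)
        pd.DataFrame(pw.values * 10_000, index=pw.ids, columns=pw.ids).to_csv(
            out / "pairwise_fst_x10000.tsv", sep="\t"
        )
        hier = fstcore.hierarchical_fst(
            G, regions, provinces, n_perm=min(n_perm_fst, 200), seed=seeds["fst"] + 1
        )
        manifest["stages"]["fst"] = {
            "theta_provinces": fst_all.theta,
            "p_perm": fst_all.p_perm,
            "f_ct": hier.f_ct,
            "f_sc": hier.f_sc,
            "f_st": hier.f_st,
        }

        # ---- freq scan ----
        stage = "scan"
        reg_main = reg_list[0]
        labels2 = np.where(regions == reg_main, reg_main, "rest")
        scan = freqdiff.chisq_scan(G, labels2)
        usable = scan.chi2[~scan.monomorphic]
        lam = freqdiff.lambda_overdispersion(usable)
        frac = freqdiff.significant_fraction(scan.p[~scan.monomorphic], 0.05)
        scan.to_frame(G.chrom, G.pos_bp).to_csv(out / "freq_scan.tsv", sep="\t", index=False)
        freqdiff.qq_coordinates(usable).to_csv(out / "qq_coords.tsv", sep="\t", index=False)
        manifest["stages"]["scan"] = {
            "comparison": f"{reg_main} vs rest",
            "lambda": lam,
            "frac_sig_0.05": frac,
        }

        # ---- ld ----
        stage = "ld"
        n_index = min(config.ld_n_index, G.n_loci)
        pair_idx = ldcore.sample_ld_pairs(
            G, n_index, config.ld_max_dist_bp, seed=seeds["ld"]
        )
        if fast:
            pair_idx = pair_idx[:200]
        prof_rows = []
        dprimes_by_region: dict[str, list[float]] = {}
        n_ld = min(config.downsample_n, min(np.bincount(pd.factorize(regions)[0])))
        for reg in reg_list:
            sub = G.take_samples(np.where(regions == reg)[0])
            sub, _ = fstcore.downsample(
                sub, np.repeat(reg, sub.n_samples), n_ld, seed=seeds["ld"] + 7
            )
            vals = []
            for (ja, jb) in pair_idx:
                try:
                    vals.append(ldcore.ld_pair(sub, ja, jb))
                except ValueError:
                    vals.append(None)
            dprimes_by_region[reg] = [p.Dprime if p else np.nan for p in vals]
            for w_start, n_pairs, med in ldcore.ld_decay_profile(
                [p for p in vals if p is not None]
            ):
                prof_rows.append((reg, w_start, n_pairs, med))
        pd.DataFrame(
            prof_rows, columns=["region", "window_start_bp", "n_pairs", "median_dprime"]
        ).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
        ld_tests = []
        for i in range(len(reg_list)):
            for j in range(i + 1, len(reg_list)):
                a = np.asarray(dprimes_by_region[reg_list[i]])
                b = np.asarray(dprimes_by_region[reg_list[j]])
                okp = ~np.isnan(a) & ~np.isnan(b)
                w, p = ldcore.compare_ld_paired(a[okp], b[okp])
                ld_tests.append((reg_list[i], reg_list[j], w, p))
        ld_df = pd.DataFrame(ld_tests, columns=["regionA", "regionB", "W", "p"])
        ld_df["p_bonferroni"] = ibsmds.bonferroni(ld_df["p"], len(ld_df))
        ld_df.to_csv(out / "ld_comparisons.tsv", sep="\t", index=False)
        manifest["stages"]["ld"] = {"n_pairs": len(pair_idx), "n_per_pop": int(n_ld)}

        # ---- spatial ----
        stage = "spatial"
        D_geo = spatial.great_circle_matrix(S)
        r_all, p_mantel = spatial.mantel_test(
            D_ibs, D_geo, n_perm=n_perm_mantel, seed=seeds["spatial"]
        )
        inb = spatial.inbreeding_coefficients(G)
        inb.to_csv(out / "inbreeding.tsv", sep="\t", index=False)
        h_kw, p_kw = spatial.kruskal_wallis_by_region(inb["F"].to_numpy(), regions)
        cells = spatial.grid_local_statistic(
            S, per_sample_values=inb["F"].to_numpy(), kind="median_inbreeding",
            radius_km=config.grid_radius_km, min_n=config.grid_min_n,
            grid_spacing_km=config.grid_spacing_km,
        )
        corr_cells = spatial.grid_local_statistic(
            S, D_gen=D_ibs, D_geo=D_geo, kind="local_correlation",
            radius_km=config.grid_radius_km, min_n=config.grid_min_n_corr,
            grid_spacing_km=config.grid_spacing_km,
        )
        spatial.grid_cells_to_frame(cells + corr_cells).to_csv(
            out / "grid_statistics.tsv", sep="\t", index=False
        )
        manifest["stages"]["spatial"] = {
            "mantel_r": r_all,
            "mantel_p": p_mantel,
            "kruskal_wallis_H": h_kw,
            "kruskal_wallis_p": p_kw,
            "n_grid_cells": len(cells) + len(corr_cells),
        }

        # ---- admix ----
        stage = "admix"
        k_lo, k_hi = config.k_range
        logliks: dict[int, list[float]] = {}
        best_runs: dict[int, admix.AdmixtureResult] = {}
        max_iter = 100 if fast else 500
        for K in range(k_lo, k_hi + 1):
            logliks[K] = []
            for rep in range(config.admix_replicates):
                res = admix.admixture_em(
                    G, K, seed=seeds["admix"] + 97 * K + rep,
                    max_iter=max_iter, n_restarts=1,
                )
                logliks[K].append(res.loglik)
                if K not in best_runs or res.loglik > best_runs[K].loglik:
                    best_runs[K] = res
        ev = admix.evanno_delta_k(logliks) if k_hi - k_lo >= 2 else None
        pd.DataFrame(
            [(k, v) for k, reps in logliks.items() for v in reps],
            columns=["K", "loglik"],
        ).to_csv(out / "admix_logliks.tsv", sep="\t", index=False)
        best_k = ev.best_k if ev else k_lo
        admix.write_q_matrix(best_runs[best_k], G.sample_ids, out / f"Q_K{best_k}.txt")
        if best_runs[best_k].Q.shape[1] >= 2:
            anc = best_runs[best_k].Q[:, 0]
            anc_cells = spatial.grid_local_statistic(
                S, per_sample_values=anc, kind="median_ancestry",
                radius_km=config.grid_radius_km, min_n=config.grid_min_n,
                grid_spacing_km=config.grid_spacing_km,
            )
            spatial.grid_cells_to_frame(anc_cells).to_csv(
                out / "grid_ancestry.tsv", sep="\t", index=False
            )
        manifest["stages"]["admix"] = {
            "best_k": best_k,
            "delta_k": {
                int(r["K"]): (None if np.isnan(r["delta_k"]) else float(r["delta_k"]))
                for r in ev.table
            }
            if ev
            else None,
        }

        # ---- barrier ----
        stage = "barrier"
        cent = {
            p: (
                float(S.loc[S["province"] == p, "lat"].astype(float).mean()),
                float(S.loc[S["province"] == p, "lon"].astype(float).mean()),
            )
            for p in dict.fromkeys(provinces)
        }
        resid = barrier.residual_fst(pw, cent)
        bres = barrier.monmonier_barriers(resid, cent, n_barriers=config.n_barriers)
        pd.DataFrame(
            barrier.barriers_to_rows(bres),
            columns=["popA", "popB", "residual", "barrier_rank"],
        ).to_csv(out / "barriers.tsv", sep="\t", index=False)
        manifest["stages"]["barrier"] = {
            "n_barriers": len(bres.barriers),
            "strengths": [b.strength for b in bres.barriers],
        }
    except Exception:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        logger.exception("pipeline halted in stage %s", stage)
        raise

    manifest["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
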