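# Demo pipeline configuration: simulate a 3-region / 6-province panel and
# run every analysis stage. Pass --fast on the CLI for a quick smoke run.
out_dir: results/demo
seed: 1
sim:
  n_snps: 5000
  f_region: 0.004
  f_province: 0.003
  clinal_weight: 0.0
  jitter_km: 30.0
  seed: 1
  missing_rate_by_platform:
    chipA: 0.005
    chipB: 0.01
  n_duplicate_pairs: 2
  provinces:
    - {name: P1, region: South,  lat: 56.0, lon: 14.0, n_samples: 60}
    - {name: P2, region: South,  lat: 58.0, lon: 13.0, n_samples: 60}
    - {name: P3, region: Middle, lat: 59.5, lon: 16.0, n_samples: 60}
    - {name: P4, region: Middle, lat: 61.0, lon: 15.0, n_samples: 60}
    - {name: P5, region: North,  lat: 64.0, lon: 18.0, n_samples: 60}
    - {name: P6, region: North,  lat: 66.0, lon: 21.0, n_samples: 60}
n_perm_fst: 5000
n_perm_mw: 10000
n_perm_mantel: 9999
downsample_n: 50
ld_n_index: 100
k_range: [1, 4]
grid_min_n: 20
grid_min_n_corr: 40
n_barriers: 2
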