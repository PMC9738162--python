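version: '1'
seed: 0
simulation:
  n_patients: 348
  profile_proportions:
  - 0.302
  - 0.193
  - 0.129
  - 0.198
  - 0.178
  genome:
  - - chr1
    - 22000000
  - - chr2
    - 21240000
  - - chr3
    - 20480000
  - - chr4
    - 19720000
  - - chr5
    - 18960000
  - - chr6
    - 18200000
  - - chr7
    - 17440000
  - - chr8
    - 16680000
  - - chr9
    - 15920000
  - - chr10
    - 15160000
  - - chr11
    - 14400000
  - - chr12
    - 13640000
  - - chr13
    - 12880000
  - - chr14
    - 12120000
  - - chr15
    - 11360000
  - - chr16
    - 10600000
  - - chr17
    - 9840000
  - - chr18
    - 9080000
  - - chr19
    - 8320000
  - - chr20
    - 7560000
  - - chr21
    - 6800000
  - - chr22
    - 6040000
  bin_size: 20000
  mean_depth: 60.0
  gc_bias_strength: 0.3
  dispersion: 0.05
  ccne1_locus:
  - chr17
  - 8000000
  - 8400000
  hrd_signature:
    n_segments:
    - 8
    - 16
    segment_length:
    - 1000000.0
    - 8000000.0
    copies:
    - 1
    - 3
    hotspot_fraction: 0.8
    hotspot_length: 8000000.0
    hotspot_position: 0.3
    hotspot_min_chrom: 12000000.0
  immune_model:
    means:
      CD8:
        BRCAm: 78.6
        nonBRCAmutHRD: 54.3
        CCNE1: 55.4
        double: 62.1
        NSMP: 93.5
      CD103:
        BRCAm: 71.8
        nonBRCAmutHRD: 53.6
        CCNE1: 37.6
        double: 50.7
        NSMP: 51.1
      CD20:
        BRCAm: 27.4
        nonBRCAmutHRD: 18.9
        CCNE1: 13.3
        double: 22.1
        NSMP: 27.5
      CD68:
        BRCAm: 159.9
        nonBRCAmutHRD: 62.4
        CCNE1: 56.2
        double: 71.0
        NSMP: 46.6
    shapes:
      CD8:
        BRCAm: 1.33
        nonBRCAmutHRD: 1.3
        CCNE1: 0.82
        double: 1.09
        NSMP: 0.72
      CD103:
        BRCAm: 0.73
        nonBRCAmutHRD: 0.55
        CCNE1: 0.66
        double: 0.83
        NSMP: 0.82
      CD20:
        BRCAm: 0.57
        nonBRCAmutHRD: 0.92
        CCNE1: 0.9
        double: 0.56
        NSMP: 0.66
      CD68:
        BRCAm: 0.49
        nonBRCAmutHRD: 0.43
        CCNE1: 1.0
        double: 0.3
        NSMP: 0.6
    n_cores: 4
  survival_model:
    base_hazard:
      BRCAm: 0.014818
      nonBRCAmutHRD: 0.018552
      CCNE1: 0.029772
      double: 0.025087
      NSMP: 0.023742
    density_multipliers:
      CD8: 1.0
      CD20: 1.0
      CD68: 1.0
      CD103: 0.6367
    density_cutoffs:
      CD8: 100
      CD20: 50
      CD68: 100
      CD103: 100
    pfs_factor: 2.3
    censor_horizon_months: 120.0
  nsmp_alteration_rate: 0.7
  brca_hrd_fraction: 0.9
  ccne1_amp_fraction: 0.37777777777777777
  amplicon_length:
  - 300000.0
  - 3000000.0
  quality_fail_rate: 0.0
  seed: 0
profile:
  qc_mapd: 0.6
  lowess_span: 0.3
  aggregate_size: 1000000
classifier:
  n_train: 200
  delta: null
  delta_grid:
  - 0.0
  - 0.5
  - 1.0
  - 1.5
  - 2.0
  - 3.0
  - 4.0
  folds: 5
segmentation:
  alpha: 0.01
  n_perm: 200
  min_width: 2
  smooth_mapd: 0.45
  merge_threshold: 0.1
tme:
  mode: fixed
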