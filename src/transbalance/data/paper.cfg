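{
 "seed": 1,
 "model": "m1",
 "n_genes": 50,
 "gene_length": 300,
 "tsp_fraction": 0.1,
 "n_a": 81,
 "n_c": 23,
 "mu": 7e-09,
 "cpg_multiplier": 3.5,
 "window_size": 100,
 "step": 1,
 "maf_min": 0.05,
 "r2_min": 0.5,
 "min_aligned": 95,
 "balanced_frequency": 0.5,
 "balanced_origin_factor": 10.0,
 "calibration_windows": 2000,
 "recombination_rate": 3.6e-08,
 "eco_permutations": 100,
 "thin_km": 5.0,
 "out_dir": "results/pipeline"
}
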