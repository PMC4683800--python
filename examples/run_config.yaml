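# Full-pipeline run configuration (flags override these values).
# `source: simulate` generates the default synthetic extraction run;
# use `source: files` with spectra_path/references_path for real tables.
source: simulate
seed: 1
n_per_phase: [40, 30, 23]

analytes:
  - glycyrrhizic_acid
  - liquiritin
  - isoliquiritin
  - total_flavonoids

split_fraction: 0.6666666666666666   # 93 samples -> 62 / 31

# pretreatment candidates to compare (subset of the default ladder);
# omit to compare all ten
ladder: [raw, sg9, sg11, snv, msc, osc1, wds, normalize]

a_max: 10

run_mwpls: true
mwpls_h: [13, 15, 17, 19, 21, 23, 25, 27, 29, 31, 33, 35, 37, 39, 41]
mwpls_step: 25        # window-start stride; 1 = exhaustive scan

n_intervals: 20
k: 3
thin: 4               # average adjacent points before the searches

alpha: 0.01
rmsep_guard: 2.0      # veto pretreatments whose RMSEP exceeds 2x the best

out_dir: runs/demo
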