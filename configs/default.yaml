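# Example run configuration (all fields optional; defaults shown in
# src/schoolpa/config.py).  Run with:
#   schoolpa run --config configs/default.yaml --seed 1 --out out/
population:
  n_surveyed: 6906
  n_clusters: 100
  n_districts: 16
raking_margins: [district_gender, ethnic_group]
population_total: 278240        # 376 schools x 740 students
raking_tol: 1.0e-8
raking_max_iter: 200
ci_level: 0.95
interventions: published_deltas # or: illustrative, none
n_schools: 376
students_per_school: 740
seed: 1
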