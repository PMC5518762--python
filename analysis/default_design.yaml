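n_genera: 4
gardens_per_genus: 2
congeners_per_genus: 4
n_occ: 300
warm_bias: true
cold_congener_frac: 0.375
breadth_range:
- 0.8
- 1.3
s_max: 1.0
min_range_cells: 50
seed: 0
nrows: 100
ncols: 100
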