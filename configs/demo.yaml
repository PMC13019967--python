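# Demo pipeline configuration: a 20-km synthetic landscape, 12 collared
# animals tracked over two years, fences at 0.8 km/km^2 that walkers
# cross with probability 0.4 per encounter, and a forage preference.
grid:
  x0: 0.0
  y0: 0.0
  cell: 30.0
  nrows: 667
  ncols: 667
  crs: EPSG:32612

seed: 11
output_dir: demo_out

seasons:
  winter: 2
  summer: 7

synthetic:
  n_animals: 12
  n_fixes: 250          # per fold, upper bound; durations vary per fold
  years: [2021, 2022]
  species: deer
  densities:            # km of line per km^2
    paved: 0.2
    unpaved: 0.3
    fence: 0.8
  pattern: random_segments
  habitat_beta:
    forage: 1.5
  permeability:
    fence: 0.4
  attraction_rate: 0.15 # 1/h
  step_scale: 250.0     # m per 2-h step

locoh:
  k: null               # null -> ceil(sqrt(n)) per fold
  levels: [0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.95]

models:
  hypotheses: [H1, H2, H3, H4]
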