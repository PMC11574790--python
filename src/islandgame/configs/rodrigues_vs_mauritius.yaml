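# Default two-island study: Rodrigues-like guyot vs Mauritius-like cone,
# one full glacial cycle of sawtooth sea-level forcing (120 -> 0 ky BP).
model:
  b: 0.15
  mu: 0.03333333333333333
  c: 0.00025
  territory_km2: 0.104
seed_fraction: 0.01
scenarios:
  - rodrigues
  - mauritius
bifurcation:
  k_min: 500.0
  k_max: 30000.0
  n_grid: 25
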