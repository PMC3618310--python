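"""Simulate a pH-step expression experiment and undo the per-sample
distortions with spike-in normalization.

The generator plants known per-sample affine distortions (scanner gain and
offset); the three-step normalization — anchor to the reference spike-in,
interpolate through the ten spike knots to concentration units, equalize the
75th percentile — removes them. With noise switched off the recovery is
exact, which is the cleanest way to see what the procedure does.
"""

import numpy as np

import phregulon as pr
from phregulon.simulate import noise_free

cfg = noise_free(pr.SyntheticConfig(n_genes=1000, archetype_sizes={}, seed=0))
matrix, meta, spikes, truth = pr.generate_expression_experiment(cfg)

print(f"raw matrix: {matrix.values.shape[0]} rows "
      f"({int(matrix.spike_flags.sum())} spike-ins) x {matrix.values.shape[1]} samples")
print(f"planted sample slopes  : {truth.sample_slope.round(3).tolist()[:4]} ...")
print(f"planted sample offsets : {truth.sample_offset.round(3).tolist()[:4]} ...")

norm, audit = pr.normalize_expression(matrix, spikes)

diff = (norm.gene_values() - truth.true_log_concentration).to_numpy()
max_err = np.abs(diff - diff.mean()).max()
print(f"\nanchor shifts applied  : {audit.anchor_shift.round(3).tolist()[:4]} ...")
print(f"max |normalized - true log10 concentration| (up to a constant): {max_err:.2e}")
print("-> the affine distortions are removed to machine precision; with real",
      "(noisy) data the same chain removes them up to the gene noise.")
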