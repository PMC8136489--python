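"""Superposition and per-residue conservation across a model ensemble.

Builds five copies of a Calpha helix with a mobile loop (residues
16-25, 3 A perturbations), superposes all models onto the first with
the Kabsch algorithm, and maps mean pairwise Calpha deviation to a
conservation score (1 = rigid, 0 = most mobile) — the score that is
painted into the B-factor column for structure viewers.
"""

import tempfile
from pathlib import Path

import numpy as np

from lipidshift import per_residue_divergence, write_conservation_bfactor
from lipidshift.simulate import SyntheticScenario, make_model_ensemble

scenario = SyntheticScenario(seed=9, loop_amplitude=3.0, n_models=5)
models, loop_mask = make_model_ensemble(scenario)
ca_sets = np.stack([m.ca_coords() for m in models])
profile = per_residue_divergence(ca_sets)

print("residue  deviation_A  conservation")
for rid, dev, cons in zip(profile.residue_ids, profile.deviation,
                          profile.conservation):
    marker = " <- planted mobile loop" if loop_mask[rid - 1] else ""
    if rid % 5 == 0 or marker:
        print(f"{rid:7d}  {dev:10.2f}  {cons:12.2f}{marker}")

loop_mean = profile.deviation[loop_mask].mean()
core_mean = profile.deviation[~loop_mask].mean()
print(f"\nmean deviation: loop {loop_mean:.2f} A vs core "
      f"{core_mean:.2f} A — the planted loop dominates the divergence")

out = Path(tempfile.mkdtemp()) / "conservation.pdb"
write_conservation_bfactor(models[0], profile, out)
print(f"wrote conservation-painted structure to {out}")
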