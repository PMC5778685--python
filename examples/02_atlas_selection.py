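"""Rank candidate atlases by Pearson correlation with a test scan's VOI.

Atlas selection picks, from all available labelled scans, the ten whose
peri-hippocampal intensity patterns correlate best with the scan to be
segmented; those ten drive the machine-learning label fusion.
"""

import numpy as np

from hippoatlas import rank_atlases

rng = np.random.default_rng(0)
test_voi = rng.normal(0.5, 0.1, size=4000)  # VOI intensity vector of the test scan

# fifteen candidate atlases with increasing dissimilarity
candidates = {f"atlas-{i:02d}": test_voi + rng.normal(0, 0.02 * (i + 1), 4000) for i in range(15)}

ranking = rank_atlases(test_voi, candidates)  # default: select m = 10
print("rank  atlas      r")
for i, (atlas_id, r) in enumerate(ranking.ranked):
    marker = "*" if i < ranking.m else " "
    print(f"{marker} {i + 1:3d}  {atlas_id}  {r:+.4f}")
print(f"\nselected {ranking.m} atlases (starred); their r values become the fusion weights")
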