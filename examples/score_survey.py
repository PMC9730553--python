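"""Score a small survey against the published FDD11 calibration.

Builds a three-person response CSV in memory, runs the full scoring
pipeline (recode -> missingness filter -> sum score -> ability -> 0-100
scale -> disability level) and prints the result.
"""

import numpy as np

import fdd11

artifact = fdd11.published()

# original 0-4 coding; the Q09 column is the summed emotion testlet (0-8)
rows = np.array([
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],   # no difficulty anywhere
    [2, 2, 2, 2, 2, 2, 2, 2, 4, 1, 1],   # moderate difficulty across domains
    [4, 4, 4, 4, 4, 4, 4, 4, 8, 4, 4],   # extreme difficulty everywhere
])
data = fdd11.ResponseMatrix(rows, ["anna", "ben", "chris"], artifact.item_ids)

recoded = fdd11.apply_recodes(data, fdd11.fdd11_recode_map(artifact))
retained, excluded = fdd11.filter_missingness(recoded, max_missing=2)
scores = fdd11.score_persons(retained, artifact)

print(f"{'person':8} {'sum':>3} {'ability':>8} {'SE':>6} {'0-100':>7}  level")
for s in scores:
    se = f"{s.se:.3f}" if s.se is not None else "  --"
    print(f"{s.person_id:8} {s.sum_score:3d} {s.theta:8.3f} {se:>6} "
          f"{s.transformed:7.2f}  {s.level}")

# The ability is the logit location on the latent disability continuum; the
# 0-100 score is its affine image (anchors -3.71 -> 0, 4.18 -> 100); levels
# use the published cut-offs 4.3 / 22.6 / 40.8.
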