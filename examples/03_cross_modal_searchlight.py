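"""Run both cross-decoding searchlights on a few phantom subjects.

The semantic-feature classifier is trained on spoken words and tested on
written words (and vice versa), so only format-independent meaning
information can drive it; the perceptual classifier is trained on non-words
and tested on words, so only meaning-free format information can. Single
subjects are noisy, so a handful are averaged here; the group-level test
lives in example 04.
"""

import numpy as np

from hubspoke import Role, SearchlightSpec, make_phantom_atlas, make_phantom_truth, make_scheme, searchlight
from hubspoke.studies import simulate_subject_patterns

atlas = make_phantom_atlas()
hub = atlas.mask(Role.SEMANTIC_HUB)
mod = atlas.mask(Role.MODALITY_REGION)
mask = hub | mod
spec = SearchlightSpec(radius=6.0)  # 123-voxel spheres on the 2 mm grid

acc = {(k, r): [] for k in ("semantic_feature", "perceptual") for r in ("hub", "mod")}
for subject in range(4):
    truth = make_phantom_truth(atlas, seed=subject)
    patterns = simulate_subject_patterns(truth, seed=100 + subject, mask=mask)
    for kind in ("semantic_feature", "perceptual"):
        amap = searchlight(patterns, mask, spec, make_scheme(kind))
        acc[(kind, "hub")].append(np.nanmean(amap.values[hub & amap.valid]))
        acc[(kind, "mod")].append(np.nanmean(amap.values[mod & amap.valid]))

for kind in ("semantic_feature", "perceptual"):
    hub_m = np.mean(acc[(kind, "hub")])
    mod_m = np.mean(acc[(kind, "mod")])
    print(f"{kind:17s}: hub {hub_m:.3f}   modality region {mod_m:.3f}")
# Accuracy above 0.5 marks regions carrying the decoded information: the hub
# decodes meaning across formats, the modality region decodes format — a
# double dissociation, here visible already in four subjects.
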