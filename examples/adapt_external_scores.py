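"""Run the DCST on interaction scores from an external inference method.

Any cell-cell communication method that scores (sender, recipient, ligand,
receptor) interactions per subject can feed the DCST after binarization:
an interaction is an active linkage when its probability exceeds 0.1.
"""

import numpy as np
import pandas as pd

from linksig import from_interaction_scores, test_differential_linkages

rng = np.random.default_rng(3)
subjects = [f"s{i}" for i in range(8)]
groups = ["classical"] * 4 + ["basal"] * 4

tables = {}
for subj, grp in zip(subjects, groups):
    # one interaction strongly group-dependent, one present everywhere
    fgf_prob = rng.uniform(0.3, 0.8) if grp == "classical" else rng.uniform(0.0, 0.08)
    tables[subj] = pd.DataFrame(
        {
            "source": ["fibroblast", "fibroblast"],
            "target": ["epithelial", "epithelial"],
            "ligand": ["FGF2", "COL1A1"],
            "receptor": ["FGFR4", "ITGB1"],
            "prob": [fgf_prob, rng.uniform(0.4, 0.9)],
        }
    )

meta = pd.DataFrame({"subject": subjects, "subtype": groups})
summary = from_interaction_scores(tables, meta, threshold=0.1)
results = test_differential_linkages(
    summary, group_var="subtype", linkage_class="cl_rec_lig",
    cell_type="epithelial", reference_group="classical",
)
cols = ["linkage", "classical_with", "basal_with", "odds_ratio", "p_value", "p_adj"]
print(results[cols].to_string(index=False))

# The FGF2 -> FGFR4 linkage is present in the classical subjects only
# (4/4 vs 0/4: p = 0.029, BH-adjusted 0.057 within the two-linkage family
# of the recipient cell type), while the ubiquitous collagen linkage tests
# at p = 1.  Four subjects per arm sit right at the exact test's resolution
# limit -- the motivation for larger cohorts or bootstrap pseudo-replicates.
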