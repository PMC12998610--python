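"""Infer one subject's signaling linkages from a small simulated sample.

Builds a two-cell-type sample (A and B) in which B expresses the receptors
R1/R2 and A sends the ligands L1/L2, then runs per-subject inference: TF
enrichment, receptor-TF correlation, and the expression gates that turn
these into binary linkages.
"""

from linksig import CCCIConfig, infer_subject
from linksig.simulate import SimulationConfig, benchmark_database, simulate_sample

cfg = SimulationConfig(seed=11)
ds, tf_scores = simulate_sample(cfg, condition="C1", index=0)
db = benchmark_database()

linkages = infer_subject(ds, tf_scores, db, CCCIConfig())

print(f"subject: {linkages.subject}")
print(f"cell types: {sorted(linkages.cell_types)}")
print(f"enriched TFs (cell type, TF): {sorted(linkages.tfs)}")
print(f"active receptors (cell type, receptor): {sorted(linkages.rec)}")
print("intracellular linkages (cell type, TF, receptor):")
for lk in sorted(linkages.tfs_rec):
    print("   ", lk)
print("intercellular linkages (recipient, receptor, ligand, sender):")
for lk in sorted(linkages.cl_rec_lig):
    print("   ", lk)

# In condition C1 the expected output is [B]: R1 <- L1: [A] (and the
# condition-independent [B]: R2 <- L2: [A]): B holds active receptors
# because its TF activity tracks receptor expression, and A passes the
# sender gate (mean scaled ligand expression > 0).
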