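"""Integrate differential methylation with differential expression for a
single pairwise comparison.

Builds a small synthetic two-group experiment (triplicates, coverage ~30)
with 24 planted coupled genes and 8 discordant decoys, then runs the full
per-comparison chain: DE -> per-CpG DMCs -> promoter/body region calls ->
direction-rule integration.
"""

import epiprog as ep

ann, catalogue = ep.make_annotation(n_genes=200, seed=1)
truth = ep.make_planted_truth(
    list(ann.gene_ids), affected_groups=["case"],
    n_coupled=24, n_decoy=8, log2fc=3.0, meth_shift=40.0, seed=2,
)
counts = ep.simulate_counts(ann, ["control", "case"], planted=truth, seed=3)
meth = ep.simulate_methylome(ann, catalogue, ["control", "case"], planted=truth, seed=4)

res = ep.run_comparison(counts, meth, ann, "control", "case")

print(f"genes tested:        {len(res.de)}")
print(f"DE genes (|lfc|>=2, q<=0.01):  {(res.de['direction'] != 'ns').sum()}")
print(f"DMCs (q<=0.01, |diff|>=25):    {int(res.dmcs['is_dmc'].sum())} of {len(res.dmcs)} tested CpGs")
print(f"region calls (>=3 DMCs):       {len(res.region_calls)}")
print(f"integrated genes:    {len(res.integrated)}")
print()
print(res.integrated.head(8).to_string(index=False))
print()
planted = set(truth.coupled["gene_id"])
emitted = set(res.integrated["gene_id"])
print(f"sensitivity on planted coupled genes: {len(emitted & planted) / len(planted):.2f}")
print(f"discordant decoys emitted (must be 0): {len(emitted & set(truth.decoys['gene_id']))}")
# Each integrated row pairs an expression change with a same-gene region
# methylation change in the canonical direction (promoter anti-correlated,
# gene body positively correlated).  At this deliberately tiny scale the
# |log2FC| >= 2 filter costs some sensitivity; at the study scale (2000
# genes) recovery is ~0.95 (see epiprog.validation.planted_recovery).
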