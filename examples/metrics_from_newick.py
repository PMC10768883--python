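"""Compute diversity-decay metrics for a small Newick phylogeny.

Builds a toy 6-cell tree whose branching all happens within the first
~15 mutations (an embryonic-like burst) except for one late pair of
cells (a small subclonal family), then reports the raw and
standardized shape statistics.
"""

from phylodecay import diversity_metrics, read_newick

NEWICK = (
    "((a:400,(b:390,c:392):10):5,"
    "(d:398,(e:30,f:31):370):8);"
)

tree = read_newick(NEWICK)
res = diversity_metrics(tree)

print(f"tips n        = {res.n}")
print(f"ancestral n_a = {res.n_a}   (lineages crossing depth t_a = {res.t_a:.2f})")
print(f"imbalance pi  = {res.pi},  ancestral pi_a = {res.pi_a}")
print(f"alpha = {res.alpha:.3f}   (log2 imbalance decay since the burst)")
print(f"beta  = {res.beta:.3f}   (log2 lineage-count decay; 0 = no displacement)")
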