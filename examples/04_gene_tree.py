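"""Perfect-phylogeny check and gene-tree construction.

Infinite-sites data rooted at the all-zero sequence is compatible with a
unique mutation-labelled tree exactly when no column pair shows the three
gametes 01, 10 and 11.  The tree below reproduces the worked dataset:
mutation 1 sits above every allele except a4, and a2's root path carries
all four mutations.
"""

import iscoal as ic

d = ic.table1()
rep = ic.four_gamete_test(d)
print(f"rooted gamete test: {'compatible' if rep.ok else rep.violations}")

tree = ic.build_gene_tree(d)
print("\nindented outline (*: internal node, edges show mutations):")
print(ic.export_tree(tree, "text"))
print("newick:")
print(ic.export_tree(tree, "newick"))
print("(leaf 'a1:2' is allele a1 sampled twice; gene trees carry no "
      "branch lengths — they are not coalescent trees)")
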