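"""Assemble a composite cladogram by grafting source trees onto a backbone.

Each published source tree shares a landmark taxon with the informal
backbone; the source's clade replaces the landmark tip in place, so the
backbone's structure is always preserved.
"""

from paleoasr import assemble_supertree_from_parts, parse_newick, write_newick
from paleoasr.trees import induced_subtree

backbone = "(Outgroup,(CrocLine,(OrnithischianA,TheropodA)));"
sources = [
    ("(CrocLine,(Aetosaur1,Aetosaur2));", "CrocLine"),
    ("(TheropodA,(TheropodB,(Paravian1,Paravian2)));", "TheropodA"),
]

supertree = assemble_supertree_from_parts(backbone, sources)
print("supertree:", write_newick(supertree))
print("tips:", supertree.n_tips)

restricted = induced_subtree(supertree, parse_newick(backbone).leaf_labels())
print("restricted to backbone taxa:", write_newick(restricted))
# The final line matches the original backbone: grafting only ever adds
# taxa inside the landmark's position, never rearranges the backbone.
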