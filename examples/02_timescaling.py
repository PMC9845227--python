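"""Date a fossil tree from stratigraphic ranges.

Tips are dated at their first appearance (FAD); each internal node is
as old as the oldest FAD among its descendants; zero-length branches
are then stretched by shifting ancestors older until every branch is at
least the minimum branch length (1 Myr here).
"""

from paleoasr import StratRange, parse_newick, timescale_tree

tree = parse_newick("((Early,Late),Oldest);")
ranges = {
    "Early": StratRange("Early", fad=150.0, lad=145.0),
    "Late": StratRange("Late", fad=140.0, lad=130.0),
    "Oldest": StratRange("Oldest", fad=160.0, lad=155.0),
}

ts = timescale_tree(tree, ranges, mbl=1.0)
for node in ts.postorder():
    name = node.label or "(internal)"
    print(f"{name:12s} age {node.age:6.1f} Ma   branch {node.length or 0:5.1f} Myr")
# The (Early,Late) node ties Early's FAD at 150 Ma, so it is pushed to
# 151 Ma by the minimum-branch-length rule; the root sits above Oldest's
# 160 Ma first appearance.
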