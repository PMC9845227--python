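"""Code specimen-level rib evidence into character state sets.

State 0 = process absent, 1 = cartilaginous (scar or calcified
evidence), 2 = ossified.  The preferred approach codes taxa without
positive evidence as uncertain "?"; the alternate approach codes taxa
with at least five scar-free ribs as absent.
"""

from paleoasr import SpecimenEvidence, code_alternate, code_preferred
from paleoasr.coding import format_states

evidence = [
    SpecimenEvidence("ScarBearer", n_ribs_examined=4, n_ribs_with_scar=2),
    SpecimenEvidence("OssifiedForm", 3, 0, "ossified"),
    SpecimenEvidence("WellSampledBlank", 8, 0),   # >=5 scar-free ribs
    SpecimenEvidence("PoorlySampled", 2, 0),
    SpecimenEvidence("Outgroup", 13, 0, override_state=frozenset({0})),
]

pref = code_preferred(evidence)
alt = code_alternate(evidence, min_ribs=5)
print(f"{'taxon':20s} {'preferred':>10s} {'alternate':>10s}")
for taxon in pref.taxa():
    print(f"{taxon:20s} {format_states(pref[taxon]):>10s} {format_states(alt[taxon]):>10s}")
# WellSampledBlank flips from "?" to "0" under the alternate approach;
# taxa with positive evidence are identical under both.
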