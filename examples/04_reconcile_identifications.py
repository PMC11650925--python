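"""Reconcile conflicting identifications from two reference databases.

Replays the curated set of real dual-database conflicts: congeners
collapse to "Genus sp.", confamilial genera to "Family sp.", curated
overrides resolve photograph- or revision-backed cases to species, and a
lone misidentified accession is outvoted by the concordant majority.
"""

from coipipe.datasets import conflict_cases, curated_overrides, outlier_reference_case
from coipipe.taxassign import flag_outlier_reference, reconcile

overrides = curated_overrides()
print(f"{'mOTU':<14} {'nt hit':<28} {'local hit':<28} {'final':<26} provenance")
for case in conflict_cases():
    idn = reconcile(case.hits_nt, case.hits_local, overrides, motu=case.motu)
    print(f"{case.motu:<14} {case.hits_nt[0].species:<28} "
          f"{case.hits_local[0].species:<28} {idn.final_name:<26} {idn.provenance}")

case = outlier_reference_case()
res = flag_outlier_reference(case.hits)
print(f"\noutlier check: top hit {case.hits[0].species} ({case.hits[0].accession}) "
      f"is outvoted -> {res.consensus_species}, flagged {res.flagged_accessions}")
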