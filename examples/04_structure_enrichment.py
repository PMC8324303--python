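"""Structural annotation and enrichment of mutation classes.

Builds a synthetic peptide chain (a geometric stand-in for a real PDB
structure), annotates residues with solvent accessibility, sector
contact and distance to the effector insertion site, then tests whether
a hypothetical set of allostery-enhancing positions is enriched on the
surface with a Fisher exact contingency test.

With a real structure, replace `make_synthetic_chain()` with
`load_structure("1rx2.pdb", chain="A")`.
"""

from dmsallo import annotate_residues, distance_profile, enrichment_test, make_synthetic_chain
from dmsallo.structure import distance_to_anchor

chain = make_synthetic_chain("ACDEFGHIKLMNPQRSTVWY")
annotation = annotate_residues(
    chain, sector_residues={4, 5, 6}, conserved_residues={4, 5}, anchor=10
)
print(annotation[["rsa", "surface", "sector", "sector_contact", "dist_anchor_A"]].head(6).round(3))

sector = set(annotation.index[annotation["sector"]])
universe = set(annotation.index)
disrupting_positions = {4, 5, 6, 9}  # hypothetical allostery-disrupting sites
table = enrichment_test(disrupting_positions, sector, universe)
print("contingency:", table.table.tolist())
print(f"odds ratio {table.odds_ratio:.2f}, Fisher two-sided p = {table.p_value:.3g}")

profile = distance_profile(
    {"enhancing": [1, 2, 8, 12, 15, 18], "disrupting": sorted(disrupting_positions)},
    distance_to_anchor(chain, anchor=10),
    bins=[10.0, 20.0, 40.0],
)
print(profile.round(2))

# The profile rows give the cumulative fraction of each mutation class
# within each Calpha distance of the insertion site; localized classes
# saturate in the first bin.
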