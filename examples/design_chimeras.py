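"""Codon-aware WDP/BamHI domain splitting and chimera assembly.

Builds two donor ORFs at the study's P74 dimensions (645 aa, WDP aspartate
at codon 458), introduces the single synonymous C->T edit that creates the
BamHI site in a GAC-aspartate donor, splits both ORFs into Nt (1..458) and
Ct (459..645) domains, and fuses the Nt of one donor to the Ct of the
other in frame.
"""

from p74kit.chimera import (
    apply_synonymous_edits,
    assemble_chimera,
    find_wdp_splits,
    restriction_scan,
    split_orf,
)
from p74kit.simulate import p74_like_orf_spec, simulate_orf

donor_a, _ = simulate_orf(p74_like_orf_spec(seed=1, id="donorA"))
donor_b, _ = simulate_orf(
    p74_like_orf_spec(seed=2, id="donorB", d_codon_choice="GAT"))

(split_a,) = find_wdp_splits(donor_a)
print(f"donorA: WDP at codons {split_a.w_codon}-{split_a.p_codon}, "
      f"BamHI present: {split_a.bamhi_present}, "
      f"required edits: {split_a.required_edits}")

edited_a = apply_synonymous_edits(donor_a, split_a)
assert edited_a.protein == donor_a.protein  # edit is synonymous
nt, ct = split_orf(edited_a, split_a)
print(f"split after codon {split_a.split_after_codon}: "
      f"Nt {len(nt.protein)} aa (ends ...{nt.protein[-2:]}), "
      f"Ct {len(ct.protein)} aa (starts {ct.protein[0]}...)")

(split_b,) = find_wdp_splits(donor_b)
chimera = assemble_chimera(donor_a, split_a, donor_b, split_b)
sites = restriction_scan(chimera.cds, ["BamHI"])
print(f"chimera {chimera.id}: {len(chimera.protein)} aa, "
      f"BamHI junction at nt {sites[0].position}")
# The chimera protein is exactly donorA residues 1..458 followed by
# donorB residues 459..645; the GGATCC site marks the in-frame junction.
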