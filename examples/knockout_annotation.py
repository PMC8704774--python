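"""CRISPR target localisation and NHEJ indel consequence annotation.

Plants the published crRNA protospacer in a synthetic ORF, locates it with
its NGG PAM, predicts the blunt SpCas9 cut 3 nt 5' of the PAM, applies a
4-bp NHEJ deletion at the cut and classifies the coding consequence.
"""

from p74kit.crispr import (
    GuideRNA,
    apply_deletion,
    classify_edit,
    locate_protospacer,
)
from p74kit.simulate import OrfSpec, simulate_orf

CRRNA = "AACTGGCTTTCAGCAAGCGC"

orf, truth = simulate_orf(
    OrfSpec(length=645, protospacers=[(CRRNA, 63)], seed=3, id="p74_target"))

guide = GuideRNA(CRRNA)
(site,) = locate_protospacer(orf.cds, guide)
print(f"protospacer at nt {site.protospacer_start} ({site.strand} strand), "
      f"PAM at {site.pam_start}, predicted cut between "
      f"nt {site.cut_after} and {site.cut_after + 1}")

outcome = apply_deletion(orf, site.cut_after, site.cut_after + 3)
print(f"4-bp deletion {site.cut_after}-{site.cut_after + 3}: "
      f"frameshift={outcome.frameshift}, "
      f"premature stop={outcome.premature_stop} "
      f"(stop codon {outcome.stop_codon_position})")
print(f"product: {outcome.product_length_aa} aa "
      f"(wild type {len(orf.protein)} aa), "
      f"novel residues after the lesion: {outcome.novel_residues!r}")
print(f"classification: {classify_edit(outcome)}")
# A lesion whose length is not a multiple of 3 shifts the frame; the first
# stop reached in the shifted frame truncates the product -> knockout.
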