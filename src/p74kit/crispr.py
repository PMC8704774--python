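"""SpCas9 target localisation and NHEJ indel consequence annotation.

A 20-nt protospacer followed by an NGG PAM is located on either strand of a
coding sequence; the blunt double-strand break is modelled 3 nt 5′ of the
PAM, i.e. between protospacer positions 17 and 18.  User-specified NHEJ
lesions (deletions/insertions) are applied to the ORF and the coding
consequence classified: a lesion length not divisible by 3 shifts the
frame, and a first stop codon upstream of where the wild-type stop would
fall marks a premature stop — together the hallmark of a knockout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .chimera import OrfRecord, STOP_CODONS, reverse_complement, translate


@dataclass
class GuideRNA:
    protospacer: str
    pam_pattern: str = "NGG"

    def __post_init__(self) -> None:
        self.protospacer = self.protospacer.upper().replace("U", "T")
        if len(self.protospacer) != 20:
            raise ValueError(
                f"protospacer must be 20 nt, got {len(self.protospacer)}"
            )
        bad = set(self.protospacer) - set("ACGT")
        if bad:
            raise ValueError(f"protospacer contains non-ACGT: {sorted(bad)}")
        if self.pam_pattern != "NGG":
            raise ValueError("only the SpCas9 NGG PAM is supported")


@dataclass
class TargetSite:
    """A protospacer match; coordinates are 1-based on the + strand of the CDS.

    ``protospacer_start``/``pam_start`` give the + strand coordinate of the
    base pairing the protospacer's / PAM's 5′ end on the target strand.
    ``cut_after = n`` places the blunt cut between + strand positions n and
    n+1 (between protospacer positions 17 and 18).
    """

    strand: str
    protospacer_start: int
    pam_start: int
    cut_after: int


@dataclass
class EditOutcome:
    """Coding consequence of one NHEJ lesion on an ORF."""

    edited_cds: str
    product: str
    product_length_aa: int
    frameshift: bool
    premature_stop: bool
    stop_codon_position: Optional[int]  # 1-based codon index in the edited CDS
    novel_residues: str
    lesion: tuple  # ("deletion", start, length) | ("insertion", after, bases)
    wildtype_product: str = ""


def locate_protospacer(cds: str, guide: GuideRNA) -> list[TargetSite]:
    """All exact protospacer+NGG matches on both strands, sorted by position."""
    cds = cds.upper()
    proto = guide.protospacer
    rc = reverse_complement(proto)
    sites: list[TargetSite] = []
    # + strand: protospacer at s..s+19, PAM at s+20..s+22 (NGG).
    i = cds.find(proto)
    while i != -1:
        s = i + 1
        if i + 23 <= len(cds) and cds[i + 21:i + 23] == "GG":
            sites.append(
                TargetSite(
                    strand="+", protospacer_start=s, pam_start=s + 20,
                    cut_after=s + 16,
                )
            )
        i = cds.find(proto, i + 1)
    # − strand: + strand carries revcomp(protospacer) at s..s+19 with CCN
    # immediately 5′ of it (s−3..s−1), the revcomp of the NGG PAM.
    i = cds.find(rc)
    while i != -1:
        s = i + 1
        if s >= 4 and cds[i - 3:i - 1] == "CC":
            sites.append(
                TargetSite(
                    strand="-", protospacer_start=s + 19, pam_start=s - 1,
                    cut_after=s + 2,
                )
            )
        i = cds.find(rc, i + 1)
    sites.sort(key=lambda t: min(t.protospacer_start, t.pam_start))
    return sites


def _outcome(orf: OrfRecord, edited_cds: str, lesion: tuple) -> EditOutcome:
    wt_product = orf.protein
    indel = (
        -lesion[2] if lesion[0] == "deletion" else len(lesion[2])
    )
    with warnings.catch_warnings():
        # a frameshifted CDS legitimately ends with a 1-2 nt remainder
        warnings.simplefilter("ignore")
        tr = translate(edited_cds)
    frameshift = indel % 3 != 0
    # Where the wild-type stop codon would start in edited coordinates, for
    # a lesion entirely upstream of it.
    wt_stop_start = 3 * len(wt_product) + 1
    expected_stop_start = wt_stop_start + indel
    if tr.stop_codon is None:
        premature = False
        stop_pos = None
    else:
        stop_pos = tr.stop_codon
        premature = (3 * (stop_pos - 1) + 1) < expected_stop_start
    product = tr.protein
    # Novel residues: edited product from the first positional mismatch on.
    i = 0
    while i < len(product) and i < len(wt_product) and product[i] == wt_product[i]:
        i += 1
    novel = product[i:]
    return EditOutcome(
        edited_cds=edited_cds,
        product=product,
        product_length_aa=len(product),
        frameshift=frameshift,
        premature_stop=premature,
        stop_codon_position=stop_pos,
        novel_residues=novel,
        lesion=lesion,
        wildtype_product=wt_product,
    )


def apply_deletion(orf: OrfRecord, start: int, end: int) -> EditOutcome:
    """Delete ORF nt ``start..end`` (1-based inclusive) and annotate."""
    if not 1 <= start <= end <= len(orf.cds):
        raise ValueError(
            f"deletion {start}..{end} outside ORF of length {len(orf.cds)}"
        )
    if start <= 3:
        raise ValueError("deletion may not remove the ATG start codon")
    edited = orf.cds[:start - 1] + orf.cds[end:]
    return _outcome(orf, edited, ("deletion", start, end - start + 1))


def apply_insertion(orf: OrfRecord, after: int, bases: str) -> EditOutcome:
    """Insert ``bases`` directly after ORF nt ``after`` (0 = before the ATG)."""
    bases = bases.upper()
    if not bases or set(bases) - set("ACGT"):
        raise ValueError(f"insertion must be non-empty ACGT, got {bases!r}")
    if not 0 <= after <= len(orf.cds):
        raise ValueError(
            f"insertion point {after} outside ORF of length {len(orf.cds)}"
        )
    edited = orf.cds[:after] + bases + orf.cds[after:]
    return _outcome(orf, edited, ("insertion", after, bases))


def classify_edit(outcome: EditOutcome) -> str:
    """Label an outcome: knockout / silent / nonsense_in_frame / in_frame_indel.

    ``knockout`` requires a frameshift *and* a premature stop; ``silent``
    means the edited product equals the wild type exactly.
    """
    if outcome.frameshift and outcome.premature_stop:
        return "knockout"
    if outcome.product == outcome.wildtype_product:
        return "silent"
    if outcome.premature_stop:
        return "nonsense_in_frame"
    return "in_frame_indel"
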