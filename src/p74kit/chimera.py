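"""WDP-triad location, synonymous BamHI engineering and chimeric ORF assembly.

The conserved tryptophan–aspartate–proline (WDP) triad at the boundary of
the P74 Nt and Ct domains is encoded TGG GAY CCN.  When the aspartate codon
is GAT the sequence already contains a BamHI site (GGATCC spanning the last
base of the W codon through the second base of the P codon); when it is GAC
a single synonymous C→T edit at the codon's third base creates it.  Cutting
immediately after the D codon splits any p74 ORF into an Nt fragment ending
…WD and a Ct fragment starting P…, so that fragments from different species
can be rejoined in frame without altering either donor's protein sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = set(_STANDARD.stop_codons)  # {"TAA", "TAG", "TGA"}

ENZYMES = {"BamHI": "GGATCC", "BglII": "AGATCT", "HindIII": "AAGCTT"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


class Translation(NamedTuple):
    """Protein up to (excluding) the first stop, plus where the stop fell."""

    protein: str
    stop_codon: Optional[int]  # 1-based codon index of the first stop, if any


def translate(cds: str) -> Translation:
    """Codon-by-codon standard-code translation.

    Stops at and excludes the first stop codon.  Codons containing N
    translate to 'X' with a warning; a trailing 1–2 nt remainder is ignored
    with a warning.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError(f"CDS of length {len(cds)} has no complete codon")
    if len(cds) % 3:
        warnings.warn(
            f"CDS length {len(cds)} not divisible by 3; trailing "
            f"{len(cds) % 3} nt ignored",
            stacklevel=2,
        )
    aas: list[str] = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in STOP_CODONS:
            return Translation("".join(aas), i // 3 + 1)
        if "N" in codon:
            warnings.warn(
                f"ambiguous codon {codon!r} at codon {i // 3 + 1} "
                "translated as 'X'",
                stacklevel=2,
            )
            aas.append("X")
        else:
            aas.append(CODON_TO_AA[codon])
    return Translation("".join(aas), None)


@dataclass
class OrfRecord:
    """A validated coding sequence: ATG … (no internal stop) … stop codon."""

    id: str
    cds: str
    applied_edits: list[tuple[int, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        bad = set(self.cds) - set("ACGTN")
        if bad:
            raise ValueError(f"ORF {self.id!r}: illegal DNA characters {sorted(bad)}")
        if len(self.cds) % 3:
            raise ValueError(
                f"ORF {self.id!r}: length {len(self.cds)} not divisible by 3"
            )
        if not self.cds.startswith("ATG"):
            raise ValueError(f"ORF {self.id!r}: does not begin with ATG")
        if self.cds[-3:] not in STOP_CODONS:
            raise ValueError(f"ORF {self.id!r}: does not end with a stop codon")
        tr = translate(self.cds)
        if tr.stop_codon is not None and tr.stop_codon != len(self.cds) // 3:
            raise ValueError(
                f"ORF {self.id!r}: internal stop at codon {tr.stop_codon}"
            )
        self._protein = tr.protein

    @property
    def protein(self) -> str:
        return self._protein

    @property
    def n_codons(self) -> int:
        """Coding codons, excluding the terminal stop."""
        return len(self._protein)


@dataclass
class SplitPoint:
    """A WDP occurrence with the edits (if any) needed for a BamHI site."""

    w_codon: int
    d_codon: int
    p_codon: int
    bamhi_present: bool
    required_edits: list[tuple[int, str, str]]  # (1-based ORF nt, from, to)
    split_after_codon: int

    def __post_init__(self) -> None:
        assert self.d_codon == self.w_codon + 1
        assert self.p_codon == self.w_codon + 2
        assert self.split_after_codon == self.d_codon
        assert self.bamhi_present == (not self.required_edits)


@dataclass
class OrfFragment:
    """A codon-range fragment of a donor ORF (Ct fragments keep the stop)."""

    donor_id: str
    cds: str
    codon_start: int
    codon_end: int

    @property
    def protein(self) -> str:
        return translate(self.cds).protein


@dataclass
class ChimeraResult:
    """An in-frame fusion: [tag] + Nt(donor A) + Ct(donor B or stop)."""

    id: str
    cds: str
    nt_donor: OrfFragment
    ct_donor: Optional[OrfFragment]
    tag: Optional[str] = None

    @property
    def protein(self) -> str:
        return translate(self.cds).protein


@dataclass
class RestrictionSite:
    enzyme: str
    motif: str
    position: int  # 1-based start of the motif
    strand: str = "+"


def find_wdp_splits(orf: OrfRecord) -> list[SplitPoint]:
    """All WDP triads in the ORF's protein, with BamHI status and edits.

    The D codon of a WDP triad is GAT or GAC.  GAT means GGATCC is already
    present (last G of TGG through the CC of the proline codon); GAC needs
    the single synonymous edit C→T at the codon's third base (ORF nt 3·d).
    """
    splits: list[SplitPoint] = []
    protein = orf.protein
    idx = protein.find("WDP")
    while idx != -1:
        w = idx + 1
        d, p = w + 1, w + 2
        d_codon_seq = orf.cds[3 * (d - 1):3 * d]
        assert d_codon_seq in ("GAT", "GAC"), d_codon_seq
        if d_codon_seq == "GAT":
            edits: list[tuple[int, str, str]] = []
        else:
            edits = [(3 * d, "C", "T")]
        splits.append(
            SplitPoint(
                w_codon=w, d_codon=d, p_codon=p,
                bamhi_present=not edits, required_edits=edits,
                split_after_codon=d,
            )
        )
        idx = protein.find("WDP", idx + 1)
    return splits


def apply_synonymous_edits(orf: OrfRecord, split: SplitPoint) -> OrfRecord:
    """Return a copy of *orf* with the split's synonymous edits applied.

    No-op when the BamHI site is already present.  The translation is
    asserted unchanged and GGATCC is asserted present across the triad.
    """
    _check_split(orf, split)
    if not split.required_edits:
        return OrfRecord(orf.id, orf.cds)
    cds = list(orf.cds)
    for pos, frm, to in split.required_edits:
        if cds[pos - 1] != frm:
            raise ValueError(
                f"edit {frm}->{to} at nt {pos}: found {cds[pos - 1]!r} instead"
            )
        cds[pos - 1] = to
    edited = OrfRecord(orf.id, "".join(cds), applied_edits=list(split.required_edits))
    assert edited.protein == orf.protein, "synonymous edit changed the protein"
    junction = edited.cds[3 * (split.w_codon - 1):3 * split.p_codon]
    assert ENZYMES["BamHI"] in junction
    return edited


def _check_split(orf: OrfRecord, split: SplitPoint) -> None:
    if not 1 <= split.w_codon <= orf.n_codons - 2:
        raise ValueError(f"split at codon {split.w_codon} outside ORF {orf.id!r}")
    if orf.protein[split.w_codon - 1:split.p_codon] != "WDP":
        raise ValueError(
            f"ORF {orf.id!r} does not read WDP at codons "
            f"{split.w_codon}..{split.p_codon}"
        )


def split_orf(orf: OrfRecord, split: SplitPoint) -> tuple[OrfFragment, OrfFragment]:
    """Cut the CDS after the D codon: Nt ends …WD, Ct begins P… (keeps stop)."""
    _check_split(orf, split)
    cut_nt = 3 * split.split_after_codon
    nt = OrfFragment(orf.id, orf.cds[:cut_nt], 1, split.split_after_codon)
    ct = OrfFragment(
        orf.id, orf.cds[cut_nt:], split.split_after_codon + 1, len(orf.cds) // 3
    )
    return nt, ct


def assemble_chimera(
    nt_donor_orf: OrfRecord,
    nt_split: SplitPoint,
    ct_donor_orf: Optional[OrfRecord] = None,
    ct_split: Optional[SplitPoint] = None,
    tag_cds: Optional[str] = None,
    id: Optional[str] = None,
) -> ChimeraResult:
    """Fuse the Nt domain of one donor to the Ct domain of another, in frame.

    Both donors are first normalised with their synonymous BamHI edits, so
    the junction always carries GGATCC.  Without a Ct donor (Nt-only
    construct) a TAA stop terminates the Nt fragment.  A tag CDS, when
    given, is prepended verbatim (it must be in frame and stop-free); the
    donor ATG is retained, mirroring a translational fusion.
    """
    nt_edited = apply_synonymous_edits(nt_donor_orf, nt_split)
    nt_frag, _ = split_orf(nt_edited, nt_split)
    ct_frag: Optional[OrfFragment] = None
    if ct_donor_orf is not None:
        if ct_split is None:
            raise ValueError("ct_split required when a Ct donor is given")
        ct_edited = apply_synonymous_edits(ct_donor_orf, ct_split)
        _, ct_frag = split_orf(ct_edited, ct_split)
        body = nt_frag.cds + ct_frag.cds
    else:
        body = nt_frag.cds + "TAA"
    if tag_cds is not None:
        tag_cds = tag_cds.upper()
        if len(tag_cds) % 3:
            raise ValueError(f"tag CDS length {len(tag_cds)} not divisible by 3")
        tag_tr = translate(tag_cds) if len(tag_cds) >= 3 else Translation("", None)
        if tag_tr.stop_codon is not None:
            raise ValueError(f"tag CDS contains a stop at codon {tag_tr.stop_codon}")
        body = tag_cds + body
    tag_codons = len(tag_cds) // 3 if tag_cds else 0
    junction_codon = tag_codons + nt_split.split_after_codon  # D codon in chimera
    result = ChimeraResult(
        id=id or _default_chimera_id(nt_donor_orf, ct_donor_orf),
        cds=body, nt_donor=nt_frag, ct_donor=ct_frag, tag=tag_cds,
    )
    protein = result.protein
    if ct_frag is not None:
        triad = protein[junction_codon - 2:junction_codon + 1]
        if triad != "WDP":
            raise ValueError(f"chimera junction reads {triad!r}, expected 'WDP'")
        expected = (
            (translate(tag_cds).protein if tag_cds else "")
            + nt_frag.protein + ct_frag.protein
        )
        assert protein == expected, "chimera protein is not the donor concatenation"
        junction_dna = result.cds[3 * (junction_codon - 2):3 * (junction_codon + 1)]
        assert ENZYMES["BamHI"] in junction_dna
    return result


def _default_chimera_id(
    nt_donor: OrfRecord, ct_donor: Optional[OrfRecord]
) -> str:
    if ct_donor is None:
        return f"{nt_donor.id}-Nt"
    return f"{nt_donor.id}-{ct_donor.id}"


def restriction_scan(dna: str, enzymes=("BamHI", "BglII", "HindIII")) -> list[RestrictionSite]:
    """All exact plus-strand motif occurrences (overlaps allowed), 1-based."""
    dna = dna.upper()
    if not dna:
        raise ValueError("empty DNA sequence")
    sites: list[RestrictionSite] = []
    for name in enzymes:
        if name not in ENZYMES:
            raise ValueError(f"unknown enzyme {name!r}; known: {sorted(ENZYMES)}")
        motif = ENZYMES[name]
        start = dna.find(motif)
        while start != -1:
            sites.append(RestrictionSite(name, motif, start + 1))
            start = dna.find(motif, start + 1)
    sites.sort(key=lambda s: (s.position, s.enzyme))
    return sites
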