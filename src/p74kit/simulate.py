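"""Synthetic protein families and ORFs with planted, auditable ground truth.

The family generator emulates the structure of the 76-sequence P74
alignment used for conservation profiling: a random template with planted
perfectly conserved residues (e.g. six cysteines), per-column conservative
(Clustal strong/weak group) or random substitutions at configurable rates,
and hydrophobic TM-like blocks drawn from {I,L,V,F,A,M}.  Families are
generated gap-free so that planted truth stays exact.

The ORF generator reverse-translates a protein with uniform synonymous
codon choice, forcing the WDP triad codons (TGG GAY CCN, the aspartate
codon selectable GAT/GAC), and can insert 20-nt protospacers with a valid
NGG PAM at codon boundaries (padded to 24 nt to preserve the reading
frame).  Every draw is governed by a single integer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chimera import CODON_TO_AA, OrfRecord, STOP_CODONS
from .consensus import STRONG_GROUPS, WEAK_GROUPS
from .crispr import GuideRNA, locate_protospacer
from .seqio import Alignment, SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC = "ILVFAM"

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


def _group_partners(residue: str, groups: Sequence[str]) -> list[str]:
    partners: set[str] = set()
    for g in groups:
        if residue in g:
            partners.update(g)
    partners.discard(residue)
    return sorted(partners)


# ---------------------------------------------------------------------------
# Protein families


@dataclass
class FamilySpec:
    n_sequences: int = 76
    length: int = 645
    conserved_columns: dict[int, str] = field(default_factory=dict)
    strong_sub_rate: float = 0.15
    weak_sub_rate: float = 0.10
    random_sub_rate: float = 0.15
    hydrophobic_blocks: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")
        rates = self.strong_sub_rate + self.weak_sub_rate + self.random_sub_rate
        if not 0 <= rates <= 1:
            raise ValueError(f"substitution rates sum to {rates}, need <= 1")
        for col, res in self.conserved_columns.items():
            if not 1 <= col <= self.length:
                raise ValueError(f"conserved column {col} outside 1..{self.length}")
            if res not in AA20:
                raise ValueError(f"conserved residue {res!r} not standard")
        for start, end in self.hydrophobic_blocks:
            if not 1 <= start <= end <= self.length:
                raise ValueError(f"block {start}..{end} outside 1..{self.length}")


@dataclass
class FamilyTruth:
    template: str
    conserved_columns: dict[int, str]
    hydrophobic_blocks: list[tuple[int, int]]
    # (sequence id, 1-based column, from, to, kind)
    mutations: list[tuple[str, int, str, str, str]]
    untouched_columns: set[int]
    fallback_events: list[tuple[str, int, str]] = field(default_factory=list)


def simulate_family(spec: FamilySpec) -> tuple[Alignment, FamilyTruth]:
    """Generate a gap-free family alignment plus its mutation bookkeeping."""
    rng = random.Random(spec.seed)
    template = [rng.choice(AA20) for _ in range(spec.length)]
    for start, end in spec.hydrophobic_blocks:
        for col in range(start, end + 1):
            if col not in spec.conserved_columns:
                template[col - 1] = rng.choice(HYDROPHOBIC)
    for col, res in spec.conserved_columns.items():
        template[col - 1] = res
    template_s = "".join(template)

    mutations: list[tuple[str, int, str, str, str]] = []
    fallback: list[tuple[str, int, str]] = []
    mutated_cols: set[int] = set()
    records: list[SequenceRecord] = []
    width = len(str(spec.n_sequences))
    for i in range(spec.n_sequences):
        sid = f"seq_{i + 1:0{width}d}"
        seq = list(template_s)
        for col in range(1, spec.length + 1):
            if col in spec.conserved_columns:
                continue
            r = rng.random()
            res = seq[col - 1]
            kind: Optional[str] = None
            if r < spec.strong_sub_rate:
                kind = "strong"
                choices = _group_partners(res, STRONG_GROUPS)
            elif r < spec.strong_sub_rate + spec.weak_sub_rate:
                kind = "weak"
                choices = _group_partners(res, WEAK_GROUPS)
            elif r < (
                spec.strong_sub_rate + spec.weak_sub_rate + spec.random_sub_rate
            ):
                kind = "random"
                choices = [a for a in AA20 if a != res]
            else:
                continue
            if not choices:  # residue without group partners
                fallback.append((sid, col, kind))
                kind = "random"
                choices = [a for a in AA20 if a != res]
            new = rng.choice(choices)
            seq[col - 1] = new
            mutations.append((sid, col, res, new, kind))
            mutated_cols.add(col)
        records.append(SequenceRecord(sid, "".join(seq), "protein"))
    untouched = set(range(1, spec.length + 1)) - mutated_cols
    truth = FamilyTruth(
        template=template_s,
        conserved_columns=dict(spec.conserved_columns),
        hydrophobic_blocks=list(spec.hydrophobic_blocks),
        mutations=mutations,
        untouched_columns=untouched,
        fallback_events=fallback,
    )
    return Alignment(records), truth


def p74_like_family_spec(seed: int = 0, **overrides) -> FamilySpec:
    """The default study-condition family: 76 sequences, 645 columns,
    six planted cysteines (three Nt pairs), three TM-like Ct blocks."""
    defaults = dict(
        n_sequences=76,
        length=645,
        conserved_columns={60: "C", 95: "C", 180: "C", 215: "C", 300: "C", 335: "C"},
        hydrophobic_blocks=[(470, 494), (560, 584), (600, 624)],
        strong_sub_rate=0.15,
        weak_sub_rate=0.10,
        random_sub_rate=0.15,
        seed=seed,
    )
    defaults.update(overrides)
    if "length" in overrides:  # keep planted defaults inside a shorter family
        L = defaults["length"]
        if "conserved_columns" not in overrides:
            defaults["conserved_columns"] = {
                c: r for c, r in defaults["conserved_columns"].items() if c <= L
            }
        if "hydrophobic_blocks" not in overrides:
            defaults["hydrophobic_blocks"] = [
                (s, e) for s, e in defaults["hydrophobic_blocks"] if e <= L
            ]
    return FamilySpec(**defaults)


# ---------------------------------------------------------------------------
# ORFs


@dataclass
class OrfSpec:
    """Blueprint of a synthetic ORF.

    ``wdp_positions`` lists the codon index of each planted triad's
    aspartate (the middle residue), matching the convention in which the
    synonymous BamHI edit of a GAC aspartate at codon k falls at ORF
    nucleotide 3k.  ``protospacers`` are (20-nt sequence, codon boundary)
    or (sequence, boundary, PAM) tuples; each is inserted verbatim after
    the boundary codon together with its NGG PAM and a 1-nt pad.
    """

    protein: Optional[str] = None
    length: Optional[int] = None
    wdp_positions: list[int] = field(default_factory=list)
    d_codon_choice: str = "GAC"  # "GAT" | "GAC" | "random"
    protospacers: list[tuple] = field(default_factory=list)
    seed: int = 0
    id: str = "synthetic_orf"

    def __post_init__(self) -> None:
        if (self.protein is None) == (self.length is None):
            raise ValueError("give exactly one of protein or length")
        if self.protein is not None:
            self.protein = self.protein.upper()
            if not self.protein.startswith("M"):
                raise ValueError("protein must start with M (the ATG)")
            self.length = len(self.protein)
        if self.d_codon_choice not in ("GAT", "GAC", "random"):
            raise ValueError(f"bad d_codon_choice {self.d_codon_choice!r}")
        for k in self.wdp_positions:
            if not 3 <= k <= self.length - 1:
                raise ValueError(
                    f"WDP aspartate codon {k} outside 3..{self.length - 1}"
                )
        seen: set[int] = set()
        for k in self.wdp_positions:
            if seen & {k - 1, k, k + 1}:
                raise ValueError("planted WDP triads overlap")
            seen.update({k - 1, k, k + 1})
        for ps in self.protospacers:
            seq, boundary = ps[0], ps[1]
            if len(seq) != 20 or set(seq.upper()) - set("ACGT"):
                raise ValueError(f"protospacer must be 20 nt ACGT, got {seq!r}")
            if not 1 <= boundary <= self.length:
                raise ValueError(
                    f"protospacer boundary {boundary} outside 1..{self.length}"
                )


@dataclass
class OrfTruth:
    protein: str
    wdp: list[dict]  # d_codon, d_codon_seq, edit_nt (or None)
    protospacers: list[dict]  # sequence, strand, protospacer_start, cut_after


class SimulationError(RuntimeError):
    pass


def _reverse_translate(protein: str, rng: random.Random, spec: OrfSpec) -> list[str]:
    codons: list[str] = []
    planted_d = set(spec.wdp_positions)
    for pos, aa in enumerate(protein, start=1):
        if pos in planted_d and spec.d_codon_choice != "random":
            codons.append(spec.d_codon_choice)
        else:
            codons.append(rng.choice(_AA_TO_CODONS[aa]))
    return codons


def simulate_orf(spec: OrfSpec, max_retries: int = 20) -> tuple[OrfRecord, OrfTruth]:
    """Generate a valid ORF with planted WDP triads and protospacers."""
    rng = random.Random(spec.seed)
    for _ in range(max_retries):
        result = _try_simulate_orf(spec, rng)
        if result is not None:
            return result
    raise SimulationError(
        f"could not place planted features after {max_retries} attempts "
        f"(spec {spec.id!r})"
    )


def _try_simulate_orf(
    spec: OrfSpec, rng: random.Random
) -> Optional[tuple[OrfRecord, OrfTruth]]:
    # Protein: given, or random with planted triads (reject spurious WDPs).
    if spec.protein is not None:
        protein = spec.protein
        if _spurious_wdp(protein, spec.wdp_positions):
            raise ValueError("supplied protein contains an unplanted WDP triad")
    else:
        for _ in range(200):
            aas = ["M"] + [rng.choice(AA20) for _ in range(spec.length - 1)]
            for k in spec.wdp_positions:
                aas[k - 2:k + 1] = ["W", "D", "P"]
            protein = "".join(aas)
            if not _spurious_wdp(protein, spec.wdp_positions):
                break
        else:
            return None
    codons = _reverse_translate(protein, rng, spec)
    codons.append("TAA")

    # Insert protospacer segments (8 codons each) at descending boundaries.
    placements: list[tuple[str, int]] = []
    for ps in sorted(spec.protospacers, key=lambda t: -t[1]):
        proto = ps[0].upper()
        pam = ps[2].upper() if len(ps) > 2 else None
        boundary = ps[1]
        # In-frame stops inside the protospacer cannot be repaired.
        for j in range(0, 18, 3):
            if proto[j:j + 3] in STOP_CODONS:
                raise SimulationError(
                    f"protospacer {proto} carries in-frame stop {proto[j:j + 3]}"
                )
        if pam is None:
            ok = [n for n in "ACGT" if proto[18:20] + n not in STOP_CODONS]
            pam = rng.choice(ok) + "GG"
        else:
            if pam[1:] != "GG" or proto[18:20] + pam[0] in STOP_CODONS:
                raise SimulationError(f"PAM {pam!r} invalid for this protospacer")
        pad = rng.choice("ACGT")
        segment = proto + pam + pad
        codons[boundary:boundary] = [segment[j:j + 3] for j in range(0, 24, 3)]
        placements.append((proto, boundary))

    cds = "".join(codons)
    orf = OrfRecord(spec.id, cds)

    # Planted protospacers must be recovered uniquely.
    proto_truth: list[dict] = []
    n_earlier = lambda b: sum(1 for _, b2 in placements if b2 < b)
    for proto, boundary in sorted(placements, key=lambda t: t[1]):
        sites = locate_protospacer(cds, GuideRNA(proto))
        if len(sites) != 1:
            return None  # chance collision elsewhere; redraw
        start = 3 * (boundary + 8 * n_earlier(boundary)) + 1
        site = sites[0]
        assert site.strand == "+" and site.protospacer_start == start
        proto_truth.append(
            dict(
                sequence=proto, strand="+",
                protospacer_start=start, cut_after=start + 16,
            )
        )

    wdp_truth: list[dict] = []
    final_protein = orf.protein
    for k in sorted(spec.wdp_positions):
        shift = 8 * sum(1 for _, b in placements if b < k - 1)
        d = k + shift
        assert final_protein[d - 2:d + 1] == "WDP"
        d_seq = cds[3 * (d - 1):3 * d]
        wdp_truth.append(
            dict(
                d_codon=d, d_codon_seq=d_seq,
                edit_nt=3 * d if d_seq == "GAC" else None,
            )
        )
    return orf, OrfTruth(
        protein=final_protein, wdp=wdp_truth, protospacers=proto_truth
    )


def _spurious_wdp(protein: str, planted: Sequence[int]) -> bool:
    planted_w = {k - 2 for k in planted}  # 0-based index of the W
    idx = protein.find("WDP")
    while idx != -1:
        if idx not in planted_w:
            return True
        idx = protein.find("WDP", idx + 1)
    return False


def p74_like_orf_spec(seed: int = 0, **overrides) -> OrfSpec:
    """The default study-condition ORF: 645 aa with the WDP aspartate at
    codon 458 encoded GAC, so the Nt/Ct split yields 458 + 187 residues and
    the synonymous BamHI edit falls at nucleotide 1374."""
    defaults = dict(
        length=645, wdp_positions=[458], d_codon_choice="GAC",
        seed=seed, id="p74_like",
    )
    defaults.update(overrides)
    return OrfSpec(**defaults)
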