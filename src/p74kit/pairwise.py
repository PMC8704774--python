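"""Global pairwise alignment and identity/similarity statistics.

Needleman–Wunsch with affine gaps (BLOSUM62, open 10 / extend 0.5 by
default; a gap of length L costs open + (L−1)·extend).  Percent identity
is identical aligned pairs over the full alignment length (gapped columns
included in the denominator); percent similarity additionally counts
aligned pairs with a positive substitution score, or — with the "group"
definition — pairs in a common Clustal strong group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .chimera import OrfRecord, find_wdp_splits
from .consensus import _STRONG_SETS
from .seqio import PROTEIN_ALPHABET, SequenceRecord

GAP = "-"


@dataclass
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    similarity_def: str = "positive"  # "positive" | "group"

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend >= 0:
            raise ValueError("need gap_open >= gap_extend >= 0")
        if self.similarity_def not in ("positive", "group"):
            raise ValueError(f"unknown similarity_def {self.similarity_def!r}")

    def load_matrix(self):
        return substitution_matrices.load(self.matrix)


@dataclass
class AlignedPair:
    a_id: str
    b_id: str
    a_gapped: str
    b_gapped: str
    score: float


@dataclass
class PairwiseResult:
    identity_pct: float
    similarity_pct: float
    alignment_length: int
    aligned_pairs: int

    def __post_init__(self) -> None:
        assert 0 <= self.identity_pct <= self.similarity_pct <= 100


def _check_protein(seq: str, name: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"sequence {name!r} is empty")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"sequence {name!r}: non-standard residues {sorted(bad)}")
    return seq


def global_align(
    a: str, b: str, params: AlignmentParams | None = None,
    a_id: str = "a", b_id: str = "b",
) -> AlignedPair:
    """Optimal global alignment of two protein sequences."""
    params = params or AlignmentParams()
    a, b = _check_protein(a, a_id), _check_protein(b, b_id)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = params.load_matrix()
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aln = aligner.align(a, b)[0]
    return AlignedPair(a_id, b_id, str(aln[0]), str(aln[1]), aln.score)


def identity_similarity(
    pair: AlignedPair, params: AlignmentParams | None = None
) -> PairwiseResult:
    """Percent identity/similarity over the full (gapped) alignment length."""
    params = params or AlignmentParams()
    ga, gb = pair.a_gapped, pair.b_gapped
    if len(ga) != len(gb):
        raise ValueError(
            f"gapped lengths differ: {len(ga)} vs {len(gb)}"
        )
    matrix = params.load_matrix()
    length = len(ga)
    aligned = identical = similar = 0
    for x, y in zip(ga, gb):
        if x == GAP or y == GAP:
            continue
        aligned += 1
        if x == y:
            identical += 1
            similar += 1
        elif params.similarity_def == "positive":
            if matrix[x, y] > 0:
                similar += 1
        else:  # "group": Clustal strong-group co-membership
            if any({x, y} <= g for g in _STRONG_SETS):
                similar += 1
    return PairwiseResult(
        identity_pct=100.0 * identical / length,
        similarity_pct=100.0 * similar / length,
        alignment_length=length,
        aligned_pairs=aligned,
    )


def compare(
    a: str, b: str, params: AlignmentParams | None = None
) -> PairwiseResult:
    """Align two proteins and report identity/similarity in one step."""
    return identity_similarity(global_align(a, b, params), params)


REGIONS = ("complete", "nt", "ct")


@dataclass
class DomainMatrices:
    """Identity/similarity for complete proteins and their Nt/Ct domains."""

    ids: list[str]
    results: dict  # region -> {(idA, idB): PairwiseResult}
    excluded: list[str] = field(default_factory=list)

    def frame(self, region: str, stat: str = "identity_pct") -> pd.DataFrame:
        df = pd.DataFrame(index=self.ids, columns=self.ids, dtype=float)
        for (a, b), res in self.results[region].items():
            v = getattr(res, stat)
            df.loc[a, b] = v
            df.loc[b, a] = v
        return df

    def to_long(self) -> pd.DataFrame:
        rows = []
        for region in REGIONS:
            for (a, b), res in self.results[region].items():
                rows.append(
                    dict(
                        seqA=a, seqB=b, region=region,
                        identity=res.identity_pct, similarity=res.similarity_pct,
                        alignment_length=res.alignment_length,
                    )
                )
        return pd.DataFrame(rows)


def _domains_of(protein: str) -> Optional[tuple[str, str]]:
    """(Nt incl. …WD, Ct from P…) for a protein with exactly one WDP triad."""
    first = protein.find("WDP")
    if first == -1 or protein.find("WDP", first + 1) != -1:
        return None
    cut = first + 2  # after the D
    return protein[:cut], protein[cut:]


def domain_matrix(
    records: Sequence[OrfRecord | SequenceRecord],
    params: AlignmentParams | None = None,
) -> DomainMatrices:
    """Pairwise identity/similarity matrices for complete / Nt / Ct regions.

    Each sequence is split at its own (unique) WDP triad; sequences without
    exactly one triad are reported and excluded.
    """
    params = params or AlignmentParams()
    proteins: dict[str, tuple[str, str, str]] = {}
    excluded: list[str] = []
    for rec in records:
        protein = rec.protein if isinstance(rec, OrfRecord) else rec.residues
        domains = _domains_of(protein)
        if domains is None:
            warnings.warn(
                f"sequence {rec.id!r} lacks a unique WDP triad; excluded",
                stacklevel=2,
            )
            excluded.append(rec.id)
            continue
        proteins[rec.id] = (protein, *domains)
    ids = list(proteins)
    results = {region: {} for region in REGIONS}
    for ri, region in enumerate(REGIONS):
        for i, a in enumerate(ids):
            for b in ids[i:]:
                if a == b:
                    seq = proteins[a][ri]
                    results[region][(a, b)] = PairwiseResult(
                        100.0, 100.0, len(seq), len(seq)
                    )
                else:
                    results[region][(a, b)] = compare(
                        proteins[a][ri], proteins[b][ri], params
                    )
    return DomainMatrices(ids=ids, results=results, excluded=excluded)
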