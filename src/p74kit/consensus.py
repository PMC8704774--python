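"""Consensus-line conservation scoring and windowed similarity profiles.

A protein alignment is reduced to a per-column conservation symbol following
Clustal conventions ('*' full identity, ':' strong-group conservation,
'.' weak-group conservation, ' ' otherwise; any gap blanks the column).
The symbol string is then scanned with an odd sliding window: every symbol
contributes a configurable score (+1 / +0.5 / +0.25 / −0.2 by default), the
window sum is normalised by the window length and assigned to the central
column.  Window values are computed through exact rational arithmetic and
rounded to float once, so they are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

from .seqio import GAP, Alignment, ConsensusLine, SequenceError

# ClustalW/X default conservation groups.
STRONG_GROUPS = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF", "HY", "FYW"]
WEAK_GROUPS = [
    "CSA", "ATV", "SAG", "STNK", "STPA", "SGND",
    "SNDEQK", "NDEQHK", "NEQHRK", "FVLIM", "HFY",
]

_STRONG_SETS = [frozenset(g) for g in STRONG_GROUPS]
_WEAK_SETS = [frozenset(g) for g in WEAK_GROUPS]


@dataclass
class ScoringScheme:
    """Symbol scores and window width for the similarity profile."""

    identity_score: float = 1.0
    strong_score: float = 0.5
    weak_score: float = 0.25
    other_score: float = -0.2
    window: int = 35

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if not (
            self.identity_score >= self.strong_score >= self.weak_score
            > self.other_score
        ):
            raise ValueError(
                "scores must satisfy identity >= strong >= weak > other"
            )

    def score_of(self, symbol: str) -> float:
        return {
            "*": self.identity_score,
            ":": self.strong_score,
            ".": self.weak_score,
            " ": self.other_score,
        }[symbol]


@dataclass
class SimilarityProfile:
    """Window-centred conservation values over 1-based alignment columns."""

    positions: list[int]
    values: list[float]
    symbols: Optional[str] = None  # symbol at each centre, for reporting

    def table_header(self) -> list[str]:
        if self.symbols is not None:
            return ["column", "symbol", "window_value"]
        return ["column", "window_value"]

    def table_rows(self):
        for i, (p, v) in enumerate(zip(self.positions, self.values)):
            if self.symbols is not None:
                yield (p, self.symbols[i], v)
            else:
                yield (p, v)


@dataclass
class FrequencyMatrix:
    """Per-column residue counts (gap included) with information content.

    Information is ``log2(20) − H`` where ``H`` is the Shannon entropy of the
    gap-excluded residue frequencies of the column.
    """

    columns: list[int]
    counts: list[Counter]
    n_sequences: int
    information: list[float] = field(default_factory=list)


def column_symbol(column: str) -> str:
    """Clustal conservation symbol for one alignment column.

    Any gap blanks the column; 'X' is never conserved (it belongs to no
    group and never matches, not even another 'X').
    """
    if GAP in column:
        return " "
    residues = set(column)
    if "X" in residues:
        return " "
    if len(residues) == 1:
        return "*"
    if any(residues <= g for g in _STRONG_SETS):
        return ":"
    if any(residues <= g for g in _WEAK_SETS):
        return "."
    return " "


def compute_consensus(alignment: Alignment) -> ConsensusLine:
    """Derive the Clustal-style conservation line of a protein alignment."""
    return ConsensusLine(
        "".join(column_symbol(alignment.column(c)) for c in range(1, alignment.length + 1))
    )


def similarity_profile(
    consensus: ConsensusLine, scheme: ScoringScheme | None = None
) -> SimilarityProfile:
    """Windowed similarity values from a consensus line.

    Only full windows are evaluated: for a consensus of length L and window
    w the profile covers centres ceil(w/2) .. L − floor(w/2).  Each value is
    the window's symbol-score sum divided by w.
    """
    scheme = scheme or ScoringScheme()
    w = scheme.window
    s = consensus.symbols
    if len(s) < w:
        raise ValueError(f"consensus length {len(s)} shorter than window {w}")
    frac = {
        "*": Fraction(scheme.identity_score),
        ":": Fraction(scheme.strong_score),
        ".": Fraction(scheme.weak_score),
        " ": Fraction(scheme.other_score),
    }
    counts = Counter(s[:w])
    positions: list[int] = []
    values: list[float] = []
    half = w // 2
    for start in range(0, len(s) - w + 1):
        if start > 0:
            counts[s[start - 1]] -= 1
            counts[s[start + w - 1]] += 1
        total = sum(frac[sym] * n for sym, n in counts.items() if n)
        positions.append(start + half + 1)
        values.append(float(total / w))
    symbols = "".join(s[p - 1] for p in positions)
    return SimilarityProfile(positions=positions, values=values, symbols=symbols)


def conserved_residue_columns(alignment: Alignment, residue: str) -> list[int]:
    """1-based columns where every sequence carries exactly *residue*."""
    residue = residue.upper()
    if len(residue) != 1 or residue not in set("ACDEFGHIKLMNPQRSTVWY"):
        raise ValueError(f"residue must be a standard amino acid, got {residue!r}")
    return [
        c
        for c in range(1, alignment.length + 1)
        if set(alignment.column(c)) == {residue}
    ]


def frequency_matrix(
    alignment: Alignment, column_range: tuple[int, int] | None = None
) -> FrequencyMatrix:
    """Residue counts per column over a 1-based inclusive column range."""
    if column_range is None:
        column_range = (1, alignment.length)
    start, end = column_range
    if start < 1 or end > alignment.length or start > end:
        raise ValueError(
            f"column range {column_range} invalid for alignment of length "
            f"{alignment.length}"
        )
    columns = list(range(start, end + 1))
    counts: list[Counter] = []
    info: list[float] = []
    for c in columns:
        col = alignment.column(c)
        cnt = Counter(col)
        counts.append(cnt)
        n_res = sum(v for k, v in cnt.items() if k != GAP)
        if n_res == 0:
            info.append(0.0)
            continue
        h = 0.0
        for k, v in cnt.items():
            if k == GAP:
                continue
            p = v / n_res
            h -= p * math.log2(p)
        info.append(math.log2(20) - h)
    return FrequencyMatrix(
        columns=columns, counts=counts, n_sequences=alignment.n_sequences,
        information=info,
    )
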