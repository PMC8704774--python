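"""Windowed hydropathy profiles, per sequence and aggregated over an alignment.

Each sequence's profile is computed on its ungapped residues with an odd
sliding window (default 21, stepped one residue at a time); the window mean
is assigned to the central residue.  For an alignment, every sequence's
centre values are projected back to the alignment column holding that
residue, and per column the mean and a population standard deviation over
the contributing sequences form the profile and its variability track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio import GAP, Alignment

# Kyte & Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class HydropathyScale:
    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} lacks residues {sorted(missing)}")


SCALES = {"kyte-doolittle": HydropathyScale("kyte-doolittle", KYTE_DOOLITTLE)}


@dataclass
class HydropathyProfile:
    """Mean hydropathy and population-sd variability per alignment column."""

    positions: list[int]
    mean: list[float]
    sd: list[float]
    n: list[int]
    scale: str = "kyte-doolittle"
    window: int = 21

    def table_header(self) -> list[str]:
        return ["column", "mean", "sd", "n"]

    def table_rows(self):
        yield from zip(self.positions, self.mean, self.sd, self.n)


def _check_window(window: int) -> None:
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")


def sequence_hydropathy(
    seq: str, scale: HydropathyScale | None = None, window: int = 21
) -> list[tuple[int, float]]:
    """Windowed mean hydropathy of an ungapped protein sequence.

    Returns ``(1-based centre position, value)`` for every full window;
    raises if the sequence is shorter than the window or carries a residue
    the scale has no value for (e.g. 'X').
    """
    scale = scale or SCALES["kyte-doolittle"]
    _check_window(window)
    seq = seq.upper()
    if len(seq) < window:
        raise ValueError(
            f"sequence length {len(seq)} shorter than window {window}"
        )
    vals = []
    for pos, ch in enumerate(seq, start=1):
        if ch not in scale.values:
            raise ValueError(
                f"residue {ch!r} at position {pos} has no value in scale "
                f"{scale.name!r}"
            )
        vals.append(scale.values[ch])
    half = window // 2
    out: list[tuple[int, float]] = []
    for start in range(0, len(seq) - window + 1):
        out.append((start + half + 1, sum(vals[start:start + window]) / window))
    return out


def alignment_hydropathy(
    alignment: Alignment, scale: HydropathyScale | None = None, window: int = 21
) -> HydropathyProfile:
    """Aggregate per-sequence hydropathy onto alignment columns.

    Windows never span gaps: each sequence is profiled on its ungapped
    residues, then each centre value is placed at the alignment column of
    its centre residue.  Columns with no contributing sequence are omitted.
    """
    scale = scale or SCALES["kyte-doolittle"]
    _check_window(window)
    per_column: dict[int, list[float]] = {}
    any_long_enough = False
    for rec in alignment.records:
        ungapped_cols = [
            c for c, ch in enumerate(rec.residues, start=1) if ch != GAP
        ]
        ungapped = rec.ungapped
        if len(ungapped) < window:
            continue
        any_long_enough = True
        for pos, value in sequence_hydropathy(ungapped, scale, window):
            per_column.setdefault(ungapped_cols[pos - 1], []).append(value)
    if not any_long_enough:
        raise ValueError(
            f"no sequence has >= {window} ungapped residues"
        )
    positions = sorted(per_column)
    mean, sd, n = [], [], []
    for c in positions:
        xs = per_column[c]
        m = sum(xs) / len(xs)
        if min(xs) == max(xs):  # duplicated inputs give sd exactly 0
            m, var = xs[0], 0.0
        else:
            var = sum((x - m) ** 2 for x in xs) / len(xs)  # population form
        mean.append(m)
        sd.append(math.sqrt(var))
        n.append(len(xs))
    return HydropathyProfile(
        positions=positions, mean=mean, sd=sd, n=n,
        scale=scale.name, window=window,
    )
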