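# Methods

This note records the models, conventions and design choices behind
`p74kit`, in the spirit of a package reference manual. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Consensus symbols and the similarity profile

A protein alignment column is reduced to a Clustal-style symbol:

* `*` — every sequence carries the same residue (no gaps);
* `:` — all residues fall within one ClustalW/X *strong* group
  (`STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW`);
* `.` — all residues fall within one *weak* group
  (`CSA, ATV, SAG, STNK, STPA, SGND, SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY`);
* space — otherwise.

Two deliberate conventions: **any gap blanks the column** (Clustal
conservation lines leave gapped columns blank), and **`X` never matches
anything, including another `X`** — an unknown residue cannot attest
conservation. When an alignment file already carries a conservation line
(Clustal `.aln`), that line is attached verbatim and takes precedence over
recomputation in the CLI, accommodating inputs whose consensus was produced
by the original aligner.

The similarity profile scans the symbol string with an odd window
(default 35 residues — the window is applied to the protein consensus)
scoring `* : . ␣` as `+1, +0.5, +0.25, −0.2`; the larger conservative score
goes to the strong class. The window sum is divided by the window length
and assigned to the central column; only full windows are evaluated, so a
consensus of length L yields L−w+1 values at centres ⌈w/2⌉…L−⌊w/2⌋. Scores
are configurable but must satisfy identity ≥ strong ≥ weak > other, and the
window must be odd so that a centre exists.

**Numerical note.** Window values are computed from per-window symbol
counts through exact rational arithmetic (`fractions.Fraction` of the score
floats) and converted to float once. The result is therefore independent of
summation order and reproducible bit-for-bit, which the tests exploit by
comparing against a symbol-by-symbol rational oracle with `==`.

## Hydropathy and its variability track

Per sequence, hydropathy is the mean of Kyte–Doolittle values over a
21-residue window stepped one residue at a time, assigned to the central
residue. The scale is pluggable (`HydropathyScale`); Kyte–Doolittle is the
default because it is the de facto standard for TM-segment inspection, and
the scale name is recorded in output metadata.

Across an alignment, each sequence is profiled **on its ungapped residues**
— windows never span gaps — and each centre value is projected to the
alignment column holding that residue. Per column the profile reports the
mean, the **population** standard deviation (divide by n; the track is
descriptive, not an estimator), and the number of contributing sequences;
columns with no contributor are omitted. When all contributing values are
identical the sd is set to exactly 0 rather than trusting floating-point
cancellation. A single-sequence alignment is accepted as a degenerate case
(mean = the sequence profile, sd = 0, n = 1).

## WDP/BamHI domain engineering

A WDP triad is encoded `TGG GAY CCN`. The tryptophan codon is unique (TGG)
and every proline codon starts `CC`, so the hexamer `GGATCC` spans the last
base of the W codon through the second base of the P codon **iff** the
aspartate codon is `GAT`. For a `GAC` aspartate at codon *k* the single
synonymous edit C→T at ORF nucleotide 3·k creates the site; no other edit
is ever needed, and the P codon is never touched. `apply_synonymous_edits`
asserts translation invariance — by construction the edit cannot change the
protein, and the assertion guards the implementation, not the biology.

The split point is **immediately after the D codon**: the Nt fragment ends
`…WD` (k residues) and the Ct fragment begins `P…` and keeps the stop
codon. Chimeras are assembled as `[tag] + Nt(donor A) + Ct(donor B)`, with
both donors normalised to the BamHI form first so every junction carries
`GGATCC`; the junction is verified to read WDP and the chimera protein to
equal the concatenation of the donors' fragment proteins. An Nt-only
construct is terminated with `TAA` (the stop choice is arbitrary and
recorded here). A tag CDS is prepended verbatim — it must be in frame and
stop-free — and the donor ATG is retained, mirroring a translational
fusion; the exact tag context of any particular expression vector is the
user's to supply. Restriction scanning covers the three palindromic
enzymes used in this workflow (BamHI `GGATCC`, BglII `AGATCT`, HindIII
`AAGCTT`) on the plus strand, overlaps allowed.

When a protein carries several WDP triads all are reported; the CLI demands
an explicit `--triad-index` in that case rather than guessing.

## CRISPR annotation

Protospacers are matched exactly (20 nt) on both strands with an `NGG` PAM
immediately 3′ on the target strand; the blunt cut is modelled 3 nt 5′ of
the PAM, between protospacer positions 17 and 18 — the standard SpCas9
model. All coordinates are reported 1-based on the plus strand of the CDS;
for minus-strand sites `protospacer_start` is the plus-strand coordinate of
the base pairing the protospacer's 5′ end. `cut_after = n` means the cut
falls between plus-strand positions n and n+1.

NHEJ lesions are user-specified deletions (1-based inclusive) or
insertions (after a position); lesions touching the ATG are refused. The
outcome annotation translates the edited CDS from the ATG to the first
stop and reports:

* **frameshift** — lesion length not divisible by 3;
* **premature stop** — the first stop starts upstream of where the
  wild-type stop would sit after shifting by the net indel length (this
  makes an in-frame single-codon deletion, whose product is one residue
  shorter but terminates at the original stop, correctly *not* premature);
* **novel residues** — the edited product from the first positional
  mismatch with the wild type onward, for display parity with
  chromatogram-style figures.

`classify_edit` maps outcomes to `knockout` (frameshift **and** premature
stop), `silent` (product identical), `nonsense_in_frame`, or
`in_frame_indel`. Limitation: a frameshift that never reaches a stop codon
(possible only in very short toy ORFs) falls into `in_frame_indel` for want
of a better label in this four-way scheme; real ORFs in a shifted frame
encounter a stop within a few dozen codons with near certainty.

## Pairwise statistics

Global alignment is Needleman–Wunsch with affine gaps via
`Bio.Align.PairwiseAligner` (BLOSUM62, open 10, extend 0.5; a gap of length
L costs `open + (L−1)·extend`). The defaults mirror the EMBOSS-needle
convention for comparability. Percent identity is identical aligned pairs
divided by the **full alignment length** (gap columns included in the
denominator) — a stated, reproducible convention. Similarity defaults to
pairs with a positive substitution score; a `group` alternative counts
Clustal strong-group co-membership instead, since published similarity
figures sometimes reflect looser definitions. Rounding to whole numbers
happens only at report time.

`domain_matrix` splits each protein at its **own** unique WDP triad
(Nt = through the D, Ct = from the P) and produces symmetric
complete/Nt/Ct matrices with 100 on the diagonal; sequences lacking exactly
one triad are warned about and excluded. The test suite cross-checks the
aligner against an exhaustive enumeration of all affine-gap global
alignments for short pairs and an independent Gotoh three-state DP — the
aligner is never its own oracle.

## Synthetic data: what it emulates and what it does not

`simulate_family` emulates the structure of a large P74 alignment: a random
template with planted invariant residues (default: six cysteines, the
three Nt disulfide-motif pairs), per-column substitutions drawn per
sequence as strong-group (rate 0.15), weak-group (0.10) or uniform random
(0.15) replacements, and hydrophobic blocks drawn from `{I,L,V,F,A,M}`
(default: three 25-column TM-like blocks in the Ct region, mirroring
TM-1/2/3). The default family is 76 sequences × 645 columns, the size of
the study's alignment and of the AcMNPV protein. All draws come from one
integer seed; every mutation is recorded, so tests can distinguish planted
conservation from columns the generator happened to leave untouched.

Families are generated **gap-free** so that planted truth stays exact; gap
behaviour is exercised with hand-built fixtures instead. No tree-structured
evolution, indels or codon-usage bias are simulated — passing tests
demonstrate correctness of the profiling/recovery machinery on alignments
with known truth, not performance on real, phylogenetically structured
data.

`simulate_orf` reverse-translates a protein with uniform synonymous codon
choice, forcing planted WDP codons (W = TGG; D = GAT/GAC as requested; P
uniform over CCN). `wdp_positions` anchors the **aspartate** codon, so a
GAC triad at codon k implies the edit at nucleotide 3k. Protospacers are
inserted at codon boundaries as a 24-nt cassette (protospacer + NGG PAM +
1-nt pad) to preserve the reading frame; the PAM's N and the pad are chosen
to avoid in-frame stops, a protospacer carrying an unavoidable in-frame
stop is rejected, and generation is retried (bounded) if the planted
protospacer is not uniquely recoverable from the final CDS.

The acceptance script builds its CRISPR context differently — the
published crRNA is placed mid-codon so that the predicted cut falls exactly
at ORF nucleotide 207, by overwriting a 23-nt window and resampling any
codon left encoding a stop — because the codon-boundary cassette cannot hit
an arbitrary nucleotide offset.

## Problem sizes and determinism

Default test and acceptance problem sizes (76×645 families, 645-codon
ORFs, ≤8-residue enumeration oracles, 100-lesion sweeps, 10-seed recovery
checks) were chosen so the whole suite runs in seconds on one core while
still exercising every code path at the study's stated dimensions. All
stochastic components take explicit integer seeds; CLI outputs embed no
timestamps, so identical inputs and flags give byte-identical data files
(run metadata lives in `.meta.json` sidecars).

## Known limitations

* Alignment computation itself is out of scope: users supply the MSA
  (any standard protein aligner's output is accepted).
* Identity/similarity depend on alignment parameters and denominator
  conventions; figures published without those details can differ by
  several points from any fixed convention, including ours.
* Restriction scanning is plus-strand/palindromic only (sufficient for
  BamHI/BglII/HindIII).
* Off-target search, microhomology-based repair prediction and guide
  efficiency scoring are out of scope; lesions are user-specified.
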