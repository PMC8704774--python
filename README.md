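# p74kit

Sequence-engineering toolkit for baculovirus **P74 (PIF0)** and related
protein families. P74 is an essential *per os* infectivity factor anchored
in the occlusion-derived virion envelope; its amino-terminal region carries
the host-specific midgut-binding function while the carboxyl-terminal
region holds the transmembrane anchors. A conserved tryptophan–aspartate–
proline (WDP) triad sits at the Nt/Ct boundary, and its codons
(`TGG GAY CCN`) either contain a BamHI site (`GGATCC`) or accept one via a
single synonymous point mutation — which makes the boundary a natural,
protein-neutral restriction junction for domain swapping between species.

`p74kit` implements the in-silico side of such a domain-swap programme:

| module | what it does |
| --- | --- |
| `p74kit.seqio` | validated FASTA/Clustal I/O (consensus line preserved), TSV profile output |
| `p74kit.consensus` | Clustal-style consensus symbols (`* : . ␣`), windowed similarity profile, invariant-residue detection, position frequency matrices |
| `p74kit.hydropathy` | Kyte–Doolittle windowed hydropathy averaged across an alignment, with a standard-deviation variability track |
| `p74kit.chimera` | WDP triad location, synonymous BamHI engineering, Nt/Ct ORF splitting, in-frame chimera assembly, restriction scanning |
| `p74kit.crispr` | SpCas9 protospacer/PAM localisation, blunt-cut prediction, NHEJ indel consequence annotation (frameshift / premature stop / knockout) |
| `p74kit.pairwise` | Needleman–Wunsch (affine gaps, BLOSUM62) percent identity/similarity for complete proteins and their Nt/Ct domains |
| `p74kit.simulate` | synthetic families and ORFs with planted, auditable ground truth |

## The core quantities

For a consensus line `s₁…s_L` and an odd window `w` (default 35), the
similarity profile assigns to each full-window centre `c` the value

```
S(c) = (1/w) · Σ score(s_i),  i = c−⌊w/2⌋ … c+⌊w/2⌋
score: '*' → +1,  ':' → +0.5,  '.' → +0.25,  ' ' → −0.2
```

Hydropathy uses a 21-residue window of Kyte–Doolittle values per sequence
(computed on ungapped residues, projected back to alignment columns), and
reports per column the mean over sequences and the population standard
deviation as a variability track.

For a WDP triad with the aspartate at codon *k*, the BamHI edit (when the
codon is GAC) is the single synonymous substitution C→T at ORF nucleotide
3*k*; the split after codon *k* yields an Nt fragment ending `…WD` and a Ct
fragment starting `P…`. The SpCas9 blunt cut is modelled 3 nt 5′ of the NGG
PAM (between protospacer positions 17/18); an NHEJ lesion whose length is
not a multiple of 3 shifts the reading frame, and a first stop codon
upstream of the (shifted) wild-type stop marks a premature stop — the two
together classify the allele as a knockout.

## Worked example

```bash
python examples/design_chimeras.py
```

prints (deterministic):

```
donorA: WDP at codons 457-459, BamHI present: False, required edits: [(1374, 'C', 'T')]
split after codon 458: Nt 458 aa (ends ...WD), Ct 187 aa (starts P...)
chimera donorA-donorB: 645 aa, BamHI junction at nt 1371
```

— a 645-aa donor whose GAC aspartate at codon 458 needs the single
synonymous edit at nucleotide 1374 (= 3·458) to create the BamHI site; the
split partitions the protein into 458 + 187 residues, and the assembled
cross-species chimera carries `GGATCC` across the in-frame junction. The
other scripts in `examples/` cover conservation profiling, hydropathy
variability, knockout annotation and domain identity matrices the same way.

There is also a thin CLI (`p74kit profile|hydropathy|split|chimera|knockout|pairstats|simulate`);
every output gets a `.meta.json` sidecar with version, parameters and input
checksums, and identical inputs and flags produce byte-identical data files.

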