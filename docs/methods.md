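# Methods

`mitoscreen` re-implements, as a tested library and CLI, a cross-species
screen for human disease-associated variants of the seven mtDNA-encoded
NADH dehydrogenase (complex I) subunits (ND1–ND6, ND4L).  The question the
screen asks is simple: when a nucleotide change that is pathogenic in humans
is found fixed in another vertebrate lineage, does that lineage's own codon
context reproduce the human amino-acid change — or does additional sequence
variation *mask* it?  Masking variation is one line of evidence that the
penetrance of an mtDNA variant can depend on its haplogroup/sequence
context rather than being a property of the variant alone.

## Coordinate model

All positions are 1-based rCRS (NC_012920.1) coordinates, matching clinical
`m.NNNN` notation.  The default gene map is the standard rCRS annotation
(ND1 3307–4262, ND2 4470–5511, ND3 10059–10404, ND4L 10470–10766, ND4
10760–12137, ND5 12337–14148, ND6 14149–14673) and ships as data
(`data/gene_map.tsv`), not code, so alternative annotations can be swapped
in.  Two features need care:

- **ND4L/ND4 overlap** (10760–10766): a position there is evaluated once per
  containing gene, each in that gene's reading frame, because the frames
  differ.
- **ND6 is light-strand**: its coding frame runs from the gene *end*
  downward, and codons are read off the reverse complement.  Variant
  alleles, which are stated on the heavy strand in m.-notation, are
  complemented onto the coding strand before translation.
- **Incomplete terminal codons** (ND1, ND2, ND3, ND4 end in 1–2 bases whose
  stop codon is completed by mRNA polyadenylation) are flagged in the map
  and excluded from codon addressing rather than auto-completed; silently
  inventing the missing bases invites wrong translations, and no variant of
  interest falls there.

Translation uses the vertebrate mitochondrial code (NCBI table 2: ATA=Met,
TGA=Trp, AGA/AGG=stop), built from Biopython's codon tables and applied
uniformly to all species; the `GeneticCode` type is pluggable per species
set should a non-vertebrate table ever be needed.

## Reference sequences

The packaged reference gene FASTA
(`data/rcrs_like_genes.synthetic.fasta`) is a **synthetic** rCRS-like
stand-in, not the NCBI record: it is generated on a single contiguous
coordinate backbone (so the ND4L/ND4 overlap is consistent between the two
records) with the codons that the worked examples depend on pinned to their
true rCRS values — ND1 codons 1–3 (ATA CCC ATG, giving the m.3308T>C M→T
change and the alternative initiation codon at position 3), ND1 codons 300
and 309 (the m.4205/m.4232 marker codons), ND3 codon 45 (TCC, the m.10191
serine codon), and ND6 coding codons 1 and 63 (ATG and ATA; the latter is
the m.14487 methionine codon spanning rCRS 14485–14487 on the light
strand).  Every computation the package reports on this fixture is exact at
those codons; users analysing real data should supply the genuine
NC_012920.1 gene sequences via `--reference`.

## Alignment and homology

The original workflow aligned each species file (with the rCRS gene row
inserted) in Clustal Omega and read variant positions off the alignment.
This package accepts such pre-aligned gapped FASTA directly, anchoring all
coordinate lifting on the embedded rCRS row: the alignment column of rCRS
position *p* is the column holding the (*p* − start + 1)-th non-gap
character of that row.  For unaligned input, each sequence is instead
anchored to the reference gene by an internal global pairwise
Needleman–Wunsch alignment — downstream analysis needs only rCRS↔sequence
homology, which pairwise anchoring provides deterministically, so no
attempt is made to reproduce a multiple-alignment program's exact columns.

Aligner choices (all configurable): match +1, mismatch −1, linear gap −2;
N/IUPAC ambiguity scores 0 against anything; traceback ties break
diagonal > gap-in-query > gap-in-reference.  Simple integer scores keep the
exhaustive-enumeration test oracle exact, and the fixed tie order makes
column maps reproducible.  The implementation is validated against full
enumeration of all global alignments for short pairs and against
Biopython's `PairwiseAligner` scores on longer random pairs.

Consensus sequences (used to summarise a species' alignment) are
majority-rule per column; a gap wins only where every row is gapped, and
ties resolve alphabetically by default or to the IUPAC code of the tied
bases on request.

## Calling, conservation and codon context

For each variant, every non-reference sequence is called at the homologous
site: carrier (base equals the alternate allele), non-carrier, or missing
(gap or ambiguity code).  **All percentages are over analysable (non-missing)
sequences, with missing counts reported separately** — the source data's
"present in 100% of sequences" statements do not state gap handling, and
explicit missingness keeps the fractions interpretable.  A base that is
neither reference nor alternate counts as a non-carrier but still lowers the
nucleotide conservation index.  Conservation is reported two ways:
nucleotide CI (% of analysable sequences retaining the rCRS base) and
amino-acid CI (% whose own codon, translated in the gene frame, retains the
human reference residue); untranslatable codons are missing for the
amino-acid index only.  Variants synonymous in the human reference context
are excluded before the codon-context and scoring stages, mirroring the
original screen.

Codon-context resolution extracts each species' observed coding-strand
codon at the variant's codon address and translates it twice — once with the
human reference base forced into the variant slot, once with the alternate:

- `IDENTICAL`: no within-codon co-variation (which implies the species
  reproduces the human amino-acid change exactly);
- `ALTERED_SUBSTITUTION`: co-variation changes the resulting substitution
  (the fish patterns: human S→P reading S→L, human M→V reading M→G);
- `SYNONYMOUS_IN_CONTEXT`: in this codon background the variant no longer
  changes the amino acid;
- `UNTRANSLATABLE`: a codon slot is gapped or ambiguous — never silently
  defaulted.

A degenerate case exists where a co-varying codon happens to reproduce the
human amino-acid pair; this package classifies it `ALTERED_SUBSTITUTION`
(reserving `IDENTICAL` for codon-identical contexts) so that
`IDENTICAL` always implies base-level identity at the non-variant slots.
When a species has several disagreeing sequences, the species-level call is
the majority codon (lexicographic tie-break) with a reported discordance
count.

Masking-candidate screening partitions sequences into carriers and
non-carriers and reports alleles perfectly concordant with carriage —
present in **all** analysable carriers and **no** analysable non-carrier
under the default strict rule, with configurable tolerance fractions.  The
source criterion ("present only in the sequences containing the variant")
is qualitative; strictness is the conservative reading.  The default scope
is gene-wide, because the motivating marker (an L0d haplogroup allele ~900
bases from its variant) lies outside the codon; within-codon co-variation
is additionally always reported by the resolver.  How far a masking variant
may lie from its variant is not defined in the source; gene-wide is an
interpretation and is flagged as such here.  The classification is purely
sequence-combinatorial — no biophysical claim is attached.

## Pathogenicity rubric

Tier assignment (Neutral/polymorphic, Possibly, Probably, Definitely
pathogenic) is a config-driven weighted-evidence sum.  The original study
applied a published clinical scoring algorithm whose point values are not
restated in a form this package can cite, so the shipped default
(`data/default_rubric.yaml`) is a documented reconstruction: conservation
(2+2 points), database rarity (3), two predictor scores (2+2), four
disease-report flags (2 each), maximum 19, with tier cuts at 6/11/16.
Every constant lives in the YAML; `validate_rubric` checks bins are
disjoint and exhaustive over each criterion's declared domain and that the
cuts increase strictly.  External predictor scores and database frequencies
are always user-supplied inputs, never recomputed — the services that
produce them are outside this package's scope.  Missing optional evidence
falls into an explicit `unknown` bin.  Because points are non-negative and
binned monotonically, strengthening any single line of evidence can never
lower the tier (property-tested).

## Synthetic data generator

The generator emulates the study's data model — multiple species, several
sequences per species, an embedded human reference row per gene — under a
star phylogeny: each species ancestor is drawn independently from the root
gene with per-site substitution probability *p*, and sequences within a
species diverge from their ancestor at rate *q*; given a substitution, a
transition is chosen with probability κ/(κ+2).  Defaults are 10 species ×
3 sequences, *p* = 0.02, *q* = 0.005, κ = 2 — divergence small enough that
homologous sites stay recoverable, as in the real compiled collections of
congeneric sequences.  A planted variant is forced into all carrier-species
sequences after background mutation; an optional within-codon co-variant is
forced into a stated fraction of carriers and no non-carriers.  Single-base
indels (off by default) never fall inside the planted codon, keeping the
planted truth unambiguous while still exercising gap-aware mapping.  Every
run emits a truth table (per-sequence carrier/co-mask status, full
substitution and indel logs, star tree of record) from which each emitted
sequence can be replayed exactly — a tested invariant.

What the generator does **not** model: tree-structured phylogeny, selection,
rate heterogeneity across sites, heteroplasmy, recombination, and real
alignment ambiguity in repetitive regions.  Passing recovery tests on this
generator therefore demonstrates the pipeline's bookkeeping (coordinate
lifting, partitioning, concordance logic) is correct, not that the screen is
robust to every artefact of real multi-species alignments.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale by design: genes of a few
hundred to ~1.8 kb bases, 7–30 sequences per set, 25–50 generator seeds per
stochastic check, 300–500 random pairs against the exhaustive alignment
oracle (length ≤ 6, where enumeration is exact).  The headline counts of
the motivating study (152 candidate variants → 87 present in other species
→ 76 scored → 3/19/26/28 per tier) depend on a dated MitoMap snapshot, a
2752-sequence compiled collection and external predictor services, and are
therefore not recomputed here; the pipeline supports reproducing them by
supplying those inputs (`--sequences` per gene, `--evidence`).

Other fixed choices: carrier fractions and conservation indices are exact
rational arithmetic in floating point (no rounding is applied before
serialisation; reports serialise numbers via JSON `repr` so TSV and JSON
agree bit-for-bit and reports round-trip to equality); report rows are
ordered by gene then position; all randomness flows through a single
`numpy` `default_rng` seed; species labels default to the two
whitespace-separated tokens after the FASTA accession, and the reference
row is recognised by the substring `NC_012920` (both configurable, since
real per-species files follow no single header convention).

## Known limitations

- The rubric constants are a reconstruction; tier outputs are only as
  meaningful as the config supplied.
- Pairwise anchoring can differ from a joint multiple alignment near long
  indels; for published alignments, supply the aligned FASTA and the
  embedded reference row is used verbatim.
- The packaged reference FASTA is synthetic outside the pinned codons (see
  above); real analyses must supply NC_012920.1-derived gene sequences.
- Heteroplasmy is not modelled; sequences are haploid strings.
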