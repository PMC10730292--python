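# Methods

## The model

Vertebrate mtDNA replicates asymmetrically: the heavy-strand origin, inside
the Control Region (CR), leaves one strand single-stranded for longer during
replication, exposing it to a characteristic deamination-driven mutation
spectrum. At sites where selection is weakest — third positions of
fourfold-degenerate codons — this imprints a compositional signature that
depends only on which strand a gene is encoded on *relative to the CR*.
`mitoskew` operationalizes that claim: a gene co-oriented with the CR is
expected to show AT skew < 0 and GC skew > 0 on its coding strand, a
counter-oriented gene the mirrored signs, with no gene special-cased (the
minority-strand nad6 receives its expectation from its strand like any
other gene).

Two corollaries drive the genome-level classification. If the CR inverts
and composition has had time to re-equilibrate, every gene again matches its
CR-relative expectation but the CR now points against the majority coding
strand: the **reversed** state. If the architecture has changed recently,
composition still reflects the *previous* layout and genes mismatch their
current expectation — uniformly (a bare CR flip) or partially (when some
genes inverted together with the CR and therefore kept their relative
polarity): the **disrupted**, transitory state. These two outcomes are
distinguished deliberately: per-gene states measure equilibrium with the
*current* CR, while the standard/reversed split at genome level is carried
by the CR's orientation against the majority strand, which is invariant to
which strand a record happens to be deposited on.

## The fourfold-site statistic

Under the vertebrate mitochondrial code (translation table 2) exactly eight
codon families are fourfold degenerate: GCN, CCN, TCN, ACN, CGN, GGN, CTN,
GTN. A codon is retained iff its first two bases match a family exactly and
its third is an unambiguous A/C/G/T; any ambiguity code anywhere in the
codon excludes it, because family membership must be certain. Start codons
are not excluded (a GTG start is a valine-family codon like any other), and
no table-2 stop codon can match a family prefix — both facts are pinned by
tests. Zero denominators leave a skew *undefined* rather than zero, since 0
is a meaningful value (perfect balance). Skews are computed on each gene's
annotated coding strand.

A note on antisymmetry: re-reading a CDS's reverse complement codon-wise
does **not** mirror the retained site set (third positions on one strand
face first positions on the other), so no codon-level sign-flip identity
exists. The invariant that does hold — and that the classifier relies on —
is site-level: reading the retained third-position sites on the
complementary strand negates both skews exactly. The test suite asserts the
site-level form.

For unannotated single-gene records the reading frame is inferred by
minimizing internal stop codons under table 2 across the three frames
(ties: most fourfold codons, then lowest frame); a best frame with ≥ 1 stop
per 100 codons in every frame is flagged low-confidence rather than
suppressed.

## CSB-II and control-region polarity

CSB-II is detected with a deterministic consensus scan rather than de novo
motif discovery, for reproducibility without external binaries. The pattern
`C{min_c5,}TAC{min_c3,}` is matched maximally on both strands; defaults
`min_c5 = 5`, `min_c3 = 4` allow one cytosine of slack against the typical
6/5 flanks. Non-coding regions are the complement of gene features on the
circle (annotated CR/D-loop features do not mask their interval and are
scanned first); intervals shorter than 200 bp are ignored as spacers, and a
region wrapping the origin is scanned as one contiguous sequence. Best hit:
longest match, then longest host region, then smallest start. No hit leaves
the polarity `undetermined` — a real outcome for deposited records lacking a
recognisable CSB-II. CSB-III, being weakly conserved and often absent in
fish, is only available as an optional secondary pattern.

## Gene-order events

The observed architecture is reduced to a signed circular permutation of
canonical labels (CR included as a non-gene entry, so a CR inversion is
itself reportable), canonically rotated to cox1 on its template strand.
Deviations from the standard 37-gene template are decomposed greedily, not
by a minimal rearrangement-distance model: copy-number differences become
duplication/loss events; maximal contiguous runs of strand-flipped genes
become one inversion each; remaining displaced genes are those left out of a
maximal common circular backbone (best linear LCS over rotations), with a
move of ≤ k backbone slots (default k = 2, configurable) typed as a shuffle
— listing the hopped genes, so an adjacent swap names both partners — and
anything farther as a translocation. Compound overlapping histories are
reported best-effort.

## The simulator

The generator emulates exactly the statistical structure the analysis
measures, nothing more. Protein-coding genes are built codon-wise: with
probability 0.5 (arbitrary, configurable; only realized site counts matter
for power) a fourfold-family codon whose third base is drawn from
P(A) = f(1+a)/2, P(T) = f(1−a)/2, P(G) = (1−f)(1+g)/2, P(C) = (1−f)(1−g)/2,
where f is the AT content at fourfold sites (default 0.6) and (a, g) are the
target skews; otherwise a codon from a fixed non-fourfold, stop-free set
with a uniform third position, so only fourfold sites carry signal. Default
targets are a = −0.35, g = +0.35 for CR-co-oriented genes (negated
otherwise), magnitudes typical of the clearly signed fourfold-site skews
reported for fish mitogenomes; genes are 200 codons (ATG start, TAA stop, no
internal stops by construction), tRNAs 70 bp, rRNAs 950/1600 bp, the CR
900 bp of uniform background with the reference CSB-II embedded mid-CR in
the chosen orientation, and 25 bp spacers between features.

Composition and architecture are independently controllable: edits
(inversion, translocation, shuffle, duplication) move sequence without
rewriting it, and the `equilibrated` switch decides whether compositional
targets anticipate the post-edit strands (a re-equilibrated genome) or stay
at the pre-edit standard regime (the transitory state). Everything is
deterministic given the seed.

What the simulator does **not** emulate: long repeat regions and assembly
artefacts around the CR, pseudogene fragments, indels, realistic tRNA/rRNA
sequence, codon-usage structure beyond the third-position model, or
mutation accumulation over generations. Passing tests therefore demonstrate
the correctness and statistical calibration of the *analysis* under the
stated compositional model — not robustness to annotation error or
assembly noise in real records.

## Classifier thresholds

* `tau = 0.05` — minimum |skew| on at least one axis for a signed per-gene
  call (dimensionless). Comparative studies read signs qualitatively; tau
  guards against calling noise. Raising tau can only demote calls to
  ambiguous (monotonicity is tested), never flip them.
* `n_min = 10` — minimum fourfold codons per gene; below this the binomial
  error makes signs uninformative.
* `quorum = 0.8` — fraction of skew-yielding PCGs that must be classifiable
  for a genome-level call. Below quorum the genome is `undetermined`, unless
  most genes are ambiguous *despite* adequate site counts and defined skews,
  which is read as the attenuated flavour of `disrupted`.

Duplicated PCGs contribute their longest copy. Genes whose two axes
disagree (one matching expectation, one its negation) are ambiguous rather
than forced into either state. With the simulator's default effect sizes the
classifier recovers ground truth essentially always; the residual failures
at weak effect sizes are conservative (toward disrupted/undetermined), never
a standard↔reversed confusion — also pinned by tests.

## Numerical and format conventions

Coordinates are 0-based half-open on the stored forward strand; GenBank I/O
converts from/to 1-based inclusive, and features joined across the circular
origin collapse to a single `wraps_origin` entry so gene-order signatures
stay one-entry-per-gene. Leucine/serine tRNA paralogs are numbered by order
of appearance in the standard arrangement (L1 = Leu(UUR), L2 = Leu(CUN),
S1 = Ser(UCN), S2 = Ser(AGY)); anticodon annotations take precedence on
ingest, then template-neighbour position, then order of appearance. Note
this is the reverse of the MITOS trnL1/trnL2 numbering. Ambiguous IUPAC
bases are preserved in sequence but treated as ambiguity by codon logic.
The standard template ships as a versioned TSV data file, not hard-coded
constants. GenBank output pins the record date so identical genomes emit
identical bytes.

## Problem sizes

The test suite and the acceptance script use simulated genomes of ~13.7 kb
(200-codon PCGs); statistical properties are measured at 500 replicate genes
(3-SE recovery), 200 random single edits (event typing), and 100 random
architectures/polarities (end-to-end classification) — sizes at which the
binomial error model makes the stated bounds meaningful while the whole
suite runs in seconds.

## Known limitations

* Event decomposition is heuristic; overlapping or repeated rearrangements
  on the same region may be reported as compound patterns rather than a
  minimal history.
* Pseudogene fragments are invisible without homology search; duplications
  rely on the annotation.
* The CSB-II consensus scan trades sensitivity for determinism; a strongly
  diverged motif (or a record genuinely lacking one) yields `undetermined`,
  which is reported rather than guessed.
* The COI screening mode inherits the single-gene statistics' power limits:
  ~100 fourfold sites put sign calls near tau only for weakly skewed
  genomes.
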