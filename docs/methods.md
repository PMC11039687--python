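# Methods

This note documents the models, algorithms and numerical choices behind
`edcscan`, and what the synthetic test bed does and does not establish
about behavior on real genome assemblies.

## The problem

EDC-like gene clusters are hard for generic annotation pipelines for three
reasons: the proteins are short and compositionally extreme (two residues
can account for half of a trichohyalin-like protein), so low-complexity
filters silently discard the true hits; the clusters contain tandem arrays
of near-identical paralogs, so best-hit logic alone cannot separate copies;
and the biologically interesting signal is often a *broken* gene — a
premature stop, a frameshift, a lost splice site — which most annotators
either "repair" or skip. The pipeline is built around those three
difficulties.

## Translated search

The genome is translated in all six frames (frames 0–2 per strand; minus-
strand features are always reported in forward-scaffold coordinates).
Exact-match 4-mer seeds from the query are looked up in a word index over
the translations, extended ungapped under an X-drop rule, and refined by
local dynamic programming (Biopython `PairwiseAligner`) in a ±15-residue
window. Defaults: BLOSUM62, gap open 11 / extend 1 (a gap of length *k*
costs 11 + *k*), X-drop 16, minimum raw score 40. No E-value statistics
are computed: within a cluster of known anchors, raw score plus identity
is sufficient, and every reported score is exactly recomputable from the
reported alignment strings (`score_alignment`).

Two guards deal with composition bias, which makes score-based stopping
rules unreliable:

* **end trimming** — biased queries extend net-positively through introns
  and off-frame repeat readings, so HSP ends are trimmed back while the
  terminal 15-column identity is below 60%;
* **identity floor** — HSPs below 45% identity are dropped *before*
  same-frame overlap suppression, so a low-identity over-extension can
  never shadow a genuine HSP. Orthologous exons at the divergences this
  tool targets sit far above the floor.

The low-complexity query filter masks residues inside any window of 12
whose Shannon entropy is below 2.2 bits. Masked residues are excluded from
seeding only, never from extension, and the filter is **off by default in
the pipeline**: biased epidermal proteins are exactly the queries such
filters eliminate. The off switch is itself under test (a poly-QP query is
found only with masking disabled).

## Chaining and locus assignment

One query's HSPs are grouped per scaffold and strand and chained by
dynamic programming: a chain must advance strictly in query coordinates
(overlap up to 40 residues tolerated — extension overshoot across an indel
— but no restarts or containments, which are the signature of paralog
copies), genomic gaps must not exceed a configurable intron bound
(10 kbp), with a small per-bp gap cost (0.01/bp) and up to 150 bp of
genomic overlap allowed between consecutive HSPs. A join across a gap is
refused when the gap itself contains a substantial HSP of the same query
re-aligning query content the chain already covers: that "intron" is a
tandem-paralog copy, not an intron. This rule is what keeps near-identical
array copies from being merged into one mega-locus.

Loci then claim genomic regions greedily by score. Two true genes never
share more than a few bp here, so any overlap above 30 bp marks a weaker
cross-hit. A region held by a locus whose template has no DNA-level
support (see below) can be re-claimed by the next-best overlapping locus;
this resolves the rare case where a close paralog's query outscores the
true ortholog's query at the protein level by a point or two.

## Gene models and architecture

Gene models are rebuilt against an `ExonTemplate` — the coding exon
structure, protein segments and coding DNA of an intact ortholog. Each
template exon is located inside the padded locus by edlib infix alignment
(accepted up to 20% edit distance), then re-aligned globally with a
substitution-friendly DNA scorer (match +1, mismatch −2, gap −7/−2, free
end gaps on the genomic window). Two details matter:

* unit-cost (edit-distance) alignment renders a fully substituted codon as
  a 1-bp deletion plus a 1-bp insertion; the re-scoring makes mismatches
  cheaper than paired indels, so codon substitutions are reported as
  substitutions;
* free end gaps on the genomic side keep terminal mismatched bases inside
  the exon instead of letting the infix alignment clip them, which would
  otherwise fabricate a 1-bp frameshift at the boundary.

Boundaries missing their GT/AG are refined to the nearest frame-preserving
(step-3) candidate within ±30 bp; any shift or failure is flagged, because
the alignment-derived boundary was near-exact to begin with. Non-coding
first exons are never predicted from sequence (no promoter model); the
analysis depends only on coding structure, and their absence is flagged.

Architecture: one coding exon → SEDC; two coding exons whose translated
N-terminus scores at least 60% of the S100-domain consensus self-score
(local BLOSUM62 alignment against a packaged synthetic ~90-residue
consensus — invented for this test bed, not a copy of a real S100
protein) → SFTP; anything else → other. A locus whose template aligns
nowhere at the DNA level (< 5% of template bases) is reported as
`unresolved` — a protein-level cross-hit without coding-sequence support —
and excluded from family counts rather than asserted as a gene.

## Lesion detection and status

Per located exon, the template/genome alignment is walked column by
column:

* in-frame stop codons before the template's final codon → `premature_stop`
  with the template codon index; stops are only called where the running
  indel offset is 0 mod 3, so stops that merely appear downstream of a
  frameshift are treated as consequences, not independent lesions;
* indel runs of length ≢ 0 mod 3 → `frameshift`; coordinates are
  left-normalised on the forward strand (VCF convention) so simulator
  truth and detector output are comparable base-for-base, including on
  minus-strand genes (deleted bases are locally re-inserted from the
  template before normalising);
* damaged acceptor AG / donor GT flanking a located exon → `splice_loss`
  (every coding exon has an upstream acceptor because a non-coding first
  exon precedes the CDS);
* unalignable template exon → `missing_exon`; lost initial ATG →
  `start_loss`.

Lesions within 6 bp of an exon boundary are annotated `boundary-uncertain`
— splice refinement can shift the local frame there, and sequencing or
assembly error cannot be excluded at such sites.

Status: no lesions → `intact`; lesions consisting solely of premature
stops, with an intact start and the first stop at ≥ 20% of template length
→ `truncated`; any other combination → `pseudogene`. A gene carrying both
a premature stop and a frameshift is a pseudogene even when the stop sits
late — the reading frame as a whole is lost. The 20% threshold is exposed
in configuration; the truncated/pseudogene boundary is a convention, not a
measurement.

`measure_orf_runway` counts complete codons from a position to the next
in-frame stop — the statistic used to argue that a premature stop is
evolutionarily recent (a long stop-free runway downstream is unexpected
under neutral decay, where stops accrue at ~3/64 per codon).

## Orthology

A query gene and target locus are called `ortholog` only when they are
reciprocal best hits (local BLOSUM62 alignment scores; ties disqualify)
*and* the fraction of shared flanking gene families (3 genes per side,
order-insensitive) reaches 0.5. Tandem-array members typically fail RBH
through ties or cross-matches between near-identical copies and are
reported `ambiguous` with their synteny support — deliberately so, since
exact copy-to-copy orthology inside an array amplified after speciation is
not a well-posed question. Family identity uses name prefixes for
synthetic data and greedy 50%-identity clustering (`infer_families`) for
unlabeled sets.

## Phylogenetics

Gene-family trees use p-distances (pairwise deletion of gapped sites) and
Saitou–Nei neighbor joining (scikit-bio's implementation), with negative
branch lengths clamped to zero and flagged. Bootstrap supports come from
resampling alignment columns with replacement and counting bipartitions.
Monophyly of a label set against an outgroup is tested as the existence of
a branch bipartitioning the leaves into exactly that set versus the rest.
Alignments for tree input come from a star-progressive aligner (pairwise
global alignments merged around the sequence with the highest summed
score, "once a gap always a gap"); an externally computed alignment can be
supplied instead. Maximum-likelihood inference is deliberately out of
scope: at within-array divergences of a few percent against outgroups at
~30%, distance/NJ answers the monophyly question robustly, which the
additive-matrix recovery and bootstrap tests demonstrate.

## The synthetic test bed

`synthetic_edc.generate_cluster` builds a scaffold holding, in order: a
left S100-like anchor, single-coding-exon (SEDC-like) genes, two-coding-
exon (SFTP-like) genes, a tandem LCE-like array, and a right anchor. All
genes have a non-coding first exon, canonical GT..AG introns, and coding
exon lengths that are multiples of three (codons never span introns — a
simplification that makes truth bookkeeping exact). Key defaults, chosen
once as the study conditions for all tests:

| parameter | default | meaning |
|---|---|---|
| `n_sedc`, `n_sftp`, `lce_array_size` | 5, 2, 10 | gene counts per family |
| `lce_divergence` | 0.02 /site | substitution rate per duplication event |
| `lesion_rate` | 0.0 | per-gene probability of one implanted lesion |
| `intergenic_mean` | 800 bp | geometric spacer length (min 50) |
| intron length | geometric, mean 400 bp (min 80) | |
| SFTP tail | 9–21-codon unit × 8–15 copies, 5% per-copy substitution | biased to a rotating two-residue alphabet (R/E, G/S, Q/K, P/T) |
| tail bias | 0.8 | combined fraction of the two biased residues, exact by construction |
| species divergence (`generate_species_pair`) | 0.05 /site/species | substitutions on shared founder genes |

Substitutions applied to coding sequence are conditioned never to create
an in-frame stop, destroy the start codon, or damage splice dinucleotides,
so `intact` truth labels are guaranteed. The SFTP tail body is rebalanced
to the configured bias exactly (a single short random unit would otherwise
set the whole tail's realized composition with high variance); the
C-terminal motif appended to every intact SFTP tail is a synthetic
placeholder sequence — the conserved motif's true sequence is a
configuration input for real analyses, not something this package invents.

Tandem arrays grow by iterated duplication of a uniformly chosen existing
copy (the copy-number mechanism of unequal crossing over), each new copy
receiving per-site substitutions; the recorded genealogy counts
duplication events as branch lengths and is therefore ultrametric, with
the array monophyletic relative to supplied outgroups by construction.

Implanted lesions are drawn from {premature stop, 1–2 bp insertion, 1–2 bp
deletion, splice-site loss}, at most one per gene, placed ≥ 9 bp from exon
boundaries and away from CDS termini. Exon deletion is supported by
`implant_lesion` (and tested) but excluded from the random menu: a deleted
exon has no alignment-recoverable point coordinate, so "exact coordinate
recovery" is not a well-defined target for it. Indel truth coordinates are
left-normalised with the same convention the detector uses.

### What passing tests do and do not show

The generator's intergenic DNA and introns are i.i.d. uniform random
sequence: there are no transposable elements, no GC heterogeneity, no
assembly gaps, no sequencing error, and codon usage is uniform over
synonyms. Perfect lesion recovery on this test bed therefore demonstrates
the correctness of the *logic* (coordinate arithmetic, strand handling,
alignment interpretation, classification rules), not robustness to real
assembly artifacts — on real data, the `boundary-uncertain` annotations,
`unresolved` loci and splice flags are the places where that uncertainty
surfaces and must be reviewed. Lesion scans in the benchmark use
same-species intact templates (the truth proteins), emulating the
availability of an intact ortholog from a close relative; at larger
template divergences indel normalisation can shift by a base or two in
repetitive contexts.

## Benchmark problem sizes

The shipped tests and `scripts/acceptance.py` use: a 30-gene two-species
null run (architecture and status agreement, zero lesions), a 50-gene
single-species cluster at lesion rate 0.3 (lesion recovery with exact kind
and coordinate, false positives on intact genes), ten 16-gene clusters at
rate 0.4 (status agreement), 100 random additive matrices with 5–8 leaves
(NJ topology recovery), an 8-copy array at 2% divergence against three
30% outgroups with 100 bootstrap replicates (monophyly and support), and a
10 kbp random sequence scanned at every position (ORF runway vs brute
force). These sizes keep the whole benchmark under a minute while giving
counting statistics (≈ 50–230 events per quantity) that make silent logic
errors visible.

## Known limitations

* No E-value model; score/identity thresholds are tuned for intra-cluster
  annotation, not genome-wide search.
* Ab initio prediction is out of scope: a gene family absent from the
  query/template set is invisible.
* The truncated-vs-pseudogene boundary (20% rule) is a labeling
  convention; borderline biological cases need human judgment.
* Orthology inside tandem arrays is reported `ambiguous` by design.
* Selection analyses (dN/dS, relaxation) and pseudogene dating are not
  implemented.
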