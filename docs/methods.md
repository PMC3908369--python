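# Methods

This note documents the models, conventions and defaults behind each stage
of the pipeline, the design choices that were genuinely open, and what the
synthetic data do and do not establish.

## Sequence core and coordinate conventions

Internally all coordinates are 0-based half-open on the forward strand.
Gene-table coordinates (1-based inclusive, `start > end` marking the reverse
strand) are produced and consumed only at I/O boundaries by explicit
converters, which keeps interval arithmetic off-by-one-free while matching
the conventional annotation format exactly on output.

ORF amino-acid counts follow the stop-inclusive rule: a span of `L`
nucleotides encodes `L/3 − 1` amino acids (the stop codon lies inside the
span and is not counted). Spans not divisible by three are rejected rather
than rounded — annotation rows that violate divisibility indicate a
coordinate error and should be surfaced, not silently repaired.

ORF finding requires an ATG start and an in-frame stop, reporting maximal
spans (first ATG after the previous in-frame stop) on both strands.
Alternative start codons (GTG/TTG) can be supplied via the `start_codons`
argument but are off by default: the conservative choice, and the table
arithmetic above is start-codon-agnostic anyway.

Translation uses the standard genetic code. An ambiguous codon is translated
to a residue only when every concrete expansion agrees (`CAR` → Q, `CAY` →
H); otherwise to `X` (`RAY` expands to {N, D} → `X`). This is deterministic
and lossless for degenerate-primer work: a pattern position never silently
commits to one reading.

## Degenerate primer design

Primer oligos are derived from conserved protein motifs by per-position
minimal-cover reverse translation: each residue becomes the IUPAC triplet
whose base set at every codon position is exactly the set used by that
residue's codons. For 17 of the 20 residues the codon set is a product set
and the triplet matches exactly the residue's codons. Leu, Arg and Ser (six
codons in two blocks) cannot be covered exactly by one IUPAC triplet; the
minimal cover necessarily also matches a few foreign codons (e.g. the Leu
cover YTN also matches the Phe codons TTY). This is the standard trade-off
in degenerate primer design and is why degeneracy, not specificity, is
reported per primer. Lowercase motif letters mark low-confidence positions
and become NNN. Reverse primers are the reverse complement of the
coding-strand pattern; degeneracy (the product of per-position expansion
counts) is invariant under complementation. Codon-usage weighting and
inosine bases are not modelled — no codon-preference information is
available for the uncultured symbionts being screened.

## In-silico PCR

A template base matches a pattern position iff its IUPAC expansion is a
subset of the pattern's (an `N` in an assembly gap therefore counts as a
mismatch against anything narrower than `N`). A site qualifies when total
mismatches ≤ `max_mismatch` and the `clamp_len` 3'-terminal positions are
mismatch-free, mimicking the polymerase's requirement for a matched 3' end.
Products pair a forward site with a downstream opposite-strand reverse site;
product length runs from the 5' end of the forward site to the 5' end of the
reverse site inclusive, so two motifs 66 codons apart with a 7-residue
reverse motif give 3·66 + 21 = 219 bp. All qualifying pairings within
`[min_len, max_len]` are reported — screening favours sensitivity, and
multiple clones per product class are expected.

Defaults: `max_mismatch 1`, `clamp_len 3`, `min_len 50`, `max_len 2000`.
Annealing stringency is not a measured quantity; `max_mismatch` is kept at 1
because the generic and swf AT forward motifs (FPGQGsQW, FSGQGTQW) differ at
exactly two pattern-constrained positions, so a 2-mismatch tolerance would
make each primer set anneal to the other's site and double-report every swf
gene. At 1 mismatch both diagnostic product classes (~290 bp and ~220 bp)
amplify from their exact sites with margin.

## Family classification

Evidence is collected per motif as absent / canonical / swf-variant, with
1-based position and matched text:

| motif | canonical | swf variant |
|---|---|---|
| KS condensation | DPQQR | DPQ[IV]R |
| KS active site | HGTGT | HATGT |
| AT signature | QCALVEL | edge-varied `.CALVE.` |
| AT substrate (reported only) | IAFH, GHSxGE | — |
| radical-SAM triad | C-x(3)-C-x(2)-C | — |

The QCALVEL signature tolerates substitution of its first and last residue
(edge tolerance 1); an internal substitution does not match. The fourth
residue of GHSxGE is recorded verbatim rather than classified — the allowed
alternatives in non-swf sequences are not well characterized.

Labels are a pure function of evidence under an ordered rule table: (1)
QCALVEL present → swf; (2) both DPQ[IV]R and HATGT → swf; (3) intact DPQQR
and HGTGT without QCALVEL → cis-AT-like; (4) Cys triad without any KS/AT
evidence → radical-SAM; (5) otherwise unclassified. Rule 1 precedes the KS
rules because the AT signature is unique to swf sequences and wins
conflicting evidence. The domain architecture string (KS-AT-DH-ER-KR-ACP)
is only ever reported from motif-anchored KS/AT evidence; DH/ER/KR/ACP
anchors are not detectable by short signature motifs and profile-HMM
detection is out of scope.

## Percent identity

Global Needleman–Wunsch alignment with linear gap costs (defaults match +1,
mismatch 0, gap −1 — an identity-style scoring, since percent identity
rather than homology score is the quantity of interest). Among equal-score
alignments the algorithm maximizes matched columns, then aligned pairs,
lexicographically — tuple addition is monotone for lexicographic order, so
this is a well-defined dynamic program and the reported identity is a
deterministic, total function of the inputs rather than an artifact of
traceback order. Identity = 100 × matches / alignment columns, gaps
included in the denominator (the stricter and more reproducible convention;
a matched-columns denominator can be derived from the reported fields).

## Neighbour-joining phylogeny

Distances are uncorrected p-distances with pairwise deletion of gap columns;
a Poisson correction (−ln(1−p)) is available by flag. p-distance is the
assumption-minimal default and the choice is echoed in the report. NJ is
the Saitou–Nei agglomeration on Q(i,j) = (m−2)d(i,j) − r(i) − r(j); ties are
broken by the lexicographically smallest pair of cluster labels (a cluster
is labelled by its smallest leaf), so output is deterministic. Negative
branch lengths are clamped to zero, the raw deficit logged.

Bootstrap support of an internal edge is the percentage of
column-resampled replicate trees (seeded resampling, seed echoed) containing
the same non-trivial leaf bipartition. Outgroup rooting places the root at
the midpoint of the outgroup's pendant edge, preserving the leaf set and all
leaf-to-leaf path lengths. Condensation collapses internal edges with
support strictly below the cutoff (support ≥ cutoff is retained — the
boundary rule is stated so tests are unambiguous); a collapsed edge's length
is added to its promoted children so root-to-leaf depths are preserved
(leaf-to-leaf paths through a deleted edge cannot all be preserved;
condensed trees are topology summaries).

## Proteoform mass spectrometry

Chemical formulas are exact element-count maps parsed from Hill-style text.
Isotope masses and abundances are an embedded snapshot of the NIST/CIAAW
compilation (version string `nist-2018`, echoed in every report), so results
are reproducible and any discrepancy with other software is attributable to
the table. Monoisotopic mass sums lightest-isotope masses.

Isotope patterns are built by convolution: each element's single-atom
distribution, keyed by nucleon shift above its lightest isotope, is raised
to its atom count by binary exponentiation and the per-element results are
convolved, pruning bins below `prune_threshold` (default 1e-10) per step.
Bins are unit-mass aggregates; each bin's mass is the abundance-weighted
mean of its isotopologues. Peak selection (monoisotopic vs most intense)
operates on these aggregated bins, matching how resolved isotopic peaks are
read off a spectrum; for a ~10 kDa protein the most intense bin lies 5–7
bins above the monoisotopic one. Charge states assume proton attachment
(positive-mode ESI): m/z = (M + z·1.007276)/z. The ppm sign convention is
10⁶ (calculated − measured)/calculated.

Phosphopantetheinylation arithmetic: the radical (odd-electron) adduct adds
C11H20N2O6PS (nominal +339, the experimentally established shift); the
even-electron adduct adds C11H21N2O6PS (nominal +340, phosphopantetheine as
the neutral dihydrogenphosphate minus water). The one-hydrogen difference
is consistent with oxidation of the terminal thiol to a disulfide dimer
(2M − H₂, also computed) followed by homolytic S–S cleavage in the source.

## Synthetic metagenome

The generator emulates the screening substrate: contigs carrying planted
genes whose encoded proteins bear the family motif bundles at fixed
positions (swf: DPQIR at aa 160, HATGT at 300 — the KS domain occupies
roughly the first 420 aa — FPGQGSQW at 425, IAFH at 480, GHSSGE at 495,
QGEIAAA at 515, FSGQGTQW at 525, QCALVEL at 591–597, mirroring the signature
position in SwfA; generic-AT product 291 bp ≈ the ~290 bp class, swf product
219 bp ≈ the ~220 bp class). Decoy cis-AT genes carry DPQQR/HGTGT and the
generic primer motifs only; radical-SAM decoys carry only the Cys triad.

Backgrounds are uniform over the 20 amino acids; back-translation uses
uniform synonymous codons (no codon-usage table exists for the uncultured
symbionts, and uniformity is assumption-free and seedable). Two rejection
rules make test outcomes structural rather than probabilistic: a protein is
redrawn if any diagnostic motif occurs outside its planted window, and a
contig is redrawn if any screening primer finds a site (at default
stringency) outside the planted windows. Requested primer-site substitution
counts are realized exactly, placed from the primer's 5' side so the 3'
clamp stays intact, each substituted base drawn outside the pattern's
expansion; a count exceeding the pattern's non-N positions is rejected as
unrealizable. All randomness flows from a single seed recorded in the
manifest, and every manifest entry is re-verified against the emitted
sequence on creation.

What the synthetic data do **not** emulate: community abundance profiles,
sequencing error, chimeras, codon bias, GC heterogeneity within a contig,
and realistic protein background composition. Passing tests therefore
demonstrate the correctness of the pipeline's logic and arithmetic on data
satisfying its assumptions, not its sensitivity/specificity on real
metagenomes, where annealing thermodynamics and divergent homologs dominate.

Alignments for phylogeny tests evolve i.i.d. sites down a tree under the
20-state uniform-exchange model: along a branch of length t (expected
substitutions per site) each site is redrawn uniformly with probability
1 − exp(−(20/19)t), so expected p-distance saturates at 0.95. Problem sizes
used in the recovery experiments (6 taxa, 2000 aligned columns, 100
replicates) were chosen as the smallest at which distance signal cleanly
exceeds sampling noise for the tree depths simulated.

## Workflows and reports

Every report header echoes the tool version, the full configuration, the
seed and the isotope-table version; logs go to stderr and reports to files
only, so identical configurations produce byte-identical outputs. The
screening workflow runs both primer pairs by default: the generic AT pair
reproduces the broad screen (its short fragment carries no diagnostic motif
and classifies as unclassified — in practice those products are sorted by
sequencing), while the swf pair's product ends in QCALVEL and classifies
directly.

## Known limitations

- No melting-temperature or secondary-structure model for primers; mismatch
  counting is a proxy for annealing.
- Percent identity from identity-style scoring is not a substitute for a
  substitution-matrix alignment when sequences are highly diverged.
- NJ with p-distances underestimates long distances (use the Poisson flag);
  no ML/Bayesian inference.
- The isotope convolution assumes natural isotopic abundances and neutral
  molecules; no fine structure within a unit-mass bin is resolved, matching
  the resolution at which most-intense-peak m/z values are reported.
- One published annotation row is internally inconsistent by one codon with
  the stop-inclusive span rule obeyed by all other rows; the arithmetic here
  follows the rule and flags the row rather than special-casing it.
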