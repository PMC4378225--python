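# Methods

## The analysis

Given a family of Mu-like phage genomes, the pipeline proceeds:

1. **Termini and host flanks.** Virions of transposable phages package
   the genome with random host DNA at both ends; the phage sequence
   proper begins at a conserved 5'-TGT. The boundary is found by
   cross-genome agreement: each TGT occurrence within 200 bp of an end
   proposes the following 40 bp as a probe, and the occurrence whose
   probe matches (≤20% mismatches) a proposal in the most other genomes
   wins. Host flanks are genome-specific noise and cannot assemble a
   majority. With a single genome the rule degenerates to an exact end
   match. The right end is handled as the left end of the reverse
   complement, which makes all terminal detectors reverse-complement
   symmetric by construction. Genomes are then trimmed to their
   boundaries.

2. **Terminal transposase-binding repeats.** Each terminal 200-bp
   window is searched for a triple of mutually similar 22-mers
   (pairwise Hamming ≤ 6, either orientation). Every window's triple
   proposes a candidate consensus; the candidate explaining the family
   best (most qualifying sites over all windows, then fewest total
   mismatches) becomes the family consensus. This vote matters: a
   *register-shifted* triple can be internally consistent within one
   window when the three flanking bases coincide, but it misfits every
   other window and loses. The consensus is oriented so that the
   majority of family sites read it directly — which makes orientation
   labels family-relative and therefore invariant under reverse
   complement (roles L/R swap, offsets are preserved). Sites are
   reported as L1–L3 and R1–R3 numbered outside-in, with offsets
   measured from the genome end to the repeat's nearest edge. An end is
   *complete* iff its TGT is present and at least two repeats were
   found; incomplete ends mark prophage-style truncated deposits.

3. **ORF annotation.** Maximal open reading frames (≥34 codons, the
   smallest accessory gene size; starts ATG/GTG/TTG) are called on both
   strands; within each stop-to-stop frame the start with the strongest
   Shine-Dalgarno support wins (consensus AGGAGG, ≥4/6 match at a
   4–13-nt spacer; ties prefer the smaller spacer, and the matched core
   is extended 3' over adjacent purines, which reproduces the printed
   7-mer SDs of this group). At 64% GC, stop codons (AT-rich) are so
   sparse that shifted and antisense frames of real genes are riddled
   with long spurious ORFs, so a separate arbitration step follows: (i)
   candidates ranked by SD score (scores <5 carry no weight) and then
   length are accepted greedily unless already-kept ORFs cover >45% of
   the candidate; (ii) a local-improvement pass swaps a kept ORF out
   when ≥2 equally-SD-supported rejected candidates it blocked are
   mutually compatible and jointly at least as long — the signature of
   a single spurious frame shadowing two adjacent genes. Genuine
   overlapping gene pairs (a −1 frameshift partner entering its host's
   3' region, ~36% overlap) sit safely below the 45% cap.

4. **Translational features.** The slippery-site scanner reports
   in-frame X XXY YYZ heptamers (first base = third base of a codon)
   followed within 200 nt by a same-strand ORF in the −1 frame whose
   start overlaps the host's 3' region; it returns the 1-based codon
   index and codons-before-stop. The internal-start scanner reports
   in-frame ATG/GTG codons strictly inside an ORF that carry SD
   support. Both quote coordinates that are recomputable from the
   sequence (a property the tests assert literally).

5. **Homology and ortholog groups.** All-vs-all protein comparison uses
   Smith–Waterman with BLOSUM62 and BLAST-style affine gaps (a gap of
   length k costs 11 + k); X scores 0 against everything. Significance
   is Karlin–Altschul, E = K·m·n·e^(−λS) with the standard gapped
   BLOSUM62 constants K = 0.041, λ = 0.267, m = the shorter sequence
   and n = the total residue count of the compared set — the shorter-m
   convention makes retention symmetric per unordered pair. A seeding
   heuristic (global edit-distance prescreen via edlib, cutoff 0.65 of
   the longer length) keeps the stage fast; the exhaustive path remains
   available and is what the tests compare against. Two ORFs are
   orthologous when a hit reaches e ≤ 1e−5 *and* they are syntenic:
   after anchoring each genome pair on mutual-best-hit pairs, the two
   ORFs' rank offsets relative to the nearest anchor differ by at most
   2 (tolerating local indels while excluding translocations). Groups
   are connected components; a genome contributing several members
   keeps its best-scoring one, the rest split off as singletons.

6. **Comparative re-annotation.** Arbitration occasionally lets a
   chance SD-bearing frame displace a real gene in one genome. For
   every group populated in at least half the genomes, each absent
   genome's syntenic slot (between its members of the nearest flanking
   groups) is re-scanned with the raw caller and the best candidate
   matching a group member at e ≤ 1e−5 is restored, flagged
   ``rescued``. The same machinery, applied to annotation gaps ≥100 nt,
   recovers ORFs overlooked in externally supplied annotations.

7. **Core, accessory, RGPs.** Core = exactly one member in every
   *complete* genome (incomplete deposits cannot veto); the backbone is
   numbered 1..n by position in the reference genome (first genome by
   default). Everything else is accessory. Within each genome, every
   maximal run of accessory ORFs between two consecutive core genes is
   assigned to the locus keyed by that anchor pair; loci are labelled
   A, B, … left-to-right; accessory ORFs upstream of the first (or
   downstream of the last) core gene fall into flagged terminal
   pseudo-loci. Accessory ORFs are typed across genomes with the same
   1e−5 standard (no synteny requirement) and named after their locus
   (a1, g3, …). Note one consequence of the operational core
   definition: a cargo gene carried by *every* genome is, correctly,
   core — accessory status requires variability.

8. **GC valleys.** Sliding-window GC (window 500 bp, step 50 bp, N
   excluded from numerator and denominator); valleys are maximal runs
   of windows below 0.55 — low enough to flag sub-kilobase low-GC
   inserts against a 64% backbone without firing on noise. The overlap
   table reports, per RGP per genome, whether the locus interval
   intersects a valley.

9. **Tree.** Distance between two genomes is one minus the
   alignment-length-weighted mean pairwise amino-acid identity over all
   core groups containing both (identity from the same Smith–Waterman
   engine; pairs sharing no core group get distance 1.0 with a
   warning). Neighbor joining (Saitou–Nei) with exact Q-ties broken by
   the lexicographically smallest label pair; negative branch estimates
   clamp to zero; the last three lineages join at an unrooted
   trifurcation. Supports come from gene-wise bootstrap: core groups
   are resampled with replacement (default 1000 replicates, seeded),
   the matrix and tree rebuilt from cached per-group identity
   statistics, and each internal edge annotated with the percentage of
   replicates containing its bipartition.

10. **Homologue counting.** Against a user-supplied protein FASTA whose
    headers carry ``taxon=virus|bacterium|other``: a record counts when
    the two sequences share ≥75% of their total length
    (shorter/longer), the alignment covers ≥75% of each, and the
    screening e-value (n = total database residues) is ≤ 1e−3; counts
    are returned split viral/bacterial, untagged records fall into an
    ignored "other" bin with a warning.

## The synthetic-data generator

The generator emits families with the architecture the analysis is
meant to dissect, plus complete truth tables. Defaults encode the study
conditions: 12 genomes, 47 core genes (130–340 codons), nine RGP loci
(A–I, anchored after core genes 2, 5, 10, 15, 20, 23, 25, 27, 40)
holding 28 accessory ORF types of 34–100 codons, loci C and G being
multi-ORF clusters and F/G carrying 46%-GC cargo; backbone GC 64%;
host flanks of 50–100 nt at 66% GC; repeats at offsets 10/93/124 and
4/46/93 with the innermost right repeat inverted; the slippery cassette
(T TTT TTC at codons 116–118 of a 161-codon tail gene, 43 codons before
its stop, partner ATG 3 nt downstream in the −1 frame) and the internal
start (GTG = Val at codon 177 of the 250-codon protease gene, ACGAGGA
at a 9-nt spacer). Divergence follows a balanced two-clade tree with
uniform per-site substitution at rate 0.06 on each clade-ancestor
branch and 0.048 on each leaf branch; the leaf rate was set so that the
anchored-alignment nucleotide identity of an intra-clade genome pair —
substitutions *plus* the indel columns contributed by their accessory
differences — matches the ~87% reported for the family's index pair.
Because uniform substitution relaxes base composition toward 0.5, the
ancestor is sampled at a compensated GC so the leaves land on the
configured value (the map g → g(1−4r/3) + 2r/3 inverted along the
root-to-leaf rates).

Several planted guards make exact recovery a well-posed target rather
than a coin flip:

* every gene's regulatory cassette (an in-frame stop, the SD, and a
  scrubbed spacer) pins the ORF caller's start choice;
* guard codons CTA-ACT-GAx after every start place stop codons in the
  +1/+2 frames so shifted frames cannot borrow the gene's SD; the
  frameshift cassette carries an extra +1-frame stop for the same
  reason;
* the non-coding termini are interleaved with a palindromic 12-mer
  (TTAATTAATTAA) carrying stops in all six frames, so the conserved
  repeat region can never present a long open frame;
* functional sites (starts, stops, SDs, heptamer, repeats, termini,
  guards) are masked from substitution, and substitutions creating
  premature in-frame stops are reverted — the generator's stand-in for
  purifying selection;
* optional left-end truncation (~2 kb) emulates incompletely deposited
  prophages for completeness-flag tests.

What the generator does **not** model: indel evolution inside genes,
recombination or gene conversion, codon-position-specific substitution
bias, genes on the reverse strand, overlapping genes beyond the one
frameshift pair, or realistic intergenic turnover (linkers are
conserved). Passing the recovery tests therefore demonstrates that the
algorithms are correct under the stated architecture, not that they are
robust to every artefact of real sequencing data; on real input the
ORF caller remains a deliberate simplification of HMM-based gene
finders, and group boundaries can differ where the homology/synteny
rules are near their thresholds.

## Numerical and design choices

* Coordinates 0-based half-open internally, 1-based inclusive in all
  emitted files; reverse-strand ORFs are stored by forward-strand span
  with the translation from the reverse complement; N-containing codons
  translate to X, and X is alignment-neutral.
* Whole-genome identity canonicalises the input pair (order by id,
  orientation by the first genome's lexicographic minimum) before
  anchoring, because optimal-alignment match counts are not unique
  across equivalent paths; this makes the statistic exactly symmetric
  and reverse-complement invariant.
* The SD "plausibility" rule (≥4/6 core match, spacer 4–13, purine
  extension) is a declared convention generalising the single
  published instance; the arbitration threshold (union overlap ≤45% of
  a candidate) leaves a wide margin on both sides: genuine frameshift
  partners overlap ~36%, spurious shadows ≥80%.
* Repeat detection parameters (22-mer, window 200, ≤6 mismatches) are
  config-exposed; offsets are measured to the repeat edge nearest the
  genome end.
* Bootstrap resampling operates on cached per-group identity/weight
  matrices, so 1000 replicates cost about a second for 12 genomes.
* Validation runs use study-scale families (12 genomes × ~37 kb) over
  20 seeds for family-level claims, and a 6-genome/12-core miniature of
  the same architecture for unit-level tests; oracle comparisons
  (exhaustive alignment enumeration, additive-tree NJ recovery, regex
  slippery scans) are exact.

## Known limitations

* The core criterion ("every complete genome") is strict: one missed
  gene copy demotes a group. The comparative re-annotation step exists
  precisely to make that event rare, but families with genuinely
  patchy gene content will interleave core and accessory differently
  than a presence-threshold definition would.
* Accessory typing merges clusters by plain homology across loci, so a
  gene family recurring at two loci is one type assigned to its
  majority locus.
* E-values use fixed Karlin–Altschul constants rather than per-query
  estimation; rankings are exact, absolute significances are
  approximate at short lengths.
* The NJ tree is unrooted and its within-clade resolution on
  star-like radiations is (correctly) weakly supported; only
  well-supported bipartitions should be interpreted.
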