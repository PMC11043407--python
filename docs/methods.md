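# Methods

casforge re-implements, as a tested library, the computational workflow used
to discover and characterize compact Cas9 nucleases from large collections
of metagenome-assembled genomes (MAGs): CRISPR-Cas locus mining, tracrRNA
and single-guide (sgRNA) scaffold inference, PAM determination from a
randomized-library cleavage assay, and targeting-range / base-editor
targetability estimation. Every stage can be exercised end to end on
synthetic data with machine-readable planted truth. This note records the
models, the tunable parameters and their defaults, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Locus mining

CRISPR arrays are detected with a CRT-style seed-and-extend scan: exact
8-mers recurring with a period compatible with one repeat-spacer unit seed
candidate repeat sets, which are extended column-by-column while every copy
stays within `max_repeat_mismatches` (default 1) of the column consensus and
at most one copy deviates per column, then trimmed back to unanimous
boundary columns. Candidates are validated against the classical bounds
(repeats 23–47 bp, spacers 26–50 bp, ≥ 3 repeats) and made non-overlapping
(most repeats wins, then longer span, then leftmost). Boundary trimming can
shift a span by a base or two when a flanking column is unanimous by chance;
planted-truth comparisons therefore use a ±3 bp tolerance.

A candidate locus is an array plus annotated *cas1*, *cas2* and *cas9* genes
on one contig with every pairwise edge-to-edge gap ≤ 10 kbp. Discovery
filters: Cas9 length in [950, 1100) amino acids and strictly more than 5
spacers. Within a species group, proteins are globally aligned (match +1,
mismatch −1, gap −2, linear) to the group reference (its longest member); a
gap run ≥ 5 aa intersecting a configured nuclease-domain span disqualifies
the member, and of the survivors the highest-coverage locus is kept (ties:
longer protein, then lexicographic id). Species labels, coverage depths and
domain coordinates are inputs — they belong to MAG construction, upstream
of this pipeline.

Greedy centroid clustering follows the CD-HIT recipe: records sorted by
length descending; a record joins the first centroid reached at the identity
threshold over an alignment core (terminal gaps excluded) covering the
required fraction of the shorter sequence. The within-cluster length-outlier
filter removes members shorter than the median minus two *population*
standard deviations.

## tracrRNA inference

The direct repeat is searched against both strands of the flanking sequence
— the two ≤ 3000-bp windows on either side of the array, concatenated (a
10-N spacer prevents alignments straddling the junction). Local alignment
uses the short-word scoring (+1/−1, gap open 2, gap extend 1); hits must
contain an exact `word_size` (8) run of identities, the condition under
which a word-seeded search can find them at all. Significance uses the
ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with n counting both
strands. For the two-valued ±1 score, the moment equation
p·e^λ + (1−p)·e^(−λ) = 1 with p = Σ_b f_b·r_b (flank × repeat composition)
has the closed form λ = ln((1−p)/p); K = (1−2p)² follows from excursion
statistics of the biased ±1 walk (gambler's ruin: excursion-start density
q−p times the excursion-maximum tail (q−p)e^(−λS)). This is an
approximation to the exact lattice constant, adequate for the permissive
default filter `evalue_max = 1`.

Rho-independent terminators are called by an explicit rule in place of
covariance-model machinery: a hairpin of stem ≥ 5 bp (G·T wobble allowed,
loop 3–10 nt, stems grown outward from each possible loop) followed within
≤ 3 nt by a 6-nt window containing ≥ 4 T; score = 2·stem + T-count. A
tracrRNA candidate runs from the anti-repeat start to the best terminator's
end, or to the first poly-T (≥ 4 T) when no terminator is found.

sgRNA scaffolds fuse the repeat (3'-truncated at the duplex end) to the
candidate through a GAAA tetraloop (FS form); the TS form trims the
repeat:anti-repeat duplex to `trim_len` (12) pairs nearest the tetraloop;
the -opt forms apply configured point substitutions. The duplex register is
the gapless antiparallel offset maximizing canonical + wobble pairs; fewer
than 8 pairable positions is an error.

### Folding

The default engine maximizes canonical base pairs (Watson–Crick + G·U,
hairpin loops ≥ 3 nt, no lonely pairs): a Nussinov-type DP in which a paired
interval is closed by a helix of ≥ 2 exactly stacked pairs followed by an
arbitrary interior. All structures within `band_pairs` (1) of the optimal
pair count are enumerated (deterministically, capped, with a bounded work
budget). Pair maximization is massively degenerate, so the returned optimum
is selected among maximal-pair structures by a second lexicographic
criterion — maximal number of stacked pairs — computed by a parallel DP.
This tie-break is a deterministic stand-in for thermodynamic stability and
never changes the optimal pair count, which is what the brute-force
enumeration oracle checks. When configured, an external thermodynamic
engine shells out to the RNAsubopt executable (`--noLP -e <band>`).

### Module check

A scaffold passes when one predicted structure simultaneously shows
(i) ≥ 8 realized pairs of the *annotated* repeat:anti-repeat register
(incidental cross-segment pairs do not count), (ii) a stem-loop of ≥ 2 bp
starting within 6 nt downstream of the realized duplex end (nexus), and
(iii) a hairpin wholly within the 3'-terminal 60 nt and downstream of the
nexus — the sequential module order of type II guides. All thresholds are
config-exposed.

### Specificity limit

With these search settings (word 8, e-value ≤ 1) a 6-kb flank yields a
non-negligible rate of statistically significant chance hits: a shuffled
flank contains an exact ≥ 13-nt reverse-complement of a 36-nt repeat with
probability ~10⁻³–10⁻⁴, and such a hit (e-value ≪ 1) can assemble a
module-passing scaffold. On 20 seeded scrambled-flank negatives the suite
observes one such event; that check is left failing rather than weakened,
as the false positive is a property of the method's parameters, not of
this implementation. In the discovery
setting this is mitigated by ranking: the planted (true) tracrRNA always
outranks chance hits by alignment score.

## PAM discovery

Reads are reduced to 8-mer counts by locating the anchor (protospacer 3'
end, ≤ 1 mismatch, leftmost match) and taking the following `pam_len` bases;
reads with no anchor, an anchor too close to the read end, or ambiguous PAM
bases are tallied in a QC report. Position profiles give per-base
frequencies and information content 2 − H (bits). The four most informative
positions (ties leftmost) define 256 combinations whose marginal
cleaved/control frequency ratios — with pseudocount 1 on both numerators —
form the enrichment table.

The consensus is the minimal-cardinality *exact cover* (disjoint partition)
of the enriched set E = {combinations with ratio ≥ 0.2 × max} by
per-position IUPAC products, found greedily (largest product inside the
remainder first) with exhaustive branch-and-bound for |E| ≤ 32. Minimal
partitions are not unique, so among them the canonical *prefix partition*
is preferred: recursively split on the leftmost position, merging letters
with identical residual suffix sets into one degenerate symbol. This is how
degenerate consensus strings are conventionally read off a heatmap and it
reproduces branch-style consensi such as GW··/GC··/AT·· exactly.

Cut-site geometry: adapter-ligation end positions are counted per strand
(positions count upstream from the PAM's 5' edge into the protospacer);
the call is blunt when the strand modes coincide, otherwise an overhang of
their difference (top mode > bottom mode ⇒ 5' overhang; the reported offset
of a staggered call is the PAM-proximal mode). Fewer than `min_support`
(10) observations on either strand gives "undetermined".

## Targeting range and base-editor targetability

A genomic position is *targetable* when a PAM pattern match places it as
the PAM-proximal protospacer base on either strand. The denominator
excludes positions within max(pam_len, spacer_len−1) of contig ends so both
strands are fully evaluable everywhere counted; genome N matches only
pattern N. On i.i.d. uniform sequence the fraction converges to
1 − (1 − p)², p = matching combinations / 4^pam_len. Comparator schemes are
configured with canonical PAMs (SpCas9 NGG, SaCas9 NNGRRT, Nme2Cas9 N4CC,
CjCas9 N4RYAC); the compact-Cas9 scheme under study is N4GWNT / N4GCDT /
N4ATDT with a 23-nt spacer and a cut 3 bp upstream of the PAM.

Editing windows are the spacer positions (numbered from the PAM-proximal
end) whose across-guide mean A>G conversion is ≥ 10%. A G>A variant is
targetable when a PAM on the + strand places the mutated adenine at a
window position w (PAM start = variant + w); C>T variants are evaluated
identically on the reverse complement, which makes the strand-symmetry
invariant hold by construction. Exclusive targetability is plain set
algebra: solely(e) = set(e) minus the union of all others.

## Synthetic data

Generators are pure functions of (parameters, seed); every stochastic draw
flows through named streams of a single seeded service, so fixed-seed runs
are byte-identical.

* **Genomes** — each locus contig (default 20 kb; the test suite uses 12 kb
  to keep runs fast) carries cas9 (1004 aa) – cas1 (300 aa) – cas2 (94 aa) –
  tracrRNA – array (24 spacers × 36-bp repeat) on the forward strand with
  100–400-bp gaps, plus random decoy contigs and one array-without-cas decoy
  so precision is always measured. The planted tracrRNA is an imperfect
  reverse complement of the repeat (2 substitutions placed to leave the
  8-mer seed intact) followed by a nexus-like hairpin and a terminator
  hairpin + T-tract. The hairpin stems are fixed sequences with strictly
  alternating {A,G}/{C,T} arms and C-only linkers, chosen by search so no
  unintended segment pair (wobble included) offers more than a few stacked
  pairs — under pair-maximization folding the planted structure is then the
  unique stable optimum, which a thermodynamic model would grant a natural
  GC-rich terminator for free.
* **PAM libraries** — control PAMs uniform over 4⁸; cleaved reads retained
  with probability 0.9 (PAM matches a planted pattern) vs 0.02 (background),
  then uniform substitution errors at 0.1% per base. The accepted-read match
  fraction has the closed form (14/256·0.9)/((14/256·0.9)+(242/256·0.02)) ≈
  0.722. Ligation/PCR mechanics are not modeled: the analysis only consumes
  frequencies.
* **Cut fragments** — per-strand end positions, 90% at the planted offset
  (default 3 bp, blunt) and 10% at ±1.
* **Reference + SNVs** — i.i.d. genome at GC 0.41 (echoing the human genome
  without shipping it); well-separated G>A / C>T SNVs whose per-editor
  verdicts are forced: positives get a concrete PAM written at a window
  placement, negatives have every qualifying placement minimally scrubbed,
  iterating across editors to a fixed point and verifying the final verdict
  against intent.
* **Editing matrices** — in-window mean `peak`, off-window `off_window`,
  Gaussian guide noise truncated to [0, 1].

What passing these benchmarks shows: the statistical machinery (enrichment,
consensus cover, window estimation, site counting, set algebra) is correct
against closed forms and planted truth, and the pipeline is deterministic.
What it does not show: robustness to real-data features the generators omit
— MAG fragmentation and chimerism, non-uniform coverage, PCR and ligation
bias, indel sequencing errors, thermodynamics of real RNA folding, and
repeat degeneracy within arrays.

## Problem sizes and runtime

Default test-suite sizes: 12-kb locus contigs, 100k-read PAM libraries
(10 seeds), 1-Mb uniform genomes for density checks, 120-kb references with
50 SNVs, 20-seed mining/tracrRNA replicates. The full suite runs in under
two minutes on one core; the demonstration pipeline (`pipeline.run_demo`)
in a few seconds.

## Known limitations

* The pair-maximization engine over-pairs relative to thermodynamics; the
  stacking tie-break and the annotated-register duplex criterion compensate,
  but borderline scaffolds should be re-checked with the external engine.
* E-values use an ungapped two-valued approximation; gapped hits inherit it.
* The cut-site caller reports modal geometry only; heterogeneous cut
  mixtures (e.g. partial staggering) collapse to the modal call.
* Array detection assumes near-identical repeat copies (≤ 1 mismatch per
  copy by default); heavily degenerate arrays would need relaxed bounds.
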