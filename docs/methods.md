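# Methods

`ssnmine` implements a desk-scale pipeline for finding novel or highly
divergent enzyme families among metagenome-predicted proteins, of the kind
used to mine extreme-environment metagenomes for specialized DNA-repair
enzymes.  This note documents the models, the numerical choices, what the
synthetic benchmark does and does not emulate, and the known limitations.

## Pipeline overview

1. **Profile retrieval.** Each target family is described by a
   position-specific scoring model (PSSM) built from a seed alignment.
   Every input protein is scored against the profile by local dynamic
   programming; proteins whose best hit has E-value below 1 are retrieved.
   The threshold is deliberately permissive — distant homologs are the
   point — and spurious inclusions are removed later by competitive
   confirmation and by the network refinement itself.
2. **Length filter.** Sequences shorter than the profile's model length
   (or a per-family override) are removed; no maximum is applied.
3. **Reference mixing.** A seeded uniform sample of reference
   (outgroup) sequences is added so that 25–35% of network nodes are
   references.  Clusters that exclude the references are the novelty
   signal, so the outgroup share must be controlled.
4. **Network construction.** All-vs-all percent identity from global,
   end-gap-free pairwise alignment (BLOSUM62, gap open −11 / extend −1),
   with a k-mer prefilter for tractability.
5. **Refinement.** The edge threshold is raised step by step until
   metagenome and reference sequences separate, or a 50%-identity ceiling
   is reached.  Cohesion is tracked by the fragmentation percentage,
   100 × components / nodes.
6. **Candidate triage.** Members of confirmed metagenome-only clusters are
   filtered for full length, measured for terminal extensions against the
   characterized references, and ranked by contig size.

## Profile scores and E-values

Match scores are pseudocount-smoothed log-odds in half-bits:

    score[c][a] = 2 * ( log2((n_ca + w·g_ca) / (N_c + w)) − log2(b_a) )

where `n_ca` counts residue `a` in match column `c`, `b` is the background
(uniform by default), and `g_c` is the pseudocount distribution.  By
default `g_c` pushes the observed column frequencies through the BLOSUM62
substitution profile (`g_c = P(a|b) @ f_c`, `w = 10`).  This choice is
essential, not cosmetic: with plain background (Laplace) pseudocounts, a
narrow seed alignment assigns harsh penalties to every residue it never
observed, and homologs at ~25% identity — exactly the divergence of
interest — score near the random background and are lost at E < 1.
Substitution-profile pseudocounts play the same role Dirichlet-mixture
priors play in profile-HMM software.  The plain prior remains available
(`prior="background"`).  Columns with >50% gaps are excluded from the
model.  `X` scores as the background-weighted column average.

Local search uses affine-gap Smith–Waterman over the profile columns
(gap open −11, extend −1 in half-bits), greedy extraction of
non-overlapping hits, ties in traceback broken diagonal → profile-gap →
target-gap.  Targets shorter than 8 residues are skipped.

Significance follows the Karlin–Altschul convention.  Maximal local
scores against random sequences are Gumbel-distributed; `calibrate_evalue`
fits location and scale to the maximal bit scores of seeded i.i.d.
background decoys (default 200 decoys of 300 aa) and reports

    E(s, L) = K · L · model_length · exp(−λ·s)

for a database of `L` total residues.  The fit is maximum likelihood, not
method of moments: the right tail of local-score maxima is long, the
moment estimator inflates the scale parameter, and the resulting E ≤ 1
count on fresh decoy databases was measured at ~0 instead of ~1.  With
the ML fit the mean count of E ≤ 1 decoy hits per database sits within a
factor of three of one, which is the calibration property the test suite
asserts.

## Pairwise identity and edge filtering

Edge weights are percent identity from a global alignment with free,
unscored terminal gaps (Biopython `PairwiseAligner`, BLOSUM62, −11/−1).
The identity denominator is the aligned core — identities + mismatches +
internal gap columns, terminal overhangs excluded — so a domain embedded
in a longer protein is compared over the shared span.  Alternative
denominators (`shorter`, `full`) are one config switch away.

One numerical trap matters here: under the end-gap-free convention, two
unrelated sequences can align over a chance core of a handful of columns
and report 50–70% "identity".  Left unchecked, such edges weld unrelated
clusters together and no threshold separates anything.  `build_network`
therefore drops edges whose aligned core covers less than half of the
shorter sequence (`min_core_fraction = 0.5`).  The k-mer prefilter
(k = 3, one shared word) bounds the quadratic all-vs-all; a sampled audit
re-aligns skipped pairs on every build and warns if any would have formed
an edge at ≥40% identity.

## Refinement and stopping criteria

The sweep starts at 10% identity and rises in 1-point steps to a 50%
ceiling.  At each threshold, connected components are classified by
composition: components smaller than `size_min = 5` are singletons;
clusters with metagenome purity ≥ `purity_min = 0.95` are
metagenome-only; the mirrored case is reference-only; anything else is
mixed.  The sweep stops with reason *separated* at the first threshold
where a metagenome-only cluster exists **and** each such cluster still
contains a metagenome-only cluster one step higher — a one-step hysteresis
guard that prevents stopping on transient splinters that dissolve at the
next threshold.  Hitting the ceiling with no metagenome-only cluster
flags the family *not unique*.  Component count and fragmentation are
non-decreasing in the threshold (monotone filtration), which the suite
asserts on random networks.

Purity and size cutoffs quantify a judgement ("exclusively/primarily
metagenome") that is qualitative in practice; 0.95 and 5 are the defaults
because a 19-metagenome/1-reference cluster should count as a novelty
signal while a pair of stray metagenome nodes should not.

Report rounding: reference percentage to one decimal, fragmentation to
the nearest integer, both half-away-from-zero.

## Candidate triage

Confirmation is competitive: each member of a metagenome-only cluster is
scored against the whole profile library (family profiles plus
confounders) and kept only if its best profile is the family's own — the
profile-scan step that discards spurious permissive-threshold inclusions.

"Aligned poorly" is judged against the cluster's *own* alignment, not the
family profile: novel-cluster members are distant from the family profile
by definition, so the pipeline builds a profile from a star alignment of
the cluster members (projected onto the longest member) and keeps members
whose coverage of it reaches 0.8.  Records lacking a probable start codon
are discarded; the stop-codon requirement is off by default because
translated-ORF FASTA rarely encodes it.

Terminal extensions are the median, over up to 25 references, of the
candidate residues before the first (after the last) aligned reference
residue in a global end-gap-free alignment.  The median is robust to one
atypical reference.  Ranking is by contig length (sequence length when
contig metadata is absent), ties by id.

## Synthetic benchmark

The generator plants the cluster phenomenology the pipeline exists to
detect.  Defaults: 4 families × 40 members, within-family identity 80%,
between-family ~20% (near the aligner's chance level), 30% of family
members labelled reference; one novel cluster of 15 metagenome-only
sequences at 25% identity to its parent family, carrying a conserved
100-residue N-terminal extension; 10% truncated sequences; 50 i.i.d.
background decoys; 200-aa roots.  Divergence is substitution-only
(BLOSUM-biased replacements) over a star topology, and every identity
target is realized by a closed loop against the package's own aligner —
"80%" means 80% as the network will measure it.  Extensions are conserved
(shared within the cluster) by default, matching the observed biology of
such clusters; a per-member random-extension mode exists.

What the benchmark does **not** emulate: indels and alignment ambiguity,
rate heterogeneity and tree-like phylogenetic structure, composition
bias, real reference databases with representative (multi-sequence)
nodes, and annotation noise.  Passing the recovery tests therefore shows
that the machinery — retrieval, thresholding, composition classification,
confirmation, extension measurement — behaves correctly under controlled
divergence; it does not certify recall on real metagenomes, where family
structure is messier.

Recovery scoring matches predicted metagenome-only clusters to planted
ones at Jaccard ≥ 0.5 (greedy, each side used once); precision and recall
are cluster-level, and extension error is the mean absolute difference
between estimated and planted N-terminal extension over candidates from
novel clusters.

## Problem sizes and determinism

The shipped configurations are desk-scale by design: default benchmark
runs involve ~225 sequences, networks of 50–130 nodes, and profiles of
~200 columns, which keeps a full pipeline run around 20 s and the
acceptance computation (5 replicate seeds plus calibration simulation) a
few minutes.  All randomness flows from a single run seed through fixed
per-stage derivations; two runs with the same config and seed produce
byte-identical output tables, which the suite checks by hashing.

## Interface choices

The library modules are the primary interface; the CLI wraps the three
entry points a user actually runs from a shell (`simulate`, `run`,
`evaluate`) and composes the stage functions internally rather than
serializing profiles and networks between subcommands.

## Known limitations

- The PSSM search is not a full profile HMM: no per-position gap
  penalties, no glocal mode, no multi-hit envelope statistics.  A parser
  for HMMER3 `--domtblout` tables lets real hmmsearch/hmmscan results be
  injected at the retrieval stage instead.
- E-value calibration assumes the decoy background matches the database
  composition; strongly biased real databases would need recalibration.
- The star alignment used for cluster-level profiles drops insertions
  relative to its center sequence; it is a triage device, not an MSA.
- With very short domains (<~120 aa) retrieval at 25% identity becomes
  unreliable — scores scale with model length while the random-score
  floor does not.  This mirrors the real difficulty of finding short
  divergent domains.
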