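# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic benchmark does and does not
establish, and the design choices made where the design was genuinely open.

## The analysis

Endogenous retroviruses (ERVs) integrate as proviruses with the canonical
5′LTR–*gag*–*pro*–*pol*–*env*–3′LTR layout. Two facts make them minable
and datable: an *env* gene that still encodes a full-length protein is a
long ATG→stop ORF (the conventional screen is > 400 codons, i.e. ≥ 1,200
coding nucleotides), and the two LTRs are identical at the moment of
integration, so their subsequent divergence — under the assumption of
neutral evolution — clocks the insertion. The pipeline chains six stages:
ORF screen → profile-HMM classification → LTR direct-repeat delimitation →
LTR-divergence dating → family clustering/consensus → Env motif
annotation. Monotreme parameters are used as defaults throughout (neutral
rate, screen thresholds), since the echidna/platypus *env* inventory is
the motivating application; every threshold is exposed in configuration.

## ORF screen

Six-frame enumeration with two modes. `start_to_stop` reports one ORF per
stop-delimited segment, from the segment's 5′-most ATG; this avoids
counting nested ATGs as separate loci, matching how a single env locus is
tallied once in copy-number tables (an all-ATG mode exists behind a flag).
`stop_to_stop` reports the full segments, used for provirus structure maps
where ORFs longer than 300 nt are drawn. The ≥ 400-codon boundary is
**inclusive** (aa_len ≥ 400, coding span ≥ 1,200 nt); whether the original
getorf-based screens counted the stop codon inside the 1,200 nt is not
knowable from the published descriptions, so a `strict_gt` flag switches
to a strict > 400 rule. Codons containing N translate to 'X' and do not
terminate an ORF; ORFs over 5% 'X' are flagged low-confidence, not
dropped.

## Profile-HMM classification

Profiles are read from HMMER3/f ASCII (probabilities recovered from the
negative-natural-log encoding; `STATS LOCAL VITERBI` supplies the Gumbel
(μ, λ)). Scoring is a **local, uni-hit Viterbi**: free begin→M_k entry and
M_k→end exit, match/insert emissions scored as log-odds against the
standard amino-acid background, transitions as log-probabilities, result
in bits. Flanking (unaligned) residues contribute zero; 'X' emits at
background odds in every state, so N-rich ORFs are neither favored nor
penalized. E-values use the Gumbel tail
E = n·(1 − exp(−exp(−λ(S − μ)))) with n the number of profiles scanned
per ORF (the hmmscan database-size convention), and the screen keeps the
per-ORF best hit iff E ≤ 10⁻¹⁰.

This deliberately deviates from hmmscan's Forward-score/exponential-tail
E-values: Viterbi has an exact exhaustive-enumeration oracle (every state
path, checked to 10⁻⁹ bits on small instances) and a one-line calibration,
and the 10⁻¹⁰ screen separates true retroviral ORFs from background by
tens of bits, so bit-compatible E-value semantics are unnecessary for the
screen to reproduce decisions. Exact hmmscan E-value reproduction is a
non-goal; no MSV/bias filters, no multi-domain chaining, no glocal mode.

Profiles built for the synthetic benchmark (`profile_from_sequence`) favor
the template residue with probability 0.9 per match state and are
calibrated by scoring 100 background sequences with λ fixed at ln 2 and μ
fit by maximum likelihood — the conventional slope for well-behaved bit
scores.

## LTR delimitation

Around each env ORF a ±10-kbp window is cut (the standard extension used
to capture a complete provirus around an env anchor). Direct repeats are
found by seed-and-extend: exact 12-mers shared between two window
positions, grouped on diagonal bands (difference ≤ 32 to tolerate small
indels), chained along the window (seed gap ≤ 500 bp), extended outward by
an ungapped X-drop scan (+1 match / −2 mismatch, drop 20), and the two
repeat copies aligned globally to obtain identity and the ranking score.
The −2 mismatch penalty was chosen by simulating the boundary-error
distribution: at repeat divergences up to 5%, it keeps the probability of
a > 5 bp boundary error near 1% per end, where −1 lets chance matches in
the flanking sequence drag the boundary out (~5%) and −3 truncates
diverged repeats. Candidates must satisfy 100 ≤ length ≤ 3,000 bp and
≥ 80% identity — defaults bracketing typical retroviral LTR sizes and
published identity floors (mid-80s%) with margin, since no LTRharvest
parameter set is recorded for the original analyses. The best-scoring pair
bracketing the env ORF is the call; ties break to the longer repeat, then
the smaller left coordinate. Target-site duplications and PBS/PPT features
are deliberately unused: downstream analysis needs only LTR coordinates
and identity.

## Dating

The LTR pair is aligned globally with affine gaps (match +1, mismatch −1,
gap open −5, extend −1; Biopython's PairwiseAligner, first optimal
alignment, deterministic). p-distance is uncorrected with pairwise gap
deletion — gapped columns excluded — matching EMBOSS distmat defaults; no
Jukes–Cantor correction. Age: **T = d / r** by default ("one_lineage"
convention), with r = 2.6 × 10⁻³ substitutions·site⁻¹·My⁻¹, the monotreme
genome-wide neutral rate. This reproduces the published arithmetic for the
single-copy echidna env locus (3.9 × 10⁻³ / 2.6 × 10⁻³ ≈ 1.5 My). The
standard two-lineage convention T = d / 2r (each LTR an independent
lineage) is provided; whether the published 1.5 MYA reflects a deliberate
convention or an arithmetic shortcut is unknowable, so neither is asserted
as correct biology and the simulator can match either. Identity is
reported to one decimal in tables; internally it is the exact complement
of d.

## Families, consensus, trees

Families are single-linkage clusters of env ORF translations at ≥ 80%
pairwise global-alignment identity. The original groupings were made "by
amino acid sequence" with no stated threshold; 80% was chosen so that the
simulator's within-family divergence (≤ ~3% at the planted ages) and
between-family divergence (templates generated independently, < 80%
identity asserted at generation) are separated by a wide margin, and it is
a config parameter. Reproducing any particular published group count on
real assemblies is not asserted.

Multicopy families are aligned progressively: 3-mer distances → NJ guide
tree (midpoint-rooted) → profile–profile alignment with affine gaps
(sum-of-pairs +1/−1, open −5, extend −1). This replaces L-INS-i; exact
MAFFT reproduction is a non-goal — the requirement is consensus accuracy
on ≤ 10%-divergent family members, which is verified against ground truth
(consensus within 0.1% of the planted template on the benchmark) and
cross-checked against the mafft CLI on one family in the test suite.
Columns with under 60% residues are then removed (the rm_gap-60 rule:
columns with more than 40% gaps are minor insertions private to few
members; the exactly-60% boundary column is kept), and the consensus takes
the per-column plurality residue, gaps not voting, ties broken
lexicographically — plurality tie behavior differs across EMBOSS cons
versions, so determinism was prioritized. Neighbor joining delegates to
scikit-bio with negative branch lengths clamped to zero (warned); it is a
distance-tree helper for group structure, not a substitute for
maximum-likelihood phylogenetics, which is out of scope.

## Env annotation

The furin site is the regular pattern R-x-[RK]-R (the minimal RXR/KR
site, covering RxRR and RxKR); among matches leaving at least 80 residues
downstream — a typical TM ectodomain + anchor + tail, configurable — the
C-terminal-most is taken, selecting the biologically plausible SU/TM
junction when the motif recurs in SU. "TM region" means the post-cleavage
subunit used as phylogeny input, not a predicted membrane helix; topology
prediction is out of scope. The RDR receptor-binding motif is
S-D-G-G-G-x-x-D-x-x-R, all (overlapping) matches reported. 'X' residues
never satisfy fixed motif positions. When no furin site exists (degraded
ORFs), callers fall back to the full-length sequence with a warning — a
plumbing decision, since how such sequences entered published TM
alignments is not recorded.

## Synthetic benchmark

`make_genome` plants proviruses into an i.i.d. background (GC 0.42,
roughly mammalian) with ≥ 25-kb spacing so ±10-kb windows never collide.
Each provirus is 5′LTR (600 bp) + gag (450 codons) + pro (250) + pol
(800) + env (450, carrying one RDR motif in SU and a furin site ≥ 80 aa
from the C terminus) + 3′LTR, with short stop-codon pads between genes so
ORF boundaries are exact. Mutation is per-site Bernoulli substitution, at
most one hit per site: each LTR copy mutates independently at p =
expected_d/2 so the expected pairwise LTR distance equals age × rate under
the chosen convention; the internal region mutates at the same rate. The
multiple-hit bias of this model is below 1% for d ≤ 0.1, the regime of
interest (published LTR identities are ≥ 84%). Indels are off by default
(p-distance with pairwise deletion is the measured quantity); an indel
mode (geometric lengths, rate p/10, LTRs only) stresses the aligner. In
intact copies the env ATG, terminal stop, and the immediately upstream
stop pad are held fixed and substitutions that would create in-frame env
stops are reverted, so intactness ground truth is exact; decayed copies
get 1–3 planted in-frame stops positioned so no ≥ 400-codon sub-ORF
survives. Intact-passes / decayed-fails is asserted at generation time.

The default benchmark — 2-Mb genome, seed 20230417, 12 proviruses, 8
intact env across 3 families (6/1/1) plus 4 decayed, ages cycling
{0.5, 1.5, 5} My — was sized to exercise every stage (multicopy
consensus, both strands, the full age range of recent expansions) while
keeping a full run under half a minute. Decayed copies are apportioned
across families by largest remainder, ties to the family with fewest
decayed copies, so decay is spread rather than concentrated.

What the benchmark does **not** emulate: repeat landscapes and GC
isochores of real chromosomes (background is i.i.d., isolating the repeat
caller's false-positive behavior; a tandem-repeat spiking mode exists for
stress testing), nested insertions, solo LTRs, rate heterogeneity and
multiple hits at high divergence, and real profile databases. Passing the
benchmark therefore establishes algorithmic correctness and calibration
under the stated model, not performance on real assemblies.

## Desk scale vs. assembly scale

The published genome-wide tallies for the monotreme assemblies — two env
ORFs in platypus, 121 in echidna, copy numbers 18/77/19 for the three
large echidna families, LTR identity ranges 86.7–100% / 94.5–100% /
84.4–99.5%, and the published group classification — require the multi-GB
platypus (mOrnAna1.p.v1) and echidna (mTacAcu1.pri) assemblies, the GyDB
profile collection, and hmmscan-compatible E-value semantics. They are
**not** reproduced at desk scale and the test suite does not assert them.
Full-assembly runs are supported as an optional integration path
(`erv-env-miner run --allow-assembly-scale` with the real FASTA and
profile collection); the simulation-based checks above are the test
surface that stands in for them.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; GFF3 is written 1-based
inclusive, BED 0-based half-open; minus-strand features are stored on the
forward strand with a strand flag. Motif positions are 1-based in TSV
reports. Empty sequences are rejected by scorers and aligners; an empty
genome yields an empty report with exit 0; an all-gap alignment column
set, an asymmetric distance matrix, an uncalibrated profile asked for an
E-value, and infeasible provirus packing are errors. Emission and
transition rows must sum to 1 within 10⁻⁶ in memory (10⁻⁴ when re-read
from 5-decimal ASCII). All pipeline stages are deterministic; reruns on
identical inputs produce byte-identical artifacts. Every stochastic
component (simulator, calibration) takes an explicit seed.
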