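# Methods

## The strand-asymmetry statistic

For a motif *m* over a set of sense-oriented sequences, counts are pooled:
F = total overlapping occurrences of *m*, R = total occurrences of its
reverse complement, and DSA = (F − R)/(F + R).  Pooling (rather than
averaging per-sequence ratios) was chosen because trimmed intronic
features are short and frequently contain zero occurrences, which makes
per-sequence ratios undefined or unstable.  F + R = 0 yields an explicit
`undefined` flag, never a silent zero.  Windows containing non-ACGT
letters are skipped and excluded from the window count.  Two identities
are exact by construction and enforced by tests: DSA(m) = −DSA(revcomp(m)),
and DSA = 0 for every defined motif on a set symmetrized with its reverse
complements.

Uncertainty is a nonparametric bootstrap over sequences (sequences, not
windows, are the exchangeable unit).  Contrasts — motif A vs motif B on
one sequence set (paired resamples) or one motif across two sets
(independent resamples) — use the two-sided, +1-corrected bootstrap
p-value p = (2·min(#{Δ* ≥ 0}, #{Δ* ≤ 0}) + 1)/(n_boot + 1), capped at 1,
so p ≥ 1/(n_boot + 1) always.  On 200 null genomes the contrast rejects at
α = 0.05 at an observed rate of 0.035 (inside the 95% binomial band).  An
optional Benjamini–Hochberg flag (`adjust_p`) adjusts an analysis' contrast
p-values; it is off by default, so raw p-values are reported.

## Feature extraction and trimming

One transcript is kept per gene (uniform random among annotated isoforms,
seeded); genes nested inside another gene's genomic span are removed
together with their host (strand-blind span containment; partial overlaps
are kept); genes with fewer than `min_introns` introns (default 2, so
first/internal/last classes are distinct; 1 is available for sensitivity
runs) are dropped.  Splice signals would dominate motif counts near
boundaries, so features are trimmed before counting: 3 nt off each exon
end, 6 nt off the intron 5' end and 40 nt off the intron 3' end; a
short-intron mode trims introns 6/6 for genomes whose introns are mostly
shorter than the acceptor-side trim.  Features shorter than the query
motif after trimming are excluded (counted in logs).

Distance profiles tile the *trimmed* intron with nonoverlapping full-width
bins (500 nt for the distance analysis, 100 nt for the strength analysis);
bin 0 is adjacent to the anchor, so a 5'-anchored bin 0 starts 6 nt into
the annotated intron — a documented offset of the trimmed convention.
Windows straddling a bin boundary are counted in neither bin; at 500-nt
widths this loses ~1% of windows and keeps bins disjoint.  The "gene 3'
end" region is operationalized as the trimmed last exon (configurable),
and the gene 5' end as the trimmed first exon.  Samples with fewer than
`min_sample_n` sequences (default 500) are flagged and carry no DSA value.

## Splice-site strength

Donor windows are 9-mers (3 exonic + 6 intronic, GT forced at intron
+1/+2); acceptor windows are 23-mers (20 intronic + 3 exonic, AG at −2/−1).
Non-canonical windows are excluded from training by default.  Strength is
log2(P_model / P_background) in bits, with the background the order-0
composition of the training set (overridable, e.g. uniform).

The model is maximum-entropy under marginal constraints, retrained from
whatever window set is supplied; numeric agreement with any published
parameter set is a non-goal.  Order 1 constrains positional nucleotide
marginals and equals the positional-frequency product model exactly.
Order 2 additionally constrains position-pair dinucleotide marginals and
is fitted by iterative proportional fitting (IPF) on the exhaustive joint
table, which is feasible for windows up to 10 positions (the 9-mer donor:
36 pairs, convergence to max violation < 1e-6 in a few hundred sweeps).
Empirical marginals carry a pseudocount (default 0.5 per cell) so scores
stay finite.

The 23-mer acceptor space (4^23) cannot be enumerated, and stochastic fits
of the fully pairwise-constrained model (iterative scaling with
importance-sampled or persistent-Gibbs marginal estimates) proved unstable
here: realistic training windows are a mixture over site strengths, which
induces weak positive couplings between *every* position pair, and the
resulting fully-connected system drives the samplers into a collapsed
phase while rare marginal cells sit below Monte-Carlo resolution.  The
acceptor model is therefore a chain of overlapping blocks (width 9, step
5): each block is IPF-fitted exhaustively with all within-block pair
constraints, and blocks are combined by conditioning each on its overlap
with the previous one, so the joint model is exactly normalized (Z = 1, no
sampling anywhere).  Pairs of positions that never share a block are only
approximately constrained — the same subset-decomposition compromise
established max-ent splice scorers make for the acceptor site.  Fit
diagnostics (iterations, max constraint violation, convergence flag) are
attached to every model, and models serialize to a flat versioned text
format from which scores rebuild bit-exactly.

Quartile labels (low ≤ Q1, high ≥ Q3, else mid; linear-interpolation
quantiles, computed per analysis sample) drive the strength-stratified
profiles; a degenerate distribution (Q1 = Q3) labels everything mid and
skips the analysis with a flag.  Under the generator's window model the
rank correlation between latent strength and donor score is ~0.76 at
n = 2000 (0.86 for the acceptor) — sufficient for quartile stratification,
and the low/high quartiles differ in mean latent strength by > 0.3.

## The synthetic-genome generator

No generative model exists for these asymmetry patterns, so all generator
choices are documented stand-ins.  Defaults define the standard study
conditions used throughout the tests: background composition
complement-symmetric and AT-rich (A = T = 0.3, C = G = 0.2, so parity
holds in expectation and AATAAA density is realistic for introns);
log-normal intron lengths (median 500 nt, σ = 0.7) and exon lengths
(median 200 nt, σ = 0.6), so multi-bin distance profiles exist; 3–6 exons
per gene (≥ 2 enforced); both strands at 50%.  Splice windows are sampled
from positional consensus models (CAG|GTAAGT donor, pyrimidine tract +
CAG|GTC acceptor) whose per-position consensus probability is
0.25 + 0.72·s for a latent per-gene strength s ~ U(0, 1); GT/AG are
forced, on the sense strand for either gene orientation.

Depletion removes each eligible forward AATAAA occurrence independently
with probability q(d, s) = q0 · exp(−d/τ) · (1 + c·(1 − s)), clipped to
[0, 1], where d is the distance from the intron 5' end (τ = 0 disables
the decay) and c couples weak splice sites to stronger depletion; an
optional expression coupling multiplies q by (1 + e·u) with u the gene's
expression rank in [0, 1], emulating expression-stratified contrasts only
when requested.  Eligibility excludes the splice-signal margins (6 nt /
40 nt), which the analysis trims away anyway, so planted windows never
collide with planted splice sites.  Under this mechanism the expected
downstream DSA is −q/(2 − q), the recovery target used everywhere.

Removal permutes the window's letters (composition-preserving — the
nucleotide multiset of every sequence is invariant under planting) until
the edited neighbourhood contains no occurrence of the motif or its
reverse complement overlapping the window.  Because AATAAA's permutations
*are* its anagram controls (TAAAAA, AAAAAT, ...), naive permutation leaks
counts into the control motifs (+0.1 DSA on AAAAAT at q = 0.5);
neutralization therefore runs two phases: 50 attempts that additionally
refuse to create any newly-protected motif (panel + controls, both
orientations), then 50 attempts with motif/rc avoidance only, so that
protection can never suppress the realized removal probability (realized
q_eff = 0.493 at nominal 0.5, with residual control leakage within ~2
standard errors of parity).  Windows that survive both phases (e.g. inside
homopolymer context) are left unchanged, logged, and counted in the truth
record.  Every removal (position, applied probability) and every latent
strength is recorded in a `TruthRecord`, alongside the generator's internal
sense sequences, so extraction round-trips are checked byte-for-byte.

Identical (config, seed) produces byte-identical FASTA/GFF3/expression/
truth text.  What the generator does *not* emulate: codon structure,
isochores, repeats, UTR annotation subtleties, alternative isoforms
(exactly one mRNA per gene is emitted), mutational strand biases
(replication/transcription-coupled), and real splice-site motif structure
beyond positional consensus.  Passing tests therefore demonstrate that the
pipeline recovers planted selection signatures under parity-symmetric
backgrounds — not that any particular real genome harbours them.

## Problem sizes and numerical choices

The standard verification conditions: null calibration uses 200 replicate
genomes of 2000 introns (500 genes × 4 introns) with 200-replicate
bootstraps; depletion recovery uses one 2000-intron genome per q in
{0.25, 0.5, 0.75} with a 3·SE acceptance band; the distance gradient uses
25 genomes of 2400 long introns (log-normal median 3000 nt, τ = 400,
q0 = 0.6), judged by one-sided sign tests across genomes (and flatness at
τ = 0 by two-sided sign tests); strength coupling uses 20 genomes of 2000
introns (median 2000 nt, q0 = 0.4, c = 1, τ = 400) with order-1 donor
scoring, which is sufficient for quartile ranking and much faster than
order 2.  These sizes give per-contrast effects of ≥ 1.2 bootstrap SEs per
genome for the weakest comparison (bin 1 vs bin 2 of the gradient), hence
sign-test power above 0.95.

Tie and degenerate-input policy: quartile ties keep their bin; all-equal
scores are degenerate-flagged; six-mer percentile ranks average ties
(mid-rank) over defined six-mers only, with an all-equal table flagged
degenerate; empty sample classes are reported with a flag rather than
dropped.  Bootstrap replicates with undefined DSA are discarded; a
contrast becomes `unreliable` when more than 10% of replicates are
undefined.  All randomness flows from explicit integer seeds (one master
seed per pipeline run; per-sample bootstrap seeds derived by hashing the
sample label), so reports are byte-reproducible.

## Known limitations

- Cross-block acceptor pair constraints are approximate (see above).
- The bootstrap contrast is a reconstruction; no claim is made that it
  matches whatever unnamed test produced previously published p-values.
- Span containment is the only nesting criterion; exotic annotation
  (trans-splicing, shared exons) is out of scope, as are GTF input and
  UTR/CDS distinctions.
- The −q/(2−q) expectation assumes independent removals and an untouched
  reverse-complement count; overlapping motif occurrences (possible for
  AATAAA with period 4) make removals very weakly dependent, a negligible
  effect at the densities tested.
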