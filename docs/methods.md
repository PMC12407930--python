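# Methods

## Problem

The ratio of nonsynonymous to synonymous substitution rates,
ω = dN/dS, is the standard summary of selective pressure on a
protein-coding sequence: ω ≈ 1 is consistent with neutral evolution,
ω < 1 with purifying selection, ω > 1 with positive selection.  The
value observed for a real gene depends not only on selection but on the
mutational process (transition/transversion bias, base composition) and
on the local sequence context of the mutated sites.  `omegasim`
quantifies that dependence by simulating mutations under explicit
nucleotide substitution models and reporting the ω those mutations alone
would produce — a mutational null against which an empirical ω can be
judged.

## Substitution models

Five classical relative-rate models are supported, all expressed as 4×4
matrices over the bases in (T, C, A, G) order (row = existing base,
column = mutated base):

| model | off-diagonal rate r(i→j) | parameters (default) |
|-------|--------------------------|----------------------|
| JC69  | μ                        | μ (1) |
| K2P   | α transitions, β transversions | α, β (1, 1) |
| K3P   | α transitions, β for A↔T / C↔G, γ for A↔C / G↔T | α, β, γ (1, 1, β) |
| F81   | π_j                      | π (uniform) |
| HKY85 | κ·π_j transitions, π_j transversions | κ, π (1, uniform) |

Rates are treated as *relative*.  Every consumer normalizes a row over
its three off-diagonal entries, P(j | i) = r(i→j) / Σ_{j'≠i} r(i→j'),
so only ratios matter and no scaling to one expected event per unit
time is performed.  Diagonal entries are stored as the negative row sum
for display only; no operation reads them.  The K3P transversion-class
assignment (β to A↔T/C↔G, γ to A↔C/G↔T) follows the common K3ST
convention and is fixed here as a documented choice.  Defaults make
every model collapse to JC69-equivalent behaviour when its parameters
are left unset, so an unconfigured run can never be silently biased.

Matrix exponentials (time-dependent transition probabilities),
likelihood estimation of parameters, and codon-level models with ω as a
free parameter are out of scope.

## Site counting and change classification

Single-base changes of a sense codon are classified against the
standard genetic code (translation table 1) as synonymous, missense or
nonsense.  Site counts follow the Nei–Gojobori convention: each of the
nine possible changes contributes weight 1/3 at its position, missense
weight accumulating into the nonsynonymous site count N and synonymous
weight into S, while stop-producing changes are excluded from both.
Across the 61 sense codons exactly 23 single-base changes create stops,
so ΣN + ΣS = 183 − 23/3 (a frozen regression constant in the tests).

Mutation tallies n_N and n_S use the same enumeration but weight each
change by the model's normalized per-base probability instead of 1/3;
nonsense draws are likewise discarded.  Sites are *always* uniformly
weighted and tallies *always* model-weighted: this asymmetry is what
makes ω respond to mutational bias at all (were sites model-weighted
too, every model would return ω = 1 identically).

All counting runs in exact rational arithmetic (`fractions.Fraction`;
conversion from a float is exact), so the identity "uniform model
weights equal uniform site weights" holds to machine identity under
JC69 and the exhaustive-mode anchor ω = 1.000 is exact, not approximate.

## Exhaustive mode

Given a coding sequence, the scan starts at the first ATG (or at base 0
with `--assume-in-frame` for pre-trimmed CDS inputs), advances codon by
codon, and stops at — and excludes — the first in-frame stop codon;
internal stops therefore truncate the scan with a logged warning, since
stop codons have no defined site counts here.  A trailing partial codon
is dropped.  Each sense codon contributes `count_sites` and
`weighted_mutation_counts` to the aggregates, and

  dN = n_N / N,  dS = n_S / S,  ω = dN / dS,

with NaN and a degeneracy flag whenever a denominator vanishes
(degeneracy is a flagged result, never an exception).  An optional BED
restriction keeps only codons whose three bases all fall inside one
merged region; codons straddling a boundary are skipped rather than
fractionally counted, because fractional-codon semantics are not
defined for this statistic.  Multi-record FASTA inputs are scanned per
record and also pooled.

Analytic consequences used as test anchors: ω = 1 exactly under JC69
for any sequence; transition-biased K2P (α > β) gives ω < 1 and
transversion-biased K2P gives ω > 1 on random sequences, because
transitions are enriched for synonymous (mostly third-position)
changes.

## Context mode

Context mode builds a mutational null anchored on the positions of
observed variants.  From a VCF, biallelic SNVs whose REF matches the
reference FASTA are kept (indels, multiallelic records, symbolic
alleles and REF mismatches are skipped and tallied by category).  For
each variant, in each replicate:

1. a frame index is drawn uniformly from {0, 1, 2} — fresh per variant
   per replicate, the minimal assumption for a "randomized position";
2. the codon is built from the reference bases flanking the variant
   with the variant base at that frame index; frames that run off the
   contig, contain an ambiguous base, or form a stop codon are skipped
   (resampling would bias the frame distribution conditional on
   sequence content) and tallied;
3. the variant-position site fractions (each alternative at weight 1/3,
   stop-producing changes excluded) are added to N and S;
4. one substitution of the variant base is drawn from the model and
   adds weight 1 to n_N or n_S by its class; nonsense draws add
   nothing.

Site normalization deliberately covers the variant position only — not
the whole constructed codon — mirroring the fact that exactly one
mutation is simulated per variant; this is the module's central
interpretive choice.  The recorded ALT allele is never used to drive
the simulation (the model is the mutational hypothesis being tested);
it is retained for audit.  Only the forward strand is considered, and
the trinucleotide-signature (96-class) formulation is out of scope.

Each replicate yields one ω; `reps` replicates form the null
distribution.  Replicate i is seeded with `SeedSequence([master_seed, i])`,
so runs are bit-reproducible and replicates independent of execution
order.  Internally, replicates are vectorized over variants through a
precompiled per-(variant, frame) table of validity, site fractions,
alternative-class codes and cumulative model probabilities; the scalar
`simulate_variant` exposes the same draw for one variant.

`exact_expected_counts` marginalizes analytically over the uniform
frame and the model's alternative distribution (invalid frames
contributing nothing, exactly as in a replicate) and serves as the
oracle for Monte-Carlo convergence tests.

## Statistics

Degenerate replicates (undefined ω) are excluded from all moments,
percentiles and tests but always counted and reported.  An observed ω
is compared to the null by the add-one empirical percentile,
p = (1 + #{ω_null ≥ ω_obs}) / (1 + n) for the "greater" alternative
(symmetrically for "less", doubled and capped for two-sided), so p is
never 0 and is bounded below by 1/(n+1).  Cross-model comparison of
null distributions uses the Kruskal–Wallis omnibus rank test
(distribution-free, k groups) — a choice of this package, recorded in
the output metadata; pairwise comparisons are not provided.

## Synthetic data

The coding-sequence generator emits ATG + n sense codons + one stop,
codons drawn base-wise from a configurable composition with stops
rejected and resampled; the reference/VCF generator emits one contig of
i.i.d. uniform bases and SNVs at distinct interior positions (≥ 3 bases
of flank, so every variant supports all three frames) whose REF always
matches the contig.  Both are deterministic NumPy PCG64 streams, giving
byte-identical fixtures across platforms.  Because the requirement of
≥ 3 flanking bases per side leaves `contig_length − 6` eligible
positions, `n_variants` is capped at that number.

What the generators do *not* emulate — codon-usage bias, CpG
hypermutability and other neighbour-dependent rate variation, selection
on the variant positions, strandedness, ambiguity codes (skip paths are
exercised by dedicated hand-built fixtures instead) — bounds what
passing tests show: they validate the machinery and its analytic
anchors, not the realism of any particular biological null.

## Problem sizes and numerical choices

Default test-suite sizes are chosen so each check is decisive yet
quick: 500-codon sequences across 20 seeds for the JC69 anchor,
100 × 300-codon sequences for the bias-direction property,
2000 replicates × 500 variants for oracle convergence (4 Monte-Carlo
standard errors), 200 replicates × ≥ 1000 variants for the neutrality
of the context-mode median (accepted band [0.9, 1.1]), and 100 trials
of 2 × 200 replicates for test calibration.  Exact rational arithmetic
covers all codon-level counting; floating point enters only in the
vectorized context replicates and summary statistics, with 1e-12
tolerances on matrix identities and 1e-9 elsewhere.

## Known limitations

Exhaustive mode measures the mutational opportunity of a single
sequence; it is not a pairwise-alignment dN/dS estimator and applies no
multiple-hit correction.  Context mode's variant-position-only site
convention means its N + S per variant is at most 1, so per-replicate ω
on few variants is noisy and may be degenerate (n_S = 0); the
degeneracy flag and counts make this visible.  Only the standard
genetic code is supported.
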