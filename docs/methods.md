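# Methods

## Cassette events and psi

Gene models are read from GTF (1-based inclusive) and stored 0-based
half-open; conversions happen only at I/O boundaries.  A transcript
"contains" an exon only on an exact coordinate match, so each unique
(chrom, start, end, strand) tuple is its own unit and membership is
unambiguous; a transcript with a longer overlapping exon counts as
excluding.  An event's exclusion set is *all* transcripts of the gene not
containing the key, including transcripts that do not span the locus at
all — the alternative (restricting to locus-spanning transcripts) would
need a spanning definition that the data do not force, and with the
package's exact-key semantics the two sets always partition the gene's
transcripts, which keeps Y = ITinc + ITexcl an identity.

Events whose inclusion/exclusion sets coincide are collapsed (their exons
are perfectly correlated across transcript structures and carry one test's
worth of information); the representative exon is the smallest-start key,
ties broken by smallest end, which makes collapsing deterministic and
idempotent.

Per sample, ITinc and ITexcl are sums of expression units (TPM-like) over
the inclusion/exclusion sets — not counts of isoform models, which would be
constant across samples and useless for regression — and
psi = ITinc/(ITinc+ITexcl), undefined when the denominator is zero.
Undefined samples are dropped pairwise in the regression; imputing them
would fabricate signal.

Flanking introns are strand-aware (on the minus strand "upstream" is the
higher-coordinate side).  When inclusion transcripts disagree about the
adjacent exon, the per-transcript gap lengths are aggregated with the
median: robust, deterministic, and naturally yielding half-integer values
for even counts.  A side is reported absent when the exon is terminal in
every inclusion transcript.

## Filtering and classification

The variability filter keeps events whose exon expression (ITinc) is >= 1
unit in at least half the samples, has mean >= 20 units and a 95th/5th
percentile ratio >= 2 (linear-interpolated percentiles; a zero 5th
percentile makes the ratio undefined and the filter fail).  The thresholds
are applied to the matrix's expression units directly.

For each passing event, OLS of Y on psi gives (beta0, beta1); the slope
p-value is the two-sided t test with n-2 degrees of freedom, and R² is the
fit's own coefficient of determination.  P-values are BH-adjusted within
each sample group.  Labels: UHP/DHP need adjusted p <= 0.05 (inclusive),
R² >= 0.5 and a 95/5 percentile ratio >= 2, with the sign of beta1 deciding
the direction; type 0 needs adjusted p >= 0.5 (inclusive) plus the same
variability evidence; anything else — including degenerate fits (fewer than
3 defined samples, constant psi) — is indeterminate.  Regression is on the
linear expression scale: the model is linear in psi, and the observation
that fitted slopes scale with the gene's expression level depends on it.

The percentile-ratio criterion appears twice: at the filter (exon level)
and in the classification rules.  Both ratios are computed and reported per
event; classification uses the **exon-level** ratio by default
(`Thresholds.ratio_basis`).  The reason is structural: when expression is
coupled to inclusion as Y = mu(1 + b·psi) with psi spanning (0.1, 0.9), the
gene-level 95/5 ratio is bounded near (1+0.86·b)/(1+0.14·b) — about 1.8 at
b = 1 — so a gene-level cut at 2 would veto genuinely coupled exons of
moderate effect size while the exon-level ratio (which inherits psi's
variability) does not.  Setting `ratio_basis="gene"` restores the stricter
reading.

Gene labels: a gene is a UHP gene when it has at least one UHP exon and no
DHP or type-0 exon (symmetrically for the other classes), MIXED when
labelled exons of several kinds coexist, NONE otherwise.  Cross-group
consistency counts exons called UHP/DHP in two or more groups and flags
any direction conflict; an optional second result set produces a label
cross-tabulation for replication-style comparisons.

## Occupancy analyses

Overlap semantics follow `bedtools intersect` defaults: two intervals
overlap iff they share >= 1 bp on the same chromosome, strand ignored;
half-open abutment does not overlap.  Counting uses sorted start/end
arrays per chromosome (a feature misses target [s,e) iff start >= e or
end <= s, and those miss-sets are disjoint), O((n+m) log n).

"Bindings per base pair" is (number of peak-to-exon overlap events) /
(summed exon length of the class within the gene), summed over experiments;
the per-gene ratio divides the focus-class density by the type-0 density,
and genes whose type-0 exons attract no peak are excluded and logged.
Collapsed events contribute their representative exon's coordinates.
PRO-seq densities divide the read-interval count overlapping the
downstream intron by the intron length and normalise within the gene so
scored events sum to 1.

The ratio-vs-1 test is a Wilcoxon signed rank on log ratios (symmetric in
ratio space), exact for n <= 25 after removing exact ones.  The
Mann-Whitney test uses the exact null distribution when both samples have
<= 20 values and no ties; with ties and a tiny total sample a full
enumeration on midranks is used (identical multisets then give p = 1
exactly); otherwise the tie-corrected normal approximation.

## Enrichment

The motif statistic is Delta = 100·(hit fraction among focus units) −
100·(hit fraction among type-0 units), in percentage points; reported
proportion differences are rounded to 10 decimals so one-decimal printed
proportions subtract exactly.  The empirical p shuffles all labels without
replacement (class sizes retained) and counts replicates with Delta'
strictly exceeding Delta — ties count against significance; an optional
(b+1)/(n+1) correction is available but off by default.  Exhaustive mode
enumerates every distinct assignment of the label multiset (<= 12 units).
Note that with a strict inequality on a heavily discrete statistic the
p-value is anti-conservative at the tie atoms; the >= convention is the
super-uniform one, and the test suite verifies that property through the
swapped-class identity P(Delta' >= Delta) = 1 − P(Delta' < Delta).

The screen runs every factor against three class comparisons (UHP vs
type 0, DHP vs type 0, UHP vs DHP) and Bonferroni-corrects over the tests
actually performed.  Tests with a tiny observed effect — |Delta| < 0.5
percentage points, or |Delta| below 5% of the larger proportion — are
flagged as excluded rather than dropped, keeping the output auditable.

GO over-representation treats all classed isoforms as the population and
UHP isoforms as successes; each term with at least `min_uhp` (default 5)
UHP isoforms annotated is tested with the upper-tail hypergeometric
P(X >= k), Bonferroni-corrected over tested terms and sorted by p.
Coverage is k_uhp/n_term.

## The synthetic generator

The generator emulates a GTEx-like study: per gene one "full" transcript,
at least one transcript skipping one internal exon, optional extra copies
of either structure, planted biotypes, and non-overlapping gene loci.  Per
sample, psi ~ Uniform(0.1, 0.9) and Y derives from psi (matching the
regression direction): Y = mu(1 + b·psi) for UHP, mu(1 + b(1−psi)) for
DHP, mu for type 0, each times (1 + eps), eps ~ Normal(0, noise_sd)
truncated at −0.9.  Multiplicative truncated noise keeps values
non-negative and gives the roughly constant coefficient of variation seen
in expression data.  The planted slope is ±mu·b, so regressing recovered
slopes on the planted gene means has generative coefficient b.  Inclusion
transcripts share Y·psi equally and exclusion transcripts share Y·(1−psi),
making psi exactly recoverable.

Defaults: 200 genes, 400 samples, b = 1, noise_sd = 0.1, class mix
0.35/0.35/0.30 (UHP/DHP/type 0), mu ~ LogNormal(log 500, 0.8).  The
lognormal location keeps essentially all genes above the mean-20 filter so
recovery measures classification rather than filtering; the sample size is
in the range of the per-tissue cohorts the analysis design targets.
Occupancy tracks draw Poisson counts per exon/intron with class-specific
per-bp rates (defaults place the coupled classes at 0.86 and 0.31 of the
type-0 peak rate, the direction the ChIP analysis is designed to detect);
hits are Bernoulli with a planted proportion difference on half the
factors; planted GO terms draw 80% of members from UHP isoforms.

With the default noise (noise_sd = 0.1) a planted type-0 gene's *total*
expression varies only ~±10%, so its gene-level 95/5 ratio sits below 2;
planted type-0 events are therefore recoverable as type 0 under the
default exon-level ratio basis but become indeterminate under the
gene-level basis.  What the generator does not emulate: library-size and
batch effects, length/GC bias, isoform-level quantification uncertainty,
correlated events within a gene, and any dependence structure between
samples — passing tests show the estimators recover planted effects under
the stated model, not that real data satisfy that model.

## Numerical conventions

Percentiles use linear interpolation between order statistics.  Reported
percentages round half away from zero at one decimal, computed through
exact Decimal arithmetic for integer counts.  BH is the standard step-up
(sorted p·n/rank, running minimum from the largest rank, capped at 1),
invariant under input permutation.  Permutation runs are bit-reproducible
given (seed, n_perm); all generator streams derive from a single seed via
SeedSequence spawning.  Degenerate inputs never crash a run: they flag the
event (indeterminate label, NaN statistic) and are logged.

## Limitations

Only exact-coordinate cassette membership is modelled — alternative 5'/3'
splice sites, intron retention and mutually exclusive exons are not
distinct categories.  No covariate adjustment or mixed-effects modelling
across donors/tissues.  Motif hit generation, splice-site scoring and peak
calling are upstream of this package; it consumes binary hit tables and
BED intervals.  The regression is a marginal per-event model: events of
one gene share Y and are not independent, which the per-group BH
correction does not model.
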