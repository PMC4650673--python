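# Methods

## Scope and model

`dualomics` implements the statistics of a two-condition, un-replicated
dual-omics comparison: one RNA-seq library per condition, one iTRAQ labelling
per condition, shared annotation catalogs, and a protein→transcript accession
map. Nothing upstream of count/ratio tables (read mapping, assembly, spectrum
search, annotation transfer) is in scope; those products are inputs.

### Exact two-library count test

The transcript test conditions on the library-1 count. If a gene draws `x`
of `N1` fragments and the two conditions express it equally, the library-2
count `Y` follows

    p(i | x) = (N2/N1)^i (x+i)! / (x! i!) (1 + N2/N1)^-(x+i+1),

equivalently NegativeBinomial(x+1, N1/(N1+N2)). This is the classical exact
test for digital expression profiles; its assumptions are (i) fragment counts
are Poisson around a per-gene rate — true when each transcript is a small
fraction of the library — and (ii) no biological replication, so the test
addresses only sampling noise, not between-animal variance. Calls on real
data are therefore statements about the two libraries, not the populations
behind them; this is the standard caveat of replicate-free designs.

Numerics: all pmf terms are computed as log-gamma expressions and tails are
accumulated with log-sum-exp, so counts up to 10^6+ are exact to double
precision and overflow is impossible. The two-sided p doubles the smaller of
the two point-inclusive tails, `p = min(1, 2 min(P(Y<=y|x), P(Y>=y|x)))`,
and is floored at the smallest positive double. Doubling a discrete tail is
conservative; the null-calibration property test verifies the rejection rate
never exceeds nominal beyond Monte-Carlo error.

A deliberate consequence of conditioning: the construction is not exactly
invariant under swapping (x, N1) with (y, N2) — the two directions differ by
at most the pmf mass of the observed points, which is negligible for the
large counts the test is meant for. What is exact is tail complementarity,
P(Y<=y|x; N1,N2) + P(X<=x|y; N2,N1) = 1, which the suite asserts to 1e-10.
Identical zero counts give p = 1 whenever N1 >= N2 (and 2·N1/(N1+N2)
otherwise), so equal libraries can never reject on equal counts.

Fold change is the FPKM ratio; a configurable floor (default 0.001 FPKM)
replaces exact zeros before the log2 so the ratio stays finite, and the floor
never touches the p-value, which uses raw counts. FPKM and RPKM share one
code path — the distinction is what the upstream counter counted.

FDR: Benjamini–Hochberg step-up by default; Benjamini–Yekutieli selectable
where dependency between genes is a concern. DE calls use FDR <= 0.001 and
|log2 ratio| >= 1, both boundaries inclusive; fold-change reporting bins are
[2, 10] (inclusive) and (10, inf) per direction, the inclusive lower edge
matching the DE threshold itself.

### Protein ratios

Per protein, shared peptides (mapping to multiple isoforms) are excluded;
the fold change is the geometric mean of the remaining reporter ratios, i.e.
exp(mean(log r)). Significance is a two-sided one-sample t on the natural-log
ratios, t = mean·sqrt(N)/sd with N−1 df — the log-ratio dispersion carries
the same information as the exponentiated confidence half-width ("error
factor") that search engines report, so this is the canonical reconstruction
of that p-value. Log base cancels in t. Edge cases: one peptide → p = 1 and
an `untestable` flag (quantified but never significant); zero dispersion with
a non-unit ratio → smallest positive double with a `degenerate_sd` flag.
Calls: p <= 0.05 (inclusive) and ratio strictly > 1.2 or < 0.8. Signed folds
are a display convention only: r if r >= 1, else −1/r. Optional global
median-centering of ratios is off by default.

### Enrichment

Exact hypergeometric upper tail P(X >= m) with background N = annotated
elements only (differential ids without any annotation carry no term
information and are dropped from n). Terms with m = 0 are not tested;
Bonferroni multiplies by k = number of tested terms. Both raw and corrected
p are emitted; the table filter defaults to raw p <= 0.05 (reproducing the
reporting style of enrichment tables that list raw values) with a switch to
the corrected column. No GO-graph propagation is performed — catalogs are
taken at the level annotated, which accommodates pre-propagated inputs. Ties
in p sort by m descending then term id, for byte-stable output.

### Integration

Accessions are case-folded and stripped of numeric version suffixes before
matching. A pair enters the matched set when protein and transcript are each
differential at p < 0.05 on their own platform. Trend uses strict sign of
the log2 ratios; a zero on either side is `indeterminate` and excluded from
both correlations. Correlations are Pearson r on (mRNA log2, protein log2);
subsets smaller than 3, or with degenerate variance, report r as absent.
The platform-overlap test is chi-squared with Yates continuity correction,
chi2 = sum (max(|O−E|−0.5, 0))^2 / E on the 2x2 table of differential-status
co-occurrence over every element quantified on either platform (protein-side
accessions mapped into transcript space). The correction is clamped at zero
so an exact-fit table scores 0 instead of acquiring spurious signal.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes, not
sequences or spectra:

- counts: `count_1 ~ Poisson(lam_g N1/sum lam)`,
  `count_2 ~ Poisson(lam_g f_g N2 / sum(lam f))` with log-normal per-gene
  rates; matching the test's own sampling model keeps calibration checks
  fair. An over-dispersion option (gamma-mixed rates) exists precisely to
  demonstrate the test's anti-conservativeness when that model fails.
- peptides: per protein, log ratios ~ Normal(log r_true, sd), a configurable
  fraction flagged shared.
- annotations: terms sample the background uniformly; planted enriched terms
  over-sample differential ids at configured odds.
- id map: matched pairs are planned first, each drawing a (mRNA, protein)
  log2-fold pair with positively correlated magnitudes and same or opposite
  signs; the planned folds are then imposed on the count and peptide
  generators so the emitted tables realise the trend structure exactly.

Defaults are desk scale and fixed once: 5,000 genes at N1 = N2 = 2×10^6
(mean count ≈ 400, a realistic mid-depth regime), rate log-sd 1.2 (about
three decades of expression), gene lengths 200–5,000 nt, 10% DE at folds
{2, 4, 8} split evenly up/down; 400 proteins with 2–8 peptides, peptide
log-sd 0.15, 10% shared, 25% differential at folds {1.5, 2}; 200 terms of
10–60 members with 5 planted at odds 5; 40% of proteins matched, 70% of
pairs same-trend, pair magnitude mean 1.5 log2 units, sd 0.5, correlation
0.8. One stage-offset RNG stream per stage makes each stage independently
reproducible from the master seed.

What the simulator does **not** model: biological replicate variance,
GC/length bias, mappability, isotope-impurity cross-talk in reporter ions,
peptide-level missingness correlated with abundance, or annotation-graph
structure. Passing tests therefore demonstrate correctness of the statistics
under their stated assumptions, not robustness of those assumptions on real
libraries.

## Problem sizes in the test suite

Property suites run at sizes chosen to make Monte-Carlo bounds sharp yet
keep the whole suite interactive: 10,000 replicates for null calibration of
the count test (rates 5/50/500) and of the protein t (3/5/8 peptides), an
exhaustive rational-arithmetic sweep of every hypergeometric configuration
with N <= 20, 200 catalog simulations for planted-term ranking, 1,000 random
2x2 tables for the Yates bound, and planted-power checks at 1,500 genes.

## Known limitations and open choices

- The two-sided doubling convention is one of several defensible exact-test
  constructions (summed minima, mid-p); doubling was chosen for its
  conservativeness and simplicity. All are asymptotically equivalent here.
- Whether the protein test should be one- or two-sided is not decidable from
  the symbols alone; two-sided is the conservative default.
- Bonferroni's k counts only terms actually tested (m >= 1), which matches
  the emitted table but is smaller than the catalog's term count.
- The chi-squared overlap universe is a design choice; with a universe
  restricted to the union of differential sets one margin is structurally
  zero, so the test uses all quantified elements instead.
- Unigene-scale headline counts from real libraries (tens of thousands of DE
  transcripts) are not reproducible at desk scale and are out of scope; the
  reporting layer is instead verified to be internally consistent (totals
  always equal the sum of the per-direction counts it derives them from).
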