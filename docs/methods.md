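# Methods

## Signal model

A reverse transcriptase crossing a modified ribonucleotide either reads
through with an elevated miscall probability or aborts. With library
protocols that ligate an adapter to the cDNA 3′ end, aborted cDNAs are
sequenced as reads whose leftmost aligned base sits one position
downstream of the blocking site. `rtsig` therefore estimates, per
reference position *i*:

- mismatch rate `M(i)` = non-reference A/C/G/T calls over coverage
  (deletion calls and N calls are not mismatches; `M` is undefined at
  zero coverage or a non-ACGT reference base);
- arrest rate `A(i)` = read starts at *i*+1 over coverage at *i*+1,
  undefined when *i*+1 is uncovered;
- context-sensitive arrest rate
  `CSA_r(i) = (A(i)+p) / (median of the 2r neighboring A values + p)`.

The pileup layer walks CIGAR strings exactly as samtools does: depth
includes deletion placeholders, insertions create no column, reference
skips (N) create no depth, soft clips never contribute, and each primary
mapped read contributes exactly one start and one end. This equivalence
is asserted against `samtools mpileup -B -Q 0` output in the test suite.

## Parameters and conventions

| parameter | default | meaning |
|---|---|---|
| `CsaConfig.r` | 5 | neighbors per side in the CSA window (2r = 10 interior) |
| `CsaConfig.pseudocount` | 0.001 | added to CSA numerator and denominator |
| S_H coverage gate | 20 reads | minimum coverage to enter the heterogeneous-site count |
| S_H median threshold | 0.1 | median of the three non-reference base frequencies |
| S_A/S_M background `p0` | 0.05 | binomial background rate for the site statistics |
| S_A/S_M cutoff `alpha` | 0.001 | one-sided binomial tail threshold |
| scan `min_coverage` | 20 reads | positions below it are never tested; m = gated count |
| scan `p0` | pooled rate | background for per-site p-values (see below) |
| block size | 1000 nt | positions per profile block file |

Conventions chosen where the behaviour was genuinely open:

- **CSA pseudocount.** The raw fold change is undefined when the window
  median is 0, which is the common case in low-arrest regions. Adding the
  same pseudocount to numerator and denominator keeps every position
  screenable and preserves CSA = 1 on flat profiles; with pseudocount 0
  the statistic is scale-invariant (both properties are tested). At
  sequence ends the window truncates to the available neighbors rather
  than returning NA; a length-1 profile has no window and yields NA.
- **Median convention.** Even-sized sets (the interior 2r = 10 window)
  use the midpoint average; the three-element mismatch-frequency set of
  S_H is odd-sized and unaffected.
- **S_A/S_M rule.** "High" arrest/mismatch sites are defined by the exact
  binomial tail P(X ≥ k | c, p0) ≤ α, a coverage-normalized threshold: a
  10% rate is noise at coverage 20 but significant at coverage 2000. A
  flat rate threshold is available as `mode="rate"`.
- **Final-position arrest.** Position n has no downstream neighbor; its
  arrest rate is stored as 0 so every row stays numeric for the formula
  engine. Undefined rates elsewhere serialize as `NA` and compare false
  in formulas; CSA treats NA arrest values inside windows as 0.
- **Profile text dialect.** Tab-separated, one `#`-prefixed header line,
  `NA` for undefined values, floats written with shortest round-trip
  representation (block files concatenate to a byte-identical whole-profile
  table, also tested).
- **Screening p-values.** The per-site test is a one-sided exact binomial
  tail of the event count (mismatch calls, or read starts one position
  downstream) against a background rate `p0`. When `p0` is not given it
  is estimated as the *pooled* rate — total event count over total
  coverage of the gated positions — rather than the median of per-site
  rates: at realistic error rates the per-site counts are small discrete
  numbers whose median rate falls below the mean, which would make the
  background anticonservative; the pooled rate is the binomial MLE and is
  biased slightly upward by true sites, i.e. conservative. Threshold-only
  screening (no test) is available via `correction="none"` and formulas
  that ignore `p`/`p_adj`.
- **Correction scope.** m = positions passing the coverage gate, not the
  reference length, so uncovered references do not dilute the correction.
- **Differential signs.** Deltas are sample 2 minus sample 1, with
  sample 2 the treated/second profile. The optional per-position test is
  a two-sided Fisher exact test on the (mismatch, match) × (sample)
  table; deltas and the Fisher p are symmetric/antisymmetric under sample
  swap (tested).
- **Formula grammar.** Precedence NOT > AND > XOR > OR, left-associative,
  parentheses override; serialization re-parses to the identical tree.
  NA comparisons are false (three-valued logic collapsed), so screening
  can never flag an uncovered position through a bare comparison.

## Synthetic data

The generator emulates the read evidence the profiler is built to detect,
and nothing more. A uniform-composition random reference is sampled;
reads of fixed length are placed uniformly; each base miscalls i.i.d. at
the error rate; at a planted mismatch site covering reads miscall with
the planted fraction and composition; at a planted arrest site a read
that would traverse the site is truncated, with the planted probability,
so its leftmost aligned base is site+1 — making the arrest-rate estimator
target the planted fraction by construction. Identical spec + seed gives
byte-identical SAM.

Deliberately absent: quality-score realism, PCR duplicates, strand and 3′
coverage bias, splicing, indel errors, multi-mapping. Passing recovery
tests therefore shows the estimators and the screening logic are correct
under clean sampling noise; they say nothing about mapping artifacts or
protocol-specific coverage structure in real libraries, which the
formula thresholds and the differential comparison exist to absorb.

Two systematic features of the simple model do surface in testing and are
worth knowing about when screening real data:

- near the 5′ end of the coverage ramp nearly every covering read starts
  locally, which mimics arrest — raise the coverage gate (e.g. to 50) for
  arrest scans;
- truncated reads reduce coverage upstream of a strong arrest site, so
  the site's own coverage dips while the arrest estimate (which uses the
  downstream column) is unaffected.

## Problem sizes

The test suite validates the CSA implementation against a literal
re-evaluation on a 10⁴-position profile, the heterogeneous-site count
against a naive per-row loop on 10³ random rows including the exact gate
boundaries, and the formula engine against brute-force evaluation on 500
random formulas × 100 random rows. The end-to-end recovery experiment
uses a 10-kb reference at 500× coverage with a 0.5% error rate and 20
planted sites (mismatch fraction 0.3 or arrest fraction 0.4); profile
metrics at planted sites must land within three binomial standard errors
of the planted fractions, and two `p_adj ≤ 0.05` Benjamini–Hochberg scans
(one per metric, backgrounds 0.01 for mismatch and 0.02 for arrest — twice
the nominal error rate and twice the 1/read-length spontaneous start
density, to guard against overdispersion) must recover all 20 sites with
no false positives.

## Known limitations

- Arrest counts for S_A and the arrest scan are recovered from the stored
  profile (rate × downstream coverage, rounded); this is exact for rates
  produced by the pipeline but assumes the profile's own convention.
- The binomial site test treats reads as independent Bernoulli trials; it
  ignores overdispersion from PCR duplicates or mapping bias. Use the
  conservative background rates above, or raw thresholds, when that
  assumption is doubtful.
- XOR precedence between AND and OR follows this package's documented
  grammar; parenthesize when sharing formulas across tools.
- No >2-sample joint statistics: differential comparison is pairwise.
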