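# rtsig

Reverse-transcription (RT) signature profiling of mapped RNA-Seq reads, for
finding candidate RNA modification sites.

Many RNA modifications leave a footprint in sequencing data: an error-prone
reverse transcriptase misincorporates bases when reading through the
modified nucleotide (a *mismatch signature* with a composition
characteristic of the modification), and/or aborts cDNA synthesis at the
site (*RT arrest*), so that — with library protocols that capture abortive
cDNAs — truncated reads pile their 5′ ends one position downstream.
`rtsig` converts SAM alignments into per-position profiles of these
signals, lets you screen every position with Boolean threshold formulas
under multiple-testing control, compares treated/untreated samples, and
renders annotated plots. It is aimed at experimentalists who need to
shortlist a handful of candidate sites from millions of positions before
committing to biochemical validation.

## Metrics

For position *i* of a reference with coverage *c(i)*:

- **Mismatch rate** `M(i)` — non-reference base calls over coverage,
  together with the counts of A/G/T/C calls.
- **Arrest rate** `A(i)` — reads starting exactly at *i*+1 divided by the
  coverage at *i*+1 (the pileup "circumflex" count).
- **Context-sensitive arrest rate**
  `CSA_r(i) = A(i) / median(A(i−r), …, A(i−1), A(i+1), …, A(i+r))` with
  *r* = 5 by default — the fold change of a site's arrest rate over its
  local background, robust to regionally elevated arrest.
- **Per-reference statistics** — coverage peak, mapped reads, and the site
  counts `S_A` (high arrest), `S_M` (high mismatch; both via a one-sided
  exact binomial tail against a background rate, so the effective rate
  threshold tightens as coverage grows) and `S_H` (heterogeneous mismatch:
  coverage ≥ 20 and the median of the three non-reference base frequencies
  ≥ 0.1, i.e. at least two mismatch types at ≥ 10%).

Profiles are stored as tab-separated block files `x_y.txt` (reference *x*,
1-kb block *y*; a 6430-nt third reference puts positions 6001–6430 in
`3_7.txt`), so any region is readable without scanning the positions
before it.

## Worked example

```sh
# a synthetic 10-kb reference, 500x coverage, 0.5% sequencing error,
# one planted mismatch site and one planted arrest site
rtsig simulate --out demo --length 10000 --coverage 500 --read-length 100 \
    --error-rate 0.005 --seed 1 --site 4000:0.3:0.0 --site 7000:0.0:0.4

rtsig profile --sam demo/reads.sam --ref demo/reference.fa --out demo/profile
# -> wrote 1 reference(s) to demo/profile

rtsig scan --profile-dir demo/profile --metric mismatch --p0 0.01 \
    --formula "p_adj <= 0.05 AND mism >= 0.1" --out demo/candidates.tsv
# -> 1 candidate(s) -> demo/candidates.tsv
```

`demo/candidates.tsv` then holds one record — position 4000 with
`mism = 0.2947` at coverage 509 and `p_adj ≈ 1e-165`: the planted mismatch
fraction of 0.3 recovered from the reads, with no background position
surviving Benjamini–Hochberg correction over the ~10⁴ tested positions.
An arrest scan (`--metric arrest --p0 0.02 --min-coverage 50 --formula
"p_adj <= 0.05 AND A >= 0.1"`) flags exactly position 7000
(`A = 0.383`, `CSA = 34.8`; raise the coverage gate for arrest scans —
near the 5′ end of the coverage ramp almost every covering read starts
there, which mimics arrest). Finally,

```sh
rtsig plot --profile-dir demo/profile --region 1:3950-4050 \
    --threshold mismatch=0.1 --out demo/site4000.png
```

draws the region with a marker on every above-threshold position.

Formulas combine comparisons on `pos, cov, mism, A, CSA, fA..fT, nA..nT,
ref, p, p_adj` (and `d_mism, d_A, d_CSA, cov1, cov2, …` for differential
comparisons) with `AND`, `OR`, `XOR`, `NOT` and parentheses; precedence is
`NOT > AND > XOR > OR`.

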