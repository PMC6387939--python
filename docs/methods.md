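# Methods

## The F-motif unit

Every token of a chunk is annotated with its occurrence count *within that
chunk* (no external reference corpus), and the value sequence is cut into
maximal non-decreasing runs: a new motif starts exactly where
`value[i] < value[i-1]`.  Two consequences are used as structural
invariants throughout the test suite: the concatenation of motif values
reproduces the input sequence, and the last position of every motif holds
its maximum — so across a corpus the mean frequency at cell (L, L) of the
position grid dominates the earlier positions of length-L motifs, which is
the quantitative footprint of motifs terminating on function words.

Motif *type* identity is the tuple of frequency values (e.g. `1-8-24`),
not the underlying word sequence; spectra over word-sequence identity can
be derived from the motif tables if needed.  Spectrum ranks are made
deterministic by sorting on descending frequency with lexicographic order
of the value tuple as tie-break.

## Tokenization and chunking

The tokenizer lowercases, keeps maximal runs of letters/digits with
internal apostrophes (`don't` is one token), splits hyphens, and discards
other punctuation; blank lines mark paragraph starts.  These are common
concordancer defaults; the classification and segmentation layers accept
any whitespace-pre-segmented input, so languages needing their own word
segmentation can be pre-processed externally.

Corpora are split into chunks of approximately equal size (default 4,000
tokens) without splitting paragraphs: paragraphs are packed greedily and a
chunk closes at the first paragraph end at which it reaches the target.
The rule is deterministic and conservative — concatenating the chunks
reproduces the token stream.  A single paragraph longer than twice the
target is emitted as its own chunk with a warning.

## Word classes

Function words are identified by a packaged, versioned stoplist covering
the closed classes: articles, conjunctions, prepositions, pronouns, and
the auxiliary verbs *do/be/have* in all inflections.  Modal verbs are
deliberately excluded — auxiliaries are restricted to do/be/have, so
modals count as lexical (content) verbs.  The list is replaceable per run;
classification is purely lexical (no tagging), because the classes are
enumerable and tagging noise would contaminate the frequency analysis.

## Distribution models

**Zipf–Mandelbrot (ZM), right-truncated.**  `P(x) = (b+x)^(-a) / F(n)`
over ranks `x = 1..n` with `F(n) = Σ (b+i)^(-a)`; `a > 0` sets the decay
rate, `b > -1` shifts the low ranks, and the truncation point `n` is fixed
at the observed number of motif types.  (An accompanying prose constraint
"b ≤ 1" seen in parts of the literature is inconsistent with routinely
reported fits of b ≈ 5–36 and is not enforced.)

**Hyper-Pascal (HP).**  `y(x) = [C(k+x-1,x)/C(m+x-1,x)] q^x p0` on
`x = 0, 1, 2, …` with `p0 = 1 / 2F1(k, 1; m; q)`.  Motif lengths `L ≥ 1`
sit on the shifted support `x = L - 1`; with 7 observed length classes
this yields df = 7 − 3 − 1 = 3 after pooling, matching the convention of
the word-length fitting tradition.  The hypergeometric normalizer is
summed directly — with the unit middle parameter the series collapses to
`Σ (k)_j/(m)_j q^j` — until the relative term falls below 1e-14 (cap
100,000 terms); the pmf uses the stable recurrence
`y(x+1) = y(x)·q·(k+x)/(m+x)`.  In fitting, the tail mass beyond the last
observed class is folded into that class so expected probabilities sum to
one exactly.

## Fitting and goodness of fit

Parameters minimize the Pearson chi-square between observed and expected
counts — the convention of the Altmann-Fitter tool family this package
replaces — via Nelder–Mead simplex with a restart from the first optimum
(absolute x-tolerance 1e-8, relative f-tolerance 1e-8, at most 10,000
evaluations per stage).  Maximum likelihood is available behind a flag for
the ZM model.  Starting values: the ZM exponent from the slope of the
log-log rank-frequency regression with `b = 1`; HP from `k = m = 1` and
`q = 1 − 1/mean(L)`.  During search `b` is clipped to `−1 + 1e-6`, `q`
into `(1e-6, 1 − 1e-6)` and `k, m` to `≥ 1e-6`.

Goodness of fit pools adjacent tail classes until every expected count is
at least 1 (the rule is explicit and the pooled class count is reported),
then reports `X²`, `df = pooled classes − parameters − 1` (floored at 0),
`P(X²)`, the discrepancy coefficient `C = X²/N`, and `R²` computed on the
*unpooled* observed-vs-expected count vectors.  `R²` definitions vary in
this literature; computing it on counts, unpooled, is this package's
documented choice and is recorded in every fit-report JSON.

Self-consistency on noiseless inputs recovers ZM `(a, b)` to 1e-3/1e-2 and
HP `(k, m, q)` to 1e-2; over 20 seeded spectra sampled at N = 20,000 from
ZM(a = 0.95, b = 5, n = 2,000), the mean absolute error of the fitted
exponent is ≈ 0.015.

## Group comparisons

Per-chunk features (fitted `a, b, k, m, q`, short/long motif counts,
position-cell means) are compared with pooled-variance two-sample t-tests
(Welch behind a flag; the pooled default matches the integer
`n1 + n2 − 2` degrees of freedom conventional in this literature), with
Cohen's d on the pooled SD so the effect sign always matches the mean
difference.  Input–output coupling uses the zero-lagged Pearson
correlation plus a simple regression for adjusted R² and F on (1, n−2) df.
Interpreter/speaker effects use plain one-way ANOVA — no mixed-effects
nesting.  No multiple-testing correction is applied; the report carries
the number of tests so users can apply their own.  Position-cell tests run
only on cells declared in the design (e.g. L2P2, L3P3, L5P3, L5P4, L6P3,
L6P4), and chunks whose fits failed carry NaN features that are dropped
per test, never zero-filled.

## Synthetic corpora

Real interpreting transcripts cannot be redistributed, so the generator
emulates the statistical structure the pipeline assumes.  Each token is
drawn i.i.d.: with probability `phi` from the top-K ranks of a
Zipf–Mandelbrot vocabulary (the "function register"), otherwise from the
remaining ranks, both renormalized.  Defaults mirror the study design the
pipeline targets: vocabulary 3,000, ZM word-frequency law `a = 1.0,
b = 2.5`, K = 50, `phi = 0.35`, chunks of 4,000 tokens, 14 chunks per
group (~57,000 running words), paragraphs of 200 tokens.  Identical specs
and seeds give byte-identical corpora.

What the generator does *not* emulate: syntax or n-gram structure,
disfluencies, bilingual alignment, topical drift.  Passing tests therefore
show that the pipeline's measurements and fits behave correctly on text
with the assumed marginal structure — not that any particular empirical
claim holds on real interpreting data.  The mechanism test is the link:
raising `phi` from 0.2 to 0.6 raises the mean short-motif (lengths 1–3)
proportion (≈ 0.884 → 0.908 over ten seeds), the signature by which denser
function words shorten motifs.

## Study sizes used in the checks

Simulation-based checks are scaled so the whole suite runs in well under a
minute of CPU: exponent recovery uses 20 replicates of 20,000 draws;
lawfulness uses one 4,000-token chunk run end to end (ZM R² ≈ 0.986, HP
R² ≈ 0.999); the type-I calibration of the comparison battery uses 100
seed pairs of two identical groups of 6 chunks × 2,000 tokens, where each
feature's flag rate at α = 0.05 stays within [0.01, 0.10].

## Known limitations

* The chi-square objective is minimized over raw (unpooled) classes;
  pooling applies to reported goodness of fit.  For very sparse spectra
  the two can differ slightly.
* ZM truncation `n` is fixed at the observed type count; treating `n` as
  free would change `b` substantially on short texts.
* With fewer than 4 rank classes (ZM) or 2 length classes (HP) fitting
  raises an insufficient-data error; the pipeline flags such chunks rather
  than failing the run.
* Degrees of freedom can floor at 0 for tiny spectra, in which case
  `P(X²)` is reported as NaN.
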