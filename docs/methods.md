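# Methods

## The quantity being estimated

A mature miRNA is only active in silencing while loaded in RISC, the
Argonaute-containing effector complex. Given paired small-RNA libraries
from the same cells — the **total** pool (all small RNAs ≤200 nt) and
the **IP** pool (RNAs co-immunoprecipitated with a pan-Ago antibody) —
each miRNA *i* is summarised by its percent share of the miRNA-aligned
reads in each library, and by the **RISC-association ratio**

    R_i = share_IP(i) / share_total(i).

Because both share vectors are normalised to 100%, R = 1 is the average
miRNA by construction: R_i > 1 means miRNA *i* occupies a larger slice
of the RISC-bound pool than of the cellular pool (selective loading or
retention), R_i < 1 the opposite. R is identified only up to this
"average" normalisation — absolute occupancies follow only under an
anchoring assumption (below).

Under the generative model used throughout (total pool sampled with
probability ∝ a_i, IP pool ∝ a_i·L_i, where a_i is cellular abundance
and L_i ∈ (0,1] the RISC-loaded fraction),

    E[R_i] ≈ L_i · Σ_j a_j / Σ_j a_j L_j,

so the ratio estimates the loading fraction up to one global constant.

Derived statistics:

- **Expression gate** — a miRNA is "expressed" when its share is ≥ 0.1%
  of the total pool and/or the IP pool (inclusive; gating on the total
  pool alone is available as `gate_mode="total"`).
- **2-fold classes** — `over` iff R > 2, `under` iff R < 1/2, strict
  inequalities at the boundary; the discrepancy count is the number of
  expressed miRNAs falling outside the 2-fold band.
- **Extreme spread** — max R / min R over expressed miRNAs with finite,
  non-pseudocounted ratios.
- **Implied RISC fraction** — anchoring the most-associated miRNA at
  100% RISC-bound, miRNA *i* is implied to be 100·R_i/R_max percent
  bound. This is an upper bound: if the anchor is itself <100% bound,
  every implied fraction shrinks proportionally.
- **Seed-family pooling** — miRNAs sharing the seed (positions 2–8,
  1-based) are sensed jointly by a reporter, so their reads are summed
  per pool before the ratio is recomputed; the pooled ratio is the
  ratio of summed shares, not the mean of member ratios.

## Read processing and exact matching

Reads are 3'-adapter trimmed (left-most full occurrence of the adapter;
otherwise the longest read suffix equal to an adapter prefix of ≥
`min_overlap` = 5 nt). The rule is applied to a fixpoint, which makes
trimming idempotent even on pathological inserts; on inserts free of
adapter-like suffixes one pass and the fixpoint coincide. Reads without
adapter evidence are dropped by default (`keep_untrimmed=False`): a
genuine ≤200-nt insert shorter than the read must exhibit the adapter.
Reads shorter than 15 nt after trimming are discarded.

Counting is exact substring matching with zero mismatches, no indels
and no clipping: a read counts toward a mature iff it is a contiguous
substring of the mature sequence (left-most offset reported). A read
matching k matures contributes 1/k to each (`multimap="fractional"`,
conserving total counts; a deterministic `"first"` lexicographic policy
is available). Reads containing N never match. Unmatched reads are kept
in an `unaligned` tally so aligned + unaligned equals the input count.
The implementation deduplicates identical read sequences before
matching; correctness is defined by equality with a naive all-pairs
substring oracle, which the test suite enforces on random instances.

Note the strictness cuts both ways: a read longer than every reference
mature — e.g. one carrying a 3' tail — aligns to nothing and leaves the
count table. This affects both pools of a given miRNA alike, so the
association ratio is robust to per-miRNA tailing-rate differences up to
a single global normalisation shift.

## Tail classification

The tail caller asks whether a read's 3' extension is *templated*
(encoded in a precursor hairpin) or a *non-templated addition*:

1. A read that is an exact substring of any hairpin is templated by
   construction; if a mature is a full prefix of it, it is reported as
   an untailed (possibly templated-extension) call, otherwise skipped.
2. Otherwise the read must begin with the complete sequence of some
   mature (a discrete 5' start, the strictest reading of shared 5'
   ends); among candidate prefixes the mature of length closest to the
   read's is chosen — equivalently the shortest extension — with ties
   broken lexicographically by id, so calls are independent of input
   order.
3. The extension is compared with the sequence immediately 3' of the
   mature's occurrence in every hairpin able to generate it (all
   occurrences, all linked hairpins). Any match ⇒ templated isomiR; no
   match ⇒ tailed. A config switch `extension_check="anywhere_in_hairpin"`
   implements the laxer alternative in which an extension found
   anywhere in a generating hairpin is deemed templated.

The classifier imposes no cap on tail length; reporting bins tails at
1, 2, 3 and ≥4 nt. Extensions containing N are "undetermined" and are
excluded from percent-tailed denominators. Summaries report, per miRNA
and pool, the percent of assigned reads that are tailed, the tail
sequence composition, the total/IP tail ratio (undefined and excluded
when the IP percentage is 0), and per-tail-sequence prevalence folds
between pools (prevalence measured among tailed reads).

## Downstream statistics

Pearson correlations (with two-sided p-values from the t transform,
n−2 df; no multiple-testing correction) connect association to
function: sensor repression — RLuc/FLuc relative to an empty control
construct set to 1 — is correlated against each target's percent share
of either the IP or the total pool. Shares enter on the linear scale by
default; a log2 option exists. Family targets use pooled shares. qPCR
values are normalised to a reference miRNA chosen for neutral loading
(ratio ≈ 1), optionally entering as Ct values via 2^−Ct; the RISC-
association change of a miRNA after target overexpression is
(IP/total)_condition / (IP/total)_control, all values reference-
normalised first.

## Synthetic data: what it emulates, and what not

The generator produces a reference (random matures of 19–23 nt, each
embedded in ≥1 hairpin of 65–90 nt with ≥4 nt of downstream context; a
configurable fraction embedded in two hairpins; rejection sampling
guarantees no mature occurs in an unrelated hairpin or inside another
mature) and paired libraries under the a_i / a_i·L_i model. Default
study conditions, chosen once:

| parameter | default | rationale |
|---|---|---|
| depth | 100 000 reads/pool | desk-scale library giving <1% relative error on percent-level shares |
| abundance a_i | lognormal, σ = 2.9 | a few miRNAs dominate; ≈7–8% of miRNAs clear the 0.1% gate, matching the observed ~76 of ~1000 detected |
| loading L_i | log-uniform over 3 decades | observed association spread of ≥3 orders of magnitude |
| tail rate t_i | log-uniform 0.002–0.2 | observed per-miRNA range, <0.3% to >20% |
| tail bases | A .4, T .4, C .15, G .05 | short A/T-rich tails with some C |
| tail length | uniform 1–3 nt | tails ≤3 nt |
| templated-extension rate | 0.05 | modest isomiR background to exercise the templated/tailed distinction |
| 5' jitter rate | 0.02 | ±1-nt 5' heterogeneity to exercise the discrete-5'-start filter |
| adapter | TruSeq small-RNA 3' adapter | standard kit chemistry |

Reads are insert + full adapter; a drawn tail is rejected (and redrawn)
whenever it equals the same-length templated continuation in any
generating hairpin, so truth labels are unambiguous; the resampling
count is reported. One integer seed drives everything through
per-stream `numpy` generators; identical seeds give byte-identical
FASTA/FASTQ (gzip mtime pinned to 0).

Deliberately not modelled: sequencing errors (an exact-match pipeline
would simply discard them; an error knob would only dilute depth),
ligation bias (a known caveat of real small-RNA libraries — estimated
shares inherit any such bias, which cancels between pools of the same
miRNA but not between miRNAs), 3' trimming (shortened isomiRs), and
multi-locus genomic copies beyond the two-hairpin option. Passing tests
on this generator therefore demonstrate correctness of the estimators
under the stated sampling model, not robustness to platform artefacts.

## Numerical and degenerate-input choices

- Shares are percentages summing to 100 within 1e−9 per pool; every
  statistic downstream of shares is invariant to rescaling all counts
  of one pool, except entries touched by the pseudocount (next item).
- A miRNA detected in exactly one pool receives a 0.5-read pseudocount
  in the empty pool before shares, keeping log2 ratios finite; such
  entries are flagged, excluded from the extreme spread, and — because
  the pseudocount is in absolute read units — are the one place where
  per-pool rescaling is not exactly neutral. Detected in neither pool ⇒
  excluded.
- Ratio of two zero shares is undefined (error); one-sided share-table
  inputs (no pseudocounting path) yield 0/∞ markers instead.
- The 0.1% gate is inclusive; the 2-fold class boundaries are strict.
- extreme_spread requires ≥2 finite positive ratios; Pearson requires
  n ≥ 3 and nonzero variance in both vectors.
- Tie-breaks (multi-mapping "first" policy, tail-caller candidate
  choice) are lexicographic by id, making every output independent of
  input ordering.

## Test problem sizes

The suite runs the full chain at 24 miRNAs × 100 000 reads per pool for
loading-fraction recovery (every estimated ratio within 3 delta-method
binomial standard errors of the model expectation), 10 miRNAs × 20 000
reads per pool for exact per-read tail-truth recovery, and 10 miRNAs ×
20 000 reads for the sensor-panel contrast, where repression is built
as a monotone function of loaded abundance over a panel of comparably
expressed miRNAs with 100-fold differential loading — the estimated
IP-share correlation must then exceed the total-share correlation in
magnitude. Property tests compare matching, linking and counting
against brute-force oracles on randomised instances, and verify
trimming idempotence and insert recovery on collision-free reads.
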