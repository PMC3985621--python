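# riscload

Differential RISC association of miRNAs from paired small-RNA
sequencing libraries.

Only the fraction of a miRNA loaded into RISC — the Argonaute-containing
RNA-induced silencing complex — can repress targets, and that fraction
varies enormously between miRNAs. `riscload` quantifies it from a pair
of small-RNA libraries sequenced from the same cells: the **total**
small-RNA pool and the **IP** pool recovered by pan-Ago
immunoprecipitation. It is aimed at small-RNA / RIP-seq analysts who
want per-miRNA loading statistics, isomiR-aware non-templated 3' tail
calls, and the downstream correlation readouts, with a simulator that
makes every stage testable against known ground truth.

## The statistic at the core

With each miRNA's abundance expressed as its percent share of the
miRNA-aligned reads in its library, the RISC-association ratio

    R_i = share_IP(i) / share_total(i)

compares miRNA *i* to the *average* miRNA (both share vectors sum to
100%, so R = 1 is the mean line). Around it the package computes the
≥0.1% expression gate, >2-fold over/under classes and discrepancy
counts, seed-family pooling (positions 2–8), the max/min extreme
spread, the implied absolute RISC-bound fraction under a 100%-bound
anchor, per-miRNA non-templated 3' tail percentages with total/IP tail
ratios and tail-sequence composition, and Pearson correlations of
sensor repression against RISC versus total shares. Reads are assigned
by exact, 0-mismatch substring matching; tails are extensions that no
generating hairpin templates. See `docs/methods.md` for the full model
and conventions.

## Worked example

`examples/01_simulate_and_quantify.py` simulates 20 miRNAs whose
loading fractions span three orders of magnitude, sequences 50 000
reads per pool, and runs the full chain:

```
20 miRNAs detected, 14 above the 0.1% gate
miRNA           %total     %IP   ratio   truth  class
syn-miR-0008     1.100   9.548    8.68    8.29  over
syn-miR-0017     0.110   0.531    4.83    5.73  over
syn-miR-0005     0.856   3.627    4.24    4.34  over
...
syn-miR-0011     1.716   0.041    0.02    0.02  under
syn-miR-0002    51.408   1.060    0.02    0.02  under

extreme spread 421-fold (syn-miR-0008 over, syn-miR-0002 under);
```

`ratio` is the estimated R_i and `truth` the generative expectation
L_i·Σa/Σ(aL): the most abundant miRNA here (51% of the total pool) is
~50-fold *under*-represented in RISC, while a miRNA at 1% of the total
pool dominates loading — total abundance does not predict effector
occupancy. The other examples cover tail classification
(`02_tailing_analysis.py`), the sensor-repression correlation contrast
(`03_sensor_correlation.py`, printing `r = -0.76` against RISC shares
versus `r = -0.30` against total shares on its panel), and the headline
arithmetic (`04_worked_arithmetic.py`).

The same chain is available from the shell:

```sh
riscload simulate --n-mirnas 20 --depth 50000 --seed 1 --outdir sim/
riscload run --mature sim/mature.fa --hairpin sim/hairpin.fa \
             --total sim/total.fastq.gz --ip sim/ip.fastq.gz --outdir out/
```

which writes `quant.tsv`, tail tables, a log2-log2 scatter export,
`stats.json` and a `report.json` embedding the resolved configuration.

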