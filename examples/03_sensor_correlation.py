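"""Correlate sensor repression with RISC versus total miRNA shares.

Emulates a dual-luciferase sensor panel: repression of each sensor is a
monotone function of the RISC-loaded abundance of its cognate miRNA.
The Pearson correlation of repression with the miRNA's share of the
RISC-associated pool is then compared with the correlation against its
share of the total pool.
"""

import numpy as np

from riscload import assoc_stats, matcher, mirref, readprep, riscquant, synth

n = 10
matures, hairpins = synth.simulate_reference(n, seed=5)
ids = [m.id for m in matures]
rng = np.random.default_rng(5)
manifest = synth.TruthManifest(
    abundance=dict(zip(ids, rng.lognormal(0, 0.6, n))),
    loading_fraction=dict(zip(ids, rng.permutation(np.logspace(-2, 0, n)))),
    tail_rate={m: 0.01 for m in ids},
    depth=20_000,
    seed=5,
)
sim = synth.simulate_libraries(matures, hairpins, manifest)
linked = mirref.link_matures(matures, hairpins)

reads_t, _ = readprep.prepare_reads(sim.reads_total, manifest.adapter)
reads_i, _ = readprep.prepare_reads(sim.reads_ip, manifest.adapter)
q = riscquant.quantify(
    matcher.count_pool(reads_t, linked, "total"),
    matcher.count_pool(reads_i, linked, "IP"),
).set_index("mirna_id")

# sensor relative expression: repressed in proportion to loaded abundance
loaded = {m: manifest.abundance[m] * manifest.loading_fraction[m] for m in ids}
scale = 100.0 / sum(loaded.values())
sensors = {m: 1.0 / (1.0 + 0.5 * v * scale) for m, v in loaded.items()}

r_risc, p_risc = assoc_stats.function_correlation(q["share_ip"].to_dict(), sensors)
r_total, p_total = assoc_stats.function_correlation(q["share_total"].to_dict(), sensors)
print(f"repression vs RISC share:  r = {r_risc:+.2f} (p = {p_risc:.3f})")
print(f"repression vs total share: r = {r_total:+.2f} (p = {p_total:.3f})")
print("\nthe RISC-pool share predicts sensor repression (strong negative r);")
print("the total-pool share does not, because loading varies ~100-fold")
print("independently of expression.")
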