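"""A small power experiment: detection probability vs phylogenetic signal.

Runs 60 filtering replicates cycling the Pagel-delta grid, bins them by the
realized Blomberg K of the host trait, and reports how often each detection
test fires.  (The full study conditions use hundreds of replicates; this is
a quick look.)
"""

from phylosym import SimulationConfig, bin_by_signal, run_set

config = SimulationConfig(
    scenario="filtering",
    deltas=(0.01, 0.1, 1.0, 10.0, 1000.0),
    metrics=("wunifrac",),
    methods=("mantel", "dendrogram"),
    n_perm=999,
    n_replicates=60,
    seed=2024,
    name="demo",
)
result = run_set(config)

binned = bin_by_signal(result.records)
print("replicates per K bin:")
print(binned["k_bin"].value_counts().sort_index().to_string())

print("\nper-bin detection proportion (p <= 0.05) and mean statistic:")
print(result.summary[result.summary["n"] > 0].to_string(index=False))

print(
    "\nExpected shape: Mantel detection climbs steeply with the host trait's "
    "Blomberg K\nwhile the dendrogram test lags behind; with K below ~0.25 "
    "both sit near the 5%\nfalse-positive floor, because without "
    "phylogenetic signal in the filtering trait\necological filtering "
    "cannot produce phylosymbiosis."
)
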