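"""Simulate a small study and detect the exogenous miRNAs spiked into it.

Builds the default synthetic world (human host genome with planted hairpins,
three exogenous species, six datasets from two studies), runs one dataset
through host filtering and exact catalog matching, and compares the recovered
counts with the simulator's ground truth.
"""

from exomir import (
    ReadSet,
    build_index,
    classify_reads,
    default_config,
    filter_host,
    simulate_study,
)

world, reads_by_dataset, truth = simulate_study(default_config(seed=1))
index = build_index(world.references, layers=world.layers)

meta = world.metadata[0]  # dataset d1, studyA, skin
reads = reads_by_dataset[meta.dataset_id]
entries: dict[str, int] = {}
for r in reads:
    entries[r] = entries.get(r, 0) + 1
readset = ReadSet(meta.dataset_id, len(reads), entries)

host, residual = filter_host(readset, index)
profile = classify_reads(residual, world.catalog, meta, world.taxonomy)

print(f"dataset {meta.dataset_id}: {readset.total_reads} reads total")
print(f"  host-filtered: {host.n_reads} reads ({host.n_unique} unique)")
print(f"  residual:      {residual.n_reads} reads, {profile.unassigned_reads} unassigned")
print("  exogenous hits (count = reads exactly equal to the mature):")
for hit in profile.hits:
    spiked = truth.datasets[meta.dataset_id].counts.get(hit.mirna_id, "shared")
    print(
        f"    {hit.mirna_id:<12} {hit.kingdom_class:<14} count={hit.count:<4}"
        f" rpm={hit.rpm:8.1f}  truth={spiked}"
    )
print(
    "\nEvery spiked count is recovered exactly: host filtering removes only\n"
    "host-derived reads, and exact matching has no losses on error-free reads.\n"
    "'shared' marks a mature credited because another species carries the\n"
    "identical sequence (the miR168a situation)."
)
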