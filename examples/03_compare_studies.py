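"""Intra- vs inter-study comparison of exo-miRNA profiles.

Datasets produced by the same laboratory share their contamination; datasets
from different laboratories mostly do not.  This script reproduces that
contrast on simulated data: shared fractions and Pearson correlations are
systematically higher for intra-study pairs.
"""

import numpy as np

from exomir import (
    ReadSet,
    build_index,
    classify_reads,
    compare_groups,
    default_config,
    filter_host,
    simulate_study,
)

world, reads_by_dataset, _ = simulate_study(default_config(seed=1))
index = build_index(world.references, layers=world.layers)

profiles = []
for meta in world.metadata:
    reads = reads_by_dataset[meta.dataset_id]
    entries: dict[str, int] = {}
    for r in reads:
        entries[r] = entries.get(r, 0) + 1
    _, residual = filter_host(ReadSet(meta.dataset_id, len(reads), entries), index)
    profiles.append(classify_reads(residual, world.catalog, meta, world.taxonomy))

results = compare_groups(
    profiles, {p.metadata.dataset_id: p.metadata.dataset_id for p in profiles}
)
print("pair        relation      shared%   r       p")
for res in results:
    print(
        f"{'-'.join(res.pair):<10}  {res.relation:<12} "
        f"{res.shared_pct:6.1f}  {res.r:+.3f}  {res.p_value:.2e}"
    )

intra = [r for r in results if r.relation == "intra_study"]
inter = [r for r in results if r.relation == "inter_study"]
print(
    f"\nmean intra-study r = {np.mean([r.r for r in intra]):+.3f}, "
    f"mean inter-study r = {np.mean([r.r for r in inter]):+.3f}"
)
print(
    "Strong intra-study agreement with weak/absent inter-study agreement is\n"
    "the signature of laboratory/process contamination rather than biology."
)
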