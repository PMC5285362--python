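"""Shared fixtures: taxonomy, small catalogs, profile factories, sim study."""

from __future__ import annotations

import pytest

from exomir.exo_classify import DatasetProfile, ExoHit, compute_rpm
from exomir.reference_io import (
    DatasetMetadata,
    SequenceRecord,
    build_mature_catalog,
    default_taxonomy,
    family_key_from_id,
)
from exomir.simulate import default_config, simulate_study


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def tiny_catalog(taxonomy):
    """Six matures over three species, incl. one sequence shared osa/zma."""
    records = [
        SequenceRecord("osa-miR156a", "TGACAGAAGAGAGTGAGCAC"),
        SequenceRecord("osa-miR168a", "TCGCTTGGTGCAGGTCGGGAA"),
        SequenceRecord("zma-miR168a", "TCGCTTGGTGCAGGTCGGGAA"),
        SequenceRecord("ebv-miR-BART1-5p", "TCTTAGTGGAAGTGACGTGCT"),
        SequenceRecord("ebv-miR-BHRF1-1", "TAACCTGATCAGCCCCGGAGT"),
        SequenceRecord("hsa-miR-21-5p", "TAGCTTATCAGACTGATGTTGA"),
    ]
    return build_mature_catalog(records, taxonomy)


def make_profile(
    dataset_id: str,
    counts: dict[str, int],
    total_reads: int = 1_000_000,
    study_id: str = "study1",
    source_label: str = "tissue",
    host_species_code: str = "hsa",
    host_kingdom: str = "animal",
    taxonomy=None,
) -> DatasetProfile:
    """Build a DatasetProfile directly from {mirna_id: count} (test shorthand)."""
    tax = taxonomy or default_taxonomy()
    hits = []
    for mid, count in sorted(counts.items()):
        species = mid.split("-", 1)[0]
        kingdom = tax.kingdom(species).value
        hits.append(
            ExoHit(
                mirna_id=mid,
                species_code=species,
                family_key=family_key_from_id(mid),
                kingdom_class="same_kingdom" if kingdom == host_kingdom else "other_kingdom",
                count=count,
                rpm=compute_rpm(count, total_reads),
            )
        )
    meta = DatasetMetadata(dataset_id, study_id, source_label, host_species_code)
    return DatasetProfile(metadata=meta, hits=hits, total_reads=total_reads)


@pytest.fixture(scope="session")
def study():
    """One fully simulated default study (world, reads, truth), seed 5."""
    return simulate_study(default_config(5))
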