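"""Exact matching of residual reads against the mature catalog.

A residual read (one that survived host filtering) is an exogenous miRNA hit
iff its sequence is exactly equal — full length, forward orientation, no
mismatches — to a catalog mature from a species other than the host.  Hits
are classified by source kingdom relative to the host and quantified as RPM
against the dataset's total read count.

When one read sequence is identical to matures of several exogenous species
(common for conserved plant families such as miR168), every matching species
is credited with the full read count; each hit carries a ``shared_with``
field listing the co-attributed species so consumers can deduplicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from exomir.errors import ValidationError
from exomir.read_prep import ReadSet
from exomir.reference_io import DatasetMetadata, MatureCatalog, TaxonomyTable


@dataclass(frozen=True)
class ExoHit:
    """One exogenous mature miRNA observed in one dataset."""

    mirna_id: str
    species_code: str
    family_key: str
    kingdom_class: str  # "same_kingdom" | "other_kingdom"
    count: int
    rpm: float
    shared_with: tuple[str, ...] = ()


@dataclass
class DatasetProfile:
    """All exogenous miRNA hits of one sequencing dataset."""

    metadata: DatasetMetadata
    hits: list[ExoHit]
    total_reads: int
    unassigned_reads: int = 0
    unassigned_unique: int = 0

    def hit_ids(self) -> set[str]:
        return {h.mirna_id for h in self.hits}

    def rpm_by_id(self) -> dict[str, float]:
        return {h.mirna_id: h.rpm for h in self.hits}

    def __post_init__(self) -> None:
        ids = [h.mirna_id for h in self.hits]
        if len(ids) != len(set(ids)):
            raise ValidationError("profile contains duplicate mirna_id hits")


def compute_rpm(count: int, total_reads: int) -> float:
    """Reads-per-million: count / total_reads * 1e6."""
    if total_reads <= 0:
        raise ZeroDivisionError("RPM undefined: total_reads must be > 0")
    return count / total_reads * 1e6


def classify_reads(
    residual: ReadSet,
    catalog: MatureCatalog,
    host: DatasetMetadata,
    taxonomy: TaxonomyTable,
) -> DatasetProfile:
    """Match residual reads exactly against the catalog and build a profile.

    Catalog entries of the host's own species are excluded before matching:
    "exogenous" is structural, not a post-hoc filter.  Unmatched residual
    reads are tallied in ``unassigned_reads``/``unassigned_unique``.
    """
    host_kingdom = taxonomy.kingdom(host.host_species_code)
    if residual.total_reads == 0:
        warnings.warn(
            f"dataset {residual.dataset_id}: empty library (total_reads 0); "
            "profile has no hits",
            stacklevel=2,
        )
        return DatasetProfile(metadata=host, hits=[], total_reads=0)

    hits: list[ExoHit] = []
    unassigned_reads = 0
    unassigned_unique = 0
    for seq, count in residual.entries.items():
        entries = [
            e
            for e in catalog.seq_index.get(seq, ())
            if e.species_code != host.host_species_code
        ]
        if not entries:
            unassigned_reads += count
            unassigned_unique += 1
            continue
        species_here = sorted({e.species_code for e in entries})
        for e in entries:
            kingdom_class = (
                "same_kingdom" if e.kingdom == host_kingdom else "other_kingdom"
            )
            hits.append(
                ExoHit(
                    mirna_id=e.mirna_id,
                    species_code=e.species_code,
                    family_key=e.family_key,
                    kingdom_class=kingdom_class,
                    count=count,
                    rpm=compute_rpm(count, residual.total_reads),
                    shared_with=tuple(
                        s for s in species_here if s != e.species_code
                    ),
                )
            )
    hits.sort(key=lambda h: h.mirna_id)
    return DatasetProfile(
        metadata=host,
        hits=hits,
        total_reads=residual.total_reads,
        unassigned_reads=unassigned_reads,
        unassigned_unique=unassigned_unique,
    )


def profile_to_frame(profile: DatasetProfile) -> pd.DataFrame:
    """Tabular view of a profile (one row per hit), as exported to TSV."""
    return pd.DataFrame(
        [
            {
                "dataset_id": profile.metadata.dataset_id,
                "mirna_id": h.mirna_id,
                "species_code": h.species_code,
                "family_key": h.family_key,
                "kingdom_class": h.kingdom_class,
                "count": h.count,
                "rpm": h.rpm,
                "shared_with": ",".join(h.shared_with),
            }
            for h in profile.hits
        ],
        columns=[
            "dataset_id", "mirna_id", "species_code", "family_key",
            "kingdom_class", "count", "rpm", "shared_with",
        ],
    )


def write_profile_tsv(profile: DatasetProfile, path) -> None:
    profile_to_frame(profile).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path, metadata: DatasetMetadata, total_reads: int | None = None) -> DatasetProfile:
    """Load a profile exported by :func:`write_profile_tsv`.

    ``total_reads`` may be omitted, in which case it is recovered from the
    first hit's count/RPM pair (exports carry RPM at full float precision).
    An export with zero hits then yields a profile with total_reads 0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"shared_with": str}, keep_default_na=False)
    if total_reads is None:
        if df.empty:
            total_reads = 0
        else:
            first = df.iloc[0]
            total_reads = round(first["count"] / first["rpm"] * 1e6)
    hits = [
        ExoHit(
            mirna_id=row["mirna_id"],
            species_code=row["species_code"],
            family_key=row["family_key"],
            kingdom_class=row["kingdom_class"],
            count=int(row["count"]),
            rpm=float(row["rpm"]),
            shared_with=tuple(s for s in str(row["shared_with"]).split(",") if s),
        )
        for row in df.to_dict("records")
    ]
    return DatasetProfile(metadata=metadata, hits=hits, total_reads=int(total_reads))
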