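"""Contamination-vs-genuine scoring of exogenous miRNAs.

Three features drive the judgment:

1. **Observed frequency** — a miRNA detected across many datasets from
   independent studies is better supported than a one-off.
2. **Evolutionary spread of the hosts** — the same exogenous miRNA turning
   up in hosts with no shared plausible acquisition route (a plant miRNA in
   both mammalian and bacterial libraries) points at a shared laboratory or
   sequencing-center contamination source, not biology.
3. **Source-species coverage** — if a species genuinely sheds miRNAs into
   another organism, many of its matures should appear, not just one or two;
   the coverage ratio is the percentage of the source species' cataloged
   matures observed anywhere in the profile collection.

A complementary host-similarity scan flags exogenous matures lying within a
relaxed mismatch bound (default 2) of host references: such sequences can be
host-derived reads in disguise and are the reason host mapping at one
mismatch (not two) is recommended before exogenous calling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from exomir.aggregate import SupportTable
from exomir.errors import ConfigurationError, ValidationError
from exomir.exo_classify import DatasetProfile
from exomir.host_filter import HostIndex, ScanHit, scan_occurrences
from exomir.reference_io import MatureCatalog, SequenceRecord, TaxonomyTable


@dataclass(frozen=True)
class ProvenanceThresholds:
    """Cutoffs turning the raw evidence features into a label.

    Defaults: at least 2 independent studies and 50% source-species coverage
    for a genuine candidate; observation in >= 3 host kingdoms, or in any
    blacklisted (source kingdom -> host kingdom) route, marks implausible
    spread.  The blacklist covers routes with no trophic/infective path:
    plant or animal miRNAs inside bacterial or protist libraries.
    """

    min_studies: int = 2
    coverage_pct: float = 50.0
    max_host_kingdoms: int = 2
    high_support: int = 5
    blacklist_routes: frozenset[tuple[str, str]] = frozenset(
        {
            ("plant", "bacteria"),
            ("plant", "protist"),
            ("animal", "bacteria"),
            ("animal", "protist"),
            ("fungi", "bacteria"),
        }
    )

    def validate(self) -> None:
        if self.min_studies < 1:
            raise ConfigurationError("min_studies must be >= 1")
        if not (0.0 <= self.coverage_pct <= 100.0):
            raise ConfigurationError("coverage_pct must be in [0, 100]")
        if self.max_host_kingdoms < 1:
            raise ConfigurationError("max_host_kingdoms must be >= 1")
        if self.high_support < 1:
            raise ConfigurationError("high_support must be >= 1")


@dataclass(frozen=True)
class ProvenanceReport:
    mirna_id: str
    species_code: str
    supporting_number: int
    n_studies: int
    host_clades: frozenset[str]
    host_kingdoms: frozenset[str]
    coverage_ratio_pct: float
    host_similar: bool
    label: str  # likely_contamination | candidate_genuine | ambiguous


def coverage_ratio(
    profiles: list[DatasetProfile], species_code: str, catalog: MatureCatalog
) -> float:
    """Percentage of the species' cataloged matures observed in any profile."""
    recorded = {e.mirna_id for e in catalog.species_entries(species_code)}
    if not recorded:
        raise ValidationError(
            f"species {species_code!r} has no entries in the mature catalog"
        )
    observed = {
        h.mirna_id
        for p in profiles
        for h in p.hits
        if h.species_code == species_code and h.mirna_id in recorded
    }
    return 100.0 * len(observed) / len(recorded)


def host_similarity_scan(
    sequence: str,
    host_references: Iterable[SequenceRecord] | HostIndex,
    max_mismatch: int = 2,
) -> list[ScanHit]:
    """All full-length occurrences of a mature in host references within
    ``max_mismatch`` substitutions, both strands (0-based forward offsets)."""
    return scan_occurrences(sequence, host_references, max_mismatch)


def _observation_spread(
    mirna_id: str, profiles: list[DatasetProfile], taxonomy: TaxonomyTable
) -> tuple[frozenset[str], frozenset[str]]:
    clades: set[str] = set()
    kingdoms: set[str] = set()
    for p in profiles:
        if any(h.mirna_id == mirna_id for h in p.hits):
            info = taxonomy.lookup(p.metadata.host_species_code)
            clades.add(info.clade)
            kingdoms.add(info.kingdom.value)
    return frozenset(clades), frozenset(kingdoms)


def score_provenance(
    support: SupportTable,
    profiles: list[DatasetProfile],
    catalog: MatureCatalog,
    taxonomy: TaxonomyTable,
    host_references: Iterable[SequenceRecord] | HostIndex | None = None,
    thresholds: ProvenanceThresholds = ProvenanceThresholds(),
) -> list[ProvenanceReport]:
    """Label every supported exo-miRNA likely_contamination, candidate_genuine
    or ambiguous from its evidence features.

    candidate_genuine: >= min_studies independent studies AND coverage ratio
    >= coverage_pct AND host spread within plausible bounds.
    likely_contamination: implausible host spread (too many kingdoms or a
    blacklisted source->host route) OR low coverage despite high support.
    Everything else: ambiguous.  Features are reported raw alongside the
    label so users can re-threshold without recomputation.
    """
    thresholds.validate()
    entries_by_id = {e.mirna_id: e for e in catalog.entries}
    host_index = None
    if host_references is not None:
        host_index = host_references  # scan_occurrences accepts either form
    coverage_cache: dict[str, float] = {}
    reports: list[ProvenanceReport] = []
    for mirna_id in sorted(support.entries):
        entry = entries_by_id.get(mirna_id)
        if entry is None:
            raise ValidationError(f"supported miRNA {mirna_id!r} not in catalog")
        sup = support[mirna_id]
        clades, kingdoms = _observation_spread(mirna_id, profiles, taxonomy)
        if entry.species_code not in coverage_cache:
            coverage_cache[entry.species_code] = coverage_ratio(
                profiles, entry.species_code, catalog
            )
        coverage = coverage_cache[entry.species_code]
        host_similar = False
        if host_index is not None:
            host_similar = bool(host_similarity_scan(entry.sequence, host_index))

        source_kingdom = entry.kingdom.value
        implausible_spread = len(kingdoms) > thresholds.max_host_kingdoms or any(
            (source_kingdom, hk) in thresholds.blacklist_routes for hk in kingdoms
        )
        n_studies = len(sup.study_ids)
        if implausible_spread or (
            coverage < thresholds.coverage_pct
            and sup.supporting_number >= thresholds.high_support
        ):
            label = "likely_contamination"
        elif (
            n_studies >= thresholds.min_studies
            and coverage >= thresholds.coverage_pct
        ):
            label = "candidate_genuine"
        else:
            label = "ambiguous"
        reports.append(
            ProvenanceReport(
                mirna_id=mirna_id,
                species_code=entry.species_code,
                supporting_number=sup.supporting_number,
                n_studies=n_studies,
                host_clades=clades,
                host_kingdoms=kingdoms,
                coverage_ratio_pct=coverage,
                host_similar=host_similar,
                label=label,
            )
        )
    return reports


def reports_to_frame(reports: list[ProvenanceReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": r.mirna_id,
                "species_code": r.species_code,
                "supporting_number": r.supporting_number,
                "n_studies": r.n_studies,
                "host_clades": ",".join(sorted(r.host_clades)),
                "host_kingdoms": ",".join(sorted(r.host_kingdoms)),
                "coverage_ratio_pct": r.coverage_ratio_pct,
                "host_similar": r.host_similar,
                "label": r.label,
            }
            for r in reports
        ]
    )


def write_provenance_tsv(reports: list[ProvenanceReport], path) -> None:
    reports_to_frame(reports).to_csv(path, sep="\t", index=False)


def write_similarity_tsv(
    hits_by_mirna: dict[str, list[ScanHit]], path
) -> None:
    """Host-similarity hits table; offsets are 0-based forward-strand."""
    rows = [
        {
            "mirna_id": mid,
            "ref_id": h.ref_id,
            "offset": h.offset,
            "strand": h.strand,
            "mismatches": h.mismatches,
        }
        for mid, hits in sorted(hits_by_mirna.items())
        for h in hits
    ]
    pd.DataFrame(
        rows, columns=["mirna_id", "ref_id", "offset", "strand", "mismatches"]
    ).to_csv(path, sep="\t", index=False)
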