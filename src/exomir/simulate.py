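"""Synthetic fixtures with full ground truth for the exo-miRNA pipeline.

The generator builds a complete miniature study: a host genome with planted
pre-miRNA hairpins, transcript and hairpin reference layers, a mature catalog
spanning the host plus configurable exogenous species (with optional
identical-sequence matures shared between two species, the miR168a
situation), a taxonomy and dataset metadata table, and per-dataset read
files drawn by a seeded multinomial over host windows, verbatim exogenous
spikes, and rejection-sampled noise.

Construction gives unambiguous classification truth: exogenous matures are
rejection-sampled to share no near-identical window with host references
(unless explicitly planted as host-similar, with a controlled number of
substitutions and copies), and noise reads are kept at least two mismatches
away from both host windows and catalog matures.  Every downstream count the
pipeline recovers can therefore be checked for exact equality against the
recorded truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from exomir.errors import ConfigurationError, ValidationError
from exomir.host_filter import ScanHit, build_index, matches_host, scan_occurrences
from exomir.reference_io import (
    Kingdom,
    MatureCatalog,
    SequenceRecord,
    SpeciesInfo,
    TaxonomyTable,
    DatasetMetadata,
    build_mature_catalog,
    default_taxonomy,
    revcomp,
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ExoSpeciesSpec:
    """One exogenous species contributing matures to the catalog."""

    code: str
    name: str
    clade: str
    kingdom: str
    n_matures: int = 8


@dataclass(frozen=True)
class PlantedSimilar:
    """Request to plant near-copies of a mature into the host genome.

    ``mismatches`` substitutions per copy; the mature itself is additionally
    rejection-sampled so those planted copies are its *only* host windows
    within that bound.
    """

    mirna_id: str
    mismatches: int = 2
    copies: int = 2


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    study_id: str
    source_label: str
    total_reads: int
    spikes: dict[str, float] = field(default_factory=dict)  # mirna_id -> proportion
    host_proportion: float = 0.9


@dataclass
class SimConfig:
    """Full description of a synthetic study; the seed determines everything."""

    seed: int
    host_species_code: str = "hsa"
    genome_length: int = 20_000
    n_transcripts: int = 5
    transcript_length: int = 800
    n_host_mirnas: int = 10
    mature_len_range: tuple[int, int] = (20, 22)
    exo_species: list[ExoSpeciesSpec] = field(default_factory=list)
    shared_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_similar: list[PlantedSimilar] = field(default_factory=list)
    datasets: list[DatasetSpec] = field(default_factory=list)
    read_len_range: tuple[int, int] = (18, 24)
    error_rate: float = 0.0

    def validate(self) -> None:
        if self.genome_length < 1000:
            raise ConfigurationError("genome_length must be >= 1000")
        for d in self.datasets:
            budget = d.host_proportion + sum(d.spikes.values())
            if budget > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"dataset {d.dataset_id}: proportions sum to {budget} > 1"
                )


@dataclass
class DatasetTruth:
    """Exact per-source read counts drawn for one dataset."""

    dataset_id: str
    counts: dict[str, int]  # keys: "host", "noise", and each spiked mirna_id
    n_error_reads: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class SimTruth:
    datasets: dict[str, DatasetTruth] = field(default_factory=dict)
    planted_hits: dict[str, list[ScanHit]] = field(default_factory=dict)


@dataclass
class SimWorld:
    config: SimConfig
    taxonomy: TaxonomyTable
    references: list[SequenceRecord]
    layers: list[str]
    mature_records: list[SequenceRecord]
    catalog: MatureCatalog
    metadata: list[DatasetMetadata]
    truth: SimTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly n_subs positions, each to a different base."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _place_nonoverlapping(
    rng: np.random.Generator,
    genome: list[str],
    occupied: list[tuple[int, int]],
    insert: str,
    max_tries: int = 1000,
) -> int:
    """Overwrite a free genome interval with *insert*; returns the offset."""
    L = len(insert)
    for _ in range(max_tries):
        start = int(rng.integers(0, len(genome) - L))
        if all(start + L <= a or start >= b for a, b in occupied):
            genome[start : start + L] = list(insert)
            occupied.append((start, start + L))
            return start
    raise ConfigurationError(
        "could not place a sequence without overlap; try a larger genome"
    )


def default_config(seed: int) -> SimConfig:
    """The bundled study design: a human host, three exogenous species
    (two plants sharing one mature sequence, one virus), six datasets from
    two studies with study-specific spike tables, and one plant mature
    planted into the host genome at two mismatches in two copies.

    Spike proportions (~1e-4..1e-3 per mature) and the 90% host fraction
    reflect the trace abundances at which exogenous miRNAs are reported in
    public small RNA-seq libraries.
    """
    exo = [
        ExoSpeciesSpec("osa", "Oryza sativa", "monocot", "plant", n_matures=10),
        ExoSpeciesSpec("zma", "Zea mays", "monocot", "plant", n_matures=8),
        ExoSpeciesSpec("ebv", "Epstein-Barr virus", "herpesvirus", "virus", n_matures=8),
    ]
    # Each study shares one spike table across its datasets — the intra-study
    # contamination pattern.  Proportions span roughly two orders of
    # magnitude (dominant contaminants like miR168a reach percent-level RPM
    # in public libraries; most sit orders of magnitude lower), which is
    # what makes abundance profiles informative for correlation.
    study_a_spikes = {
        "osa-miR101": 5e-3,
        "osa-miR102": 2e-3,
        "osa-miR103": 1e-3,
        "osa-miR105": 6e-4,
        "zma-miR201": 4e-4,
        "zma-miR202": 3e-4,
        "zma-miR203": 2e-4,
        "osa-miR106": 1.5e-4,
    }
    study_b_spikes = {
        "ebv-miR301": 8e-3,
        "ebv-miR302": 3e-3,
        "ebv-miR303": 1e-3,
        "ebv-miR304": 5e-4,
        "ebv-miR305": 2e-4,
        "osa-miR101": 4e-4,  # two matures recur across studies
        "osa-miR102": 1.5e-4,
    }
    datasets = [
        DatasetSpec("d1", "studyA", "skin", 20_000, dict(study_a_spikes), 0.90),
        DatasetSpec("d2", "studyA", "skin", 20_000, dict(study_a_spikes), 0.90),
        DatasetSpec("d3", "studyA", "skin", 20_000, dict(study_a_spikes), 0.90),
        DatasetSpec("d4", "studyB", "b_cell", 20_000, dict(study_b_spikes), 0.90),
        DatasetSpec("d5", "studyB", "b_cell", 20_000, dict(study_b_spikes), 0.90),
        DatasetSpec("d6", "studyB", "b_cell", 20_000, dict(study_b_spikes), 0.90),
    ]
    return SimConfig(
        seed=seed,
        exo_species=exo,
        shared_pairs=[("osa", "zma")],
        planted_similar=[PlantedSimilar("osa-miR104", mismatches=2, copies=2)],
        datasets=datasets,
    )


def _build_taxonomy(config: SimConfig) -> TaxonomyTable:
    base = default_taxonomy()
    entries = {
        config.host_species_code: base.lookup(config.host_species_code),
    }
    for sp in config.exo_species:
        entries[sp.code] = SpeciesInfo(sp.name, sp.clade, Kingdom(sp.kingdom))
    return TaxonomyTable(entries)


def generate_world(config: SimConfig) -> SimWorld:
    """Deterministically generate references, catalog, taxonomy and metadata.

    Exogenous matures are rejection-sampled against the host references: no
    full-length window within 1 mismatch (within ``planted.mismatches`` for
    matures that will be planted as host-similar, so the planted copies are
    their only near-matches).  Raises :class:`ConfigurationError` when
    rejection sampling fails repeatedly — the genome is too small.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    host = config.host_species_code

    genome = list(_random_seq(rng, config.genome_length))
    occupied: list[tuple[int, int]] = []

    # host matures embedded in hairpins (mature + loop + reverse complement)
    lo, hi = config.mature_len_range
    host_mature_recs: list[SequenceRecord] = []
    hairpins: list[SequenceRecord] = []
    for i in range(config.n_host_mirnas):
        mature = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        loop = _random_seq(rng, 8)
        hairpin = mature + loop + revcomp(mature)
        _place_nonoverlapping(rng, genome, occupied, hairpin)
        mid = f"{host}-miR{500 + i}"
        host_mature_recs.append(SequenceRecord(mid, mature))
        hairpins.append(SequenceRecord(f"{mid}-precursor", hairpin))

    # exogenous matures, rejection-sampled against provisional host refs
    planted_by_id = {p.mirna_id: p for p in config.planted_similar}
    provisional_genome = SequenceRecord("host_genome_1", "".join(genome))
    provisional_refs = [provisional_genome] + hairpins
    exo_recs: list[SequenceRecord] = []
    for si, sp in enumerate(config.exo_species):
        for j in range(sp.n_matures):
            mid = f"{sp.code}-miR{(si + 1) * 100 + j + 1}"
            reject_bound = planted_by_id[mid].mismatches if mid in planted_by_id else 1
            for attempt in range(500):
                cand = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                if any(cand == r.sequence for r in exo_recs):
                    continue
                if not scan_occurrences(cand, provisional_refs, reject_bound):
                    break
            else:
                raise ConfigurationError(
                    f"rejection sampling failed for {mid}; try a larger genome"
                )
            exo_recs.append(SequenceRecord(mid, cand))

    # identical-sequence matures shared between species pairs
    by_species = {sp.code: [r for r in exo_recs if r.id.startswith(sp.code + "-")]
                  for sp in config.exo_species}
    for a, b in config.shared_pairs:
        if not by_species.get(a):
            raise ConfigurationError(f"shared pair references unknown species {a!r}")
        donor = by_species[a][0]
        # same family name under the other species code, miR168a-style
        shared_id = f"{b}-{donor.id.split('-', 1)[1]}"
        exo_recs.append(SequenceRecord(shared_id, donor.sequence))

    # plant host-similar near-copies into the genome
    planted_hits: dict[str, list[ScanHit]] = {}
    mature_by_id = {r.id: r for r in host_mature_recs + exo_recs}
    for p in config.planted_similar:
        if p.mirna_id not in mature_by_id:
            raise ConfigurationError(f"planted_similar id {p.mirna_id!r} unknown")
        seq = mature_by_id[p.mirna_id].sequence
        hits: list[ScanHit] = []
        for _ in range(p.copies):
            variant = _mutate(rng, seq, p.mismatches)
            off = _place_nonoverlapping(rng, genome, occupied, variant)
            hits.append(ScanHit("host_genome_1", off, "+", p.mismatches))
        planted_hits[p.mirna_id] = sorted(hits, key=lambda h: h.offset)

    genome_rec = SequenceRecord("host_genome_1", "".join(genome))

    # transcript layer: windows of the final genome (adds no new content,
    # mirrors layered genome/transcript/ncRNA references).  Windows avoid
    # planted host-similar regions so those stay single-copy per planting.
    planted_intervals = [
        (h.offset, h.offset + len(mature_by_id[mid].sequence))
        for mid, hits in planted_hits.items()
        for h in hits
    ]
    transcripts: list[SequenceRecord] = []
    for t in range(config.n_transcripts):
        for _ in range(200):
            start = int(rng.integers(0, config.genome_length - config.transcript_length))
            end = start + config.transcript_length
            if all(end <= a or start >= b for a, b in planted_intervals):
                break
        else:
            raise ConfigurationError("cannot place transcripts off planted regions")
        transcripts.append(
            SequenceRecord(f"transcript_{t + 1}", genome_rec.sequence[start:end])
        )

    references = [genome_rec] + transcripts + hairpins
    layers = (
        ["genome"] + ["transcript"] * len(transcripts) + ["pre-miRNA"] * len(hairpins)
    )

    taxonomy = _build_taxonomy(config)
    mature_records = host_mature_recs + exo_recs
    catalog = build_mature_catalog(mature_records, taxonomy)
    metadata = [
        DatasetMetadata(d.dataset_id, d.study_id, d.source_label, host)
        for d in config.datasets
    ]

    # verify the planted-truth invariant on the final references
    for mid, hits in planted_hits.items():
        seq = mature_by_id[mid].sequence
        bound = planted_by_id[mid].mismatches
        found = scan_occurrences(seq, [genome_rec] + hairpins, bound)
        genome_hits = [h for h in found if h.ref_id == "host_genome_1"]
        if len(genome_hits) != len(hits):
            raise ConfigurationError(
                f"planted copies of {mid} collide with background genome; "
                "rerun with a different seed or larger genome"
            )

    return SimWorld(
        config=config,
        taxonomy=taxonomy,
        references=references,
        layers=layers,
        mature_records=mature_records,
        catalog=catalog,
        metadata=metadata,
        truth=SimTruth(planted_hits=planted_hits),
    )


def simulate_dataset(
    world: SimWorld, spec: DatasetSpec, seed: int
) -> tuple[list[str], DatasetTruth]:
    """Draw one dataset's reads by a seeded multinomial over sources.

    Sources are: host genome windows (either strand), each spiked mature
    (verbatim), and noise rejection-sampled to sit >= 2 mismatches from every
    host window and every catalog mature.  The returned truth records the
    exact count drawn per source; counts sum to ``spec.total_reads``.
    """
    rng = np.random.default_rng(seed)
    for mid in spec.spikes:
        if not any(r.id == mid for r in world.mature_records):
            raise ValidationError(f"spiked miRNA {mid!r} not in the catalog")
    spike_ids = sorted(spec.spikes)
    noise_prop = 1.0 - spec.host_proportion - sum(spec.spikes.values())
    if noise_prop < -1e-12:
        raise ConfigurationError("proportions exceed 1")
    probs = [spec.host_proportion] + [spec.spikes[m] for m in spike_ids] + [max(noise_prop, 0.0)]
    if spec.total_reads == 0:
        return [], DatasetTruth(spec.dataset_id, {"host": 0, "noise": 0, **{m: 0 for m in spike_ids}})
    draws = rng.multinomial(spec.total_reads, np.array(probs) / sum(probs))

    genome = world.references[0].sequence
    mature_by_id = {r.id: r for r in world.mature_records}
    lo, hi = world.config.read_len_range
    # small index over all references for noise rejection
    noise_index = build_index(world.references, k=9, max_mismatch=1, min_read_len=lo)
    mature_seqs = [r.sequence for r in world.mature_records]

    reads: list[str] = []
    counts: dict[str, int] = {}
    # host: random genome windows, either strand
    counts["host"] = int(draws[0])
    n_host = counts["host"]
    lengths = rng.integers(lo, hi + 1, size=n_host)
    starts = rng.integers(0, len(genome) - hi, size=n_host)
    strands = rng.integers(0, 2, size=n_host)
    for L, start, flip in zip(lengths, starts, strands):
        window = genome[start : start + L]
        reads.append(revcomp(window) if flip else window)
    # spikes: verbatim matures
    for mid, n in zip(spike_ids, draws[1:-1]):
        counts[mid] = int(n)
        reads.extend([mature_by_id[mid].sequence] * int(n))
    # noise: >= 2 mismatches from host windows and catalog matures
    counts["noise"] = int(draws[-1])
    for _ in range(counts["noise"]):
        for attempt in range(200):
            cand = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            if matches_host(cand, noise_index, max_mismatch=1):
                continue
            if any(
                len(cand) == len(m)
                and sum(a != b for a, b in zip(cand, m)) <= 1
                for m in mature_seqs
            ):
                continue
            reads.append(cand)
            break
        else:
            raise ConfigurationError("noise rejection sampling failed")

    n_error_reads = 0
    if world.config.error_rate > 0:
        mutated = []
        for r in reads:
            mask = rng.random(len(r)) < world.config.error_rate
            if mask.any():
                chars = list(r)
                for pos in np.flatnonzero(mask):
                    alternatives = [b for b in "ACGT" if b != chars[pos]]
                    chars[pos] = alternatives[rng.integers(3)]
                mutated.append("".join(chars))
                n_error_reads += 1
            else:
                mutated.append(r)
        reads = mutated

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = DatasetTruth(spec.dataset_id, counts, n_error_reads=n_error_reads)
    assert truth.total == spec.total_reads
    return reads, truth


def write_fastq(reads: list[str], path) -> None:
    """Write reads as FASTQ with a fixed dummy quality ('I')."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_world(world: SimWorld, outdir) -> dict[str, str]:
    """Write the world's reference FASTAs, catalog, taxonomy and metadata.

    Returns {relative filename: sha256 of contents} for determinism checks.
    """
    from pathlib import Path

    from exomir.reference_io import write_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(world.references, out / "host_references.fa")
    write_fasta(world.mature_records, out / "mature_catalog.fa")
    tax_lines = ["species_code\tspecies_name\tclade\tkingdom"]
    for code in world.taxonomy.codes():
        info = world.taxonomy.lookup(code)
        tax_lines.append(
            f"{code}\t{info.species_name}\t{info.clade}\t{info.kingdom.value}"
        )
    (out / "taxonomy.tsv").write_text("\n".join(tax_lines) + "\n")
    meta_lines = ["dataset_id\tstudy_id\tsource_label\thost_species_code"]
    for m in world.metadata:
        meta_lines.append(
            f"{m.dataset_id}\t{m.study_id}\t{m.source_label}\t{m.host_species_code}"
        )
    (out / "metadata.tsv").write_text("\n".join(meta_lines) + "\n")
    digests = {}
    for p in sorted(out.iterdir()):
        if p.is_file():
            digests[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return digests


def simulate_study(
    config: SimConfig,
) -> tuple[SimWorld, dict[str, list[str]], SimTruth]:
    """Generate the world and all configured datasets in one call.

    Per-dataset seeds are derived deterministically from the config seed.
    Returns (world, reads per dataset_id, truth with all dataset entries).
    """
    world = generate_world(config)
    truth = world.truth
    reads_by_dataset: dict[str, list[str]] = {}
    for i, d in enumerate(config.datasets):
        ds_seed = (config.seed * 100_003 + i * 7919 + 1) % (2**31 - 1)
        reads, dt = simulate_dataset(world, d, ds_seed)
        reads_by_dataset[d.dataset_id] = reads
        truth.datasets[d.dataset_id] = dt
    return world, reads_by_dataset, truth

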