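"""Reference input/output: FASTA sequences, taxonomy, mature-miRNA catalog, metadata.

All sequences are normalized at load time to an uppercase DNA alphabet
(``U`` -> ``T``), so that every downstream comparison — host filtering and
exact catalog matching alike — happens in a single alphabet.  Mature miRNA
identifiers follow miRBase conventions: a three-letter species prefix
(``osa-miR156a``, ``ebv-miR-BART1-5p``) from which the source species, and
through the taxonomy its kingdom, are resolved.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from exomir.errors import ParseError, ValidationError

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str, context: str = "sequence") -> str:
    """Uppercase, substitute U->T, and validate the {A,C,G,T,N} alphabet."""
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise ParseError(f"empty sequence for {context}")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ParseError(
            f"{context}: characters outside DNA alphabet: {sorted(bad)}"
        )
    return seq


class Kingdom(str, Enum):
    animal = "animal"
    plant = "plant"
    virus = "virus"
    protist = "protist"
    bacteria = "bacteria"
    fungi = "fungi"
    other = "other"


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence (reference contig, transcript, or mature miRNA)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("SequenceRecord id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"SequenceRecord {self.id!r}: empty sequence")


@dataclass(frozen=True)
class SpeciesInfo:
    species_name: str
    clade: str
    kingdom: Kingdom


class TaxonomyTable:
    """Maps miRBase species codes (e.g. ``osa``) to name, clade and kingdom.

    Lookups of unknown codes raise ``KeyError`` — the kingdom of a species is
    never silently guessed from its code.
    """

    def __init__(self, entries: dict[str, SpeciesInfo]):
        self._entries = dict(entries)

    def lookup(self, species_code: str) -> SpeciesInfo:
        try:
            return self._entries[species_code]
        except KeyError:
            raise KeyError(
                f"species code {species_code!r} not present in taxonomy"
            ) from None

    def kingdom(self, species_code: str) -> Kingdom:
        return self.lookup(species_code).kingdom

    def __contains__(self, species_code: str) -> bool:
        return species_code in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def codes(self) -> list[str]:
        return sorted(self._entries)


@dataclass(frozen=True)
class MatureEntry:
    mirna_id: str
    species_code: str
    family_key: str
    sequence: str
    kingdom: Kingdom


@dataclass
class MatureCatalog:
    """Species/kingdom/family-annotated mature miRNAs with a sequence index.

    Identical sequences occurring in several species (the miR168a situation,
    where many plant genomes encode the same mature) are all retained;
    ``seq_index`` maps each distinct sequence to every entry carrying it.
    """

    entries: list[MatureEntry]
    seq_index: dict[str, list[MatureEntry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.seq_index:
            index: dict[str, list[MatureEntry]] = {}
            for e in self.entries:
                index.setdefault(e.sequence, []).append(e)
            self.seq_index = index

    def species_entries(self, species_code: str) -> list[MatureEntry]:
        return [e for e in self.entries if e.species_code == species_code]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DatasetMetadata:
    """One sequencing dataset: id, owning study/lab series, source, host."""

    dataset_id: str
    study_id: str
    source_label: str
    host_species_code: str


# --- FASTA ------------------------------------------------------------------

def load_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into normalized :class:`SequenceRecord` objects.

    Sequences are uppercased with U->T substitution; duplicate ids and empty
    sequences are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seen:
                raise ValidationError(f"duplicate FASTA id {rec.id!r} in {path}")
            seen.add(rec.id)
            seq = normalize_sequence(str(rec.seq), context=f"FASTA record {rec.id!r}")
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(SequenceRecord(rec.id, seq, desc))
    except ValueError as exc:  # Biopython's malformed-FASTA signal
        raise ParseError(f"{path}: {exc}") from None
    if not records:
        # distinguish "no FASTA entries" from an unreadable file
        with open(path) as fh:
            head = fh.read(1)
        if head not in (">", ""):
            raise ParseError(f"{path}: not FASTA-formatted (no '>' header)")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records as FASTA; round-trips bit-identically through load_fasta."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# --- Taxonomy ---------------------------------------------------------------

def load_taxonomy(path) -> TaxonomyTable:
    """Load a TSV with columns species_code, species_name, clade, kingdom."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_code", "species_name", "clade", "kingdom"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"taxonomy {path}: missing columns {sorted(missing)}")
    return _taxonomy_from_frame(df, origin=str(path))


def _taxonomy_from_frame(df: pd.DataFrame, origin: str) -> TaxonomyTable:
    entries: dict[str, SpeciesInfo] = {}
    for row in df.itertuples(index=False):
        code = row.species_code
        if code in entries:
            raise ValidationError(f"taxonomy {origin}: duplicate species code {code!r}")
        try:
            kingdom = Kingdom(row.kingdom)
        except ValueError:
            raise ValidationError(
                f"taxonomy {origin}: unknown kingdom {row.kingdom!r} for {code!r} "
                f"(expected one of {[k.value for k in Kingdom]})"
            ) from None
        entries[code] = SpeciesInfo(row.species_name, row.clade, kingdom)
    return TaxonomyTable(entries)


#: Bundled default taxonomy for common miRBase species prefixes.  Covers the
#: codes used by the bundled simulator and the usual suspects of xenomiR
#: studies; anything else must be supplied explicitly.
_DEFAULT_TAXONOMY_TSV = """\
species_code\tspecies_name\tclade\tkingdom
hsa\tHomo sapiens\tmammal\tanimal
mmu\tMus musculus\tmammal\tanimal
rno\tRattus norvegicus\tmammal\tanimal
ssc\tSus scrofa\tmammal\tanimal
bta\tBos taurus\tmammal\tanimal
ptr\tPan troglodytes\tmammal\tanimal
mml\tMacaca mulatta\tmammal\tanimal
gga\tGallus gallus\tbird\tanimal
dre\tDanio rerio\tfish\tanimal
cel\tCaenorhabditis elegans\tnematode\tanimal
dme\tDrosophila melanogaster\tinsect\tanimal
bfl\tBranchiostoma floridae\tcephalochordate\tanimal
nve\tNematostella vectensis\tcnidarian\tanimal
osa\tOryza sativa\tmonocot\tplant
zma\tZea mays\tmonocot\tplant
tae\tTriticum aestivum\tmonocot\tplant
ath\tArabidopsis thaliana\teudicot\tplant
gma\tGlycine max\teudicot\tplant
mdm\tMalus domestica\teudicot\tplant
han\tHelianthus annuus\teudicot\tplant
ebv\tEpstein-Barr virus\therpesvirus\tvirus
kshv\tKaposi sarcoma herpesvirus\therpesvirus\tvirus
hcmv\tHuman cytomegalovirus\therpesvirus\tvirus
tbr\tTrypanosoma brucei\tkinetoplastid\tprotist
eco\tEscherichia coli\tproteobacteria\tbacteria
sce\tSaccharomyces cerevisiae\tascomycete\tfungi
"""


def default_taxonomy() -> TaxonomyTable:
    """The bundled taxonomy covering common miRBase species codes."""
    df = pd.read_csv(io.StringIO(_DEFAULT_TAXONOMY_TSV), sep="\t", dtype=str)
    return _taxonomy_from_frame(df, origin="<bundled default>")


# --- Dataset metadata -------------------------------------------------------

def load_metadata(path, taxonomy: TaxonomyTable) -> list[DatasetMetadata]:
    """Load TSV with columns dataset_id, study_id, source_label, host_species_code."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"dataset_id", "study_id", "source_label", "host_species_code"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"metadata {path}: missing columns {sorted(missing)}")
    out: list[DatasetMetadata] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.dataset_id in seen:
            raise ValidationError(f"metadata {path}: duplicate dataset_id {row.dataset_id!r}")
        seen.add(row.dataset_id)
        if row.host_species_code not in taxonomy:
            raise ValidationError(
                f"metadata {path}: host species {row.host_species_code!r} not in taxonomy"
            )
        out.append(
            DatasetMetadata(row.dataset_id, row.study_id, row.source_label, row.host_species_code)
        )
    return out


# --- Mature catalog ---------------------------------------------------------

_ID_RE = re.compile(r"^(?P<species>[a-z]{2,4})-(?P<name>.+)$")
_ARM_SUFFIX_RE = re.compile(r"-(5p|3p)$")
_VARIANT_LETTER_RE = re.compile(r"[a-z]$")


def family_key_from_id(mirna_id: str) -> str:
    """Derive a miRNA family key from a miRBase-style mature id.

    The species prefix is stripped, then an arm suffix (``-5p``/``-3p``), then
    a single trailing lowercase variant letter: ``osa-miR156a`` -> ``miR156``,
    ``ebv-miR-BART1-5p`` -> ``miR-BART1``, ``cel-let-7a`` -> ``let-7``.
    Numeric locus suffixes (``-1``, ``-2``) are kept as-is.
    """
    m = _ID_RE.match(mirna_id)
    if not m:
        raise ValidationError(
            f"mature id {mirna_id!r} lacks a parsable species prefix "
            "(expected '<code>-<name>')"
        )
    name = m.group("name")
    name = _ARM_SUFFIX_RE.sub("", name)
    name = _VARIANT_LETTER_RE.sub("", name)
    return name


def build_mature_catalog(
    records: Iterable[SequenceRecord], taxonomy: TaxonomyTable
) -> MatureCatalog:
    """Classify mature miRNA records by source species, kingdom and family.

    Identifiers must carry a miRBase species prefix resolvable in *taxonomy*;
    identical sequences shared across species are all retained.
    """
    entries: list[MatureEntry] = []
    for rec in records:
        m = _ID_RE.match(rec.id)
        if not m:
            raise ValidationError(
                f"mature id {rec.id!r} lacks a parsable species prefix"
            )
        species = m.group("species")
        if species not in taxonomy:
            raise ValidationError(
                f"mature {rec.id!r}: species code {species!r} not in taxonomy"
            )
        entries.append(
            MatureEntry(
                mirna_id=rec.id,
                species_code=species,
                family_key=family_key_from_id(rec.id),
                sequence=rec.sequence,
                kingdom=taxonomy.kingdom(species),
            )
        )
    ids = [e.mirna_id for e in entries]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate mature ids in catalog: {dupes}")
    return MatureCatalog(entries=entries)
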