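"""Sequence normalization, FASTA/FASTQ I/O and reference-library loading.

Internally every sequence is RNA (uppercase, ``T`` mapped to ``U``); mature
miRNA references are natively RNA while sequencer reads arrive as DNA, so
normalization happens once on ingest and FASTQ can be written back in either
alphabet.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqParseError, MalformedSequenceError, ReferenceFormatError

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")
_INPUT_ALPHABET = frozenset("ACGTUNacgtun")

#: miRNA classes recognised in reference libraries.
RNA_CLASSES = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA")

_CLASS_KEYWORDS = {
    "rrna": "rRNA",
    "trna": "tRNA",
    "snrna": "snRNA",
    "snorna": "snoRNA",
    "mirna": "miRNA",
}


def normalize_sequence(raw: str) -> str:
    """Uppercase a sequence and map T to U, validating the alphabet.

    ``N`` is retained so that reads containing ambiguous calls can later be
    classified as artifacts. Any other character raises
    :class:`MalformedSequenceError` naming the (1-based) offending position.
    """
    if not raw:
        raise ValueError("empty sequence")
    for i, ch in enumerate(raw):
        if ch not in _INPUT_ALPHABET:
            raise MalformedSequenceError(raw, i + 1)
    return raw.upper().replace("T", "U")


def to_dna(sequence: str) -> str:
    """Render a normalized RNA sequence in the DNA alphabet (U -> T)."""
    return sequence.replace("U", "T")


@dataclass
class SmallRNARead:
    """A single sequencing read with a normalized RNA sequence.

    ``quality`` is the Phred+33 string as read from the FASTQ file (same
    length as ``sequence``), or ``None`` for quality-less reads.
    ``clipped`` records whether the 3' adapter was found and removed.
    """

    read_id: str
    sequence: str
    quality: str | None = None
    clipped: bool | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FastqParseError(
                f"sequence length {len(self.sequence)} != quality length "
                f"{len(self.quality)} for read {self.read_id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phred(self) -> list[int] | None:
        """Per-base Phred scores decoded from the quality string."""
        if self.quality is None:
            return None
        return [ord(c) - 33 for c in self.quality]


@dataclass(frozen=True)
class UniqueTag:
    """A collapsed unique sequence and the number of reads carrying it."""

    sequence: str
    count: int


def read_fastq(path: str | Path) -> Iterator[SmallRNARead]:
    """Stream reads from a 4-line-record FASTQ file, normalizing sequences.

    Read ids are preserved verbatim.  A truncated record or a
    sequence/quality length mismatch raises :class:`FastqParseError` carrying
    the 1-based record index.  An empty file yields nothing.
    """
    index = 0
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            index += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:  # Biopython's malformed-record signal
                raise FastqParseError(str(exc), record_index=index) from exc
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"sequence length {len(seq)} != quality length {len(qual)}",
                    record_index=index,
                )
            yield SmallRNARead(read_id=title, sequence=normalize_sequence(seq),
                               quality=qual)


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path,
                alphabet: str = "RNA") -> int:
    """Write reads to FASTQ; returns the number of records written.

    ``alphabet`` selects whether sequences are emitted as stored (RNA) or
    back-translated to DNA, matching the alphabet of the original source.
    """
    if alphabet not in ("RNA", "DNA"):
        raise ValueError(f"alphabet must be 'RNA' or 'DNA', got {alphabet!r}")
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            seq = read.sequence if alphabet == "RNA" else to_dna(read.sequence)
            qual = read.quality if read.quality is not None else "I" * len(seq)
            handle.write(f"@{read.read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Reference libraries
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^([A-Za-z]{3,4})-(.+)$")
_ARM_SUFFIX_RE = re.compile(r"-(5p|3p)$")
_FAMILY_RE = re.compile(r"^(miR\d+)", re.IGNORECASE)


@dataclass
class ReferenceEntry:
    """One mature miRNA or ncRNA reference record."""

    accession: str
    species_code: str
    name: str
    family: str
    rna_class: str
    sequence: str
    arm: str = "unspecified"  # mature | star | unspecified

    @property
    def full_name(self) -> str:
        return f"{self.species_code}-{self.name}"


def derive_family(name: str) -> str:
    """Derive the family label from a member name.

    Strips a species prefix if present, then the arm suffix (``-5p``/``-3p``)
    and trailing star marker, then ``.N`` variant suffixes and trailing
    lowercase letters: ``mol-miR159b.1`` -> ``miR159``,
    ``miR156f-5p`` -> ``miR156``.  Names without a ``miR<digits>`` stem are
    returned unchanged (minus prefix/suffixes).
    """
    m = _NAME_RE.match(name)
    if m and _FAMILY_RE.match(m.group(2)):
        name = m.group(2)
    name = name.rstrip("*")
    name = _ARM_SUFFIX_RE.sub("", name)
    name = re.sub(r"\.\d+$", "", name)
    fam = _FAMILY_RE.match(name)
    if fam:
        return fam.group(1)
    return name


def arm_from_name(name: str) -> str:
    """Arm annotation implied by a member name suffix.

    By the reporting convention used here the 5' arm is the mature (miR)
    strand and the 3' arm the star (miR*) strand; a trailing ``*`` also marks
    the star arm.  Without a suffix the arm is unspecified.
    """
    if name.endswith("*"):
        return "star"
    m = _ARM_SUFFIX_RE.search(name)
    if m:
        return "mature" if m.group(1) == "5p" else "star"
    return "unspecified"


def load_reference(path: str | Path, species_map: dict[str, str] | None = None,
                   class_map: dict[str, str] | None = None,
                   default_class: str = "miRNA",
                   default_species: str | None = None) -> list[ReferenceEntry]:
    """Load a FASTA reference library into :class:`ReferenceEntry` records.

    Headers are expected to carry species-prefixed names (``>ath-miR166a``);
    otherwise the first header token is treated as an accession resolvable
    through ``species_map``/``class_map``, falling back to
    ``default_species``/``default_class``.  Duplicate (species, name,
    sequence) triples collapse to one entry with a logged warning.
    """
    species_map = species_map or {}
    class_map = class_map or {}
    entries: list[ReferenceEntry] = []
    seen: set[tuple[str, str, str]] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        token = record.id
        description = record.description
        sequence = normalize_sequence(str(record.seq))
        m = _NAME_RE.match(token)
        if m and _FAMILY_RE.match(m.group(2)):
            species, name = m.group(1).lower(), m.group(2)
        elif token in species_map:
            species, name = species_map[token], token
        elif default_species is not None:
            species, name = default_species, token
        else:
            raise ReferenceFormatError(
                f"header {token!r} cannot be resolved to a species code"
            )
        rna_class = class_map.get(token)
        if rna_class is None:
            rna_class = _guess_class(description) or default_class
        key = (species, name, sequence)
        if key in seen:
            logger.warning("duplicate reference record %s-%s collapsed", species, name)
            continue
        seen.add(key)
        entries.append(ReferenceEntry(
            accession=token,
            species_code=species,
            name=name,
            family=derive_family(name) if rna_class == "miRNA" else name,
            rna_class=rna_class,
            sequence=sequence,
            arm=arm_from_name(name) if rna_class == "miRNA" else "unspecified",
        ))
    return entries


def _guess_class(description: str) -> str | None:
    lowered = description.lower()
    for keyword, rna_class in _CLASS_KEYWORDS.items():
        if keyword in lowered:
            return rna_class
    return None


def write_reference(entries: Iterable[ReferenceEntry], path: str | Path) -> int:
    """Serialize reference entries to FASTA (``>species-name`` headers)."""
    n = 0
    with open(path, "w") as handle:
        for entry in entries:
            handle.write(f">{entry.species_code}-{entry.name} {entry.rna_class}\n")
            handle.write(entry.sequence + "\n")
            n += 1
    return n


@dataclass
class StageCounts:
    """Ordered read/tag accounting across the filtering cascade."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, entering: int, surviving: int) -> None:
        if surviving > entering:
            raise ValueError(f"stage {stage!r}: surviving {surviving} > entering {entering}")
        self.rows.append((stage, entering, surviving))

    def extend(self, other: "StageCounts") -> None:
        self.rows.extend(other.rows)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rows, columns=["stage", "entering", "surviving"]).assign(
            discarded=lambda df: df.entering - df.surviving
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
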