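"""Synthetic small-RNA libraries with known ground truth.

The generator emulates the salient features of a real plant seed small-RNA
library so that every downstream stage is testable without a sequencing
deposit: an insert-length distribution peaked at 21 and 24 nt, per-miRNA
abundances skewed over about four orders of magnitude (log-normal weights),
miR/miR* duplex arms, cross-species copies of a subset of mature sequences
(to exercise conservation scoring), animal miRNAs at controlled Hamming
distance from plant ones (to exercise the cross-kingdom comparison), ncRNA
and mRNA-degradation contamination, and 3' adapter read-through on a
fixed-length sequencer read.  The seed fully determines all outputs, and a
:class:`TruthManifest` records the exact planted composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ReferenceEntry, SmallRNARead, normalize_sequence
from .errors import ConfigError

_BASES = np.array(list("ACGU"))

#: Insert-length weights emulating the observed bimodal 21/24-nt profile.
DEFAULT_LENGTH_WEIGHTS = {18: 0.03, 19: 0.05, 20: 0.08, 21: 0.34,
                          22: 0.10, 23: 0.10, 24: 0.30}

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimulationConfig:
    """Study conditions of a simulated library.

    Defaults are chosen to mirror a seed small-RNA library at desk scale:
    50,000 reads (the real library had tens of millions), log-normal
    abundance weights with sigma 1.8 spreading planted counts over roughly
    four orders of magnitude, 15% structural-ncRNA and 10% mRNA-degradation
    contamination, and 1x50 reads with full 3' adapter read-through.
    """

    seed: int = 0
    n_reads: int = 50_000
    n_plant_species: int = 5
    n_families: int = 20
    members_per_family: tuple[int, int] = (1, 8)
    mature_length_range: tuple[int, int] = (18, 24)
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    abundance_sigma: float = 1.8
    explicit_abundances: dict[str, int] | None = None
    star_fraction: float = 0.3
    shared_fraction: float = 0.3
    n_novel: int = 2
    ncrna_fraction: float = 0.15
    degradation_fraction: float = 0.10
    n_ncrna_refs: int = 8
    ncrna_length_range: tuple[int, int] = (80, 300)
    n_decoys: int = 4
    decoy_length: int = 400
    fragment_length_range: tuple[int, int] = (15, 35)
    n_animal: int = 30
    animal_mimic_fraction: float = 0.3
    animal_mimic_distances: tuple[int, ...] = (0, 1, 2, 3)
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 50
    error_rate: float = 0.0
    base_quality: int = 36
    error_quality: int = 5
    focal_species: str = "mol"

    def __post_init__(self) -> None:
        for frac in (self.ncrna_fraction, self.degradation_fraction,
                     self.star_fraction, self.shared_fraction,
                     self.animal_mimic_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if self.ncrna_fraction + self.degradation_fraction > 1.0:
            raise ConfigError("contamination fractions must sum to <= 1")
        if len(self.adapter) < 5:
            raise ConfigError("adapter must be >= 5 nt (adapter detection "
                              "needs a minimum anchor)")
        lo, hi = self.members_per_family
        if not 1 <= lo <= hi:
            raise ConfigError("members_per_family range must satisfy 1 <= lo <= hi")
        lo, hi = self.mature_length_range
        if not 1 <= lo <= hi:
            raise ConfigError("mature_length_range must satisfy 1 <= lo <= hi")
        n_lengths = hi - lo + 1
        if 4 ** lo < 4 * self.n_families * self.members_per_family[1]:
            raise ConfigError("length range too short for the requested "
                              "number of distinct members")


@dataclass
class BuiltReferences:
    """Reference libraries plus the planted sharing/mimicry ground truth."""

    plant: list[ReferenceEntry]
    ncrna: list[ReferenceEntry]
    animal: list[ReferenceEntry]
    #: focal mature sequence -> number of other-species copies planted
    shared_copies: dict[str, int]
    #: animal name -> (plant full name, Hamming distance)
    mimic_pairs: dict[str, tuple[str, int]]


@dataclass
class TruthManifest:
    """Exact planted composition of a simulated library.

    ``planted`` has one row per planted small RNA (known miRNA arms and
    novel miRNAs) with species, name, family, arm, sequence and read count;
    ``contaminants`` has one row per contaminant class with its read count.
    """

    planted: pd.DataFrame
    contaminants: pd.DataFrame

    @property
    def total_reads(self) -> int:
        return int(self.planted["count"].sum() + self.contaminants["count"].sum())

    def write(self, path) -> None:
        planted = self.planted.assign(kind="planted")
        contam = self.contaminants.assign(kind="contaminant")
        pd.concat([planted, contam], ignore_index=True).to_csv(
            path, sep="\t", index=False)


def _random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _sample_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    lo, hi = config.mature_length_range
    lengths = [l for l in range(lo, hi + 1)]
    weights = np.array([config.length_weights.get(l, 0.01) for l in lengths],
                       dtype=float)
    weights /= weights.sum()
    return int(rng.choice(lengths, p=weights))


def _mutate(rng: np.random.Generator, sequence: str, n_subs: int) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    if n_subs == 0:
        return sequence
    seq = list(sequence)
    positions = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGU" if b != seq[pos]]
        seq[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(seq)


def _reverse_complement(sequence: str) -> str:
    comp = {"A": "U", "U": "A", "C": "G", "G": "C"}
    return "".join(comp[b] for b in reversed(sequence))


def build_references(config: SimulationConfig) -> BuiltReferences:
    """Generate plant-miRNA, ncRNA and animal-miRNA reference libraries.

    The focal species' mature sequences are mutually distinct, never contain
    the 3' adapter, and are never substrings of an ncRNA reference (so exact
    recovery is well defined).  A configurable subset of matures is copied
    under additional species codes; a configurable subset of animal entries
    sits at controlled Hamming distance from plant matures.
    """
    rng = np.random.default_rng([config.seed, 0])
    adapter_rna = normalize_sequence(config.adapter)
    focal = config.focal_species
    other_species = [f"sp{c}" for c in "abcdefghijklmnopqrstuvwxyz"[:config.n_plant_species - 1]]

    plant: list[ReferenceEntry] = []
    focal_sequences: set[str] = set()
    lo, hi = config.members_per_family
    family_ids = [101 + i for i in range(config.n_families)]
    member_records: list[tuple[str, str, str]] = []  # (name, family, sequence)
    for fam_id in family_ids:
        family = f"miR{fam_id}"
        n_members = int(rng.integers(lo, hi + 1))
        for j in range(n_members):
            name = family + "abcdefghij"[j] if n_members > 1 else family
            while True:
                seq = "U" + _random_rna(rng, _sample_length(rng, config) - 1)
                if seq not in focal_sequences and adapter_rna not in seq:
                    break
            focal_sequences.add(seq)
            member_records.append((name, family, seq))
            plant.append(ReferenceEntry(
                accession=f"{focal}-{name}", species_code=focal, name=name,
                family=family, rna_class="miRNA", sequence=seq, arm="mature"))

    # miR* passenger arms for a subset of members
    n_star = int(round(config.star_fraction * len(member_records)))
    star_indices = rng.choice(len(member_records), size=n_star, replace=False)
    for idx in sorted(star_indices):
        name, family, seq = member_records[idx]
        while True:
            star_seq = _mutate(rng, _reverse_complement(seq), 2)
            if star_seq not in focal_sequences and adapter_rna not in star_seq:
                break
        focal_sequences.add(star_seq)
        plant.append(ReferenceEntry(
            accession=f"{focal}-{name}*", species_code=focal, name=f"{name}*",
            family=family, rna_class="miRNA", sequence=star_seq, arm="star"))

    # cross-species copies of a subset of focal matures
    shared_copies: dict[str, int] = {}
    n_shared = int(round(config.shared_fraction * len(member_records)))
    shared_indices = rng.choice(len(member_records), size=n_shared, replace=False)
    for idx in sorted(shared_indices):
        name, family, seq = member_records[idx]
        k = int(rng.integers(1, max(2, len(other_species) + 1)))
        species_subset = list(rng.choice(other_species, size=k, replace=False))
        for sp in species_subset:
            plant.append(ReferenceEntry(
                accession=f"{sp}-{name}", species_code=sp, name=name,
                family=family, rna_class="miRNA", sequence=seq, arm="mature"))
        shared_copies[seq] = k

    # structural ncRNA references; focal matures must not occur inside them
    ncrna: list[ReferenceEntry] = []
    classes = ["rRNA", "tRNA", "snRNA", "snoRNA"]
    nc_lo, nc_hi = config.ncrna_length_range
    for i in range(config.n_ncrna_refs):
        rna_class = classes[i % len(classes)]
        while True:
            seq = _random_rna(rng, int(rng.integers(nc_lo, nc_hi + 1)))
            if (adapter_rna not in seq
                    and not any(m in seq for m in focal_sequences)):
                break
        ncrna.append(ReferenceEntry(
            accession=f"NC{i + 1:04d}", species_code="ref", name=f"{rna_class}_{i + 1}",
            family=f"{rna_class}_{i + 1}", rna_class=rna_class, sequence=seq))

    # animal miRNAs: mimics at controlled Hamming distance, plus random ones
    animal: list[ReferenceEntry] = []
    mimic_pairs: dict[str, tuple[str, int]] = {}
    n_mimic = min(int(round(config.animal_mimic_fraction * config.n_animal)),
                  len(member_records))
    mimic_indices = rng.choice(len(member_records), size=n_mimic, replace=False)
    for i, idx in enumerate(sorted(mimic_indices)):
        name, _, seq = member_records[idx]
        distance = config.animal_mimic_distances[i % len(config.animal_mimic_distances)]
        mimic_seq = _mutate(rng, seq, distance)
        animal_name = f"mir{9000 + i}"
        animal.append(ReferenceEntry(
            accession=f"hsa-{animal_name}", species_code="hsa", name=animal_name,
            family=animal_name, rna_class="miRNA", sequence=mimic_seq, arm="mature"))
        mimic_pairs[f"hsa-{animal_name}"] = (f"{focal}-{name}", distance)
    for i in range(config.n_animal - n_mimic):
        seq = _random_rna(rng, int(rng.integers(20, 24)))
        animal_name = f"mir{9500 + i}"
        animal.append(ReferenceEntry(
            accession=f"hsa-{animal_name}", species_code="hsa", name=animal_name,
            family=animal_name, rna_class="miRNA", sequence=seq, arm="mature"))

    return BuiltReferences(plant=plant, ncrna=ncrna, animal=animal,
                           shared_copies=shared_copies, mimic_pairs=mimic_pairs)


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` by ``weights`` (exact)."""
    if total == 0 or len(weights) == 0:
        return np.zeros(len(weights), dtype=int)
    shares = weights / weights.sum() * total
    counts = np.floor(shares).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(shares - counts))
    counts[order[:remainder]] += 1
    return counts


def simulate_library(config: SimulationConfig, references: BuiltReferences
                     ) -> tuple[list[SmallRNARead], TruthManifest]:
    """Synthesize reads and the matching ground-truth manifest.

    Each read is insert + 3' adapter, padded with random bases and truncated
    to ``read_length``.  Planted counts sum exactly to
    (1 - contamination fractions) x n_reads; with ``error_rate`` 0 every
    planted read's insert equals its reference sequence byte for byte.
    """
    rng = np.random.default_rng([config.seed, 1])
    focal = config.focal_species
    adapter_rna = normalize_sequence(config.adapter)

    focal_entries = [e for e in references.plant if e.species_code == focal]
    focal_sequences = {e.sequence for e in focal_entries}

    # novel (unannotated) miRNAs: planted but absent from every reference
    ncrna_haystack = "#".join(e.sequence for e in references.ncrna)
    novel_records: list[tuple[str, str]] = []
    for i in range(config.n_novel):
        while True:
            seq = "U" + _random_rna(rng, max(18, config.mature_length_range[0]) - 1 + 3)
            if (seq not in focal_sequences and adapter_rna not in seq
                    and seq not in ncrna_haystack):
                break
        focal_sequences.add(seq)
        novel_records.append((f"{focal}-miRn{i + 1}p", seq))

    n_ncrna = int(round(config.ncrna_fraction * config.n_reads))
    n_degr = int(round(config.degradation_fraction * config.n_reads))
    n_planted = config.n_reads - n_ncrna - n_degr

    planted_names = [e.full_name for e in focal_entries] + [n for n, _ in novel_records]
    planted_seqs = [e.sequence for e in focal_entries] + [s for _, s in novel_records]
    if config.explicit_abundances is not None:
        missing = set(config.explicit_abundances) - set(planted_names)
        if missing:
            raise ConfigError(f"explicit abundances for unknown entries: {missing}")
        counts = np.array([config.explicit_abundances.get(n, 0)
                           for n in planted_names], dtype=int)
        n_planted = int(counts.sum())
        n_total = n_planted + n_ncrna + n_degr
    else:
        weights = rng.lognormal(mean=0.0, sigma=config.abundance_sigma,
                                size=len(planted_names))
        # passenger arms ride at a fraction of the duplex abundance
        for i, entry in enumerate(focal_entries):
            if entry.arm == "star":
                weights[i] *= rng.uniform(0.02, 0.2)
        counts = _apportion(weights, n_planted)
        n_total = config.n_reads

    reads: list[SmallRNARead] = []
    read_index = 0

    def emit(insert: str) -> None:
        nonlocal read_index
        read_index += 1
        full = insert + adapter_rna
        if len(full) < config.read_length:
            full += _random_rna(rng, config.read_length - len(full))
        full = full[:config.read_length]
        qual = [config.base_quality] * len(full)
        if config.error_rate > 0:
            seq_list = list(full)
            for pos in range(len(seq_list)):
                if rng.random() < config.error_rate:
                    seq_list[pos] = _mutate(rng, seq_list[pos], 1)
                    qual[pos] = config.error_quality
            full = "".join(seq_list)
        reads.append(SmallRNARead(
            read_id=f"sim_{read_index:07d}",
            sequence=full,
            quality="".join(chr(33 + q) for q in qual),
        ))

    planted_rows = []
    for name, seq, count in zip(planted_names, planted_seqs, counts):
        entry = next((e for e in focal_entries if e.full_name == name), None)
        planted_rows.append({
            "species_code": focal,
            "name": name,
            "family": entry.family if entry is not None else "novel",
            "arm": entry.arm if entry is not None else "mature",
            "known": entry is not None,
            "sequence": seq,
            "count": int(count),
        })
        for _ in range(int(count)):
            emit(seq)

    frag_lo, frag_hi = config.fragment_length_range
    for _ in range(n_ncrna):
        ref = references.ncrna[int(rng.integers(len(references.ncrna)))]
        length = int(rng.integers(frag_lo, frag_hi + 1))
        start = int(rng.integers(0, len(ref.sequence) - length + 1))
        emit(ref.sequence[start:start + length])

    decoys = []
    for _ in range(config.n_decoys):
        while True:
            seq = _random_rna(rng, config.decoy_length)
            if (adapter_rna not in seq and seq not in ncrna_haystack
                    and not any(m in seq for m in focal_sequences)):
                break
        decoys.append(seq)
    for _ in range(n_degr):
        decoy = decoys[int(rng.integers(len(decoys)))]
        length = int(rng.integers(frag_lo, frag_hi + 1))
        start = int(rng.integers(0, len(decoy) - length + 1))
        emit(decoy[start:start + length])

    manifest = TruthManifest(
        planted=pd.DataFrame(planted_rows, columns=[
            "species_code", "name", "family", "arm", "known", "sequence", "count"]),
        contaminants=pd.DataFrame(
            [{"class": "ncrna_fragment", "count": n_ncrna},
             {"class": "degradation", "count": n_degr}]),
    )
    assert manifest.total_reads == n_total == len(reads)
    return reads, manifest
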