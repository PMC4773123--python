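"""Exact-identity classification of unique tags.

Two stages replace the original BLASTn runs at 100% identity, where exact
matching is the same predicate as megablast/-perc_identity 100 but fully
deterministic:

* ncRNA subtraction — a tag is removed iff its sequence occurs as an exact,
  contiguous, full-tag substring of any ncRNA reference sequence (rRNA,
  tRNA, snRNA, snoRNA, degradation decoys);
* conserved-miRNA identification — a tag is annotated iff it is
  character-identical, over its full length, to a mature miRNA reference
  sequence of another species.

Tags below the copy-number threshold (default 10) are discarded at the
identification stage; unmatched tags of length >= 18 nt become novel-miRNA
candidates for downstream prediction tools.  Every tag ends in exactly one
bin, so stage counts always conserve the input.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .core_io import ReferenceEntry, StageCounts, UniqueTag, derive_family
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class AnnotationParams:
    """Thresholds of the two classification stages.

    ``min_tag_length`` (default 15 nt) removes short tags at the ncRNA
    stage; ``min_count`` (default 10 copies) is the abundance filter applied
    at the identification stage; ``novel_min_length`` (default 18 nt) gates
    novel-miRNA candidates.
    """

    min_tag_length: int = 15
    min_count: int = 10
    novel_min_length: int = 18
    ncrna_match_mode: str = "substring_of_reference"
    mirna_match_mode: str = "exact_equal"

    def __post_init__(self) -> None:
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")
        if self.novel_min_length < self.min_tag_length:
            raise ConfigError("novel_min_length must be >= min_tag_length")


@dataclass
class AnnotatedMiRNA:
    """A conserved-miRNA call for one unique tag."""

    assigned_name: str
    family: str
    arm: str  # mature | star
    sequence: str
    count: int
    sources: list[tuple[str, str, str]]  # (species_code, name, accession)


@dataclass
class FamilySummary:
    family: str
    n_members: int
    total_count: int


@dataclass
class AnnotationBins:
    """Partition of the input tags produced by :func:`annotate_tags`."""

    short: list[UniqueTag] = field(default_factory=list)
    ncrna: list[UniqueTag] = field(default_factory=list)
    conserved: list[AnnotatedMiRNA] = field(default_factory=list)
    below_abundance: list[UniqueTag] = field(default_factory=list)
    candidate: list[UniqueTag] = field(default_factory=list)
    other_unmatched: list[UniqueTag] = field(default_factory=list)


def subtract_ncrna(tags: Sequence[UniqueTag], ncrna_reference: Sequence[ReferenceEntry],
                   params: AnnotationParams
                   ) -> tuple[list[UniqueTag], list[UniqueTag], list[UniqueTag], StageCounts]:
    """Remove tags contained in any ncRNA reference sequence.

    Tags shorter than ``min_tag_length`` are removed first with their own
    count.  Returns (retained, ncRNA-removed, short-removed, stage counts).
    Matching is strand-as-given, exact, full-tag containment.
    """
    if not ncrna_reference:
        raise ConfigError("ncRNA reference is empty; refusing silent pass-through")
    counts = StageCounts()
    long_enough = [t for t in tags if len(t.sequence) >= params.min_tag_length]
    short = [t for t in tags if len(t.sequence) < params.min_tag_length]
    counts.add("short_tag_filter", len(tags), len(long_enough))

    # One concatenated haystack; '#' separators prevent cross-boundary hits.
    haystack = "#".join(e.sequence for e in ncrna_reference)
    retained = [t for t in long_enough if t.sequence not in haystack]
    removed = [t for t in long_enough if t.sequence in haystack]
    counts.add("ncrna_subtraction", len(long_enough), len(retained))
    return retained, removed, short, counts


def identify_conserved(tags: Sequence[UniqueTag], plant_reference: Sequence[ReferenceEntry],
                       params: AnnotationParams, species_prefix: str = "mol"
                       ) -> tuple[list[AnnotatedMiRNA], list[UniqueTag], list[UniqueTag]]:
    """Annotate tags identical to a mature miRNA reference sequence.

    The abundance filter runs first: tags with fewer than ``min_count``
    copies are discarded (returned separately) before any matching, so
    neither annotations nor novel candidates contain low-copy tags.  The
    assigned name is ``species_prefix + "-" + member name``; when several
    reference species share the identical sequence the lexicographically
    smallest (species_code, name) pair names the call and every source is
    recorded.  Returns (annotations, unmatched, below-abundance).
    """
    by_sequence: dict[str, list[ReferenceEntry]] = defaultdict(list)
    for entry in plant_reference:
        if entry.rna_class == "miRNA":
            by_sequence[entry.sequence].append(entry)

    annotations: list[AnnotatedMiRNA] = []
    unmatched: list[UniqueTag] = []
    below: list[UniqueTag] = []
    for tag in tags:
        if tag.count < params.min_count:
            below.append(tag)
            continue
        entries = by_sequence.get(tag.sequence)
        if not entries:
            unmatched.append(tag)
            continue
        chosen = min(entries, key=lambda e: (e.species_code, e.name))
        name = chosen.name
        arm = chosen.arm if chosen.arm in ("mature", "star") else "mature"
        annotations.append(AnnotatedMiRNA(
            assigned_name=f"{species_prefix}-{name}",
            family=derive_family(name),
            arm=arm,
            sequence=tag.sequence,
            count=tag.count,
            sources=[(e.species_code, e.name, e.accession) for e in entries],
        ))
    return annotations, unmatched, below


def extract_novel_candidates(unmatched: Sequence[UniqueTag], params: AnnotationParams
                             ) -> tuple[list[UniqueTag], list[UniqueTag]]:
    """Split unmatched tags into novel candidates (length >= 18 nt) and rest."""
    candidates = [t for t in unmatched if len(t.sequence) >= params.novel_min_length]
    rest = [t for t in unmatched if len(t.sequence) < params.novel_min_length]
    return candidates, rest


def write_candidates_fasta(candidates: Sequence[UniqueTag], path) -> int:
    """Emit candidate tags as FASTA for external novel-miRNA tools."""
    with open(path, "w") as handle:
        for i, tag in enumerate(candidates, 1):
            handle.write(f">candidate_{i}_x{tag.count}\n{tag.sequence}\n")
    return len(candidates)


def annotate_tags(tags: Sequence[UniqueTag], ncrna_reference: Sequence[ReferenceEntry],
                  plant_reference: Sequence[ReferenceEntry], params: AnnotationParams,
                  species_prefix: str = "mol") -> tuple[AnnotationBins, StageCounts]:
    """Run both classification stages; every tag lands in exactly one bin."""
    retained, removed, short, counts = subtract_ncrna(tags, ncrna_reference, params)
    annotations, unmatched, below = identify_conserved(
        retained, plant_reference, params, species_prefix)
    counts.add("abundance_and_identification", len(retained),
               len(annotations) + len(unmatched))
    candidates, rest = extract_novel_candidates(unmatched, params)
    counts.add("novel_candidate_length_filter", len(unmatched), len(candidates))
    bins = AnnotationBins(short=short, ncrna=removed, conserved=annotations,
                          below_abundance=below, candidate=candidates,
                          other_unmatched=rest)
    return bins, counts


# ---------------------------------------------------------------------------
# Profiling
# ---------------------------------------------------------------------------

def _strip_arm(name: str) -> str:
    import re

    return re.sub(r"-(5p|3p)$", "", name.rstrip("*"))


def family_summary(annotations: Iterable[AnnotatedMiRNA]) -> list[FamilySummary]:
    """Group annotations by family; totals sum miR and miR* counts."""
    members: dict[str, set[str]] = defaultdict(set)
    totals: dict[str, int] = defaultdict(int)
    for ann in annotations:
        members[ann.family].add(_strip_arm(ann.assigned_name))
        totals[ann.family] += ann.count
    return [FamilySummary(f, len(members[f]), totals[f])
            for f in sorted(members, key=lambda f: (-totals[f], f))]


def family_summary_from_table(rows: pd.DataFrame) -> list[FamilySummary]:
    """Family summary over a known-miRNA catalogue table.

    Expects ``member`` plus ``mir_count``/``mirstar_count`` columns (absent
    values as NA).  Each row is one member (duplicate member labels stay
    distinct, matching the printed catalogue); absent counts contribute
    nothing to family totals.
    """
    n_members: dict[str, int] = defaultdict(int)
    totals: dict[str, int] = defaultdict(int)
    for row in rows.itertuples():
        fam = derive_family(row.member)
        n_members[fam] += 1
        for value in (row.mir_count, row.mirstar_count):
            if value is not pd.NA and not pd.isna(value):
                totals[fam] += int(value)
    return [FamilySummary(f, n_members[f], totals[f])
            for f in sorted(n_members, key=lambda f: (-totals[f], f))]


def length_distribution(tags: Sequence[UniqueTag], weighting: str = "by_read") -> pd.Series:
    """Proportion of reads (or unique tags) per integer sequence length.

    ``by_read`` weights each tag by its copy count; ``by_tag`` counts each
    unique sequence once.  Proportions sum to 1 over observed lengths; an
    empty input yields an empty distribution.
    """
    if weighting not in ("by_read", "by_tag"):
        raise ConfigError(f"unknown weighting {weighting!r}")
    if not tags:
        return pd.Series(dtype=float)
    weights: dict[int, float] = defaultdict(float)
    for tag in tags:
        weights[len(tag.sequence)] += tag.count if weighting == "by_read" else 1
    total = sum(weights.values())
    return pd.Series({k: v / total for k, v in sorted(weights.items())}, dtype=float)


def annotations_to_frame(annotations: Iterable[AnnotatedMiRNA]) -> pd.DataFrame:
    """Tabular (catalogue-shaped) view of conserved-miRNA calls."""
    rows = []
    for ann in annotations:
        rows.append({
            "member": ann.assigned_name,
            "family": ann.family,
            "arm": ann.arm,
            "sequence": ann.sequence,
            "count": ann.count,
            "sources": ";".join(f"{s}-{n}" for s, n, _ in ann.sources),
        })
    return pd.DataFrame(rows, columns=["member", "family", "arm", "sequence",
                                       "count", "sources"])
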