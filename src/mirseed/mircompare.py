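"""Cross-kingdom plant/animal miRNA comparison by ungapped overlay.

Every plant-animal pair is scored by sliding the plant sequence across the
animal sequence without gaps and keeping the offset with the most matching
positions.  The alignment frame is the animal miRNA: the match pattern is a
string indexed by animal positions (a letter where the plant base agrees,
``-`` elsewhere) and the r-value is matches / animal length.  A pair passes
when the r-value reaches ``r_min`` (default 0.55) and the number of matches
inside the animal seed region (positions 2-8, 1-based, by default) reaches
``seed_min`` (default 5).  r-values are reported rounded half-up to two
decimals and compared at full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .core_io import ReferenceEntry, normalize_sequence
from .errors import ConfigError, InvalidOffsetError, MalformedPatternError

logger = logging.getLogger(__name__)

_PATTERN_ALPHABET = frozenset("ACGU-")

DENOMINATORS = ("animal", "overlap", "longer")


@dataclass
class CompareParams:
    """Thresholds and coordinate conventions of the pair comparison."""

    r_min: float = 0.55
    seed_min: int = 5
    seed_window: tuple[int, int] = (2, 8)  # 1-based inclusive, animal coords
    min_overlap: int = 10
    denominator: str = "animal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_min <= 1.0:
            raise ConfigError("r_min must be in [0, 1]")
        start, end = self.seed_window
        if not 1 <= start <= end:
            raise ConfigError("seed_window must satisfy 1 <= start <= end")
        if self.denominator not in DENOMINATORS:
            raise ConfigError(f"unknown denominator {self.denominator!r}")


@dataclass
class ComparisonResult:
    """Best ungapped overlay for one plant-animal miRNA pair."""

    plant_name: str
    animal_name: str
    offset: int
    pattern: str
    matches: int
    alignment_length: int
    r_value: float
    seed_matches: int
    passes: bool

    @property
    def r_rounded(self) -> float:
        return round_half_up(self.matches, self.alignment_length)


def round_half_up(matches: int, length: int) -> float:
    """Round matches/length half-up to 2 decimals (exact rational arithmetic)."""
    if length == 0:
        return 0.0
    ratio = Decimal(matches) / Decimal(length)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def score_pattern(pattern_text: str) -> tuple[int, int, float]:
    """Score a printed alignment pattern.

    Returns (matches, alignment_length, r-value at full precision); matches
    is the letter count, the length the total character count.  A character
    outside {A,C,G,U,-} raises :class:`MalformedPatternError`.
    """
    for ch in pattern_text:
        if ch not in _PATTERN_ALPHABET:
            raise MalformedPatternError(
                f"invalid pattern character {ch!r} in {pattern_text!r}")
    matches = sum(1 for ch in pattern_text if ch != "-")
    length = len(pattern_text)
    r = matches / length if length else 0.0
    return matches, length, r


def overlay(plant_seq: str, animal_seq: str, offset: int) -> tuple[str, int, int]:
    """Ungapped overlay of the plant sequence on the animal frame.

    ``offset`` is the number of animal positions preceding the plant
    sequence's first base (0 aligns both starts; negative offsets let the
    plant overhang the animal 5' end).  The pattern is indexed by animal
    positions 1..len(animal): a position holds the plant base where the
    plant covers it and agrees with the animal base, ``-`` otherwise.
    Raises :class:`InvalidOffsetError` if the overlap is empty.
    """
    n_animal, n_plant = len(animal_seq), len(plant_seq)
    lo = max(0, offset)
    hi = min(n_animal, offset + n_plant)
    if hi <= lo:
        raise InvalidOffsetError(
            f"offset {offset} leaves no overlap between sequences of lengths "
            f"{n_plant} and {n_animal}")
    chars = []
    matches = 0
    for i in range(n_animal):
        j = i - offset
        if 0 <= j < n_plant and plant_seq[j] == animal_seq[i]:
            chars.append(plant_seq[j])
            matches += 1
        else:
            chars.append("-")
    return "".join(chars), matches, n_animal


def _overlap_length(n_plant: int, n_animal: int, offset: int) -> int:
    return min(n_animal, offset + n_plant) - max(0, offset)


def compare_pair(plant_seq: str, animal_seq: str, params: CompareParams,
                 plant_name: str = "plant", animal_name: str = "animal"
                 ) -> ComparisonResult:
    """Best overlay over all offsets with overlap >= ``min_overlap``.

    The winning offset maximizes matches; ties prefer the smaller absolute
    offset, then the smaller offset.  Both sequences must reach the end of
    the seed window.
    """
    plant_seq = normalize_sequence(plant_seq)
    animal_seq = normalize_sequence(animal_seq)
    seed_start, seed_end = params.seed_window
    if len(plant_seq) < seed_end or len(animal_seq) < seed_end:
        raise ConfigError(
            f"sequences must reach the seed window end ({seed_end}); "
            f"got lengths {len(plant_seq)} and {len(animal_seq)}")
    n_plant, n_animal = len(plant_seq), len(animal_seq)
    min_ov = min(params.min_overlap, n_plant, n_animal)
    best: tuple[int, int, int] | None = None  # (-matches, |offset|, offset)
    best_overlay: tuple[str, int, int] | None = None
    for offset in range(-(n_plant - min_ov), n_animal - min_ov + 1):
        if _overlap_length(n_plant, n_animal, offset) < min_ov:
            continue
        pattern, matches, length = overlay(plant_seq, animal_seq, offset)
        key = (-matches, abs(offset), offset)
        if best is None or key < best:
            best = key
            best_overlay = (pattern, matches, length)
    assert best is not None and best_overlay is not None
    offset = best[2]
    pattern, matches, _ = best_overlay
    alignment_length = _denominator_length(params.denominator, n_plant, n_animal,
                                           offset)
    r_value = matches / alignment_length
    seed_matches = sum(1 for i in range(seed_start - 1, min(seed_end, n_animal))
                       if pattern[i] != "-")
    return ComparisonResult(
        plant_name=plant_name,
        animal_name=animal_name,
        offset=offset,
        pattern=pattern,
        matches=matches,
        alignment_length=alignment_length,
        r_value=r_value,
        seed_matches=seed_matches,
        passes=(r_value >= params.r_min and seed_matches >= params.seed_min),
    )


def _denominator_length(denominator: str, n_plant: int, n_animal: int,
                        offset: int) -> int:
    if denominator == "animal":
        return n_animal
    if denominator == "longer":
        return max(n_plant, n_animal)
    return _overlap_length(n_plant, n_animal, offset)


def compare_libraries(plant_reference: Sequence[ReferenceEntry],
                      animal_reference: Sequence[ReferenceEntry],
                      params: CompareParams) -> list[ComparisonResult]:
    """Score all plant x animal pairs; emit only passing pairs.

    Results sort by descending r-value, then plant name, then animal name.
    Pairs whose sequences do not reach the seed window are skipped with a
    logged reason.
    """
    if not plant_reference or not animal_reference:
        raise ConfigError("both reference libraries must be non-empty")
    results: list[ComparisonResult] = []
    for plant in plant_reference:
        for animal in animal_reference:
            try:
                res = compare_pair(plant.sequence, animal.sequence, params,
                                   plant_name=plant.full_name,
                                   animal_name=animal.full_name)
            except ConfigError as exc:
                logger.info("pair %s / %s skipped: %s",
                            plant.full_name, animal.full_name, exc)
                continue
            if res.passes:
                results.append(res)
    results.sort(key=lambda r: (-r.r_value, r.plant_name, r.animal_name))
    return results


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Report table shaped like the published comparison: rounded r-value
    plus full-precision columns."""
    rows = [{
        "human_mirna": r.animal_name,
        "plant_mirna": r.plant_name,
        "r_value": r.r_rounded,
        "alignment_pattern": r.pattern,
        "matches": r.matches,
        "alignment_length": r.alignment_length,
        "r_value_full": r.r_value,
        "seed_matches": r.seed_matches,
        "offset": r.offset,
    } for r in results]
    return pd.DataFrame(rows, columns=["human_mirna", "plant_mirna", "r_value",
                                       "alignment_pattern", "matches",
                                       "alignment_length", "r_value_full",
                                       "seed_matches", "offset"])
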