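"""Cross-species conservation scoring of annotated miRNAs.

The conservation rate of a mature miRNA is the number of mature reference
entries from *other* species whose sequence matches the query.  The unit is
reference entries (not distinct species) and the default matching mode is
exact full-length equality; both are configurable because redundant
reference libraries list near-identical mature sequences under many species
and the appropriate granularity depends on how the library was prepared.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .annotate import AnnotatedMiRNA
from .core_io import ReferenceEntry
from .errors import ConfigError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

MODES = ("exact_equal", "containment_either_direction")


@dataclass
class ConservationResult:
    mirna_name: str
    sequence: str
    conservation_rate: int
    seed_count: int  # read count in the study tissue


def _matches(query: str, entry_seq: str, mode: str) -> bool:
    if mode == "exact_equal":
        return query == entry_seq
    return query in entry_seq or entry_seq in query


def conservation_rate(query_sequence: str, plant_reference: Sequence[ReferenceEntry],
                      mode: str = "exact_equal", query_species: str = "mol") -> int:
    """Count other-species mature reference entries matching the query.

    Entries of the query's own species are excluded from the scan.  An empty
    reference yields 0 with a warning (visible in logs, unlike silent
    success).
    """
    if mode not in MODES:
        raise ConfigError(f"unknown conservation mode {mode!r}")
    if not plant_reference:
        logger.warning("conservation scan against an empty reference; rate is 0")
        return 0
    return sum(
        1 for e in plant_reference
        if e.rna_class == "miRNA" and e.species_code != query_species
        and _matches(query_sequence, e.sequence, mode)
    )


def conservation_profile(annotations: Sequence[AnnotatedMiRNA],
                         plant_reference: Sequence[ReferenceEntry],
                         mode: str = "exact_equal",
                         query_species: str = "mol") -> list[ConservationResult]:
    """Score every annotated miRNA against the reference library."""
    return [
        ConservationResult(
            mirna_name=ann.assigned_name,
            sequence=ann.sequence,
            conservation_rate=conservation_rate(ann.sequence, plant_reference,
                                                mode, query_species),
            seed_count=ann.count,
        )
        for ann in annotations
    ]


def rank_by_conservation(results: Sequence[ConservationResult], top_n: int
                         ) -> list[ConservationResult]:
    """Top-n results by descending rate; ties break by descending read
    count, then name."""
    if top_n < 1:
        raise ConfigError("top_n must be >= 1")
    ordered = sorted(results, key=lambda r: (-r.conservation_rate, -r.seed_count,
                                             r.mirna_name))
    return ordered[:top_n]


def conservation_abundance_correlation(results: Sequence[ConservationResult]
                                       ) -> tuple[float, int]:
    """Pearson correlation between conservation rate and log10 read count.

    Abundances span orders of magnitude, so the count axis is logarithmic
    (base 10; the base only rescales and leaves Pearson r unchanged).
    Requires at least 3 results with positive counts and non-zero variance
    on both axes.
    """
    points = [(r.conservation_rate, math.log10(r.seed_count))
              for r in results if r.seed_count > 0]
    if len(points) < 3:
        raise UndefinedCorrelationError(
            f"need >= 3 results with positive counts, have {len(points)}")
    rates = [p[0] for p in points]
    logs = [p[1] for p in points]
    if len(set(rates)) == 1 or len(set(logs)) == 1:
        raise UndefinedCorrelationError("zero variance on one axis")
    r, _ = stats.pearsonr(rates, logs)
    return float(r), len(points)


def results_to_frame(results: Sequence[ConservationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.mirna_name, r.sequence, r.conservation_rate, r.seed_count)
         for r in results],
        columns=["mirna_name", "sequence", "conservation_rate", "read_counts"],
    )


def plot_conservation_scatter(results: Sequence[ConservationResult], path) -> None:
    """Scatter of conservation rate against log-scaled read count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter([r.seed_count for r in results],
               [r.conservation_rate for r in results], s=18)
    ax.set_xscale("log")
    ax.set_xlabel("read count (log scale)")
    ax.set_ylabel("conservation rate (matching entries)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
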