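"""Raw-read preprocessing: adapter clipping, quality trimming, length
filtering, artifact removal and collapsing to unique tags.

The cascade mirrors a standard FASTX-Toolkit small-RNA workflow: the 3'
sequencing adapter is clipped by exact prefix matching (minimum anchor of 5
bases, no mismatches), terminal low-quality bases are trimmed from both
ends, inserts shorter than 15 nt are discarded, and sequencing artifacts
(reads containing N, homopolymers, strict dinucleotide repeats) are removed
before reads collapse into unique tags with copy counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .core_io import SmallRNARead, StageCounts, UniqueTag, normalize_sequence
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Parameters of the read-cleaning cascade.

    ``adapter`` is the 3' adapter in either alphabet (normalized on use);
    ``min_length_post_trim`` is the inclusive survival cutoff (default 15 nt);
    ``quality_threshold`` the Phred score below which terminal bases are
    trimmed (default 20); ``min_adapter_overlap`` the shortest adapter prefix
    accepted as evidence of read-through (default 5); unclipped reads are
    kept by default.
    """

    adapter: str
    min_length_post_trim: int = 15
    quality_threshold: int = 20
    min_adapter_overlap: int = 5
    keep_unclipped: bool = True

    def __post_init__(self) -> None:
        if self.min_length_post_trim < 1:
            raise ConfigError("min_length_post_trim must be >= 1")
        if self.min_adapter_overlap < 1:
            raise ConfigError("min_adapter_overlap must be >= 1")
        self.adapter = normalize_sequence(self.adapter)
        if len(self.adapter) < self.min_adapter_overlap:
            raise ConfigError("adapter is shorter than min_adapter_overlap; "
                              "it could never be detected")


def clip_adapter(read: SmallRNARead, params: PreprocessParams) -> SmallRNARead:
    """Clip the 3' adapter from a read by exact prefix matching.

    The read is truncated at the leftmost position where a prefix of the
    adapter (>= ``min_adapter_overlap`` bases, extending to the end of the
    read or covering the whole adapter) occurs.  Reads without such an
    occurrence are returned unmodified and flagged ``clipped=False``.
    """
    seq = read.sequence
    adapter = params.adapter
    n = len(seq)
    for i in range(n):
        k = min(len(adapter), n - i)
        if k < params.min_adapter_overlap:
            break
        if seq[i:i + k] == adapter[:k]:
            return SmallRNARead(
                read_id=read.read_id,
                sequence=seq[:i],
                quality=read.quality[:i] if read.quality is not None else None,
                clipped=True,
            )
    return SmallRNARead(read.read_id, seq, read.quality, clipped=False)


def trim_quality(read: SmallRNARead, params: PreprocessParams) -> SmallRNARead:
    """Trim terminal runs of bases with quality below the threshold.

    Both the 5' and 3' ends are trimmed; interior bases are never touched.
    Reads without quality scores pass through with a warning.
    """
    if read.quality is None:
        logger.warning("read %s has no quality scores; quality trim skipped", read.read_id)
        return read
    phred = read.phred
    start, end = 0, len(phred)
    while start < end and phred[start] < params.quality_threshold:
        start += 1
    while end > start and phred[end - 1] < params.quality_threshold:
        end -= 1
    if start == 0 and end == len(phred):
        return read
    return SmallRNARead(read.read_id, read.sequence[start:end],
                        read.quality[start:end], clipped=read.clipped)


def filter_length(reads: Sequence[SmallRNARead], min_len: int) -> tuple[list[SmallRNARead], tuple[str, int, int]]:
    """Keep reads of length >= ``min_len`` (inclusive boundary).

    Returns the survivors and a ``(stage, entering, surviving)`` record.
    """
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    survivors = [r for r in reads if len(r) >= min_len]
    return survivors, ("length_filter", len(reads), len(survivors))


def is_artifact(sequence: str) -> bool:
    """True for reads that are sequencing artifacts.

    Artifacts are reads containing N, homopolymers, and strict dinucleotide
    repeats spanning the whole insert (e.g. ``ACACAC...``).
    """
    if "N" in sequence:
        return True
    if len(set(sequence)) == 1:
        return True
    if len(sequence) >= 2 and len(set(sequence)) == 2:
        a, b = sequence[0], sequence[1]
        if a != b and all(sequence[i] == (a if i % 2 == 0 else b)
                          for i in range(len(sequence))):
            return True
    return False


def remove_artifacts(reads: Sequence[SmallRNARead]) -> tuple[list[SmallRNARead], tuple[str, int, int]]:
    """Drop artifact reads; returns survivors and a stage-count record."""
    # empty reads flow through to the length filter rather than counting here
    survivors = [r for r in reads if not (len(r) > 0 and is_artifact(r.sequence))]
    return survivors, ("artifact_filter", len(reads), len(survivors))


def collapse(reads: Iterable[SmallRNARead | str]) -> list[UniqueTag]:
    """Collapse reads into unique tags with multiplicities.

    The sum of tag counts equals the number of input reads; output order is
    deterministic (descending count, then lexicographic sequence).
    """
    counts: dict[str, int] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        counts[seq] = counts.get(seq, 0) + 1
    return [UniqueTag(seq, c)
            for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def run_preprocess(reads: Iterable[SmallRNARead], params: PreprocessParams
                   ) -> tuple[list[SmallRNARead], StageCounts]:
    """Run the full read-level cascade: clip, quality-trim, de-artifact,
    length-filter.  Returns cleaned reads plus per-stage counts."""
    reads = list(reads)
    counts = StageCounts()

    clipped = [clip_adapter(r, params) for r in reads]
    if not params.keep_unclipped:
        clipped = [r for r in clipped if r.clipped]
    counts.add("adapter_clip", len(reads), len(clipped))

    trimmed = [trim_quality(r, params) for r in clipped]
    counts.add("quality_trim", len(clipped), len(trimmed))

    kept, stage = remove_artifacts(trimmed)
    counts.add(*stage)

    survivors, stage = filter_length(kept, params.min_length_post_trim)
    counts.add(*stage)
    return survivors, counts


def preprocess_to_tags(reads: Iterable[SmallRNARead], params: PreprocessParams
                       ) -> tuple[list[UniqueTag], StageCounts]:
    """Full cascade plus collapsing to unique tags."""
    survivors, counts = run_preprocess(reads, params)
    tags = collapse(survivors)
    counts.add("collapse_reads", len(survivors), len(survivors))
    return tags, counts


def write_tags(tags: Iterable[UniqueTag], path) -> None:
    """Write unique tags as a two-column TSV (sequence, count)."""
    import pandas as pd

    pd.DataFrame([(t.sequence, t.count) for t in tags],
                 columns=["sequence", "count"]).to_csv(path, sep="\t", index=False)


def read_tags(path) -> list[UniqueTag]:
    """Read a tags TSV written by :func:`write_tags`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [UniqueTag(row.sequence, int(row.count)) for row in df.itertuples()]
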