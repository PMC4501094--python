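"""Quality, abundance and length filtering of small-RNA libraries.

The filters mirror the usual small-RNA pre-processing: reads with
undetermined bases (N) or low PHRED quality are discarded, the survivors
are deduplicated into unique sequences with per-stage counts, and unique
reads are then filtered on pooled abundance (default >= 5) and length
(default 25–45 nt).  Every filter reports a tally so read accounting is
conserved at each step.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "UniqueRead",
    "FilterTally",
    "quality_filter",
    "deduplicate",
    "abundance_filter",
    "length_filter",
    "filter_stage_libraries",
]


@dataclass(frozen=True)
class UniqueRead:
    """A deduplicated read sequence with per-stage raw counts."""

    sequence: str
    counts: tuple[int, ...]

    @property
    def pooled_count(self) -> int:
        return sum(self.counts)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class FilterTally:
    """Read accounting for one filtering step (counts of reads, not
    unique sequences, except where noted)."""

    step: str
    input: int = 0
    passed: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str, n: int = 1) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + n

    @property
    def rejected_total(self) -> int:
        return sum(self.rejected.values())

    def check_conservation(self) -> None:
        if self.input != self.passed + self.rejected_total:
            raise AssertionError(
                f"{self.step}: {self.input} in != {self.passed} passed + "
                f"{self.rejected_total} rejected"
            )


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path: str | Path) -> Iterator:
    with _open_maybe_gzip(path) as handle:
        yield from SeqIO.parse(handle, "fastq")


def quality_filter(
    reads: Iterable,
    *,
    min_quality: float = 20.0,
    mode: str = "mean",
) -> tuple[list[str], FilterTally]:
    """Discard reads containing N and low-quality reads.

    ``reads`` is an iterable of Biopython SeqRecords with
    ``phred_quality`` annotations (as produced by :func:`iter_fastq`).
    ``mode='mean'`` rejects reads whose mean base quality is below the
    threshold; ``mode='min'`` rejects on any single base below it.
    Returns the passing sequences (as uppercase strings) and the tally.
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"unknown quality mode {mode!r}")
    tally = FilterTally(step="quality")
    passed: list[str] = []
    for rec in reads:
        tally.input += 1
        seq = str(rec.seq).upper()
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(seq):
            raise ValueError(f"read {rec.id}: sequence/quality length mismatch")
        if "N" in seq:
            tally.reject("contains_n")
            continue
        score = (sum(quals) / len(quals)) if mode == "mean" else min(quals)
        if score < min_quality:
            tally.reject("low_quality")
            continue
        passed.append(seq)
        tally.passed += 1
    tally.check_conservation()
    return passed, tally


def deduplicate(
    reads_per_stage: dict[str, Iterable[str]],
    stage_order: Sequence[str] | None = None,
) -> list[UniqueRead]:
    """Collapse per-stage read lists into unique sequences with per-stage
    counts, preserving counts exactly.  Output is sorted by sequence for
    determinism."""
    stages = list(stage_order) if stage_order is not None else sorted(reads_per_stage)
    counters = {stage: Counter(reads_per_stage.get(stage, ())) for stage in stages}
    sequences = sorted(set().union(*[c.keys() for c in counters.values()]) if counters else ())
    return [
        UniqueRead(
            sequence=seq,
            counts=tuple(counters[stage].get(seq, 0) for stage in stages),
        )
        for seq in sequences
    ]


def abundance_filter(
    unique_reads: Iterable[UniqueRead],
    min_count: int = 5,
    *,
    per_stage: bool = False,
) -> tuple[list[UniqueRead], FilterTally]:
    """Remove unique reads sequenced fewer than ``min_count`` times.

    By default the threshold applies to the pooled count across all
    stages; ``per_stage=True`` instead requires some single stage to
    reach it.  The tally counts reads (count-weighted), so conservation
    holds in read units.
    """
    tally = FilterTally(step="abundance")
    passed = []
    for read in unique_reads:
        tally.input += read.pooled_count
        ok = (
            max(read.counts, default=0) >= min_count
            if per_stage
            else read.pooled_count >= min_count
        )
        if ok:
            passed.append(read)
            tally.passed += read.pooled_count
        else:
            tally.reject("below_threshold", read.pooled_count)
    tally.check_conservation()
    return passed, tally


def length_filter(
    unique_reads: Iterable[UniqueRead],
    min_length: int = 25,
    max_length: int = 45,
) -> tuple[list[UniqueRead], FilterTally]:
    """Keep unique reads with min_length <= length <= max_length."""
    if min_length > max_length:
        raise ValueError(f"min_length {min_length} > max_length {max_length}")
    tally = FilterTally(step="length")
    passed = []
    for read in unique_reads:
        tally.input += read.pooled_count
        if read.length < min_length:
            tally.reject("too_short", read.pooled_count)
        elif read.length > max_length:
            tally.reject("too_long", read.pooled_count)
        else:
            passed.append(read)
            tally.passed += read.pooled_count
    tally.check_conservation()
    return passed, tally


def filter_stage_libraries(
    fastq_paths: dict[str, str | Path],
    stage_order: Sequence[str],
    *,
    min_quality: float = 20.0,
    quality_mode: str = "mean",
    min_count: int = 5,
    per_stage_abundance: bool = False,
    min_length: int = 25,
    max_length: int = 45,
) -> tuple[list[UniqueRead], list[UniqueRead], dict[str, FilterTally]]:
    """Run the full filter chain over six stage FASTQ libraries.

    Returns (filtered unique reads, all quality-passed unique reads
    before abundance/length filtering, tallies per step).  The second
    list is what spike-in counting should use, since spikes must be
    countable regardless of the tRF length window.
    """
    quality_tally = FilterTally(step="quality")
    passed_per_stage: dict[str, list[str]] = {}
    for stage in stage_order:
        passed, tally = quality_filter(
            iter_fastq(fastq_paths[stage]), min_quality=min_quality, mode=quality_mode
        )
        passed_per_stage[stage] = passed
        quality_tally.input += tally.input
        quality_tally.passed += tally.passed
        for reason, n in tally.rejected.items():
            quality_tally.reject(reason, n)
    quality_tally.check_conservation()

    unique = deduplicate(passed_per_stage, stage_order)
    abundant, abundance_tally = abundance_filter(unique, min_count, per_stage=per_stage_abundance)
    final, length_tally = length_filter(abundant, min_length, max_length)
    tallies = {
        "quality": quality_tally,
        "abundance": abundance_tally,
        "length": length_tally,
    }
    return final, unique, tallies
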