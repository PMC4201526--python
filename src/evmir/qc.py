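"""Raw-read quality control: adapter trimming and clean-read filtering.

Clean reads are defined as the 18-30 nt inserts that survive, in order:
no undetermined base ("N"), at most 6 bases below Phred quality 13, at most
4 bases below quality 10, and the 18-30 nt length window. Reads are first
trimmed at the leftmost admissible occurrence of a 3' adapter prefix
(>= ``min_overlap`` bases, at most 1 mismatch per 10 matched bases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
# DNA form of the standard small-RNA 5' adapter; insert-less ligation products
# begin with it and carry no biological sequence.
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


class ReadRecord(NamedTuple):
    id: str
    sequence: str
    quality: str  # Phred+33 encoded, same length as sequence

    def phred(self) -> list[int]:
        return [ord(c) - PHRED_OFFSET for c in self.quality]


@dataclass
class QCStats:
    """Per-library tally of read fates; every raw read lands in one bucket."""

    raw_reads: int = 0
    clean_reads: int = 0
    removed_n_base: int = 0
    removed_low_quality: int = 0
    removed_short: int = 0
    removed_long: int = 0
    removed_no_insert: int = 0
    library: str = ""

    @property
    def clean_fraction(self) -> float:
        return self.clean_reads / self.raw_reads if self.raw_reads else 0.0

    def check(self) -> None:
        removed = (
            self.removed_n_base
            + self.removed_low_quality
            + self.removed_short
            + self.removed_long
            + self.removed_no_insert
        )
        if self.raw_reads != self.clean_reads + removed:
            raise AssertionError("QC buckets do not partition the raw reads")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["clean_fraction"] = self.clean_fraction
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_tsv(self, path: str | Path) -> None:
        d = self.to_dict()
        lines = ["\t".join(d.keys()), "\t".join(str(v) for v in d.values())]
        Path(path).write_text("\n".join(lines) + "\n")


def trim_adapter(
    read: ReadRecord,
    adapter3: str = DEFAULT_ADAPTER3,
    min_overlap: int = 6,
) -> tuple[ReadRecord, bool]:
    """Truncate at the leftmost admissible 3' adapter occurrence.

    A position is admissible when the adapter prefix of length
    ``L = min(len(adapter3), bases remaining)`` matches with at most
    ``L // 10`` mismatches and ``L >= min_overlap``. Qualities are truncated
    in lockstep. Returns the (possibly) trimmed read and whether trimming
    occurred.
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = read.sequence
    n = len(seq)
    for i in range(n - min_overlap + 1):
        L = min(len(adapter3), n - i)
        allowed = L // 10
        mismatches = 0
        for a, b in zip(seq[i : i + L], adapter3):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        if mismatches <= allowed:
            return ReadRecord(read.id, seq[:i], read.quality[:i]), True
    return read, False


def filter_read(
    read: ReadRecord,
    min_len: int = 18,
    max_len: int = 30,
    q_soft: int = 13,
    max_soft: int = 6,
    q_hard: int = 10,
    max_hard: int = 4,
) -> str:
    """Classify an adapter-trimmed read: ``keep`` or a rejection reason.

    Rules are evaluated in a fixed order and the first failure is recorded:
    n_base, low_quality, short, long.
    """
    if "N" in read.sequence:
        return "n_base"
    qual = read.quality
    soft_thr = chr(q_soft + PHRED_OFFSET)
    hard_thr = chr(q_hard + PHRED_OFFSET)
    n_soft = sum(1 for c in qual if c < soft_thr)
    if n_soft > max_soft:
        return "low_quality"
    n_hard = sum(1 for c in qual if c < hard_thr)
    if n_hard > max_hard:
        return "low_quality"
    if len(read.sequence) < min_len:
        return "short"
    if len(read.sequence) > max_len:
        return "long"
    return "keep"


def parse_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream FASTQ records; raises ValueError naming the failing record index."""
    import gzip

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc
            yield ReadRecord(title.split()[0], seq, qual)
            index += 1


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")


def run_qc(
    reads: Iterable[ReadRecord],
    adapter3: str = DEFAULT_ADAPTER3,
    adapter5: str | None = DEFAULT_ADAPTER5,
    min_overlap: int = 6,
    min_len: int = 18,
    max_len: int = 30,
    library: str = "",
) -> tuple[list[ReadRecord], QCStats]:
    """Trim and filter a library; returns clean reads (input order) and stats."""
    stats = QCStats(library=library)
    clean: list[ReadRecord] = []
    for read in reads:
        stats.raw_reads += 1
        if adapter5 and read.sequence.startswith(adapter5):
            stats.removed_no_insert += 1
            continue
        trimmed, _ = trim_adapter(read, adapter3, min_overlap)
        if len(trimmed.sequence) == 0:
            stats.removed_no_insert += 1
            continue
        verdict = filter_read(trimmed, min_len=min_len, max_len=max_len)
        if verdict == "keep":
            stats.clean_reads += 1
            clean.append(trimmed)
        else:
            setattr(stats, f"removed_{verdict}", getattr(stats, f"removed_{verdict}") + 1)
    stats.check()
    return clean, stats
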