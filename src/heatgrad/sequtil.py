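"""FASTQ read quality and adapter screening.

Implements the whole-read exclusion rule used upstream of alignment in the
heat-gradient pipeline: a read is discarded when *more than* 30% of its
bases have a Phred quality of 20 *or less* (the 30% bound is strict, the
quality bound inclusive), or when it contains a primer/adapter sequence as
an exact forward-strand substring.  Reads are never trimmed, only kept or
dropped, and input order is preserved.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    qualities: np.ndarray  # Phred scores, one per base

    def __post_init__(self):
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality scores"
            )
        if (self.qualities < 0).any():
            raise ValueError(f"read {self.read_id!r}: negative quality score")


@dataclass
class FilterReport:
    total: int = 0
    kept: int = 0
    dropped_adapter: int = 0
    dropped_low_quality: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "reason": ["kept", "adapter", "low_quality", "total"],
                "count": [self.kept, self.dropped_adapter, self.dropped_low_quality, self.total],
            }
        )


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, encoding: str = "phred33") -> Iterator[ReadRecord]:
    """Iterate FASTQ records (plain or .gz) as :class:`ReadRecord`."""
    fmt = {"phred33": "fastq", "phred64": "fastq-illumina"}[encoding]
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq),
                qualities=np.array(rec.letter_annotations["phred_quality"]),
            )


def write_fastq(records: Iterable[ReadRecord], path) -> int:
    """Write records as Phred+33 FASTQ; returns the number written."""
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for r in records:
            rec = SeqRecord(
                Seq(r.sequence),
                id=r.read_id,
                description="",
                letter_annotations={"phred_quality": list(map(int, r.qualities))},
            )
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def low_quality_fraction(qualities, q_threshold: int = 20) -> float:
    """Fraction of bases with Phred quality <= ``q_threshold`` (inclusive)."""
    q = np.asarray(qualities)
    return float((q <= q_threshold).sum()) / len(q)


def keep_read(
    read: ReadRecord,
    q_threshold: int = 20,
    max_lowq_frac: float = 0.30,
    adapters: Iterable[str] = (),
) -> tuple[bool, str | None]:
    """Apply the exclusion rule to one read; returns (kept, drop_reason)."""
    for ad in adapters:
        if ad and ad in read.sequence:
            return False, "adapter"
    if low_quality_fraction(read.qualities, q_threshold) > max_lowq_frac:
        return False, "low_quality"
    return True, None


def filter_reads(
    reads: Iterable[ReadRecord],
    q_threshold: int = 20,
    max_lowq_frac: float = 0.30,
    adapters: Iterable[str] = (),
) -> tuple[list[ReadRecord], FilterReport]:
    """Screen reads; returns (kept reads in input order, per-reason report).

    Adapter screening runs first, quality screening second; a read failing
    both counts once, under "adapter".  Passing ``adapters=()`` disables
    the adapter screen.
    """
    adapters = tuple(adapters)
    kept: list[ReadRecord] = []
    report = FilterReport()
    for read in reads:
        report.total += 1
        ok, reason = keep_read(read, q_threshold, max_lowq_frac, adapters)
        if ok:
            kept.append(read)
            report.kept += 1
        elif reason == "adapter":
            report.dropped_adapter += 1
        else:
            report.dropped_low_quality += 1
    return kept, report


def filter_fastq_file(
    fastq_in,
    fastq_out,
    q_threshold: int = 20,
    max_lowq_frac: float = 0.30,
    adapters: Iterable[str] = (),
    encoding: str = "phred33",
) -> FilterReport:
    """File-to-file version of :func:`filter_reads` (gzip by suffix)."""
    kept, report = filter_reads(
        read_fastq(fastq_in, encoding), q_threshold, max_lowq_frac, adapters
    )
    write_fastq(kept, fastq_out)
    return report
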