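"""Read-pair preprocessing: transposon-prefix trimming and FASTQ input.

Read 1 of a splinkerette junction library is expected to begin with the
transposon-derived sequence 5'-TAGGGTTAA-3' (terminal-repeat fragment plus
the duplicated TTAA target site).  Pairs whose read 1 does not begin with
the prefix are discarded and counted; in real libraries this discard
fraction is typically around 1%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .config import TRANSPOSON_PREFIX

_ALPHABET = set("ACGTN")


@dataclass
class ReadPair:
    """One paired-end read (sequences uppercase ACGTN)."""

    read1_seq: str
    read2_seq: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.read1_seq or not self.read2_seq:
            raise ValueError("read sequences must be non-empty")
        if not (_ALPHABET >= set(self.read1_seq) and _ALPHABET >= set(self.read2_seq)):
            raise ValueError("read sequences must be ACGTN")


@dataclass
class DiscardStats:
    """Counts of pairs dropped for a missing transposon prefix."""

    total: int = 0
    discarded: int = 0

    @property
    def kept(self) -> int:
        return self.total - self.discarded

    @property
    def fraction(self) -> float:
        return self.discarded / self.total if self.total else 0.0


def trim_prefix(pairs: Iterable[ReadPair],
                prefix: str = TRANSPOSON_PREFIX) -> tuple[list[ReadPair], DiscardStats]:
    """Remove ``prefix`` from read 1 of each pair; discard non-matching pairs.

    Returns the trimmed pairs and the discard statistics.  Trimming is
    idempotent on its own output provided the genomic sequence following the
    junction does not itself begin with the prefix (vanishingly rare and
    biologically meaningful if it does).
    """
    if not prefix or not set(prefix) <= set("ACGT"):
        raise ValueError("prefix must be non-empty uppercase ACGT")
    stats = DiscardStats()
    out: list[ReadPair] = []
    for pair in pairs:
        stats.total += 1
        if pair.read1_seq.startswith(prefix) and len(pair.read1_seq) > len(prefix):
            out.append(ReadPair(pair.read1_seq[len(prefix):], pair.read2_seq,
                                pair.sample_id))
        else:
            stats.discarded += 1
    return out, stats


def read_fastq_pairs(r1_path, r2_path, sample_id: str = "") -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""
    import pysam

    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        for rec1, rec2 in zip(f1, f2):
            yield ReadPair(rec1.sequence.upper(), rec2.sequence.upper(), sample_id)
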