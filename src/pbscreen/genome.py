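"""Reference genome container and small sequence utilities.

Coordinates are 0-based half-open throughout the package; 1-based
coordinates appear only at SAM boundaries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: piggyBac target tetranucleotide; its own reverse complement, which is why
#: insertions can be called identically on either strand.
TTAA = "TTAA"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_ttaa(seq: str) -> list[int]:
    """0-based start positions of every TTAA occurrence in ``seq``.

    Overlapping occurrences are impossible for this motif, but the scan is a
    plain sliding ``str.find`` loop and would report them if they existed.
    """
    hits = []
    i = seq.find(TTAA)
    while i != -1:
        hits.append(i)
        i = seq.find(TTAA, i + 1)
    return hits


@dataclass
class ReferenceGenome:
    """In-memory reference: chromosome name -> uppercase sequence."""

    chroms: dict[str, str]
    _ttaa_cache: dict[str, list[int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.chroms = {name: seq.upper() for name, seq in self.chroms.items()}

    def __getitem__(self, chrom: str) -> str:
        return self.chroms[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chroms

    def names(self) -> list[str]:
        return list(self.chroms)

    def length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence on the forward strand; out-of-bounds positions become N."""
        seq = self.chroms[chrom]
        if start >= 0 and end <= len(seq):
            return seq[start:end]
        left = "N" * max(0, -start)
        right = "N" * max(0, end - len(seq))
        return left + seq[max(0, start):min(end, len(seq))] + right

    def ttaa_sites(self, chrom: str) -> list[int]:
        """Cached TTAA start positions for one chromosome."""
        if chrom not in self._ttaa_cache:
            self._ttaa_cache[chrom] = find_ttaa(self.chroms[chrom])
        return self._ttaa_cache[chrom]

    def write_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.chroms.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "ReferenceGenome":
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})
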