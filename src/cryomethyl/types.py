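"""Core domain containers shared by every stage of the pipeline.

Coordinates are 1-based throughout (matching cytosine-report conventions);
conversion to 0-based half-open BED happens only at the I/O boundary.
A CpG dinucleotide contributes one assayable cytosine per strand and both
are kept as distinct sites — the redundancy between the ``+`` cytosine at
position ``p`` and the ``-`` cytosine at ``p + 1`` is deliberately not
collapsed, because symmetric and asymmetric changes at one CpG cannot be
told apart otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

#: (chrom, pos, strand) — the canonical key of one strand-resolved cytosine.
SiteKey = Tuple[str, int, str]

CONDITIONS = ("fresh", "DMSO", "MeOH", "glycerol")
CRYOPROTECTANTS = ("DMSO", "MeOH", "glycerol")


@dataclass(frozen=True, slots=True)
class CytosineRecord:
    """Methylation counts for one strand-resolved CpG cytosine in one sample.

    ``strand`` is the sense of the cytosine on the reference: ``+`` means the
    reference base at ``pos`` is C (followed by G), ``-`` means it is G
    (preceded by C, i.e. the cytosine lies on the reverse strand). ``.`` marks
    records from the 6-column coverage dialect, which does not carry strand.
    """

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("negative read count")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def ratio(self) -> float:
        """Methylated fraction, recomputed from counts (never trusted from file)."""
        return self.n_meth / self.depth

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)


@dataclass
class SampleMethylome:
    """All cytosine records of one male under one condition, keyed by site."""

    male_id: int
    condition: str
    records: Dict[SiteKey, CytosineRecord] = field(default_factory=dict)

    def add(self, rec: CytosineRecord) -> None:
        self.records[rec.key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def depths(self) -> List[int]:
        return [r.depth for r in self.records.values()]


@dataclass
class GeneModel:
    """One gene reduced to its longest transcript's exon chain.

    ``tss``/``tes`` are the strand-aware 5' and 3' ends; ``exons`` are 1-based
    closed intervals sorted in transcription order (descending coordinates on
    the minus strand). Introns are the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: List[Tuple[int, int]]

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    def introns(self) -> List[Tuple[int, int]]:
        """Gaps between consecutive exons, in transcription order."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return out


def union_site_keys(samples: Iterable[SampleMethylome]) -> set:
    """Distinct site keys over a collection of samples."""
    keys: set = set()
    for s in samples:
        keys.update(s.records.keys())
    return keys
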