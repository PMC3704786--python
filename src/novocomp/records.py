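"""Core record types for multi-replicon bacterial genomes.

A genome is modelled as a set of replicons (chromosome, plasmids, or
unplaced contigs for draft assemblies) plus a proteome of CDS translations.
Each protein remembers the replicon it was encoded on and its ordinal
position along that replicon, which downstream orthology clustering uses
for gene-order-conservation tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class RepliconKind(str, Enum):
    CHROMOSOME = "chromosome"
    PLASMID = "plasmid"
    CONTIG = "contig"


@dataclass
class Replicon:
    """A single DNA molecule (or contig) of a genome.

    ``seq`` is upper-case over {A,C,G,T,N}; degenerate IUPAC codes are
    normalised to N on construction because every downstream statistic is
    defined over the unambiguous alphabet.
    """

    id: str
    seq: str
    kind: RepliconKind = RepliconKind.CONTIG

    _VALID = set("ACGTN")

    def __post_init__(self) -> None:
        s = self.seq.upper()
        if set(s) - self._VALID:
            s = "".join(c if c in self._VALID else "N" for c in s)
        self.seq = s
        if isinstance(self.kind, str):
            self.kind = RepliconKind(self.kind)

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """One CDS translation with its genomic context.

    ``gene_order_index`` is the 0-based position of the CDS along its
    replicon in annotation order; it is unique within a replicon.
    ``start``/``end`` are 0-based half-open nucleotide coordinates when
    known (GenBank input or synthetic genomes), else None.
    """

    id: str
    genome_id: str
    replicon_id: str
    seq: str
    gene_order_index: int
    start: Optional[int] = None
    end: Optional[int] = None
    strand: int = 1

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"protein {self.id}: empty sequence")
        self.seq = self.seq.upper().rstrip("*")


@dataclass
class GenomeRecord:
    """A genome: replicons plus extracted proteome."""

    id: str
    replicons: list[Replicon] = field(default_factory=list)
    proteome: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {r.id for r in self.replicons}
        for p in self.proteome:
            if p.replicon_id not in known:
                raise ValueError(
                    f"protein {p.id} references unknown replicon {p.replicon_id!r}"
                )

    def replicon(self, rid: str) -> Replicon:
        for r in self.replicons:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.replicons)

    @property
    def has_labelled_replicons(self) -> bool:
        """True when replicon kinds are assigned (complete genome), i.e.
        at least one replicon is not an unplaced contig."""
        return any(r.kind is not RepliconKind.CONTIG for r in self.replicons)

    def proteins_on(self, rid: str) -> list[ProteinRecord]:
        return [p for p in self.proteome if p.replicon_id == rid]


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def iter_proteins(genomes: Iterable[GenomeRecord]) -> Iterable[ProteinRecord]:
    for g in genomes:
        yield from g.proteome
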