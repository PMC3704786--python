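"""Reading and writing genomes: FASTA and GenBank flat files.

GenBank input populates the proteome from CDS ``/translation`` qualifiers
in feature order; CDS features lacking a translation are translated
in-frame from their coordinates (bacterial table 11), and pseudo-genes are
skipped with a warning. Replicon kind is inferred per record: a
``/plasmid`` source qualifier marks a plasmid, a complete (non-WGS)
record without one is a chromosome, anything else stays a contig.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import GenomeRecord, ProteinRecord, Replicon, RepliconKind

logger = logging.getLogger(__name__)


class GenomeParseError(ValueError):
    """Raised when an input record cannot be parsed; names the record."""


def _infer_kind(rec: SeqRecord) -> RepliconKind:
    for feat in rec.features:
        if feat.type == "source" and "plasmid" in feat.qualifiers:
            return RepliconKind.PLASMID
    ann = rec.annotations
    if "plasmid" in (rec.description or "").lower():
        return RepliconKind.PLASMID
    topology_complete = ann.get("topology") == "circular"
    data_division_wgs = "wgs" in {k.lower() for k in ann.get("keywords", [])} or bool(
        ann.get("wgs")
    )
    if topology_complete and not data_division_wgs:
        return RepliconKind.CHROMOSOME
    if "complete genome" in (rec.description or "").lower():
        return RepliconKind.CHROMOSOME
    return RepliconKind.CONTIG


def _extract_cds(rec: SeqRecord, genome_id: str) -> list[ProteinRecord]:
    proteins: list[ProteinRecord] = []
    order = 0
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        quals = feat.qualifiers
        if "pseudo" in quals or "pseudogene" in quals:
            logger.warning("skipping pseudo CDS in %s at %s", rec.id, feat.location)
            continue
        pid = (
            quals.get("locus_tag", quals.get("protein_id", [None]))[0]
            or f"{rec.id}_cds{order}"
        )
        translation = quals.get("translation", [None])[0]
        if translation is None:
            try:
                translation = str(
                    feat.extract(rec.seq).translate(table=11, cds=False)
                ).rstrip("*")
            except Exception as exc:  # malformed coordinates
                logger.warning("cannot translate CDS %s in %s: %s", pid, rec.id, exc)
                continue
        if not translation:
            continue
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = feat.location.strand or 1
        proteins.append(
            ProteinRecord(
                id=pid,
                genome_id=genome_id,
                replicon_id=rec.id,
                seq=translation,
                gene_order_index=order,
                start=start,
                end=end,
                strand=strand,
            )
        )
        order += 1
    return proteins


def read_genome(
    path: str | Path,
    format: str = "genbank",
    genome_id: Optional[str] = None,
    protein_fasta: Optional[str | Path] = None,
) -> GenomeRecord:
    """Read a (possibly multi-replicon) genome.

    Parameters
    ----------
    path
        FASTA or GenBank file; every record becomes one replicon.
    format
        ``"fasta"`` or ``"genbank"``.
    genome_id
        Genome identifier; defaults to the file stem.
    protein_fasta
        Optional companion protein FASTA (FASTA input carries no CDS
        features, so the proteome is empty unless this is given).
    """
    path = Path(path)
    gid = genome_id or path.stem
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unknown format {format!r}")
    replicons: list[Replicon] = []
    proteome: list[ProteinRecord] = []
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:
        raise GenomeParseError(f"{path}: cannot parse as {format}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"{path}: no records parsed as {format}")
    for rec in records:
        if len(rec.seq) == 0:
            raise GenomeParseError(f"{path}: record {rec.id} has empty sequence")
        kind = _infer_kind(rec) if format == "genbank" else RepliconKind.CONTIG
        replicons.append(Replicon(id=rec.id, seq=str(rec.seq), kind=kind))
        if format == "genbank":
            proteome.extend(_extract_cds(rec, gid))
    if protein_fasta is not None:
        proteome.extend(
            read_protein_fasta(protein_fasta, genome_id=gid, replicon_id=replicons[0].id)
        )
    return GenomeRecord(id=gid, replicons=replicons, proteome=proteome)


def read_protein_fasta(
    path: str | Path, genome_id: str, replicon_id: str = "unplaced"
) -> list[ProteinRecord]:
    """Read a proteome FASTA; gene order follows file order."""
    out = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        out.append(
            ProteinRecord(
                id=rec.id,
                genome_id=genome_id,
                replicon_id=replicon_id,
                seq=str(rec.seq),
                gene_order_index=i,
            )
        )
    return out


def write_protein_fasta(proteome: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(p.seq), id=p.id, description=p.genome_id) for p in proteome]
    SeqIO.write(recs, str(path), "fasta")


def write_genbank(genome: GenomeRecord, path: str | Path) -> None:
    """Write a GenomeRecord as a GenBank flat file (one record per replicon).

    CDS features carry /locus_tag and /translation; plasmid replicons get a
    /plasmid source qualifier so kind inference round-trips.
    """
    records = []
    for rep in genome.replicons:
        rec = SeqRecord(Seq(rep.seq), id=rep.id, name=rep.id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        if rep.kind is RepliconKind.CHROMOSOME:
            rec.annotations["topology"] = "circular"
            rec.description = f"{genome.id} complete genome"
        elif rep.kind is RepliconKind.PLASMID:
            rec.annotations["topology"] = "circular"
        src_quals = {"organism": [genome.id]}
        if rep.kind is RepliconKind.PLASMID:
            src_quals["plasmid"] = [rep.id]
        rec.features.append(
            SeqFeature(FeatureLocation(0, rep.length), type="source", qualifiers=src_quals)
        )
        for p in sorted(genome.proteins_on(rep.id), key=lambda p: p.gene_order_index):
            start = p.start if p.start is not None else 0
            end = p.end if p.end is not None else rep.length
            rec.features.append(
                SeqFeature(
                    FeatureLocation(start, end, strand=p.strand),
                    type="CDS",
                    qualifiers={"locus_tag": [p.id], "translation": [p.seq]},
                )
            )
        records.append(rec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # BiopythonWarning on long locus names
        SeqIO.write(records, str(path), "genbank")


def gc_content(genome: GenomeRecord, chromosome_only: bool = False) -> float:
    """GC percentage over all replicons: 100·(G+C)/(A+C+G+T), N excluded.

    ``chromosome_only`` restricts to replicons labelled chromosome (the
    convention for a complete genome's headline GC% is ambiguous, so both
    views are available).
    """
    g = c = a = t = 0
    for rep in genome.replicons:
        if chromosome_only and rep.kind is not RepliconKind.CHROMOSOME:
            continue
        s = rep.seq
        g += s.count("G")
        c += s.count("C")
        a += s.count("A")
        t += s.count("T")
    total = a + c + g + t
    if total == 0:
        raise ValueError(f"genome {genome.id}: no unambiguous bases, GC% undefined")
    return 100.0 * (g + c) / total
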