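"""Pan-genome orthologous clustering and core/singleton partitioning.

Proteins from all genomes are clustered into orthologous groups by
connected components of a cross-genome reciprocal-best-hit graph at the
stated thresholds (default 65% identity, alignment covering >=70% of the
longer sequence, E <= 1e-10). Paralog ambiguities — a query with several
equally scoring candidate partners in another genome — are resolved by a
conservation-of-gene-order tie-break: the candidate whose flanking +-3
genes share more cross-genome best-hit partners with the query's flanks
wins. This is a deliberate simplification of PanOCT's weighted BLAST
score ratio + gene-order scheme: the partition contract at the stated
cutoffs is kept, the full weighting is not reproduced.

The partition labels each cluster: *core* (present in every genome),
*unique core* of a genome subset (present in exactly that subset), and
*singletons* (clusters of one protein). For complete genomes with
labelled replicons, the fraction of singletons of plasmid origin is
reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .align import HomologHit, _hit_key, search
from .records import GenomeRecord, ProteinRecord, RepliconKind

logger = logging.getLogger(__name__)


@dataclass
class ClusterThresholds:
    min_identity: float = 65.0
    min_overlap: float = 0.70  # aligned columns / longer sequence
    max_evalue: float = 1e-10
    overlap_of: str = "longer"  # or "shorter"


@dataclass
class OrthologCluster:
    id: str
    members: list[tuple[str, str]]  # (genome_id, protein_id)

    @property
    def genome_set(self) -> frozenset[str]:
        return frozenset(g for g, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PanGenomePartition:
    clusters: list[OrthologCluster]
    genome_ids: list[str]
    venn: dict[frozenset[str], int] = field(init=False)

    def __post_init__(self) -> None:
        self.venn = {}
        for c in self.clusters:
            self.venn[c.genome_set] = self.venn.get(c.genome_set, 0) + 1

    @property
    def core(self) -> list[OrthologCluster]:
        full = frozenset(self.genome_ids)
        return [c for c in self.clusters if c.genome_set == full]

    def unique_core(self, subset: Sequence[str]) -> list[OrthologCluster]:
        """Clusters present in exactly this genome subset (and no other)."""
        target = frozenset(subset)
        return [c for c in self.clusters if c.genome_set == target]

    def singletons(self, genome_id: Optional[str] = None) -> list[OrthologCluster]:
        """Clusters of a single protein, optionally for one genome."""
        single = [c for c in self.clusters if len(c) == 1]
        if genome_id is None:
            return single
        return [c for c in single if c.members[0][0] == genome_id]


def _pair_hits(
    prot_a: Sequence[ProteinRecord],
    prot_b: Sequence[ProteinRecord],
    th: ClusterThresholds,
    precomputed: Optional[Sequence[HomologHit]] = None,
) -> list[HomologHit]:
    if precomputed is not None:
        return [
            h
            for h in precomputed
            if h.pct_identity >= th.min_identity
            and (h.longer_overlap if th.overlap_of == "longer" else h.shorter_cov)
            >= th.min_overlap
            and h.evalue <= th.max_evalue
        ]
    return search(
        prot_a,
        prot_b,
        th.min_identity,
        th.min_overlap,
        th.max_evalue,
        coverage_of=th.overlap_of,
    )


def _cgo_support(
    query: ProteinRecord,
    candidate: ProteinRecord,
    order_index: dict[str, ProteinRecord],
    provisional: dict[tuple[str, str], str],
    window: int = 3,
) -> int:
    """Conservation-of-gene-order support: how many of the query's flanking
    +-window genes have a provisional best hit among the candidate's
    flanking +-window genes."""
    qn = _neighbours(query, order_index, window)
    cn = {p.id for p in _neighbours(candidate, order_index, window)}
    support = 0
    for q in qn:
        partner = provisional.get((q.id, candidate.genome_id))
        if partner is not None and partner in cn:
            support += 1
    return support


def _neighbours(
    p: ProteinRecord, order_index: dict[str, ProteinRecord], window: int
) -> list[ProteinRecord]:
    out = []
    for d in range(-window, window + 1):
        if d == 0:
            continue
        q = order_index.get(f"{p.genome_id}\t{p.replicon_id}\t{p.gene_order_index + d}")
        if q is not None:
            out.append(q)
    return out


def cluster_orthologs(
    genomes: Sequence[GenomeRecord],
    thresholds: ClusterThresholds | None = None,
    precomputed: Optional[dict[tuple[str, str], list[HomologHit]]] = None,
) -> list[OrthologCluster]:
    """Cluster all proteins into orthologous groups across genomes.

    Builds the RBH graph for every genome pair under the thresholds, then
    takes connected components; every protein lands in exactly one cluster
    (unmatched proteins become singleton clusters). ``precomputed`` maps
    ordered genome-id pairs to unfiltered hit lists.
    """
    th = thresholds or ClusterThresholds()
    prot_by_genome = {g.id: list(g.proteome) for g in genomes}
    by_id = {(g.id, p.id): p for g in genomes for p in g.proteome}
    have_order = all(
        p.gene_order_index is not None for g in genomes for p in g.proteome
    )
    if not have_order:
        logger.info("gene order missing; paralog tie-break degrades to score only")
    order_index = {
        f"{p.genome_id}\t{p.replicon_id}\t{p.gene_order_index}": p
        for g in genomes
        for p in g.proteome
    }

    graph = nx.Graph()
    for g in genomes:
        for p in g.proteome:
            graph.add_node((g.id, p.id))

    gids = [g.id for g in genomes]
    for i in range(len(gids)):
        for j in range(i + 1, len(gids)):
            a, b = gids[i], gids[j]
            hits_ab = _pair_hits(
                prot_by_genome[a],
                prot_by_genome[b],
                th,
                None if precomputed is None else precomputed[(a, b)],
            )
            hits_ba = _pair_hits(
                prot_by_genome[b],
                prot_by_genome[a],
                th,
                None if precomputed is None else precomputed[(b, a)],
            )
            best_ab = _resolve_best(hits_ab, a, b, by_id, order_index, have_order)
            best_ba = _resolve_best(hits_ba, b, a, by_id, order_index, have_order)
            for qa, sb in best_ab.items():
                if best_ba.get(sb) == qa:
                    graph.add_edge((a, qa), (b, sb))

    clusters = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(comps):
        members = sorted(comp)
        clusters.append(OrthologCluster(id=f"OG{k + 1:05d}", members=members))
    return clusters


def _resolve_best(
    hits: list[HomologHit],
    qg: str,
    sg: str,
    by_id: dict[tuple[str, str], ProteinRecord],
    order_index: dict[str, ProteinRecord],
    have_order: bool,
) -> dict[str, str]:
    """Best subject per query with CGO tie-break on exact raw-score ties."""
    by_query: dict[str, list[HomologHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    # provisional winners by score alone, for CGO context
    provisional: dict[tuple[str, str], str] = {}
    for q, hs in by_query.items():
        provisional[(q, sg)] = max(hs, key=_hit_key).subject_id
    resolved: dict[str, str] = {}
    for q, hs in by_query.items():
        top = max(h.raw_score for h in hs)
        tied = [h for h in hs if h.raw_score == top]
        if len(tied) > 1 and have_order:
            query = by_id[(qg, q)]
            scored = [
                (
                    _cgo_support(query, by_id[(sg, h.subject_id)], order_index, provisional),
                    h,
                )
                for h in tied
            ]
            best_cgo = max(s for s, _ in scored)
            tied = [h for s, h in scored if s == best_cgo]
        resolved[q] = max(tied, key=_hit_key).subject_id
    return resolved


def partition(
    clusters: Sequence[OrthologCluster], genome_ids: Sequence[str]
) -> PanGenomePartition:
    """Partition clusters into Venn cells over the genome set."""
    return PanGenomePartition(clusters=list(clusters), genome_ids=list(genome_ids))


def singleton_replicon_fraction(
    part: PanGenomePartition, genome: GenomeRecord
) -> Optional[float]:
    """Percentage of a genome's singletons of plasmid origin (integer-rounded).

    Returns None (not-computable) for draft genomes whose replicons carry
    no chromosome/plasmid labels, and for genomes without singletons.
    """
    if not genome.has_labelled_replicons:
        logger.warning("genome %s has unlabelled replicons; plasmid fraction not computable", genome.id)
        return None
    kind_of = {p.id: genome.replicon(p.replicon_id).kind for p in genome.proteome}
    singles = part.singletons(genome.id)
    if not singles:
        return None
    on_plasmid = sum(
        1 for c in singles if kind_of.get(c.members[0][1]) is RepliconKind.PLASMID
    )
    return float(round(100.0 * on_plasmid / len(singles)))
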