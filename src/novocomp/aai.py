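"""Average amino acid identity (AAI) between genome pairs.

AAI is the unweighted mean percent identity over reciprocal-best-hit (RBH)
protein pairs of two genomes, the standard whole-genome relatedness index
for species delineation. Default thresholds follow the conventional AAI
protocol: >=30% identity, alignment covering >=70% of the shorter
sequence, E <= 1e-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .align import HomologHit, best_hits, search
from .records import GenomeRecord, ProteinRecord


@dataclass
class AAIThresholds:
    min_identity: float = 30.0
    min_cov: float = 0.70
    max_evalue: float = 1e-6


@dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    n_rbh: int
    aai: float


def reciprocal_best_hits(
    hits_ab: Sequence[HomologHit], hits_ba: Sequence[HomologHit]
) -> list[tuple[str, str]]:
    """RBH pairs (a, b): b is a's best hit in B and a is b's best hit in A.

    Ties in score break by higher percent identity then lexicographic
    subject id, so the pairing is deterministic.
    """
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = []
    for a, hab in best_ab.items():
        b = hab.subject_id
        hba = best_ba.get(b)
        if hba is not None and hba.subject_id == a:
            pairs.append((a, b))
    return sorted(pairs)


def aai(
    genome_a: GenomeRecord | Sequence[ProteinRecord],
    genome_b: GenomeRecord | Sequence[ProteinRecord],
    thresholds: AAIThresholds | None = None,
    one_way: bool = False,
    precomputed: Optional[tuple[Sequence[HomologHit], Sequence[HomologHit]]] = None,
) -> AAIResult:
    """AAI between two proteomes.

    ``one_way`` averages over A's best hits only instead of RBH pairs.
    ``precomputed`` supplies (hits_ab, hits_ba) from an earlier search so
    callers can filter a single permissive search at several thresholds.
    """
    th = thresholds or AAIThresholds()
    prot_a = genome_a.proteome if isinstance(genome_a, GenomeRecord) else list(genome_a)
    prot_b = genome_b.proteome if isinstance(genome_b, GenomeRecord) else list(genome_b)
    name_a = genome_a.id if isinstance(genome_a, GenomeRecord) else prot_a[0].genome_id
    name_b = genome_b.id if isinstance(genome_b, GenomeRecord) else prot_b[0].genome_id

    if precomputed is not None:
        hits_ab = _filter(precomputed[0], th)
        hits_ba = _filter(precomputed[1], th)
    else:
        hits_ab = search(prot_a, prot_b, th.min_identity, th.min_cov, th.max_evalue)
        hits_ba = search(prot_b, prot_a, th.min_identity, th.min_cov, th.max_evalue)

    ident = {(h.query_id, h.subject_id): h.pct_identity for h in hits_ab}
    ident.update({(h.subject_id, h.query_id): h.pct_identity for h in hits_ba})

    if one_way:
        best = best_hits(hits_ab)
        vals = [h.pct_identity for h in best.values()]
        n = len(vals)
    else:
        pairs = reciprocal_best_hits(hits_ab, hits_ba)
        vals = [ident[p] for p in pairs]
        n = len(pairs)
    if n == 0:
        raise ValueError(f"no RBH pairs between {name_a} and {name_b}; AAI undefined")
    return AAIResult(genome_a=name_a, genome_b=name_b, n_rbh=n, aai=float(np.mean(vals)))


def _filter(hits: Sequence[HomologHit], th: AAIThresholds) -> list[HomologHit]:
    return [
        h
        for h in hits
        if h.pct_identity >= th.min_identity
        and h.shorter_cov >= th.min_cov
        and h.evalue <= th.max_evalue
    ]


def aai_matrix(
    genomes: Sequence[GenomeRecord],
    thresholds: AAIThresholds | None = None,
    precomputed: Optional[dict[tuple[str, str], list[HomologHit]]] = None,
) -> "np.ndarray":
    """Symmetric AAI matrix over a genome list (diagonal = 100).

    ``precomputed`` maps ordered genome-id pairs to hit lists from one
    permissive all-vs-all search.
    """
    n = len(genomes)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pre = None
            if precomputed is not None:
                pre = (
                    precomputed[(genomes[i].id, genomes[j].id)],
                    precomputed[(genomes[j].id, genomes[i].id)],
                )
            res = aai(genomes[i], genomes[j], thresholds, precomputed=pre)
            mat[i, j] = mat[j, i] = res.aai
    return mat
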