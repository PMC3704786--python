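"""Trait screening: quorum-sensing and marine-adaptation markers, pI.

Screens a proteome against curated reference sets (AHL synthases LuxI,
LuxR regulators, the sodium-pumping NADH dehydrogenase Nqr, ring-
hydroxylating dioxygenases, and the ectoine biosynthesis enzymes
EctA/B/C), verifies diagnostic features, and computes protein isoelectric
points:

* LuxI candidates must carry the three absolutely conserved synthase
  residues Arg24, Phe28 and Trp34 (numbering of a designated reference
  synthase), read off a global alignment to that reference.
* Rieske [2Fe-2S] binding sites match C-x-H-x(13..25)-C-x-x-H; the
  residue count between the first His and the second Cys separates
  dioxygenase groups (17 canonical for Group II; 19 in variant enzymes).
* The ectoine cassette is called complete when hits to all of EctA, EctB
  and EctC fall within one genomic window (default 20 kb) on a single
  replicon.
* pI is the bisection root of the Henderson–Hasselbalch net charge with
  the EMBOSS pKa table (ProPAS-style calculation; exact tables differ by
  ~0.1 pH unit between tools).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from Bio import Align
from Bio.Align import substitution_matrices

from .align import HomologHit, search
from .records import GenomeRecord, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSet:
    """Named set of curated reference proteins."""

    name: str
    members: list[tuple[str, str, str]]  # (id, protein seq, annotation)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"reference set {self.name}: empty")
        ids = [m[0] for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"reference set {self.name}: duplicate ids")

    def as_proteins(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(
                id=rid, genome_id=self.name, replicon_id="ref", seq=seq, gene_order_index=i
            )
            for i, (rid, seq, _ann) in enumerate(self.members)
        ]


@dataclass
class MotifReport:
    protein_id: str
    motif: str  # "luxI_triad" or "rieske"
    residues_found: dict[str, str] = field(default_factory=dict)
    spacing: Optional[int] = None
    verdict: bool = False


@dataclass
class CassetteCall:
    genome_id: str
    components_found: set[str] = field(default_factory=set)
    window_span: Optional[int] = None
    replicon_id: Optional[str] = None
    complete: bool = False


def screen(
    proteome: Sequence[ProteinRecord] | GenomeRecord,
    refset: ReferenceSet,
    min_identity: float = 30.0,
    max_evalue: float = 1e-6,
) -> list[HomologHit]:
    """Screen a proteome against a reference set.

    Returns the best-scoring passing reference hit per query protein; an
    empty list is a meaningful negative (e.g. absence of the Nqr sodium
    pump in a genome).
    """
    prots = proteome.proteome if isinstance(proteome, GenomeRecord) else list(proteome)
    hits = search(
        prots,
        refset.as_proteins(),
        min_identity=min_identity,
        max_evalue=max_evalue,
    )
    best: dict[str, HomologHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (h.raw_score, h.pct_identity) > (cur.raw_score, cur.pct_identity):
            best[h.query_id] = h
    return sorted(best.values(), key=lambda h: h.query_id)


# ---------------------------------------------------------------- motifs

_TRIAD = {24: "R", 28: "F", 34: "W"}


def check_luxI_triad(candidate: str, reference: str) -> MotifReport:
    """Verify the conserved AHL-synthase triad Arg24/Phe28/Trp34.

    The candidate is globally aligned to the reference synthase and the
    candidate residues in the alignment columns of reference positions
    24, 28 and 34 (1-based) are read; pass iff they are R, F, W. A gap in
    any column is recorded as "-" and fails.
    """
    a = Align.PairwiseAligner()
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    a.mode = "global"
    aln = a.align(reference, candidate)[0]
    ref_row, cand_row = str(aln[0]), str(aln[1])
    found: dict[str, str] = {}
    ref_pos = 0
    want = dict(_TRIAD)
    for col in range(len(ref_row)):
        if ref_row[col] != "-":
            ref_pos += 1
            if ref_pos in want:
                found[str(ref_pos)] = cand_row[col]
    for pos in _TRIAD:
        found.setdefault(str(pos), "-")
    verdict = all(found[str(p)] == aa for p, aa in _TRIAD.items())
    return MotifReport(
        protein_id="", motif="luxI_triad", residues_found=found, verdict=verdict
    )


_RIESKE = re.compile(r"C.H(.{13,25}?)C..H")


def rieske_spacing(seq: str) -> Optional[int]:
    """Residues between first His and second Cys of a Rieske [2Fe-2S] site.

    Matches C-x-H-x(13..25)-C-x-x-H (non-greedy, first match); additional
    matches are logged. Returns None when the motif is absent.
    """
    matches = list(_RIESKE.finditer(seq))
    if not matches:
        return None
    if len(matches) > 1:
        logger.info(
            "multiple Rieske motifs (%d); reporting the first", len(matches)
        )
    return len(matches[0].group(1))


def rieske_report(protein: ProteinRecord) -> MotifReport:
    spacing = rieske_spacing(protein.seq)
    return MotifReport(
        protein_id=protein.id,
        motif="rieske",
        spacing=spacing,
        verdict=spacing is not None,
    )


# ---------------------------------------------------------------- cassette

def detect_cassette(
    genome: GenomeRecord,
    component_refsets: dict[str, ReferenceSet],
    window: int = 20000,
    min_identity: float = 30.0,
    max_evalue: float = 1e-6,
) -> CassetteCall:
    """Detect a colocalised gene cassette (e.g. ectABC).

    Screens the proteome against each component's reference set; the call
    is complete iff at least one hit of every component lies within a
    single window of ``window`` bp on one replicon. Requires CDS
    coordinates on the proteome.
    """
    comp_hits: dict[str, list[ProteinRecord]] = {}
    by_id = {p.id: p for p in genome.proteome}
    for comp, refset in component_refsets.items():
        hits = screen(genome, refset, min_identity, max_evalue)
        comp_hits[comp] = [by_id[h.query_id] for h in hits]
    found = {c for c, hs in comp_hits.items() if hs}
    call = CassetteCall(genome_id=genome.id, components_found=found)
    if found != set(component_refsets):
        return call
    best_span: Optional[tuple[int, str]] = None
    for rep in genome.replicons:
        per_comp = [
            [p for p in comp_hits[c] if p.replicon_id == rep.id and p.start is not None]
            for c in component_refsets
        ]
        if any(not lst for lst in per_comp):
            continue
        import itertools

        for combo in itertools.product(*per_comp):
            lo = min(p.start for p in combo)
            hi = max(p.end for p in combo)
            span = hi - lo
            if span <= window and (best_span is None or span < best_span[0]):
                best_span = (span, rep.id)
    if best_span is not None:
        call.complete = True
        call.window_span = best_span[0]
        call.replicon_id = best_span[1]
    return call


# ---------------------------------------------------------------- pI

#: EMBOSS pKa values: termini plus ionisable side chains
PKA_EMBOSS = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_ACIDIC = ("C", "D", "E", "Y")
_BASIC = ("H", "K", "R")


def net_charge(seq: str, ph: float | np.ndarray, pka: dict[str, float] = PKA_EMBOSS):
    """Henderson–Hasselbalch net charge at a pH (scalar or array).

    Positive groups (N-terminus, H, K, R) contribute 1/(1+10^(pH−pKa));
    negative groups (C-terminus, C, D, E, Y) contribute −1/(1+10^(pKa−pH)).
    X and other unknown residues carry no charge.
    """
    ph = np.asarray(ph, dtype=float)
    z = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    z = z - 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in _BASIC:
        n = seq.count(aa)
        if n:
            z = z + n / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        n = seq.count(aa)
        if n:
            z = z - n / (1.0 + 10.0 ** (pka[aa] - ph))
    return z if z.shape else float(z)


def isoelectric_point(
    seq: str, pka: dict[str, float] = PKA_EMBOSS, tol: float = 0.001
) -> float:
    """pI by bisection of the net-charge curve on [0, 14] to ``tol``.

    The charge curve is strictly decreasing in pH, so the root is unique.
    Termini always ionise, so every non-empty sequence has a defined pI;
    an empty sequence raises.
    """
    if not seq:
        raise ValueError("empty sequence: pI undefined")
    lo, hi = 0.0, 14.0
    zlo, zhi = net_charge(seq, lo, pka), net_charge(seq, hi, pka)
    if zlo < 0 or zhi > 0:  # pragma: no cover - termini make this unreachable
        raise ValueError("net charge does not change sign on [0, 14]; pI undefined")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def median_proteome_pI(
    proteome: Sequence[ProteinRecord] | GenomeRecord,
    pka: dict[str, float] = PKA_EMBOSS,
) -> float:
    """Median pI over all proteins of a proteome."""
    prots = proteome.proteome if isinstance(proteome, GenomeRecord) else list(proteome)
    vals = []
    for p in prots:
        try:
            vals.append(isoelectric_point(p.seq, pka))
        except ValueError:
            continue
    if not vals:
        raise ValueError("no protein with defined pI")
    return float(np.median(vals))
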