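"""Synthetic genomes and proteomes with known ground truth.

Everything the pipeline measures can be planted here and recovered:

* nucleotide replicons are first-order Markov chains, so the expected
  strand-symmetrised dinucleotide signature (rho*) of every genome is
  available in closed form from the chain's stationary distribution;
* proteomes are built from ortholog families diverged to a target percent
  identity (BLOSUM-weighted substitutions, no indels) plus per-genome
  singletons, with chromosome/plasmid assignment and gene order laid out
  explicitly;
* diagnostic markers are planted with controlled properties: AHL-synthase
  (LuxI-like) candidates with the Arg24/Phe28/Trp34 triad intact or
  broken, Rieske-motif proteins with a chosen His–Cys spacing, cognate
  LuxR partners and LuxR "solos", and colocalised ectABC cassettes.

Protein sequences are generated independently of the nucleotide sequence
(CDS translations are written directly into the GenBank features); this
decouples signature tests from proteome tests, mirroring how the analyses
themselves are independent.

All randomness flows from a single mandatory seed; identical spec + seed
gives byte-identical output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .records import GenomeRecord, ProteinRecord, Replicon, RepliconKind
from .signature import BASES, DINUCS, DinucProfile

AA = "ACDEFGHIKLMNPQRSTVWY"

#: background amino-acid frequencies (approximate bacterial proteome
#: composition), normalised at import
_AA_FREQ = np.array(
    [7.8, 1.1, 5.2, 6.3, 4.0, 7.2, 2.2, 5.6, 5.6, 9.5, 2.3, 4.3, 4.9, 4.0, 5.3, 6.9, 5.7, 6.8, 1.2, 3.1]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()


def _blosum_replacement_matrix() -> np.ndarray:
    """P(b | a, substitution) proportional to 2^(S62(a,b)/2), b != a."""
    blosum = substitution_matrices.load("BLOSUM62")
    m = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            if i != j:
                m[i, j] = 2.0 ** (blosum[a, b] / 2.0)
        m[i] /= m[i].sum()
    return m


_REPLACE = _blosum_replacement_matrix()
_AA_INDEX = {a: i for i, a in enumerate(AA)}


def random_protein(length: int, rng: np.random.Generator, alphabet: str = AA) -> str:
    if alphabet == AA:
        return "".join(rng.choice(list(AA), size=length, p=_AA_FREQ))
    return "".join(rng.choice(list(alphabet), size=length))


def mutate_protein(
    seq: str,
    sub_rate: float,
    rng: np.random.Generator,
    preserve: frozenset[int] = frozenset(),
) -> str:
    """Substitute each position independently at ``sub_rate`` with a
    BLOSUM62-weighted replacement; 0-based positions in ``preserve`` are
    never touched."""
    out = list(seq)
    hit = np.flatnonzero(rng.random(len(seq)) < sub_rate)
    for pos in hit:
        if pos in preserve or seq[pos] not in _AA_INDEX:
            continue
        out[pos] = AA[rng.choice(20, p=_REPLACE[_AA_INDEX[seq[pos]]])]
    return "".join(out)


def pairwise_identity(a: str, b: str) -> float:
    """Column-wise identity of two equal-length (indel-free) sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def gen_ortholog_family(
    ancestor_length: int,
    n_copies: int,
    target_identity: float,
    seed_or_rng: int | np.random.Generator,
    preserve: frozenset[int] = frozenset(),
    ancestor: Optional[str] = None,
) -> tuple[list[str], np.ndarray]:
    """Generate an ortholog family at a target pairwise identity.

    Each copy is independently mutated from a common ancestor at rate
    s = 1 − sqrt(target), so the expected pairwise identity between any
    two copies is ~target (two independent survival events per column,
    plus a negligible convergent-substitution term). Returns the copies
    and the realised pairwise identity matrix.
    """
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target identity must be in (0, 1]")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    anc = ancestor if ancestor is not None else random_protein(ancestor_length, rng)
    rate = 1.0 - np.sqrt(target_identity)
    copies = [mutate_protein(anc, rate, rng, preserve) for _ in range(n_copies)]
    ident = np.ones((n_copies, n_copies))
    for i in range(n_copies):
        for j in range(i + 1, n_copies):
            ident[i, j] = ident[j, i] = pairwise_identity(copies[i], copies[j])
    return copies, ident


# ------------------------------------------------------------- nucleotide

@dataclass
class MarkovParams:
    """First-order Markov chain over ACGT: initial distribution and a
    4x4 row-stochastic transition matrix (rows/cols in ACGT order)."""

    initial: np.ndarray
    transition: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.initial.shape != (4,) or self.transition.shape != (4, 4):
            raise ValueError("initial must be length-4, transition 4x4")
        if np.any(self.initial < 0) or np.any(self.transition < 0):
            raise ValueError("negative probabilities")
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")

    def stationary(self) -> np.ndarray:
        vals, vecs = np.linalg.eig(self.transition.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi)
        return pi / pi.sum()

    @classmethod
    def uniform(cls) -> "MarkovParams":
        return cls(np.full(4, 0.25), np.full((4, 4), 0.25))


def expected_profile(params: MarkovParams, genome_id: str = "expected") -> DinucProfile:
    """Analytic strand-symmetrised signature of the chain at stationarity.

    q(XY) = pi_X P_XY; symmetrisation averages each quantity with its
    reverse complement (complement of base index i is 3−i in ACGT order).
    """
    pi = params.stationary()
    q = pi[:, None] * params.transition
    q_sym = 0.5 * (q + q[::-1, ::-1].T)
    pi_sym = 0.5 * (pi + pi[::-1])
    rho = {}
    dinuc_freq = {}
    for i, x in enumerate(BASES):
        for j, y in enumerate(BASES):
            xy = x + y
            dinuc_freq[xy] = float(q_sym[i, j])
            denom = pi_sym[i] * pi_sym[j]
            rho[xy] = float(q_sym[i, j] / denom) if denom > 0 else 0.0
    return DinucProfile(
        genome_id=genome_id,
        mono_freq={b: float(pi_sym[i]) for i, b in enumerate(BASES)},
        dinuc_freq=dinuc_freq,
        rho=rho,
    )


def gen_markov_sequence(
    params: MarkovParams, length: int, rng: np.random.Generator
) -> str:
    """Sample a sequence from the chain (started at its stationary
    distribution, so expected dinucleotide frequencies are stationary)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    cum = np.cumsum(params.transition, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int8)
    state = int(np.searchsorted(np.cumsum(params.stationary()), u[0]))
    state = min(state, 3)
    out[0] = state
    for k in range(1, length):
        state = int(np.searchsorted(cum[state], u[k]))
        state = min(state, 3)
        out[k] = state
    return "".join(BASES[i] for i in out)


def gen_genome(
    params: MarkovParams,
    length: int,
    seed: int,
    replicon_id: str = "chr",
) -> tuple[Replicon, DinucProfile]:
    """One Markov replicon plus its analytic expected signature."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    seq = gen_markov_sequence(params, length, rng)
    return Replicon(id=replicon_id, seq=seq), expected_profile(params, replicon_id)


def gc_markov(gc: float = 0.63, cg_factor: float = 0.6, aa_factor: float = 1.0) -> MarkovParams:
    """Convenience chain with a target GC content, CpG-style depletion of
    the CG dinucleotide (``cg_factor`` < 1) and optional boosting of
    AA/TT stacking (``aa_factor`` > 1)."""
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    t = np.tile(base, (4, 1))
    t[1, 2] *= cg_factor  # C -> G suppressed
    t[0, 0] *= aa_factor  # A -> A
    t[3, 3] *= aa_factor  # T -> T
    t /= t.sum(axis=1, keepdims=True)
    return MarkovParams(initial=base.copy(), transition=t)


# ------------------------------------------------------------- scenario

@dataclass
class PlantedMarker:
    """A diagnostic feature to plant: kind in {luxI, luxR_solo, rieske,
    ect_cassette}; params are kind-specific (e.g. ``triad_intact``,
    ``spacing``, ``identity``, ``with_luxR``)."""

    kind: str
    genome_ids: list[str]
    params: dict = field(default_factory=dict)


@dataclass
class ScenarioSpec:
    """Declarative description of a synthetic comparative-genomics world."""

    genome_ids: list[str]
    markov: dict[str, MarkovParams]
    seed: int
    n_core_families: int = 20
    core_identity: float = 0.85
    core_length: int = 250
    unique_families: dict[tuple[str, ...], tuple[int, float]] = field(default_factory=dict)
    n_singletons: dict[str, int] = field(default_factory=dict)
    singleton_on_plasmid: dict[str, int] = field(default_factory=dict)
    singleton_length: int = 180
    plasmids: dict[str, list[str]] = field(default_factory=dict)
    chromosome_length: dict[str, int] = field(default_factory=dict)
    markers: list[PlantedMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for gid in self.genome_ids:
            if gid not in self.markov:
                raise ValueError(f"no Markov parameters for genome {gid}")
        for subset in self.unique_families:
            unknown = set(subset) - set(self.genome_ids)
            if unknown:
                raise ValueError(f"unique-family subset names unknown genomes {unknown}")
        for gid, n_pl in self.singleton_on_plasmid.items():
            if n_pl > self.n_singletons.get(gid, 0):
                raise ValueError(f"{gid}: more plasmid singletons than singletons")
            if n_pl > 0 and not self.plasmids.get(gid):
                raise ValueError(f"{gid}: plasmid singletons but no plasmid declared")


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a built scenario."""

    expected_rho: dict[str, dict[str, float]]
    clusters: list[list[tuple[str, str]]]
    family_identity: dict[str, float]
    markers: dict[str, list[dict]]
    singleton_plasmid_fraction: dict[str, Optional[float]]
    expected_counts: dict[str, int | dict]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "expected_rho": self.expected_rho,
            "clusters": [[list(m) for m in c] for c in self.clusters],
            "family_identity": self.family_identity,
            "markers": self.markers,
            "singleton_plasmid_fraction": self.singleton_plasmid_fraction,
            "expected_counts": self.expected_counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


_GENE_GAP = 60  # intergenic spacer, bp
_LUX_SOLO_CLEARANCE = 6  # genes between a LuxR solo and any LuxI


def build_scenario(
    spec: ScenarioSpec, outdir: Optional[str | Path] = None
) -> tuple[list[GenomeRecord], GroundTruth]:
    """Materialise a scenario: genomes with laid-out CDS features plus the
    ground truth needed to check every downstream stage.

    With ``outdir`` set, writes one GenBank per genome, a protein FASTA
    per genome, and ``ground_truth.json``.
    """
    from . import refsets
    from .genome_io import write_genbank, write_protein_fasta

    rng = np.random.default_rng(spec.seed)
    gids = list(spec.genome_ids)

    # --- protein content per genome, tracked with cluster ground truth
    per_genome: dict[str, list[dict]] = {g: [] for g in gids}  # queued genes
    clusters: list[list[tuple[str, str]]] = []
    family_identity: dict[str, float] = {}
    markers_truth: dict[str, list[dict]] = {
        "luxI": [],
        "luxR": [],
        "luxR_solo": [],
        "rieske": [],
        "ect_cassette": [],
    }

    def queue(gid: str, pid: str, seq: str, plasmid: bool = False, tag: str = "") -> None:
        per_genome[gid].append({"id": pid, "seq": seq, "plasmid": plasmid, "tag": tag})

    # core families: one member in every genome
    for k in range(spec.n_core_families):
        length = int(spec.core_length * rng.uniform(0.8, 1.2))
        copies, _ = gen_ortholog_family(length, len(gids), spec.core_identity, rng)
        members = []
        for gid, seq in zip(gids, copies):
            pid = f"{gid}_core{k:03d}"
            queue(gid, pid, seq, tag="core")
            members.append((gid, pid))
        clusters.append(members)
        family_identity[f"core{k:03d}"] = spec.core_identity

    # unique-core families: one member in exactly a subset of genomes
    for subset, (count, identity) in spec.unique_families.items():
        for k in range(count):
            length = int(spec.core_length * rng.uniform(0.8, 1.2))
            copies, _ = gen_ortholog_family(length, len(subset), identity, rng)
            members = []
            for gid, seq in zip(subset, copies):
                pid = f"{gid}_uniq_{'_'.join(sorted(subset))}_{k:03d}"
                queue(gid, pid, seq, tag="unique")
                members.append((gid, pid))
            clusters.append(members)
            family_identity[f"uniq_{'_'.join(sorted(subset))}_{k:03d}"] = identity

    # singletons
    for gid in gids:
        n = spec.n_singletons.get(gid, 0)
        n_pl = spec.singleton_on_plasmid.get(gid, 0)
        for k in range(n):
            pid = f"{gid}_single{k:03d}"
            seq = random_protein(int(spec.singleton_length * rng.uniform(0.8, 1.2)), rng)
            queue(gid, pid, seq, plasmid=k < n_pl, tag="singleton")
            clusters.append([(gid, pid)])

    # planted markers
    sets = refsets.build_all()
    lux_ref = sets["luxI"].members[0][1]
    luxr_ref = sets["luxR"].members[0][1]
    ardo_ref = sets["ardo"].members[0][1]
    ect_refs = {c: sets[f"ect{c}"].members[0][1] for c in "ABC"}
    triad_positions = frozenset(p - 1 for p in (24, 28, 34))

    lux_counter: dict[str, int] = {}
    for marker in spec.markers:
        kind = marker.kind
        for gid in marker.genome_ids:
            if kind == "luxI":
                n = lux_counter.get(gid, 0)
                lux_counter[gid] = n + 1
                intact = marker.params.get("triad_intact", True)
                ident = marker.params.get("identity", 0.6)
                seq = mutate_protein(lux_ref, 1.0 - ident, rng, preserve=triad_positions)
                if not intact:
                    broken = list(seq)
                    broken[27] = "A"  # position 28 of the reference frame
                    seq = "".join(broken)
                pid = f"{gid}_luxI{n}"
                queue(gid, pid, seq, tag="luxI")
                clusters.append([(gid, pid)])
                markers_truth["luxI"].append(
                    {"genome": gid, "protein": pid, "triad_intact": bool(intact)}
                )
                if marker.params.get("with_luxR", True):
                    rid = f"{gid}_luxR{n}"
                    rseq = mutate_protein(luxr_ref, 0.4, rng)
                    queue(gid, rid, rseq, tag="luxR")
                    clusters.append([(gid, rid)])
                    markers_truth["luxR"].append({"genome": gid, "protein": rid})
            elif kind == "luxR_solo":
                pid = f"{gid}_luxRsolo"
                seq = mutate_protein(luxr_ref, 0.4, rng)
                queue(gid, pid, seq, tag="luxR_solo")
                clusters.append([(gid, pid)])
                markers_truth["luxR_solo"].append({"genome": gid, "protein": pid})
            elif kind == "rieske":
                spacing = int(marker.params.get("spacing", 17))
                seq = _rieske_protein(ardo_ref, spacing, rng)
                pid = f"{gid}_ardo{spacing}"
                queue(gid, pid, seq, tag="rieske")
                clusters.append([(gid, pid)])
                markers_truth["rieske"].append(
                    {"genome": gid, "protein": pid, "spacing": spacing}
                )
            elif kind == "ect_cassette":
                ident = marker.params.get("identity", 0.9)
                pids = []
                for comp in "ABC":
                    pid = f"{gid}_ect{comp}"
                    seq = mutate_protein(ect_refs[comp], 1.0 - np.sqrt(ident), rng)
                    queue(gid, pid, seq, tag=f"ect{comp}")
                    pids.append(pid)
                markers_truth["ect_cassette"].append({"genome": gid, "proteins": pids})
            else:
                raise ValueError(f"unknown marker kind {kind!r}")

    # ect cassettes across genomes form per-component families when more
    # than one genome carries the cassette (same reference ancestor)
    for comp in "ABC":
        members = [
            (m["genome"], f"{m['genome']}_ect{comp}")
            for m in markers_truth["ect_cassette"]
        ]
        if members:
            clusters.append(members)

    # --- lay out genes on replicons and generate nucleotide sequence
    genomes: list[GenomeRecord] = []
    expected_rho: dict[str, dict[str, float]] = {}
    for gid in gids:
        genes = _ordered_genes(per_genome[gid])
        chrom_genes = [g for g in genes if not g["plasmid"]]
        plasmid_genes = [g for g in genes if g["plasmid"]]
        replicons = []
        proteome: list[ProteinRecord] = []

        def lay_out(gene_list, rep_id):
            """Assign order indices and coordinates; return required bp."""
            pos = 100
            for order, g in enumerate(gene_list):
                span = 3 * len(g["seq"]) + 3
                proteome.append(
                    ProteinRecord(
                        id=g["id"],
                        genome_id=gid,
                        replicon_id=rep_id,
                        seq=g["seq"],
                        gene_order_index=order,
                        start=pos,
                        end=pos + span,
                        strand=1,
                    )
                )
                pos += span + _GENE_GAP
            return pos + 100

        # a genome is "complete" (labelled replicons) iff it declares plasmids
        complete = spec.plasmids.get(gid) is not None
        chrom_id = f"{gid}_chr"
        needed = lay_out(chrom_genes, chrom_id)
        declared = spec.chromosome_length.get(gid)
        if declared is not None and declared < needed:
            raise ValueError(
                f"{gid}: declared chromosome length {declared} cannot hold "
                f"{len(chrom_genes)} genes ({needed} bp needed)"
            )
        chrom_len = declared or needed
        sub = np.random.default_rng([spec.seed, zlib.crc32(gid.encode())])
        seq = gen_markov_sequence(spec.markov[gid], chrom_len, sub)
        replicons.append(
            Replicon(
                id=chrom_id,
                seq=seq,
                kind=RepliconKind.CHROMOSOME if complete else RepliconKind.CONTIG,
            )
        )
        for pl_id in spec.plasmids.get(gid) or []:
            pl_genes = plasmid_genes  # all plasmid-bound genes on first plasmid
            plasmid_genes = []
            pl_len = max(lay_out(pl_genes, pl_id), 2000)
            pseq = gen_markov_sequence(spec.markov[gid], pl_len, sub)
            replicons.append(Replicon(id=pl_id, seq=pseq, kind=RepliconKind.PLASMID))
        genomes.append(GenomeRecord(id=gid, replicons=replicons, proteome=proteome))
        expected_rho[gid] = expected_profile(spec.markov[gid], gid).rho

    # --- derived ground-truth summaries
    singleton_fraction: dict[str, Optional[float]] = {}
    single_by_genome: dict[str, list[tuple[str, str]]] = {g: [] for g in gids}
    for c in clusters:
        if len(c) == 1:
            single_by_genome[c[0][0]].append(c[0])
    plasmid_ids = {
        (p.genome_id, p.id)
        for g in genomes
        for p in g.proteome
        if g.replicon(p.replicon_id).kind is RepliconKind.PLASMID
    }
    for gid, g in zip(gids, genomes):
        singles = single_by_genome[gid]
        if not g.has_labelled_replicons or not singles:
            singleton_fraction[gid] = None
        else:
            on_pl = sum(1 for s in singles if s in plasmid_ids)
            singleton_fraction[gid] = float(round(100.0 * on_pl / len(singles)))

    truth = GroundTruth(
        expected_rho=expected_rho,
        clusters=clusters,
        family_identity=family_identity,
        markers=markers_truth,
        singleton_plasmid_fraction=singleton_fraction,
        expected_counts={
            "core": spec.n_core_families,
            "unique": {
                "+".join(sorted(s)): n for s, (n, _i) in spec.unique_families.items()
            },
            "singletons": {g: len(single_by_genome[g]) for g in gids},
            "clusters_total": len(clusters),
        },
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g in genomes:
            write_genbank(g, outdir / f"{g.id}.gbk")
            write_protein_fasta(g.proteome, outdir / f"{g.id}.faa")
        truth.to_json(outdir / "ground_truth.json")
    return genomes, truth


def _ordered_genes(genes: list[dict]) -> list[dict]:
    """Chromosome gene order: families and markers first, then singletons,
    with any LuxR solo last so no LuxI sits within its +-5 gene window."""

    def rank(g):
        order = {"core": 0, "unique": 1, "luxI": 2, "luxR": 2, "rieske": 3,
                 "ectA": 4, "ectB": 4, "ectC": 4, "singleton": 5, "luxR_solo": 6}
        return order.get(g["tag"], 5)

    ordered = sorted(genes, key=rank)
    # keep each luxI immediately followed by its cognate luxR
    solos = [g for g in ordered if g["tag"] == "luxR_solo"]
    lux_near_end = [
        g for g in ordered[-(_LUX_SOLO_CLEARANCE + len(solos)):] if g["tag"] == "luxI"
    ]
    assert not lux_near_end, "layout failed to isolate the LuxR solo"
    return ordered


def _rieske_protein(ardo_ref: str, spacing: int, rng: np.random.Generator) -> str:
    """A dioxygenase-like protein whose first Rieske-motif match has
    exactly ``spacing`` residues between first His and second Cys.

    The reference's own motif region is replaced by a constructed site;
    alphabet outside the planted site avoids C and H so the regex cannot
    match earlier or shorter."""
    safe = "ADEFGIKLMNPQRSTVWY"
    site = (
        "C" + random_protein(1, rng, safe) + "H"
        + random_protein(spacing, rng, safe)
        + "C" + random_protein(2, rng, safe) + "H"
    )
    body = mutate_protein(ardo_ref, 0.25, rng)
    clean = body.replace("C", "S").replace("H", "N")
    insert_at = 40
    return clean[:insert_at] + site + clean[insert_at + len(site):]


def paper_shaped_scenario(seed: int) -> ScenarioSpec:
    """The default six-genome world.

    Mirrors the shape of the study this toolkit reproduces: a marine pair
    sharing a large unique core and an ectoine cassette, an epiphyte with
    a single AHL synthase, a complete multi-plasmid genome with
    plasmid-borne singletons and a LuxR solo, five LuxI candidates in
    total, and Rieske proteins with both 17- and 19-residue spacings.
    """
    gids = ["mill", "marineA", "marineB", "epiphyte", "rhizo", "sediment"]
    markov = {
        "mill": gc_markov(gc=0.64, cg_factor=0.55, aa_factor=1.35),
        "marineA": gc_markov(gc=0.63, cg_factor=0.70),
        "marineB": gc_markov(gc=0.632, cg_factor=0.71),
        "epiphyte": gc_markov(gc=0.627, cg_factor=0.75, aa_factor=1.1),
        "rhizo": gc_markov(gc=0.659, cg_factor=0.65),
        "sediment": gc_markov(gc=0.651, cg_factor=0.62, aa_factor=1.15),
    }
    return ScenarioSpec(
        genome_ids=gids,
        markov=markov,
        seed=seed,
        n_core_families=24,
        core_identity=0.85,
        core_length=250,
        unique_families={
            ("marineA", "marineB"): (12, 0.90),
            ("mill", "sediment"): (3, 0.85),
        },
        n_singletons={"mill": 6, "marineA": 6, "marineB": 10, "epiphyte": 6,
                      "rhizo": 6, "sediment": 8},
        singleton_on_plasmid={"marineB": 7, "sediment": 3},
        plasmids={"marineB": ["marineB_pl1"], "sediment": ["sediment_pl1"]},
        markers=[
            PlantedMarker("luxI", ["marineA", "epiphyte", "rhizo"]),
            PlantedMarker("luxI", ["marineB", "marineB"]),
            PlantedMarker("luxR_solo", ["marineB"]),
            PlantedMarker("rieske", ["epiphyte", "sediment"], {"spacing": 17}),
            PlantedMarker("rieske", ["marineA", "marineB"], {"spacing": 19}),
            PlantedMarker("ect_cassette", ["marineA", "marineB"], {"identity": 0.9}),
        ],
    )
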