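"""End-to-end comparative analysis on a set of genomes.

``run_all`` executes the full stack on two or more genomes — dinucleotide
signature dissimilarity (delta* ×1000), AAI, pan-genome partition,
per-genome trait table (GC%, median pI, LuxI/LuxR counts and triad
checks, LuxR solos, Nqr presence, ectoine cassette, Rieske spacings,
plasmid singleton fraction) and a distance tree — and writes a report
bundle of TSV/JSON/Newick files plus a manifest recording thresholds,
seed and versions so every number is traceable.

The expensive all-vs-all protein search runs once per genome pair at
permissive thresholds; AAI and orthology clustering filter the same hit
lists at their own cutoffs. The tree is built by neighbor joining on
Poisson-corrected mean RBH dissimilarity, d(a,b) = −ln(AAI/100), with
support from resampling the underlying RBH families (the alignment-based
route of :mod:`novocomp.phylo` is available when a concatenated protein
alignment exists).

Rounding follows reporting convention: AAI one decimal, delta* integer,
pI two decimals, percentages integer; machine-readable outputs keep full
precision.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, refsets
from .aai import AAIThresholds, aai, reciprocal_best_hits
from .align import HomologHit, search
from .genome_io import gc_content, read_genome
from .pangenome import (
    ClusterThresholds,
    cluster_orthologs,
    partition,
    singleton_replicon_fraction,
)
from .phylo import DistanceMatrix, TreeNode, _bipartitions, nj_tree
from .records import GenomeRecord
from .signature import dinuc_profile, signature_matrix
from .traits import (
    check_luxI_triad,
    detect_cassette,
    median_proteome_pI,
    rieske_spacing,
    screen,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of the end-to-end run; defaults are the study values."""

    inputs: list[str] = field(default_factory=list)
    outdir: str = "novocomp_out"
    seed: int = 0
    # orthologous clustering
    cluster_min_identity: float = 65.0
    cluster_min_overlap: float = 0.70
    cluster_max_evalue: float = 1e-10
    # homology screening (traits, AAI identity floor)
    screen_min_identity: float = 30.0
    screen_max_evalue: float = 1e-6
    aai_min_cov: float = 0.70
    # cassette and phylogeny
    cassette_window: int = 20000
    bootstrap_replicates: int = 1000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.cluster_min_identity <= 100:
            raise ValueError("cluster_min_identity out of range")
        if not 0 < self.cluster_min_overlap <= 1:
            raise ValueError("cluster_min_overlap out of range")
        if self.cassette_window <= 0 or self.bootstrap_replicates < 0:
            raise ValueError("invalid window or replicate count")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _pairwise_hits(
    genomes: Sequence[GenomeRecord], min_identity: float
) -> dict[tuple[str, str], list[HomologHit]]:
    """One permissive all-vs-all search per ordered genome pair."""
    hits: dict[tuple[str, str], list[HomologHit]] = {}
    for i, a in enumerate(genomes):
        for b in genomes[i + 1:]:
            logger.info("searching %s vs %s", a.id, b.id)
            hits[(a.id, b.id)] = search(a.proteome, b.proteome, min_identity=min_identity)
            hits[(b.id, a.id)] = search(b.proteome, a.proteome, min_identity=min_identity)
    return hits


def tree_from_aai(
    genomes: Sequence[GenomeRecord],
    hits: dict[tuple[str, str], list[HomologHit]],
    th: AAIThresholds,
    replicates: int = 100,
    seed: int = 0,
) -> TreeNode:
    """NJ tree on Poisson-corrected RBH dissimilarity with family-resampling
    support.

    For each genome pair the mean RBH mismatch fraction p = 1 − AAI/100 is
    Poisson-corrected, d = −ln(1 − p); bootstrap replicates resample the
    per-pair RBH identity lists with replacement.
    """
    ids = [g.id for g in genomes]
    n = len(ids)
    pair_idents: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        for j in range(i + 1, n):
            from .aai import _filter

            hab = _filter(hits[(ids[i], ids[j])], th)
            hba = _filter(hits[(ids[j], ids[i])], th)
            pairs = reciprocal_best_hits(hab, hba)
            ident = {(h.query_id, h.subject_id): h.pct_identity for h in hab}
            ident.update({(h.subject_id, h.query_id): h.pct_identity for h in hba})
            vals = np.array([ident[p] for p in pairs])
            if vals.size == 0:
                raise ValueError(f"no RBH pairs between {ids[i]} and {ids[j]}")
            pair_idents[(i, j)] = vals

    def dist_matrix(sample: bool, rng: Optional[np.random.Generator]) -> DistanceMatrix:
        d = np.zeros((n, n))
        for (i, j), vals in pair_idents.items():
            v = vals if not sample else vals[rng.integers(0, vals.size, vals.size)]
            p = 1.0 - v.mean() / 100.0
            d[i, j] = d[j, i] = -math.log(max(1.0 - p, 1e-9))
        return DistanceMatrix(ids, d)

    ref = nj_tree(dist_matrix(False, None))
    if replicates and n >= 4:
        taxa = frozenset(ids)
        ref_splits = _bipartitions(ref, taxa)
        counts = {s: 0 for s in ref_splits}
        rng = np.random.default_rng(seed)
        for _ in range(replicates):
            rep = nj_tree(dist_matrix(True, rng))
            rep_splits = _bipartitions(rep, taxa)
            for s in ref_splits:
                if s in rep_splits:
                    counts[s] += 1
        for node in ref.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if len(side) < 2 or len(taxa - side) < 2:
                continue
            canonical = taxa - side if min(taxa) in side else side
            node.name = str(int(round(100.0 * counts[canonical] / replicates)))
    return ref


def trait_table(
    genomes: Sequence[GenomeRecord], config: RunConfig
) -> pd.DataFrame:
    """Per-genome trait summary."""
    lux_set = refsets.load_refset("luxI")
    luxr_set = refsets.load_refset("luxR")
    nqr_set = refsets.load_refset("nqr")
    ect_sets = refsets.ect_refsets()
    lux_ref = lux_set.members[0][1]
    rows = []
    for g in genomes:
        lux_hits = screen(g, lux_set, config.screen_min_identity, config.screen_max_evalue)
        luxr_hits = screen(g, luxr_set, config.screen_min_identity, config.screen_max_evalue)
        nqr_hits = screen(g, nqr_set, config.screen_min_identity, config.screen_max_evalue)
        by_id = {p.id: p for p in g.proteome}
        triad_ok = []
        for h in lux_hits:
            rep = check_luxI_triad(by_id[h.query_id].seq, lux_ref)
            if rep.verdict:
                triad_ok.append(h.query_id)
        # LuxR solo: a LuxR hit with no LuxI hit within +-5 genes on its replicon
        lux_pos = {
            (by_id[h.query_id].replicon_id, by_id[h.query_id].gene_order_index)
            for h in lux_hits
        }
        solos = []
        for h in luxr_hits:
            p = by_id[h.query_id]
            near = any(
                (p.replicon_id, p.gene_order_index + d) in lux_pos
                for d in range(-5, 6)
            )
            if not near:
                solos.append(h.query_id)
        cassette = detect_cassette(
            g, ect_sets, config.cassette_window,
            config.screen_min_identity, config.screen_max_evalue,
        )
        spacings = sorted(
            {s for p in g.proteome if (s := rieske_spacing(p.seq)) is not None}
        )
        rows.append(
            {
                "genome": g.id,
                "n_proteins": len(g.proteome),
                "gc_pct": round(gc_content(g), 2),
                "median_pI": round(median_proteome_pI(g), 2),
                "n_luxI": len(lux_hits),
                "n_luxI_triad_ok": len(triad_ok),
                "n_luxR": len(luxr_hits),
                "luxR_solos": ";".join(sorted(solos)) or "-",
                "nqr_present": bool(nqr_hits),
                "ect_cassette_complete": cassette.complete,
                "rieske_spacings": ";".join(map(str, spacings)) or "-",
            }
        )
    return pd.DataFrame(rows)


def run_all(
    config: RunConfig, genomes: Optional[Sequence[GenomeRecord]] = None
) -> dict:
    """Run every stage and write the report bundle; returns the results.

    ``genomes`` may be passed directly (e.g. from the synthetic
    generator); otherwise ``config.inputs`` are read as GenBank.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genomes is None:
        genomes = [read_genome(p, format="genbank") for p in config.inputs]
    genomes = list(genomes)
    manifest: dict = {
        "novocomp_version": __version__,
        "refset_version": refsets.REFSET_VERSION,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "genomes": [g.id for g in genomes],
        "stages": {},
        "failures": {},
    }
    results: dict = {"manifest": manifest}
    ids = [g.id for g in genomes]

    # --- signature
    profiles = [dinuc_profile(g) for g in genomes]
    sig = signature_matrix(profiles)
    sig_df = sig.to_frame()
    sig_df.round(6).to_csv(outdir / "delta_star.tsv", sep="\t")
    sig_df.round(0).astype(int).to_csv(outdir / "delta_star_rounded.tsv", sep="\t")
    pd.DataFrame(
        {p.genome_id: p.rho for p in profiles}
    ).T.to_csv(outdir / "rho_star.tsv", sep="\t")
    manifest["stages"]["signature"] = {"n_genomes": len(genomes)}
    results["delta_star"] = sig
    results["profiles"] = profiles

    # --- traits (single-genome stage; runs regardless of pair count)
    traits = trait_table(genomes, config)
    traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
    manifest["stages"]["traits"] = {
        "screen_min_identity": config.screen_min_identity,
        "screen_max_evalue": config.screen_max_evalue,
        "cassette_window": config.cassette_window,
    }
    results["traits"] = traits

    if len(genomes) < 2:
        logger.warning("single genome: pairwise stages skipped")
        manifest["stages"]["pairwise"] = "skipped (single genome)"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return results

    # --- one permissive search, reused by AAI, clustering and the tree
    hits = _pairwise_hits(genomes, min_identity=min(config.screen_min_identity, 25.0))
    aai_th = AAIThresholds(
        min_identity=config.screen_min_identity,
        min_cov=config.aai_min_cov,
        max_evalue=config.screen_max_evalue,
    )
    n = len(genomes)
    aai_mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = aai(
                genomes[i], genomes[j], aai_th,
                precomputed=(hits[(ids[i], ids[j])], hits[(ids[j], ids[i])]),
            )
            aai_mat[i, j] = aai_mat[j, i] = res.aai
    aai_df = pd.DataFrame(aai_mat, index=ids, columns=ids)
    aai_df.to_csv(outdir / "aai.tsv", sep="\t")
    aai_df.round(1).to_csv(outdir / "aai_rounded.tsv", sep="\t")
    manifest["stages"]["aai"] = dataclasses.asdict(aai_th)
    results["aai"] = aai_df

    # --- pan-genome
    cl_th = ClusterThresholds(
        min_identity=config.cluster_min_identity,
        min_overlap=config.cluster_min_overlap,
        max_evalue=config.cluster_max_evalue,
    )
    clusters = cluster_orthologs(genomes, cl_th, precomputed=hits)
    part = partition(clusters, ids)
    pd.DataFrame(
        [
            {"cluster": c.id, "genome": g, "protein": p}
            for c in clusters
            for g, p in c.members
        ]
    ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    venn_rows = [
        {"genomes": "+".join(sorted(s)), "n_clusters": cnt}
        for s, cnt in sorted(part.venn.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    ]
    pd.DataFrame(venn_rows).to_csv(outdir / "venn_cells.tsv", sep="\t", index=False)
    single_rows = []
    plasmid_fracs = {}
    for g in genomes:
        frac = singleton_replicon_fraction(part, g)
        plasmid_fracs[g.id] = frac
        for c in part.singletons(g.id):
            pid = c.members[0][1]
            prot = next(p for p in g.proteome if p.id == pid)
            single_rows.append(
                {
                    "genome": g.id,
                    "protein": pid,
                    "replicon": prot.replicon_id,
                    "replicon_kind": g.replicon(prot.replicon_id).kind.value,
                }
            )
    pd.DataFrame(single_rows).to_csv(outdir / "singletons.tsv", sep="\t", index=False)
    manifest["stages"]["pangenome"] = {
        **dataclasses.asdict(cl_th),
        "n_clusters": len(clusters),
        "n_core": len(part.core),
        "singleton_plasmid_pct": plasmid_fracs,
    }
    results["partition"] = part
    results["singleton_plasmid_pct"] = plasmid_fracs

    # --- tree
    if n >= 3:
        try:
            tree = tree_from_aai(
                genomes, hits, aai_th,
                replicates=config.bootstrap_replicates, seed=config.seed,
            )
            tree.write(str(outdir / "tree.nwk"))
            results["tree"] = tree
            manifest["stages"]["tree"] = {
                "method": "NJ on -ln(AAI/100), RBH-family bootstrap",
                "replicates": config.bootstrap_replicates,
            }
        except ValueError as exc:
            logger.error("tree stage failed: %s", exc)
            manifest["failures"]["tree"] = str(exc)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results
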