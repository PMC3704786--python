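"""Curated reference protein sets for trait screening.

The real screens in this field are built from reviewed UniProt entries
(AHL synthases, LuxR regulators, the Nqr sodium pump, functionally
validated ring-hydroxylating dioxygenases, EctABC). Those sequences are
not redistributable here, so the shipped sets are *synthetic stand-ins*:
deterministic generated families that carry the diagnostic features the
screens test for —

* ``luxI``: a designated reference synthase with Arg24/Phe28/Trp34 and
  homologs that preserve the triad;
* ``luxR``: a regulator family;
* ``nqr``: six unrelated subunit stand-ins (NqrA–F) used as a negative
  screen;
* ``ardo``: dioxygenase stand-ins with a canonical 17-spacing Rieske
  [2Fe-2S] site;
* ``ectA`` (162 aa, the length reported for the natural homologs),
  ``ectB``, ``ectC``: ectoine-pathway component families.

Sets are shipped as protein FASTA plus a TSV manifest under
``novocomp/data`` (files carry ``synthetic`` in their names); loading
falls back to in-memory generation, which is bit-identical.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .traits import ReferenceSet

REFSET_VERSION = "2024.1-synthetic"
_SEED = 1729

_SIZES = {
    "luxI": (6, 200),
    "luxR": (5, 240),
    "nqr": (6, 300),
    "ardo": (4, 380),
    "ectA": (3, 162),
    "ectB": (3, 420),
    "ectC": (3, 130),
}

_TRIAD = {24: "R", 28: "F", 34: "W"}


def build_all() -> dict[str, ReferenceSet]:
    """Generate every reference set deterministically (fixed seed)."""
    from .synthetic import mutate_protein, random_protein

    rng = np.random.default_rng(_SEED)
    sets: dict[str, ReferenceSet] = {}

    for name, (n, length) in _SIZES.items():
        members = []
        if name == "nqr":
            # six independent subunits, not a homolog family
            for i, sub in enumerate("ABCDEF"):
                members.append(
                    (f"nqr{sub}_ref", random_protein(length, rng),
                     f"Na+-translocating NADH dehydrogenase subunit Nqr{sub} (synthetic stand-in)")
                )
        else:
            anc = list(random_protein(length, rng))
            preserve: frozenset[int] = frozenset()
            if name == "luxI":
                for pos, aa in _TRIAD.items():
                    anc[pos - 1] = aa
                preserve = frozenset(p - 1 for p in _TRIAD)
            elif name == "ardo":
                # canonical Rieske site, 17 residues between His1 and Cys2
                site = "C" + "".join(anc[41:42]) + "H" + "".join(anc[43:60]) + "C" + "".join(anc[61:63]) + "H"
                anc[40:40 + len(site)] = list(site)
                preserve = frozenset(range(40, 40 + len(site)))
            anc = "".join(anc)
            members.append((f"{name}_ref1", anc, f"{name} designated reference (synthetic stand-in)"))
            for i in range(1, n):
                seq = mutate_protein(anc, 0.3, rng, preserve=preserve)
                members.append((f"{name}_ref{i + 1}", seq, f"{name} homolog (synthetic stand-in)"))
        sets[name] = ReferenceSet(
            name=name,
            members=members,
            provenance=f"synthetic stand-in family, novocomp refsets {REFSET_VERSION}",
        )
    return sets


def export(outdir: str | Path) -> None:
    """Write every set as FASTA plus a manifest TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sets = build_all()
    manifest = ["id\tset\tannotation"]
    for name, rs in sets.items():
        lines = []
        for rid, seq, ann in rs.members:
            lines.append(f">{rid} {ann}")
            lines.extend(seq[i:i + 70] for i in range(0, len(seq), 70))
            manifest.append(f"{rid}\t{name}\t{ann}")
        (outdir / f"{name}.synthetic.faa").write_text("\n".join(lines) + "\n")
    (outdir / "refsets.synthetic.manifest.tsv").write_text("\n".join(manifest) + "\n")


def load_refset(name: str) -> ReferenceSet:
    """Load a shipped reference set by name (``luxI``, ``nqr``, ...)."""
    if name not in _SIZES:
        raise KeyError(f"unknown reference set {name!r}; known: {sorted(_SIZES)}")
    try:
        data = resources.files("novocomp").joinpath(f"data/{name}.synthetic.faa")
        text = data.read_text()
    except (FileNotFoundError, ModuleNotFoundError):
        return build_all()[name]
    members = []
    rid, ann, chunks = None, "", []
    for line in text.splitlines():
        if line.startswith(">"):
            if rid is not None:
                members.append((rid, "".join(chunks), ann))
            head = line[1:].split(None, 1)
            rid, ann = head[0], head[1] if len(head) > 1 else ""
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if rid is not None:
        members.append((rid, "".join(chunks), ann))
    return ReferenceSet(
        name=name, members=members,
        provenance=f"shipped synthetic stand-in, novocomp refsets {REFSET_VERSION}",
    )


def ect_refsets() -> dict[str, ReferenceSet]:
    """The three ectoine-pathway component sets keyed EctA/EctB/EctC."""
    return {f"Ect{c}": load_refset(f"ect{c}") for c in "ABC"}
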