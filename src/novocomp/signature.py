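"""Dinucleotide relative abundance genomic signatures.

The genome signature of Karlin: for each of the 16 dinucleotides XY the
relative abundance is

    rho*_XY = f*_XY / (f*_X · f*_Y)

where f* denotes frequencies computed on the sequence concatenated with
its reverse complement (strand symmetrisation). Two genomes f and g are
compared with the average absolute difference

    delta*(f, g) = (1/16) · sum_XY | rho*_f(XY) − rho*_g(XY) |

conventionally reported multiplied by 1000. Values near 1 indicate a
dinucleotide is as abundant as expected under mononucleotide independence;
empirical ranges classify each rho* as normal (0.78–1.23), over/under
represented, or extreme (>1.30 / <0.55).

Counting never spans a replicon junction or the forward/reverse-complement
seam, and windows containing N are skipped; mononucleotide frequencies are
taken over all unambiguous bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import GenomeRecord, Replicon

BASES = "ACGT"
DINUCS = tuple(a + b for a in BASES for b in BASES)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp_dinuc(xy: str) -> str:
    return _COMP[xy[1]] + _COMP[xy[0]]


_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i


@dataclass
class DinucProfile:
    """Strand-symmetrised mono/dinucleotide frequencies and rho* ratios."""

    genome_id: str
    mono_freq: dict[str, float]
    dinuc_freq: dict[str, float]
    rho: dict[str, float]

    def rho_vector(self) -> np.ndarray:
        return np.array([self.rho[d] for d in DINUCS])


@dataclass
class SignatureMatrix:
    """Pairwise delta* dissimilarities, scaled ×1000, input order preserved."""

    genome_ids: list[str]
    delta: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.delta, index=self.genome_ids, columns=self.genome_ids)


def _count_seq(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Forward-strand mono and dinucleotide counts of one replicon.

    Windows containing an ambiguous base contribute nothing; the caller
    handles symmetrisation.
    """
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    mono = np.bincount(codes[codes >= 0], minlength=4)
    if len(codes) < 2:
        return mono, np.zeros(16, dtype=np.int64)
    left, right = codes[:-1], codes[1:]
    valid = (left >= 0) & (right >= 0)
    pair_codes = left[valid] * 4 + right[valid]
    dinuc = np.bincount(pair_codes, minlength=16)
    return mono, dinuc


def dinuc_profile(genome: GenomeRecord | Replicon | str, chromosome_only: bool = False) -> DinucProfile:
    """Compute the strand-symmetrised dinucleotide signature of a genome.

    Accepts a GenomeRecord, a single Replicon, or a raw sequence string.
    Counts accumulate over every replicon's forward strand and reverse
    complement; no window crosses a replicon boundary.
    """
    if isinstance(genome, str):
        genome = GenomeRecord(id="seq", replicons=[Replicon(id="seq", seq=genome)])
    elif isinstance(genome, Replicon):
        genome = GenomeRecord(id=genome.id, replicons=[genome])

    mono = np.zeros(4, dtype=np.int64)
    dinuc = np.zeros(16, dtype=np.int64)
    from .records import RepliconKind

    for rep in genome.replicons:
        if chromosome_only and rep.kind is not RepliconKind.CHROMOSOME:
            continue
        m, d = _count_seq(rep.seq)
        # reverse-complement counts follow from forward counts by symmetry:
        # count of XY on revcomp == count of revcomp(XY) forward
        mono += m + m[::-1]
        d16 = d.reshape(4, 4)
        dinuc += d + d16[::-1, ::-1].T.reshape(16)

    if dinuc.sum() == 0:
        raise ValueError(f"genome {genome.id}: no valid dinucleotide window, profile undefined")

    mono_f = mono / mono.sum()
    dinuc_f = dinuc / dinuc.sum()
    rho = {}
    for k, xy in enumerate(DINUCS):
        denom = mono_f[BASES.index(xy[0])] * mono_f[BASES.index(xy[1])]
        rho[xy] = float(dinuc_f[k] / denom) if denom > 0 else 0.0
    return DinucProfile(
        genome_id=genome.id,
        mono_freq={b: float(mono_f[i]) for i, b in enumerate(BASES)},
        dinuc_freq={d: float(dinuc_f[i]) for i, d in enumerate(DINUCS)},
        rho=rho,
    )


def delta_star(f: DinucProfile, g: DinucProfile) -> float:
    """Genome dissimilarity delta*(f,g) ×1000: mean |rho*_f − rho*_g| over
    the 16 dinucleotides, scaled by 1000."""
    diff = np.abs(f.rho_vector() - g.rho_vector())
    return float(1000.0 * diff.mean())


def signature_matrix(profiles: list[DinucProfile]) -> SignatureMatrix:
    n = len(profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = delta_star(profiles[i], profiles[j])
    return SignatureMatrix([p.genome_id for p in profiles], mat)


#: class boundaries for rho*; boundary values fall in the lower class
_RHO_CLASSES = (
    (0.55, "extreme_under"),
    (0.78, "under"),
    (1.23, "normal"),
    (1.30, "over"),
)


def classify_rho(rho_value: float) -> str:
    """Representation class of a rho* value.

    <0.55 extreme_under; 0.55–0.78 under; 0.78–1.23 normal; 1.23–1.30 over;
    >1.30 extreme_over. Exact boundary values take the lower class.
    """
    if rho_value < 0:
        raise ValueError(f"rho* must be non-negative, got {rho_value}")
    for bound, label in _RHO_CLASSES:
        if rho_value <= bound:
            return label
    return "extreme_over"
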