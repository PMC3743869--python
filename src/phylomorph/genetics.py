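"""Allele-aware p-distances between diploid samples.

Nuclear intron (EPIC) markers yield one allele sequence for homozygote
samples and two for heterozygotes.  To standardize comparisons, the single
allele of a homozygote is duplicated so every sample contributes two
alleles, and the distance between two samples is the average of the four
inter-allele p-distance comparisons.

p-distance = differing sites / comparable sites, with pairwise deletion of
sites containing a gap or N in either sequence.  Handling is
case-insensitive; IUPAC ambiguity codes other than N are treated as N with
a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .matrices import DistanceMatrix

__all__ = [
    "SampleGenotype",
    "p_distance",
    "sample_distance",
    "genetic_distance_matrix",
    "read_genotypes_fasta",
]

_VALID = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SampleGenotype:
    """A sample's alleles at one marker (1 = homozygote, 2 = heterozygote)."""

    sample_id: str
    species_code: str
    alleles: list[str]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError(f"{self.sample_id}: expected 1 or 2 alleles, got {len(self.alleles)}")
        lengths = {len(a) for a in self.alleles}
        if len(lengths) > 1:
            raise ValueError(f"{self.sample_id}: alleles differ in aligned length")

    @property
    def is_heterozygote(self) -> bool:
        return len(self.alleles) == 2

    def duplicated(self) -> list[str]:
        """Both alleles, with a homozygote's single allele duplicated."""
        return self.alleles if len(self.alleles) == 2 else [self.alleles[0]] * 2


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1").copy()
    known = np.isin(arr, np.frombuffer(b"ACGT-N", dtype="S1"))
    if not known.all():
        bad = sorted({b.decode() for b in arr[~known]})
        warnings.warn(f"ambiguity codes {bad} treated as N")
        arr[~known] = b"N"
    return arr


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites over comparable sites (pairwise deletion)."""
    xa, xb = _encode(a), _encode(b)
    if xa.size != xb.size:
        raise ValueError("sequences differ in aligned length")
    comparable = np.isin(xa, _VALID) & np.isin(xb, _VALID)
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable sites between the two sequences")
    return float(np.sum(xa[comparable] != xb[comparable]) / n)


def sample_distance(x: SampleGenotype, y: SampleGenotype) -> float:
    """Mean of the four cross-sample inter-allele p-distances.

    Homozygote alleles are duplicated first, so a homozygote/homozygote
    pair reduces to the plain allele p-distance.
    """
    xs, ys = x.duplicated(), y.duplicated()
    return float(np.mean([p_distance(a, b) for a in xs for b in ys]))


def genetic_distance_matrix(genotypes: list[SampleGenotype]) -> DistanceMatrix:
    """Sample-level p-distance matrix with a zero diagonal.

    The self comparison of a heterozygote would average to half its
    inter-allele distance; by convention the diagonal is defined as 0 so
    the matrix is usable for clustering and permutation tests.
    """
    if len(genotypes) < 2:
        raise ValueError("need at least 2 samples")
    ids = [g.sample_id for g in genotypes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids")
    n = len(genotypes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sample_distance(genotypes[i], genotypes[j])
    return DistanceMatrix(ids, d)


def read_genotypes_fasta(path: str | Path, species_prefix_len: int = 3) -> list[SampleGenotype]:
    """Read aligned alleles from FASTA using the allele-suffix convention.

    Records named ``<Sample>`` are homozygotes; ``<Sample>-1`` and
    ``<Sample>-2`` are the two alleles of a heterozygote.  The species code
    is the first ``species_prefix_len`` characters of the sample id (the
    Car/For/Dec style prefix).
    """
    by_sample: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if len(name) > 2 and name[-2] == "-" and name[-1] in "12":
            sid, allele = name[:-2], name[-1]
        else:
            sid, allele = name, "0"
        by_sample.setdefault(sid, {})[allele] = str(rec.seq)
    genotypes = []
    for sid, alleles in by_sample.items():
        if "0" in alleles and len(alleles) > 1:
            raise ValueError(f"{sid}: mixes suffixed and unsuffixed records")
        seqs = [alleles[k] for k in sorted(alleles)]
        genotypes.append(SampleGenotype(sid, sid[:species_prefix_len], seqs))
    lengths = {len(a) for g in genotypes for a in g.alleles}
    if len(lengths) > 1:
        raise ValueError("alleles in the FASTA differ in aligned length")
    return genotypes
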