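"""Nei-Gojobori synonymous/nonsynonymous distances and Poisson amino-acid distances.

The Nei-Gojobori (NG86) method counts, per codon, the fraction of the nine
possible single-nucleotide changes that are synonymous (``s``; ``n = 3 - s``),
and classifies observed differences between a codon pair by averaging over all
orderings of single-step mutational pathways, excluding pathways that pass
through a stop codon. Proportions ``pS = Sd/S`` and ``pN = Nd/N`` are corrected
for multiple hits with the Jukes-Cantor formula

    d = -(3/4) ln(1 - (4/3) p),

undefined for ``p >= 3/4``. Amino-acid distances use the Poisson correction
``d = -ln(1 - p)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from httscan.core_io import SequenceRecord

BASES = "ACGT"

# standard genetic code, DNA codons
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(set(GENETIC_CODE) - STOP_CODONS))


class FrameError(ValueError):
    """Sequence length or gap structure violates the codon frame."""


@dataclass(frozen=True)
class PairCounts:
    """NG86 site and difference counts for one sequence pair.

    S and N are averages of the two sequences' synonymous/nonsynonymous site
    counts; Sd and Nd are pathway-averaged difference counts. S + N equals
    3 x codons_used. Note Sd can exceed S on very short sequences (a single
    AAA/AAG pair has Sd = 1 but S = 1/3); such proportions land beyond the
    Jukes-Cantor domain and the distance is then reported undefined.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    codons_used: int

    def __post_init__(self) -> None:
        if self.Sd < -1e-9 or self.Nd < -1e-9:
            raise ValueError("difference counts must be non-negative")
        if abs(self.S + self.N - 3 * self.codons_used) > 1e-9:
            raise ValueError("S + N must equal 3 * codons_used")


@dataclass(frozen=True)
class DistanceEstimate:
    """Jukes-Cantor-corrected NG86 distances; ``defined`` is False when the
    correction diverges (pS or pN >= 3/4, or no comparable sites)."""

    pS: float
    pN: float
    dS: float
    dN: float
    defined: bool
    counts: PairCounts | None = None


@dataclass(frozen=True)
class AADistanceMatrix:
    """Poisson-corrected amino-acid distance matrix with raw p-distances.

    ``d[i, j] = -ln(1 - p[i, j])``; entries where the correction is undefined
    (p >= 1 or no comparable columns) are NaN.
    """

    labels: tuple[str, ...]
    d: np.ndarray
    p: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def _check_codon(codon: str) -> None:
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no NG86 site counts")


@lru_cache(maxsize=None)
def count_codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (s, n) of one sense codon.

    Each of the three positions contributes (synonymous single-nucleotide
    changes)/3 to s; a change producing a stop codon is never synonymous, so
    it falls on the nonsynonymous side. n = 3 - s exactly.
    """
    _check_codon(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if GENETIC_CODE[mut] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def count_pair_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts (sd, nd).

    For k differing positions, all k! orderings of single-nucleotide steps are
    averaged; orderings whose intermediate codons are stops are excluded
    (unless every ordering is blocked, in which case all are used).
    """
    _check_codon(codon1)
    _check_codon(codon2)
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon1
        sd = nd = 0.0
        stop_hit = False
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                stop_hit = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        # the endpoint codon2 is a sense codon by precondition, so stop_hit
        # can only come from intermediates
        (blocked if stop_hit else valid).append((sd, nd))
    pathways = valid if valid else blocked
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return sd, nd


def _usable_codon(codon: str) -> bool:
    return (len(codon) == 3 and all(b in BASES for b in codon)
            and codon not in STOP_CODONS)


def pair_counts(seq1: str, seq2: str) -> PairCounts:
    """NG86 counts for an in-frame pair with pairwise deletion.

    Codon columns containing a gap, an ambiguous base (N) or a stop codon in
    either sequence are excluded as a whole.
    """
    if len(seq1) != len(seq2):
        raise FrameError("sequences must be the same aligned length")
    if len(seq1) % 3 != 0:
        raise FrameError(f"aligned length {len(seq1)} is not a multiple of 3")
    S1 = S2 = Sd = Nd = 0.0
    used = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i:i + 3], seq2[i:i + 3]
        if not (_usable_codon(c1) and _usable_codon(c2)):
            continue
        used += 1
        s1, _ = count_codon_sites(c1)
        s2, _ = count_codon_sites(c2)
        S1 += s1
        S2 += s2
        sd, nd = count_pair_differences(c1, c2)
        Sd += sd
        Nd += nd
    S = (S1 + S2) / 2.0
    N = 3.0 * used - S
    return PairCounts(S=S, N=N, Sd=Sd, Nd=Nd, codons_used=used)


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; math domain error for p >= 3/4."""
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng_distance(seq1: str, seq2: str) -> DistanceEstimate:
    """Pairwise NG86 synonymous and nonsynonymous distances.

    Returns ``defined=False`` (NaN distances) if no codons are comparable, a
    site class is empty, or a proportion reaches the Jukes-Cantor bound 3/4.
    """
    counts = pair_counts(seq1, seq2)
    if counts.codons_used == 0 or counts.S <= 0.0 or counts.N <= 0.0:
        return DistanceEstimate(math.nan, math.nan, math.nan, math.nan,
                                False, counts)
    pS = counts.Sd / counts.S
    pN = counts.Nd / counts.N
    if pS >= 0.75 or pN >= 0.75:
        return DistanceEstimate(pS, pN, math.nan, math.nan, False, counts)
    return DistanceEstimate(pS, pN, jukes_cantor(pS), jukes_cantor(pN),
                            True, counts)


def translate_codon(codon: str) -> str:
    if codon == "---":
        return "-"
    if any(b not in BASES for b in codon):
        return "X"
    return GENETIC_CODE[codon]


def translate_alignment(records: list[SequenceRecord], *,
                        allow_stops: bool = False) -> list[SequenceRecord]:
    """Translate a codon alignment to amino acids.

    Whole-gap codons map to '-', codons with ambiguity to 'X'. Internal stops
    raise unless ``allow_stops``; partial-gap codons always raise (use
    :func:`httscan.screening.validate_codon_alignment` first).
    """
    out = []
    for rec in records:
        if len(rec.seq) % 3 != 0:
            raise FrameError(f"{rec.id}: length {len(rec.seq)} not a multiple of 3")
        aa_chars = []
        for i in range(0, len(rec.seq), 3):
            codon = rec.seq[i:i + 3]
            if "-" in codon and codon != "---":
                raise FrameError(f"{rec.id}: partial gap codon {codon!r} at "
                                 f"column {i}")
            aa = translate_codon(codon)
            if aa == "*" and not allow_stops:
                raise ValueError(f"{rec.id}: internal stop codon at column {i}")
            aa_chars.append(aa)
        out.append(_aa_record(rec, "".join(aa_chars)))
    return out


def _aa_record(rec: SequenceRecord, aa: str) -> SequenceRecord:
    # SequenceRecord validates a nucleotide alphabet; amino-acid records reuse
    # the container via object construction bypassing that check.
    obj = object.__new__(SequenceRecord)
    object.__setattr__(obj, "id", rec.id)
    object.__setattr__(obj, "seq", aa)
    object.__setattr__(obj, "species", rec.species)
    return obj


def poisson_distance_matrix(aa_records: list[SequenceRecord]) -> AADistanceMatrix:
    """Poisson-corrected distance matrix over an amino-acid alignment.

    Columns with '-' or 'X' in either member of a pair are deleted pairwise;
    ``d = -ln(1 - p)``. Pairs with p >= 1 or no comparable columns get NaN.
    """
    if len(aa_records) < 2:
        raise ValueError("need at least 2 sequences")
    L = len(aa_records[0].seq)
    if any(len(r.seq) != L for r in aa_records):
        raise ValueError("amino-acid sequences must have equal length")
    labels = tuple(r.id for r in aa_records)
    n = len(aa_records)
    p = np.zeros((n, n))
    d = np.zeros((n, n))
    seqs = [r.seq for r in aa_records]
    for i in range(n):
        for j in range(i + 1, n):
            compared = mismatch = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "-X" or b in "-X":
                    continue
                compared += 1
                if a != b:
                    mismatch += 1
            if compared == 0:
                pij = math.nan
            else:
                pij = mismatch / compared
            p[i, j] = p[j, i] = pij
            if math.isnan(pij) or pij >= 1.0:
                d[i, j] = d[j, i] = math.nan
            else:
                d[i, j] = d[j, i] = -math.log(1.0 - pij)
    return AADistanceMatrix(labels=labels, d=d, p=p)
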