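"""Readers and writers for FASTA, newick and BLAST tabular files, plus run configuration.

Sequence ids encode the source species by convention (e.g. ``Dbuzzatii_04_2`` is a
copy from *D. buzzatii*): the species label is the id token before the first
underscore, overridable with a regex in :class:`Config`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

NUCLEOTIDES = set("ACGTN-")

__all__ = [
    "Config",
    "FormatError",
    "SequenceRecord",
    "HitRecord",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "read_hits_tab",
    "species_from_id",
]


class FormatError(ValueError):
    """A file does not conform to its expected format."""


@dataclass(frozen=True)
class Config:
    """Thresholds and run parameters for the whole pipeline.

    Attributes
    ----------
    min_score : float
        Bit-score threshold for homology hits; hits must score strictly above it.
    max_evalue : float
        E-value threshold; hits must fall strictly below it.
    flank_bp : int
        Flanking bases extracted on each side of a retained hit.
    min_homology_bp : int
        Minimum confirmed homology (bp) to the best query; shorter fragments
        are withdrawn.
    subfamily_threshold : float
        Amino-acid divergence below which a reciprocally monophyletic clade is
        a single subfamily (Poisson-corrected distance, default 0.3 = 30%).
    alpha : float
        Significance level of the one-tailed Fisher's exact test.
    syn_rate_r : float
        Synonymous substitution rate, substitutions per synonymous site per
        million years per lineage (Drosophila low-codon-bias estimate 0.016).
    outgroup_label : str
        Leaf label used to root input trees.
    species_regex : str
        Regex whose first group extracts the species label from a sequence id.
    clock_per_lineage : bool
        If True (default) a pairwise dS reflects two lineages and divergence
        time is dS / (2 r); if False, dS / r.
    subfamily_statistic : str
        "mean" (default) or "max" pairwise within-clade divergence.
    homology_identical_only : bool
        If True, confirmed homology counts identical aligned columns instead
        of all aligned non-gap columns.
    rng_seed : int
        Seed for stochastic stages.
    """

    min_score: float = 50.0
    max_evalue: float = 1.0e-5
    flank_bp: int = 2000
    min_homology_bp: int = 300
    subfamily_threshold: float = 0.3
    alpha: float = 0.05
    syn_rate_r: float = 0.016
    outgroup_label: str = ""
    species_regex: str = r"^([^_]+)"
    clock_per_lineage: bool = True
    subfamily_statistic: str = "mean"
    homology_identical_only: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        for name in ("min_score", "max_evalue", "flank_bp", "min_homology_bp",
                     "subfamily_threshold", "syn_rate_r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.subfamily_statistic not in ("mean", "max"):
            raise ValueError("subfamily_statistic must be 'mean' or 'max'")

    def with_(self, **kwargs) -> "Config":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load a flat ``key=value`` config file (# comments, blank lines ok)."""
        values: dict[str, object] = {}
        types = cls.__dataclass_fields__
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, _, val = (t.strip() for t in line.partition("="))
            if key not in types:
                raise FormatError(f"{path}:{lineno}: unknown config key {key!r}")
            typ = types[key].type
            if typ in ("int", int):
                values[key] = int(val)
            elif typ in ("float", float):
                values[key] = float(val)
            elif typ in ("bool", bool):
                values[key] = val.lower() in ("1", "true", "yes")
            else:
                values[key] = val
        return cls(**values)


def species_from_id(record_id: str, species_regex: str = r"^([^_]+)") -> str:
    """Extract the species label from a sequence id.

    >>> species_from_id("Dbuzzatii_04_2")
    'Dbuzzatii'
    """
    m = re.search(species_regex, record_id)
    if not m or not m.group(1):
        raise ValueError(f"cannot parse species from id {record_id!r} "
                         f"with regex {species_regex!r}")
    return m.group(1)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with a species label parsed from its id."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValueError(f"sequence {self.id!r} contains invalid characters "
                             f"{sorted(bad)}")

    @property
    def ungapped(self) -> str:
        return self.seq.replace("-", "")


@dataclass(frozen=True)
class HitRecord:
    """One row of BLAST tabular (outfmt 6) output.

    Subject coordinates are 1-based inclusive; ``sstart > send`` marks a
    minus-strand hit.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.sstart < 1 or self.send < 1:
            raise ValueError("subject coordinates are 1-based (>= 1)")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def minus_strand(self) -> bool:
        return self.sstart > self.send

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span as a 0-based half-open interval, strand-independent."""
        lo, hi = sorted((self.sstart, self.send))
        return lo - 1, hi


def read_fasta(path: str | Path, *, aligned: bool = False,
               species_regex: str | None = r"^([^_]+)") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; gap characters are rejected unless ``aligned``.
    ``species_regex=None`` skips species parsing (label left empty).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        if not aligned and "-" in seq:
            raise FormatError(f"{path}: {rec.id!r} contains gaps but file was "
                              "read as unaligned (pass aligned=True)")
        species = species_from_id(rec.id, species_regex) if species_regex else ""
        records.append(SequenceRecord(id=rec.id, seq=seq, species=species))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as multi-FASTA, wrapped at 60 columns."""
    bio = [BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_newick(path: str | Path, outgroup_label: str | None = None) -> dendropy.Tree:
    """Read a newick tree, optionally rooting it on the outgroup leaf branch.

    Polytomies are preserved. Rooting delegates to
    :func:`httscan.classify.root_at_outgroup`.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"{path}: cannot parse newick: {exc}") from exc
    if outgroup_label:
        from httscan.classify import root_at_outgroup
        tree = root_at_outgroup(tree, outgroup_label)
    return tree


def read_hits_tab(path: str | Path) -> list[HitRecord]:
    """Parse BLAST tabular output (12-column outfmt 6)."""
    path = Path(path)
    hits: list[HitRecord] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise FormatError(f"{path}:{lineno}: expected 12 tab-separated "
                              f"columns, got {len(cols)}")
        try:
            hits.append(HitRecord(
                query_id=cols[0], subject_id=cols[1],
                pct_identity=float(cols[2]), aln_len=int(cols[3]),
                mismatches=int(cols[4]), gap_opens=int(cols[5]),
                qstart=int(cols[6]), qend=int(cols[7]),
                sstart=int(cols[8]), send=int(cols[9]),
                evalue=float(cols[10]), bitscore=float(cols[11]),
            ))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits
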