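"""Homology-search screening: hit thresholding, flank extraction, minimum-homology
filtering, per-species deduplication and codon-alignment validation.

These are the two desk filtering rounds applied to raw homology-search output
before any distance or tree work: (1) keep hits scoring above the bit-score
threshold and below the E-value threshold and pull the hit region plus flanks
out of the scaffold; (2) drop fragments with too little confirmed homology to
their best query, and collapse identical sequences recorded for the same
species into one representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from httscan.core_io import Config, HitRecord, SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "HomologySpan",
    "ValidationReport",
    "filter_hits",
    "extract_hit_region",
    "confirmed_homology",
    "filter_min_homology",
    "merge_identical_by_species",
    "validate_codon_alignment",
]


@dataclass(frozen=True)
class HomologySpan:
    """Confirmed homology (aligned bp to the best query) of one fragment."""

    record_id: str
    confirmed_bp: int

    def __post_init__(self) -> None:
        if self.confirmed_bp < 0:
            raise ValueError("confirmed_bp must be >= 0")


@dataclass
class ValidationReport:
    """Outcome of codon-alignment validation; one entry per violation."""

    violations: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def add(self, record_id: str, column: int, message: str) -> None:
        self.violations.append((record_id, column, message))

    def offending_ids(self) -> set[str]:
        return {v[0] for v in self.violations}


def filter_hits(hits: list[HitRecord], cfg: Config) -> list[HitRecord]:
    """Keep hits with bit score strictly above ``cfg.min_score`` and E-value
    strictly below ``cfg.max_evalue``; input order preserved."""
    return [h for h in hits
            if h.bitscore > cfg.min_score and h.evalue < cfg.max_evalue]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_hit_region(scaffold_seq: str, hit: HitRecord,
                       cfg: Config) -> SequenceRecord:
    """Extract the hit subject region plus ``cfg.flank_bp`` on each side.

    The window is clipped to the scaffold; minus-strand hits are returned
    reverse-complemented. The record id encodes scaffold and 1-based
    coordinates of the extracted window.
    """
    lo, hi = hit.subject_interval  # 0-based half-open
    if hi > len(scaffold_seq):
        raise ValueError(f"hit {hit.subject_id}:{hit.sstart}-{hit.send} exceeds "
                         f"scaffold length {len(scaffold_seq)}")
    start = max(0, lo - cfg.flank_bp)
    end = min(len(scaffold_seq), hi + cfg.flank_bp)
    region = scaffold_seq[start:end].upper()
    strand = "-" if hit.minus_strand else "+"
    if hit.minus_strand:
        region = reverse_complement(region)
    return SequenceRecord(
        id=f"{hit.subject_id}_{start + 1}_{end}{strand}",
        seq=region,
        species="",
    )


def confirmed_homology(fragment_aln: str, query_aln: str, *,
                       identical_only: bool = False) -> int:
    """Confirmed homology (bp) of a fragment against its best query, both given
    as rows of a pairwise alignment: columns where neither row is gapped
    (optionally also requiring identity)."""
    if len(fragment_aln) != len(query_aln):
        raise ValueError("alignment rows must have equal length")
    n = 0
    for f, q in zip(fragment_aln.upper(), query_aln.upper()):
        if f == "-" or q == "-":
            continue
        if identical_only and f != q:
            continue
        n += 1
    return n


def filter_min_homology(spans: list[HomologySpan], cfg: Config) -> list[str]:
    """Ids of fragments with at least ``cfg.min_homology_bp`` of confirmed
    homology ("less than 300 bp" are withdrawn, so exactly 300 survives)."""
    return [s.record_id for s in spans if s.confirmed_bp >= cfg.min_homology_bp]


def merge_identical_by_species(
        records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Collapse byte-identical sequences recorded for the same species.

    Identity is judged on the gap-stripped uppercase sequence so alignment
    padding cannot defeat deduplication. The first record of each identity
    group is kept, its id annotated with the merged ids. Identical sequences
    from different species are never merged.
    """
    groups: dict[tuple[str, str], list[SequenceRecord]] = {}
    order: list[tuple[str, str]] = []
    for rec in records:
        key = (rec.species, rec.ungapped.upper())
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(rec)
    out: list[SequenceRecord] = []
    for key in order:
        members = groups[key]
        rep = members[0]
        if len(members) > 1:
            merged = "|".join(m.id for m in members[1:])
            rep = SequenceRecord(id=f"{rep.id}(={merged})", seq=rep.seq,
                                 species=rep.species)
        out.append(rep)
    return out


def validate_codon_alignment(records: list[SequenceRecord]) -> ValidationReport:
    """Check that an alignment is usable as an in-frame codon matrix.

    Requirements: length a multiple of 3 and equal across records; every gap
    run starts on a codon boundary and has length a multiple of 3; no internal
    stop codon in frame 0 of the gap-stripped sequence (the terminal codon may
    be a stop). Violations are reported, not repaired.
    """
    report = ValidationReport()
    if not records:
        report.add("", 0, "empty alignment")
        return report
    L = len(records[0].seq)
    if L % 3 != 0:
        report.add(records[0].id, L, f"alignment length {L} not a multiple of 3")
    for rec in records:
        if len(rec.seq) != L:
            report.add(rec.id, len(rec.seq),
                       f"length {len(rec.seq)} differs from {L}")
            continue
        # gap runs must be codon-shaped
        i = 0
        while i < L:
            if rec.seq[i] == "-":
                j = i
                while j < L and rec.seq[j] == "-":
                    j += 1
                if i % 3 != 0:
                    report.add(rec.id, i, f"gap run starts mid-codon at column {i}")
                elif (j - i) % 3 != 0:
                    report.add(rec.id, i,
                               f"gap run length {j - i} not a multiple of 3")
                i = j
            else:
                i += 1
        # no internal in-frame stops, frame 0 of the gap-stripped sequence
        # (equivalent to positional frame when gap runs are codon-shaped)
        from httscan.distances import STOP_CODONS
        stripped = rec.seq.replace("-", "")
        for c in range((len(stripped) // 3) - 1):  # terminal codon may be a stop
            codon = stripped[3 * c:3 * c + 3]
            if codon in STOP_CODONS:
                report.add(rec.id, 3 * c,
                           f"internal stop codon {codon} at codon {c}")
    return report


def drop_violating(records: list[SequenceRecord],
                   report: ValidationReport) -> list[SequenceRecord]:
    """Remove records named in a validation report (the non-repairing
    alternative to manual gap resolution)."""
    bad = report.offending_ids()
    return [r for r in records if r.id not in bad]
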