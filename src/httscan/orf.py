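"""Coding-potential screen: which reading frames of a fragment are stop-free.

The fragments analysed are internal reverse-transcriptase domain slices, so an
"open" frame means a stop-free translation of the whole fragment rather than
an ATG-initiated ORF (a start-codon requirement is available as a flag).
Frames 0-2 are the forward frames; 3-5 are the frames of the
reverse-complement, scanned only when six-frame mode is on.
"""

from __future__ import annotations

from dataclasses import dataclass

from httscan.distances import STOP_CODONS
from httscan.screening import reverse_complement

__all__ = ["CodingReport", "find_coding_frames"]


@dataclass(frozen=True)
class CodingReport:
    record_id: str
    open_frames: tuple[int, ...]

    @property
    def potentially_coding(self) -> bool:
        return bool(self.open_frames)


def _frame_open(seq: str, offset: int, require_start: bool) -> bool:
    """True iff the maximal in-frame codon run from ``offset`` is stop-free
    (trailing partial codon ignored). Codons with ambiguity codes are not
    stops unless they resolve to one unambiguously, i.e. N-containing codons
    never close a frame."""
    codons = [seq[i:i + 3] for i in range(offset, len(seq) - 2, 3)]
    if not codons:
        return False
    if any(c in STOP_CODONS for c in codons):
        return False
    if require_start and codons[0] != "ATG":
        return False
    return True


def find_coding_frames(record_id: str, seq: str, *, six_frame: bool = False,
                       require_start: bool = False) -> CodingReport:
    """Report which reading frames of an (unaligned) sequence are open.

    Gaps are stripped before scanning; the sequence must then be at least one
    codon long.
    """
    seq = seq.replace("-", "").upper()
    if len(seq) < 3:
        raise ValueError(f"{record_id}: sequence shorter than one codon "
                         "after gap removal")
    frames = []
    for f in range(3):
        if _frame_open(seq, f, require_start):
            frames.append(f)
    if six_frame:
        rc = reverse_complement(seq)
        for f in range(3):
            if _frame_open(rc, f, require_start):
                frames.append(3 + f)
    return CodingReport(record_id=record_id, open_frames=tuple(frames))
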