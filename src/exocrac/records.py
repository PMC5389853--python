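"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array of ASCII codes (uppercased)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


@dataclass
class ReadRecord:
    """One sequencing read.

    ``sequence``/``quality`` always have equal length; ``barcode`` is the
    3-nt random portion of the 5' linker once extracted (None before).
    """

    read_id: str
    sequence: str
    quality: str
    barcode: str | None = None
    adapter_found: bool = False
    trimmed_length: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.read_id}: sequence and quality lengths differ"
            )
        if self.barcode is not None and len(self.barcode) != 3:
            raise ValueError(f"{self.read_id}: barcode must be 3 nt")


@dataclass
class AlignmentRecord:
    """One placement of a read on a reference.

    Coordinates are 0-based half-open on the forward strand of the
    reference. ``n_hits`` is the number of equally best placements found
    for the read (ties at the minimum score). Deletion and substitution
    positions are reference coordinates.
    """

    read_id: str
    reference_id: str
    start: int
    end: int
    strand: str = "+"
    n_hits: int = 1
    deletion_positions: tuple[int, ...] = ()
    substitution_positions: tuple[int, ...] = ()
    softclip_3p: int = 0
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("alignment start must precede end")
        if self.n_hits < 1:
            raise ValueError("n_hits must be >= 1")
        for pos in self.deletion_positions:
            if not (self.start <= pos < self.end):
                raise ValueError("deletion position outside alignment span")

    @property
    def span(self) -> int:
        return self.end - self.start
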