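"""Core read container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

PHRED_OFFSET = 33


@dataclass(frozen=True)
class ReadRecord:
    """A single sequencing read.

    ``quality`` is the Phred+33 ASCII string, kept in string form so records
    round-trip through FASTQ byte-identically.
    """

    read_id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def phred(self) -> list[int]:
        """Per-base Phred scores as integers."""
        return [ord(c) - PHRED_OFFSET for c in self.quality]

    def slice(self, start: int, stop: int | None = None) -> "ReadRecord":
        """Sub-read over python half-open coordinates [start, stop)."""
        return ReadRecord(self.read_id, self.sequence[start:stop], self.quality[start:stop])


def quality_string(scores, clamp: tuple[int, int] = (0, 41)) -> str:
    """Encode integer Phred scores as a Phred+33 string."""
    lo, hi = clamp
    return "".join(chr(min(hi, max(lo, int(q))) + PHRED_OFFSET) for q in scores)
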