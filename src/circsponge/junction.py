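"""Back-spliced junction coordinates and per-sample circRNA detection records.

A circRNA is identified by its back-spliced junction (BSJ): the genomic
coordinates at which the 3' end of a downstream exon is joined back to the
5' end of an upstream exon.  The canonical in-memory convention is 1-based,
inclusive on both ends (the convention of the ``chr:start|end`` ID strings
emitted by CIRI2).  Strand is recorded but deliberately excluded from
junction identity: the two callers occasionally disagree on strand for the
same event, and the human-readable ID omits it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "BackspliceJunction",
    "CircRecord",
    "DetectionSummary",
    "detection_summary",
]

_VALID_STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class BackspliceJunction:
    """A back-spliced junction in 1-based, fully inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"junction start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def circ_id(self) -> str:
        """Canonical ID string, ``chrom:start|end``."""
        return f"{self.chrom}:{self.start}|{self.end}"

    @property
    def key(self) -> tuple[str, int, int]:
        """Identity key: (chrom, start, end).  Strand is not part of identity."""
        return (self.chrom, self.start, self.end)

    @classmethod
    def from_circ_id(cls, circ_id: str, strand: str = ".") -> "BackspliceJunction":
        """Parse a ``chrom:start|end`` ID string."""
        try:
            chrom, rest = circ_id.rsplit(":", 1)
            start_s, end_s = rest.split("|")
            return cls(chrom, int(start_s), int(end_s), strand)
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"malformed circRNA ID {circ_id!r}") from exc

    @classmethod
    def from_zero_based(
        cls, chrom: str, start0: int, end0: int, strand: str = "."
    ) -> "BackspliceJunction":
        """Convert from 0-based half-open (BED-style) coordinates."""
        return cls(chrom, start0 + 1, end0, strand)

    def to_zero_based(self) -> tuple[str, int, int]:
        """Inverse of :meth:`from_zero_based`."""
        return (self.chrom, self.start - 1, self.end)

    # Identity and hashing on the strand-free key so that junction sets from
    # the two callers intersect even when strand calls disagree.
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BackspliceJunction):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)


@dataclass(frozen=True)
class CircRecord:
    """One junction observation: a junction, in one sample, from one caller."""

    junction: BackspliceJunction
    sample_id: str
    junction_reads: float
    caller: str  # "A" (CIRI2-like) or "B" (CIRCexplorer2-like)

    def __post_init__(self) -> None:
        if self.junction_reads < 0:
            raise ValueError("junction_reads must be non-negative")
        if self.caller not in ("A", "B"):
            raise ValueError(f"caller must be 'A' or 'B', got {self.caller!r}")


@dataclass
class DetectionSummary:
    """Per-tissue detection counts in the layout of a detection table:

    how many junctions were seen in cases, in controls, in both, and in
    exactly one condition.
    """

    tissue: str
    n_case: int
    n_control: int
    detected_case: int
    detected_control: int
    common: int
    unique_case: int = field(init=False)
    unique_control: int = field(init=False)

    def __post_init__(self) -> None:
        if self.common > min(self.detected_case, self.detected_control):
            raise ValueError(
                "common detections cannot exceed either condition's total"
            )
        self.unique_case = self.detected_case - self.common
        self.unique_control = self.detected_control - self.common


def detection_summary(
    per_condition_detected: Mapping[str, Iterable],
    tissue: str = "",
    n_case: int = 0,
    n_control: int = 0,
) -> DetectionSummary:
    """Summarise detected-junction sets for one tissue.

    ``per_condition_detected`` maps condition labels (exactly ``"case"`` and
    ``"control"``) to junction sets.  ``unique_case``/``unique_control`` are
    the set differences, derived from the cardinalities by inclusion-
    exclusion.
    """
    labels = set(per_condition_detected)
    if labels != {"case", "control"}:
        raise ValueError(
            f"conditions must be exactly {{'case', 'control'}}, got {sorted(labels)}"
        )
    case = set(per_condition_detected["case"])
    control = set(per_condition_detected["control"])
    return DetectionSummary(
        tissue=tissue,
        n_case=n_case,
        n_control=n_control,
        detected_case=len(case),
        detected_control=len(control),
        common=len(case & control),
    )


def detection_summary_from_counts(
    tissue: str,
    detected_case: int,
    detected_control: int,
    common: int,
    n_case: int = 0,
    n_control: int = 0,
) -> DetectionSummary:
    """Build a summary directly from cardinalities (e.g. a published table)."""
    return DetectionSummary(
        tissue=tissue,
        n_case=n_case,
        n_control=n_control,
        detected_case=detected_case,
        detected_control=detected_control,
        common=common,
    )
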