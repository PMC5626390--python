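"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open (``[start, end)``), the BED
convention, regardless of input dialect. The TSS of a minus-strand gene is
``end - 1`` (its last covered base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Set


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: the coordinate anchor for every peak-assignment rule.

    The gene body is the full transcript span, introns included; exon-level
    structure is deliberately not modelled.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if not self.start < self.end:
            raise ValidationError(
                f"gene {self.gene_id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.start < 0:
            raise ValidationError(f"gene {self.gene_id!r}: negative start")

    @property
    def tss(self) -> int:
        """Transcriptional start site (always inside ``[start, end)``)."""
        return self.start if self.strand == "+" else self.end - 1


class GeneModelSet:
    """Ordered, id-unique collection of gene models.

    Iteration order is deterministic: (chrom, start, gene_id).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        by_id: Dict[str, GeneModel] = {}
        for g in ordered:
            if g.gene_id in by_id:
                raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
            by_id[g.gene_id] = g
        self._genes: List[GeneModel] = ordered
        self._by_id = by_id

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self._genes]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModelSet):
            return NotImplemented
        return self._genes == other._genes


@dataclass(frozen=True)
class Peak:
    """A scored ChIP-seq interval; ``amplitude`` is the tag count (peak height)."""

    chrom: str
    start: int
    end: int
    peak_id: str
    amplitude: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"peak {self.peak_id!r}: zero/negative-length interval "
                f"[{self.start}, {self.end})"
            )
        if self.amplitude < 0:
            raise ValidationError(
                f"peak {self.peak_id!r}: negative amplitude {self.amplitude}"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0


class PeakSet:
    """Named collection of peaks for one TF/condition."""

    def __init__(self, name: str, peaks: Iterable[Peak]):
        self.name = name
        self._peaks: List[Peak] = sorted(
            peaks, key=lambda p: (p.chrom, p.start, p.peak_id)
        )
        ids = [p.peak_id for p in self._peaks]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"peak set {name!r}: duplicate peak ids")
        self._by_id = {p.peak_id: p for p in self._peaks}

    def __iter__(self) -> Iterator[Peak]:
        return iter(self._peaks)

    def __len__(self) -> int:
        return len(self._peaks)

    def __getitem__(self, peak_id: str) -> Peak:
        return self._by_id[peak_id]

    def amplitudes(self) -> List[float]:
        return [p.amplitude for p in self._peaks]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.name == other.name and self._peaks == other._peaks


class GeneSetCollection:
    """name -> set of gene ids; empty sets are rejected, duplicates collapsed."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        self._sets: Dict[str, Set[str]] = {}
        for name, members in sets.items():
            collapsed = set(members)
            if not collapsed:
                raise ValidationError(f"gene set {name!r} is empty")
            self._sets[name] = collapsed

    def __getitem__(self, name: str) -> Set[str]:
        return set(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def names(self) -> List[str]:
        return sorted(self._sets)

    def items(self):
        for name in self.names():
            yield name, set(self._sets[name])


@dataclass(frozen=True)
class SignatureEvidence:
    """Per-gene evidence backing signature membership."""

    fold_change: float
    p_value: float
    direction: str  # "up" | "down"
    best_peak_id: str
    best_amplitude: float
    relation: str  # "in_body" | "near_tss"


@dataclass
class Signature:
    """Derived target-gene list with per-gene evidence and its rule tier."""

    tier: str  # "full" | "compact"
    members: Dict[str, SignatureEvidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tier not in ("full", "compact"):
            raise ValidationError(f"unknown signature tier {self.tier!r}")

    @property
    def gene_ids(self) -> Set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.members
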