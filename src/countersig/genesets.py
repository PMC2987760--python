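"""Directional gene signatures: parsing, normalisation, pooling and Venn decomposition.

The analysis operates on plain gene-symbol sets. A *directional signature* is
the (up-regulated, down-regulated) pair of sets summarising one
differential-expression study; signatures from several studies of the same
disease are pooled by set union before being compared against a drug gene
set. Symbols are stored in a single canonical case (upper, the human
gene-symbol convention) so that lists originating from different sources
match textually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import MalformedIdentifierError, SpeciesMismatchError

__all__ = [
    "GeneSet",
    "DirectionalSignature",
    "VennCounts",
    "normalize_id",
    "parse_gene_list",
    "read_gene_list",
    "pool_signatures",
    "venn_counts",
]

COMMENT_CHAR = "#"


def normalize_id(raw: str) -> str:
    """Return the canonical form of a gene identifier.

    Canonicalisation strips surrounding whitespace and upper-cases the
    symbol. The operation is deterministic and idempotent:
    ``normalize_id(normalize_id(x)) == normalize_id(x)``.

    Raises
    ------
    MalformedIdentifierError
        If ``raw`` is empty or whitespace-only.
    """
    symbol = raw.strip().upper()
    if not symbol:
        raise MalformedIdentifierError(
            f"gene identifier is empty after stripping whitespace: {raw!r}"
        )
    return symbol


@dataclass(frozen=True)
class GeneSet:
    """A labelled, species-tagged set of normalised gene symbols."""

    label: str
    species: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("GeneSet label must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def from_iterable(cls, label: str, species: str, raw: Iterable[str]) -> "GeneSet":
        """Build a set from raw identifiers, normalising and deduplicating."""
        return cls(label, species, frozenset(normalize_id(r) for r in raw))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def intersection(self, other: "GeneSet") -> frozenset[str]:
        return self.members & other.members

    def union(self, other: "GeneSet") -> frozenset[str]:
        return self.members | other.members

    def require_same_species(self, other: "GeneSet") -> None:
        if self.species != other.species:
            raise SpeciesMismatchError(
                f"species mismatch: {self.label!r} is {self.species!r} but "
                f"{other.label!r} is {other.species!r}"
            )


def parse_gene_list(
    stream: Iterable[str] | IO[str], label: str, species: str
) -> GeneSet:
    """Parse a one-symbol-per-line gene list into a :class:`GeneSet`.

    Blank lines and lines starting with ``#`` are ignored. Duplicate
    symbols (after normalisation) collapse to one member, so the returned
    set size never exceeds the usable line count. A list with zero usable
    lines yields an empty set and a warning rather than an error: empty
    signatures are legitimate (a study may report no down-regulated genes).
    """
    members: set[str] = set()
    for line in stream:
        stripped = line.strip()
        if not stripped or stripped.startswith(COMMENT_CHAR):
            continue
        members.add(normalize_id(stripped))
    if not members:
        warnings.warn(f"gene list {label!r} contains no usable lines", stacklevel=2)
    return GeneSet(label, species, frozenset(members))


def read_gene_list(path, label: str | None = None, species: str = "human") -> GeneSet:
    """Read a gene list file from ``path`` (convenience wrapper)."""
    import os

    with open(path, "rt", encoding="utf-8") as fh:
        return parse_gene_list(fh, label or os.path.basename(str(path)), species)


@dataclass(frozen=True)
class DirectionalSignature:
    """One study's (or a pool's) up- and down-regulated gene sets.

    ``up`` and ``down`` may intersect: after pooling several studies, a gene
    reported up in one study and down in another legitimately appears in
    both directional sets, while being counted once in the universe.
    """

    study_label: str
    up: GeneSet
    down: GeneSet

    def __post_init__(self) -> None:
        self.up.require_same_species(self.down)

    @property
    def species(self) -> str:
        return self.up.species

    @property
    def universe(self) -> frozenset[str]:
        """All genes in the signature: ``up ∪ down``."""
        return self.up.members | self.down.members


def pool_signatures(signatures: list[DirectionalSignature]) -> DirectionalSignature:
    """Pool study signatures by set union of their directional lists.

    The pooled ``up`` (``down``) set is the union of every study's up
    (down) list; a gene with conflicting directions across studies is kept
    in both pooled directional sets but contributes once to the pooled
    universe. Pooling is associative and order-independent.

    Raises
    ------
    SpeciesMismatchError
        If the signatures do not all share one species tag.
    ValueError
        If ``signatures`` is empty.
    """
    if not signatures:
        raise ValueError("cannot pool an empty list of signatures")
    species = signatures[0].species
    for sig in signatures[1:]:
        if sig.species != species:
            raise SpeciesMismatchError(
                f"cannot pool signatures across species: {species!r} vs "
                f"{sig.species!r} ({sig.study_label!r})"
            )
    up_members: frozenset[str] = frozenset().union(*(s.up.members for s in signatures))
    down_members: frozenset[str] = frozenset().union(
        *(s.down.members for s in signatures)
    )
    label = "pooled(" + "+".join(s.study_label for s in signatures) + ")"
    return DirectionalSignature(
        study_label=label,
        up=GeneSet(f"{label}:up", species, up_members),
        down=GeneSet(f"{label}:down", species, down_members),
    )


@dataclass(frozen=True)
class VennCounts:
    """Cardinalities of the disease-universe / drug-set Venn decomposition.

    Satisfies the inclusion-exclusion identity
    ``drug_in_universe = drug_in_up + drug_in_down - drug_in_both``.
    """

    universe_size: int
    up_size: int
    down_size: int
    drug_in_universe: int
    drug_in_up: int
    drug_in_down: int
    drug_in_both: int

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        """The six headline counts (universe, up, down, ∩drug, up∩drug, down∩drug)."""
        return (
            self.universe_size,
            self.up_size,
            self.down_size,
            self.drug_in_universe,
            self.drug_in_up,
            self.drug_in_down,
        )


def venn_counts(pooled: DirectionalSignature, drug: GeneSet) -> VennCounts:
    """Count the overlaps between a pooled signature and a drug gene set.

    The drug set must already be mapped to the signature's species.
    """
    pooled.up.require_same_species(drug)
    both = pooled.up.members & pooled.down.members
    return VennCounts(
        universe_size=len(pooled.universe),
        up_size=len(pooled.up),
        down_size=len(pooled.down),
        drug_in_universe=len(pooled.universe & drug.members),
        drug_in_up=len(pooled.up.members & drug.members),
        drug_in_down=len(pooled.down.members & drug.members),
        drug_in_both=len(both & drug.members),
    )
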