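"""Cross-species homolog mapping through a local two-column table.

A drug gene set measured in a model organism (here, fly genes) must be
translated to the disease species' gene symbols before any overlap
statistic makes sense. The mapping is a multimap: one source gene may have
several homologs (paralog expansion) and several sources may share one
target (collapse). Sources with no table entry are dropped from downstream
statistics but enumerated in the mapping report, since the overlap universe
is defined on the disease side and unmapped drug genes cannot participate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import MalformedInputError, SpeciesMismatchError
from .genesets import GeneSet, normalize_id

__all__ = ["HomologyMap", "MappingReport", "load_homology_table", "map_to_human"]


@dataclass(frozen=True)
class HomologyMap:
    """Multimap from source-species gene IDs to target-species symbols."""

    source_species: str
    target_species: str
    pairs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def sources(self) -> frozenset[str]:
        return frozenset(s for s, _ in self.pairs)

    def targets_of(self, source: str) -> frozenset[str]:
        return frozenset(t for s, t in self.pairs if s == source)

    def as_dict(self) -> dict[str, frozenset[str]]:
        """The multimap as ``{source: {targets}}``."""
        out: dict[str, set[str]] = {}
        for s, t in self.pairs:
            out.setdefault(s, set()).add(t)
        return {s: frozenset(ts) for s, ts in out.items()}


@dataclass(frozen=True)
class MappingReport:
    """Bookkeeping of a homolog-mapping step."""

    n_source: int
    n_mapped_source: int
    n_target_genes: int
    multiplicity_histogram: dict[int, int]
    unmapped: tuple[str, ...]

    @property
    def n_unmapped(self) -> int:
        return self.n_source - self.n_mapped_source

    def to_dict(self) -> dict:
        return {
            "n_source": self.n_source,
            "n_mapped_source": self.n_mapped_source,
            "n_unmapped_source": self.n_unmapped,
            "n_target_genes": self.n_target_genes,
            "multiplicity_histogram": {
                str(k): v for k, v in sorted(self.multiplicity_histogram.items())
            },
            "unmapped": list(self.unmapped),
        }


def load_homology_table(
    stream: Iterable[str] | IO[str],
    source_species: str = "drosophila",
    target_species: str = "human",
) -> HomologyMap:
    """Load a two-column tab-separated homology table.

    Each data row carries ``source_gene<TAB>target_gene`` (extra columns are
    ignored). Lines starting with ``#`` and blank lines are skipped.
    Duplicate pairs collapse; row order is irrelevant to the result.

    Raises
    ------
    MalformedInputError
        If a data row has fewer than two tab-separated fields; the message
        names the offending line number.
    """
    import warnings

    pairs: set[tuple[str, str]] = set()
    for lineno, line in enumerate(stream, start=1):
        stripped = line.rstrip("\n")
        if not stripped.strip() or stripped.lstrip().startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise MalformedInputError(
                f"homology table line {lineno}: expected at least two "
                f"tab-separated fields, got {stripped!r}"
            )
        pairs.add((normalize_id(fields[0]), normalize_id(fields[1])))
    if not pairs:
        warnings.warn("homology table contains no usable rows", stacklevel=2)
    return HomologyMap(source_species, target_species, frozenset(pairs))


def map_to_human(
    drug: GeneSet, homology: HomologyMap
) -> tuple[GeneSet, MappingReport]:
    """Map a source-species gene set to target-species symbols.

    The output is the deduplicated union of all targets of every mapped
    source, tagged with the target species. Because the relation is
    many-to-many the output may be larger or smaller than the input. The
    report records how many sources mapped, the targets-per-source
    multiplicity histogram over the input set, and which sources were
    unmapped.

    Raises
    ------
    SpeciesMismatchError
        If ``drug.species`` differs from the table's source species.
    """
    if drug.species != homology.source_species:
        raise SpeciesMismatchError(
            f"drug set species {drug.species!r} does not match homology "
            f"table source species {homology.source_species!r}"
        )
    multimap = homology.as_dict()
    targets: set[str] = set()
    histogram: Counter[int] = Counter()
    unmapped: list[str] = []
    for source in sorted(drug.members):
        source_targets = multimap.get(source, frozenset())
        histogram[len(source_targets)] += 1
        if source_targets:
            targets |= source_targets
        else:
            unmapped.append(source)
    mapped = GeneSet(
        label=f"{drug.label}:{homology.target_species}-homologs",
        species=homology.target_species,
        members=frozenset(targets),
    )
    report = MappingReport(
        n_source=len(drug),
        n_mapped_source=len(drug) - len(unmapped),
        n_target_genes=len(targets),
        multiplicity_histogram=dict(histogram),
        unmapped=tuple(unmapped),
    )
    return mapped, report
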