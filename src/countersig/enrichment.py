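"""Pathway over-representation of a foreground gene set within a background.

The foreground here is typically the *counteracting commonality* set — genes
both down-regulated by the drug and up-regulated in the disease — and the
background is the full disease-upregulated set, not the genome: pathway
membership K is counted within the background by intersection, so genes a
pathway annotates outside the background are invisible to the test.

Each pathway gets the full hypergeometric treatment (point mass and both
tails); the default significance call uses the upper tail, while the
``point`` convention reproduces values published from legacy spreadsheet
point-mass calculations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable

import pandas as pd

from .errors import ContainmentError, MalformedInputError, UndefinedTestError
from .genesets import GeneSet, normalize_id
from .overlap_stats import (
    Convention,
    OverlapCounts,
    hypergeom_lower,
    hypergeom_pmf,
    hypergeom_upper,
)

__all__ = [
    "PathwayCollection",
    "EnrichmentRecord",
    "load_gmt",
    "read_gmt",
    "write_gmt",
    "pathway_enrichment",
    "scan_pathways",
    "scan_to_frame",
]


@dataclass(frozen=True)
class PathwayCollection:
    """A named collection of pathways, each a gene set."""

    name: str
    pathways: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def __getitem__(self, pathway: str) -> GeneSet:
        return self.pathways[pathway]


def load_gmt(
    stream: Iterable[str] | IO[str], name: str = "collection", species: str = "human"
) -> PathwayCollection:
    """Parse a GMT stream (pathway name, description, member genes per line).

    Genes are normalised and deduplicated per pathway; line order is
    irrelevant to the result.

    Raises
    ------
    MalformedInputError
        On a line with fewer than three tab-separated fields, or a duplicate
        pathway name; messages carry the line number.
    """
    pathways: dict[str, GeneSet] = {}
    for lineno, line in enumerate(stream, start=1):
        stripped = line.rstrip("\n")
        if not stripped.strip():
            continue
        fields = stripped.split("\t")
        if len(fields) < 3:
            raise MalformedInputError(
                f"GMT line {lineno}: expected name, description and at least "
                f"one gene (>=3 tab-separated fields), got {len(fields)}"
            )
        pname = fields[0].strip()
        if not pname:
            raise MalformedInputError(f"GMT line {lineno}: empty pathway name")
        if pname in pathways:
            raise MalformedInputError(
                f"GMT line {lineno}: duplicate pathway name {pname!r}"
            )
        members = frozenset(normalize_id(g) for g in fields[2:] if g.strip())
        if not members:
            raise MalformedInputError(f"GMT line {lineno}: pathway has no genes")
        pathways[pname] = GeneSet(pname, species, members)
    return PathwayCollection(name, pathways)


def read_gmt(path, name: str | None = None, species: str = "human") -> PathwayCollection:
    import os

    with open(path, "rt", encoding="utf-8") as fh:
        return load_gmt(fh, name or os.path.basename(str(path)), species)


def write_gmt(collection: PathwayCollection, path) -> None:
    """Write a collection as GMT, members sorted for deterministic output."""
    with open(path, "wt", encoding="utf-8") as fh:
        for pname, gs in collection:
            fh.write("\t".join([pname, "synthetic", *sorted(gs.members)]) + "\n")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's over-representation test result."""

    pathway: str
    background_size: int
    background_hits: int
    foreground_size: int
    foreground_hits: int
    hit_genes: tuple[str, ...]
    expected: float
    p_point: float
    p_upper: float
    p_lower: float
    alpha: float
    convention: str
    eligible: bool = True
    significant: bool = False
    q_value: float | None = None

    @property
    def p(self) -> float:
        """The nominal p-value under this record's convention."""
        return self.p_point if self.convention == "point" else self.p_upper

    def to_dict(self) -> dict:
        return {
            "pathway": self.pathway,
            "N": self.background_size,
            "K": self.background_hits,
            "n": self.foreground_size,
            "k": self.foreground_hits,
            "expected": self.expected,
            "p_point": self.p_point,
            "p_upper": self.p_upper,
            "p_lower": self.p_lower,
            "p": self.p,
            "q_value": self.q_value,
            "convention": self.convention,
            "alpha": self.alpha,
            "eligible": self.eligible,
            "significant": self.significant,
            "hit_genes": list(self.hit_genes),
        }


def pathway_enrichment(
    foreground: GeneSet,
    background: GeneSet,
    pathway: GeneSet,
    alpha: float = 0.05,
    convention: Convention = "tail",
) -> EnrichmentRecord:
    """Test one pathway for over-representation in the foreground.

    Counts: N = |background|, K = |background ∩ pathway|,
    n = |foreground|, k = |foreground ∩ pathway|. The foreground must be
    contained in the background (the test is meaningless otherwise).
    Pathway members outside the background do not affect the result.

    Raises
    ------
    ContainmentError
        If foreground ⊄ background; the message lists the offending genes.
    UndefinedTestError
        If the background is empty.
    """
    if not background.members:
        raise UndefinedTestError("pathway enrichment on an empty background")
    stray = foreground.members - background.members
    if stray:
        raise ContainmentError(
            "foreground genes missing from background: "
            + ", ".join(sorted(stray)[:10])
            + ("..." if len(stray) > 10 else "")
        )
    pathway_in_bg = background.members & pathway.members
    hits = sorted(foreground.members & pathway_in_bg)
    counts = OverlapCounts(
        N=len(background), K=len(pathway_in_bg), n=len(foreground), k=len(hits)
    )
    p_point = hypergeom_pmf(counts)
    p_upper = hypergeom_upper(counts)
    p_lower = hypergeom_lower(counts)
    nominal = p_point if convention == "point" else p_upper
    return EnrichmentRecord(
        pathway=pathway.label,
        background_size=counts.N,
        background_hits=counts.K,
        foreground_size=counts.n,
        foreground_hits=counts.k,
        hit_genes=tuple(hits),
        expected=counts.expected,
        p_point=p_point,
        p_upper=p_upper,
        p_lower=p_lower,
        alpha=alpha,
        convention=convention,
        eligible=True,
        significant=nominal < alpha,
    )


def scan_pathways(
    foreground: GeneSet,
    background: GeneSet,
    collection: PathwayCollection,
    alpha: float = 0.05,
    min_hits: int = 3,
    convention: Convention = "tail",
    bh: bool = False,
) -> list[EnrichmentRecord]:
    """Test every pathway in a collection; deterministic (p, name) order.

    Pathways with fewer than ``min_hits`` foreground hits are marked
    ineligible and never called significant regardless of their p-value
    (small-k point-mass "enrichment" is unstable). Nominal p-values are
    used by default, matching the significance rule this analysis follows;
    ``bh=True`` adds Benjamini-Hochberg q-values over the eligible
    records' nominal p-values and calls significance on q < alpha instead.
    """
    records = []
    for _, pathway in collection:
        rec = pathway_enrichment(
            foreground, background, pathway, alpha=alpha, convention=convention
        )
        if rec.foreground_hits < min_hits:
            rec = replace(rec, eligible=False, significant=False)
        records.append(rec)
    if bh and any(r.eligible for r in records):
        from statsmodels.stats.multitest import multipletests

        eligible = [r for r in records if r.eligible]
        _, qvals, _, _ = multipletests(
            [r.p for r in eligible], alpha=alpha, method="fdr_bh"
        )
        adjusted = {
            r.pathway: replace(r, q_value=float(q), significant=bool(q < alpha))
            for r, q in zip(eligible, qvals)
        }
        records = [adjusted.get(r.pathway, r) for r in records]
    records.sort(key=lambda r: (r.p, r.pathway))
    if not records:
        warnings.warn("pathway scan over an empty collection", stacklevel=2)
    return records


def scan_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate scan records (one row per pathway, hit genes comma-joined)."""
    rows = []
    for r in records:
        d = r.to_dict()
        d["hit_genes"] = ",".join(r.hit_genes)
        rows.append(d)
    columns = [
        "pathway", "N", "K", "n", "k", "expected",
        "p_point", "p_upper", "p_lower", "p", "q_value",
        "eligible", "significant", "hit_genes",
    ]
    return pd.DataFrame(rows, columns=columns)
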