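"""Exact-planting synthetic input bundles for the whole pipeline.

The analysis consumes gene *lists*, so the generator emulates list
structure, not expression values: fixed-size directional DEG lists with
partial inter-study overlap, a lossy many-to-many homology table, and
pathway membership concentrated where the planting plan says. Planting is
exact-combinatorial — the universe is partitioned and genes assigned, never
sampled against a target — so every feasible configured cardinality is
recovered exactly by the pipeline, which is what makes the fixtures usable
as arithmetic oracles.

Synthetic symbols carry reserved prefixes (``DSG`` disease genes, ``DPTZ``
drug-source genes, ``HX`` out-of-universe homolog targets, ``PWX`` pathway
decoys) so that optionally injected real symbols (e.g. BRAF, PAK1, PRKCA,
kept for documentation fidelity) can never collide with generated ones.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InfeasibleConfigError
from .enrichment import PathwayCollection, write_gmt
from .genesets import DirectionalSignature, GeneSet, pool_signatures
from .homology import HomologyMap, map_to_human

__all__ = [
    "PathwayPlan",
    "SyntheticConfig",
    "SyntheticBundle",
    "published_example_config",
    "generate_disease_signatures",
    "generate_drug_bundle",
    "generate_pathway_collection",
    "generate_bundle",
    "write_bundle",
]

DISEASE_PREFIX = "DSG"
DRUG_PREFIX = "DPTZ"
EXTRA_TARGET_PREFIX = "HX"
DECOY_PREFIX = "PWX"


@dataclass(frozen=True)
class PathwayPlan:
    """One pathway to plant: K background hits, k foreground hits, padding.

    ``foreground_hits=None`` plants a *null* pathway: its K background
    members are drawn uniformly, so the foreground hit count is genuinely
    hypergeometric — the construction used for false-positive-rate checks.
    ``force_hits`` lists symbols that must be among the foreground hits
    (they must be present in the foreground at generation time).
    """

    name: str
    background_hits: int
    foreground_hits: int | None
    decoy_size: int = 50
    force_hits: tuple[str, ...] = ()


@dataclass(frozen=True)
class SyntheticConfig:
    """Sizes, planted overlaps and seed for one synthetic bundle.

    Pooled targets are exact: pooling the generated signatures yields
    precisely ``pooled_up``/``pooled_down``/``pooled_universe`` genes, and
    mapping the drug set through the generated homology table yields
    precisely the planted Venn counts.
    """

    n_studies: int = 3
    pooled_up: int = 419
    pooled_down: int = 301
    pooled_universe: int = 716
    drug_source_size: int = 200
    multiplicity_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.2, 1: 0.6, 2: 0.2}
    )
    planted_universe_overlap: int = 56
    planted_up_overlap: int = 41
    planted_down_overlap: int = 16
    pathway_plan: tuple[PathwayPlan, ...] = ()
    inject_symbols: tuple[str, ...] = ()
    source_species: str = "drosophila"
    target_species: str = "human"
    seed: int = 0

    @property
    def direction_conflicts(self) -> int:
        """Genes that must land in both pooled directions: |up| + |down| - |universe|."""
        return self.pooled_up + self.pooled_down - self.pooled_universe

    @property
    def drug_in_both(self) -> int:
        """Planted drug genes in up ∩ down, forced by inclusion-exclusion."""
        return (
            self.planted_up_overlap
            + self.planted_down_overlap
            - self.planted_universe_overlap
        )

    def validate(self) -> None:
        c = self.direction_conflicts
        if c < 0:
            raise InfeasibleConfigError(
                f"pooled_universe={self.pooled_universe} exceeds "
                f"pooled_up + pooled_down = {self.pooled_up + self.pooled_down}: "
                "the universe cannot be larger than the union of directions"
            )
        if max(self.pooled_up, self.pooled_down) > self.pooled_universe:
            raise InfeasibleConfigError(
                "a directional set cannot exceed the pooled universe"
            )
        if self.n_studies < 1:
            raise InfeasibleConfigError("need at least one study")
        b = self.drug_in_both
        if b < 0:
            raise InfeasibleConfigError(
                f"planted_universe_overlap={self.planted_universe_overlap} exceeds "
                f"planted_up_overlap + planted_down_overlap = "
                f"{self.planted_up_overlap + self.planted_down_overlap}"
            )
        if b > c:
            raise InfeasibleConfigError(
                f"planting needs {b} drug genes in up∩down but pooling only "
                f"creates {c} such genes"
            )
        up_only = self.pooled_up - c
        down_only = self.pooled_down - c
        if self.planted_up_overlap - b > up_only:
            raise InfeasibleConfigError(
                f"planting needs {self.planted_up_overlap - b} up-only drug genes "
                f"but only {up_only} exist"
            )
        if self.planted_down_overlap - b > down_only:
            raise InfeasibleConfigError(
                f"planting needs {self.planted_down_overlap - b} down-only drug "
                f"genes but only {down_only} exist"
            )
        if any(p < 0 for p in self.multiplicity_probs.values()) or not any(
            self.multiplicity_probs.values()
        ):
            raise InfeasibleConfigError("multiplicity probabilities must be >= 0, not all zero")
        if all(m == 0 for m, p in self.multiplicity_probs.items() if p > 0):
            raise InfeasibleConfigError(
                "multiplicity distribution maps every source to zero targets"
            )
        for plan in self.pathway_plan:
            if plan.background_hits > self.pooled_up:
                raise InfeasibleConfigError(
                    f"pathway {plan.name!r}: background_hits={plan.background_hits} "
                    f"exceeds background size {self.pooled_up}"
                )
            if plan.foreground_hits is not None:
                if plan.foreground_hits > min(
                    plan.background_hits, self.planted_up_overlap
                ):
                    raise InfeasibleConfigError(
                        f"pathway {plan.name!r}: foreground_hits="
                        f"{plan.foreground_hits} exceeds min(background_hits, "
                        f"foreground size {self.planted_up_overlap})"
                    )
                if len(plan.force_hits) > plan.foreground_hits:
                    raise InfeasibleConfigError(
                        f"pathway {plan.name!r}: more forced hits than foreground_hits"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pathway_plan"] = [dataclasses.asdict(p) for p in self.pathway_plan]
        d["multiplicity_probs"] = {str(k): v for k, v in self.multiplicity_probs.items()}
        return d


def published_example_config(seed: int = 0) -> SyntheticConfig:
    """The bundled default configuration.

    Reproduces every printed cardinality of the analysis this package
    re-implements: three studies pooling to 419 up / 301 down / 716 total
    disease genes, 56 drug homologs in the universe splitting 41 up / 16
    down, and a pathway collection whose planted counts give point
    probabilities 0.041 (MAPK-like and focal-adhesion-like, 3 of 9),
    0.007 (NK-cytotoxicity-like, 3 of 5) and 0.02 (3 of 7, three pathways),
    plus a large metabolic-like pathway and null decoys.
    """
    plan = (
        PathwayPlan("MAPK_signaling_like", 9, 3, 180, ("BRAF", "PAK1", "PRKCA")),
        PathwayPlan("Metabolic_like", 36, 6, 900),
        PathwayPlan("Focal_adhesion_like", 9, 3, 190),
        PathwayPlan("ErbB_signaling_like", 7, 3, 80),
        PathwayPlan("Arginine_proline_like", 7, 3, 45),
        PathwayPlan("NK_cytotoxicity_like", 5, 3, 130),
        PathwayPlan("Vascular_smooth_muscle_like", 7, 3, 110),
        PathwayPlan("null_pathway_01", 20, None, 60),
        PathwayPlan("null_pathway_02", 12, None, 40),
        PathwayPlan("null_pathway_03", 30, None, 150),
    )
    return SyntheticConfig(
        pathway_plan=plan, inject_symbols=("BRAF", "PAK1", "PRKCA"), seed=seed
    )


def _disease_tokens(n: int) -> list[str]:
    return [f"{DISEASE_PREFIX}{i:05d}" for i in range(n)]


def generate_disease_signatures(
    config: SyntheticConfig, rng: random.Random | None = None
) -> list[DirectionalSignature]:
    """Generate study signatures that pool to the exact configured sizes.

    The universe is partitioned into both-direction, up-only and down-only
    genes; each (gene, direction) claim is then assigned to one study. A
    gene with conflicting directions goes up in one study and down in a
    different one where possible, emulating inter-study disagreement.
    Deterministic given the config seed.
    """
    config.validate()
    rng = rng or random.Random(config.seed)
    tokens = _disease_tokens(config.pooled_universe)
    rng.shuffle(tokens)
    c = config.direction_conflicts
    both = tokens[:c]
    up_only = tokens[c : config.pooled_up]
    down_only = tokens[config.pooled_up : config.pooled_universe]

    up_assign: dict[int, set[str]] = {i: set() for i in range(config.n_studies)}
    down_assign: dict[int, set[str]] = {i: set() for i in range(config.n_studies)}
    for g in up_only:
        up_assign[rng.randrange(config.n_studies)].add(g)
    for g in down_only:
        down_assign[rng.randrange(config.n_studies)].add(g)
    for g in both:
        i = rng.randrange(config.n_studies)
        choices = [j for j in range(config.n_studies) if j != i] or [i]
        up_assign[i].add(g)
        down_assign[rng.choice(choices)].add(g)

    species = config.target_species
    return [
        DirectionalSignature(
            study_label=f"study{i + 1}",
            up=GeneSet(f"study{i + 1}:up", species, frozenset(up_assign[i])),
            down=GeneSet(f"study{i + 1}:down", species, frozenset(down_assign[i])),
        )
        for i in range(config.n_studies)
    ]


def generate_drug_bundle(
    config: SyntheticConfig,
    pooled: DirectionalSignature,
    rng: random.Random | None = None,
) -> tuple[GeneSet, HomologyMap]:
    """Generate the drug-source gene set and its homology table.

    Picks the planted overlap genes from the pooled partition (inclusion-
    exclusion fixes how many come from up∩down), samples a targets-per-
    source multiplicity for every drug-source gene from the configured
    distribution, and routes each required human target through one mapping
    slot; leftover slots map to fresh out-of-universe symbols. Running
    ``map_to_human`` followed by ``venn_counts`` on the output reproduces
    the planted counts exactly.
    """
    config.validate()
    rng = rng or random.Random(config.seed + 1)
    both = sorted(pooled.up.members & pooled.down.members)
    up_only = sorted(pooled.up.members - pooled.down.members)
    down_only = sorted(pooled.down.members - pooled.up.members)
    b = config.drug_in_both
    required = (
        rng.sample(both, b)
        + rng.sample(up_only, config.planted_up_overlap - b)
        + rng.sample(down_only, config.planted_down_overlap - b)
    )

    sources = [f"{DRUG_PREFIX}{i:04d}" for i in range(config.drug_source_size)]
    mults, weights = zip(*sorted(config.multiplicity_probs.items()))
    multiplicity = {s: rng.choices(mults, weights=weights)[0] for s in sources}
    slots = [s for s in sources for _ in range(multiplicity[s])]
    if len(slots) < len(required):
        raise InfeasibleConfigError(
            f"homology table has only {len(slots)} mapping slots but "
            f"{len(required)} planted targets are required; increase "
            "drug_source_size or the multiplicity distribution"
        )
    rng.shuffle(slots)
    pairs: set[tuple[str, str]] = set()
    for slot, target in zip(slots, required):
        pairs.add((slot, target))
    for j, slot in enumerate(slots[len(required) :]):
        pairs.add((slot, f"{EXTRA_TARGET_PREFIX}{j:05d}"))

    drug = GeneSet("drug_downregulated", config.source_species, frozenset(sources))
    homology = HomologyMap(
        config.source_species, config.target_species, frozenset(pairs)
    )
    return drug, homology


def generate_pathway_collection(
    config: SyntheticConfig,
    background: GeneSet,
    foreground: GeneSet,
    rng: random.Random | None = None,
) -> PathwayCollection:
    """Build a GMT-ready collection with exact planted (K, k) per pathway.

    Each planted pathway takes exactly ``foreground_hits`` genes from the
    foreground (forced symbols first) and ``background_hits -
    foreground_hits`` from the background outside the foreground, then pads
    with decoy genes outside the background. Null pathways draw their
    background members uniformly instead, leaving the foreground hit count
    to chance.
    """
    config.validate()
    rng = rng or random.Random(config.seed + 2)
    bg_sorted = sorted(background.members)
    fg_sorted = sorted(foreground.members)
    bg_not_fg = sorted(background.members - foreground.members)
    pathways: dict[str, GeneSet] = {}
    decoy_counter = 0
    for plan in config.pathway_plan:
        if plan.foreground_hits is None:
            in_bg = rng.sample(bg_sorted, plan.background_hits)
        else:
            missing = [g for g in plan.force_hits if g not in foreground.members]
            if missing:
                raise InfeasibleConfigError(
                    f"pathway {plan.name!r}: forced hits absent from the "
                    f"foreground: {', '.join(missing)}"
                )
            pool = [g for g in fg_sorted if g not in plan.force_hits]
            fg_hits = list(plan.force_hits) + rng.sample(
                pool, plan.foreground_hits - len(plan.force_hits)
            )
            if plan.background_hits - plan.foreground_hits > len(bg_not_fg):
                raise InfeasibleConfigError(
                    f"pathway {plan.name!r}: not enough background-only genes "
                    f"for {plan.background_hits - plan.foreground_hits} non-hits"
                )
            bg_rest = rng.sample(bg_not_fg, plan.background_hits - plan.foreground_hits)
            in_bg = fg_hits + bg_rest
        decoys = [
            f"{DECOY_PREFIX}{decoy_counter + i:05d}" for i in range(plan.decoy_size)
        ]
        decoy_counter += plan.decoy_size
        pathways[plan.name] = GeneSet(
            plan.name, config.target_species, frozenset(in_bg) | frozenset(decoys)
        )
    return PathwayCollection("synthetic_pathways", pathways)


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete generated input bundle plus its derived intermediates."""

    config: SyntheticConfig
    signatures: list[DirectionalSignature]
    drug: GeneSet
    homology: HomologyMap
    collection: PathwayCollection
    pooled: DirectionalSignature
    drug_mapped: GeneSet
    commonality: GeneSet


def _rename_members(members: frozenset[str], renames: dict[str, str]) -> frozenset[str]:
    return frozenset(renames.get(g, g) for g in members)


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """Generate signatures, drug bundle and pathways as one coherent fixture.

    If ``inject_symbols`` is set, that many planted commonality genes
    (preferring ones outside up∩down) are renamed to the real symbols across
    every generated structure before pathways are planted, so forced pathway
    hits can reference them.
    """
    config.validate()
    rng = random.Random(config.seed)
    signatures = generate_disease_signatures(config, rng)
    pooled = pool_signatures(signatures)
    drug, homology = generate_drug_bundle(config, pooled, rng)
    mapped, _ = map_to_human(drug, homology)
    commonality_members = pooled.up.members & mapped.members

    if config.inject_symbols:
        clean = sorted(commonality_members - pooled.down.members)
        if len(config.inject_symbols) > len(clean):
            raise InfeasibleConfigError(
                "not enough single-direction commonality genes to carry the "
                f"{len(config.inject_symbols)} injected symbols"
            )
        renames = dict(zip(clean, config.inject_symbols))
        signatures = [
            DirectionalSignature(
                s.study_label,
                GeneSet(s.up.label, s.up.species, _rename_members(s.up.members, renames)),
                GeneSet(s.down.label, s.down.species, _rename_members(s.down.members, renames)),
            )
            for s in signatures
        ]
        homology = HomologyMap(
            homology.source_species,
            homology.target_species,
            frozenset((s, renames.get(t, t)) for s, t in homology.pairs),
        )
        pooled = pool_signatures(signatures)
        mapped, _ = map_to_human(drug, homology)
        commonality_members = pooled.up.members & mapped.members

    commonality = GeneSet("commonality", config.target_species, commonality_members)
    collection = generate_pathway_collection(config, pooled.up, commonality, rng)
    return SyntheticBundle(
        config=config,
        signatures=signatures,
        drug=drug,
        homology=homology,
        collection=collection,
        pooled=pooled,
        drug_mapped=mapped,
        commonality=commonality,
    )


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, str]:
    """Write a bundle as the plain-text files the pipeline consumes.

    Emits the drug gene list, per-study up/down lists, the homology TSV,
    the pathway GMT, a ready-to-run pipeline config (YAML) and a manifest
    recording the generating configuration. All files are sorted, so
    identical config+seed yields byte-identical output. Returns a mapping
    of logical names to written paths.
    """
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _write_list(name: str, genes) -> str:
        p = out / name
        p.write_text("".join(f"{g}\n" for g in sorted(genes)), encoding="utf-8")
        paths[name] = str(p)
        return str(p)

    _write_list("drug_genes.txt", bundle.drug.members)
    signature_entries = []
    for sig in bundle.signatures:
        up_path = _write_list(f"{sig.study_label}_up.txt", sig.up.members)
        down_path = _write_list(f"{sig.study_label}_down.txt", sig.down.members)
        signature_entries.append(
            {"label": sig.study_label, "up": up_path, "down": down_path}
        )

    homology_path = out / "homology.tsv"
    with open(homology_path, "wt", encoding="utf-8") as fh:
        fh.write("#source\ttarget\n")
        for s, t in sorted(bundle.homology.pairs):
            fh.write(f"{s}\t{t}\n")
    paths["homology.tsv"] = str(homology_path)

    gmt_path = out / "pathways.gmt"
    write_gmt(bundle.collection, gmt_path)
    paths["pathways.gmt"] = str(gmt_path)

    pipeline_config = {
        "drug_list": paths["drug_genes.txt"],
        "homology_table": paths["homology.tsv"],
        "signatures": signature_entries,
        "pathways": paths["pathways.gmt"],
        "source_species": bundle.config.source_species,
        "target_species": bundle.config.target_species,
        "alpha": 0.05,
        "convention": "tail",
        "min_hits": 3,
        "bh": False,
        "out_dir": str(out / "results"),
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(pipeline_config, sort_keys=True))
    paths["config.yaml"] = str(config_path)

    manifest = {"seed": bundle.config.seed, "config": bundle.config.to_dict(), "files": paths}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest.json"] = str(manifest_path)
    return paths
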