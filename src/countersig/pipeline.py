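"""End-to-end orchestration: files in, overlap report + pathway scan out.

Stages: load and normalise inputs → map the drug set to the disease species
→ pool the study signatures → Venn counts → directional overlap tests →
extract the counteracting commonality genes (drug-hit ∩ disease-up) → scan
the pathway collection with the commonality set as foreground and the
disease-up set as background. Every stage logs its in/out counts, inputs
are digested for provenance, and the report stores the raw (N, K, n, k)
counts next to every p-value so each number can be recomputed from the
report alone.

Malformed or missing inputs fail fast with the offending path — silent
identifier loss is the classic enrichment-analysis bug.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import yaml

from .enrichment import (
    EnrichmentRecord,
    read_gmt,
    scan_pathways,
    scan_to_frame,
)
from .errors import MalformedInputError
from .genesets import (
    DirectionalSignature,
    GeneSet,
    VennCounts,
    pool_signatures,
    read_gene_list,
    venn_counts,
)
from .homology import MappingReport, load_homology_table, map_to_human
from .overlap_stats import (
    Call,
    OverlapResult,
    TSV_HEADER,
    directional_overlap_test,
    result_tsv_row,
)

__all__ = ["PipelineConfig", "AnalysisReport", "extract_commonality", "run_pipeline"]

try:
    __version__ = version("countersig")
except PackageNotFoundError:  # pragma: no cover - not installed
    __version__ = "unknown"


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    ``signatures`` is a list of ``{"label": ..., "up": path, "down": path}``
    mappings, one per disease study. ``convention`` selects which p-value
    drives pathway significance calls: ``tail`` (sound one-sided inference,
    the default) or ``point`` (legacy spreadsheet compatibility).
    """

    drug_list: str
    homology_table: str
    signatures: tuple[dict, ...]
    pathways: str
    out_dir: str
    alpha: float = 0.05
    convention: str = "tail"
    min_hits: int = 3
    bh: bool = False
    source_species: str = "drosophila"
    target_species: str = "human"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.convention not in ("tail", "point"):
            raise ValueError(f"convention must be 'tail' or 'point', got {self.convention!r}")
        object.__setattr__(self, "signatures", tuple(dict(s) for s in self.signatures))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        import dataclasses

        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MalformedInputError(
                f"unknown pipeline config keys in {path}: {', '.join(sorted(unknown))}"
            )
        return cls(**raw)

    def input_paths(self) -> dict[str, str]:
        paths = {"drug_list": self.drug_list, "homology_table": self.homology_table,
                 "pathways": self.pathways}
        for sig in self.signatures:
            paths[f"signature:{sig['label']}:up"] = sig["up"]
            paths[f"signature:{sig['label']}:down"] = sig["down"]
        return paths


@dataclass
class AnalysisReport:
    """Everything one run computed, with provenance.

    The commonality list length always equals the up-test's k, and every
    stored p-value is recomputable from the (N, K, n, k) stored beside it.
    """

    mapping: MappingReport
    venn: VennCounts
    up_test: OverlapResult
    down_test: OverlapResult
    commonality: tuple[str, ...]
    enrichment: list[EnrichmentRecord]
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "mapping": self.mapping.to_dict(),
            "venn": {
                "universe": self.venn.universe_size,
                "up": self.venn.up_size,
                "down": self.venn.down_size,
                "drug_in_universe": self.venn.drug_in_universe,
                "drug_in_up": self.venn.drug_in_up,
                "drug_in_down": self.venn.drug_in_down,
                "drug_in_both": self.venn.drug_in_both,
            },
            "overlap": {
                "up_test": self.up_test.to_dict(),
                "down_test": self.down_test.to_dict(),
            },
            "commonality_genes": list(self.commonality),
            "enrichment": [r.to_dict() for r in self.enrichment],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def extract_commonality(pooled: DirectionalSignature, drug: GeneSet) -> GeneSet:
    """The counteracting commonality genes: disease-up ∩ drug, deterministic.

    These are the candidate therapeutic mediators — genes the disease pushes
    up and the drug (via homologs) pushes down. Iteration over the returned
    set is sorted.
    """
    pooled.up.require_same_species(drug)
    return GeneSet(
        "counteracting_commonality",
        drug.species,
        pooled.up.members & drug.members,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, log_timestamps: bool = False) -> AnalysisReport:
    """Execute the full analysis and write all outputs to ``config.out_dir``.

    Writes ``report.json``, ``overlap.tsv``, ``enrichment.tsv``,
    ``commonality_genes.txt`` and ``run.log``. Re-running on identical
    inputs yields byte-identical outputs (timestamps are off by default in
    the log). If the drug set maps to nothing, the report is still produced
    with neutral calls and a prominent warning in the log.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger = logging.getLogger(f"countersig.pipeline.{id(config)}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    logger.propagate = False
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    fmt = "%(asctime)s %(levelname)s %(message)s" if log_timestamps else "%(levelname)s %(message)s"
    handler.setFormatter(logging.Formatter(fmt))
    logger.addHandler(handler)

    try:
        for name, path in config.input_paths().items():
            if not Path(path).exists():
                raise FileNotFoundError(f"input {name} not found: {path}")

        drug = read_gene_list(config.drug_list, "drug", config.source_species)
        logger.info("loaded drug list: %d genes", len(drug))
        with open(config.homology_table, "rt", encoding="utf-8") as fh:
            homology = load_homology_table(
                fh, config.source_species, config.target_species
            )
        logger.info("loaded homology table: %d pairs, %d sources",
                    homology.n_pairs, len(homology.sources))

        signatures = []
        for sig in config.signatures:
            up = read_gene_list(sig["up"], f"{sig['label']}:up", config.target_species)
            down = read_gene_list(sig["down"], f"{sig['label']}:down", config.target_species)
            signatures.append(DirectionalSignature(sig["label"], up, down))
            logger.info("loaded signature %s: %d up, %d down",
                        sig["label"], len(up), len(down))
        collection = read_gmt(config.pathways)
        logger.info("loaded pathway collection: %d pathways", len(collection))

        mapped, mapping_report = map_to_human(drug, homology)
        logger.info(
            "homolog mapping: %d/%d sources mapped -> %d %s genes",
            mapping_report.n_mapped_source, mapping_report.n_source,
            mapping_report.n_target_genes, config.target_species,
        )
        if not mapped.members:
            logger.warning(
                "DRUG SET MAPS TO NOTHING: all overlap tests will be neutral"
            )

        pooled = pool_signatures(signatures)
        logger.info("pooled signature: %d up, %d down, %d universe",
                    len(pooled.up), len(pooled.down), len(pooled.universe))
        venn = venn_counts(pooled, mapped)
        logger.info("venn counts: %s", venn.as_tuple())

        up_test, down_test = directional_overlap_test(pooled, mapped, config.alpha)
        logger.info("up-test: k=%d, p_upper=%.4g, call=%s",
                    up_test.counts.k, up_test.p_upper, up_test.call.value)
        logger.info("down-test: k=%d, p_lower=%.4g, call=%s",
                    down_test.counts.k, down_test.p_lower, down_test.call.value)

        commonality = extract_commonality(pooled, mapped)
        logger.info("commonality genes: %d", len(commonality))

        records = scan_pathways(
            commonality,
            pooled.up,
            collection,
            alpha=config.alpha,
            min_hits=config.min_hits,
            convention=config.convention,  # type: ignore[arg-type]
            bh=config.bh,
        )
        n_sig = sum(r.significant for r in records)
        logger.info("pathway scan: %d pathways, %d significant at alpha=%.3g (%s)",
                    len(records), n_sig, config.alpha, config.convention)

        provenance = {
            "tool": "countersig",
            "version": __version__,
            "parameters": {
                "alpha": config.alpha,
                "convention": config.convention,
                "min_hits": config.min_hits,
                "bh": config.bh,
                "source_species": config.source_species,
                "target_species": config.target_species,
            },
            "inputs": {
                name: {"path": path, "sha256": _sha256(path)}
                for name, path in config.input_paths().items()
            },
        }
        report = AnalysisReport(
            mapping=mapping_report,
            venn=venn,
            up_test=up_test,
            down_test=down_test,
            commonality=tuple(sorted(commonality.members)),
            enrichment=records,
            provenance=provenance,
        )

        (out_dir / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        (out_dir / "overlap.tsv").write_text(
            TSV_HEADER + "\n"
            + result_tsv_row("up_enrichment", up_test) + "\n"
            + result_tsv_row("down_depletion", down_test) + "\n",
            encoding="utf-8",
        )
        scan_to_frame(records).to_csv(out_dir / "enrichment.tsv", sep="\t", index=False)
        (out_dir / "commonality_genes.txt").write_text(
            "".join(f"{g}\n" for g in report.commonality), encoding="utf-8"
        )
        logger.info("wrote outputs to %s", out_dir)
        return report
    finally:
        handler.close()
        logger.removeHandler(handler)
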