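"""Exact-planting guarantees of the synthetic bundle generator."""

import random

import pytest

from countersig import (
    InfeasibleConfigError,
    PathwayPlan,
    SyntheticConfig,
    generate_bundle,
    generate_disease_signatures,
    generate_drug_bundle,
    generate_pathway_collection,
    map_to_human,
    published_example_config,
    pathway_enrichment,
    pool_signatures,
    venn_counts,
    write_bundle,
)


class TestGenerateDiseaseSignatures:
    def test_published_pool_targets_hit_exactly(self):
        sigs = generate_disease_signatures(SyntheticConfig(seed=4))
        pooled = pool_signatures(sigs)
        assert (len(pooled.up), len(pooled.down), len(pooled.universe)) == (419, 301, 716)

    def test_single_study_no_conflicts(self):
        config = SyntheticConfig(
            n_studies=1, pooled_up=30, pooled_down=20, pooled_universe=50,
            planted_universe_overlap=0, planted_up_overlap=0, planted_down_overlap=0,
        )
        sigs = generate_disease_signatures(config)
        assert len(sigs) == 1
        pooled = pool_signatures(sigs)
        assert pooled.up.members == sigs[0].up.members
        assert pooled.down.members == sigs[0].down.members

    def test_two_seeds_same_cardinalities_different_assignment(self):
        a = pool_signatures(generate_disease_signatures(SyntheticConfig(seed=1)))
        b = pool_signatures(generate_disease_signatures(SyntheticConfig(seed=2)))
        assert len(a.up) == len(b.up) and len(a.universe) == len(b.universe)
        assert a.up.members != b.up.members  # different gene identities per seed

    def test_infeasible_universe_rejected(self):
        with pytest.raises(InfeasibleConfigError, match="universe"):
            SyntheticConfig(pooled_up=10, pooled_down=10, pooled_universe=30).validate()


class TestGenerateDrugBundle:
    def test_published_planting_round_trip(self):
        config = SyntheticConfig(seed=9)
        pooled = pool_signatures(generate_disease_signatures(config))
        drug, homology = generate_drug_bundle(config, pooled)
        mapped, _ = map_to_human(drug, homology)
        assert venn_counts(pooled, mapped).as_tuple() == (716, 419, 301, 56, 41, 16)

    def test_all_zero_planting_gives_disjoint_drug(self):
        config = SyntheticConfig(
            seed=9,
            planted_universe_overlap=0,
            planted_up_overlap=0,
            planted_down_overlap=0,
        )
        pooled = pool_signatures(generate_disease_signatures(config))
        drug, homology = generate_drug_bundle(config, pooled)
        mapped, _ = map_to_human(drug, homology)
        assert venn_counts(pooled, mapped).as_tuple()[3:] == (0, 0, 0)

    def test_random_feasible_plantings_reproduced_exactly(self):
        rng = random.Random(123)
        for trial in range(100):
            up = rng.randrange(20, 60)
            down = rng.randrange(20, 60)
            conflicts = rng.randrange(0, min(up, down) // 2)
            universe = up + down - conflicts
            b = rng.randrange(0, conflicts + 1)
            up_hit = rng.randrange(b, up - conflicts + b + 1)
            down_hit = rng.randrange(b, down - conflicts + b + 1)
            config = SyntheticConfig(
                n_studies=rng.randrange(1, 4),
                pooled_up=up,
                pooled_down=down,
                pooled_universe=universe,
                drug_source_size=150,
                planted_universe_overlap=up_hit + down_hit - b,
                planted_up_overlap=up_hit,
                planted_down_overlap=down_hit,
                seed=trial,
            )
            pooled = pool_signatures(generate_disease_signatures(config))
            drug, homology = generate_drug_bundle(config, pooled)
            mapped, _ = map_to_human(drug, homology)
            assert venn_counts(pooled, mapped).as_tuple() == (
                universe, up, down, up_hit + down_hit - b, up_hit, down_hit,
            )

    def test_infeasible_planting_explains_constraint(self):
        config = SyntheticConfig(
            pooled_up=10, pooled_down=10, pooled_universe=20,
            planted_universe_overlap=15, planted_up_overlap=15, planted_down_overlap=0,
        )
        with pytest.raises(InfeasibleConfigError, match="up-only"):
            config.validate()

    def test_multiplicity_histogram_tracks_distribution(self):
        config = SyntheticConfig(
            seed=5, drug_source_size=600,
            multiplicity_probs={0: 0.3, 1: 0.5, 2: 0.2},
        )
        pooled = pool_signatures(generate_disease_signatures(config))
        drug, homology = generate_drug_bundle(config, pooled)
        _, report = map_to_human(drug, homology)
        hist = report.multiplicity_histogram
        total = sum(hist.values())
        assert total == 600
        for mult, prob in config.multiplicity_probs.items():
            observed = hist.get(mult, 0) / total
            assert abs(observed - prob) < 4 * (prob * (1 - prob) / total) ** 0.5 + 0.01


class TestGeneratePathwayCollection:
    def test_planted_counts_exact_and_p_values(self, planted_bundle):
        fg, bg = planted_bundle.commonality, planted_bundle.pooled.up
        plan_by_name = {p.name: p for p in planted_bundle.config.pathway_plan}
        for name, pathway in planted_bundle.collection:
            plan = plan_by_name[name]
            rec = pathway_enrichment(fg, bg, pathway, convention="point")
            assert rec.background_hits == plan.background_hits
            if plan.foreground_hits is not None:
                assert rec.foreground_hits == plan.foreground_hits

    def test_null_plan_pathway_has_exact_background_hits(self, planted_bundle):
        rec = pathway_enrichment(
            planted_bundle.commonality,
            planted_bundle.pooled.up,
            planted_bundle.collection["null_pathway_01"],
        )
        assert rec.background_hits == 20

    def test_null_hit_rate_near_analytic_expectation(self):
        # k for a uniformly drawn K-subset is hypergeometric: E[k] = nK/N
        config = SyntheticConfig(
            pathway_plan=tuple(
                PathwayPlan(f"null{i}", 30, None, decoy_size=5) for i in range(40)
            ),
            seed=6,
        )
        bundle = generate_bundle(config)
        ks = [
            pathway_enrichment(
                bundle.commonality, bundle.pooled.up, pathway
            ).foreground_hits
            for _, pathway in bundle.collection
        ]
        expected = 41 * 30 / 419
        mean = sum(ks) / len(ks)
        assert abs(mean - expected) < 1.0  # SD of the mean is ~0.25

    def test_forced_hits_must_exist(self, planted_bundle):
        config = SyntheticConfig(
            pathway_plan=(PathwayPlan("p", 5, 3, 5, ("NOT_A_GENE",)),), seed=0
        )
        with pytest.raises(InfeasibleConfigError, match="NOT_A_GENE"):
            generate_pathway_collection(
                config, planted_bundle.pooled.up, planted_bundle.commonality
            )


class TestBundleDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        for sub in ("a", "b"):
            write_bundle(generate_bundle(published_example_config(seed=42)), tmp_path / sub)
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        assert names == sorted(p.name for p in (tmp_path / "b").iterdir())
        for name in names:
            a = (tmp_path / "a" / name).read_bytes()
            b = (tmp_path / "b" / name).read_bytes()
            if name == "config.yaml" or name == "manifest.json":
                # paths differ between directories; compare structure-free lines
                assert len(a.splitlines()) == len(b.splitlines())
            else:
                assert a == b

    def test_injected_symbols_present_everywhere(self, planted_bundle):
        for symbol in ("BRAF", "PAK1", "PRKCA"):
            assert symbol in planted_bundle.pooled.up.members
            assert symbol in planted_bundle.commonality.members
            assert symbol in planted_bundle.collection["MAPK_signaling_like"].members
            assert any(t == symbol for _, t in planted_bundle.homology.pairs)
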