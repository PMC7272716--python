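"""Generator tests: determinism, planted-signal fidelity, forced counts."""

import numpy as np
import pandas as pd
import pytest

from lncnet import cerna, enrichment, simulate, survival
from lncnet.coexpression import pearson_r
from lncnet.simulate import (
    PlantedHub,
    SimulationConfig,
    SurvivalSimConfig,
    generate_expression,
    generate_gene_sets,
    generate_interactions,
    generate_survival,
)


class TestExpressionGenerator:
    def test_same_seed_identical_output(self):
        cfg = SimulationConfig(
            n_genes=50, planted_de=((4, 4.0),), planted_hubs=(PlantedHub(size=3),),
            seed=5,
        )
        m1, t1 = generate_expression(cfg)
        m2, t2 = generate_expression(cfg)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        assert t1.true_fc == t2.true_fc and t1.hub_edges == t2.hub_edges

    def test_null_model_plants_nothing(self):
        _, truth = generate_expression(SimulationConfig(n_genes=30, seed=0))
        assert truth.true_fc == {} and truth.hubs == []

    def test_shape_and_design(self):
        cfg = SimulationConfig(n_genes=40, frac_lncrna=0.25, n_per_group=3, seed=1)
        matrix, _ = generate_expression(cfg)
        assert matrix.values.shape == (40, 6)
        assert len(matrix.samples_in("case")) == 3
        assert len(matrix.genes_of("lncRNA")) == 10

    def test_noiseless_hub_with_target_one_gives_exact_unit_correlation(self):
        cfg = SimulationConfig(
            n_genes=30,
            planted_hubs=(PlantedHub(size=5, target_r=1.0),),
            noise_sd=0.0,
            seed=3,
        )
        matrix, truth = generate_expression(cfg)
        hub = truth.hubs[0]
        for _, partner in truth.hub_edges:
            r = pearson_r(matrix.values.loc[hub], matrix.values.loc[partner])
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_planted_fc_fidelity_over_replicates(self):
        # mean realized log2 group difference must match log2 of the planted FC
        diffs = []
        for seed in range(40):
            cfg = SimulationConfig(
                n_genes=20, planted_de=((1, 4.0),), noise_sd=0.25, seed=seed
            )
            matrix, truth = generate_expression(cfg)
            (gene,) = truth.true_fc
            case = matrix.values.loc[gene, matrix.samples_in("case")]
            ctrl = matrix.values.loc[gene, matrix.samples_in("control")]
            diffs.append(case.mean() - ctrl.mean())
        assert np.mean(diffs) == pytest.approx(2.0, abs=0.1)

    def test_hub_correlation_approaches_target_at_low_noise(self):
        rs = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_genes=40,
                planted_hubs=(PlantedHub(size=6, target_r=0.95),),
                noise_sd=0.01,
                seed=seed,
            )
            matrix, truth = generate_expression(cfg)
            hub = truth.hubs[0]
            rs += [
                pearson_r(matrix.values.loc[hub], matrix.values.loc[m])
                for _, m in truth.hub_edges
            ]
        assert np.mean(rs) == pytest.approx(0.95, abs=0.03)

    def test_negative_partner_fc_gives_negative_correlation(self):
        cfg = SimulationConfig(
            n_genes=30,
            planted_hubs=(PlantedHub(size=3, target_r=0.999, partner_fc=-8.0),),
            noise_sd=0.1,
            seed=2,
        )
        matrix, truth = generate_expression(cfg)
        hub = truth.hubs[0]
        for _, partner in truth.hub_edges:
            assert pearson_r(matrix.values.loc[hub], matrix.values.loc[partner]) < -0.9

    def test_oversized_module_raises(self):
        cfg = SimulationConfig(
            n_genes=10, frac_lncrna=0.5, planted_hubs=(PlantedHub(size=50),)
        )
        with pytest.raises(ValueError, match="mRNA"):
            generate_expression(cfg)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frac_lncrna": 1.5},
            {"n_genes": 0},
            {"planted_de": ((3, 1.5),)},  # |fc| < 2 allowed, but |fc| < 1 is not
        ],
    )
    def test_config_validation(self, kwargs):
        if kwargs.get("planted_de"):
            kwargs = {"planted_de": ((3, 0.5),)}
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSurvivalGenerator:
    def test_determinism(self):
        cfg = SurvivalSimConfig(n_patients=50, seed=9)
        pd.testing.assert_frame_equal(generate_survival(cfg), generate_survival(cfg))

    def test_exact_zero_expression_count(self):
        cfg = SurvivalSimConfig(n_patients=100, frac_zero_expression=0.1, seed=4)
        cohort = generate_survival(cfg)
        assert int((cohort["expression"] == 0).sum()) == 10

    def test_exact_short_followup_count(self):
        cfg = SurvivalSimConfig(
            n_patients=100, baseline_hazard=1e-7, frac_short_followup=0.07, seed=4
        )
        cohort = generate_survival(cfg)
        # hazard low enough that natural sub-30-day times cannot occur here
        assert int((cohort["time"] < 30).sum()) == 7

    def test_censor_rate_close_to_nominal(self):
        cfg = SurvivalSimConfig(n_patients=2000, censor_rate=0.3, seed=6)
        cohort = generate_survival(cfg)
        assert (1 - cohort["event"]).mean() == pytest.approx(0.3, abs=0.04)

    def test_null_hr_gives_nominal_logrank_rejection(self):
        rejections = 0
        reps = 200
        for seed in range(reps):
            cohort = generate_survival(
                SurvivalSimConfig(n_patients=80, true_hr=1.0, censor_rate=0.1,
                                  seed=seed)
            )
            res = survival.analyze_cohort(cohort, min_time=0.0)
            rejections += res.p < 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_hr3_recovery_within_20pct(self):
        hrs = [
            survival.analyze_cohort(
                generate_survival(
                    SurvivalSimConfig(n_patients=500, true_hr=3.0, censor_rate=0.0,
                                      seed=seed)
                ),
                min_time=0.0,
            ).hr
            for seed in range(8)
        ]
        assert abs(np.mean(hrs) - 3.0) / 3.0 <= 0.20

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SurvivalSimConfig(true_hr=0.0)
        with pytest.raises(ValueError):
            SurvivalSimConfig(censor_rate=1.5)


class TestGeneSets:
    def test_planted_term_attains_minimum_p(self):
        universe = [f"G{i}" for i in range(500)]
        study = universe[:25]
        coll = generate_gene_sets(
            universe, n_terms=30, planted_term_genes=study, seed=0
        )
        res = enrichment.enrich(study, coll, universe)
        assert res.iloc[0]["term_id"].endswith("PLANTED")
        assert res.iloc[0]["p"] == res["p"].min()

    def test_determinism_and_empty(self):
        universe = [f"G{i}" for i in range(100)]
        c1 = generate_gene_sets(universe, n_terms=5, seed=3)
        c2 = generate_gene_sets(universe, n_terms=5, seed=3)
        assert {t: c1[t].genes for t in c1} == {t: c2[t].genes for t in c2}
        empty = generate_gene_sets(universe, n_terms=0, seed=3)
        assert len(empty) == 0
        assert enrichment.enrich(universe[:5], empty, universe).empty

    def test_planted_gene_outside_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            generate_gene_sets(["A", "B"], n_terms=1, term_size_range=(1, 2),
                               planted_term_genes=["Z"], seed=0)


class TestInteractions:
    LNC = ["LNCX"]
    MIRNAS = [f"miR-{i}" for i in range(5)]
    MRNAS = [f"M{i}" for i in range(4)]

    def test_all_planted_passing_survive_filters(self):
        pairs1 = [(self.LNC[0], m) for m in self.MIRNAS]
        pairs2 = [(m, t) for m in self.MIRNAS for t in self.MRNAS]
        t1, t2 = generate_interactions(
            self.LNC, self.MIRNAS, self.MRNAS,
            planted_lnc_mirna=pairs1, planted_mirna_mrna=pairs2, seed=0,
        )
        assert len(cerna.filter_lnc_mirna(t1)) == len(t1)
        assert len(cerna.filter_mirna_mrna(t2)) == len(t2)

    def test_all_failing_gives_empty_network(self):
        t1, t2 = generate_interactions(self.LNC, self.MIRNAS, self.MRNAS, seed=1)
        triplets, summary = cerna.assemble_cerna(
            self.LNC[0], t1, t2, hub_partners=self.MRNAS
        )
        assert triplets.empty and summary["n_mirnas"] == 0

    def test_planted_passing_mirnas_become_nodes(self):
        pairs1 = [(self.LNC[0], m) for m in self.MIRNAS]  # 5 passing miRNAs
        pairs2 = [(m, self.MRNAS[0]) for m in self.MIRNAS]
        t1, t2 = generate_interactions(
            self.LNC, self.MIRNAS, self.MRNAS,
            planted_lnc_mirna=pairs1, planted_mirna_mrna=pairs2, seed=2,
        )
        _, summary = cerna.assemble_cerna(
            self.LNC[0], t1, t2, hub_partners=self.MRNAS
        )
        assert summary["n_mirnas"] == 5

    def test_overlapping_namespaces_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            generate_interactions(["X"], ["X"], ["Y"], seed=0)
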