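import numpy as np
import pandas as pd
import pytest

from stagescreen.coexpression_screen import CorrelationRecord, pearson_r, screen_pathway
from stagescreen.data_model import ScreenConfig, StageAxis
from stagescreen.synthetic_data import (
    PlantedLink,
    SimConfig,
    SyntheticTruth,
    generate_archetypes,
    recovery_metrics,
    simulate_experiment,
    simulate_null_profiles,
)

SMALL = dict(n_tfs=80, n_background_genes=120)
LOG_CFG = ScreenConfig(correlation_scale="log2", log2_pseudocount=0.0)


class TestArchetypes:
    def test_k2_is_opposed_monotone_pair(self):
        arch = generate_archetypes(2)
        assert arch.names == ["increasing", "decreasing"]
        assert np.corrcoef(arch.shapes)[0, 1] < 0

    def test_canonical_families_present_at_k20(self):
        names = set(generate_archetypes(20).names)
        for required in ("increasing", "decreasing", "peak", "valley",
                         "high-low-high", "flat-high", "late-induction"):
            assert required in names

    def test_high_low_high_dips_interior(self):
        arch = generate_archetypes(20)
        hlh = arch.shapes[arch.names.index("high-low-high")]
        assert 0 < hlh.argmin() < len(hlh) - 1

    def test_shapes_span_axis_and_are_distinct(self):
        axis = StageAxis()
        arch = generate_archetypes(28, axis)
        assert arch.shapes.shape == (28, len(axis))
        R = np.corrcoef(arch.shapes)
        off = R[~np.eye(28, dtype=bool)]
        assert off.max() < 0.95
        assert len(set(arch.names)) == 28

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            generate_archetypes(1)


class TestSimulateExperiment:
    def test_default_catalog_matches_study_dimensions(self):
        cfg = SimConfig(seed=0, n_background_genes=50)
        sim = simulate_experiment(cfg)
        sizes = {p: len(g) for p, g in sim.catalog.pathways.items()}
        assert sizes == {"ascorbate": 46, "carotenoid": 18, "flavonoid": 14}
        assert len(sim.catalog.tf_ids) == 823
        assert len(sim.truth.links) == 50
        assert set(sim.matrices) == {"AC", "HG6-61"}
        m = sim.matrices["AC"]
        assert m.axis.stages == (7, 14, 21, 28, 35, 42, 49)

    def test_same_seed_bit_identical(self):
        a = simulate_experiment(SimConfig(seed=9, **SMALL))
        b = simulate_experiment(SimConfig(seed=9, **SMALL))
        for geno in a.matrices:
            pd.testing.assert_frame_equal(a.matrices[geno].data,
                                          b.matrices[geno].data)
        assert a.truth.links == b.truth.links
        for s, t in zip(a.metabolites, b.metabolites):
            np.testing.assert_array_equal(s.values, t.values)

    def test_different_seed_differs(self):
        a = simulate_experiment(SimConfig(seed=1, **SMALL))
        b = simulate_experiment(SimConfig(seed=2, **SMALL))
        assert not a.matrices["AC"].data.equals(b.matrices["AC"].data)

    def test_zero_noise_links_correlate_exactly(self):
        sim = simulate_experiment(SimConfig(seed=4, noise_sd=0.0, **SMALL))
        m = sim.matrices["AC"]
        for link in sim.truth.links[:10]:
            r = pearson_r(np.log2(m.data.loc[link.tf_id]),
                          np.log2(m.data.loc[link.target_id]))
            assert r == pytest.approx(float(link.sign), abs=1e-12)

    def test_second_genotype_lags_ripening_archetypes(self):
        sim = simulate_experiment(SimConfig(seed=5, noise_sd=0.0, **SMALL))
        arch = generate_archetypes(20)
        # a gene on a ripening archetype peaks later in the lagged genotype
        for gene, a_idx in sim.truth.archetype_of.items():
            if arch.ripening[a_idx] and arch.names[a_idx] == "increasing":
                ac = sim.matrices["AC"].data.loc[gene].to_numpy()
                hg = sim.matrices["HG6-61"].data.loc[gene].to_numpy()
                assert np.argmax(np.diff(np.log2(hg))) >= \
                    np.argmax(np.diff(np.log2(ac)))
                break

    def test_oversized_link_request_rejected(self):
        with pytest.raises(ValueError, match="n_links"):
            SimConfig(n_links={"ascorbate": 47})

    def test_metabolites_track_pathway_integral(self):
        sim = simulate_experiment(SimConfig(seed=6, metabolite_noise_sd=0.0,
                                            **SMALL))
        met = [s for s in sim.metabolites
               if s.metabolite_id == "AsA" and s.genotype_id == "AC"][0]
        integral = np.cumsum(
            sim.matrices["AC"].data.loc[
                sim.catalog.pathway_genes("ascorbate")].mean(axis=0).to_numpy())
        assert pearson_r(met.values, integral) == pytest.approx(1.0)
        assert (np.diff(met.values) >= 0).all()   # accumulation is monotone

    def test_negative_binomial_counts_approach_intended_rpkm(self):
        """With Poisson sampling at a deep library the recomputed RPKM
        tracks the noiseless intended profile."""
        base = SimConfig(seed=8, n_tfs=40, n_background_genes=150,
                         noise_sd=0.0)
        intended = simulate_experiment(base).matrices["AC"]
        counted = simulate_experiment(
            SimConfig(seed=8, n_tfs=40, n_background_genes=150, noise_sd=0.0,
                      count_model="negative-binomial", dispersion=0.0,
                      library_size=10_000_000)).matrices["AC"]
        a = intended.data.to_numpy().ravel()
        b = counted.data.to_numpy().ravel()
        keep = a >= 5.0
        rel_err = np.abs(b[keep] - a[keep]) / a[keep]
        assert np.median(rel_err) < 0.1
        assert pearson_r(np.log2(a[keep]), np.log2(b[keep] + 0.5)) > 0.99

    def test_nb_dispersion_adds_spread(self):
        kw = dict(n_tfs=40, n_background_genes=100, noise_sd=0.0,
                  count_model="negative-binomial", library_size=10_000_000)
        tight = simulate_experiment(SimConfig(seed=8, dispersion=0.0, **kw))
        wide = simulate_experiment(SimConfig(seed=8, dispersion=0.5, **kw))
        ref = simulate_experiment(SimConfig(seed=8, n_tfs=40,
                                            n_background_genes=100,
                                            noise_sd=0.0)).matrices["AC"]
        a = ref.data.to_numpy().ravel()
        keep = a >= 5.0
        err_tight = np.abs(tight.matrices["AC"].data.to_numpy().ravel()[keep]
                           - a[keep]) / a[keep]
        err_wide = np.abs(wide.matrices["AC"].data.to_numpy().ravel()[keep]
                          - a[keep]) / a[keep]
        assert np.median(err_wide) > np.median(err_tight)


class TestNullProfiles:
    def test_flat_profiles_have_no_temporal_structure(self):
        S, T = simulate_null_profiles(200, 50, seed=0)
        assert S.shape == (200, 7) and T.shape == (50, 7)
        # mean per-series lag-1 autocorrelation of log2 values sits at the
        # finite-sample null bias -1/(n_pairs), with no positive structure
        logs = np.log2(S.to_numpy())
        ac = [pearson_r(row[:-1], row[1:]) for row in logs]
        assert abs(np.mean(ac) + 1.0 / 6.0) < 0.1


class TestRecoveryMetrics:
    def _truth(self):
        links = [PlantedLink("TF1", "SG1", 1, 1.0),
                 PlantedLink("TF2", "SG2", -1, 1.0)]
        return SyntheticTruth(links=links, archetype_of={}, noise_sd=0.0,
                              library_sizes={}, seed=0,
                              config=SimConfig(n_links={"ascorbate": 0}))

    def _rec(self, src, tgt, sig, sign="positive"):
        return CorrelationRecord(source_id=src, target_id=tgt,
                                 genotype_id="AC", r=0.9 if sign == "positive"
                                 else -0.9, n=7, t_stat=4.0, df=5,
                                 significant=sig, sign=sign)

    def test_perfect_recovery(self):
        recs = [self._rec("TF1", "SG1", True, "positive"),
                self._rec("TF2", "SG2", True, "negative")]
        m = recovery_metrics(self._truth(), recs)
        assert (m.sensitivity, m.fdp, m.sign_accuracy) == (1.0, 0.0, 1.0)

    def test_empty_prediction(self):
        recs = [self._rec("TF1", "SG1", False)]
        m = recovery_metrics(self._truth(), recs)
        assert m.sensitivity == 0.0 and m.n_called == 0 and m.fdp == 0.0

    def test_half_recovered_no_extras(self):
        recs = [self._rec("TF1", "SG1", True, "positive"),
                self._rec("TF2", "SG2", False, "negative")]
        m = recovery_metrics(self._truth(), recs)
        assert m.sensitivity == 0.5 and m.fdp == 0.0

    def test_wrong_sign_counted(self):
        recs = [self._rec("TF2", "SG2", True, "positive")]
        m = recovery_metrics(self._truth(), recs)
        assert m.sign_accuracy == 0.0

    def test_disjoint_id_spaces_rejected(self):
        recs = [self._rec("X1", "Y1", True)]
        with pytest.raises(ValueError, match="disjoint"):
            recovery_metrics(self._truth(), recs)


class TestScreenRecoversPlantedLinks:
    def test_zero_noise_full_sensitivity(self):
        sim = simulate_experiment(SimConfig(seed=3, noise_sd=0.0, **SMALL))
        records = []
        for pathway in sim.catalog.pathways:
            records.extend(screen_pathway(sim.matrices["AC"], sim.catalog,
                                          pathway, LOG_CFG))
        m = recovery_metrics(sim.truth, records)
        assert m.sensitivity == 1.0
        assert m.sign_accuracy == 1.0
        planted = sim.truth.link_set()
        for rec in records:
            if (rec.source_id, rec.target_id) in planted \
                    and rec.excluded_reason is None:
                assert abs(rec.r) == pytest.approx(1.0, abs=1e-12)
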