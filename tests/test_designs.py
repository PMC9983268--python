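"""Benchmark-design generators: SE, clustering scenarios, CCC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from srtgen import (CCC_SCENARIOS, CCCDesign, SEDesign, assign_lr_pairs,
                    ccc_benchmark, clustering_scenarios, make_reference_fixture,
                    se_benchmark, synthetic_lr_pairs)
from srtgen.designs import apply_adjacency_boost
from srtgen.metrics import morans_i_matrix
from srtgen._rng import spawn_rng


@pytest.fixture(scope="module")
def template():
    """A 673-location STARmap-like annotated template (counts unused)."""
    data, _ = make_reference_fixture(1, 673, layout="random", n_domains=5,
                                     pattern="layered", seed=31)
    return data


class TestSEBenchmark:
    def test_truth_table_split(self, template):
        design = SEDesign(n_genes=300, n_se=100, baseline_mu=0.4, phi=0.35,
                          target_domain="domain_3", folds=(5.0, 0.2), seed=1)
        data, truth = se_benchmark(template, design)
        assert data.counts.shape == (300, 673)
        assert truth.is_se.sum() == 100
        assert (truth.direction == "up").sum() == 50
        assert (truth.direction == "down").sum() == 50

    @pytest.mark.parametrize("fold", [5.0, 10.0, 0.2, 0.1])
    def test_realized_fold_within_three_se(self, template, fold):
        design = SEDesign(n_genes=60, n_se=60, baseline_mu=0.4, phi=0.35,
                          target_domain="domain_3", folds=(fold,), seed=2)
        data, truth = se_benchmark(template, design)
        inside = data.domains == "domain_3"
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        mu_in, mu_out = 0.4 * fold, 0.4
        # pooled across the 60 SE genes; delta-method SE of the mean ratio
        m_in = data.counts[:, inside].mean()
        m_out = data.counts[:, ~inside].mean()
        var_in = (mu_in + 0.35 * mu_in ** 2) / (60 * n_in)
        var_out = (mu_out + 0.35 * mu_out ** 2) / (60 * n_out)
        ratio = m_in / m_out
        se = ratio * np.sqrt(var_in / mu_in ** 2 + var_out / mu_out ** 2)
        assert abs(ratio - fold) < 3 * se

    def test_null_design_has_no_spatial_structure(self, template):
        design = SEDesign(n_genes=400, n_se=0, baseline_mu=0.4, phi=0.35,
                          target_domain="domain_1", seed=3)
        data, truth = se_benchmark(template, design)
        assert not truth.is_se.any()
        obs = morans_i_matrix(data.counts, data.coords, "knn", 5)
        obs = obs[~np.isnan(obs)]
        # permutation-null 95% band, pooled across genes
        rng = spawn_rng(0, "null_band")
        null = []
        for g in range(60):
            x = data.counts[g].astype(float)
            if len(np.unique(x)) == 1:
                continue
            for _ in range(20):
                null.append(rng.permutation(x))
        null_i = morans_i_matrix(np.array(null), data.coords, "knn", 5)
        lo, hi = np.nanquantile(null_i, [0.025, 0.975])
        coverage = np.mean((obs >= lo) & (obs <= hi))
        assert coverage >= 0.93

    def test_se_genes_detectable_by_rank_test(self, template):
        """In/out Wilcoxon separates SE from non-SE genes (AUROC > 0.9)."""
        design = SEDesign(n_genes=250, n_se=50, baseline_mu=0.4, phi=0.35,
                          target_domain="domain_3", folds=(5.0,), seed=4)
        data, truth = se_benchmark(template, design)
        inside = data.domains == "domain_3"
        scores = np.array([
            -np.log10(max(stats.mannwhitneyu(
                data.counts[g, inside], data.counts[g, ~inside]).pvalue, 1e-300))
            for g in range(data.n_genes)])
        auroc = stats.mannwhitneyu(scores[truth.is_se], scores[~truth.is_se]).statistic \
            / (truth.is_se.sum() * (~truth.is_se).sum())
        assert auroc > 0.9

    def test_unknown_domain_rejected(self, template):
        with pytest.raises(ValueError, match="unknown domain"):
            se_benchmark(template, SEDesign(n_genes=10, n_se=5,
                                            target_domain="nope"))


@pytest.fixture(scope="module")
def ref():
    data, _ = make_reference_fixture(25, 300, layout="grid", n_domains=3,
                                     param_sampler="starmap_like", seed=8)
    return data


@pytest.fixture(scope="module")
def shape_ref():
    data, _ = make_reference_fixture(1, 400, layout="random", n_domains=1,
                                     seed=9)
    return data


@pytest.fixture(scope="module")
def small_design_kwargs():
    return dict(n_locations=1500, n_genes=120, cells_per_type=500,
                lr_pairs=synthetic_lr_pairs(60, 100, seed=5))


class TestClusteringScenarios:
    def test_scenario_i_depth_ratio(self, ref):
        total = float(ref.counts.sum())
        outs = clustering_scenarios(ref, depths=[0.5 * total, total],
                                    scenario="I", seed=2)
        t0, t1 = (o.data.counts.sum() for o in outs)
        sigma = np.sqrt(total)
        assert abs(t0 - 0.5 * total) < 3 * sigma + 0.05 * total
        assert abs(t1 - total) < 3 * sigma + 0.05 * total
        assert abs(t1 / t0 - 2.0) < 0.3

    def test_scenario_ii_per_location_depth_halves(self, ref):
        total = float(ref.counts.sum())
        outs = clustering_scenarios(ref, depths=[total],
                                    n_locations_list=[150, 300],
                                    scenario="II", seed=3)
        per_loc = [o.data.counts.sum() / o.data.n_locations for o in outs]
        # fixed total: per-location depth halves when locations double
        assert per_loc[0] / per_loc[1] == pytest.approx(2.0, rel=0.25)

    def test_scenario_iii_grid_size(self, ref):
        total = float(ref.counts.sum())
        outs = clustering_scenarios(ref, depths=[total] * 5,
                                    n_locations_list=[60, 100, 150, 200, 250, 300],
                                    scenario="III", seed=4)
        assert len(outs) == 30

    def test_requires_domains(self):
        data, _ = make_reference_fixture(5, 50, n_domains=1, seed=1)
        data.domains = None
        with pytest.raises(ValueError):
            clustering_scenarios(data, [100.0], scenario="I")


class TestCCC:
    def test_region_compositions_within_three_se(self, shape_ref):
        design = CCCDesign(n_locations=5000, scenario=1, n_genes=10,
                           cells_per_type=1500,
                           lr_pairs=synthetic_lr_pairs(10, 10, seed=1),
                           fold=1.0, seed=11)
        res = ccc_benchmark(shape_ref, design)
        comp = CCC_SCENARIOS[1]
        for r in range(4):
            mask = res.regions == f"region_{r + 1}"
            n = int(mask.sum())
            assert n == pytest.approx(1250, abs=1)      # equal-count regions
            for i in range(4):
                t = (r + i) % 4
                frac = (res.data.domains[mask] == f"type_{t + 1}").mean()
                se = np.sqrt(comp[i] * (1 - comp[i]) / n)
                assert abs(frac - comp[i]) < 3 * se

    def test_fold_one_is_preboost_identity(self, shape_ref, small_design_kwargs):
        d0 = CCCDesign(fold=1.0, seed=13, **small_design_kwargs)
        d5 = CCCDesign(fold=5.0, seed=13, **small_design_kwargs)
        r0 = ccc_benchmark(shape_ref, d0)
        r5 = ccc_benchmark(shape_ref, d5)
        assert not r0.boosted.any()
        assert r5.boosted.any()
        # the boost leaves everything except boosted entries untouched
        assert np.array_equal(r0.data.counts[~r5.boosted],
                              r5.data.counts[~r5.boosted])
        assert r0.truth.interacting.eq(False).all()
        assert r5.truth.interacting.eq(True).all()

    def test_boost_ratio_converges_to_fold(self, shape_ref, small_design_kwargs):
        # unique ligand genes: every boosted entry is boosted exactly once,
        # so the boosted/pre-boost ratio is the fold itself
        fold = 10.0
        kwargs = dict(small_design_kwargs)
        kwargs["lr_pairs"] = pd.DataFrame({
            "ligand": [f"gene_{i + 1:04d}" for i in range(30)],
            "receptor": [f"gene_{i + 31:04d}" for i in range(30)]})
        res = ccc_benchmark(shape_ref, CCCDesign(fold=fold, seed=17, **kwargs))
        base = ccc_benchmark(shape_ref, CCCDesign(fold=1.0, seed=17, **kwargs))
        boosted_vals = base.data.counts[res.boosted]
        ratio = res.data.counts[res.boosted].sum() / max(boosted_vals.sum(), 1)
        assert ratio == pytest.approx(fold, rel=0.05)

    def test_pair_assignment_conservation(self):
        pairs = synthetic_lr_pairs(930, 691, seed=3)
        assigned = assign_lr_pairs(pairs, 4, seed=3)
        counts = assigned.groupby(["type_a", "type_b"]).size()
        assert counts.sum() == 930
        assert len(assigned) == 930
        assert assigned[["ligand", "receptor"]].equals(pairs)

    def test_heterogeneous_mode_type_specific_means(self, shape_ref):
        tp = pd.DataFrame({"type": [f"type_{i}" for i in range(1, 5)],
                           "mu": [0.2, 0.5, 1.0, 3.0],
                           "phi": [0.35] * 4})
        design = CCCDesign(n_locations=1200, n_genes=60, cells_per_type=400,
                           expression_mode="heterogeneous", type_params=tp,
                           lr_pairs=synthetic_lr_pairs(10, 60, seed=2),
                           fold=1.0, seed=19)
        res = ccc_benchmark(shape_ref, design)
        means = [res.data.counts[:, res.data.domains == f"type_{t}"].mean()
                 for t in range(1, 5)]
        assert means == sorted(means)

    def test_adjacency_boost_unit(self):
        coords = np.array([[0.0, 0], [0.1, 0], [5, 5], [5.1, 5], [9, 9]])
        types = np.array(["type_1", "type_2", "type_1", "type_1", "type_1"])
        counts = np.full((1, 5), 4)
        assignments = pd.DataFrame({"ligand": ["gene_1"], "receptor": ["gene_x"],
                                    "type_a": ["type_1"], "type_b": ["type_2"]})
        out, boosted = apply_adjacency_boost(
            counts, coords, types, np.array(["gene_1"]), assignments,
            fold=2.5, n_adjacent=1)
        # only the type_1 cell adjacent to the type_2 cell is boosted; 4*2.5=10
        assert list(out[0]) == [10, 4, 4, 4, 4]
        assert boosted.sum() == 1

    def test_determinism(self, shape_ref, small_design_kwargs):
        d = CCCDesign(fold=5.0, seed=23, **small_design_kwargs)
        a = ccc_benchmark(shape_ref, d)
        b = ccc_benchmark(shape_ref, d)
        assert np.array_equal(a.data.counts, b.data.counts)
        assert np.array_equal(a.regions, b.regions)
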