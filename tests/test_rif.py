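"""Differential-connectivity scoring: selection, correlations, RIF1/RIF2."""

import numpy as np
import pandas as pd
import pytest

import musclenet as mn
from musclenet.rif import CorrelationProfiles, DEGeneSelection
from conftest import make_means, run_chain


class TestSelectDEGenes:
    def test_fraction_of_background_per_tail(self, rng):
        means = make_means({f"g{i:04d}": list(rng.normal(8, 1, 8))
                            for i in range(1000)})
        sel = mn.select_de_genes(mn.compute_diff(means), fraction=0.05)
        assert sel.n_de == 100                      # 2 x 50

    def test_pif_and_de_rules_agree_at_equal_abundance(self):
        # constant abundance makes pif a monotone transform of d
        rows = {}
        rng = np.random.default_rng(11)
        for i in range(200):
            d = rng.normal(0, 1, 4)
            ba, ch = 8 + d / 2, 8 - d / 2
            rows[f"g{i:03d}"] = list(ba) + list(ch)
        diff = mn.compute_diff(make_means(rows))
        s1 = mn.select_de_genes(diff, rule="pif-extreme", fraction=0.05)
        s2 = mn.select_de_genes(diff, rule="de-extreme", fraction=0.05)
        assert set(s1.genes) == set(s2.genes)

    def test_planted_de_genes_all_selected(self, default_run):
        sel = mn.select_de_genes(default_run["diff"], fraction=0.05)
        assert set(default_run["truth"].de_gene_names) <= set(sel.genes)

    def test_weight_vectors_consistent(self, default_run):
        diff = default_run["diff"]
        sel = mn.select_de_genes(diff)
        g = sel.genes[0]
        means = default_run["gene_means"]
        assert sel.e_bar[g] == pytest.approx(means.loc[g].mean())
        assert sel.e1[g] == pytest.approx(means.loc[g, "BA"].mean())
        assert sel.e2[g] == pytest.approx(means.loc[g, "CH"].mean())
        assert sel.d[g] == pytest.approx(diff.d.loc[g].mean())


class TestBreedCorrelationProfiles:
    def _means_from_profiles(self, profiles: dict[str, tuple[list, list]]):
        rows = {g: list(ba) + list(ch) for g, (ba, ch) in profiles.items()}
        return make_means(rows)

    def test_identical_opposite_and_constant_profiles(self):
        base = [1.0, 2.0, 3.0, 4.0]
        mirrored = [2 * np.mean(base) - x for x in base]
        means = self._means_from_profiles({
            "REG": (base, base),
            "SAME": (base, base),
            "OPP": (mirrored, base),
            "CONST": ([5, 5, 5, 5], [5, 5, 5, 5]),
        })
        sel = DEGeneSelection(genes=pd.Index(["SAME", "OPP", "CONST"]), rule="manual",
                              e_bar=pd.Series(1.0, index=["SAME", "OPP", "CONST"]),
                              d=pd.Series(1.0, index=["SAME", "OPP", "CONST"]),
                              e1=pd.Series(1.0, index=["SAME", "OPP", "CONST"]),
                              e2=pd.Series(1.0, index=["SAME", "OPP", "CONST"]))
        prof = mn.breed_correlation_profiles(means, ["REG"], sel)
        assert prof.r1.loc["REG", "SAME"] == pytest.approx(1.0)
        assert prof.r1.loc["REG", "OPP"] == pytest.approx(-1.0)
        assert prof.r1.loc["REG", "CONST"] == 0.0
        assert prof.degenerate.loc["REG", "CONST"]
        assert not prof.degenerate.loc["REG", "SAME"]

    def test_too_few_shared_stages_gives_missing(self):
        means = self._means_from_profiles({
            "REG": ([1, 2, 3, 4], [1, 2, 3, 4]),
            "HOLEY": ([1.0, None, None, 2.0], [1, 2, 3, 4]),
        })
        sel = DEGeneSelection(genes=pd.Index(["HOLEY"]), rule="manual",
                              e_bar=pd.Series(1.0, index=["HOLEY"]),
                              d=pd.Series(1.0, index=["HOLEY"]),
                              e1=pd.Series(1.0, index=["HOLEY"]),
                              e2=pd.Series(1.0, index=["HOLEY"]))
        prof = mn.breed_correlation_profiles(means, ["REG"], sel)
        assert np.isnan(prof.r1.loc["REG", "HOLEY"])
        assert prof.r2.loc["REG", "HOLEY"] == pytest.approx(1.0)

    def test_correlations_bounded(self, default_run):
        sel = mn.select_de_genes(default_run["diff"])
        prof = mn.breed_correlation_profiles(
            default_run["gene_means"], default_run["truth"].regulators, sel)
        for r in (prof.r1, prof.r2):
            vals = r.stack().dropna()
            assert vals.between(-1.0, 1.0).all()


def _toy_profiles():
    """The hand-worked two-gene example: RIF1 = -2.75, RIF2 = 53.98625."""
    genes = pd.Index(["j1", "j2"])
    sel = DEGeneSelection(
        genes=genes, rule="manual",
        e_bar=pd.Series([10.0, 8.0], index=genes),
        d=pd.Series([1.0, -1.0], index=genes),
        e1=pd.Series([10.5, 7.5], index=genes),
        e2=pd.Series([9.5, 8.5], index=genes),
    )
    prof = CorrelationProfiles(
        r1=pd.DataFrame([[0.9, -0.8]], index=["r"], columns=genes),
        r2=pd.DataFrame([[0.4, 0.2]], index=["r"], columns=genes),
    )
    return prof, sel


class TestComputeRIF:
    def test_hand_worked_two_gene_example(self):
        prof, sel = _toy_profiles()
        out = mn.compute_rif(prof, sel)
        assert out.loc["r", "n_de_used"] == 2
        assert out.loc["r", "rif1_raw"] == pytest.approx(-2.75)
        assert out.loc["r", "rif2_raw"] == pytest.approx(53.98625)

    def test_equal_wiring_gives_zero_rif1(self):
        prof, sel = _toy_profiles()
        prof.r2 = prof.r1.copy()
        out = mn.compute_rif(prof, sel)
        assert out.loc["r", "rif1_raw"] == 0.0

    def test_equal_wiring_and_expression_gives_zero_rif2(self):
        prof, sel = _toy_profiles()
        prof.r2 = prof.r1.copy()
        sel.e2 = sel.e1.copy()
        out = mn.compute_rif(prof, sel)
        assert out.loc["r", "rif2_raw"] == 0.0

    def test_missing_pairs_shrink_n_de(self):
        prof, sel = _toy_profiles()
        prof.r1.loc["r", "j2"] = np.nan
        out = mn.compute_rif(prof, sel)
        assert out.loc["r", "n_de_used"] == 1
        assert out.loc["r", "rif1_raw"] == pytest.approx(10 * 1 * 0.25)

    def test_breed_relabel_negates_rif1_and_rif2(self, rng):
        # swapping breeds: r1<->r2, e1<->e2, d -> -d
        genes = pd.Index([f"g{i}" for i in range(12)])
        regs = ["r1", "r2", "r3"]
        e1 = pd.Series(rng.uniform(6, 10, 12), index=genes)
        e2 = pd.Series(rng.uniform(6, 10, 12), index=genes)
        sel = DEGeneSelection(genes=genes, rule="manual", e_bar=(e1 + e2) / 2,
                              d=e1 - e2, e1=e1, e2=e2)
        c1 = pd.DataFrame(rng.uniform(-1, 1, (3, 12)), index=regs, columns=genes)
        c2 = pd.DataFrame(rng.uniform(-1, 1, (3, 12)), index=regs, columns=genes)
        fwd = mn.compute_rif(CorrelationProfiles(r1=c1, r2=c2), sel)
        swapped_sel = DEGeneSelection(genes=genes, rule="manual",
                                      e_bar=sel.e_bar, d=-sel.d, e1=e2, e2=e1)
        rev = mn.compute_rif(CorrelationProfiles(r1=c2, r2=c1), swapped_sel)
        pd.testing.assert_series_equal(fwd["rif1_raw"], -rev["rif1_raw"])
        pd.testing.assert_series_equal(fwd["rif2_raw"], -rev["rif2_raw"])


class TestStandardizeAndRank:
    def test_z_columns_have_zero_mean_unit_sd(self, default_run):
        sel = mn.select_de_genes(default_run["diff"])
        prof = mn.breed_correlation_profiles(
            default_run["gene_means"], default_run["truth"].regulators, sel)
        out = mn.standardize_and_rank(mn.compute_rif(prof, sel))
        for col in ("rif1_z", "rif2_z"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[col].std(ddof=1) == pytest.approx(1.0)

    def test_extreme_set_monotone_in_cutoff(self, default_run):
        sel = mn.select_de_genes(default_run["diff"])
        prof = mn.breed_correlation_profiles(
            default_run["gene_means"], default_run["truth"].regulators, sel)
        raw = mn.compute_rif(prof, sel)
        counts = [mn.standardize_and_rank(raw, cutoff=c)["extreme_both"].sum()
                  for c in (0.5, 1.0, 1.96, 3.0)]
        assert counts == sorted(counts, reverse=True)

    def test_single_rewired_regulator_dominates_both_scores(self):
        # a deliberately dominant single plant (strong DE targets coupled in
        # BA only, low noise), scored with replicate-level correlations so
        # the null correlation distribution is tight; seeded run
        from musclenet.rif import breed_correlation_profiles_replicates

        cfg = mn.SimulationConfig(seed=42, rewired_regulator_count=1,
                                  de_effect=2.0, rewiring_strength=1.0,
                                  replicate_noise_sd=0.2, missing_rate=0.0)
        matrix, design, pmap, truth = mn.simulate_dataset(cfg)
        matrix, design = mn.average_technical_replicates(matrix, design)
        means = mn.filter_expressed(mn.compute_treatment_means(matrix, design))
        gm = mn.map_to_genes(means, pmap)
        sample_matrix = matrix.loc[
            [f"P_{g}_1" for g in pmap.unique() if f"P_{g}_1" in matrix.index]]
        sample_matrix.index = [pmap[p] for p in sample_matrix.index]
        sel = mn.select_de_genes(mn.compute_diff(gm), fraction=0.02)
        prof = breed_correlation_profiles_replicates(
            sample_matrix, design, truth.regulators, sel)
        out = mn.standardize_and_rank(mn.compute_rif(prof, sel))
        reg = truth.rewired_regulators[0][0]
        assert out["rif1_z"].abs().idxmax() == reg
        assert out["rif2_z"].abs().idxmax() == reg

    def test_null_z_scores_sign_symmetric(self):
        from scipy import stats
        cfg = mn.SimulationConfig(seed=7, n_genes=1500, n_regulators=500,
                                  rewired_regulator_count=0, mito_set_size=0)
        run = run_chain(cfg)
        sel = mn.select_de_genes(run["diff"])
        prof = mn.breed_correlation_profiles(
            run["gene_means"], run["truth"].regulators, sel)
        out = mn.standardize_and_rank(mn.compute_rif(prof, sel))
        for col in ("rif1_z", "rif2_z"):
            k = int((out[col] > 0).sum())
            n = int((out[col] != 0).sum())
            assert stats.binomtest(k, n, 0.5).pvalue > 0.01
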