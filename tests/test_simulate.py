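"""Planted-truth checks on the synthetic tissue generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synovniche import simulate
from synovniche.simulate import (
    CohortConfig,
    ConfigError,
    ExpressionConfig,
    TissueConfig,
)


def _uniform_config(n_cells, n_types=3, seed=0, **kw):
    types = [f"t{j}" for j in range(n_types)]
    return TissueConfig(
        n_cells=n_cells,
        composition=np.full((1, n_types), 1.0 / n_types),
        cell_types=types,
        n_niches=1,
        fov_grid=(1, 1),
        fov_size_um=200.0,
        seed=seed,
        **kw,
    )


class TestGenerateTissue:
    def test_degenerate_single_type_single_niche(self):
        config = TissueConfig(
            n_cells=100, composition=np.array([[1.0]]), cell_types=["A"],
            n_niches=1, fov_grid=(1, 1), seed=0,
        )
        cells = simulate.generate_tissue(config)
        assert len(cells) == 100
        assert (cells["cell_type"] == "A").all()
        assert (cells["niche_true"] == 0).all()

    def test_positions_inside_fov_bounds(self):
        cells = simulate.generate_tissue(_uniform_config(500))
        assert cells["x_um"].between(0, 200).all()
        assert cells["y_um"].between(0, 200).all()

    def test_reproducible_given_seed(self):
        config = simulate.default_tissue_config(n_cells=1000, seed=42)
        a = simulate.generate_tissue(config)
        b = simulate.generate_tissue(simulate.default_tissue_config(n_cells=1000, seed=42))
        pd.testing.assert_frame_equal(a, b)

    def test_bands_exclusive_types_match_composition(self):
        """Per-niche type frequencies within 3 binomial SE of the planted rows."""
        comp = np.array([[0.7, 0.3], [0.2, 0.8]])
        config = TissueConfig(
            n_cells=10_000, composition=comp, cell_types=["A", "B"],
            n_niches=2, niche_layout="bands", fov_grid=(1, 1),
            fov_size_um=400.0, seed=3,
        )
        cells = simulate.generate_tissue(config)
        for niche in (0, 1):
            sub = cells[cells["niche_true"] == niche]
            n = len(sub)
            p_hat = (sub["cell_type"] == "A").mean()
            p = comp[niche, 0]
            assert abs(p_hat - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_chi2_goodness_of_fit_on_planted_labels(self):
        comp = np.array([[0.5, 0.3, 0.2]])
        config = TissueConfig(
            n_cells=10_000, composition=comp, cell_types=["A", "B", "C"],
            n_niches=1, fov_grid=(1, 1), seed=11,
        )
        cells = simulate.generate_tissue(config)
        obs = cells["cell_type"].value_counts().reindex(["A", "B", "C"]).to_numpy()
        p = stats.chisquare(obs, comp[0] * len(cells)).pvalue
        assert p > 0.01

    def test_doublets_planted_within_two_um(self):
        config = _uniform_config(2000, n_types=2, seed=5,
                                 doublet_pairs=[("t0", "t1", 0.3)])
        cells = simulate.generate_tissue(config)
        from scipy.spatial import cKDTree

        a = cells[cells["cell_type"] == "t0"][["x_um", "y_um"]].to_numpy()
        b = cells[cells["cell_type"] == "t1"][["x_um", "y_um"]].to_numpy()
        d, _ = cKDTree(b).query(a)
        n_expected = round(0.3 * len(a))
        assert (d <= 2.0).sum() >= 0.99 * n_expected

    def test_zero_mass_composition_row_rejected(self):
        with pytest.raises(ConfigError):
            TissueConfig(
                n_cells=10, composition=np.array([[0.0, 0.0]]),
                cell_types=["A", "B"], n_niches=1,
            )

    @pytest.mark.parametrize("layout", ["bands", "blobs", "mixed"])
    def test_layouts_cover_all_niches(self, layout):
        config = TissueConfig(
            n_cells=5000, composition=np.full((3, 2), 0.5),
            cell_types=["A", "B"], n_niches=3, niche_layout=layout,
            fov_grid=(2, 2), seed=1,
        )
        cells = simulate.generate_tissue(config)
        assert set(cells["niche_true"]) == {0, 1, 2}


class TestGenerateExpression:
    def _config(self, dispersion=10.0, lib=(1000.0, 1000.0)):
        markers = pd.DataFrame(
            [[20.0, 0.1, 0.0], [0.1, 20.0, 0.0]],
            index=["A", "B"], columns=["g1", "g2", "g0"],
        )
        return ExpressionConfig(markers=markers, baseline_mean=0.05,
                                dispersion=dispersion, library_size_range=lib, seed=2)

    def _cells(self, n_per_type=500):
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(2 * n_per_type)],
                "cell_type": ["A"] * n_per_type + ["B"] * n_per_type,
            }
        )

    def test_zero_mean_gene_gives_all_zero_column(self):
        adata = simulate.generate_expression(self._cells(50), self._config())
        assert adata[:, "g0"].X.sum() == 0

    def test_marker_gene_enriched_in_its_type(self):
        adata = simulate.generate_expression(self._cells(500), self._config())
        x = np.asarray(adata[:, "g1"].X.todense()).ravel()
        is_a = (adata.obs["cell_type"] == "A").to_numpy()
        assert x[is_a].mean() >= 10 * x[~is_a].mean()

    def test_poisson_limit_variance_to_mean(self):
        """At huge dispersion and fixed library size the counts are Poisson-like."""
        cells = self._cells(2500)
        adata = simulate.generate_expression(cells, self._config(dispersion=1e8))
        is_a = (adata.obs["cell_type"] == "A").to_numpy()
        x = np.asarray(adata[is_a, "g1"].X.todense()).ravel()
        assert x.mean() > 5
        assert abs(x.var() / x.mean() - 1.0) < 0.1

    def test_unknown_cell_type_raises_with_name(self):
        cells = pd.DataFrame({"cell_id": ["c0"], "cell_type": ["Z"]})
        with pytest.raises(ConfigError, match="Z"):
            simulate.generate_expression(cells, self._config())

    def test_counts_nonnegative_integer_and_reproducible(self):
        a = simulate.generate_expression(self._cells(100), self._config())
        b = simulate.generate_expression(self._cells(100), self._config())
        assert (a.X.data >= 0).all()
        assert np.array_equal(a.X.toarray(), b.X.toarray())


class TestIFIntensities:
    def test_zero_noise_limit_equals_signatures(self, if_panel):
        cells = pd.DataFrame(
            {"cell_id": ["c0", "c1"], "cell_type": ["T cell", "Mast cell"]}
        )
        out = simulate.generate_if_intensities(cells, if_panel, snr=1e12, seed=0)
        np.testing.assert_allclose(out.iloc[0], if_panel.loc["T cell"], atol=1e-6)
        np.testing.assert_allclose(out.iloc[1], if_panel.loc["Mast cell"], atol=1e-6)

    def test_panel_has_21_markers_12_types(self, if_panel):
        assert if_panel.shape == (12, 21)
        assert if_panel.drop_duplicates().shape[0] == 12

    def test_nonpositive_snr_rejected(self, if_panel):
        cells = pd.DataFrame({"cell_id": ["c0"], "cell_type": ["T cell"]})
        with pytest.raises(ConfigError):
            simulate.generate_if_intensities(cells, if_panel, snr=0.0)


class TestCohort:
    def test_identical_proportions_give_zero_expected_log2fd(self):
        props = pd.DataFrame(
            [[0.5, 0.5], [0.5, 0.5]], index=["g1", "g2"], columns=["A", "B"]
        )
        config = CohortConfig(
            n_samples_per_group=30, true_proportions=props,
            cells_per_sample_range=(2000, 2000), seed=0,
        )
        cohort = simulate.generate_cohort_counts(config)
        g1 = cohort.counts[cohort.samples["group"] == "g1"].sum()
        g2 = cohort.counts[cohort.samples["group"] == "g2"].sum()
        lfd = np.log2((g1 / g1.sum()) / (g2 / g2.sum()))
        assert np.all(np.abs(lfd) < 0.05)

    def test_planted_log2fd_matches_closed_form(self):
        """0.30 vs 0.10 pooled proportions converge to log2(3) ~ 1.585."""
        props = pd.DataFrame(
            [[0.30, 0.70], [0.10, 0.90]], index=["g1", "g2"], columns=["A", "B"]
        )
        config = CohortConfig(
            n_samples_per_group=40, true_proportions=props,
            cells_per_sample_range=(3000, 3000), seed=1,
        )
        cohort = simulate.generate_cohort_counts(config)
        g1 = cohort.counts[cohort.samples["group"] == "g1"].sum()
        g2 = cohort.counts[cohort.samples["group"] == "g2"].sum()
        lfd = np.log2((g1["A"] / g1.sum()) / (g2["A"] / g2.sum()))
        assert abs(lfd - np.log2(3.0)) < 0.05

    def test_severity_clamped_to_krenn_scale(self):
        props = pd.DataFrame([[0.8, 0.2]], index=["g"], columns=["N0", "N1"])
        config = CohortConfig(
            n_samples_per_group=50, true_proportions=props,
            severity_link={"N0": 50.0}, severity_noise_sd=1.0, seed=2,
        )
        cohort = simulate.generate_cohort_counts(config)
        assert cohort.samples["severity"].between(0, 3).all()

    def test_positive_link_gives_positive_correlation(self):
        props = pd.DataFrame([[0.3, 0.7]], index=["g"], columns=["plasma", "rest"])
        config = CohortConfig(
            n_samples_per_group=30, true_proportions=props,
            cells_per_sample_range=(300, 600),
            severity_link={"plasma": 5.0}, severity_noise_sd=0.05,
            severity_baseline=0.5, seed=3,
        )
        cohort = simulate.generate_cohort_counts(config)
        r = np.corrcoef(cohort.proportions["plasma"], cohort.samples["severity"])[0, 1]
        assert r > 0.5

    def test_empty_group_rejected(self):
        props = pd.DataFrame([[1.0]], index=["g"], columns=["A"])
        with pytest.raises(ConfigError):
            CohortConfig(n_samples_per_group=0, true_proportions=props)


class TestLRTruth:
    def test_planted_overrides_point_at_sender_and_receiver(self):
        db, overrides = simulate.generate_lr_truth(
            8, ("L1", "R1", "A", "B"), ["A", "B", "C"], seed=0
        )
        assert overrides[("A", "L1")] > overrides.get(("B", "L1"), 0)
        assert ("B", "R1") in overrides
        assert not db.duplicated(["ligand", "receptor"]).any()
        assert db["pathway"].nunique() > 1  # several pairs per pathway group

    def test_no_planted_signal_gives_no_overrides(self):
        db, overrides = simulate.generate_lr_truth(5, None, ["A", "B"], seed=0)
        assert overrides == {}
        assert len(db) == 5

    def test_unknown_planted_type_rejected(self):
        with pytest.raises(ConfigError):
            simulate.generate_lr_truth(3, ("L", "R", "A", "Z"), ["A", "B"])
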