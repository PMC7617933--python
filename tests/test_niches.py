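"""Neighbourhood composition, niche clustering and niche-gene enrichment."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from synovniche import niches, simulate
from tests.conftest import brute_force_knn


class TestNeighborhoodComposition:
    def test_single_type_rows_are_indicators(self, small_tissue):
        cells = small_tissue.copy()
        cells["cell_type"] = "A"
        comp, _ = niches.neighborhood_composition(cells, k=5)
        assert (comp["A"] == 1.0).all()

    def test_six_cell_fixture_matches_hand_computation(self, six_cell_fixture):
        comp, _ = niches.neighborhood_composition(six_cell_fixture, k=2)
        # cell c0 at (0,0): neighbours (1,0)=A and (2,0)=B
        assert comp.loc["c0", "A"] == pytest.approx(0.5)
        assert comp.loc["c0", "B"] == pytest.approx(0.5)

    def test_matches_brute_force_knn_oracle(self, small_tissue):
        sub = small_tissue.iloc[:80].reset_index(drop=True)
        comp, _ = niches.neighborhood_composition(sub, k=4)
        types = sorted(sub["cell_type"].unique())
        for i in [0, 13, 41, 79]:
            nbrs = brute_force_knn(sub, i, 4)
            expected = (
                sub["cell_type"].iloc[nbrs].value_counts(normalize=True)
                .reindex(types, fill_value=0.0)
            )
            np.testing.assert_allclose(
                comp.loc[sub["cell_id"].iloc[i]].to_numpy(),
                expected.to_numpy(), atol=1e-12,
            )

    def test_rows_sum_to_one(self, small_tissue):
        comp, flagged = niches.neighborhood_composition(small_tissue, k=10)
        assert not flagged.any()
        np.testing.assert_allclose(comp.sum(axis=1), 1.0, atol=1e-9)

    def test_small_fov_flagged_unassigned(self, six_cell_fixture):
        comp, flagged = niches.neighborhood_composition(six_cell_fixture, k=10)
        assert flagged.all()
        assert comp.isna().all().all()


class TestDetectNiches:
    def test_two_half_plane_niches_perfectly_recovered(self):
        """Spatially separated half-planes with exclusive types: ARI = 1."""
        rng = np.random.default_rng(0)
        n = 600
        y = np.r_[rng.uniform(0, 120, n // 2), rng.uniform(180, 300, n // 2)]
        cells = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "sample_id": "s",
                "fov_id": "f",
                "x_um": rng.uniform(0, 300, n),
                "y_um": y,
                "cell_type": ["A"] * (n // 2) + ["B"] * (n // 2),
                "niche_true": [0] * (n // 2) + [1] * (n // 2),
            }
        )
        comp, _ = niches.neighborhood_composition(cells, k=5)
        model = niches.detect_niches(comp, cells, n_niches=2, seed=0)
        ari = adjusted_rand_score(cells["niche_true"], model.labels.to_numpy())
        assert ari == pytest.approx(1.0)

    def test_single_niche_trivial(self, small_tissue):
        comp, _ = niches.neighborhood_composition(small_tissue, k=5)
        model = niches.detect_niches(comp, small_tissue, n_niches=1, seed=0)
        assert (model.labels == 0).all()

    def test_too_many_niches_rejected(self, six_cell_fixture):
        cells = six_cell_fixture
        comp, _ = niches.neighborhood_composition(cells, k=2)
        with pytest.raises(ValueError):
            niches.detect_niches(comp, cells, n_niches=50, seed=0)

    def test_labels_invariant_to_rigid_motion_and_order(self, small_tissue):
        comp, _ = niches.neighborhood_composition(small_tissue, k=5)
        base = niches.detect_niches(comp, small_tissue, n_niches=2, seed=0)

        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = small_tissue.copy()
        xy = moved[["x_um", "y_um"]].to_numpy() @ rot.T + np.array([13.0, -5.0])
        moved[["x_um", "y_um"]] = xy
        shuffled = moved.sample(frac=1, random_state=1).reset_index(drop=True)
        comp2, _ = niches.neighborhood_composition(shuffled, k=5)
        model2 = niches.detect_niches(comp2, shuffled, n_niches=2, seed=0)

        merged = pd.DataFrame({"a": base.labels}).join(
            model2.labels.rename("b"), how="inner"
        )
        assert adjusted_rand_score(merged["a"], merged["b"]) == pytest.approx(1.0)

    def test_composition_matrix_row_stochastic(self, small_tissue):
        comp, _ = niches.neighborhood_composition(small_tissue, k=5)
        model = niches.detect_niches(comp, small_tissue, n_niches=2, seed=0)
        np.testing.assert_allclose(model.composition.sum(axis=1), 1.0, atol=1e-9)


class TestCompositionSummary:
    def test_uniform_labels_match_global_frequencies(self, small_tissue):
        rng = np.random.default_rng(0)
        comp, _ = niches.neighborhood_composition(small_tissue, k=5)
        model = niches.detect_niches(comp, small_tissue, n_niches=2, seed=0)
        model.labels[:] = rng.integers(0, 2, len(model.labels))
        summary, by_sample = niches.niche_composition_summary(model, small_tissue)
        global_freq = small_tissue["cell_type"].value_counts(normalize=True)
        for niche in summary.index:
            n = (model.labels == niche).sum()
            for t in summary.columns:
                p = global_freq[t]
                se = np.sqrt(p * (1 - p) / n)
                assert abs(summary.loc[niche, t] - p) <= 3 * se
        np.testing.assert_allclose(by_sample.sum(axis=1), 1.0, atol=1e-9)

    def test_absent_niche_gets_zero_proportion(self, small_tissue):
        comp, _ = niches.neighborhood_composition(small_tissue, k=5)
        model = niches.detect_niches(comp, small_tissue, n_niches=2, seed=0)
        model.labels[:] = 0  # niche 1 absent everywhere
        _, by_sample = niches.niche_composition_summary(model, small_tissue)
        assert (by_sample[1] == 0).all()


class TestNicheMarkerEnrichment:
    def _dataset(self, seed=0):
        from synovniche.benchmarks import _pathway_dataset

        return _pathway_dataset(seed, n_cells=2500)

    def test_separating_gene_confirmed(self):
        adata, labels, pathway_sets, truth = self._dataset()
        one = {"pathway00": pathway_sets["pathway00"]}
        _, per_pathway = niches.niche_marker_enrichment(adata, labels, one)
        assert per_pathway.loc["pathway00", "confirmed"]

    def test_absent_gene_reported_untested(self):
        adata, labels, _, _ = self._dataset()
        sets = {"ghost": (0, ["NOT_A_GENE"])}
        per_gene, per_pathway = niches.niche_marker_enrichment(adata, labels, sets)
        assert not per_gene["tested"].iloc[0]
        assert not per_pathway.loc["ghost", "confirmed"]

    def test_recovers_planted_twelve_of_fifteen(self):
        adata, labels, pathway_sets, truth = self._dataset(seed=1)
        _, per_pathway = niches.niche_marker_enrichment(adata, labels, pathway_sets)
        confirmed = per_pathway["confirmed"]
        true_up = [p for p, up in truth.items() if up]
        assert confirmed[true_up].sum() >= 11
        false_up = [p for p, up in truth.items() if not up]
        assert confirmed[false_up].sum() <= 1
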