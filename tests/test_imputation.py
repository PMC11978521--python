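import numpy as np
import pytest

from spotdecon.decomposition import SpotComposition, composition_from_counts, decompose_all, annotate_in_spot_nuclei
from spotdecon.geometry import assign_nuclei_to_spots
from spotdecon.imputation import (
    annotate_out_spot_nuclei,
    export_pseudo_image,
    fit_proportion_field,
    impute_cell_expression,
    predict_proportions,
)
from spotdecon.io import NucleusSet, PipelineConfig, ValidationError, read_nuclei
from spotdecon.simulation import generate_truth_pattern, simulate_spots


def _composition(pattern):
    return SpotComposition(
        spot_ids=pattern.geometry.spot_ids,
        type_ids=pattern.type_ids,
        N=pattern.n.sum(axis=1),
        n=pattern.n,
        p_tilde=pattern.P_true,
    )


@pytest.fixture(scope="module")
def bump_pattern():
    return generate_truth_pattern(
        100, 3, "gaussian-bumps", seed=23, mean_cells_per_spot=50
    )


@pytest.fixture(scope="module")
def bump_field(bump_pattern):
    return fit_proportion_field(
        bump_pattern.geometry, _composition(bump_pattern), PipelineConfig()
    )


class TestFitProportionField:
    def test_constant_field(self):
        pattern = generate_truth_pattern(36, 2, "uniform", seed=3)
        comp = _composition(pattern)
        comp.p_tilde = np.tile([0.3, 0.7], (36, 1))
        field = fit_proportion_field(pattern.geometry, comp, PipelineConfig())
        center = pattern.geometry.centers.mean(axis=0)
        pred = field.predict_raw(center)
        assert pred[0, 0] == pytest.approx(0.3, abs=1e-3)
        assert pred[0, 1] == pytest.approx(0.7, abs=1e-3)

    def test_interpolates_training_points(self, bump_pattern):
        comp = _composition(bump_pattern)
        # short length scale keeps the kernel matrix well conditioned so the
        # zero-noise interpolation limit is numerically attainable
        field = fit_proportion_field(
            bump_pattern.geometry, comp,
            PipelineConfig(gp_noise=1e-12, gp_length_scale=40.0),
        )
        pred = field.predict_raw(bump_pattern.geometry.centers[:5])
        assert np.allclose(pred, comp.p_tilde[:5], atol=1e-6)

    def test_too_few_spots_errors(self):
        pattern = generate_truth_pattern(5, 2, "uniform", seed=0)
        with pytest.raises(ValidationError):
            fit_proportion_field(pattern.geometry, _composition(pattern), PipelineConfig())

    def test_holdout_beats_global_mean(self, bump_pattern):
        rng = np.random.default_rng(23)
        comp = _composition(bump_pattern)
        S = bump_pattern.geometry.n_spots
        held = rng.choice(S, size=S // 5, replace=False)
        train_mask = np.ones(S, dtype=bool)
        train_mask[held] = False
        from spotdecon.io import SpotGeometry

        geo_train = SpotGeometry(
            spot_ids=[bump_pattern.geometry.spot_ids[i] for i in np.flatnonzero(train_mask)],
            centers=bump_pattern.geometry.centers[train_mask],
            spot_diameter_px=bump_pattern.geometry.spot_diameter_px,
            microns_per_px=bump_pattern.geometry.microns_per_px,
        )
        comp_train = SpotComposition(
            spot_ids=geo_train.spot_ids,
            type_ids=comp.type_ids,
            N=comp.N[train_mask],
            n=comp.n[train_mask],
            p_tilde=comp.p_tilde[train_mask],
        )
        field = fit_proportion_field(geo_train, comp_train, PipelineConfig())
        pred = predict_proportions(field, bump_pattern.geometry.centers[held])
        # score against the smooth planted field, not its multinomial draw
        truth = bump_pattern.expected_weights[held]
        mae_gp = np.abs(pred - truth).mean()
        mae_mean = np.abs(comp.p_tilde[train_mask].mean(axis=0)[None, :] - truth).mean()
        assert mae_gp < mae_mean


class TestPredictProportions:
    def test_training_point_value(self, bump_pattern):
        comp = _composition(bump_pattern)
        field = fit_proportion_field(
            bump_pattern.geometry, comp, PipelineConfig(gp_noise=1e-10)
        )
        pred = predict_proportions(field, bump_pattern.geometry.centers[7])
        assert np.allclose(pred[0], comp.p_tilde[7], atol=1e-3)

    def test_simplex_at_random_coords(self, bump_field, bump_pattern):
        rng = np.random.default_rng(29)
        lo = bump_pattern.geometry.centers.min(axis=0)
        hi = bump_pattern.geometry.centers.max(axis=0)
        coords = rng.uniform(lo, hi, size=(1000, 2))
        pred = predict_proportions(bump_field, coords)
        assert np.all(pred >= 0)
        assert np.allclose(pred.sum(axis=1), 1.0, atol=1e-9)

    def test_far_field_is_valid_simplex(self, bump_field):
        pred = predict_proportions(bump_field, np.array([[1e7, 1e7]]))
        assert np.allclose(pred.sum(), 1.0, atol=1e-9)

    def test_non_finite_coords_error(self, bump_field):
        with pytest.raises(ValidationError):
            predict_proportions(bump_field, np.array([[np.nan, 0.0]]))


class TestAnnotateOutSpot:
    def test_one_hot_deterministic(self, bump_field):
        field = bump_field
        nuclei = NucleusSet(
            nucleus_ids=["n0"], coords=[[0.0, 0.0]], assigned_spot=[None]
        )
        # monkeypatch-free: far-field prediction is slide average; instead test
        # determinism of the categorical draw under a fixed seed
        a = annotate_out_spot_nuclei(nuclei, field, seed=3)
        b = annotate_out_spot_nuclei(nuclei, field, seed=3)
        assert a.assigned_type == b.assigned_type

    def test_in_spot_nuclei_untouched(self, bump_field):
        nuclei = NucleusSet(
            nucleus_ids=["n0"], coords=[[0.0, 0.0]],
            assigned_spot=["spot0"], assigned_type=["type1"],
        )
        out = annotate_out_spot_nuclei(nuclei, bump_field, seed=0)
        assert out.assigned_type == ["type1"]

    def test_binomial_frequency(self, bump_pattern):
        # constant 50/50 field -> draws should be ~balanced
        comp = _composition(bump_pattern)
        comp = SpotComposition(
            spot_ids=comp.spot_ids, type_ids=["a", "b"],
            N=comp.N, n=np.column_stack([comp.N // 2, comp.N - comp.N // 2]),
            p_tilde=np.tile([0.5, 0.5], (len(comp.spot_ids), 1)),
        )
        field = fit_proportion_field(bump_pattern.geometry, comp, PipelineConfig())
        center = bump_pattern.geometry.centers.mean(axis=0)
        nuclei = NucleusSet(
            nucleus_ids=[f"n{i}" for i in range(2000)],
            coords=np.tile(center, (2000, 1)),
            assigned_spot=[None] * 2000,
        )
        out = annotate_out_spot_nuclei(nuclei, field, seed=11)
        freq = np.mean(np.asarray(out.assigned_type) == "a")
        assert freq == pytest.approx(0.5, abs=0.03)


class TestImputeCellExpression:
    def _decomposed(self, pattern, reference_counts, signature_full):
        X, truth = simulate_spots(reference_counts, pattern, "none", seed=31)
        comp = _composition(pattern)
        decomposed, _ = decompose_all(X.matrix, comp, signature_full, nuclei=None)
        return X, comp, decomposed

    def test_constant_profile_recovered(self, signature_full):
        from spotdecon.decomposition import DecomposedSpot

        pattern = generate_truth_pattern(16, 5, "uniform", seed=31, mean_cells_per_spot=5)
        comp = _composition(pattern)
        G = len(signature_full.gene_ids)
        v = np.arange(G, dtype=float)
        decomposed = []
        for i, s in enumerate(comp.spot_ids):
            U = np.zeros((5, G))
            for t in range(5):
                U[t] = v * comp.n[i, t]
            decomposed.append(DecomposedSpot(spot_id=s, U=U, omega=np.zeros((5, G))))
        out = impute_cell_expression(
            np.array([50.0, 50.0]), "type0", decomposed, comp, pattern.geometry,
            PipelineConfig(),
        )
        present = comp.n[:, 0] > 0
        assert present.any()
        assert np.allclose(out, v, rtol=1e-9)

    def test_absent_type_errors(self, reference_counts, signature_full):
        pattern = generate_truth_pattern(9, 5, "uniform", seed=31)
        X, comp, decomposed = self._decomposed(pattern, reference_counts, signature_full)
        comp.n[:, 2] = 0
        comp.N = comp.n.sum(axis=1)
        with pytest.raises(ValidationError):
            impute_cell_expression(
                np.zeros(2), "type2", decomposed, comp, pattern.geometry, PipelineConfig()
            )

    def test_gradient_midpoint(self, signature_full):
        # planted linear gradient in a single gene across x
        from spotdecon.decomposition import DecomposedSpot

        pattern = generate_truth_pattern(49, 5, "uniform", seed=31, mean_cells_per_spot=4)
        comp = _composition(pattern)
        G = len(signature_full.gene_ids)
        decomposed = []
        xs = pattern.geometry.centers[:, 0]
        span = xs.max() - xs.min()
        for i, s in enumerate(comp.spot_ids):
            level = 10.0 + 90.0 * (xs[i] - xs.min()) / span
            U = np.zeros((5, G))
            for t in range(5):
                U[t] = level * comp.n[i, t]
            decomposed.append(DecomposedSpot(spot_id=s, U=U, omega=np.zeros((5, G))))
        mid = np.array([(xs.min() + xs.max()) / 2, pattern.geometry.centers[:, 1].mean()])
        out = impute_cell_expression(
            mid, "type0", decomposed, comp, pattern.geometry,
            PipelineConfig(k_neighbors=10),
        )
        assert np.median(np.abs(out - 55.0) / 55.0) < 0.10


class TestExportPseudoImage:
    def test_csv_round_trip(self, tmp_path):
        nuclei = NucleusSet(
            nucleus_ids=[f"n{i}" for i in range(10)],
            coords=np.arange(20, dtype=float).reshape(10, 2),
            assigned_spot=["s0"] * 5 + [None] * 5,
            assigned_type=["A"] * 5 + ["B"] * 5,
        )
        table = export_pseudo_image(nuclei, {"A": "red", "B": "blue"}, tmp_path / "n.csv")
        assert len(table) == 10
        back = read_nuclei(tmp_path / "n.csv")
        assert back.nucleus_ids == nuclei.nucleus_ids
        assert back.assigned_type == nuclei.assigned_type
        assert back.assigned_spot == nuclei.assigned_spot

    def test_untyped_errors(self, tmp_path):
        nuclei = NucleusSet(
            nucleus_ids=["n0"], coords=[[0.0, 0.0]], assigned_type=[None]
        )
        with pytest.raises(ValidationError):
            export_pseudo_image(nuclei, {}, tmp_path / "n.csv")

    def test_missing_palette_errors(self, tmp_path):
        nuclei = NucleusSet(
            nucleus_ids=["n0"], coords=[[0.0, 0.0]], assigned_type=["A"]
        )
        with pytest.raises(ValidationError):
            export_pseudo_image(nuclei, {"B": "red"}, tmp_path / "n.csv")
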