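import numpy as np
import pytest
from scipy import stats

from spotdecon.io import AnnotatedCounts, ValidationError, cpm_normalize
from spotdecon.reference import (
    build_signature,
    coverage,
    fold_change_quantile,
    marker_z_test,
    select_markers,
)


def _cpm_with_means(means_by_type, cells_per_type=3):
    """CPM-flagged matrix where single-gene columns are padded by a filler
    gene so the type means of gene 0 equal the requested values."""
    rows, labels = [], []
    for t, m in enumerate(means_by_type):
        for _ in range(cells_per_type):
            rows.append([m, 1e6 - m])
            labels.append(f"t{t}")
    counts = AnnotatedCounts(
        np.asarray(rows, float),
        [f"c{i}" for i in range(len(rows))],
        ["g0", "fill"],
        labels=labels,
    )
    counts.normalized = "CPM"
    return counts


class TestFoldChangeQuantile:
    def test_linear_interpolation(self):
        counts = _cpm_with_means([10, 2, 5])
        # fold set {10/2, 10/5} = {5, 2}; 0.15-quantile of [2, 5] = 2.45
        assert fold_change_quantile(counts, "g0", "t0", 0.15) == pytest.approx(2.45, abs=1e-6)

    def test_two_types_single_element(self):
        counts = _cpm_with_means([10, 2])
        for v in (0.01, 0.5, 0.99):
            assert fold_change_quantile(counts, "g0", "t0", v) == pytest.approx(5.0, rel=1e-6)

    def test_all_zero_means(self):
        counts = _cpm_with_means([0, 0, 0])
        assert fold_change_quantile(counts, "g0", "t0", 0.15) == 1.0

    def test_missing_type(self):
        counts = _cpm_with_means([1, 2])
        with pytest.raises(ValidationError):
            fold_change_quantile(counts, "g0", "zzz", 0.15)


class TestMarkerZTest:
    def test_identical_groups(self):
        counts = _cpm_with_means([5, 5])
        assert marker_z_test(counts, "g0", "t0", "t1") == 0.5

    def test_zero_variance_separation(self):
        counts = _cpm_with_means([10, 2], cells_per_type=4)
        assert marker_z_test(counts, "g0", "t0", "t1") == 0.0
        assert marker_z_test(counts, "g0", "t1", "t0") == 1.0

    def test_matches_normal_cdf_oracle(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 1, 50)
        b = rng.normal(2, 0.5, 50)  # tight sd keeps CPM values nonnegative
        mat = np.zeros((100, 2))
        mat[:50, 0] = a
        mat[50:, 0] = b
        mat[:, 1] = 1e6 - mat[:, 0]
        counts = AnnotatedCounts(
            mat, [f"c{i}" for i in range(100)], ["g0", "fill"],
            labels=["t0"] * 50 + ["t1"] * 50,
        )
        counts.normalized = "CPM"
        p = marker_z_test(counts, "g0", "t0", "t1")
        # independent oracle: one-sided Welch z through the normal CDF
        z = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 50 + b.var(ddof=1) / 50)
        assert p == pytest.approx(1 - stats.norm.cdf(z), abs=1e-15)
        assert p < 1e-10

    def test_too_few_cells(self):
        counts = _cpm_with_means([1, 2], cells_per_type=1)
        with pytest.raises(ValidationError):
            marker_z_test(counts, "g0", "t0", "t1")


class TestCoverage:
    @pytest.mark.parametrize(
        "values,expected", [([0, 1, 2, 0], 0.5), ([0, 0, 0, 0], 0.0), ([1, 2, 3, 4], 1.0)]
    )
    def test_fraction(self, values, expected):
        mat = np.asarray([[v] for v in values], dtype=float)
        counts = AnnotatedCounts(
            mat, [f"c{i}" for i in range(4)], ["g0"], labels=["t0"] * 4
        )
        assert coverage(counts, "g0", "t0") == expected


def brute_force_select(Y_cpm, l_fold=1.5, l_lambda=0.1, l_cover=0.60, v=0.15, n_select=50):
    """Literal three-condition filter + ranking, independent of the library path."""
    labels = np.asarray(Y_cpm.labels)
    types = sorted(set(Y_cpm.labels))
    selected = {}
    for t in types:
        cand = []
        for g in Y_cpm.gene_ids:
            gi = Y_cpm.gene_ids.index(g)
            means = {u: Y_cpm.matrix[labels == u, gi].mean() for u in types}
            folds = []
            for u in types:
                if u == t:
                    continue
                if means[t] == 0 and means[u] == 0:
                    folds.append(1.0)
                else:
                    folds.append(means[t] / (means[u] + 1e-9))
            fq = float(np.quantile(folds, v))
            pvals = []
            for u in types:
                if u == t:
                    continue
                a = Y_cpm.matrix[labels == t, gi]
                b = Y_cpm.matrix[labels == u, gi]
                se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
                if se2 == 0:
                    pvals.append(0.5 if a.mean() == b.mean() else (0.0 if a.mean() > b.mean() else 1.0))
                else:
                    pvals.append(float(stats.norm.sf((a.mean() - b.mean()) / np.sqrt(se2))))
            cov = float((Y_cpm.matrix[labels == t, gi] > 0).mean())
            if fq > l_fold and max(pvals) < l_lambda and cov > l_cover:
                cand.append((g, fq))
        cand.sort(key=lambda x: (-x[1], x[0]))
        selected[t] = [g for g, _ in cand[:n_select]]
    return selected


class TestSelectMarkers:
    def test_constructed_marker_selected(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(5.0, size=(40, 5)).astype(float) + 1
        mat[:20, 0] = 1000.0  # type-1 exclusive
        mat[20:, 0] = 0.0
        counts = AnnotatedCounts(
            mat, [f"c{i}" for i in range(40)], [f"g{i}" for i in range(5)],
            labels=["A"] * 20 + ["B"] * 20,
        )
        table, markers = select_markers(cpm_normalize(counts))
        assert "g0" in markers
        row = table[(table["gene"] == "g0") & (table["type"] == "A")].iloc[0]
        assert row["selected"]

    def test_coverage_threshold_rejects(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(5.0, size=(40, 5)).astype(float) + 1
        mat[:20, 0] = 1000.0
        mat[:9, 0] = 0.0  # coverage 11/20 = 0.55 < 0.60
        mat[20:, 0] = 0.0
        counts = AnnotatedCounts(
            mat, [f"c{i}" for i in range(40)], [f"g{i}" for i in range(5)],
            labels=["A"] * 20 + ["B"] * 20,
        )
        table, markers = select_markers(cpm_normalize(counts))
        assert "g0" not in markers

    def test_matches_brute_force_planted_panel(self):
        from spotdecon.simulation import synthetic_reference

        Y = synthetic_reference(
            T=3, cells_per_type=20, n_genes=30, markers_per_type=12, fold=8.0, seed=3
        )
        Y_cpm = cpm_normalize(Y)
        table, markers = select_markers(Y_cpm)
        expected = brute_force_select(Y_cpm)
        got = {
            t: table[(table["type"] == t) & table["selected"]]
            .sort_values("rank")["gene"]
            .tolist()
            for t in expected
        }
        assert got == expected

    def test_deterministic(self, reference_cpm):
        t1, m1 = select_markers(reference_cpm)
        t2, m2 = select_markers(reference_cpm)
        assert m1 == m2
        assert t1.equals(t2)


class TestBuildSignature:
    def test_pooled_estimator(self):
        counts = AnnotatedCounts(
            [[1, 3], [3, 1]], ["c1", "c2"], ["g1", "g2"], labels=["t", "t"]
        )
        sig = build_signature(counts)
        assert np.allclose(sig.phi[0], [0.5, 0.5])
        assert sig.nu[0] == 4.0

    def test_single_cell(self):
        counts = AnnotatedCounts([[0, 5]], ["c"], ["g1", "g2"], labels=["t"])
        sig = build_signature(counts)
        assert sig.phi[0].tolist() == [0.0, 1.0]

    def test_rows_sum_to_one(self, signature):
        assert np.allclose(signature.phi.sum(axis=1), 1.0, atol=1e-9)

    def test_invariant_to_cell_order(self, reference_counts):
        rng = np.random.default_rng(5)
        perm = rng.permutation(reference_counts.n_obs)
        shuffled = AnnotatedCounts(
            reference_counts.matrix[perm],
            [reference_counts.row_ids[i] for i in perm],
            reference_counts.gene_ids,
            labels=[reference_counts.labels[i] for i in perm],
        )
        a = build_signature(reference_counts)
        b = build_signature(shuffled)
        assert np.allclose(a.phi, b.phi)
        assert np.allclose(a.nu, b.nu)

    def test_invariant_to_uniform_type_rescale(self):
        counts = AnnotatedCounts(
            [[1, 3], [3, 1], [2, 2]], ["c1", "c2", "c3"], ["g1", "g2"],
            labels=["t", "t", "u"],
        )
        scaled = AnnotatedCounts(
            [[2, 6], [6, 2], [2, 2]], ["c1", "c2", "c3"], ["g1", "g2"],
            labels=["t", "t", "u"],
        )
        assert np.allclose(build_signature(counts).phi, build_signature(scaled).phi)

    def test_zero_pooled_type_errors(self):
        counts = AnnotatedCounts(
            [[0, 0], [1, 1]], ["c1", "c2"], ["g1", "g2"], labels=["t", "u"]
        )
        with pytest.raises(ValidationError, match="t"):
            build_signature(counts)

    def test_empty_subset_errors(self, reference_counts):
        with pytest.raises(ValidationError):
            build_signature(reference_counts, [])

    def test_csv_round_trip(self, signature, tmp_path):
        from spotdecon.reference import SignatureMatrix

        signature.to_csv(tmp_path / "sig.csv")
        back = SignatureMatrix.from_csv(tmp_path / "sig.csv")
        assert np.allclose(back.phi, signature.phi)
        assert np.allclose(back.nu, signature.nu)
        assert back.type_ids == signature.type_ids
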