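"""Cell/gene QC, sparse median-of-ratios normalization, HVG, knee point."""

import numpy as np
import pytest
import scipy.sparse as sp

from clonotrace import (
    CountMatrix,
    filter_cells,
    filter_genes,
    knee_point,
    normalize_sparse_mor,
    select_hvg,
)
from clonotrace.scqc import compute_reference


def build_matrix(counts, mito=None, prefix="g"):
    counts = np.asarray(counts)
    g, c = counts.shape
    return CountMatrix(
        genes=np.array([f"{prefix}{i}" for i in range(g)], dtype=object),
        cells=np.array([f"cell{i}" for i in range(c)], dtype=object),
        counts=sp.csr_matrix(counts),
        mito=np.zeros(g, bool) if mito is None else np.asarray(mito, bool),
    )


def random_sparse_counts(rng, n_genes=80, n_cells=40, density=0.3):
    """Random UMI-like matrix where every cell expresses >= 1 gene."""
    counts = (rng.random((n_genes, n_cells)) < density) * rng.integers(
        1, 50, (n_genes, n_cells)
    )
    for c in range(n_cells):  # guarantee usable ratios per cell
        if counts[:, c].sum() == 0:
            counts[rng.integers(n_genes), c] = rng.integers(1, 50)
    return counts


class TestFilterCells:
    def test_high_mito_cell_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 20, size=(30, 20))
        mito = np.zeros(30, bool)
        mito[:3] = True
        counts[:3, :] = 1
        counts[:3, 5] = 200  # cell 5: mito-dominated
        cm = build_matrix(counts, mito)
        kept = filter_cells(cm, mito_max=0.15, low_gene_quantile=0,
                            high_umi_quantile=0, outlier_z=np.inf)
        assert "cell5" not in kept
        assert len(kept) == 19

    def test_disabled_filters_keep_everyone(self):
        rng = np.random.default_rng(1)
        cm = build_matrix(rng.integers(0, 8, size=(40, 25)))
        kept = filter_cells(cm, mito_max=1.0, low_gene_quantile=0,
                            high_umi_quantile=0, outlier_z=np.inf)
        assert len(kept) == 25

    def test_quantile_rules_trim_expected_tails(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(5, size=(200, 100))
        cm = build_matrix(counts)
        kept = filter_cells(cm, mito_max=1.0, low_gene_quantile=0.05,
                            high_umi_quantile=0.01, outlier_z=np.inf)
        genes_per_cell = (counts > 0).sum(0)
        totals = counts.sum(0)
        q_lo = np.quantile(genes_per_cell, 0.05)
        q_hi = np.quantile(totals, 0.99)
        expected = {
            f"cell{i}"
            for i in range(100)
            if genes_per_cell[i] >= q_lo and totals[i] <= q_hi
        }
        assert set(kept) == expected

    def test_planted_off_curve_cells_removed_exactly(self):
        """500 cells on a smooth genes-vs-UMI relation, 5 planted far off."""
        rng = np.random.default_rng(3)
        n_genes, n_cells = 1500, 505
        umi = np.round(np.exp(rng.uniform(np.log(500), np.log(5000), n_cells)))
        n_expr = np.round(3.0 * umi**0.65 * np.exp(rng.normal(0, 0.02, n_cells)))
        planted = rng.choice(n_cells, 5, replace=False)
        n_expr[planted] = np.round(n_expr[planted] * 0.25)  # far below curve
        counts = np.zeros((n_genes, n_cells), dtype=np.int64)
        for c in range(n_cells):
            k = int(min(n_expr[c], n_genes))
            genes = rng.choice(n_genes, k, replace=False)
            alloc = rng.multinomial(int(umi[c]) - k, np.ones(k) / k)
            counts[genes, c] = 1 + alloc
        cm = build_matrix(counts)
        kept = filter_cells(cm, mito_max=1.0, low_gene_quantile=0,
                            high_umi_quantile=0, outlier_z=3.0)
        removed = set(cm.cells) - set(kept)
        assert removed == {f"cell{i}" for i in planted}

    def test_all_cells_removed_raises(self):
        cm = build_matrix(np.ones((12, 12), dtype=int), mito=np.ones(12, bool))
        with pytest.raises(ValueError, match="every cell"):
            filter_cells(cm, mito_max=0.5, low_gene_quantile=0,
                         high_umi_quantile=0, outlier_z=np.inf)


class TestFilterGenes:
    def test_unexpressed_gene_removed(self):
        counts = np.ones((3, 50), dtype=int)
        counts[1, :] = 0
        cm = build_matrix(counts)
        assert "g1" not in filter_genes(cm)

    def test_exactly_one_percent_kept(self):
        counts = np.zeros((2, 100), dtype=int)
        counts[0, 0] = 5        # 1% of cells: kept (strict less-than removes)
        counts[1, :2] = 5
        cm = build_matrix(counts)
        kept = set(filter_genes(cm, min_cell_fraction=0.01))
        assert kept == {"g0", "g1"}

    def test_kept_set_matches_prevalence_recount(self):
        rng = np.random.default_rng(5)
        counts = (rng.random((1000, 200)) < rng.uniform(0, 0.05, (1000, 1))) * 3
        cm = build_matrix(counts.astype(int))
        kept = set(filter_genes(cm, 0.01))
        recount = {
            f"g{i}"
            for i in range(1000)
            if (counts[i] > 0).sum() / 200 >= 0.01
        }
        assert kept == recount


class TestNormalizeSparseMor:
    def test_identical_cells_get_identical_size_factors(self, rng):
        col = rng.integers(0, 12, size=60)
        col[0] = 4
        counts = np.stack([col, col, col], axis=1)
        nm = normalize_sparse_mor(build_matrix(counts))
        assert np.allclose(nm.size_factors, nm.size_factors[0])
        dense = nm.values.toarray()
        assert np.allclose(dense[:, 0], dense[:, 1])

    def test_single_gene_closed_form(self):
        counts = np.array([[2, 4, 8]])
        nm = normalize_sparse_mor(build_matrix(counts))
        ref = (2 * 4 * 8) ** (1 / 3)
        assert np.allclose(nm.size_factors, np.array([2, 4, 8]) / ref)
        pre_log = 2 ** nm.values.toarray() - 1
        assert np.allclose(pre_log, ref)

    def test_column_scaling_equivariance_with_fixed_reference(self, rng):
        """Tripling one cell's counts against a fixed reference profile
        triples its size factor and leaves normalized values unchanged."""
        for trial in range(10):
            counts = random_sparse_counts(rng)
            cm = build_matrix(counts)
            ref = compute_reference(cm)
            nm = normalize_sparse_mor(cm, reference=ref)
            scaled = counts.copy()
            c = int(rng.integers(counts.shape[1]))
            scaled[:, c] *= 3
            nm3 = normalize_sparse_mor(build_matrix(scaled), reference=ref)
            assert nm3.size_factors[c] == pytest.approx(3 * nm.size_factors[c])
            assert np.allclose(
                nm3.values[:, c].toarray(), nm.values[:, c].toarray()
            )

    def test_column_scaling_bound_with_recomputed_reference(self, rng):
        """With the reference recomputed from the scaled matrix, each
        per-gene reference shifts by 3**(1/m_g), so the scaled cell's size
        factor lies in [3**(1 - 1/m_min) sf, 3 sf]."""
        for trial in range(10):
            counts = random_sparse_counts(rng)
            cm = build_matrix(counts)
            nm = normalize_sparse_mor(cm)
            c = int(rng.integers(counts.shape[1]))
            scaled = counts.copy()
            scaled[:, c] *= 3
            nm3 = normalize_sparse_mor(build_matrix(scaled))
            expressed = np.nonzero(counts[:, c])[0]
            m_min = min((counts[g] > 0).sum() for g in expressed)
            lo = 3.0 ** (1.0 - 1.0 / m_min) * nm.size_factors[c]
            hi = 3.0 * nm.size_factors[c]
            assert lo * (1 - 1e-12) <= nm3.size_factors[c] <= hi * (1 + 1e-12)

    def test_zeros_stay_zero_and_factors_positive(self, rng):
        for trial in range(5):
            counts = random_sparse_counts(rng)
            nm = normalize_sparse_mor(build_matrix(counts))
            assert (nm.size_factors > 0).all()
            dense = nm.values.toarray()
            assert ((dense == 0) == (counts == 0)).all()
            assert (dense >= 0).all()

    def test_all_zero_cell_is_an_error(self):
        counts = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="cell1"):
            normalize_sparse_mor(build_matrix(counts))


def normalized_from_values(values):
    from clonotrace.scqc import NormalizedMatrix

    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return NormalizedMatrix(
        genes=np.array([f"g{i}" for i in range(g)], dtype=object),
        cells=np.array([f"cell{i}" for i in range(c)], dtype=object),
        values=sp.csr_matrix(values),
        size_factors=np.ones(c),
    )


class TestSelectHvg:
    def make_null(self, rng, n_genes=1000, n_cells=120):
        mean = 2.0 ** rng.uniform(-2, 4, n_genes)
        sd = np.sqrt(mean)  # variance follows the mean exactly (Poisson-like)
        vals = np.abs(mean[:, None] + rng.normal(0, 1, (n_genes, n_cells)) * (
            sd[:, None]
        ))
        return mean, vals

    def test_planted_high_variance_genes_recovered(self, rng):
        mean, vals = self.make_null(rng)
        # plant in well-expressed interior genes: folding at zero would eat
        # the inflation for weak genes, and at the extreme right edge of the
        # mean range the spline can bend through an outlier
        planted = rng.choice(
            np.nonzero((mean >= 4) & (mean <= 12))[0], 20, replace=False
        )
        centers = vals[planted].mean(axis=1, keepdims=True)
        vals[planted] = np.abs(
            centers + (vals[planted] - centers) * np.sqrt(10)
        )
        nm = normalized_from_values(vals)
        hvg = set(select_hvg(nm))
        assert {f"g{i}" for i in planted} <= hvg

    def test_null_false_positive_rate_below_one_percent(self, rng):
        _, vals = self.make_null(rng)
        hvg = select_hvg(normalized_from_values(vals))
        assert len(hvg) <= 10  # <= 1% of 1000 genes

    def test_too_few_variable_genes_raises(self):
        vals = np.ones((12, 20))
        with pytest.raises(ValueError):
            select_hvg(normalized_from_values(vals))


class TestKneePoint:
    def test_piecewise_linear_elbow(self):
        v = [100, 90, 80, 79.9, 79.8, 79.7]  # slopes -10 then -0.1, knee at 3
        assert knee_point(v) == 3

    def test_exactly_linear_series_gives_first_index(self):
        assert knee_point([10.0, 8.0, 6.0, 4.0, 2.0]) == 1

    def test_constant_series_warns_and_returns_one(self):
        assert knee_point([5.0] * 6) == 1

    def test_convex_series_matches_brute_force(self):
        values = [1.0 / k for k in range(1, 11)]
        K = len(values)
        x1, y1, xk, yk = 1, values[0], K, values[-1]
        dists = []
        for k, v in enumerate(values, start=1):
            num = abs((yk - y1) * k - (xk - x1) * v + xk * y1 - yk * x1)
            dists.append(num / np.hypot(xk - x1, yk - y1))
        assert knee_point(values) == int(np.argmax(dists)) + 1

    def test_affine_invariance(self, rng):
        for _ in range(20):
            v = np.sort(rng.random(12))[::-1]
            k0 = knee_point(v)
            a, b = float(rng.uniform(0.1, 9)), float(rng.uniform(-5, 5))
            assert knee_point(a * v + b) == k0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            knee_point([3.0, 1.0])


def test_mtx_roundtrip(tmp_path, rng):
    counts = random_sparse_counts(rng, 30, 10)
    genes = [f"MT-{i}" if i < 3 else f"G{i}" for i in range(30)]
    cm = CountMatrix(
        genes=np.array(genes, dtype=object),
        cells=np.array([f"c{i}" for i in range(10)], dtype=object),
        counts=sp.csr_matrix(counts),
        mito=np.array([g.startswith("MT-") for g in genes]),
    )
    cm.to_mtx(tmp_path / "m.mtx", tmp_path / "genes.txt", tmp_path / "cells.txt")
    back = CountMatrix.from_mtx(
        tmp_path / "m.mtx", tmp_path / "genes.txt", tmp_path / "cells.txt"
    )
    assert (back.counts.toarray() == counts).all()
    assert back.mito.sum() == 3
    assert list(back.genes) == genes
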