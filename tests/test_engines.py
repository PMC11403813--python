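import numpy as np
import pytest

from ccnet.engines import (
    METHOD_TAGS,
    complex_expression,
    permutation_pvalues,
    run_all_engines,
    run_engine,
    score_cellchat_like,
    score_cellphonedb_like,
    score_celltalker_like,
)
from ccnet.errors import GeneLookupError
from ccnet.lrdb import GeneComplex, LRDatabase
from ccnet.preprocess import (
    CellAnnotation,
    NormalizedMatrix,
    TypeSummary,
    log_transform,
    normalize_library_size,
)
from ccnet.synthetic import generate_dataset, standard_spec

from conftest import pair


def make_summary(mean_expr, expr_fraction, genes, types):
    mean_expr = np.asarray(mean_expr, float)
    return TypeSummary(
        cell_types=list(types),
        gene_names=list(genes),
        mean_expr=mean_expr,
        expr_fraction=np.asarray(expr_fraction, float),
        cells_per_type=np.full(len(types), 10),
    )


@pytest.fixture
def summary2x4():
    # types A, B; genes L1 R1 X Y
    return make_summary(
        mean_expr=[[2.0, 3.0, 4.0, 1.0], [0.5, 0.2, 9.0, 1.0]],
        expr_fraction=[[0.5, 0.9, 1.0, 0.3], [0.05, 0.2, 1.0, 0.3]],
        genes=["L1", "R1", "X", "Y"],
        types=["A", "B"],
    )


class TestComplexExpression:
    def test_geometric_two_subunits(self, summary2x4):
        cx = GeneComplex.from_token("X&Y")
        assert complex_expression(summary2x4, cx, "A", "geometric") == pytest.approx(2.0)

    def test_minimum_two_subunits(self, summary2x4):
        cx = GeneComplex.from_token("L1&R1")
        assert complex_expression(summary2x4, cx, "B", "minimum") == pytest.approx(0.2)

    def test_single_subunit_same_under_both_modes(self, summary2x4):
        cx = GeneComplex.from_token("R1")
        for mode in ("geometric", "minimum"):
            assert complex_expression(summary2x4, cx, "A", mode) == pytest.approx(3.0)

    def test_missing_gene_raises(self, summary2x4):
        with pytest.raises(GeneLookupError, match="NOPE"):
            complex_expression(
                summary2x4, GeneComplex.from_token("NOPE"), "A", "geometric"
            )

    def test_missing_type_raises(self, summary2x4):
        with pytest.raises(GeneLookupError, match="C"):
            complex_expression(
                summary2x4, GeneComplex.from_token("X"), "C", "geometric"
            )


class TestScorers:
    def test_cellchat_product(self, summary2x4):
        db = LRDatabase([pair("L1", "R1")])
        s = score_cellchat_like(summary2x4, db)
        # score[A, A] = 2 * 3
        assert s[0, 0, 0] == pytest.approx(6.0)
        # score[A, B] = 2 * 0.2
        assert s[0, 1, 0] == pytest.approx(0.4)

    def test_cellchat_zero_absorbing(self):
        summary = make_summary([[0.0, 5.0]], [[0.0, 1.0]], ["L1", "R1"], ["A"])
        db = LRDatabase([pair("L1", "R1")])
        assert score_cellchat_like(summary, db)[0, 0, 0] == 0.0

    def test_cellchat_complex_geometric(self):
        # ligand complex means (4, 1) -> 2; receptor complex (9, 1) -> 3
        summary = make_summary(
            [[4.0, 1.0, 9.0, 1.0]], [[1.0] * 4], ["LA", "LB", "RA", "RB"], ["A"]
        )
        db = LRDatabase([pair("LA&LB", "RA&RB")])
        assert score_cellchat_like(summary, db)[0, 0, 0] == pytest.approx(6.0)

    def test_cellphonedb_mean_of_minima(self, summary2x4):
        db = LRDatabase([pair("L1", "R1")])
        s = score_cellphonedb_like(summary2x4, db)
        assert s[0, 0, 0] == pytest.approx(0.5 * (2.0 + 3.0))

    def test_cellphonedb_min_then_average(self):
        # receptor subunit means (0.5, 0.2), ligand mean 0.8 -> 0.5*(0.8+0.2)
        summary = make_summary(
            [[0.8, 0.5, 0.2]], [[1.0] * 3], ["L", "RA", "RB"], ["A"]
        )
        db = LRDatabase([pair("L", "RA&RB")])
        assert score_cellphonedb_like(summary, db)[0, 0, 0] == pytest.approx(0.5)

    def test_celltalker_threshold_masks(self, summary2x4):
        db = LRDatabase([pair("L1", "R1")])
        scores, tested = score_celltalker_like(summary2x4, db, min_fraction=0.1)
        # ligand fraction in B is 0.05 < 0.1 -> B cannot send
        assert tested[0, 0, 0] and tested[0, 1, 0]
        assert not tested[1, 0, 0] and not tested[1, 1, 0]
        np.testing.assert_allclose(scores, score_cellchat_like(summary2x4, db))

    def test_celltalker_zero_threshold_tests_all(self, summary2x4):
        db = LRDatabase([pair("L1", "R1")])
        _, tested = score_celltalker_like(summary2x4, db, min_fraction=0.0)
        assert tested.all()

    def test_celltalker_only_aa_tested(self):
        # fractions {A: 0.5, B: 0.05} for both genes, threshold 0.1
        summary = make_summary(
            [[1.0, 1.0], [1.0, 1.0]],
            [[0.5, 0.5], [0.05, 0.05]],
            ["L", "R"], ["A", "B"],
        )
        db = LRDatabase([pair("L", "R")])
        _, tested = score_celltalker_like(summary, db, min_fraction=0.1)
        assert tested[0, 0, 0]
        assert tested.sum() == 1

    def test_monotone_in_subunit_mean(self, summary2x4):
        db = LRDatabase([pair("L1", "R1")])
        lo_chat = score_cellchat_like(summary2x4, db)
        lo_pdb = score_cellphonedb_like(summary2x4, db)
        bumped = make_summary(
            summary2x4.mean_expr + np.array([[1.0, 0, 0, 0], [0, 0, 0, 0]]),
            summary2x4.expr_fraction,
            summary2x4.gene_names,
            summary2x4.cell_types,
        )
        assert (score_cellchat_like(bumped, db) >= lo_chat).all()
        assert (score_cellphonedb_like(bumped, db) >= lo_pdb).all()


def _null_fixture(n_types=2, cells_per_type=30, n_genes=20, n_pairs=4, seed=0):
    spec = standard_spec(
        n_cell_types=n_types, cells_per_type=cells_per_type, n_genes=n_genes,
        n_channels=0, n_decoy_pairs=n_pairs, seed=seed,
    )
    X, ann, db, truth = generate_dataset(spec)
    Xlog = log_transform(normalize_library_size(X))
    return Xlog, ann, db, truth


class TestPermutations:
    def test_constant_matrix_gives_p_one(self):
        vals = np.full((3, 8), np.log(2.0))
        Xlog = NormalizedMatrix(vals, ["L", "R", "Z"],
                                [f"c{i}" for i in range(8)], stage="log")
        ann = CellAnnotation.from_pairs(
            [(f"c{i}", "A" if i < 4 else "B") for i in range(8)]
        )
        db = LRDatabase([pair("L", "R")])
        for tag in METHOD_TAGS:
            p = permutation_pvalues(Xlog, ann, db, tag, n_perm=50, seed=1)
            np.testing.assert_allclose(p[~np.isnan(p)], 1.0)

    def test_extreme_case_min_p(self):
        # one gene pair wildly higher in A than anywhere else; with few cells
        # some shuffles may tie, so force separation with huge values
        vals = np.zeros((2, 40))
        vals[:, :20] = 10.0
        Xlog = NormalizedMatrix(vals, ["L", "R"],
                                [f"c{i}" for i in range(40)], stage="log")
        ann = CellAnnotation.from_pairs(
            [(f"c{i}", "A" if i < 20 else "B") for i in range(40)]
        )
        db = LRDatabase([pair("L", "R")])
        res = run_engine("cellchat_like", Xlog, ann, db, n_perm=99, seed=2)
        assert res.pvalues[0, 0, 0] == pytest.approx(1 / 100)

    def test_pvalues_on_addone_grid(self):
        Xlog, ann, db, _ = _null_fixture()
        res = run_engine("cellchat_like", Xlog, ann, db, n_perm=19, seed=3)
        p = res.pvalues[res.tested]
        grid = np.arange(1, 21) / 20.0
        assert np.isin(np.round(p, 12), np.round(grid, 12)).all()

    def test_n_perm_zero_rejected(self):
        Xlog, ann, db, _ = _null_fixture()
        with pytest.raises(ValueError):
            run_engine("cellchat_like", Xlog, ann, db, n_perm=0, seed=0)

    def test_null_calibration_500_entries(self):
        # 5 types x 20 decoy pairs = 500 null entries
        spec = standard_spec(
            n_cell_types=5, cells_per_type=60, n_genes=100, n_channels=0,
            n_decoy_pairs=20, seed=42,
        )
        X, ann, db, _ = generate_dataset(spec)
        Xlog = log_transform(normalize_library_size(X))
        for res in run_all_engines(Xlog, ann, db, n_perm=100, seed=7):
            frac = float((res.pvalues[res.tested] <= 0.05).mean())
            # binomial 99% band around 0.05 at n = 500
            assert 0.0249 <= frac <= 0.0752, res.method


class TestRunEngine:
    def test_determinism(self):
        Xlog, ann, db, _ = _null_fixture()
        a = run_engine("cellphonedb_like", Xlog, ann, db, n_perm=25, seed=9)
        b = run_engine("cellphonedb_like", Xlog, ann, db, n_perm=25, seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.pvalues, b.pvalues)

    def test_shared_permutation_stream(self):
        # a single-engine run must see the same shuffles as the joint run
        Xlog, ann, db, _ = _null_fixture()
        joint = run_all_engines(Xlog, ann, db, n_perm=25, seed=9)
        solo = run_engine("celltalker_like", Xlog, ann, db, n_perm=25, seed=9)
        ref = next(r for r in joint if r.method == "celltalker_like")
        np.testing.assert_array_equal(solo.pvalues, ref.pvalues)

    def test_unknown_tag_rejected(self):
        Xlog, ann, db, _ = _null_fixture()
        with pytest.raises(ValueError):
            run_engine("not_a_method", Xlog, ann, db, n_perm=5, seed=0)

    def test_shape_contract(self):
        spec = standard_spec(
            n_cell_types=3, cells_per_type=20, n_genes=20, n_channels=0,
            n_decoy_pairs=2, seed=1,
        )
        X, ann, db, _ = generate_dataset(spec)
        Xlog = log_transform(normalize_library_size(X))
        res = run_engine("cellchat_like", Xlog, ann, db, n_perm=5, seed=0)
        assert res.scores.shape == (3, 3, 2)

    def test_min_fraction_one_masks_everything(self):
        Xlog, ann, db, _ = _null_fixture()
        assert (Xlog.values == 0).any()
        res = run_engine("celltalker_like", Xlog, ann, db, n_perm=5, seed=0,
                         min_fraction=1.0)
        assert not res.tested.all()

    def test_cell_order_invariance(self):
        Xlog, ann, db, _ = _null_fixture()
        order = np.random.default_rng(4).permutation(Xlog.n_cells)
        shuffled = NormalizedMatrix(
            Xlog.values[:, order],
            Xlog.gene_names,
            [Xlog.cell_barcodes[i] for i in order],
            stage="log",
        )
        for tag in METHOD_TAGS:
            a = run_engine(tag, Xlog, ann, db, n_perm=1, seed=0)
            b = run_engine(tag, shuffled, ann, db, n_perm=1, seed=0)
            np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_planted_channels_hit_min_p(self):
        spec = standard_spec(
            n_cell_types=5, cells_per_type=100, n_genes=200, n_channels=10,
            fold=8.0, n_decoy_pairs=10, seed=21,
        )
        X, ann, db, truth = generate_dataset(spec)
        Xlog = log_transform(normalize_library_size(X))
        results = run_all_engines(Xlog, ann, db, n_perm=200, seed=13)
        pair_pos = {pid: i for i, pid in enumerate(results[0].pair_ids)}
        type_pos = {t: i for i, t in enumerate(results[0].cell_types)}
        min_p = 1.0 / 201
        for res in results:
            hits = 0
            for s, r, pid in truth.planted:
                e = (type_pos[s], type_pos[r], pair_pos[pid])
                if res.tested[e] and res.pvalues[e] <= min_p + 1e-12:
                    hits += 1
            assert hits >= 0.9 * len(truth.planted), res.method
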