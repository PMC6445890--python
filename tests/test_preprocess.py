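import numpy as np
import pandas as pd
import pytest

from autoborutarf import preprocess as pp
from autoborutarf.core_io import FeatureMatrix, ResponseTable
from autoborutarf.preprocess import (NeighborSet, cell_distance,
                                     filter_missing, find_neighbors,
                                     impute_all, impute_binary, impute_real)


def _fm(arr, cells, feats, kind="cna"):
    return FeatureMatrix(pd.DataFrame(arr, index=cells, columns=feats), kind)


def _expr(n_cells, seed=0):
    rng = np.random.default_rng(seed)
    cells = [f"c{i}" for i in range(n_cells)]
    return _fm(rng.standard_normal((n_cells, 4)), cells,
               [f"e{j}" for j in range(4)], "expression")


class TestFilterMissing:
    def test_strictly_more_than_threshold_removes_column(self):
        cells = ["c0", "c1", "c2", "c3"]
        arr = np.ones((4, 2))
        arr[0:3, 0] = np.nan  # 75% missing -> dropped
        arr[0:2, 1] = np.nan  # 50% missing -> kept (strict rule)
        feats = {"expression": _expr(4), "cna": _fm(arr, cells, ["a", "b"])}
        resp = ResponseTable(pd.DataFrame([[1.0, 2, 3, 4]], index=["d"],
                                          columns=cells))
        kept, _, report = filter_missing(feats, resp)
        assert kept["cna"].feature_ids == ["b"]
        assert report["features"] == ["cna:a"]

    def test_features_dropped_before_cells(self):
        # cell c0 is missing in both cna columns; one column is itself 75%
        # missing and goes first, after which c0 is only 50% missing and stays
        cells = ["c0", "c1", "c2", "c3"]
        arr = np.ones((4, 2))
        arr[:3, 0] = np.nan
        arr[0, 1] = np.nan
        feats = {"expression": _expr(4), "cna": _fm(arr, cells, ["a", "b"])}
        resp = ResponseTable(pd.DataFrame([[1.0, 2, 3, 4]], index=["d"],
                                          columns=cells))
        kept, resp2, report = filter_missing(feats, resp,
                                             joint_cell_filter=False)
        assert report["cells"] == []
        assert kept["cna"].cell_line_ids == cells

    def test_toy_grid_matches_hand_enumeration(self):
        # 6 cells x 6 cna features with a hand-checked pattern
        cells = [f"c{i}" for i in range(6)]
        feats_ids = list("abcdef")
        arr = np.ones((6, 6))
        arr[0:4, 0] = np.nan          # a: 4/6 missing -> drop
        arr[0:3, 1] = np.nan          # b: with c5's row, 4/6 -> drop
        arr[0, 2] = np.nan            # c: 2/6 -> keep
        arr[5, 1:6] = np.nan          # c5 missing in b..f
        feats = {"expression": _expr(6), "cna": _fm(arr, cells, feats_ids)}
        ic50 = pd.DataFrame([[np.nan, 1, 2, 3, 4, np.nan]], index=["d"],
                            columns=cells)
        kept, resp, report = filter_missing(feats, ResponseTable(ic50))
        assert report["features"] == ["cna:a", "cna:b"]
        # per-cell entries: 4 surviving cna + 1 ic50 = 5
        # c5: missing c,d,e,f + ic50 = 5/5 -> dropped
        # c0: missing c + ic50 = 2/5 -> kept
        assert report["cells"] == ["c5"]
        assert kept["cna"].feature_ids == ["c", "d", "e", "f"]
        assert kept["cna"].cell_line_ids == cells[:5]
        assert resp.cell_line_ids == cells[:5]

    def test_idempotent(self, holey_dataset):
        kept, resp, _ = filter_missing(holey_dataset.features,
                                       holey_dataset.response)
        kept2, resp2, report2 = filter_missing(kept, resp)
        assert all(kept2[k].equals(kept[k]) for k in kept)
        assert resp2.equals(resp)
        assert report2 == {"features": [], "drugs": [], "cells": []}


class TestDistance:
    def test_identical_rows_zero(self):
        fm = _fm([[1.0, 2.0], [1.0, 2.0]], ["c1", "c2"], ["e1", "e2"],
                 "expression")
        assert cell_distance("c1", "c2", fm) == 0.0

    def test_hand_value(self):
        fm = _fm([[0.0, 0.0], [1.0, 2.0]], ["c1", "c2"], ["e1", "e2"],
                 "expression")
        assert cell_distance("c1", "c2", fm) == 5.0  # 1^2 + 2^2

    def test_matches_brute_force_loop(self):
        fm = _expr(5, seed=3)
        dm = pp.distance_matrix(fm)
        for a in fm.cell_line_ids:
            for b in fm.cell_line_ids:
                expected = sum(
                    (fm.values.loc[a, g] - fm.values.loc[b, g]) ** 2
                    for g in fm.feature_ids)
                assert dm.loc[a, b] == pytest.approx(expected, abs=1e-12)
                assert dm.loc[a, b] == pytest.approx(dm.loc[b, a])


class TestNeighbors:
    def test_truncation_warns_and_returns_all(self, caplog):
        fm = _expr(4)
        ns = find_neighbors("c0", K=10, expression=fm,
                            candidates=["c1", "c2", "c3"])
        assert len(ns.neighbor_ids) == 3

    def test_k_smallest(self):
        fm = _fm([[0.0], [1.0], [2.0], [3.0], [4.0]],
                 [f"c{i}" for i in range(5)], ["e"], "expression")
        ns = find_neighbors("c0", K=2, expression=fm,
                            candidates=["c1", "c2", "c3", "c4"])
        assert ns.neighbor_ids == ["c1", "c2"]
        np.testing.assert_allclose(ns.distances, [1.0, 4.0])

    def test_tie_broken_by_stable_order(self):
        fm = _fm([[0.0], [1.0], [-1.0], [2.0]], ["c0", "c1", "c2", "c3"],
                 ["e"], "expression")
        ns = find_neighbors("c0", K=1, expression=fm,
                            candidates=["c1", "c2", "c3"])
        assert ns.neighbor_ids == ["c1"]  # d=1 tie with c2; input order wins

    def test_zero_candidates_error(self):
        fm = _expr(2)
        with pytest.raises(pp.ImputationError):
            find_neighbors("c0", K=3, expression=fm, candidates=["c0"])


class TestImputeEntry:
    def _ns(self, dists):
        return NeighborSet("c", [f"n{i}" for i in range(len(dists))],
                           np.asarray(dists, float))

    @pytest.mark.parametrize("mode", ["as_printed", "inverse_distance"])
    def test_constant_values_invariant(self, mode):
        ns = self._ns([1.0, 2.0, 7.0])
        assert impute_real([5.0, 5.0, 5.0], ns, mode) == pytest.approx(5.0)

    def test_as_printed_weights_farther_more(self):
        ns = self._ns([1.0, 3.0])
        assert impute_real([10.0, 20.0], ns, "as_printed") == pytest.approx(17.5)

    def test_inverse_distance_weights_nearer_more(self):
        ns = self._ns([1.0, 3.0])
        got = impute_real([10.0, 20.0], ns, "inverse_distance")
        assert got == pytest.approx(12.5, abs=1e-6)

    def test_binary_majority_and_ties(self):
        ns7 = self._ns([1.0] * 10)
        assert impute_binary([1] * 7 + [0] * 3, ns7) == 1
        assert impute_binary([1] * 5 + [0] * 5, ns7) == 0  # tie -> 0
        assert impute_binary([0] * 10, ns7) == 0

    def test_empty_neighbors_error(self):
        ns = NeighborSet("c", [], np.array([]))
        with pytest.raises(pp.ImputationError):
            impute_real([1.0], ns)


def _entrywise_oracle(features, response, K, mode):
    """Independent per-entry reimplementation of the KNN imputation."""
    expr = features["expression"]
    filled = {}
    for kind, fm in features.items():
        if kind == "expression":
            filled[kind] = fm.values.copy()
            continue
        out = fm.values.copy()
        for g in fm.values.columns:
            for c in fm.values.index:
                if not np.isnan(fm.values.loc[c, g]):
                    continue
                obs = [k for k in fm.values.index
                       if k != c and not np.isnan(fm.values.loc[k, g])]
                d = np.array([cell_distance(c, k, expr) for k in obs])
                order = np.argsort(d, kind="stable")[:K]
                ns = NeighborSet(c, [obs[i] for i in order], d[order])
                vals = [fm.values.loc[n, g] for n in ns.neighbor_ids]
                out.loc[c, g] = (impute_binary(vals, ns) if kind == "snv"
                                 else impute_real(vals, ns, mode))
        filled[kind] = out
    orig = response.ic50
    resp = orig.copy()
    for drug in resp.index:
        for c in resp.columns:
            if not np.isnan(orig.loc[drug, c]):
                continue
            obs = [k for k in orig.columns
                   if k != c and not np.isnan(orig.loc[drug, k])]
            d = np.array([cell_distance(c, k, expr) for k in obs])
            order = np.argsort(d, kind="stable")[:K]
            ns = NeighborSet(c, [obs[i] for i in order], d[order])
            vals = [orig.loc[drug, n] for n in ns.neighbor_ids]
            resp.loc[drug, c] = impute_real(vals, ns, mode)
    return filled, resp


class TestImputeAll:
    def test_no_missing_is_identity(self, small_dataset):
        feats, resp = impute_all(small_dataset.features,
                                 small_dataset.response)
        for kind in feats:
            assert feats[kind].equals(small_dataset.features[kind])
        assert resp.equals(small_dataset.response)

    @pytest.mark.parametrize("mode", ["as_printed", "inverse_distance"])
    def test_matches_entrywise_oracle(self, holey_dataset, mode):
        feats, resp = impute_all(holey_dataset.features,
                                 holey_dataset.response, K=10,
                                 weight_mode=mode)
        efeats, eresp = _entrywise_oracle(holey_dataset.features,
                                          holey_dataset.response, 10, mode)
        for kind in feats:
            np.testing.assert_allclose(feats[kind].values.to_numpy(),
                                       efeats[kind].to_numpy(), atol=1e-12)
        np.testing.assert_allclose(resp.ic50.to_numpy(), eresp.to_numpy(),
                                   atol=1e-12)

    def test_observed_untouched_and_complete(self, holey_dataset):
        feats, resp = impute_all(holey_dataset.features,
                                 holey_dataset.response)
        for kind, fm in feats.items():
            orig = holey_dataset.features[kind]
            assert fm.n_missing == 0
            obs = ~orig.values.isna()
            pd.testing.assert_frame_equal(fm.values[obs], orig.values[obs])
        assert not resp.ic50.isna().any().any()

    def test_snv_stays_binary(self, holey_dataset):
        feats, _ = impute_all(holey_dataset.features, holey_dataset.response)
        assert set(np.unique(feats["snv"].values.to_numpy())) <= {0.0, 1.0}

    def test_imputed_real_within_neighbor_range(self, holey_dataset):
        feats, resp = impute_all(holey_dataset.features,
                                 holey_dataset.response)
        orig = holey_dataset.features["cna"].values
        filled = feats["cna"].values
        for g in orig.columns:
            col = orig[g]
            lo, hi = col.min(), col.max()
            for c in col.index[col.isna()]:
                assert lo - 1e-12 <= filled.loc[c, g] <= hi + 1e-12
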