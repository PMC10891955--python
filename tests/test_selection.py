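import numpy as np
import pandas as pd
import pytest

import nichecast as nc
from nichecast.grids import EnvGrid, GridGeometry, InputError, OccurrenceRecord, OccurrenceSet, locate_cells
from nichecast.selection import TieError, pearson_at_presences, select_variables


def _brute_force(corr: pd.DataFrame, contrib: pd.Series, r_thr=0.7, min_c=1.0):
    """Independent re-statement of the two rules, pair by pair."""
    names = list(corr.columns)
    stage_a = []
    for v in names:
        doomed = any(
            contrib[u] > contrib[v] and abs(corr.loc[u, v]) > r_thr
            for u in names if u != v
        )
        if not doomed:
            stage_a.append(v)
    return {v for v in stage_a if contrib[v] > min_c}


class TestSelectVariables:
    def test_reference_tables_reproduce_published_kept_set(self, reference_tables):
        rep = select_variables(reference_tables.matrix,
                               reference_tables.contributions_initial)
        assert rep.kept == ["bio11", "bio13", "bio14"]
        assert rep.dropped["bio3"]["partner"] == "bio11"
        assert rep.dropped["bio3"]["r"] == 0.95
        assert rep.dropped["bio18"] == {"reason": "low_contribution", "percent": 0.6}

    def test_greedy_inconsistent_variable_dropped_through_its_dominator(self, reference_tables):
        # bio2 (1.3%) is only weakly correlated with the final trio but is
        # eliminated by bio20 (4%, |r| = 0.92) under the all-pairs rule
        rep = select_variables(reference_tables.matrix,
                               reference_tables.contributions_initial)
        assert rep.dropped["bio2"]["partner"] == "bio20"
        assert rep.dropped["bio2"]["r"] == 0.92

    def test_signed_comparison_would_change_the_outcome(self, reference_tables):
        """Regression guard for the |r| convention: with signed r, bio4
        (r = -0.96 with bio11) would survive the correlation filter."""
        corr = reference_tables.matrix
        contrib = reference_tables.contributions_initial
        signed_kept = set()
        for v in corr.columns:
            doomed = any(contrib[u] > contrib[v] and corr.loc[u, v] > 0.7
                         for u in corr.columns if u != v)
            if not doomed and contrib[v] > 1.0:
                signed_kept.add(v)
        assert "bio4" in signed_kept  # signed rule fails to drop it
        rep = select_variables(corr, contrib)
        assert "bio4" not in rep.kept

    def test_identity_matrix_keeps_all_above_threshold(self):
        names = ["a", "b", "c"]
        corr = pd.DataFrame(np.eye(3), index=names, columns=names)
        rep = select_variables(corr, {"a": 50.0, "b": 30.0, "c": 20.0})
        assert rep.kept == ["a", "b", "c"]

    def test_matches_brute_force_on_random_instances(self, rng):
        names = ["v1", "v2", "v3", "v4"]
        for _ in range(200):
            a = rng.uniform(-1, 1, size=(4, 4))
            corr = (a + a.T) / 2
            np.fill_diagonal(corr, 1.0)
            corr = pd.DataFrame(corr, index=names, columns=names)
            contrib = pd.Series(rng.choice(np.arange(0.0, 40.0, 0.1), size=4,
                                           replace=False), index=names)
            rep = select_variables(corr, contrib)
            assert set(rep.kept) == _brute_force(corr, contrib)

    def test_order_independence(self, reference_tables, rng):
        base = select_variables(reference_tables.matrix,
                                reference_tables.contributions_initial).kept
        names = list(reference_tables.matrix.columns)
        for _ in range(20):
            perm = list(rng.permutation(names))
            rep = select_variables(reference_tables.matrix.loc[perm, perm],
                                   reference_tables.contributions_initial)
            assert sorted(rep.kept) == sorted(base)

    def test_no_kept_pair_violates_threshold(self, reference_tables):
        rep = select_variables(reference_tables.matrix,
                               reference_tables.contributions_initial)
        for a in rep.kept:
            for b in rep.kept:
                if a != b:
                    assert abs(reference_tables.matrix.loc[a, b]) <= 0.7

    def test_decision_relevant_tie_raises(self):
        names = ["a", "b", "c"]
        corr = pd.DataFrame([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]],
                            index=names, columns=names)
        with pytest.raises(TieError):
            select_variables(corr, {"a": 10.0, "b": 10.0, "c": 5.0})

    def test_irrelevant_tie_passes(self):
        # the tied pair (a, b) is wiped out by d anyway
        names = ["a", "b", "d"]
        corr = pd.DataFrame([[1.0, 0.9, 0.8], [0.9, 1.0, 0.8], [0.8, 0.8, 1.0]],
                            index=names, columns=names)
        rep = select_variables(corr, {"a": 10.0, "b": 10.0, "d": 30.0})
        assert rep.kept == ["d"]

    def test_missing_contribution_rejected(self):
        corr = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(InputError):
            select_variables(corr, {"a": 10.0})


class TestPearsonAtPresences:
    def _world(self, values, n=5):
        geo = GridGeometry(n_rows=n, n_cols=n, x_origin=0, y_origin=n, cell_size=1.0)
        grid = EnvGrid(geo, [f"b{i}" for i in range(values.shape[0])], values,
                       np.zeros((n, n), dtype=bool))
        occ = OccurrenceSet([OccurrenceRecord(c + 0.5, n - r - 0.5)
                             for r in range(n) for c in range(n)])
        return grid, locate_cells(occ, geo)

    def test_self_correlation_is_one(self, rng):
        vals = rng.normal(size=(2, 5, 5))
        grid, occ = self._world(vals)
        corr = pearson_at_presences(grid, occ)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_perfect_anticorrelation(self, rng):
        x = rng.normal(size=(5, 5))
        grid, occ = self._world(np.stack([x, -x]))
        corr = pearson_at_presences(grid, occ)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        grid, occ = self._world(np.stack([x.reshape(5, 5), y.reshape(5, 5)]))
        r = pearson_at_presences(grid, occ).iloc[0, 1]
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_computed_at_presences_not_all_cells(self, rng):
        # correlation differs between the presence subset and the full grid
        vals = rng.normal(size=(2, 6, 6))
        geo = GridGeometry(n_rows=6, n_cols=6, x_origin=0, y_origin=6, cell_size=1.0)
        grid = EnvGrid(geo, ["a", "b"], vals, np.zeros((6, 6), dtype=bool))
        occ = locate_cells(OccurrenceSet(
            [OccurrenceRecord(c + 0.5, 5.5) for c in range(6)]), geo)  # top row only
        r_pres = pearson_at_presences(grid, occ).iloc[0, 1]
        top = vals[:, 0, :]
        oracle = np.corrcoef(top[0], top[1])[0, 1]
        assert r_pres == pytest.approx(oracle, abs=1e-12)

    def test_too_few_records_rejected(self, rng):
        vals = rng.normal(size=(2, 5, 5))
        grid, occ = self._world(vals)
        occ.records = occ.records[:2]
        with pytest.raises(InputError):
            pearson_at_presences(grid, occ)

    def test_zero_variance_variable_warns(self):
        vals = np.stack([np.arange(25.0).reshape(5, 5), np.full((5, 5), 7.0)])
        grid, occ = self._world(vals)
        with pytest.warns(UserWarning, match="zero variance"):
            corr = pearson_at_presences(grid, occ)
        assert corr.loc["b1", "b0"] == 0.0
        assert corr.loc["b1", "b1"] == 1.0
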