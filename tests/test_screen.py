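"""Disruption calls, the hypergeometric tail, and the screen matrix."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom as scipy_hypergeom

from clustercoherence.genome import detect_clusters
from clustercoherence.screen import (
    ExpressionCompendium,
    call_disrupted,
    group_mutants,
    hypergeom_tail,
    load_compendium,
    screen,
    transform_deviation,
)

from conftest import family, make_annotation


def brute_force_upper_tail(N, K, m, x):
    """Enumeration oracle: exact-integer sum of the hypergeometric upper tail."""
    num = sum(
        math.comb(K, j) * math.comb(N - K, m - j)
        for j in range(x, min(K, m) + 1)
        if m - j <= N - K
    )
    return num / math.comb(N, m)


# ---------------------------------------------------------------------------
# disruption calls
# ---------------------------------------------------------------------------

class TestCallDisrupted:
    def setup_method(self):
        self.comp = ExpressionCompendium(
            pd.DataFrame(
                {"gene1": [1.5], "gene2": [-0.2], "gene3": [-2.0], "gene4": [np.nan]},
                index=["mutA"],
            )
        )

    def test_threshold_rule_and_missing_exclusion(self):
        calls = call_disrupted(self.comp, "mutA", threshold=1.0)
        assert calls.disrupted == {"gene1", "gene3"}
        assert calls.n_measured == 3
        assert calls.K == 2

    def test_extreme_threshold_gives_no_calls(self):
        assert call_disrupted(self.comp, "mutA", threshold=10.0).K == 0

    def test_all_missing_row_warns(self, caplog):
        comp = ExpressionCompendium(
            pd.DataFrame({"g": [np.nan], "h": [np.nan]}, index=["m"])
        )
        with caplog.at_level("WARNING"):
            calls = call_disrupted(comp, "m")
        assert (calls.n_measured, calls.K) == (0, 0)
        assert any("no measured" in r.message for r in caplog.records)

    def test_unknown_mutant_raises(self):
        with pytest.raises(KeyError):
            call_disrupted(self.comp, "nope")

    def test_top_fraction_mode(self):
        calls = call_disrupted(self.comp, "mutA", top_fraction=1 / 3)
        assert calls.disrupted == {"gene3"}


def test_load_compendium_missing_cells(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("gene\tm1\tm2\ng1\t1.5\t\ng2\t-0.2\t0.4\n")
    comp = load_compendium(p)
    assert comp.mutants == ["m1", "m2"]
    assert np.isnan(comp.values.loc["m2", "g1"])


# ---------------------------------------------------------------------------
# hypergeometric tail
# ---------------------------------------------------------------------------

class TestHypergeomTail:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((20, 6, 5, 0), 1.0),  # P(X >= 0) is certain
            ((20, 20, 5, 5), 1.0),  # everything disrupted forces x = m
            ((20, 0, 5, 1), 0.0),  # no disrupted genes at all
        ],
    )
    def test_forced_values(self, args, expected):
        assert hypergeom_tail(*args) == expected

    def test_matches_enumeration_oracle(self):
        val = hypergeom_tail(20, 6, 5, 3)
        assert val == pytest.approx(brute_force_upper_tail(20, 6, 5, 3), abs=1e-14)

    def test_agrees_with_enumeration_small_n(self):
        """Exhaustive sweep for N <= 12 (the full N <= 30 sweep runs in CI-grade checks)."""
        for N in range(13):
            for K in range(N + 1):
                for m in range(N + 1):
                    for x in range(m + 1):
                        assert hypergeom_tail(N, K, m, x) == pytest.approx(
                            brute_force_upper_tail(N, K, m, x), abs=1e-12
                        )

    def test_agrees_with_scipy_large_n(self):
        for args in [(100000, 5000, 300, 30), (10000, 100, 50, 5)]:
            assert hypergeom_tail(*args) == pytest.approx(
                float(scipy_hypergeom.sf(args[3] - 1, args[0], args[1], args[2])),
                rel=1e-9,
            )

    def test_lower_tail_complements_upper(self):
        up = hypergeom_tail(30, 10, 8, 4)
        lo = hypergeom_tail(30, 10, 8, 3, tail="lower")
        assert up + lo == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "args", [(10, 11, 5, 1), (10, 5, 11, 1), (10, 5, 5, 6), (10, 5, 5, -1)]
    )
    def test_invalid_arguments_never_clamped(self, args):
        with pytest.raises(ValueError):
            hypergeom_tail(*args)

    @given(
        N=st.integers(5, 40),
        data=st.data(),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_in_x(self, N, data):
        K = data.draw(st.integers(0, N))
        m = data.draw(st.integers(1, N))
        x = data.draw(st.integers(1, m))
        assert hypergeom_tail(N, K, m, x) <= hypergeom_tail(N, K, m, x - 1) + 1e-12


def test_transform_deviation():
    assert transform_deviation(1.0) == 0.0
    assert transform_deviation(0.05) == pytest.approx(0.95)
    assert transform_deviation(0.0) == 1.0
    with pytest.raises(ValueError):
        transform_deviation(1.5)


# ---------------------------------------------------------------------------
# the screen
# ---------------------------------------------------------------------------

def toy_screen_inputs(n_genes=100, seed=0):
    """100-gene genome, two families each with one planted cluster."""
    ann = make_annotation(n_genes)
    fam_c = family("clustered_fam", "g010", "g011", "g012", "g050", "g070")
    fam_o = family("other_fam", "g020", "g021", "g040", "g060", "g080")
    parts = [detect_clusters(ann, fam_c), detect_clusters(ann, fam_o)]
    return ann, parts


class TestScreen:
    def test_exact_cluster_hit_matches_enumeration(self):
        ann, parts = toy_screen_inputs()
        values = pd.DataFrame(
            np.zeros((1, 100)), index=["mut0"], columns=ann.gene_ids
        )
        values.loc["mut0", ["g010", "g011", "g012"]] = 2.5  # K = 3, all clustered
        comp = ExpressionCompendium(values)
        mat = screen(comp, parts, threshold=1.0)
        cell = mat.table.set_index("family").loc["clustered_fam"]
        assert (cell.N, cell.K, cell.m, cell.x) == (100, 3, 3, 3)
        assert cell.P == pytest.approx(
            math.comb(3, 3) * math.comb(97, 0) / math.comb(100, 3), abs=1e-15
        )
        # no disrupted gene touches the other family's cluster: P = 1, score = 0
        other = mat.table.set_index("family").loc["other_fam"]
        assert other.P == 1.0 and other.score == 0.0

    def test_all_singleton_family_is_not_applicable(self):
        ann, _ = toy_screen_inputs()
        fam_s = family("no_cluster_fam", "g020", "g040", "g060")
        part = detect_clusters(ann, fam_s)
        comp = ExpressionCompendium(
            pd.DataFrame(np.zeros((1, 100)), index=["m"], columns=ann.gene_ids)
        )
        cell = screen(comp, [part]).table.iloc[0]
        assert not cell.applicable and cell.m == 0

    def test_mutant_without_calls_scores_zero_everywhere(self):
        ann, parts = toy_screen_inputs()
        comp = ExpressionCompendium(
            pd.DataFrame(np.zeros((2, 100)), index=["a", "b"], columns=ann.gene_ids)
        )
        mat = screen(comp, parts)
        assert (mat.pvalues.to_numpy() == 1.0).all()
        assert (mat.scores.to_numpy() == 0.0).all()

    def test_family_without_measured_cluster_is_not_applicable(self):
        ann, parts = toy_screen_inputs()
        values = pd.DataFrame(
            np.zeros((1, 100)), index=["m"], columns=ann.gene_ids
        )
        values.loc["m", ["g010", "g011", "g012"]] = np.nan  # whole cluster missing
        mat = screen(ExpressionCompendium(values), parts)
        cell = mat.table.set_index("family").loc["clustered_fam"]
        assert not cell.applicable and np.isnan(cell.P)

    def test_deterministic_output(self, tmp_path):
        ann, parts = toy_screen_inputs()
        rng = np.random.default_rng(4)
        values = pd.DataFrame(
            rng.normal(0, 1, (5, 100)),
            index=[f"m{i}" for i in range(5)],
            columns=ann.gene_ids,
        )
        out = []
        for name in ("a.tsv", "b.tsv"):
            mat = screen(ExpressionCompendium(values.copy()), parts)
            p = tmp_path / name
            mat.cell_table().to_csv(p, sep="\t", index=False)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_bh_column_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        ann, parts = toy_screen_inputs()
        rng = np.random.default_rng(11)
        values = pd.DataFrame(
            rng.normal(0, 1.2, (6, 100)),
            index=[f"m{i}" for i in range(6)],
            columns=ann.gene_ids,
        )
        table = screen(ExpressionCompendium(values), parts).cell_table()
        mask = table["applicable"]
        ref = multipletests(table.loc[mask, "P"], method="fdr_bh")[1]
        assert np.allclose(table.loc[mask, "q_bh"], ref)


class TestGroupMutants:
    def _matrix_from_scores(self, scores: pd.DataFrame):
        ann, parts = toy_screen_inputs()
        # build a ScreenMatrix-compatible object directly from score rows
        from clustercoherence.screen import ScreenCell, ScreenMatrix

        cells = [
            ScreenCell(m, f, 100, 0, 5, 3, 0, P=1 - scores.loc[m, f],
                       score=scores.loc[m, f])
            for m in scores.index
            for f in scores.columns
        ]
        return ScreenMatrix(cells)

    def test_identical_rows_share_a_label(self):
        scores = pd.DataFrame(
            [[0.9, 0.9], [0.9, 0.9], [0.0, 0.0]],
            index=["a", "b", "c"],
            columns=["f1", "f2"],
        )
        mat = group_mutants(self._matrix_from_scores(scores), k=2, seed=0)
        assert mat.mutant_groups["a"] == mat.mutant_groups["b"]
        assert mat.mutant_groups["a"] != mat.mutant_groups["c"]

    def test_recovers_three_archetypes(self, rng):
        """Global / family-specific / null archetypes are regrouped exactly."""
        fams = [f"f{j}" for j in range(6)]
        rows, labels, idx = [], [], []
        for i in range(10):
            rows.append(np.clip(0.95 + rng.normal(0, 0.02, 6), 0, 1))  # global
            labels.append("global")
            idx.append(f"glob{i}")
        for i in range(10):
            r = np.clip(rng.normal(0.02, 0.01, 6), 0, 1)
            r[0] = 0.97
            rows.append(r)
            labels.append("specific")
            idx.append(f"spec{i}")
        for i in range(10):
            rows.append(np.clip(rng.normal(0.02, 0.01, 6), 0, 1))
            labels.append("null")
            idx.append(f"null{i}")
        scores = pd.DataFrame(rows, index=idx, columns=fams)
        mat = group_mutants(self._matrix_from_scores(scores), k=3, seed=1)
        df = pd.DataFrame({"label": labels, "group": mat.mutant_groups.to_numpy()})
        # each planted archetype maps to exactly one k-means group
        assert (df.groupby("label")["group"].nunique() == 1).all()
        assert df.groupby("label")["group"].first().nunique() == 3

    def test_single_group_inertia_is_total_variance(self):
        scores = pd.DataFrame(
            [[0.0, 0.2], [0.4, 0.6], [0.8, 1.0]],
            index=list("abc"),
            columns=["f1", "f2"],
        )
        mat = group_mutants(self._matrix_from_scores(scores), k=1, seed=0)
        assert mat.mutant_groups.nunique() == 1
        X = scores.to_numpy()
        assert mat.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_k_exceeding_mutants_raises(self):
        scores = pd.DataFrame([[0.1, 0.2]], index=["a"], columns=["f1", "f2"])
        with pytest.raises(ValueError):
            group_mutants(self._matrix_from_scores(scores), k=2)
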