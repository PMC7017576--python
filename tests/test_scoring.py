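"""The five activity statistics, each checked against an independent oracle."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from footprintbench.genesets import FootprintModel, RegulonNetwork
from footprintbench.scoring import (
    AUCellScorer,
    ConsensusRegulonScorer,
    FootprintScorer,
    GSEAScorer,
    RegulonScorer,
    ScoringError,
    aucell_scores,
    consensus_nes,
    footprint_scores,
    gsea_scores,
    regulon_nes,
    scale_gene_wise,
)


def regulon_frame(rows):
    return RegulonNetwork(pd.DataFrame(
        rows, columns=["tf", "target", "mode", "likelihood", "confidence"]))


class TestScaleGeneWise:
    def test_hand_computed_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        out = scale_gene_wise(m)
        np.testing.assert_allclose(out.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_row_zeroed_with_warning(self):
        m = pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["c", "g"])
        with pytest.warns(UserWarning, match="constant"):
            out = scale_gene_wise(m)
        assert (out.loc["c"] == 0).all()

    def test_idempotent_on_standardized_rows(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 8)))
        once = scale_gene_wise(m)
        np.testing.assert_allclose(scale_gene_wise(once), once, atol=1e-12)

    def test_single_column_rejected(self):
        with pytest.raises(ScoringError):
            scale_gene_wise(pd.DataFrame([[1.0]]))


class TestFootprintScores:
    def test_hand_weighted_sum(self):
        model = FootprintModel(pd.DataFrame({
            "pathway": ["P", "P"], "gene": ["g1", "g2"],
            "weight": [1.0, -1.0], "responsiveness_rank": [1, 2]}))
        sig = pd.DataFrame({"s": [2.0, 1.0]}, index=["g1", "g2"])
        out = footprint_scores(sig, model, scale=False)
        assert out.loc["P", "s"] == pytest.approx(1.0)

    def test_zero_signature_scores_zero_everywhere(self, small_footprint):
        genes = sorted(set(small_footprint.entries["gene"]))
        sig = pd.DataFrame({"s": np.zeros(len(genes))}, index=genes)
        out = footprint_scores(sig, small_footprint, scale=False)
        assert (out == 0).all().all()

    def test_fourteen_pathway_model_gives_fourteen_rows(self, rng):
        rows = []
        for p in range(14):
            for j in range(5):
                rows.append((f"P{p}", f"g{(p * 5 + j) % 40}", rng.normal(), j + 1))
        model = FootprintModel(pd.DataFrame(
            rows, columns=["pathway", "gene", "weight", "responsiveness_rank"]))
        sig = pd.DataFrame(rng.normal(size=(40, 3)),
                           index=[f"g{i}" for i in range(40)])
        out = footprint_scores(sig, model, scale=False)
        assert out.shape[0] == 14

    def test_linearity_in_the_signature(self, small_footprint, rng):
        genes = [f"g{i}" for i in range(30)]
        x = pd.DataFrame(rng.normal(size=(30, 2)), index=genes)
        y = pd.DataFrame(rng.normal(size=(30, 2)), index=genes)
        a, b = 2.0, -0.5
        sx = footprint_scores(x, small_footprint, scale=False)
        sy = footprint_scores(y, small_footprint, scale=False)
        sxy = footprint_scores(a * x + b * y, small_footprint, scale=False)
        pd.testing.assert_frame_equal(sxy, a * sx + b * sy)

    def test_scaling_standardizes_rows(self, small_footprint, rng):
        genes = [f"g{i}" for i in range(30)]
        x = pd.DataFrame(rng.normal(size=(30, 6)), index=genes)
        out = footprint_scores(x, small_footprint, scale=True)
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_uncovered_pathway_absent_with_warning(self, rng):
        model = FootprintModel(pd.DataFrame({
            "pathway": ["P", "Q"], "gene": ["g1", "absent"],
            "weight": [1.0, 1.0], "responsiveness_rank": [1, 1]}))
        sig = pd.DataFrame({"s": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="Q"):
            out = footprint_scores(sig, model, scale=False)
        assert list(out.index) == ["P"]


class TestRegulonNES:
    def test_symmetric_balanced_regulon_scores_zero(self):
        genes = [f"g{i}" for i in range(10)]
        sig = pd.Series(np.arange(10, dtype=float), index=genes)
        # targets at symmetric ranks k and n+1-k, equal mode and likelihood
        rows = [("T", "g1", 1, 1.0, "A"), ("T", "g8", 1, 1.0, "A"),
                ("T", "g2", 1, 1.0, "A"), ("T", "g7", 1, 1.0, "A")]
        out = regulon_nes(sig, regulon_frame(rows))
        assert out["T"] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_four_targets_absent(self):
        genes = [f"g{i}" for i in range(10)]
        sig = pd.Series(np.arange(10, dtype=float), index=genes)
        rows = [("T", g, 1, 1.0, "A") for g in ["g1", "g2", "g3"]]
        assert "T" not in regulon_nes(sig, regulon_frame(rows))

    def test_matches_permutation_null_z_score(self, rng):
        """Analytic NES vs z-score of a 10,000-shuffle permutation null."""
        n = 50
        genes = [f"g{i}" for i in range(n)]
        sig = pd.Series(rng.normal(size=n), index=genes)
        targets = rng.choice(genes, size=6, replace=False)
        modes = [1, 1, -1, 1, -1, 1]
        liks = [1.0, 0.8, 1.0, 0.5, 0.9, 1.0]
        rows = [("T", g, m, l, "A") for g, m, l in zip(targets, modes, liks)]
        net = regulon_frame(rows)
        nes = regulon_nes(sig, net)["T"]

        # oracle: raw weighted quantile sum under signature-label shuffles
        ranks = stats.rankdata(sig.to_numpy())
        q = stats.norm.ppf(ranks / (n + 1))
        pos = [genes.index(g) for g in targets]
        w = np.array(modes, dtype=float) * np.array(liks)
        observed = float(w @ q[pos])
        null = np.empty(10_000)
        for b in range(10_000):
            perm = rng.permutation(q)
            null[b] = w @ perm[pos]
        z = (observed - null.mean()) / null.std(ddof=1)
        assert abs(nes - z) < 0.15

    def test_flipping_modes_negates_nes(self, small_network, signature):
        out = regulon_nes(signature, small_network)
        flipped = small_network.edges.copy()
        flipped["mode"] = -flipped["mode"]
        out_f = regulon_nes(signature, RegulonNetwork(flipped))
        pd.testing.assert_series_equal(out_f, -out)

    def test_likelihood_scaling_leaves_nes_unchanged(self, small_network, signature):
        out = regulon_nes(signature, small_network)
        scaled = small_network.edges.copy()
        scaled["likelihood"] = scaled["likelihood"] * 0.35
        out_s = regulon_nes(signature, RegulonNetwork(scaled))
        pd.testing.assert_series_equal(out, out_s)

    def test_scorer_transform_matches_per_column_function(self, small_network, rng):
        genes = [f"g{i}" for i in range(30)]
        X = pd.DataFrame(rng.normal(size=(30, 4)), index=genes)
        scorer = RegulonScorer(small_network).fit(X)
        out = scorer.transform(X)
        for c in X.columns:
            ref = regulon_nes(X[c], scorer.network_)
            np.testing.assert_allclose(out[c].sort_index(), ref, atol=1e-12)

    def test_sklearn_param_round_trip(self, small_network):
        scorer = RegulonScorer(small_network, min_targets=5)
        params = scorer.get_params()
        assert params["min_targets"] == 5
        scorer.set_params(min_targets=4)
        assert scorer.min_targets == 4


class TestConsensusNES:
    def test_identical_scores_are_identity(self):
        s = pd.Series({"T": 1.3})
        out = consensus_nes([("a", s), ("b", s), ("c", s)])
        assert out["T"] == pytest.approx(1.3)

    def test_stated_formula_on_two_networks(self):
        out = consensus_nes([("a", pd.Series({"T": 2.0})),
                             ("b", pd.Series({"T": -1.0}))])
        assert out["T"] == pytest.approx((4 * 2 + 1 * (-1)) / 5)  # 1.4

    def test_single_network_tf_passes_through(self):
        out = consensus_nes([("a", pd.Series({"T": 1.7})), ("b", pd.Series({}))])
        assert out["T"] == pytest.approx(1.7)

    def test_all_zero_scores_give_zero(self):
        out = consensus_nes([("a", pd.Series({"T": 0.0})), ("b", pd.Series({"T": 0.0}))])
        assert out["T"] == 0.0

    def test_consensus_scorer_of_one_network_equals_regulon_scorer(self, small_network, rng):
        genes = [f"g{i}" for i in range(30)]
        X = pd.DataFrame(rng.normal(size=(30, 3)), index=genes)
        single = RegulonScorer(small_network).fit(X).transform(X)
        cons = ConsensusRegulonScorer([small_network]).fit(X).transform(X)
        np.testing.assert_allclose(cons.sort_index(), single.sort_index(), atol=1e-12)


def brute_force_recovery_score(counts: pd.Series, members, quantile=0.05):
    """Direct step-curve summation: the independent AUCell oracle."""
    order = sorted(range(len(counts)), key=lambda i: (-counts.iloc[i], i))
    ranked_genes = [counts.index[i] for i in order]
    k = math.ceil(quantile * len(counts))
    members = [g for g in members if g in counts.index]
    hits = 0
    area = 0
    for i in range(k):
        if ranked_genes[i] in members:
            hits += 1
        area += hits
    m = min(len(members), k)
    max_area = sum(min(i, m) for i in range(1, k + 1))
    return area / max_area


class TestAUCell:
    def make_counts(self, rng, n=100, cells=3):
        return pd.DataFrame(
            rng.integers(0, 50, size=(n, cells)).astype(float),
            index=[f"g{i}" for i in range(n)],
            columns=[f"c{j}" for j in range(cells)],
        )

    def test_set_filling_top_ranks_scores_one(self):
        counts = pd.DataFrame({"c": np.arange(100, 0, -1, dtype=float)},
                              index=[f"g{i}" for i in range(100)])
        out = aucell_scores(counts, {"S": ["g0", "g1", "g2"]}, quantile=0.05)
        assert out.loc["S", "c"] == pytest.approx(1.0)

    def test_top_quantile_window_is_five_percent(self, rng):
        scorer = AUCellScorer({"S": ["g0"]}, quantile=0.05)
        counts = self.make_counts(rng, n=100, cells=1)
        scorer.fit(counts)
        assert math.ceil(scorer.quantile * 100) == 5

    def test_matches_brute_force_step_curve(self, rng):
        counts = self.make_counts(rng, n=100, cells=4)
        sets = {"A": [f"g{i}" for i in (0, 2, 4)],
                "B": [f"g{i}" for i in rng.choice(100, 10, replace=False)]}
        out = aucell_scores(counts, sets, quantile=0.05)
        for name, members in sets.items():
            for c in counts.columns:
                expected = brute_force_recovery_score(counts[c], members)
                assert out.loc[name, c] == pytest.approx(expected)

    def test_known_rank_positions(self):
        counts = pd.DataFrame({"c": np.arange(100, 0, -1, dtype=float)},
                              index=[f"g{i}" for i in range(100)])
        out = aucell_scores(counts, {"S": ["g0", "g2", "g4"]}, quantile=0.05)
        # members at ranks 1, 3, 5: area 1+1+2+2+3=9; max 1+2+3+3+3=12
        assert out.loc["S", "c"] == pytest.approx(9 / 12)

    def test_scores_bounded_and_monotone_invariant(self, rng):
        counts = self.make_counts(rng, n=80, cells=5)
        sets = {"S": [f"g{i}" for i in rng.choice(80, 8, replace=False)]}
        out = aucell_scores(counts, sets)
        assert ((out >= 0) & (out <= 1)).all().all()
        transformed = np.log1p(counts) * 3.7  # strictly monotone
        out_t = aucell_scores(transformed, sets)
        np.testing.assert_allclose(out, out_t, atol=1e-12)

    def test_weights_and_modes_ignored(self, small_network, rng):
        counts = pd.DataFrame(
            rng.integers(0, 30, size=(30, 2)).astype(float),
            index=[f"g{i}" for i in range(30)])
        flipped = small_network.edges.copy()
        flipped["mode"] = -flipped["mode"]
        flipped["likelihood"] = 0.5
        a = aucell_scores(counts, small_network, quantile=0.3)
        b = aucell_scores(counts, RegulonNetwork(flipped), quantile=0.3)
        np.testing.assert_allclose(a, b)

    def test_unmeasured_set_skipped_with_warning(self, rng):
        counts = self.make_counts(rng, n=20, cells=1)
        with pytest.warns(UserWarning, match="no measured member"):
            out = aucell_scores(counts, {"S": ["g1"], "ghost": ["nope"]}, quantile=0.25)
        assert "ghost" not in out.index


def brute_force_es(contrast: pd.Series, members):
    """Independent weighted running-sum implementation (weight exponent 1)."""
    ordered = contrast.sort_values(ascending=False, kind="stable")
    members = set(members) & set(contrast.index)
    nr = sum(abs(ordered[g]) for g in members)
    n_miss = len(ordered) - len(members)
    running, best = 0.0, 0.0
    for g, v in ordered.items():
        if g in members:
            running += abs(v) / nr if nr > 0 else 1.0 / len(members)
        elif n_miss > 0:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def test_es_matches_brute_force_running_sum(self, rng):
        genes = [f"g{i}" for i in range(40)]
        contrast = pd.Series(rng.normal(size=40), index=genes)
        sets = {"A": list(rng.choice(genes, 6, replace=False)),
                "B": list(rng.choice(genes, 12, replace=False))}
        out = gsea_scores(contrast, sets, n_permutations=10, seed=0)
        for name, members in sets.items():
            assert out.loc[name, "es"] == pytest.approx(brute_force_es(contrast, members))

    def test_whole_universe_set_matches_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        contrast = pd.Series(rng.normal(size=12), index=genes)
        out = gsea_scores(contrast, {"ALL": genes}, n_permutations=5, seed=0)
        assert out.loc["ALL", "es"] == pytest.approx(brute_force_es(contrast, genes))

    def test_singleton_top_gene_es_is_its_increment(self, rng):
        genes = [f"g{i}" for i in range(10)]
        contrast = pd.Series(np.arange(10, 0, -1, dtype=float), index=genes)
        out = gsea_scores(contrast, {"S": ["g0"]}, n_permutations=10, seed=0)
        assert out.loc["S", "es"] == pytest.approx(1.0)  # |stat|/N_R = 1 at rank 1
        assert out.loc["S", "es"] > 0

    def test_exhaustive_small_signature_es(self, rng):
        """ES on <= 8 genes equals the exhaustive running-sum maximum."""
        genes = list("abcdefgh")
        contrast = pd.Series(rng.normal(size=8), index=genes)
        for members in (["a", "c"], ["b", "d", "f"], list("abcd")):
            out = gsea_scores(contrast, {"S": members}, n_permutations=2, seed=0)
            assert out.loc["S", "es"] == pytest.approx(brute_force_es(contrast, members))

    def test_default_null_is_1000_permutations(self):
        assert GSEAScorer({}).n_permutations == 1000

    def test_extreme_set_gets_small_p(self, rng):
        genes = [f"g{i}" for i in range(50)]
        vals = np.concatenate([np.full(5, 10.0), rng.normal(size=45)])
        contrast = pd.Series(vals, index=genes)
        out = gsea_scores(contrast, {"S": genes[:5]}, n_permutations=200, seed=1)
        assert out.loc["S", "pval"] < 0.05
        assert out.loc["S", "nes"] > 1


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=8, max_size=20, unique=True))
def test_regulon_nes_mode_flip_antisymmetry_property(values):
    genes = [f"g{i}" for i in range(len(values))]
    sig = pd.Series(values, index=genes)
    rows = [("T", g, 1 if i % 2 else -1, 1.0, "A") for i, g in enumerate(genes[:5])]
    net = regulon_frame(rows)
    flipped = net.edges.copy()
    flipped["mode"] = -flipped["mode"]
    a = regulon_nes(sig, net)["T"]
    b = regulon_nes(sig, RegulonNetwork(flipped))["T"]
    assert a == pytest.approx(-b)


def test_activity_tsv_round_trip(tmp_path, rng):
    from footprintbench.scoring import read_activity_tsv, write_activity_tsv

    act = pd.DataFrame(rng.normal(size=(3, 4)),
                       index=["T1", "T2", "T3"],
                       columns=[f"c{i}" for i in range(4)])
    act.attrs["statistic"] = "nes"
    path = tmp_path / "activity.tsv"
    write_activity_tsv(act, path)
    back = read_activity_tsv(path)
    pd.testing.assert_frame_equal(back, act)
    assert back.attrs["statistic"] == "nes"
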