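import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau

from allomap.classification import classify_matrix
from allomap.linkage_mapping import (
    GeneticMap,
    attach_dominant_loci,
    bin_loci,
    build_map,
    convert_to_coupling,
    estimate_r,
    group_loci,
    haldane_cm,
    impute_solitary_missing,
    inverse_haldane,
    order_group,
    pairwise_stats,
)
from allomap.synthetic_data import (
    GenotypeMatrix,
    SimulationConfig,
    default_genome,
    simulate_population,
)

from _oracles import calls_from_table, grid_ml_r, random_joint_table


def _codominant_vector(n_aa=41, n_ab=82, n_bb=41):
    return np.array([0] * n_aa + [1] * n_ab + [2] * n_bb, dtype=np.int8)


class TestEstimateR:
    def test_perfect_cosegregation(self):
        v = _codominant_vector()
        ps = estimate_r(v, v)
        assert ps.r_hat == pytest.approx(0.0, abs=1e-6)
        assert ps.phase == "coupling"
        assert ps.lod > 10

    def test_independent_loci(self):
        # joint counts equal to the product of 1:2:1 margins (x16)
        counts = np.outer([1, 2, 1], [1, 2, 1]) * 16
        a, b = calls_from_table(counts)
        ps = estimate_r(a, b)
        assert ps.r_hat == pytest.approx(0.5, abs=1e-6)
        assert ps.lod == pytest.approx(0.0, abs=1e-9)

    def test_repulsion_detected(self):
        v = _codominant_vector()
        swapped = np.where(v == 0, 2, np.where(v == 2, 0, v)).astype(np.int8)
        ps = estimate_r(v, swapped)
        assert ps.phase == "repulsion"
        assert ps.r_hat == pytest.approx(0.0, abs=1e-6)

    def test_too_few_informative(self):
        a = np.array([0, -1, -1], dtype=np.int8)
        b = np.array([-1, 0, -1], dtype=np.int8)
        with pytest.raises(ValueError, match="informative"):
            estimate_r(a, b)

    def test_accepts_string_calls(self):
        ps = estimate_r(["AA", "AB", "BB", "AA", "AB", "BB"],
                        ["AA", "AB", "BB", "AA", "AB", "BB"])
        assert ps.r_hat == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_oracle_codominant(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            counts = random_joint_table(rng)
            a, b = calls_from_table(counts)
            try:
                ps = estimate_r(a, b)
            except ValueError:
                continue
            r_grid, phase, _ = grid_ml_r(counts)
            assert ps.r_hat == pytest.approx(r_grid, abs=1e-4)

    def test_dominant_pair_recovers_linkage(self):
        # tightly linked dominant x codominant pair in coupling
        rng = np.random.default_rng(3)
        n = 400
        g1 = rng.integers(0, 2, (n, 2)).sum(axis=1)  # locus genotypes 0/1/2
        ps_same = estimate_r(np.where(g1 == 0, 1, g1).astype(np.int8),
                             g1.astype(np.int8),
                             class_a="dominant_AB_BB", class_b="codominant")
        assert ps_same.r_hat == pytest.approx(0.0, abs=1e-6)


class TestHaldane:
    def test_zero(self):
        assert haldane_cm(0.0) == 0.0

    def test_closed_form(self):
        assert haldane_cm(0.2) == pytest.approx(-50 * math.log(0.6), abs=1e-10)
        assert haldane_cm(0.2) == pytest.approx(25.54128, abs=1e-4)

    def test_inverse_identity(self):
        for r in np.linspace(0.001, 0.49, 50):
            assert inverse_haldane(haldane_cm(r)) == pytest.approx(r, abs=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            haldane_cm(0.5)
        with pytest.raises(ValueError):
            haldane_cm(-0.1)

    def test_cap_flag(self):
        assert haldane_cm(0.5, cap=True) == haldane_cm(0.4999, cap=True)


class TestConvertToCoupling:
    def test_involution(self, pop_clean):
        matrix, _ = pop_clean
        phases = {l: "repulsion" for l in matrix.loci[:10]}
        twice = convert_to_coupling(convert_to_coupling(matrix, phases), phases)
        assert np.array_equal(twice.calls, matrix.calls)

    def test_all_ab_unchanged(self):
        m = GenotypeMatrix(["L1"], ["i1", "i2", "i3"],
                           np.array([[1, 1, 1]], dtype=np.int8))
        out = convert_to_coupling(m, {"L1": "repulsion"})
        assert np.array_equal(out.calls, m.calls)

    def test_swap_restores_coupling_phase(self):
        v = _codominant_vector()
        swapped = np.where(v == 0, 2, np.where(v == 2, 0, v)).astype(np.int8)
        m = GenotypeMatrix(["a", "b"], [f"i{j}" for j in range(v.size)],
                           np.stack([v, swapped]))
        out = convert_to_coupling(m, {"b": "repulsion"})
        ps = estimate_r(out.row("a"), out.row("b"))
        assert ps.phase == "coupling"
        assert ps.r_hat == pytest.approx(0.0, abs=1e-6)


class TestGrouping:
    def test_two_chromosomes_recovered(self):
        genome = default_genome(n_hg=2, n_subgenomes=4, loci_per_chrom=20,
                                chrom_length_cm=100.0, fraction_specific=1.0,
                                seed=5)
        cfg = SimulationConfig(n_individuals=164, error_rate=0.0,
                               missing_rate=0.0, seed=6)
        matrix, truth = simulate_population(genome, cfg)
        classes = classify_matrix(matrix)
        # two unlinked chromosomes only
        on_two = truth[truth["chrom"].isin(["chr1a", "chr2a"])].index
        retained = [l for l in classes.index
                    if classes.at[l, "class"] == "codominant_1_2_1"
                    and l in set(on_two)]
        pairs = pairwise_stats(matrix, loci=list(retained))
        groups = group_loci(pairs, lod_threshold=5.0, max_r=0.4)
        assert len(groups) == 2
        for g in groups:
            chroms = truth.loc[list(g.members), "chrom"].unique()
            assert len(chroms) == 1

    def test_singleton_group(self):
        pairs = pd.DataFrame(columns=["a", "b", "r", "lod", "phase",
                                      "n_informative"])
        groups = group_loci(pairs, loci=["L1"])
        assert len(groups) == 1 and groups[0].members == ("L1",)

    def test_infinite_threshold_gives_singletons(self, pop_clean, classes_clean):
        matrix, _ = pop_clean
        retained = list(classes_clean[classes_clean["class"]
                                      == "codominant_1_2_1"].index)[:30]
        pairs = pairwise_stats(matrix, loci=retained)
        groups = group_loci(pairs, lod_threshold=math.inf, loci=retained)
        assert len(groups) == len(retained)


class TestOrdering:
    def test_additive_three_locus_chain(self):
        pairs = pd.DataFrame([
            {"a": "m1", "b": "m2", "r": 0.05, "lod": 10, "phase": "coupling"},
            {"a": "m2", "b": "m3", "r": 0.05, "lod": 10, "phase": "coupling"},
            {"a": "m1", "b": "m3", "r": 0.10, "lod": 8, "phase": "coupling"},
        ])
        order = order_group(["m1", "m2", "m3"], pairs)
        assert order in (["m1", "m2", "m3"], ["m3", "m2", "m1"])

    def test_single_locus(self):
        pairs = pd.DataFrame(columns=["a", "b", "r", "lod", "phase"])
        assert order_group(["only"], pairs) == ["only"]

    def test_fifty_locus_order_recovery(self):
        genome = default_genome(n_hg=1, n_subgenomes=4, loci_per_chrom=50,
                                chrom_length_cm=98.0, fraction_specific=1.0,
                                seed=8)
        cfg = SimulationConfig(n_individuals=164, error_rate=0.0,
                               missing_rate=0.0, seed=9)
        matrix, truth = simulate_population(genome, cfg)
        loci = list(truth[truth["chrom"] == "chr1a"].index)
        pairs = pairwise_stats(matrix, loci=loci)
        order = order_group(loci, pairs)
        true_pos = truth.loc[order, "pos_cm"].to_numpy()
        tau = abs(kendalltau(np.arange(len(order)), true_pos).statistic)
        assert tau >= 0.95


class TestImputation:
    def _matrix(self, rows, loci=None):
        loci = loci or [f"L{i}" for i in range(len(rows))]
        n = len(rows[0])
        return GenotypeMatrix(loci, [f"i{j}" for j in range(n)],
                              np.array(rows, dtype=np.int8))

    def test_agreeing_flanks_filled(self):
        m = self._matrix([[1], [-1], [1]])
        out = impute_solitary_missing(m, {"LG1": ["L0", "L1", "L2"]})
        assert out.calls[1, 0] == 1

    def test_disagreeing_flanks_left_missing(self):
        m = self._matrix([[0], [-1], [2]])
        out = impute_solitary_missing(m, {"LG1": ["L0", "L1", "L2"]})
        assert out.calls[1, 0] == -1

    def test_terminal_never_imputed(self):
        m = self._matrix([[-1], [1], [1]])
        out = impute_solitary_missing(m, {"LG1": ["L0", "L1", "L2"]})
        assert out.calls[0, 0] == -1

    def test_idempotent_and_preserves_nonmissing(self, pop_noisy):
        matrix, truth = pop_noisy
        order = {c: list(truth[truth["chrom"] == c].sort_values("pos_cm").index)
                 for c in truth["chrom"].unique()}
        once = impute_solitary_missing(matrix, order)
        twice = impute_solitary_missing(once, order)
        assert np.array_equal(once.calls, twice.calls)
        nonmissing = matrix.calls >= 0
        assert np.array_equal(once.calls[nonmissing], matrix.calls[nonmissing])


class TestBinning:
    def test_duplicated_locus_shares_bin(self):
        v = _codominant_vector(10, 20, 10)
        m = GenotypeMatrix(["a", "b"], [f"i{j}" for j in range(v.size)],
                           np.stack([v, v]))
        groups = group_loci(pairwise_stats(m), loci=["a", "b"])
        bins = bin_loci(m, groups)
        assert bins["a"] == bins["b"] == "a"

    def test_single_recombinant_splits_bins(self):
        v = _codominant_vector(10, 20, 10)
        w = v.copy()
        w[0] = 1  # one recombinant individual
        m = GenotypeMatrix(["a", "b"], [f"i{j}" for j in range(v.size)],
                           np.stack([v, w]))
        bins = bin_loci(m, group_loci(pairwise_stats(m), loci=["a", "b"]))
        assert bins["a"] != bins["b"]


class TestAttachDominant:
    def _table(self):
        return pd.DataFrame({
            "hg": ["ref1", "ref1"],
            "lg": ["LG01", "LG01"],
            "position_cm": [10.0, 20.0],
            "bin": ["c1", "c2"],
            "class": ["codominant_1_2_1"] * 2,
            "phase": ["coupling"] * 2,
            "attached": [False, False],
        }, index=pd.Index(["c1", "c2"], name="locus"))

    def test_nearest_physical_position_wins(self):
        anchors = pd.DataFrame({
            "ref_chrom": ["ref1"] * 3,
            "ref_pos": [900_000, 1_200_000, 1_000_000],
        }, index=pd.Index(["c1", "c2", "d1"], name="locus"))
        dominant = pd.DataFrame({"variant": ["dominant_AB_BB_3_1"]},
                                index=pd.Index(["d1"], name="locus"))
        table, unplaced = attach_dominant_loci(self._table(), dominant, anchors)
        assert unplaced == []
        assert table.at["d1", "position_cm"] == 10.0  # the 900 kb bin
        assert table.at["d1", "attached"]

    def test_unanchored_reported(self):
        anchors = pd.DataFrame({"ref_chrom": ["ref1"], "ref_pos": [1]},
                               index=pd.Index(["c1"], name="locus"))
        dominant = pd.DataFrame({"variant": ["dominant_AB_BB_3_1"]},
                                index=pd.Index(["d9"], name="locus"))
        table, unplaced = attach_dominant_loci(self._table(), dominant, anchors)
        assert unplaced == ["d9"]
        assert "d9" not in table.index

    def test_simulated_placement_accuracy(self):
        genome = default_genome(n_hg=2, n_subgenomes=4, loci_per_chrom=25,
                                chrom_length_cm=48.0, fraction_specific=0.6,
                                ref_mode="per_chromosome", seed=17)
        cfg = SimulationConfig(n_individuals=164, error_rate=0.0,
                               missing_rate=0.0, seed=18)
        matrix, truth = simulate_population(genome, cfg)
        classes = classify_matrix(matrix)
        anchors = truth[["ref_chrom", "ref_pos"]]
        gmap = build_map(matrix, classes, anchors=anchors, lod_threshold=5.0)
        attached = gmap.locus_table[gmap.locus_table["attached"]]
        assert len(attached) >= 20
        core = gmap.locus_table[~gmap.locus_table["attached"]]
        lg_chrom = {}
        lg_fit = {}  # per-LG affine map coordinate -> truth cM
        for lg, sub in core.groupby("lg"):
            lg_chrom[lg] = truth.loc[sub.index, "chrom"].mode().iloc[0]
            lg_fit[lg] = np.polyfit(sub["position_cm"],
                                    truth.loc[sub.index, "pos_cm"], 1)
        ok = 0
        for locus, row in attached.iterrows():
            right_lg = lg_chrom[row["lg"]] == truth.at[locus, "chrom"]
            predicted = np.polyval(lg_fit[row["lg"]], row["position_cm"])
            close = abs(predicted - truth.at[locus, "pos_cm"]) <= 5.0
            ok += right_lg and close
        assert ok / len(attached) >= 0.90


@pytest.fixture(scope="module")
def gmap(pop_clean, classes_clean, anchors_clean):
    matrix, _ = pop_clean
    return build_map(matrix, classes_clean, anchors=anchors_clean,
                     lod_threshold=5.0)


class TestBuildMapInvariants:
    def test_positions_nonnegative_and_bounded(self, gmap):
        core = gmap.locus_table[~gmap.locus_table["attached"]]
        assert (core["position_cm"] >= 0).all()

    def test_bin_members_share_position(self, gmap):
        core = gmap.locus_table[~gmap.locus_table["attached"]]
        for (_, _), sub in core.groupby(["lg", "bin"]):
            assert sub["position_cm"].nunique() == 1

    def test_bin_members_have_zero_recombinants(self, gmap):
        core = gmap.locus_table[~gmap.locus_table["attached"]]
        for (_, _), sub in core.groupby(["lg", "bin"]):
            loci = list(sub.index)
            for i in range(len(loci)):
                a = gmap.matrix.row(loci[i])
                for j in range(i + 1, len(loci)):
                    b = gmap.matrix.row(loci[j])
                    joint = (a >= 0) & (b >= 0)
                    assert not (a[joint] != b[joint]).any()

    def test_lg_purity_against_truth(self, gmap, pop_clean):
        _, truth = pop_clean
        core = gmap.locus_table[~gmap.locus_table["attached"]]
        for lg, sub in core.groupby("lg"):
            assert truth.loc[sub.index, "chrom"].nunique() == 1

    def test_summary_consistency(self, gmap):
        summary = gmap.summary()
        table = gmap.locus_table
        assert summary["n_loci"].sum() == len(table)
        assert (summary["length_cm"] >= 0).all()
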