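"""The rectification loop: set algebra, the hand-traced round, stopping."""

import pytest

import tworect as tw
from tworect.exceptions import ConfigurationError


# ---------------------------------------------------------------------------
# small arithmetic operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("total, frac, expected", [
    (8088, 0.15, 1213),   # floor(0.15 * 8088)
    (100, 0.15, 15),
    (3, 0.15, 1),         # floor gives 0, clamped
])
def test_compute_ng(total, frac, expected):
    assert tw.compute_ng(total, frac) == expected


def test_take_initial_prefix(worked_ranked):
    assert tw.take_initial(worked_ranked, 2) == {"g01", "g09"}
    assert tw.take_initial(worked_ranked, len(worked_ranked)) == \
        set(worked_ranked.genes)
    with pytest.raises(ConfigurationError):
        tw.take_initial(worked_ranked, 0)
    with pytest.raises(ConfigurationError):
        tw.take_initial(worked_ranked, len(worked_ranked) + 1)


@pytest.mark.parametrize("m, size, expected", [
    (0.1, 40, 4),
    (0.05, 19, 0),     # floor(0.95): pruning-only round
    (1.0, 7, 7),
])
def test_expansion_size(m, size, expected):
    C = [f"c{i}" for i in range(size)]
    assert tw.expansion_size(m, C, ["u1", "u2"]) == expected


def test_split_annotated_set_algebra(worked, worked_ranked):
    universe = tw.default_universe(worked_ranked, worked.pathways)
    table = tw.enrich({"g01", "g02", "g07"}, worked.pathways, universe)
    sig = tw.significant_pathways(table, alpha=1.0, min_overlap=1)
    U, C = tw.split_annotated({"g01", "g02", "g07"}, sig, worked.pathways,
                              universe, worked_ranked)
    # both pathways pass at alpha=1: annotation pool is g01..g08
    assert U == ["g01", "g02", "g07"]
    assert C == ["g03", "g04", "g05", "g06", "g08"]
    assert set(U) & set(C) == set()


def test_split_annotated_boundaries(worked, worked_ranked):
    universe = tw.default_universe(worked_ranked, worked.pathways)
    table = tw.enrich({"g01", "g07"}, worked.pathways, universe)
    sig = tw.significant_pathways(table, alpha=1.0, min_overlap=1)
    assert set(sig["pathway_id"]) == {"P1", "P2"}
    # degs disjoint from the annotation pool: U empty, C = everything
    U, C = tw.split_annotated({"g09", "g10"}, sig, worked.pathways,
                              universe, worked_ranked)
    assert U == []
    assert set(C) == set(universe)
    # annotation pool inside degs: C empty (pure pruning round)
    U, C = tw.split_annotated(set(universe) | {"g09"}, sig, worked.pathways,
                              universe, worked_ranked)
    assert set(U) == set(universe)
    assert C == []


# ---------------------------------------------------------------------------
# the committed hand trace
# ---------------------------------------------------------------------------

def test_rectify_round_reproduces_hand_trace(worked, worked_ranked):
    """One round on the 10-gene fixture, derived entirely by hand.

    Initial list = top 4 of L = {g01, g09, g02, g03}.  Within the
    annotated universe {g01..g08} the query is {g01,g02,g03} (n=3), so
    P1 = {g01..g05} has k=3, K=5, N=8: p = C(5,3)/C(8,3) = 10/56 ~ 0.179,
    significant at alpha=0.2; P2 has no overlap.  Hence the pool A =
    {g01..g05}: U = (g01,g02,g03), C = (g04,g05) by score,
    |D| = floor(0.5*2) = 1 so D = (g04), and the unannotated g09 is
    pruned: DEGs-12 = {g01,g02,g03,g04}.
    """
    cfg = tw.RectifyConfig(n=4, m=0.5, alpha=0.2, min_overlap=1)
    universe = tw.default_universe(worked_ranked, worked.pathways)
    degs0 = tw.take_initial(worked_ranked, 4)
    assert degs0 == {"g01", "g09", "g02", "g03"}
    rnd = tw.rectify_round(1, degs0, worked_ranked, worked.pathways,
                           universe, cfg)
    assert list(rnd.significant_pathways["pathway_id"]) == ["P1"]
    assert rnd.significant_pathways.iloc[0]["p_value"] == \
        pytest.approx(10 / 56, abs=1e-12)
    assert rnd.U == ["g01", "g02", "g03"]
    assert rnd.C == ["g04", "g05"]
    assert rnd.D == ["g04"]
    assert rnd.degs_out == {"g01", "g02", "g03", "g04"}


def test_round_reaching_fixed_point(worked, worked_ranked):
    """U = degs_in and |D| = 0 leaves the list unchanged."""
    cfg = tw.RectifyConfig(n=5, m=0.2, alpha=0.05, min_overlap=1)
    universe = tw.default_universe(worked_ranked, worked.pathways)
    # top-5 genes by |log_fc| include g09; use the annotated five directly
    degs = {"g01", "g02", "g03", "g04", "g05"}
    rnd = tw.rectify_round(1, degs, worked_ranked, worked.pathways,
                           universe, cfg)
    # P1 fully hit: p = 1/C(8,5) = 1/56; C = {} so no expansion possible
    assert rnd.degs_out == degs


def test_unannotated_gene_is_pruned(worked, worked_ranked):
    cfg = tw.RectifyConfig(n=4, m=0.5, alpha=0.2, min_overlap=1)
    universe = tw.default_universe(worked_ranked, worked.pathways)
    rnd = tw.rectify_round(1, {"g01", "g02", "g03", "g09"}, worked_ranked,
                           worked.pathways, universe, cfg)
    assert "g09" not in rnd.degs_out


def test_no_significant_pathways_flag(worked, worked_ranked):
    cfg = tw.RectifyConfig(n=4, m=0.5, alpha=1e-9, min_overlap=1)
    universe = tw.default_universe(worked_ranked, worked.pathways)
    rnd = tw.rectify_round(1, {"g01", "g02"}, worked_ranked, worked.pathways,
                           universe, cfg)
    assert rnd.no_significant_pathways
    assert rnd.degs_out == set()


# ---------------------------------------------------------------------------
# the driver
# ---------------------------------------------------------------------------

def test_strict_alpha_stops_with_no_pathways_and_empty_result(small_study):
    L = tw.rank_genes(tw.moderated_t_scores(small_study.expression))
    cfg = tw.RectifyConfig(n=20, m=0.1, alpha=1e-12)
    result = tw.run_rectification(L, small_study.pathways, cfg)
    assert result.stop_reason == "no_significant_pathways"
    assert result.final_degs == set()
    assert result.rounds == []


def test_ng_bound_reached_quickly_with_aggressive_expansion(worked,
                                                            worked_ranked):
    # N_g = floor(0.15*10) = 1; the first round already overshoots
    cfg = tw.RectifyConfig(n=4, m=1.0, alpha=0.2, min_overlap=1,
                           ng_fraction=0.15)
    result = tw.run_rectification(worked_ranked, worked.pathways, cfg)
    assert result.stop_reason == "ng_bound"
    assert len(result.rounds) <= 3
    assert len(result.final_degs) <= result.n_g


def test_growth_until_stop_on_standard_study(small_study):
    L = tw.rank_genes(tw.moderated_t_scores(small_study.expression))
    cfg = tw.RectifyConfig(n=15, m=0.1, alpha=0.25, use_adjusted=False,
                           max_rounds=30)
    result = tw.run_rectification(L, small_study.pathways, cfg)
    sizes = [len(r.degs_out) for r in result.rounds]
    assert len(sizes) >= 2
    assert all(b >= a for a, b in zip(sizes, sizes[1:]))
    assert len(result.final_degs) <= result.n_g


def test_round_invariants_hold_along_a_run(small_study):
    L = tw.rank_genes(tw.moderated_t_scores(small_study.expression))
    universe = tw.default_universe(L, small_study.pathways)
    cfg = tw.RectifyConfig(n=20, m=0.15, alpha=0.1)
    result = tw.run_rectification(L, small_study.pathways, cfg)
    assert result.rounds
    for rnd in result.rounds:
        annotated = set()
        for pid in rnd.significant_pathways["pathway_id"]:
            annotated |= small_study.pathways.genes_of(pid) & universe
        assert set(rnd.U) <= rnd.degs_in
        assert not set(rnd.C) & rnd.degs_in
        assert len(rnd.D) == tw.expansion_size(cfg.m, rnd.C, rnd.U)
        assert rnd.degs_out == set(rnd.U) | set(rnd.D)
        assert rnd.degs_out <= annotated


def test_rerun_is_bit_identical(small_study):
    L = tw.rank_genes(tw.moderated_t_scores(small_study.expression))
    cfg = tw.RectifyConfig(n=25, m=0.1, alpha=0.1)
    a = tw.run_rectification(L, small_study.pathways, cfg)
    b = tw.run_rectification(L, small_study.pathways, cfg)
    assert a.to_json() == b.to_json()


def test_termination_on_adversarial_inputs(worked, worked_ranked):
    """Whatever the config, the driver halts within max_rounds."""
    for m in (0.01, 0.5, 1.0):
        for alpha in (0.01, 0.5, 1.0):
            cfg = tw.RectifyConfig(n=3, m=m, alpha=alpha, min_overlap=1,
                                   max_rounds=10)
            result = tw.run_rectification(worked_ranked, worked.pathways, cfg)
            assert len(result.rounds) <= 10
            assert result.stop_reason in {"ng_bound", "fixed_point",
                                          "no_significant_pathways",
                                          "max_rounds"}
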