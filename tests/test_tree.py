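"""Tree substrate: Newick I/O, LTT curves, inflection, cropping, subsampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phylodecay import (
    Expansion,
    NewickParseError,
    SimConfig,
    TreeError,
    compute_ltt,
    crop_at,
    detect_inflection,
    patristic_distance,
    prune_germline,
    read_newick,
    simulate_phylogeny,
    subsample_tips,
    write_newick,
)


# ---------------------------------------------------------------- I/O

class TestNewickIO:
    def test_three_tip_depths(self, three_tip):
        assert three_tip.n_tips == 3
        assert three_tip.tip_depths() == {"A": 15.0, "B": 15.0, "C": 15.0}

    def test_minimal_two_tip_tree(self):
        t = read_newick("(A:1,B:1);")
        assert t.n_tips == 2
        assert t.max_depth == 1.0

    @pytest.mark.parametrize("bad", ["((A:5,B:5", "(A:1,:2);", "", "(A:1,A:2);"])
    def test_malformed_or_invalid_input_raises(self, bad):
        with pytest.raises((NewickParseError, TreeError)):
            read_newick(bad)

    def test_missing_branch_length_requires_opt_in(self):
        with pytest.raises(NewickParseError):
            read_newick("(A,B);")
        t = read_newick("(A,B);", default_branch_length=0)
        assert t.max_depth == 0.0

    def test_negative_branch_length_rejected(self):
        with pytest.raises(TreeError):
            read_newick("(A:-1,B:2);")

    @pytest.mark.parametrize("seed", range(4))
    def test_roundtrip_preserves_topology_and_lengths(self, seed):
        phylo, _ = simulate_phylogeny(SimConfig(age=60, seed=seed))
        again = read_newick(write_newick(phylo))
        assert sorted(again.tip_labels) == sorted(phylo.tip_labels)
        d0, d1 = phylo.tip_depths(), again.tip_depths()
        for lab in d0:
            assert d1[lab] == pytest.approx(d0[lab], rel=1e-9)
        assert write_newick(again) == write_newick(phylo)


# ---------------------------------------------------------------- LTT

class TestLTT:
    def test_manual_enumeration_three_tips(self, three_tip):
        ltt = compute_ltt(three_tip)
        assert list(ltt.depths) == [0.0, 10.0]
        assert list(ltt.counts) == [2, 3]

    def test_manual_enumeration_balanced_four(self, four_tip_balanced):
        ltt = compute_ltt(four_tip_balanced)
        assert list(ltt.depths) == [0.0, 3.0, 3.0]
        assert list(ltt.counts) == [2, 3, 4]

    @pytest.mark.parametrize("seed", range(5))
    def test_final_count_equals_tip_count(self, seed):
        phylo, _ = simulate_phylogeny(SimConfig(age=50, seed=seed))
        assert compute_ltt(phylo).counts[-1] == phylo.n_tips

    def test_single_tip_rejected(self):
        with pytest.raises((TreeError, NewickParseError)):
            compute_ltt(read_newick("(A:1);"))


# ------------------------------------------------------- inflection

class TestInflection:
    def test_changepoint_recovers_burst_end(self):
        """A high-rate burst to depth ~30 followed by near-zero branching
        is detected within +/-20% of the true changepoint (a stray
        post-burst event adjacent to the burst may occasionally be
        absorbed into it, so a small miss rate is tolerated)."""
        tas = []
        for seed in range(100):
            phylo, _ = simulate_phylogeny(
                SimConfig(age=45, seed=seed, neutral_split_rate=0.001)
            )
            tas.append(detect_inflection(compute_ltt(phylo)))
        hits = sum(abs(t - 30.0) <= 6.0 for t in tas)
        assert hits >= 85
        assert abs(sorted(tas)[len(tas) // 2] - 30.0) <= 6.0

    def test_fallback_small_tree_uses_deepest_branching(self, three_tip):
        t_a = detect_inflection(compute_ltt(three_tip))
        assert t_a == pytest.approx(10.0, rel=1e-6)

    def test_degenerate_burst_at_zero(self):
        t = read_newick("((A:5,B:5):0,(C:5,D:5):0);")
        t_a = detect_inflection(compute_ltt(t))
        assert 0 < t_a < 1e-6

    def test_deterministic_given_curve(self):
        phylo, _ = simulate_phylogeny(SimConfig(age=70, seed=5))
        ltt = compute_ltt(phylo)
        assert detect_inflection(ltt) == detect_inflection(ltt)


# ------------------------------------------------------------- crop

class TestCrop:
    def test_crossing_count_at_depth8(self, three_tip):
        anc = crop_at(three_tip, 8)
        assert anc.n_a == 2
        assert anc.tip_to_lineage["A"] == anc.tip_to_lineage["B"]
        assert anc.tip_to_lineage["C"] == "C"

    def test_crossing_count_at_depth12(self, three_tip):
        assert crop_at(three_tip, 12).n_a == 3

    def test_limit_near_zero_gives_root_children(self, three_tip):
        assert crop_at(three_tip, 1e-9).n_a == 2

    @pytest.mark.parametrize("t", [0.0, -1.0, 15.1])
    def test_out_of_range_depths_rejected(self, three_tip, t):
        with pytest.raises(TreeError):
            crop_at(three_tip, t)

    def test_shallow_tip_counts_as_own_lineage(self):
        t = read_newick("((A:5,B:5):10,C:4);")
        anc = crop_at(t, 8)
        assert anc.n_a == 2
        assert anc.tip_to_lineage["C"] == "C"

    @pytest.mark.parametrize("seed", range(3))
    def test_conservation_every_tip_maps_to_one_lineage(self, seed):
        phylo, _ = simulate_phylogeny(
            SimConfig(age=70, seed=seed, expansions=(Expansion(40, 0.2),))
        )
        anc = crop_at(phylo, 30.0)
        assert set(anc.tip_to_lineage) == set(phylo.tip_labels)
        lineages = set(anc.tip_to_lineage.values())
        assert lineages == set(anc.tree.tip_labels)
        assert anc.n_a == anc.tree.n_tips <= phylo.n_tips


# -------------------------------------------------------- subsample

class TestSubsample:
    @given(n=st.integers(5, 60), frac=st.floats(0.01, 1.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_retained_count_is_clamp_formula(self, n, frac):
        nwk = "(" + ",".join(f"t{i}:1" for i in range(n)) + ");"
        sub = subsample_tips(read_newick(nwk), frac, seed=0)
        assert sub.n_tips == max(2, int(math.floor(frac * n + 0.5)))

    def test_full_fraction_is_identity(self, three_tip):
        assert write_newick(subsample_tips(three_tip, 1.0, 0)) == write_newick(three_tip)

    def test_small_tree_clamps_to_two(self):
        t = read_newick("(a:1,(b:1,(c:1,(d:1,e:1):1):1):1);")
        assert subsample_tips(t, 0.1, seed=3).n_tips == 2

    def test_reproducible_for_seed(self):
        phylo, _ = simulate_phylogeny(SimConfig(age=60, seed=1))
        a = subsample_tips(phylo, 0.4, seed=9)
        b = subsample_tips(phylo, 0.4, seed=9)
        assert write_newick(a) == write_newick(b)

    def test_pairwise_path_lengths_unchanged(self):
        phylo, _ = simulate_phylogeny(SimConfig(age=60, seed=2))
        sub = subsample_tips(phylo, 0.3, seed=4)
        labs = sub.tip_labels
        for a, b in [(labs[0], labs[1]), (labs[0], labs[-1]), (labs[2], labs[-2])]:
            assert patristic_distance(sub, a, b) == pytest.approx(
                patristic_distance(phylo, a, b), rel=1e-9
            )

    def test_invalid_fraction_rejected(self, three_tip):
        for frac in (0.0, -0.5, 1.5):
            with pytest.raises(TreeError):
                subsample_tips(three_tip, frac, seed=0)


# --------------------------------------------------------- germline

class TestGermline:
    def test_stem_preserved_and_counts_as_single_lineage(self):
        t = read_newick("(germ:0.0,((A:5,B:5):10,C:15):200);")
        pruned = prune_germline(t, "germ")
        assert sorted(pruned.tip_labels) == ["A", "B", "C"]
        assert pruned.max_depth == 215.0
        assert crop_at(pruned, 100.0).n_a == 1

    def test_unknown_label_rejected(self, three_tip):
        with pytest.raises(TreeError):
            prune_germline(three_tip, "nope")
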