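"""Simulation layers: birth-death trees, Mk characters, evidence, fixture."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare

from paleoasr import (
    CharacterCoding,
    Node,
    SimulationSpec,
    Tree,
    code_alternate,
    code_preferred,
    fit_mk,
    make_study_fixture,
    marginal_asr_ml,
    parse_newick,
    simulate_evidence,
    simulate_mk_character,
    simulate_strat_ranges,
    simulate_tree,
    write_newick,
    yule_expected_root_age,
)
from paleoasr.synthetic import SimulationError


def star_tree(n: int, t: float) -> Tree:
    root = Node()
    for i in range(n):
        root.add_child(Node(label=f"s{i}", length=t))
    tree = Tree(root)
    tree.branch_mode = "timescaled"
    return tree


class TestSimulateTree:
    def test_smallest_case_is_cherry(self):
        t = simulate_tree(2, birth_rate=0.1, seed=1)
        assert t.n_tips == 2
        assert t.root.age > 0

    def test_same_seed_identical_newick(self):
        a = simulate_tree(12, birth_rate=0.1, death_rate=0.05, seed=7)
        b = simulate_tree(12, birth_rate=0.1, death_rate=0.05, seed=7)
        assert write_newick(a) == write_newick(b)

    def test_different_seeds_differ(self):
        a = simulate_tree(12, birth_rate=0.1, seed=1)
        b = simulate_tree(12, birth_rate=0.1, seed=2)
        assert write_newick(a) != write_newick(b)

    def test_requested_tip_count_with_extinction(self):
        t = simulate_tree(25, birth_rate=0.2, death_rate=0.15, seed=3)
        assert t.n_tips == 25
        assert all(n.length > 0 for n in t.postorder() if n.parent is not None)

    def test_ages_consistent_with_lengths(self):
        t = simulate_tree(10, birth_rate=0.1, seed=5)
        for node in t.postorder():
            if node.parent is not None:
                assert node.parent.age - node.age == pytest.approx(node.length)
        assert min(n.age for n in t.leaves()) == pytest.approx(0.0)

    def test_yule_mean_root_age_matches_closed_form(self):
        """Mean root age over many Yule trees vs Σ_{i=2..n} 1/(λ i)."""
        lam, n = 0.5, 10
        ages = [simulate_tree(n, birth_rate=lam, seed=s).root.age for s in range(500)]
        expected = yule_expected_root_age(n, lam)
        assert np.mean(ages) == pytest.approx(expected, rel=0.15)

    def test_invalid_inputs(self):
        with pytest.raises(SimulationError):
            simulate_tree(1, birth_rate=0.1)
        with pytest.raises(SimulationError):
            simulate_tree(5, birth_rate=0.0)


class TestSimulateMkCharacter:
    def test_zero_rate_freezes_root_state(self):
        t = simulate_tree(15, birth_rate=0.1, seed=2)
        states = simulate_mk_character(t, q=0.0, root_state=2, seed=0)
        assert set(states.values()) == {2}

    def test_high_rate_reaches_uniform_stationary_distribution(self):
        t = star_tree(3000, 10.0)
        states = simulate_mk_character(t, q=1.0, root_state=0, seed=4)
        counts = np.bincount(list(states.values()), minlength=3)
        assert chisquare(counts).pvalue > 0.001

    def test_transition_fraction_matches_closed_form(self):
        """Fraction of tips retaining the root state on branches of length t
        follows P_same(t) = 1/3 + 2/3 e^(-3qt) within binomial error."""
        q, t, n = 0.1, 3.0, 2000
        tree = star_tree(n, t)
        states = simulate_mk_character(tree, q=q, root_state=1, seed=8)
        p_same = 1 / 3 + 2 / 3 * math.exp(-3 * q * t)
        observed = sum(1 for s in states.values() if s == 1) / n
        tol = 4 * math.sqrt(p_same * (1 - p_same) / n)
        assert abs(observed - p_same) < tol

    def test_deterministic_under_seed(self):
        t = simulate_tree(20, birth_rate=0.1, seed=6)
        assert simulate_mk_character(t, 0.05, 1, seed=9) == \
            simulate_mk_character(t, 0.05, 1, seed=9)


class TestSimulateStratRanges:
    def test_ranges_bracket_true_tip_ages(self):
        t = simulate_tree(20, birth_rate=0.05, seed=10)
        ranges = simulate_strat_ranges(t, max_offset=5.0, seed=11)
        for tip in t.leaves():
            r = ranges[tip.label]
            assert r.lad <= tip.age <= r.fad
            assert r.fad - tip.age <= 5.0


class TestSimulateEvidence:
    def test_zero_detection_yields_all_uncertain(self):
        spec = SimulationSpec(scar_detection_prob=0.0, process_preservation_prob=0.0,
                              seed=1)
        states = {f"t{i}": 1 for i in range(20)}
        coding = code_preferred(simulate_evidence(states, spec))
        assert all(coding.is_uncertain(t) for t in coding.taxa())

    def test_perfect_observation_recovers_true_states(self):
        spec = SimulationSpec(rib_count_mean=30.0, scar_detection_prob=1.0,
                              process_preservation_prob=1.0, seed=2)
        states = {"a": 0, "b": 1, "c": 2, "d": 1}
        coding = code_preferred(simulate_evidence(states, spec))
        assert coding["c"] == {2}
        assert coding["b"] == coding["d"] == {1}
        assert coding.is_uncertain("a")  # absence is never directly observable

    def test_lower_detection_never_increases_present_count_on_average(self):
        states = {f"t{i}": (1 if i % 2 else 2) for i in range(40)}
        means = []
        for p in (0.1, 0.4, 0.9):
            counts = [
                code_preferred(
                    simulate_evidence(states, SimulationSpec(scar_detection_prob=p,
                                                             seed=s))
                ).n_present()
                for s in range(30)
            ]
            means.append(np.mean(counts))
        assert means[0] <= means[1] <= means[2]


class TestEndToEndRecovery:
    def test_root_state_recovered_under_moderate_rate(self):
        """Planting root state 1 with moderate rate, marginal ML puts its
        top root probability on state 1 in >=90% of replicates."""
        # q chosen so lineages expect ~0.3 changes root-to-tip: the slow
        # regime of a skeletal character; root signal decays at higher q
        wins = 0
        reps = 100
        for s in range(reps):
            tree = simulate_tree(60, birth_rate=0.25, seed=1000 + s)
            states = simulate_mk_character(tree, q=0.01, root_state=1, seed=2000 + s)
            coding = CharacterCoding({k: frozenset({v}) for k, v in states.items()})
            model, _, _ = fit_mk(tree, coding)
            res = marginal_asr_ml(tree, coding, model)
            if int(np.argmax(res.node_states[tree.root.id])) == 1:
                wins += 1
        assert wins >= 0.90 * reps


class TestStudyFixture:
    def test_shape_mirrors_study(self, study_fixture):
        tree = parse_newick(study_fixture.supertree_newick)
        assert tree.n_tips == 40
        pref = code_preferred(study_fixture.evidence)
        alt = code_alternate(study_fixture.evidence)
        assert pref.n_present() >= 19
        assert alt.n_absent() == 9
        assert pref["OUT01"] == {0}
        # ossified evidence confined to the nested pennaraptoran-like clade
        ossified = {t for t in pref.taxa() if pref[t] == {2}}
        assert ossified == {t for t in tree.leaf_labels() if t.startswith("penna")}
        assert set(study_fixture.clades) == {
            "Archosauria", "Dinosauria", "Maniraptoriformes", "Pennaraptora",
        }

    def test_clades_are_nested(self, study_fixture):
        tree = parse_newick(study_fixture.supertree_newick)
        spans = {
            name: frozenset(
                n.label for n in tree.mrca(taxa).leaves()
            )
            for name, taxa in study_fixture.clades.items()
        }
        assert spans["Pennaraptora"] < spans["Maniraptoriformes"] \
            < spans["Dinosauria"] < spans["Archosauria"]

    def test_every_taxon_has_range_and_evidence(self, study_fixture):
        tree = parse_newick(study_fixture.supertree_newick)
        taxa = set(tree.leaf_labels())
        assert set(study_fixture.ranges) == taxa
        assert {e.taxon for e in study_fixture.evidence} == taxa

    def test_fixture_files_byte_identical_across_runs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_study_fixture().write(d1)
        make_study_fixture().write(d2)
        files = sorted(p.name for p in d1.iterdir())
        assert files == sorted(p.name for p in d2.iterdir())
        for name in files:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()
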