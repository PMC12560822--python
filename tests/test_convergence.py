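import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rifconv as rc
from rifconv.asr import AncestralReconstruction
from conftest import make_alignment
from oracles import brute_force_convergent_sites, stepup_bh

AA = rc.AMINO_ACIDS.index


def onehot_reconstruction(tree, state_rows, gene_id="g"):
    """Build a reconstruction with assigned states fixed and posterior 1."""
    states = np.array(state_rows, dtype=np.int8)
    n_nodes, n_sites = states.shape
    post = np.zeros((n_nodes, n_sites, 20))
    for v in range(n_nodes):
        post[v, np.arange(n_sites), states[v]] = 1.0
    return AncestralReconstruction(
        gene_id=gene_id, posteriors=post, states=states,
        missing=np.zeros((n_nodes, n_sites), dtype=bool),
        site_log_likelihood=np.zeros(n_sites),
    )


@pytest.fixture()
def three_leaf_setup():
    """((A,B),C) with terminal foreground branches A and C."""
    tree = rc.read_tree("((A:0.1,B:0.1):0.1,C:0.2);")
    rc.resolve_foreground(tree, [("A",), ("C",)])
    return tree


class TestEnumerateSubstitutions:
    def test_call_emitted_with_notation(self, three_leaf_setup):
        tree = three_leaf_setup
        # leaves A,B then internal (A,B), leaf C, root — postorder ids 0..4
        seq_a = "T" * 202 + "S"
        aln = make_alignment("g", ["A", "B", "C"],
                             [seq_a, "T" * 203, "T" * 203])
        states = np.tile(AA("T"), (5, 203))
        rec = onehot_reconstruction(tree, states)
        calls = rc.enumerate_substitutions(rec, aln, tree)
        assert len(calls) == 1
        (call,) = calls
        assert call.site == 203
        assert call.notation == "T203S"
        assert call.child_posterior == 1.0

    def test_no_call_when_states_equal_or_missing(self, three_leaf_setup):
        tree = three_leaf_setup
        aln = make_alignment("g", ["A", "B", "C"], ["S-", "SS", "SS"])
        states = np.tile(AA("S"), (5, 2))
        rec = onehot_reconstruction(tree, states)
        assert rc.enumerate_substitutions(rec, aln, tree) == []

    def test_min_posterior_filters(self, three_leaf_setup):
        tree = three_leaf_setup
        aln = make_alignment("g", ["A", "B", "C"], ["S", "T", "S"])
        states = np.tile(AA("T"), (5, 1))
        rec = onehot_reconstruction(tree, states)
        rec.posteriors[tree.parent[tree.node_of_label("A")], 0, AA("T")] = 0.6
        assert len(rc.enumerate_substitutions(rec, aln, tree)) == 2
        assert len(rc.enumerate_substitutions(rec, aln, tree,
                                              min_posterior=0.7)) == 1


class TestCallConvergentSites:
    def _setup(self):
        tree = rc.default_tree()
        return tree

    def test_mixed_class_two_ancestral_states(self):
        """Foreground ancestors {A, A, E} all deriving S is class 'mixed'."""
        tree = rc.read_tree(
            "(((A1:0.1,A2:0.1):0.1,(B1:0.1,B2:0.1):0.1):0.1,"
            "((C1:0.1,C2:0.1):0.1,O:0.3):0.1);")
        rc.resolve_foreground(tree, [("A1", "A2"), ("B1", "B2"), ("C1", "C2")])
        fg = sorted(tree.foreground)
        aln = make_alignment("g", ["A1", "A2", "B1", "B2", "C1", "C2", "O"],
                             ["S"] * 6 + ["A"])
        states = np.tile(AA("A"), (tree.n_nodes, 1))
        for b in fg:
            states[b] = AA("S")
        states[tree.parent[fg[2]]] = AA("E")
        rec = onehot_reconstruction(tree, states)
        calls = rc.enumerate_substitutions(rec, aln, tree)
        sites = rc.call_convergent_sites(calls, rec, aln, tree)
        assert len(sites) == 1
        site = sites[0]
        assert site.classification == "mixed"
        assert site.derived_state == AA("S")
        assert set(site.notation.split(",")) == {"A1S", "E1S"}

    def test_parallel_class(self, three_leaf_setup):
        tree = three_leaf_setup
        aln = make_alignment("g", ["A", "B", "C"], ["S", "T", "S"])
        states = np.tile(AA("T"), (5, 1))
        rec = onehot_reconstruction(tree, states)
        calls = rc.enumerate_substitutions(rec, aln, tree)
        sites = rc.call_convergent_sites(calls, rec, aln, tree)
        assert len(sites) == 1
        assert sites[0].classification == "parallel"

    def test_gap_in_foreground_leaf_fails_identity(self):
        tree = rc.read_tree("(((A1:0.1,A2:0.1):0.1,B:0.2):0.1,C:0.3);")
        rc.resolve_foreground(tree, [("A1", "A2"), ("C",)])
        fg = sorted(tree.foreground)
        aln = make_alignment("g", ["A1", "A2", "B", "C"], ["S", "-", "T", "S"])
        states = np.tile(AA("T"), (tree.n_nodes, 1))
        states[fg[0]] = AA("S")
        rec = onehot_reconstruction(tree, states)
        calls = rc.enumerate_substitutions(rec, aln, tree)
        assert rc.call_convergent_sites(calls, rec, aln, tree) == []

    def test_fewer_than_two_foreground_errors(self):
        tree = rc.read_tree("((A:0.1,B:0.1):0.1,C:0.2);")
        rc.resolve_foreground(tree, [("A",)])
        aln = make_alignment("g", ["A", "B", "C"], ["S", "T", "T"])
        rec = onehot_reconstruction(tree, np.tile(AA("T"), (5, 1)))
        with pytest.raises(rc.RifconvError, match="2 foreground"):
            rc.call_convergent_sites([], rec, aln, tree)

    @pytest.mark.parametrize("mode", ["all_foreground", "pairwise"])
    def test_agrees_with_brute_force_scanner(self, bench_tree, mode):
        """Synthetic genes: site calls equal a literal rule-by-rule scan."""
        cfg = rc.SimulationConfig(n_genes=6, sites_per_gene=120, seed=11,
                                  n_injected_genes=4, sites_per_injected_gene=2)
        alns, _, tree = rc.simulate_benchmark(cfg)
        for aln in alns:
            model = rc.build_model(rc.estimate_f_gene(aln))
            rec = rc.reconstruct(aln, tree, model)
            calls = rc.enumerate_substitutions(rec, aln, tree)
            mine = {s.site for s in rc.call_convergent_sites(
                calls, rec, aln, tree, mode=mode)}
            assert mine == brute_force_convergent_sites(aln, rec, tree, mode)

    def test_pairwise_superset_of_all_foreground(self, bench_tree):
        cfg = rc.SimulationConfig(n_genes=4, sites_per_gene=150, seed=3,
                                  n_injected_genes=2)
        alns, _, tree = rc.simulate_benchmark(cfg)
        for aln in alns:
            model = rc.build_model(rc.estimate_f_gene(aln))
            rec = rc.reconstruct(aln, tree, model)
            calls = rc.enumerate_substitutions(rec, aln, tree)
            all_fg = {s.site for s in rc.call_convergent_sites(
                calls, rec, aln, tree, mode="all_foreground")}
            pair = {s.site for s in rc.call_convergent_sites(
                calls, rec, aln, tree, mode="pairwise")}
            assert all_fg <= pair


class TestExpectedCount:
    def test_zero_branch_lengths_give_zero(self):
        # zero-length foreground branches: P(0)=I so substitute-to prob is 0
        tree2 = rc.read_tree("(((A:0.0,B:0.1):0.1,C:0.0):0.1,D:0.3);")
        rc.resolve_foreground(tree2, [("A",), ("C",)])
        aln = make_alignment("g", list("ABCD"), ["KR", "KN", "QN", "KD"])
        model = rc.build_model(rc.estimate_f_gene(aln))
        rec = rc.reconstruct(aln, tree2, model)
        lam = rc.expected_convergent_count(rec, aln, tree2, model)
        assert lam == pytest.approx(0.0, abs=1e-14)

    def test_concentrated_parent_hand_formula(self):
        tree = rc.read_tree("((A:0.15,B:0.1):0.1,C:0.25);")
        rc.resolve_foreground(tree, [("A",), ("C",)])
        aln = make_alignment("g", list("ABC"), ["K", "K", "K"])
        model = rc.build_model(rc.estimate_f_gene(aln, pseudocount=1))
        states = np.tile(AA("K"), (5, 1))
        rec = onehot_reconstruction(tree, states)
        lam = rc.expected_convergent_count(rec, aln, tree, model)
        P1 = model.transition_matrix(0.15)
        P2 = model.transition_matrix(0.25)
        x = AA("K")
        expected = sum(P1[x, a] * P2[x, a] for a in range(20) if a != x)
        assert lam == pytest.approx(expected, rel=1e-10)

    def test_monte_carlo_oracle(self, bench_tree):
        """Simulated site evolutions from the posteriors match analytic rate."""
        cfg = rc.SimulationConfig(n_genes=1, sites_per_gene=1, seed=21)
        alns, _, tree = rc.simulate_benchmark(cfg)
        aln = make_alignment("g", alns[0].taxa,
                             [s * 1 for s in ("K", "K", "R", "K", "K",
                                              "Q", "K", "K", "K")])
        model = rc.build_model(rc.estimate_f_gene(aln))
        rec = rc.reconstruct(aln, tree, model)
        lam = rc.expected_convergent_count(rec, aln, tree, model)
        fg = sorted(tree.foreground)
        rng = np.random.default_rng(5)
        n = 10_000
        hits = 0
        for _ in range(n):
            ends = []
            ok = True
            for b in fg:
                u = int(tree.parent[b])
                x = rng.choice(20, p=rec.posteriors[u, 0])
                P = model.transition_matrix(tree.branch_lengths[b])
                y = rng.choice(20, p=P[x])
                if y == x:
                    ok = False
                    break
                ends.append(y)
            if ok and len(set(ends)) == 1:
                hits += 1
        se = np.sqrt(lam * (1 - lam) / n)
        assert abs(hits / n - lam) <= 3 * se + 1e-12

    def test_additive_over_sites_and_row_order_invariant(self, bench_tree):
        cfg = rc.SimulationConfig(n_genes=1, sites_per_gene=80, seed=9,
                                  n_injected_genes=1)
        alns, _, tree = rc.simulate_benchmark(cfg)
        aln = alns[0]
        model = rc.build_model(rc.estimate_f_gene(aln))
        rec = rc.reconstruct(aln, tree, model)
        lam = rc.expected_convergent_count(rec, aln, tree, model)
        # split alignment columns: lambda adds across the parts
        parts = []
        for sl in (slice(0, 37), slice(37, 80)):
            sub = rc.Alignment(aln.gene_id, aln.taxa, aln.codes[:, sl])
            r = rc.reconstruct(sub, tree, model)  # same model for all parts
            parts.append(rc.expected_convergent_count(r, sub, tree, model))
        assert lam == pytest.approx(sum(parts), rel=1e-9)
        # row order invariance
        perm = list(reversed(range(aln.n_taxa)))
        aln2 = rc.Alignment(aln.gene_id, [aln.taxa[i] for i in perm],
                            aln.codes[perm])
        rec2 = rc.reconstruct(aln2, tree, model)
        lam2 = rc.expected_convergent_count(rec2, aln2, tree, model)
        assert lam2 == pytest.approx(lam, rel=1e-9)


class TestPoissonAndBH:
    def test_zero_observed_gives_one(self):
        assert rc.poisson_test(0, 0.5) == 1.0

    def test_closed_form_partial_sum(self):
        expected = 1 - np.exp(-0.1) * 1.1
        assert rc.poisson_test(2, 0.1) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_null_warns(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            assert rc.poisson_test(3, 0.0) == 0.0

    def test_limit_monotone_to_zero(self):
        ps = [rc.poisson_test(1, lam) for lam in (1e-1, 1e-3, 1e-6, 1e-9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 1e-8

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            rc.poisson_test(-1, 0.5)
        with pytest.raises(ValueError):
            rc.poisson_test(1, -0.5)

    def test_bh_stepup_example(self):
        q = rc.bh_adjust([0.001, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.004, 0.04, 4 * 0.04 / 3, 0.5],
                                   atol=1e-12)

    def test_bh_equal_ps_unchanged(self):
        np.testing.assert_allclose(rc.bh_adjust([0.3] * 5), [0.3] * 5)

    def test_bh_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            rc.bh_adjust([0.5, 1.2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_bh_matches_stepup_oracle_and_is_monotone(self, ps):
        q = rc.bh_adjust(ps)
        np.testing.assert_allclose(q, stepup_bh(ps), atol=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestScanGenes:
    def test_empty_collection(self, bench_tree):
        results, summary = rc.scan_genes([], bench_tree)
        assert results == []
        assert summary["n_genes_scanned"] == 0

    def test_gene_with_missing_taxa_skipped(self, bench_tree):
        aln = make_alignment("bad", ["A", "B"], ["KK", "KR"])
        results, summary = rc.scan_genes([aln], bench_tree)
        assert results == []
        assert summary["skipped_genes"] == ["bad"]

    def test_recovery_scaled_down(self):
        """Injected genes attain the smallest q and their sites are listed."""
        cfg = rc.SimulationConfig(n_genes=40, sites_per_gene=200, seed=13,
                                  n_injected_genes=3)
        alns, manifest, tree = rc.simulate_benchmark(cfg)
        results, summary = rc.scan_genes(alns, tree)
        injected = {m.gene_id for m in manifest}
        top = {r.gene_id for r in results[:3]}
        assert top == injected
        by_gene = {r.gene_id: r for r in results}
        recovered = sum(
            any(s.site == m.site for s in by_gene[m.gene_id].sites)
            for m in manifest
        )
        assert recovered >= 0.8 * len(manifest)
        df = rc.results_to_frame(results)
        assert list(df.columns) == ["gene_id", "k", "lambda", "p", "q",
                                    "mode", "sites"]

    def test_null_no_significant_genes(self):
        cfg = rc.SimulationConfig(n_genes=40, sites_per_gene=200, seed=17)
        alns, _, tree = rc.simulate_benchmark(cfg)
        results, summary = rc.scan_genes(alns, tree)
        assert summary["n_significant"] <= 1
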