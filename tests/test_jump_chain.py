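"""Jump-chain engine: dwell times, event draws, branches, trees, roots."""

import math

import numpy as np
import pytest
from scipy import stats

from cpgjump.jump_chain import (
    JumpChainEngine,
    burn_in_root,
    draw_dwell,
    draw_event,
    draw_root,
    simulate_alignment,
    simulate_branch_reference,
    stationary_root,
)
from cpgjump.phylo_io import Phylogeny
from cpgjump.substitution_model import (
    SequenceState,
    build_rate_table,
    resolve_site_omega,
    stationary_m0,
)
from cpgjump.genetic_code import STANDARD_CODE
from conftest import make_params


class TestDrawDwell:
    def test_inverse_transform_values(self):
        assert draw_dwell(2.0, 0.0) == 0.0
        assert draw_dwell(2.0, 1 - math.exp(-2.0)) == pytest.approx(1.0)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            draw_dwell(0.0, 0.5)
        with pytest.raises(ValueError):
            draw_dwell(2.0, 1.0)

    def test_mean_matches_exponential(self):
        rng = np.random.RandomState(1)
        draws = np.array([draw_dwell(2.0, u) for u in rng.random_sample(20000)])
        se = 0.5 / math.sqrt(draws.size)
        assert abs(draws.mean() - 0.5) < 3 * se


class TestDrawEvent:
    def test_single_site_proportions(self):
        """Empirical event frequencies match rate proportions (chi-square)."""
        p = make_params(lam=8.0, omega=0.3)
        seq = SequenceState.from_codon_strings(["ACG", "CAT", "TCG"])
        table = build_rate_table(p, seq)
        rng = np.random.RandomState(3)
        counts = {}
        n = 20000
        for u in rng.random_sample(n):
            counts[draw_event(table, u)] = counts.get(draw_event(table, u), 0) + 1
        keys = sorted(counts)
        observed = np.array([counts[k] for k in keys])
        expected = np.array([table.rates[k] for k in keys])
        expected = expected / expected.sum() * observed.sum()
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_degenerate_table_returns_only_event(self):
        # a 1-codon sequence: every draw lands on one of its events
        p = make_params()
        table = build_rate_table(p, SequenceState.from_codon_strings(["TGG"]))
        for u in (0.0, 0.5, 0.999999):
            site, slot = draw_event(table, u)
            assert site == 0 and table.rates[0, slot] > 0


class TestBranchSimulation:
    def test_zero_length_branch_is_identity(self):
        p = make_params()
        seq = SequenceState.from_dna("ATGAAACCC")
        eng = JumpChainEngine(p, resolve_site_omega(p, 3))
        end, events, counts = eng.simulate_branch(seq, 0.0, 1)
        assert np.array_equal(end.codons, seq.codons)
        assert events == [] and counts.sum() == 0

    def test_same_seed_reproduces_exactly(self):
        p = make_params(lam=4.0)
        seq = SequenceState(np.random.default_rng(0).integers(0, 61, 50))
        eng = JumpChainEngine(p, resolve_site_omega(p, 50))
        a = eng.simulate_branch(seq, 1.5, 42)
        b = eng.simulate_branch(seq, 1.5, 42)
        assert np.array_equal(a[0].codons, b[0].codons)
        assert a[1] == b[1]

    def test_kernel_matches_pure_python_reference(self):
        """The compiled loop and the documented step-by-step path agree
        event for event on the same random stream."""
        p = make_params(lam=8.0, omega=0.3)
        rng = np.random.default_rng(8)
        seq = SequenceState(rng.integers(0, 61, 20))
        so = resolve_site_omega(p, 20)
        eng = JumpChainEngine(p, so)
        end_k, ev_k, _ = eng.simulate_branch(seq, 2.0, 12345)
        end_r, ev_r = simulate_branch_reference(p, seq, 2.0, 12345, so)
        assert np.array_equal(end_k.codons, end_r.codons)
        assert len(ev_k) == len(ev_r) > 10
        for a, b in zip(ev_k, ev_r):
            assert (a.site, a.position, a.from_codon, a.to_codon, a.klass) == (
                b.site, b.position, b.from_codon, b.to_codon, b.klass
            )
            assert a.time == pytest.approx(b.time, rel=1e-12)

    def test_mean_event_count_matches_unit_rate(self):
        """Normalized lam=1 process: expected events = sites x branch length."""
        p = make_params(lam=1.0, omega=0.5)
        n_sites, t, reps = 30, 2.0, 300
        eng = JumpChainEngine(p, resolve_site_omega(p, n_sites))
        rng = np.random.default_rng(17)
        counts = []
        for r in range(reps):
            root = stationary_root(p, n_sites, rng)
            _, _, c = eng.simulate_branch(root, t, 1000 + r, want_events=False)
            counts.append(c.sum())
        counts = np.array(counts)
        se = counts.std(ddof=1) / math.sqrt(reps)
        assert abs(counts.mean() - n_sites * t) < 3 * se

    def test_transition_fraction_increases_with_kappa(self):
        fractions = []
        for kappa in (1.0, 4.0, 16.0):
            p = make_params(kappa=kappa, lam=1.0, omega=1.0)
            eng = JumpChainEngine(p, resolve_site_omega(p, 30))
            rng = np.random.default_rng(23)
            root = stationary_root(p, 30, rng)
            _, _, c = eng.simulate_branch(root, 30.0, 99, want_events=False)
            ts = c[1] + c[2] + c[4] + c[5]
            fractions.append(ts / c.sum())
        assert fractions[0] < fractions[1] < fractions[2]


class TestRootDraws:
    def test_fixed_mode_echoes_input(self):
        p = make_params()
        seq = SequenceState.from_dna("ATGCCC")
        out = draw_root("fixed", p, 2, np.random.default_rng(0), fixed=seq)
        assert np.array_equal(out.codons, seq.codons)

    def test_zero_burn_in_returns_start(self):
        p = make_params()
        seq = SequenceState.from_dna("ATGCCCAAA")
        out = burn_in_root(p, 3, 0, np.random.default_rng(0), start=seq)
        assert np.array_equal(out.codons, seq.codons)

    def test_burn_in_at_lam_one_preserves_stationarity(self, phi):
        """lam=1 burn-in keeps the closed-form codon distribution."""
        p = make_params(lam=1.0)
        pi = stationary_m0(phi)
        rng = np.random.default_rng(31)
        eng = JumpChainEngine(p, resolve_site_omega(p, 100))
        freqs = np.zeros(61)
        n_chains = 300
        for k in range(n_chains):
            start = stationary_root(p, 100, rng)
            end = eng.burn_in(start, 2000, 7000 + k)
            freqs += np.bincount(end.codons, minlength=61)
        freqs /= freqs.sum()
        assert 0.5 * np.abs(freqs - pi).sum() < 0.02

    def test_burn_in_insensitive_to_doubling(self):
        """The default burn-in length has converged: doubling it leaves the
        CpG dinucleotide content statistically unchanged (lam=8)."""
        from cpgjump.genetic_code import CODON_NUCS

        p = make_params(lam=8.0, omega=0.5)
        n_sites, n_chains = 60, 120

        def cpg_fracs(n_events, seed0):
            rng = np.random.default_rng(seed0)
            out = []
            for _ in range(n_chains):
                seq = burn_in_root(p, n_sites, n_events, rng)
                nucs = CODON_NUCS[seq.codons].ravel()
                out.append(np.mean((nucs[:-1] == 1) & (nucs[1:] == 2)))
            return np.asarray(out)

        short = cpg_fracs(50 * n_sites, 41)
        doubled = cpg_fracs(100 * n_sites, 42)
        se = math.sqrt(short.var(ddof=1) / n_chains + doubled.var(ddof=1) / n_chains)
        assert abs(short.mean() - doubled.mean()) < 3 * se

    def test_hypermutability_depletes_cpg(self, phi):
        """Burned-in sequences at lam=8 carry fewer CpG dinucleotides."""
        from cpgjump.genetic_code import CODON_NUCS

        def mean_cpg(lam):
            p = make_params(lam=lam, omega=0.5)
            rng = np.random.default_rng(13)
            vals = []
            for k in range(40):
                seq = burn_in_root(p, 60, 3000, rng)
                nucs = CODON_NUCS[seq.codons].ravel()
                vals.append(np.mean((nucs[:-1] == 1) & (nucs[1:] == 2)))
            return np.mean(vals)

        assert mean_cpg(8.0) < 0.7 * mean_cpg(1.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            draw_root("nope", make_params(), 5, np.random.default_rng(0))


class TestTreeSimulation:
    def test_zero_length_tree_copies_root_everywhere(self):
        tree = Phylogeny.from_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        p = make_params()
        aln, hist = simulate_alignment(tree, p, 20, seed=5)
        seqs = list(aln.sequences.values())
        for s in seqs[1:]:
            assert np.array_equal(s.codons, seqs[0].codons)
        assert hist.n_events == 0

    def test_identical_seed_identical_alignment(self, small_tree):
        p = make_params(lam=4.0)
        a1, h1 = simulate_alignment(small_tree, p, 40, seed=77)
        a2, h2 = simulate_alignment(small_tree, p, 40, seed=77)
        for t in a1.taxa:
            assert np.array_equal(a1.sequences[t].codons, a2.sequences[t].codons)
        assert h1.branch_events == h2.branch_events

    def test_history_replay_reproduces_node_states(self, small_tree):
        """Applying each branch's recorded events to the parent state must
        land exactly on the stored child state."""
        p = make_params(lam=8.0, omega=0.3)
        _, hist = simulate_alignment(small_tree, p, 30, seed=21)
        for child, parent, length in small_tree.branches():
            cname, pname = small_tree.names[child], small_tree.names[parent]
            state = hist.node_states[pname].codons.copy()
            prev_t = 0.0
            for ev in hist.branch_events[cname]:
                assert prev_t < ev.time < length
                prev_t = ev.time
                site = ev.site
                assert STANDARD_CODE.index_to_codon[state[site]] == ev.from_codon
                state[site] = STANDARD_CODE.codon_to_index[ev.to_codon]
            assert np.array_equal(state, hist.node_states[cname].codons)

    def test_root_placement_invariance_at_lam_one(self, phi):
        """For the reversible lam=1 model the joint tip distribution on a
        two-tip tree does not depend on where the root splits the path."""
        p = make_params(lam=1.0, omega=0.5)
        pi = stationary_m0(phi)
        total = 0.6
        placements = [(0.0, 0.6), (0.2, 0.4), (0.3, 0.3)]
        n = 30000
        rng = np.random.default_rng(3)
        eng = JumpChainEngine(p, resolve_site_omega(p, 1))
        joints = []
        for pl_idx, (ta, tb) in enumerate(placements):
            root_counts = rng.multinomial(n, pi)
            joint = np.zeros((61, 61), dtype=int)
            for c in np.flatnonzero(root_counts):
                m = int(root_counts[c])
                start = SequenceState(np.array([c]))
                seed = 100000 + 1000 * pl_idx + int(c)
                if ta == 0.0:
                    ends_a = np.full(m, c)
                else:
                    ends_a = eng.branch_end_states(start, ta, m, seed)[:, 0]
                ends_b = eng.branch_end_states(start, tb, m, seed + 500)[:, 0]
                np.add.at(joint, (ends_a, ends_b), 1)
            joints.append(joint.ravel())
        joints = np.array(joints)
        pooled = joints.sum(axis=0)
        big = pooled >= 15
        table = np.column_stack([
            joints[:, big], joints[:, ~big].sum(axis=1)
        ])
        assert stats.chi2_contingency(table).pvalue > 0.001
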