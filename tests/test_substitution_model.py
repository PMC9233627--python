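"""The six-class CpG rate law, rate tables, and the lam=1 generator."""

import numpy as np
import pytest

from cpgjump.genetic_code import STANDARD_CODE
from cpgjump.substitution_model import (
    CpGModelParams,
    OmegaMixture,
    SequenceState,
    build_m0_matrix,
    build_rate_table,
    classify_event,
    event_rate,
    rate_scale,
    stationary_m0,
    update_rate_table,
)
from conftest import make_params


class TestClassifyEvent:
    def test_cross_codon_cpg_context_g_to_a(self):
        # ACG|GAT: G at site 0 position 3 has 5' C within its codon -> CpG;
        # ACG -> ACA is synonymous (both Thr)
        seq = SequenceState.from_codon_strings(["ACG", "GAT"])
        k = classify_event(seq, 0, 3, "G", "A", is_syn=True)
        assert k == "syn_ts_cpg"
        # the G starting site 1 is preceded by G (last nucleotide of ACG),
        # not C, so it is not in CpG context
        k = classify_event(seq, 1, 1, "G", "A", is_syn=False)
        assert k == "nonsyn_ts_noncpg"

    def test_cross_codon_boundary_context(self):
        # TAC|GAT: C at site 0 position 3 followed by G at site 1 position 1
        seq = SequenceState.from_codon_strings(["TAC", "GAT"])
        assert classify_event(seq, 0, 3, "C", "T", is_syn=True) == "syn_ts_cpg"
        # and the G of site 1 is preceded by C -> CpG for G->A
        assert (
            classify_event(seq, 1, 1, "G", "A", is_syn=False) == "nonsyn_ts_cpg"
        )
        # c_to_t_only mode ignores the G->A strand
        assert (
            classify_event(seq, 1, 1, "G", "A", is_syn=False, cpg_mode="c_to_t_only")
            == "nonsyn_ts_noncpg"
        )

    def test_within_codon_cpg(self):
        # TCG: C at position 2 followed by G at position 3
        seq = SequenceState.from_codon_strings(["TCG", "AAA"])
        assert classify_event(seq, 0, 2, "C", "T", is_syn=False) == "nonsyn_ts_cpg"

    def test_transversions_never_cpg(self):
        seq = SequenceState.from_codon_strings(["TCG", "AAA"])
        assert classify_event(seq, 0, 2, "C", "G", is_syn=False) == "nonsyn_tv"
        assert classify_event(seq, 0, 2, "C", "A", is_syn=True) == "syn_tv"

    def test_terminus_has_no_external_context(self):
        # lone codon: C at position 3 has no 3' neighbour -> not CpG
        seq = SequenceState.from_codon_strings(["TAC"])
        assert classify_event(seq, 0, 3, "C", "T", is_syn=True) == "syn_ts_noncpg"
        # G at position 1 of the first codon has no 5' neighbour
        seq = SequenceState.from_codon_strings(["GAT", "AAA"])
        assert classify_event(seq, 0, 1, "G", "A", is_syn=False) == "nonsyn_ts_noncpg"

    def test_out_of_range_rejected(self):
        seq = SequenceState.from_codon_strings(["AAA"])
        with pytest.raises(ValueError):
            classify_event(seq, 1, 1, "A", "G", True)
        with pytest.raises(ValueError):
            classify_event(seq, 0, 4, "A", "G", True)


class TestEventRate:
    def test_full_product_form(self):
        p = CpGModelParams(
            phi=(0.25, 0.25, 0.25, 0.25), kappa=4, lam=8, omega=0.2,
            normalization="none",
        )
        assert event_rate(p, "nonsyn_ts_cpg", "T") == pytest.approx(
            0.25 * 4 * 0.2 * 8
        )
        assert event_rate(p, "syn_tv", "T") == pytest.approx(0.25)
        assert event_rate(p, "syn_ts_noncpg", "G") == pytest.approx(0.25 * 4)
        assert event_rate(p, "nonsyn_tv", "A") == pytest.approx(0.25 * 0.2)

    def test_lam_one_collapses_cpg_classes(self):
        p = make_params(lam=1.0, normalization="none")
        for prefix in ("syn", "nonsyn"):
            assert event_rate(p, f"{prefix}_ts_cpg", "T") == pytest.approx(
                event_rate(p, f"{prefix}_ts_noncpg", "T")
            )

    def test_omega_one_collapses_syn_classes(self):
        p = make_params(omega=1.0, normalization="none")
        for suffix in ("tv", "ts_noncpg", "ts_cpg"):
            assert event_rate(p, f"syn_{suffix}", "C") == pytest.approx(
                event_rate(p, f"nonsyn_{suffix}", "C")
            )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CpGModelParams(phi=(0.5, 0.5, 0.1, -0.1))
        with pytest.raises(ValueError):
            CpGModelParams(kappa=0)
        with pytest.raises(ValueError):
            OmegaMixture((0.2, 0.5), weights=(0.9, 0.9))


class TestRateTable:
    def test_single_aaa_codon_total(self):
        # AAA has 8 sense neighbours; uniform phi and unit multipliers give
        # R = 8 * 0.25
        p = CpGModelParams(
            phi=(0.25,) * 4, kappa=1, lam=1, omega=1, normalization="none"
        )
        table = build_rate_table(p, SequenceState.from_codon_strings(["AAA"]))
        assert table.total == pytest.approx(2.0)
        assert table.n_events == 8

    def test_increasing_lam_never_decreases_total(self):
        seq = SequenceState.from_dna("ACGGATTCGCGATTTAAACCG")
        totals = [
            build_rate_table(make_params(lam=lam, normalization="none"), seq).total
            for lam in (1, 2, 4, 8)
        ]
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_total_matches_m0_diagonal_at_lam_one(self):
        p = make_params(lam=1.0)
        rng = np.random.default_rng(5)
        seq = SequenceState(rng.integers(0, 61, size=40))
        Q, _ = build_m0_matrix(p)
        expected = -np.diag(Q)[seq.codons].sum()
        assert build_rate_table(p, seq).total == pytest.approx(expected, rel=1e-12)

    def test_incremental_update_matches_rebuild(self):
        """Randomized oracle: apply events, compare running table to rebuild."""
        p = make_params(lam=8.0, omega=0.3)
        rng = np.random.default_rng(11)
        seq = SequenceState(rng.integers(0, 61, size=25))
        table = build_rate_table(p, seq)
        from cpgjump.genetic_code import NEIGHBOR_COUNTS, NEIGHBOR_STATE

        for _ in range(300):
            site = int(rng.integers(seq.n_sites))
            c = seq.codons[site]
            slot = int(rng.integers(NEIGHBOR_COUNTS[c]))
            seq.codons[site] = NEIGHBOR_STATE[c, slot]
            table = update_rate_table(table, site, seq)
            rebuilt = build_rate_table(p, seq, table.site_omega)
            np.testing.assert_allclose(table.rates, rebuilt.rates, rtol=1e-9)
            assert table.total == pytest.approx(rebuilt.total, rel=1e-9)

    def test_update_leaves_distant_sites_bit_identical(self):
        p = make_params(lam=4.0)
        seq = SequenceState.from_dna("ACG" * 10)
        table = build_rate_table(p, seq)
        from cpgjump.genetic_code import NEIGHBOR_STATE

        seq.codons[0] = NEIGHBOR_STATE[seq.codons[0], 0]
        updated = update_rate_table(table, 0, seq)
        assert np.array_equal(updated.site_totals[2:], table.site_totals[2:])
        assert np.array_equal(updated.rates[2:], table.rates[2:])

    def test_context_dependence_iff_lam_not_one(self):
        """Changing a flanking codon changes focal rates exactly when lam != 1."""
        # focal codon GAT: its position-1 G->A transition is in CpG context
        # exactly when the previous codon ends in C
        left_c = SequenceState.from_codon_strings(["ACC", "GAT", "AAA"])
        left_a = SequenceState.from_codon_strings(["ACA", "GAT", "AAA"])
        for lam, should_differ in ((1.0, False), (8.0, True)):
            p = make_params(lam=lam)
            r_c = build_rate_table(p, left_c).rates[1]
            r_a = build_rate_table(p, left_a).rates[1]
            assert np.array_equal(r_c, r_a) is not should_differ


class TestM0Matrix:
    def test_generator_rows_sum_to_zero(self, phi):
        Q, _ = build_m0_matrix(make_params())
        assert np.abs(Q.sum(axis=1)).max() < 1e-12

    def test_uniform_phi_gives_uniform_stationary(self):
        _, pi = build_m0_matrix(
            CpGModelParams(phi=(0.25,) * 4, kappa=3, omega=0.4)
        )
        np.testing.assert_allclose(pi, np.full(61, 1 / 61), atol=1e-14)

    def test_detailed_balance(self):
        Q, pi = build_m0_matrix(make_params(omega=0.3, kappa=5))
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_reference_normalization_unit_mean_rate(self):
        Q, pi = build_m0_matrix(make_params(omega=0.7))
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_stationary_is_phi_product(self, phi):
        pi = stationary_m0(phi)
        from cpgjump.genetic_code import CODON_NUCS

        raw = np.asarray(phi)[CODON_NUCS].prod(axis=1)
        np.testing.assert_allclose(pi, raw / raw.sum())

    def test_mixture_rejected(self):
        with pytest.raises(ValueError):
            build_m0_matrix(make_params(omega=OmegaMixture((0.2, 0.5))))


def test_rate_scale_is_inverse_mean_rate():
    p = make_params(omega=0.5)
    Q_none, pi = build_m0_matrix(
        CpGModelParams(phi=p.phi, kappa=p.kappa, omega=0.5, normalization="none")
    )
    mu = -(pi * np.diag(Q_none)).sum()
    assert rate_scale(p) == pytest.approx(1 / mu, rel=1e-12)
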