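import numpy as np
import pytest
from hypothesis import given, strategies as st

import chromlik as ck
from chromlik.statespace import LARGE

RATE = st.floats(min_value=0.0, max_value=50.0, allow_nan=False)


def bichrom(**overrides):
    base = dict(lambda0=0.01, lambda1=0.005, mu0=0.01, mu1=0.005,
                rho0=0.01, rho1=0.002, q01=0.01, q10=0.005,
                eps0=1e-6, eps1=1e-6)
    base.update(overrides)
    return ck.BiChroMParams(**base)


class TestBiChroMBuilder:
    def test_doubling_rate_appears_at_count_to_double(self, bichrom_space):
        Q = ck.build_q_bichrom(bichrom(), bichrom_space)
        assert Q.rate((5, 0), (10, 0)) == pytest.approx(0.01)
        assert Q.rate((5, 1), (10, 1)) == pytest.approx(0.002)

    def test_large_states_only_flip_trait(self, bichrom_space):
        Q = ck.build_q_bichrom(bichrom(), bichrom_space)
        assert Q.rate((LARGE, 0), (LARGE, 1)) == pytest.approx(1e-6)
        assert Q.rate((LARGE, 1), (LARGE, 0)) == pytest.approx(1e-6)
        i = bichrom_space.index_of(LARGE, 0)
        row = Q.dense()[i]
        off = [j for j, v in enumerate(row) if v != 0 and j != i]
        assert off == [bichrom_space.index_of(LARGE, 1)]

    def test_gain_and_doubling_overflow_into_large(self, bichrom_space):
        Q = ck.build_q_bichrom(bichrom(), bichrom_space)
        # gain from c_max and doubling from any count above c_max/2
        assert Q.rate((25, 0), (LARGE, 0)) == pytest.approx(0.01 + 0.01)
        assert Q.rate((13, 1), (LARGE, 1)) == pytest.approx(0.002)

    def test_contributions_to_same_cell_accumulate(self, bichrom_space):
        # from count 1, a single gain and a doubling both land on count 2
        Q = ck.build_q_bichrom(bichrom(), bichrom_space)
        assert Q.rate((1, 0), (2, 0)) == pytest.approx(0.01 + 0.01)

    def test_no_loss_from_count_one(self, bichrom_space):
        Q = ck.build_q_bichrom(bichrom(mu0=0.7), bichrom_space)
        i = bichrom_space.index_of(1, 0)
        dense = Q.dense()
        assert dense[i, :i].sum() == 0.0

    def test_all_zero_rates_give_zero_matrix(self, bichrom_space):
        p = ck.BiChroMParams(*([0.0] * 10))
        Q = ck.build_q_bichrom(p, bichrom_space)
        assert np.all(Q.dense() == 0.0)

    def test_dimension_and_row_sums_at_cmax_25(self, bichrom_space):
        Q = ck.build_q_bichrom(bichrom(), bichrom_space)
        assert Q.shape == (52, 52)
        assert np.abs(Q.dense().sum(axis=1)).max() < 1e-12

    def test_negative_rate_rejected(self):
        with pytest.raises(ck.InvalidArgumentError):
            bichrom(rho0=-0.1)

    def test_space_mismatch_rejected(self, solanum_space):
        with pytest.raises(ck.InvalidArgumentError):
            ck.build_q_bichrom(bichrom(), solanum_space)

    def test_sparsity_is_linear_in_state_count(self, bichrom_space):
        # at most 4 transitions per count row plus 1 per LARGE row
        Q = ck.build_q_bichrom(bichrom(), bichrom_space)
        c_max = bichrom_space.c_max
        assert Q.n_transitions() <= 4 * 2 * c_max + 2

    def test_trait_swap_symmetry(self, bichrom_space):
        """Swapping trait labels with their rate pairs permutes the matrix."""
        p = bichrom()
        swapped = ck.BiChroMParams(
            lambda0=p.lambda1, lambda1=p.lambda0, mu0=p.mu1, mu1=p.mu0,
            rho0=p.rho1, rho1=p.rho0, q01=p.q10, q10=p.q01,
            eps0=p.eps1, eps1=p.eps0)
        Q = ck.build_q_bichrom(p, bichrom_space).dense()
        Qs = ck.build_q_bichrom(swapped, bichrom_space).dense()
        perm = [bichrom_space.index_of(c, 1 - t)
                for c, t in bichrom_space.states]
        assert np.allclose(Qs[np.ix_(perm, perm)], Q, atol=0, rtol=0)

    @given(rates=st.lists(RATE, min_size=10, max_size=10))
    def test_generator_property_for_random_rates(self, rates):
        space = ck.build_state_space(8, (0, 1))
        Q = ck.build_q_bichrom(ck.BiChroMParams(*rates), space).dense()
        off = Q - np.diag(np.diag(Q))
        assert off.min() >= 0.0
        assert np.abs(Q.sum(axis=1)).max() <= 1e-12


class TestReducedBiChroM:
    def test_reduced_equals_full_with_shared_rho_entrywise(self, bichrom_space):
        r = ck.ReducedBiChroMParams(0.01, 0.005, 0.01, 0.005, 0.003,
                                    0.01, 0.005, 1e-6, 1e-6)
        full = ck.build_q_bichrom(r.expand(), bichrom_space).dense()
        red = ck.build_q_bichrom_reduced(r, bichrom_space).dense()
        assert np.array_equal(full, red)

    def test_shared_rho_is_trait_independent(self, bichrom_space):
        r = ck.ReducedBiChroMParams(0.01, 0.005, 0.01, 0.005, 0.003,
                                    0.01, 0.005, 1e-6, 1e-6)
        Q = ck.build_q_bichrom_reduced(r, bichrom_space)
        assert Q.rate((5, 0), (10, 0)) == Q.rate((5, 1), (10, 1)) == 0.003


class TestSolanumBuilder:
    def test_demiploidy_rate_twelve_to_eighteen(self):
        p = ck.SolanumParams(0.1, 0.01, 0.05, 0.02, 0.3, 0.4)
        Q = ck.build_q_solanum(p)
        assert Q.rate((12, "H"), (18, "H")) == pytest.approx(0.05)
        assert Q.rate((12, "W"), (18, "W")) == pytest.approx(0.02)

    def test_doubling_edges(self):
        p = ck.SolanumParams(0.1, 0.01, 0.05, 0.02, 0.3, 0.4)
        Q = ck.build_q_solanum(p)
        for src, dst in ((12, 24), (18, 36), (24, 48)):
            assert Q.rate((src, "H"), (dst, "H")) == pytest.approx(0.1)
            assert Q.rate((src, "W"), (dst, "W")) == pytest.approx(0.01)
        # demiploidy from 24 (1.5 x 24 = 36) is distinct from doubling 18->36
        assert Q.rate((24, "H"), (36, "H")) == pytest.approx(0.05)

    def test_out_of_set_targets_are_absent(self):
        """36 doubles to 72 and 48 to 96: outside the data's counts."""
        p = ck.SolanumParams(0.1, 0.01, 0.05, 0.02, 0.3, 0.4)
        Q = ck.build_q_solanum(p)
        space = Q.space
        i = space.index_of(36, "H")
        row = Q.dense()[i]
        off = [j for j, v in enumerate(row) if v != 0 and j != i]
        assert off == [space.index_of(36, "W")]
        assert row[space.index_of(36, "W")] == pytest.approx(0.3)

    def test_dimension_and_row_sums(self):
        p = ck.SolanumParams(0.1, 0.01, 0.05, 0.02, 0.3, 0.4)
        Q = ck.build_q_solanum(p)
        assert Q.shape == (10, 10)
        assert np.abs(Q.dense().sum(axis=1)).max() < 1e-12

    def test_reduced_solanum_nests_in_full(self):
        r = ck.ReducedSolanumParams(0.07, 0.05, 0.02, 0.3, 0.4)
        full = ck.build_q_solanum(r.expand()).dense()
        red = ck.build_q_solanum_reduced(r).dense()
        assert np.array_equal(full, red)


class TestChromEvolBuilder:
    @pytest.fixture
    def space(self):
        return ck.build_state_space(20, ("x",))

    def test_even_count_demiploidy_is_exact(self, space):
        p = ck.ChromEvolParams(0.0, 0.0, 0.0, 0.08)
        Q = ck.build_q_chromevol(p, space)
        assert Q.rate((10, "x"), (15, "x")) == pytest.approx(0.08)

    def test_odd_count_demiploidy_splits_between_floor_and_ceil(self, space):
        p = ck.ChromEvolParams(0.0, 0.0, 0.0, 0.08)
        Q = ck.build_q_chromevol(p, space)
        assert Q.rate((9, "x"), (13, "x")) == pytest.approx(0.04)
        assert Q.rate((9, "x"), (14, "x")) == pytest.approx(0.04)

    def test_row_sums_zero(self, space):
        p = ck.ChromEvolParams(0.02, 0.01, 0.005, 0.003)
        Q = ck.build_q_chromevol(p, space)
        assert np.abs(Q.dense().sum(axis=1)).max() < 1e-12

    def test_doubling_and_demiploidy_overflow_to_large(self, space):
        p = ck.ChromEvolParams(0.0, 0.0, 0.06, 0.08)
        Q = ck.build_q_chromevol(p, space)
        assert Q.rate((11, "x"), (LARGE, "x")) == pytest.approx(0.06)  # 22 > 20
        # 15: doubling 30 and both demiploidy targets 22/23 all overflow
        assert Q.rate((15, "x"), (LARGE, "x")) == pytest.approx(0.06 + 0.08)
        assert Q.rate((12, "x"), (18, "x")) == pytest.approx(0.08)


class TestRateMatrixValidation:
    def test_negative_off_diagonal_rejected_naming_row(self, solanum_space):
        import scipy.sparse as sp
        bad = np.zeros((10, 10))
        bad[3, 4] = -0.5
        rm = ck.RateMatrix(solanum_space, sp.csr_matrix(bad))
        with pytest.raises(ck.ModelDefinitionError, match="row 3"):
            rm.validate()

    def test_nonzero_row_sum_rejected(self, solanum_space):
        import scipy.sparse as sp
        bad = np.zeros((10, 10))
        bad[2, 5] = 0.5  # diagonal not closed
        rm = ck.RateMatrix(solanum_space, sp.csr_matrix(bad))
        with pytest.raises(ck.ModelDefinitionError, match="row 2"):
            rm.validate()

    def test_registry_exposes_the_five_named_models(self):
        assert set(ck.MODELS) == {"bichrom", "bichrom_reduced",
                                  "chromevol_m3", "solanum",
                                  "solanum_reduced"}
        assert ck.get_model("bichrom_reduced").reduced_of == "bichrom"
        with pytest.raises(ck.InvalidArgumentError):
            ck.get_model("nope")
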