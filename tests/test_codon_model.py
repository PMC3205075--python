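"""Codon-model mathematics: generator structure, matrix exponentials,
discrete-gamma discretization, and the pruning likelihood."""

import numpy as np
import pytest
from scipy.linalg import null_space

from claderates.alignment import AlignmentError, CodonAlignment, encode_sequence
from claderates.codon_model import (
    BranchParams,
    CodonModelMatrices,
    LikelihoodTree,
    Mg94Params,
    SiteRateModel,
    branch_expected_rates,
    build_mg94_matrix,
    discrete_gamma,
    log_likelihood,
    stationary_distribution,
    transition_probabilities,
)
from conftest import random_mg94


def n_nt_differences(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class TestMg94Matrix:
    def test_uniform_model_has_equal_single_change_rates(self, standard_code):
        params = Mg94Params.uniform(omega=1.0)
        Q = build_mg94_matrix(params, standard_code)
        sense = standard_code.sense_codons
        offdiag = []
        for i, ci in enumerate(sense):
            for j, cj in enumerate(sense):
                if i == j:
                    continue
                d = n_nt_differences(ci, cj)
                if d == 1:
                    offdiag.append(Q[i, j])
                else:
                    assert Q[i, j] == 0.0
        assert np.allclose(offdiag, offdiag[0])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_rows_sum_to_zero(self, standard_code, seed):
        Q = build_mg94_matrix(random_mg94(seed), standard_code)
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-10

    def test_stationary_distribution_matches_nullspace_solve(self, standard_code):
        params = random_mg94(5)
        Q = build_mg94_matrix(params, standard_code)
        pi = stationary_distribution(params, standard_code)
        # independent oracle: left null space of Q
        ns = null_space(Q.T)
        assert ns.shape[1] == 1
        pi_oracle = ns[:, 0] / ns[:, 0].sum()
        assert np.max(np.abs(pi - pi_oracle)) < 1e-8
        assert np.max(np.abs(pi @ Q)) < 1e-8

    @pytest.mark.parametrize("seed", [7, 8])
    def test_detailed_balance(self, standard_code, seed):
        params = random_mg94(seed)
        Q = build_mg94_matrix(params, standard_code)
        pi = stationary_distribution(params, standard_code)
        F = pi[:, None] * Q
        assert np.max(np.abs(F - F.T)) < 1e-10

    def test_mito_code_has_60_states(self, mito_code):
        Q = build_mg94_matrix(random_mg94(9), mito_code)
        assert Q.shape == (60, 60)
        assert np.max(np.abs(Q.sum(axis=1))) < 1e-10

    def test_invalid_frequencies_rejected(self):
        pi = np.full((3, 4), 0.3)  # rows sum to 1.2
        with pytest.raises(ValueError):
            Mg94Params(np.ones(6), pi)


class TestTransitionProbabilities:
    def test_t_zero_is_identity(self, standard_code):
        Q = build_mg94_matrix(random_mg94(1), standard_code)
        assert np.array_equal(transition_probabilities(Q, 0.0), np.eye(61))

    def test_negative_t_rejected(self, standard_code):
        Q = build_mg94_matrix(random_mg94(1), standard_code)
        with pytest.raises(ValueError):
            transition_probabilities(Q, -0.1)

    def test_matches_taylor_series_oracle(self, standard_code):
        params = random_mg94(3)
        Q = build_mg94_matrix(params, standard_code, normalize=True)
        t = 0.3
        P = transition_probabilities(Q, t)
        series = np.eye(61)
        term = np.eye(61)
        for k in range(1, 40):
            term = term @ (Q * t) / k
            series += term
        assert np.max(np.abs(P - series)) < 1e-8
        assert np.max(np.abs(P.sum(axis=1) - 1.0)) < 1e-10
        assert P.min() >= 0

    def test_semigroup_property(self, standard_mats):
        P1 = standard_mats.transition_matrix(0.2, 0.05)
        P2 = standard_mats.transition_matrix(0.3, 0.075)
        P3 = standard_mats.transition_matrix(0.5, 0.125)
        assert np.max(np.abs(P1 @ P2 - P3)) < 1e-8

    def test_eigen_route_matches_scipy_expm(self, standard_mats):
        from scipy.linalg import expm

        M = 0.4 * standard_mats.A_syn + 0.1 * standard_mats.A_nonsyn
        assert np.max(np.abs(standard_mats.transition_matrix(0.4, 0.1) - expm(M))) < 1e-10


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.2, 0.7, 1.0, 3.5])
    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_category_means_average_to_one(self, alpha, k):
        m = discrete_gamma(alpha, k)
        assert len(m) == k
        assert abs(m.mean() - 1.0) < 1e-9
        assert np.all(np.diff(m) > 0)

    def test_single_category_is_one(self):
        assert np.array_equal(discrete_gamma(0.5, 1), np.ones(1))


def two_taxon_tree():
    return LikelihoodTree(np.array([-1, 0, 0]), [None, "A", "B"], ["root", "A", "B"])


def quartet_tree():
    # root with children A, B, and internal node I -> (C, D)
    parent = np.array([-1, 0, 0, 0, 3, 3])
    taxon = [None, "A", "B", None, "C", "D"]
    names = ["root", "A", "B", "I", "C", "D"]
    return LikelihoodTree(parent, taxon, names)


class TestLikelihood:
    def test_two_taxon_single_codon_enumeration(self, standard_mats, standard_code):
        aln = CodonAlignment(["A", "B"], np.array([[7], [19]]), standard_code)
        bp = {"A": BranchParams(0.3, 0.1), "B": BranchParams(0.1, 0.02)}
        lnL = log_likelihood(aln, two_taxon_tree(), bp, standard_mats)
        PA = standard_mats.transition_matrix(0.3, 0.1)
        PB = standard_mats.transition_matrix(0.1, 0.02)
        direct = float(np.sum(standard_mats.pi_star * PA[:, 7] * PB[:, 19]))
        assert abs(lnL - np.log(direct)) < 1e-10

    def test_rerooting_invariance(self, standard_mats, standard_code):
        rng = np.random.default_rng(4)
        aln = CodonAlignment(
            ["A", "B", "C", "D"], rng.integers(0, 61, size=(4, 20)), standard_code
        )
        bp = {
            "A": BranchParams(0.2, 0.05),
            "B": BranchParams(0.15, 0.02),
            "C": BranchParams(0.3, 0.08),
            "D": BranchParams(0.1, 0.01),
            "I": BranchParams(0.12, 0.03),
        }
        lnL1 = log_likelihood(aln, quartet_tree(), bp, standard_mats)
        # reroot at the other internal node: root' children C, D, I'; I' -> (A, B)
        tree2 = LikelihoodTree(
            np.array([-1, 0, 0, 0, 3, 3]),
            [None, "C", "D", None, "A", "B"],
            ["root", "C", "D", "I", "A", "B"],
        )
        lnL2 = log_likelihood(aln, tree2, bp, standard_mats)
        assert abs(lnL1 - lnL2) < 1e-8

    def test_zero_length_internal_branch_is_identity(self, standard_mats, standard_code):
        rng = np.random.default_rng(5)
        aln = CodonAlignment(["A", "B"], rng.integers(0, 61, size=(2, 10)), standard_code)
        bp = {"A": BranchParams(0.3, 0.1), "B": BranchParams(0.1, 0.02)}
        lnL1 = log_likelihood(aln, two_taxon_tree(), bp, standard_mats)
        # insert a zero-length internal node above B
        tree2 = LikelihoodTree(
            np.array([-1, 0, 0, 2]), [None, "A", None, "B"], ["root", "A", "Z", "B"]
        )
        bp2 = {"A": BranchParams(0.3, 0.1), "Z": BranchParams(0.0, 0.0), "B": BranchParams(0.1, 0.02)}
        lnL2 = log_likelihood(aln, tree2, bp2, standard_mats)
        assert abs(lnL1 - lnL2) < 1e-10

    def test_pruning_equals_bruteforce_state_summation(self, standard_mats, standard_code):
        rng = np.random.default_rng(6)
        aln = CodonAlignment(
            ["A", "B", "C", "D"], rng.integers(0, 61, size=(4, 3)), standard_code
        )
        bp = {
            "A": BranchParams(0.2, 0.05),
            "B": BranchParams(0.15, 0.02),
            "C": BranchParams(0.3, 0.08),
            "D": BranchParams(0.1, 0.01),
            "I": BranchParams(0.12, 0.03),
        }
        tree = quartet_tree()
        lnL = log_likelihood(aln, tree, bp, standard_mats)
        P = {nm: standard_mats.transition_matrix(b.s, b.n) for nm, b in bp.items()}
        pi = standard_mats.pi_star
        total = 0.0
        for col in range(3):
            a, b, c, d = aln.codons[:, col]
            # sum over root state r and internal state i
            site = 0.0
            for r in range(61):
                inner = float(P["I"][r] @ (P["C"][:, c] * P["D"][:, d]))
                site += pi[r] * P["A"][r, a] * P["B"][r, b] * inner
            total += np.log(site)
        assert abs(lnL - total) < 1e-9

    def test_dual_rate_categories_average_site_likelihood(self, standard_mats, standard_code):
        aln = CodonAlignment(["A", "B"], np.array([[7], [19]]), standard_code)
        bp = {"A": BranchParams(0.3, 0.1), "B": BranchParams(0.1, 0.02)}
        sm = SiteRateModel(3, 2, 0.6, 1.4)
        lnL = log_likelihood(aln, two_taxon_tree(), bp, standard_mats, sm)
        acc = 0.0
        for cs, cn, w in sm.categories():
            PA = standard_mats.transition_matrix(0.3 * cs, 0.1 * cn)
            PB = standard_mats.transition_matrix(0.1 * cs, 0.02 * cn)
            acc += w * float(np.sum(standard_mats.pi_star * PA[:, 7] * PB[:, 19]))
        assert abs(lnL - np.log(acc)) < 1e-10

    def test_missing_codons_are_marginalized(self, standard_mats, standard_code):
        aln = CodonAlignment(["A", "B"], np.array([[7], [-1]]), standard_code)
        bp = {"A": BranchParams(0.3, 0.1), "B": BranchParams(0.1, 0.02)}
        lnL = log_likelihood(aln, two_taxon_tree(), bp, standard_mats)
        # with B missing the site likelihood is the marginal P(A=7)
        PA = standard_mats.transition_matrix(0.3, 0.1)
        assert abs(lnL - np.log(float(standard_mats.pi_star @ PA[:, 7]))) < 1e-10

    def test_entirely_missing_column_rejected(self, standard_mats, standard_code):
        aln = CodonAlignment(["A", "B"], np.array([[-1], [-1]]), standard_code)
        bp = {"A": BranchParams(0.1, 0.1), "B": BranchParams(0.1, 0.1)}
        with pytest.raises(ValueError, match="entirely missing"):
            log_likelihood(aln, two_taxon_tree(), bp, standard_mats)

    def test_negative_branch_rejected(self, standard_mats, standard_code):
        aln = CodonAlignment(["A", "B"], np.array([[7], [19]]), standard_code)
        bp = {"A": BranchParams(0.1, 0.0), "B": BranchParams(0.1, 0.0)}
        bp["A"].s = -0.1  # bypass the dataclass check to exercise the guard
        with pytest.raises(ValueError, match="negative"):
            log_likelihood(aln, two_taxon_tree(), bp, standard_mats)

    def test_analytic_gradient_matches_finite_differences(self, standard_mats, standard_code):
        rng = np.random.default_rng(11)
        aln = CodonAlignment(["A", "B"], rng.integers(0, 61, size=(2, 30)), standard_code)
        bp = {"A": BranchParams(0.25, 0.06), "B": BranchParams(0.12, 0.03)}
        sm = SiteRateModel(2, 2, 0.8, 1.2)
        lnL, grad = log_likelihood(
            aln, two_taxon_tree(), bp, standard_mats, sm, return_gradient=True
        )
        eps = 1e-6
        for nm in ("A", "B"):
            for k, comp in enumerate(("s", "n")):
                bp2 = {x: BranchParams(v.s, v.n) for x, v in bp.items()}
                setattr(bp2[nm], comp, getattr(bp2[nm], comp) + eps)
                fd = (log_likelihood(aln, two_taxon_tree(), bp2, standard_mats, sm) - lnL) / eps
                assert abs(fd - grad[nm][k]) < 1e-4 * max(1.0, abs(fd))


class TestBranchExpectedRates:
    def test_zero_length_branch(self, random_params, standard_code):
        dS, dN, T, omega = branch_expected_rates(
            BranchParams(0.0, 0.0), random_params, standard_code
        )
        assert (dS, dN, T) == (0.0, 0.0, 0.0)
        assert omega is None

    def test_no_nonsynonymous_component(self, random_params, standard_code):
        dS, dN, T, omega = branch_expected_rates(
            BranchParams(0.3, 0.0), random_params, standard_code
        )
        assert dN == 0.0 and dS == 0.3 and omega == 0.0

    def test_total_rate_matches_generator_sum_oracle(self, random_params, standard_code):
        bp = BranchParams(0.37, 0.11)
        dS, dN, T, omega = branch_expected_rates(bp, random_params, standard_code)
        mats = CodonModelMatrices(random_params, standard_code)
        M = bp.s * mats.A_syn + bp.n * mats.A_nonsyn
        total = -float(mats.pi_star @ np.diag(M))
        assert abs((dN + dS) - total) < 1e-8
        assert abs(T - total / 3.0) < 1e-12
        assert abs(omega - bp.n / bp.s) < 1e-12


class TestAlignmentParsing:
    def test_in_frame_stop_reported_with_coordinate(self, standard_code):
        with pytest.raises(AlignmentError, match="codon 2"):
            encode_sequence("ATGTAAAAA", standard_code, label="x")

    def test_frame_violation_rejected(self, standard_code):
        with pytest.raises(AlignmentError, match="divisible by 3"):
            encode_sequence("ATGA", standard_code)

    def test_gap_codons_missing(self, standard_code):
        out = encode_sequence("ATG---NNA", standard_code)
        assert out[0] == standard_code.index["ATG"]
        assert list(out[1:]) == [-1, -1]

    def test_mito_specific_stops(self, mito_code, standard_code):
        # AGA is sense in the standard code but a stop in vertebrate mito
        assert "AGA" in standard_code.index
        with pytest.raises(AlignmentError):
            encode_sequence("AGA", mito_code)
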