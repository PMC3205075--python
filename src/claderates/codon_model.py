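"""MG94xREV codon substitution model with dual across-site rate variation.

The model combines single-nucleotide codon changes, general-time-reversible
(REV) nucleotide exchangeabilities, positional (3x4) nucleotide frequencies,
and an omega multiplier on non-synonymous changes. Branches carry two
components: a synonymous length ``s`` and a non-synonymous length ``n``, each
in expected substitutions per codon of its class (at site-rate 1). Across-site
rate variation is modelled by two independent discrete-gamma distributions,
one multiplying ``s`` and one multiplying ``n`` ("dual" rate variation).

The generator is reversible with respect to the stationary codon distribution
implied by the positional frequencies, which makes the matrix exponential
exactly computable by symmetrization + eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alignment import MISSING, CodonAlignment
from .genetic_codes import NUCLEOTIDES, GeneticCode

#: canonical ordering of the six REV exchangeability pairs
REV_PAIRS = (("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T"))


@dataclass
class Mg94Params:
    """Parameters of the MG94xREV_3x4 model.

    Attributes
    ----------
    exchangeabilities:
        The six symmetric nucleotide-pair rates in :data:`REV_PAIRS` order
        (AC, AG, AT, CG, CT, GT); GT is conventionally fixed to 1.
    pi:
        ``(3, 4)`` positional nucleotide frequencies (rows sum to 1), columns
        in ACGT order.
    omega:
        Non-synonymous/synonymous rate ratio (>= 0); used when building a
        single rate matrix. Branch-level fits carry omega implicitly in the
        ``n``/``s`` components instead.
    """

    exchangeabilities: np.ndarray
    pi: np.ndarray
    omega: float = 1.0

    def __post_init__(self) -> None:
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.exchangeabilities.shape != (6,) or np.any(
            self.exchangeabilities <= 0
        ):
            raise ValueError("need 6 positive exchangeabilities")
        if self.pi.shape != (3, 4):
            raise ValueError("pi must be 3x4")
        if not np.allclose(self.pi.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each pi row must sum to 1")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")

    @classmethod
    def uniform(cls, omega: float = 1.0) -> "Mg94Params":
        return cls(np.ones(6), np.full((3, 4), 0.25), omega)


def discrete_gamma(alpha: float, n_categories: int) -> np.ndarray:
    """Mean-one discrete gamma category multipliers (equal-weight categories).

    Categories are equal-probability bins of a Gamma(alpha, 1/alpha)
    distribution; each category's multiplier is the bin's conditional mean, so
    the multipliers average exactly to 1.
    """
    if n_categories < 1:
        raise ValueError("need at least one category")
    if n_categories == 1:
        return np.ones(1)
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_categories
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    # conditional bin means via the incomplete-gamma identity:
    # E[X; X in bin] = F_{alpha+1}(b) - F_{alpha+1}(a) for a mean-1 gamma
    upper = gamma_dist.cdf(edges, alpha + 1, scale=1.0 / alpha)
    means = (upper[1:] - upper[:-1]) * k
    return means / means.mean()


@dataclass
class SiteRateModel:
    """Dual discrete-gamma across-site rate variation.

    Two independent discrete-gamma distributions multiply the synonymous and
    non-synonymous branch components respectively. ``n_categories_* = 1``
    disables variation for that class.
    """

    n_categories_syn: int = 4
    n_categories_nonsyn: int = 4
    alpha_syn: float = 1.0
    alpha_nonsyn: float = 1.0

    @property
    def syn_multipliers(self) -> np.ndarray:
        return discrete_gamma(self.alpha_syn, self.n_categories_syn)

    @property
    def nonsyn_multipliers(self) -> np.ndarray:
        return discrete_gamma(self.alpha_nonsyn, self.n_categories_nonsyn)

    def categories(self) -> list[tuple[float, float, float]]:
        """(syn multiplier, nonsyn multiplier, weight) over the product set."""
        ms, mn = self.syn_multipliers, self.nonsyn_multipliers
        w = 1.0 / (len(ms) * len(mn))
        return [(cs, cn, w) for cs in ms for cn in mn]


@dataclass
class BranchParams:
    """Per-branch synonymous and non-synonymous lengths.

    ``s`` and ``n`` are expected substitutions per codon of each class on the
    branch at reference site-rate 1.
    """

    s: float
    n: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s) and np.isfinite(self.n)):
            raise ValueError("branch components must be finite")
        if self.s < 0 or self.n < 0:
            raise ValueError("branch components must be non-negative")


def stationary_distribution(params: Mg94Params, code: GeneticCode) -> np.ndarray:
    """Stationary codon distribution: product of positional frequencies,
    restricted to sense codons and renormalized."""
    pi = np.empty(code.n_states)
    for i, codon in enumerate(code.sense_codons):
        pi[i] = np.prod(
            [params.pi[p, NUCLEOTIDES.index(codon[p])] for p in range(3)]
        )
    return pi / pi.sum()


def _single_change_topology(code: GeneticCode):
    """Index arrays describing all single-nucleotide codon changes.

    Returns (i, j, pair_index, position, target_nt, is_syn) arrays covering
    every ordered sense-codon pair differing at exactly one position.
    """
    pair_idx = {}
    for k, (x, y) in enumerate(REV_PAIRS):
        pair_idx[(x, y)] = k
        pair_idx[(y, x)] = k
    I, J, K, P, Y, S = [], [], [], [], [], []
    for i, ci in enumerate(code.sense_codons):
        for p in range(3):
            for y in NUCLEOTIDES:
                if y == ci[p]:
                    continue
                cj = ci[:p] + y + ci[p + 1 :]
                j = code.index.get(cj)
                if j is None:
                    continue
                I.append(i)
                J.append(j)
                K.append(pair_idx[(ci[p], y)])
                P.append(p)
                Y.append(NUCLEOTIDES.index(y))
                S.append(code.is_synonymous(ci, cj))
    return (
        np.array(I),
        np.array(J),
        np.array(K),
        np.array(P),
        np.array(Y),
        np.array(S, dtype=bool),
    )


_TOPOLOGY_CACHE: dict[str, tuple] = {}


def _topology(code: GeneticCode):
    if code.code_id not in _TOPOLOGY_CACHE:
        _TOPOLOGY_CACHE[code.code_id] = _single_change_topology(code)
    return _TOPOLOGY_CACHE[code.code_id]


def build_mg94_matrix(
    params: Mg94Params, code: GeneticCode, normalize: bool = False
) -> np.ndarray:
    """MG94xREV rate matrix over sense codons.

    Off-diagonal entries for codons differing at one position ``p`` by the
    change x->y equal ``rev(x, y) * pi[p][y]``, times ``omega`` for
    non-synonymous changes; multi-position changes have rate 0; rows sum to 0.
    With ``normalize=True`` the matrix is rescaled to one expected
    substitution per codon at stationarity.
    """
    I, J, K, P, Y, S = _topology(code)
    Q = np.zeros((code.n_states, code.n_states))
    rates = params.exchangeabilities[K] * params.pi[P, Y]
    rates = np.where(S, rates, rates * params.omega)
    Q[I, J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        pi_star = stationary_distribution(params, code)
        mu = -float(pi_star @ np.diag(Q))
        if mu > 0:
            Q = Q / mu
    return Q


class CodonModelMatrices:
    """Precomputed generator pieces for one (exchangeabilities, pi, code).

    ``A_syn`` and ``A_nonsyn`` are the synonymous and non-synonymous parts of
    the MG94xREV generator, each normalized to unit expected flux at
    stationarity, so a branch with components (s, n) has generator
    ``s * A_syn + n * A_nonsyn`` and expected synonymous (non-synonymous)
    substitutions per codon exactly s (n).
    """

    def __init__(self, params: Mg94Params, code: GeneticCode):
        self.params = params
        self.code = code
        self.pi_star = stationary_distribution(params, code)
        I, J, K, P, Y, S = _topology(code)
        ns = code.n_states
        rates = params.exchangeabilities[K] * params.pi[P, Y]

        def _part(mask):
            A = np.zeros((ns, ns))
            A[I[mask], J[mask]] = rates[mask]
            np.fill_diagonal(A, -A.sum(axis=1))
            flux = -float(self.pi_star @ np.diag(A))
            return A / flux if flux > 0 else A, flux

        self.A_syn, self.syn_flux = _part(S)
        self.A_nonsyn, self.nonsyn_flux = _part(~S)
        sqrt_pi = np.sqrt(self.pi_star)
        self._phi = sqrt_pi
        self._phi_inv = 1.0 / sqrt_pi
        # symmetrized parts: Phi A Phi^-1 (symmetric by reversibility)
        self.S_syn = self.A_syn * np.outer(sqrt_pi, 1.0 / sqrt_pi)
        self.S_syn = 0.5 * (self.S_syn + self.S_syn.T)
        self.S_nonsyn = self.A_nonsyn * np.outer(sqrt_pi, 1.0 / sqrt_pi)
        self.S_nonsyn = 0.5 * (self.S_nonsyn + self.S_nonsyn.T)

    def branch_eig(self, s_eff: float, n_eff: float):
        """Eigendecomposition of the symmetrized branch generator."""
        M = s_eff * self.S_syn + n_eff * self.S_nonsyn
        lam, U = np.linalg.eigh(M)
        return lam, U

    def transition_matrix(self, s_eff: float, n_eff: float) -> np.ndarray:
        """P = expm(s_eff * A_syn + n_eff * A_nonsyn), exact via eigen."""
        if s_eff < 0 or n_eff < 0:
            raise ValueError("branch lengths must be non-negative")
        lam, U = self.branch_eig(s_eff, n_eff)
        E = (U * np.exp(lam)) @ U.T
        P = (self._phi_inv[:, None] * E) * self._phi[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t) for an arbitrary valid rate matrix.

    Used for the single-matrix API; reversible branch generators go through
    :meth:`CodonModelMatrices.transition_matrix` instead. Falls back to
    scipy's scaling-and-squaring.
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if t == 0:
        return np.eye(Q.shape[0])
    from scipy.linalg import expm

    P = expm(Q * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def branch_expected_rates(
    branch: BranchParams, params: Mg94Params, code: GeneticCode
) -> tuple[float, float, float, float | None]:
    """(dS per codon, dN per codon, T per site, omega) for one branch.

    dS and dN are the expected synonymous and non-synonymous substitutions per
    codon (equal to the branch components by the unit-flux normalization);
    T = (dN + dS) / 3 per nucleotide site; omega = dN/dS, ``None`` when
    dS = 0.
    """
    dS, dN = float(branch.s), float(branch.n)
    T = (dN + dS) / 3.0
    omega = dN / dS if dS > 0 else None
    return dS, dN, T, omega


# ---------------------------------------------------------------------------
# Tree representation and pruning likelihood
# ---------------------------------------------------------------------------


@dataclass
class LikelihoodTree:
    """Rooted working topology for the pruning algorithm.

    ``parent[i]`` is the parent index of node ``i`` (-1 for root), nodes in a
    postorder consistent order (children before parents, root last). Tips
    carry taxon labels; every non-root node has one branch, identified by the
    child node's index.
    """

    parent: np.ndarray
    taxon: list[str | None]
    names: list[str]  # branch names (child-node labels) indexed by node

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.postorder = np.argsort(
            -np.arange(len(self.parent))
        )  # placeholder, fixed below
        order = []
        children: dict[int, list[int]] = {i: [] for i in range(len(self.parent))}
        root = None
        for i, p in enumerate(self.parent):
            if p < 0:
                root = i
            else:
                children[int(p)].append(i)
        stack = [root]
        seen = []
        while stack:
            v = stack.pop()
            seen.append(v)
            stack.extend(children[v])
        order = seen[::-1]  # children before parents
        self.postorder = np.array(order)
        self.children = children
        self.root = root
        self.tip_indices = [i for i, t in enumerate(self.taxon) if t is not None]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def branch_names(self) -> list[str]:
        return [self.names[i] for i in range(self.n_nodes) if self.parent[i] >= 0]

    @classmethod
    def from_dendropy(cls, tree) -> "LikelihoodTree":
        """Build from a dendropy tree (rooted arbitrarily at its seed node)."""
        nodes = list(tree.preorder_node_iter())
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.array(
            [idx[id(nd.parent_node)] if nd.parent_node is not None else -1 for nd in nodes]
        )
        taxon = [nd.taxon.label if nd.taxon is not None else None for nd in nodes]
        names = [
            (nd.taxon.label if nd.taxon is not None else (nd.label or f"node{i}"))
            for i, nd in enumerate(nodes)
        ]
        return cls(parent, taxon, names)


def _tip_partials(aln: CodonAlignment, tree: LikelihoodTree):
    """Compress alignment columns to site patterns restricted to tree taxa.

    Returns (pattern matrix of shape (n_tree_tips, n_patterns), weights,
    ordered tip node indices).
    """
    tips = tree.tip_indices
    rows = np.vstack([aln.row(tree.taxon[i]) for i in tips])
    if np.any(np.all(rows == MISSING, axis=0)):
        col = int(np.where(np.all(rows == MISSING, axis=0))[0][0])
        raise ValueError(f"alignment column {col} entirely missing for tree taxa")
    patterns, counts = np.unique(rows, axis=1, return_counts=True)
    return patterns, counts.astype(float), tips


def log_likelihood(
    aln: CodonAlignment,
    tree: LikelihoodTree,
    branch_params: dict[str, BranchParams],
    mats: CodonModelMatrices,
    rates: SiteRateModel | None = None,
    return_gradient: bool = False,
    site_patterns=None,
):
    """Felsenstein pruning log-likelihood under MG94xREV + dual rate variation.

    Per site the likelihood is averaged over the product set of synonymous x
    non-synonymous rate categories; category multipliers scale each branch's
    ``s`` and ``n`` components respectively. The root distribution is the
    stationary codon distribution (reversible, so the value is independent of
    the rooting). Missing codons contribute a partial likelihood of 1 over all
    states.

    With ``return_gradient=True``, also returns ``d lnL / d(s_b, n_b)`` for
    every branch as a dict ``name -> (ds, dn)`` (analytic, via the eigenframe
    Frechet derivative of the matrix exponential).
    """
    if rates is None:
        rates = SiteRateModel(1, 1)
    if site_patterns is None:
        patterns, weights, tips = _tip_partials(aln, tree)
    else:
        patterns, weights, tips = site_patterns
    npat = patterns.shape[1]
    ns = mats.code.n_states
    cats = rates.categories()

    for name, bp in branch_params.items():
        if bp.s < 0 or bp.n < 0:
            raise ValueError(f"negative branch parameter on {name}")

    tip_row = {node: r for r, node in enumerate(tips)}
    nonroot = [i for i in tree.postorder if tree.parent[i] >= 0]

    site_like = np.zeros(npat)
    per_cat = []  # cache for gradient pass
    for cs, cn, w in cats:
        P = {}
        eig = {}
        for i in nonroot:
            bp = branch_params[tree.names[i]]
            lam, U = mats.branch_eig(bp.s * cs, bp.n * cn)
            eig[i] = (lam, U)
            E = (U * np.exp(lam)) @ U.T
            Pi = (mats._phi_inv[:, None] * E) * mats._phi[None, :]
            np.clip(Pi, 0.0, None, out=Pi)
            P[i] = Pi
        partial = {}
        up = {}  # up[i] = P_i @ partial_i, the message from child i to parent
        for i in tree.postorder:
            if tree.taxon[i] is not None:
                states = patterns[tip_row[i]]
                L = np.zeros((ns, npat))
                miss = states == MISSING
                L[:, miss] = 1.0
                obs = ~miss
                L[states[obs], np.nonzero(obs)[0]] = 1.0
            else:
                L = np.ones((ns, npat))
                for c in tree.children[i]:
                    L = L * up[c]
            partial[i] = L
            if tree.parent[i] >= 0:
                up[i] = P[i] @ L
        site_c = mats.pi_star @ partial[tree.root]
        site_like += w * site_c
        if return_gradient:
            per_cat.append((cs, cn, w, P, eig, partial, up))

    if np.any(site_like <= 0):
        lnL = -np.inf
    else:
        lnL = float(weights @ np.log(site_like))
    if not return_gradient:
        return lnL

    grad = {tree.names[i]: np.zeros(2) for i in nonroot}
    if not np.isfinite(lnL):
        return lnL, {k: (v[0], v[1]) for k, v in grad.items()}
    wl = weights / site_like
    for cs, cn, w, P, eig, partial, up in per_cat:
        # outside partials: O[root] = pi_star broadcast; preorder
        outside = {tree.root: np.tile(mats.pi_star[:, None], (1, npat))}
        for i in tree.postorder[::-1]:
            O_i = outside[i]
            kids = tree.children[i]
            for c in kids:
                prod = O_i.copy()
                for c2 in kids:
                    if c2 != c:
                        prod = prod * up[c2]
                outside[c] = P[c].T @ prod
                # gradient for branch c: <dP, R_c> with
                # R_c = sum_pat (w * wl * w_cat) prod[:,pat] partial_c[:,pat]^T
                sc = wl * w
                R = (prod * sc) @ partial[c].T  # ns x ns
                lam, U = eig[c]
                # dP/dtheta = Phi^-1 U (K o (U^T Phi dM Phi^-1 U)) U^T Phi
                # <dP, R> = <K o X_theta, U^T Phi^-1 R Phi U>
                dl = lam[:, None] - lam[None, :]
                elam = np.exp(lam)
                with np.errstate(divide="ignore", invalid="ignore"):
                    Kmat = (elam[:, None] - elam[None, :]) / dl
                small = np.abs(dl) < 1e-12
                avg = 0.5 * (elam[:, None] + elam[None, :])
                Kmat[small] = avg[small]
                Z = U.T @ ((mats._phi_inv[:, None] * R) * mats._phi[None, :]) @ U
                KZ = Kmat * Z
                Xs = U.T @ mats.S_syn @ U
                Xn = U.T @ mats.S_nonsyn @ U
                g = grad[tree.names[c]]
                g[0] += cs * float(np.sum(KZ * Xs))
                g[1] += cn * float(np.sum(KZ * Xn))
    return lnL, {k: (float(v[0]), float(v[1])) for k, v in grad.items()}
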