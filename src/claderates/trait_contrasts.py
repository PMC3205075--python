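"""Body-mass contrasts between sister clades.

The primary estimator is a time-averaged clade value under Brownian motion:
generalized-least-squares ancestral expectations are computed at every node of
the clade's crown subtree, and the clade value is the branch-duration-weighted
average of per-branch midpoint expectations (stem excluded). This downweights
extreme tip values, tolerates unmeasured tips, and reflects the trait's value
over the clade's evolutionary history rather than only at the present. A
simpler alternative, the log of the clade's geometric mean mass, is provided
for comparison, together with a paired t-test between the two methods and a
two-sided F test of the homogeneity-of-variance assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats


@dataclass
class TraitRecord:
    """One species' body mass in grams."""

    species: str
    mass_g: float

    def __post_init__(self) -> None:
        if not (self.mass_g > 0 and math.isfinite(self.mass_g)):
            raise ValueError(f"mass must be positive and finite, got {self.mass_g}")

    @property
    def log_mass(self) -> float:
        return math.log(self.mass_g)


@dataclass
class TraitContrast:
    pair_id: str
    mle_contrast: float
    geometric_contrast: float
    homogeneity_pass: bool = True
    homogeneity_note: str | None = None


def _node_depths(tree: dendropy.Tree):
    nodes = list(tree.preorder_node_iter())
    depth = {}
    for nd in nodes:
        if nd.parent_node is None:
            depth[id(nd)] = 0.0
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + (nd.edge.length or 0.0)
    return nodes, depth


def bm_time_averaged_mean(
    subtree: dendropy.Tree, tip_log_values: dict[str, float]
) -> float:
    """Branch-duration-weighted average of Brownian-motion expectations over
    a clade's crown subtree.

    GLS ancestral expectations are computed at every node from the observed
    tips (the BM rate cancels); each branch contributes its midpoint
    expectation, (E[parent] + E[child]) / 2 — exact under BM since the
    midpoint's tip covariances are the average of its endpoints' — weighted by
    its duration. Tips without values contribute branches but no observations.
    A single-tip clade returns its (observed) tip value.
    """
    nodes, depth = _node_depths(subtree)
    leaves = [nd for nd in nodes if nd.is_leaf()]
    observed = [
        nd for nd in leaves if nd.taxon and nd.taxon.label in tip_log_values
    ]
    if not observed:
        raise ValueError("no observed tips in clade subtree")
    if len(leaves) == 1:
        return float(tip_log_values[leaves[0].taxon.label])

    y = np.array([tip_log_values[nd.taxon.label] for nd in observed])
    # ancestor sets for O(1) MRCA depth lookups on small subtrees
    anc: dict[int, list] = {}
    for nd in nodes:
        chain = []
        cur = nd
        while cur is not None:
            chain.append(id(cur))
            cur = cur.parent_node
        anc[id(nd)] = chain

    def mrca_depth(a, b) -> float:
        sa = set(anc[id(a)])
        for x in anc[id(b)]:
            if x in sa:
                return depth[x]
        return 0.0

    n = len(observed)
    C = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            C[i, j] = C[j, i] = (
                depth[id(observed[i])] if i == j else mrca_depth(observed[i], observed[j])
            )
    one = np.ones(n)
    try:
        Ci_y = np.linalg.solve(C, y)
        Ci_1 = np.linalg.solve(C, one)
    except np.linalg.LinAlgError:
        Ci = np.linalg.pinv(C)
        Ci_y, Ci_1 = Ci @ y, Ci @ one
    mu = float(one @ Ci_y) / float(one @ Ci_1)
    resid_w = Ci_y - mu * Ci_1  # = C^-1 (y - mu 1)

    expectation = {}
    for nd in nodes:
        c_v = np.array([mrca_depth(nd, o) for o in observed])
        expectation[id(nd)] = mu + float(c_v @ resid_w)

    total_len = 0.0
    acc = 0.0
    for nd in nodes:
        if nd.parent_node is None:
            continue
        length = nd.edge.length or 0.0
        mid = 0.5 * (expectation[id(nd.parent_node)] + expectation[id(nd)])
        acc += length * mid
        total_len += length
    if total_len == 0:
        # degenerate (all zero-length branches): fall back to the root state
        return mu
    return acc / total_len


def mle_contrast(
    subtree_a: dendropy.Tree,
    subtree_b: dendropy.Tree,
    trait_records: dict[str, TraitRecord],
    pair_id: str = "",
) -> float:
    """Difference of time-averaged log masses, clade A minus clade B."""
    logs = {sp: rec.log_mass for sp, rec in trait_records.items()}

    def clade_value(subtree):
        labels = {
            nd.taxon.label
            for nd in subtree.leaf_node_iter()
            if nd.taxon is not None
        }
        vals = {sp: v for sp, v in logs.items() if sp in labels}
        if not vals:
            raise ValueError(f"no observed tips for pair {pair_id!r}")
        return bm_time_averaged_mean(subtree, vals)

    return clade_value(subtree_a) - clade_value(subtree_b)


def geometric_mean_contrast(masses_a, masses_b) -> float:
    """ln(geometric mean of A) - ln(geometric mean of B)."""
    a = np.asarray(list(masses_a), dtype=float)
    b = np.asarray(list(masses_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both clades need at least one mass")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("masses must be positive")
    return float(np.mean(np.log(a)) - np.mean(np.log(b)))


@dataclass
class PairedComparison:
    t_statistic: float
    p_value: float
    n: int
    note: str | None = None


def compare_contrast_methods(
    mle_contrasts, geometric_contrasts
) -> PairedComparison:
    """Paired t-test of per-pair differences between the two contrast methods."""
    a = np.asarray(list(mle_contrasts), dtype=float)
    b = np.asarray(list(geometric_contrasts), dtype=float)
    if a.size != b.size:
        raise ValueError("contrast vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(np.var(d, ddof=1), 0.0):
        t = 0.0 if np.allclose(d, 0.0) else math.copysign(math.inf, float(d.mean()))
        return PairedComparison(t, 1.0, a.size, note="zero variance of differences")
    res = stats.ttest_rel(a, b)
    return PairedComparison(float(res.statistic), float(res.pvalue), a.size)


@dataclass
class HomogeneityResult:
    statistic: float | None
    p_value: float | None
    passed: bool
    note: str | None = None


def variance_homogeneity(log_masses_a, log_masses_b) -> HomogeneityResult:
    """Two-sided F test on the sample variances of log mass in the two clades.

    Passes iff P > 0.05. With fewer than two values in a clade the test is
    not applicable and passes with a note.
    """
    a = np.asarray(list(log_masses_a), dtype=float)
    b = np.asarray(list(log_masses_b), dtype=float)
    if a.size < 2 or b.size < 2:
        return HomogeneityResult(None, None, True, note="fewer than 2 values in a clade")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return HomogeneityResult(1.0, 1.0, True, note="both variances zero")
    if va == 0 or vb == 0:
        return HomogeneityResult(math.inf, 0.0, False, note="one variance zero")
    F = va / vb
    dfa, dfb = a.size - 1, b.size - 1
    p = 2 * min(stats.f.cdf(F, dfa, dfb), stats.f.sf(F, dfa, dfb))
    p = min(float(p), 1.0)
    return HomogeneityResult(float(F), p, p > 0.05)
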