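"""Maximum-likelihood branch-rate estimation for sister-pair trees.

Each sister pair is represented by a small fixed topology (representative of
clade A, representative of clade B, one or more outgroups). Branch-specific
synonymous and non-synonymous lengths are fitted by bounded quasi-Newton
maximization of the pruning likelihood, together (optionally) with the REV
exchangeabilities and the dual-gamma shape parameters. Rate variation between
the pair's terminal branches is assessed by comparing a free-rate model with
an equal-rate model (the relevant components of the two terminal branches
constrained equal) using an AIC difference threshold of 10.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import dendropy
import numpy as np
from scipy.optimize import minimize

from .alignment import MISSING, CodonAlignment
from .codon_model import (
    BranchParams,
    CodonModelMatrices,
    LikelihoodTree,
    Mg94Params,
    SiteRateModel,
    _tip_partials,
    log_likelihood,
)

MEASURES = ("T", "dN", "dS")

#: saturation thresholds, strict ">" in each measure's own unit
SATURATION_THRESHOLD = 1.0


@dataclass
class FitConfig:
    """Optimizer and model settings for pair fits.

    ``shallow_floor`` is the minimum total pair divergence T_A + T_B
    (substitutions per site) below which a pair is flagged as too shallow for
    reliable contrasts.
    """

    estimate_exchangeabilities: bool = True
    n_categories_syn: int = 4
    n_categories_nonsyn: int = 4
    estimate_alpha: bool = True
    restarts: int = 3
    ftol: float = 1e-9
    maxiter: int = 300
    seed: int = 0
    branch_bound: float = 20.0
    shallow_floor: float = 0.01


@dataclass
class PairTree:
    """Fixed unrooted topology for one sister pair.

    ``terminal_a``/``terminal_b`` name the taxa whose root-to-tip branches are
    the pair's terminal branches (one per clade).
    """

    pair_id: str
    tree: LikelihoodTree
    terminal_a: str
    terminal_b: str
    branch_params: dict[str, BranchParams] | None = None

    def __post_init__(self) -> None:
        names = set(self.tree.branch_names)
        for t in (self.terminal_a, self.terminal_b):
            if t not in names:
                raise ValueError(f"terminal taxon {t!r} has no branch in the tree")

    @classmethod
    def from_newick(cls, pair_id: str, newick: str, terminal_a: str, terminal_b: str):
        dt = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        return cls(pair_id, LikelihoodTree.from_dendropy(dt), terminal_a, terminal_b)

    @property
    def taxa(self) -> list[str]:
        return [t for t in self.tree.taxon if t is not None]


@dataclass
class BranchRateEstimates:
    """Per-terminal-branch rate estimates for one pair."""

    pair_id: str
    branch: str
    T: float
    dN: float
    dS: float
    omega: float | None
    scheme: str = "pooled"

    @classmethod
    def from_branch(cls, pair_id: str, branch: str, bp: BranchParams, scheme="pooled"):
        dS, dN = float(bp.s), float(bp.n)
        return cls(
            pair_id,
            branch,
            T=(dS + dN) / 3.0,
            dN=dN,
            dS=dS,
            omega=(dN / dS if dS > 0 else None),
            scheme=scheme,
        )


@dataclass
class ModelComparison:
    measure: str
    lnL_free: float
    k_free: int
    lnL_equal: float
    k_equal: int

    @property
    def aic_free(self) -> float:
        return 2 * self.k_free - 2 * self.lnL_free

    @property
    def aic_equal(self) -> float:
        return 2 * self.k_equal - 2 * self.lnL_equal

    @property
    def delta_aic(self) -> float:
        return self.aic_equal - self.aic_free

    @property
    def verdict(self) -> str:
        return "rate variation" if self.delta_aic >= 10.0 else "no rate variation"


@dataclass
class FitResult:
    params: Mg94Params
    rates: SiteRateModel
    tree: PairTree
    lnL: float
    k: int
    converged: bool
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------


class _ParamMap:
    """Maps the optimizer vector to branch parameters and back-propagates
    analytic gradients, honouring an optional equal-rate constraint on the
    two terminal branches (T: s+n shared; dN: n shared; dS: s shared)."""

    def __init__(self, branch_names, terminal_a, terminal_b, constraint, bound):
        self.names = list(branch_names)
        self.terminals = (terminal_a, terminal_b)
        self.constraint = constraint
        self.bound = bound
        self.slots: list[tuple] = []
        lo = 1e-8
        if constraint is None:
            for nm in self.names:
                self.slots.append(("s", nm))
                self.slots.append(("n", nm))
        elif constraint in ("dN", "dS"):
            shared = "n" if constraint == "dN" else "s"
            free = "s" if constraint == "dN" else "n"
            self.slots.append((shared, "__shared__"))
            for nm in self.names:
                if nm in self.terminals:
                    self.slots.append((free, nm))
                else:
                    self.slots.append(("s", nm))
                    self.slots.append(("n", nm))
        elif constraint == "T":
            self.slots.append(("tau", "__shared__"))
            for nm in self.names:
                if nm in self.terminals:
                    self.slots.append(("frac", nm))
                else:
                    self.slots.append(("s", nm))
                    self.slots.append(("n", nm))
        else:
            raise ValueError(f"unknown constraint {constraint!r}")
        self.bounds = [
            ((1e-6, 1 - 1e-6) if kind == "frac" else (lo, bound))
            for kind, _ in self.slots
        ]

    @property
    def n_params(self) -> int:
        return len(self.slots)

    def unpack(self, x) -> dict[str, BranchParams]:
        vals = {}
        shared = None
        fracs = {}
        for v, (kind, nm) in zip(x, self.slots):
            if nm == "__shared__":
                shared = v
            elif kind == "frac":
                fracs[nm] = v
            else:
                vals.setdefault(nm, {})[kind] = v
        out = {}
        for nm in self.names:
            if self.constraint is None or nm not in self.terminals:
                out[nm] = BranchParams(vals[nm]["s"], vals[nm]["n"])
            elif self.constraint == "dN":
                out[nm] = BranchParams(vals[nm]["s"], shared)
            elif self.constraint == "dS":
                out[nm] = BranchParams(shared, vals[nm]["n"])
            else:  # T: s = tau*f, n = tau*(1-f)
                f = fracs[nm]
                out[nm] = BranchParams(shared * f, shared * (1 - f))
        return out

    def pack_grad(self, x, grad: dict[str, tuple[float, float]]) -> np.ndarray:
        g = np.zeros(self.n_params)
        shared_idx = None
        fracs = {}
        shared = None
        for i, (kind, nm) in enumerate(self.slots):
            if nm == "__shared__":
                shared_idx = i
                shared = x[i]
            elif kind == "frac":
                fracs[nm] = (i, x[i])
        for i, (kind, nm) in enumerate(self.slots):
            if nm == "__shared__" or kind == "frac":
                continue
            gs, gn = grad[nm]
            g[i] = gs if kind == "s" else gn
        if self.constraint in ("dN", "dS"):
            comp = 1 if self.constraint == "dN" else 0
            g[shared_idx] = sum(grad[t][comp] for t in self.terminals)
        elif self.constraint == "T":
            acc = 0.0
            for t in self.terminals:
                gs, gn = grad[t]
                i, f = fracs[t]
                acc += f * gs + (1 - f) * gn
                g[i] = shared * (gs - gn)
            g[shared_idx] = acc
        return g

    def initial(self, branch_init: dict[str, tuple[float, float]]) -> np.ndarray:
        x = np.zeros(self.n_params)
        for i, (kind, nm) in enumerate(self.slots):
            if nm == "__shared__":
                if self.constraint == "T":
                    x[i] = float(
                        np.mean([sum(branch_init[t]) for t in self.terminals])
                    )
                else:
                    comp = 1 if self.constraint == "dN" else 0
                    x[i] = float(np.mean([branch_init[t][comp] for t in self.terminals]))
            elif kind == "frac":
                s0, n0 = branch_init[nm]
                x[i] = s0 / (s0 + n0)
            else:
                x[i] = branch_init[nm][0 if kind == "s" else 1]
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        return np.clip(x, lo, hi)


def _branch_init(aln: CodonAlignment, tree: PairTree) -> dict:
    """Moment-style starting values: per-branch lengths from the mean pairwise
    codon mismatch fraction, split 4:1 synonymous:non-synonymous."""
    taxa = tree.taxa
    ps = []
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            a, b = aln.row(taxa[i]), aln.row(taxa[j])
            ok = (a != MISSING) & (b != MISSING)
            if ok.sum():
                ps.append(float(np.mean(a[ok] != b[ok])))
    p = float(np.clip(np.mean(ps) if ps else 0.1, 1e-4, 0.85))
    total = -np.log(1 - p) / 2.0  # rough per-branch substitutions per codon
    total = float(np.clip(total, 5e-3, 5.0))
    return {nm: (0.8 * total, 0.2 * total) for nm in tree.tree.branch_names}


def fit_pair(
    aln: CodonAlignment,
    tree: PairTree,
    config: FitConfig | None = None,
    constraint: str | None = None,
) -> FitResult:
    """Fit MG94xREV branch components (and optionally exchangeabilities and
    gamma shapes) for one pair tree by bounded quasi-Newton.

    Positional nucleotide frequencies are the alignment's empirical 3x4
    frequencies (not free parameters). Branch gradients are analytic; the
    handful of global parameters use forward differences. Deterministic given
    ``config.seed``: one moment-based start plus ``restarts - 1`` jittered
    restarts, keeping the best optimum.
    """
    config = config or FitConfig()
    code = aln.code
    sub = aln.subset(tree.taxa) if set(aln.taxa) != set(tree.taxa) else aln
    pi = sub.positional_frequencies()
    pmap = _ParamMap(
        tree.tree.branch_names,
        tree.terminal_a,
        tree.terminal_b,
        constraint,
        config.branch_bound,
    )

    est_alpha_s = config.estimate_alpha and config.n_categories_syn > 1
    est_alpha_n = config.estimate_alpha and config.n_categories_nonsyn > 1
    n_ex = 5 if config.estimate_exchangeabilities else 0
    n_global = n_ex + int(est_alpha_s) + int(est_alpha_n)
    nb = pmap.n_params

    mats_cache: dict[tuple, CodonModelMatrices] = {}

    def make_mats(ex_log: np.ndarray) -> CodonModelMatrices:
        key = tuple(np.round(ex_log, 12))
        if key not in mats_cache:
            ex = np.ones(6)
            ex[:5] = np.exp(ex_log)
            mats_cache[key] = CodonModelMatrices(Mg94Params(ex, pi), code)
        return mats_cache[key]

    base_mats = make_mats(np.zeros(5))
    patterns = _tip_partials(sub, tree.tree)

    def split(x):
        bx = x[:nb]
        gx = x[nb:]
        ex_log = gx[:n_ex] if n_ex else np.zeros(5)
        k = n_ex
        a_s = np.exp(gx[k]) if est_alpha_s else 1.0
        k += int(est_alpha_s)
        a_n = np.exp(gx[k]) if est_alpha_n else 1.0
        sm = SiteRateModel(
            config.n_categories_syn, config.n_categories_nonsyn, a_s, a_n
        )
        return bx, ex_log, sm

    neval = [0]

    def lnl_only(x):
        bx, ex_log, sm = split(x)
        mats = make_mats(ex_log) if n_ex else base_mats
        return log_likelihood(
            sub, tree.tree, pmap.unpack(bx), mats, sm, site_patterns=patterns
        )

    def objective(x):
        neval[0] += 1
        bx, ex_log, sm = split(x)
        mats = make_mats(ex_log) if n_ex else base_mats
        lnL, bgrad = log_likelihood(
            sub, tree.tree, pmap.unpack(bx), mats, sm, return_gradient=True,
            site_patterns=patterns,
        )
        g = np.zeros_like(x)
        g[:nb] = pmap.pack_grad(bx, bgrad)
        if n_global:
            h = 1e-5
            for i in range(nb, len(x)):
                xe = x.copy()
                xe[i] += h
                g[i] = (lnl_only(xe) - lnL) / h
        if not np.isfinite(lnL):
            return 1e12, np.zeros_like(x)
        return -lnL, -g

    bounds = list(pmap.bounds)
    bounds += [(np.log(1e-3), np.log(1e3))] * n_ex
    bounds += [(np.log(0.05), np.log(50.0))] * (int(est_alpha_s) + int(est_alpha_n))

    x0 = np.concatenate([pmap.initial(_branch_init(sub, tree)), np.zeros(n_global)])
    rng = np.random.default_rng(config.seed)
    best = None
    for r in range(max(1, config.restarts)):
        xs = x0.copy()
        if r > 0:
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            xs = np.clip(
                xs * np.exp(rng.normal(0, 0.5, xs.size)) + rng.normal(0, 0.01, xs.size),
                lo,
                hi,
            )
        res = minimize(
            objective,
            xs,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": config.ftol, "maxiter": config.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res

    bx, ex_log, sm = split(best.x)
    ex = np.ones(6)
    ex[:5] = np.exp(ex_log)
    fitted = replace(tree, branch_params=pmap.unpack(bx))
    k = nb + n_global
    return FitResult(
        params=Mg94Params(ex, pi),
        rates=sm,
        tree=fitted,
        lnL=-float(best.fun),
        k=k,
        converged=bool(best.success or best.status == 1),
        n_evaluations=neval[0],
    )


def terminal_estimates(fit: FitResult, scheme: str = "pooled") -> list[BranchRateEstimates]:
    """Retain rate estimates for the pair's two terminal branches only."""
    tree = fit.tree
    return [
        BranchRateEstimates.from_branch(
            tree.pair_id, br, tree.branch_params[br], scheme
        )
        for br in (tree.terminal_a, tree.terminal_b)
    ]


@dataclass
class PartitionComparison:
    fits_pooled: list[FitResult]
    fits_per_gene: list[FitResult]
    aic_pooled: float
    aic_per_gene: float

    @property
    def preferred(self) -> str:
        return "per_gene" if self.aic_per_gene < self.aic_pooled else "pooled"


def fit_partitioned(
    gene_alignments: dict[str, CodonAlignment],
    tree: PairTree,
    config: FitConfig | None = None,
) -> PartitionComparison:
    """Compare a pooled model (one MG94xREV fit on the concatenation) against
    per-gene models (independent fit per gene) by AIC."""
    if not gene_alignments:
        raise ValueError("no gene alignments supplied")
    for gene, a in gene_alignments.items():
        if a.n_codons == 0:
            raise ValueError(f"empty partition {gene!r}")
    config = config or FitConfig()
    genes = sorted(gene_alignments)
    first = gene_alignments[genes[0]]
    taxa = list(first.taxa)
    concat = CodonAlignment(
        taxa,
        np.hstack([gene_alignments[g].subset(taxa).codons for g in genes]),
        first.code,
    )
    pooled = fit_pair(concat, tree, config)
    per_gene = [fit_pair(gene_alignments[g], tree, config) for g in genes]
    aic_pooled = 2 * pooled.k - 2 * pooled.lnL
    lnl_pg = sum(f.lnL for f in per_gene)
    k_pg = sum(f.k for f in per_gene)
    return PartitionComparison([pooled], per_gene, aic_pooled, 2 * k_pg - 2 * lnl_pg)


def compare_rate_models(
    aln: CodonAlignment,
    tree: PairTree,
    measure: str,
    config: FitConfig | None = None,
) -> ModelComparison:
    """Free-rate vs equal-rate model comparison for one measure.

    The equal-rate model constrains the relevant component(s) of the two
    terminal branches equal (T: s+n; dN: n; dS: s). Verdict is "rate
    variation" iff AIC_equal - AIC_free >= 10.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    config = config or FitConfig()
    free = fit_pair(aln, tree, config)
    equal = fit_pair(aln, tree, config, constraint=measure)
    return ModelComparison(measure, free.lnL, free.k, equal.lnL, equal.k)


def flag_saturation(est: BranchRateEstimates) -> dict[str, tuple[bool, str | None]]:
    """Per-measure inclusion flags for one branch's estimates.

    A measure is excluded iff strictly greater than 1 in its own unit
    (T: substitutions/site; dN, dS: substitutions/codon). omega follows dS
    (a saturated denominator makes the ratio unreliable).
    """
    flags: dict[str, tuple[bool, str | None]] = {}
    for measure, value in (("T", est.T), ("dN", est.dN), ("dS", est.dS)):
        if value > SATURATION_THRESHOLD:
            flags[measure] = (False, "saturated")
        else:
            flags[measure] = (True, None)
    if est.omega is None:
        flags["omega"] = (False, "missing")
    elif not flags["dS"][0]:
        flags["omega"] = (False, "saturated")
    else:
        flags["omega"] = (True, None)
    return flags


def fit_report_tsv(rows: list[BranchRateEstimates]) -> str:
    """Structured fit report: pair, branch, scheme, T/dN/dS/omega and flags."""
    out = io.StringIO()
    out.write("pair_id\tbranch\tscheme\tmeasure\testimate\tincluded\treason\n")
    for est in rows:
        flags = flag_saturation(est)
        for measure, value in (
            ("T", est.T),
            ("dN", est.dN),
            ("dS", est.dS),
            ("omega", est.omega),
        ):
            inc, reason = flags[measure]
            sval = "NA" if value is None else f"{value:.6g}"
            out.write(
                f"{est.pair_id}\t{est.branch}\t{est.scheme}\t{measure}\t"
                f"{sval}\t{int(inc)}\t{reason or ''}\n"
            )
    return out.getvalue()
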