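"""Through-origin regressions and df-weighted Z meta-analysis.

Standardized sister-pair contrasts have expectation zero when the predictor
does not differ within a pair, so regressions are forced through the origin:
slope = sum(xy) / sum(x^2), residual df = n - 1, and R^2 is the uncentered
1 - RSS / sum(y^2). Tests of the same hypothesis across datasets are combined
with a weighted Stouffer Z: two-tailed regression P values are converted to
one-tailed P values under an assumed direction (positive for rate ~ clade
size, negative for rate ~ body mass), Z-transformed, and combined as
Z_w = sum(df_i * Z_i) / sqrt(sum(df_i^2)), with combined one-tailed
P = 1 - Phi(Z_w). A positive combined Z denotes support for the assumed
direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: clamp for degenerate one-tailed P values
P_EPSILON = 1e-12


@dataclass
class RegressionResult:
    response: str
    predictor: str
    slope: float
    r_squared: float
    df: int
    p_value: float
    n: int
    dataset: str = ""


def regress_through_origin(
    x, y, response: str = "y", predictor: str = "x", dataset: str = ""
) -> RegressionResult:
    """Least-squares regression of y on x with no intercept.

    slope = sum(xy)/sum(x^2); the slope's standard error uses RSS on n - 1
    residual degrees of freedom; P is two-tailed from the t distribution;
    R^2 = 1 - RSS / sum(y^2), truncated at 0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    sxx = float(x @ x)
    if sxx == 0:
        raise ZeroDivisionError("sum(x^2) is zero")
    slope = float(x @ y) / sxx
    resid = y - slope * x
    rss = float(resid @ resid)
    syy = float(y @ y)
    df = n - 1
    if rss <= 0:
        return RegressionResult(response, predictor, slope, 1.0, df, 0.0, n, dataset)
    se = math.sqrt(rss / df / sxx)
    t = slope / se
    p = 2 * float(stats.t.sf(abs(t), df))
    r2 = max(0.0, 1.0 - rss / syy) if syy > 0 else 0.0
    return RegressionResult(response, predictor, slope, r2, df, min(p, 1.0), n, dataset)


def one_tailed(p_two: float, slope_sign: float, assumed_direction: str) -> float:
    """Convert a two-tailed regression P to one-tailed under an assumed
    direction of association ('positive' or 'negative').

    Half the two-tailed P if the observed slope's sign matches the assumed
    direction, else 1 - P/2; a zero slope gives 0.5.
    """
    if assumed_direction not in ("positive", "negative"):
        raise ValueError("assumed_direction must be 'positive' or 'negative'")
    if not (0 < p_two <= 1):
        raise ValueError(f"two-tailed P must be in (0, 1], got {p_two}")
    if slope_sign == 0:
        return 0.5
    wanted = 1.0 if assumed_direction == "positive" else -1.0
    if math.copysign(1.0, slope_sign) == wanted:
        return p_two / 2
    return 1 - p_two / 2


@dataclass
class WeightedZComponent:
    dataset: str
    p_two: float
    slope_sign: float
    df: float
    p_one: float = field(init=False)
    z: float = field(init=False)
    assumed_direction: str = "positive"

    def __post_init__(self) -> None:
        self.p_one = one_tailed(self.p_two, self.slope_sign, self.assumed_direction)
        self.z = float(stats.norm.isf(self.p_one))


@dataclass
class WeightedZResult:
    hypothesis: str
    components: list[WeightedZComponent]
    z_combined: float
    p_combined: float

    @property
    def n_tests(self) -> int:
        return len(self.components)


def weighted_z(
    components: list[WeightedZComponent], hypothesis: str = ""
) -> WeightedZResult:
    """df-weighted Stouffer combination of one-tailed P values.

    Z_i = Phi^-1(1 - P_one_i); Z_w = sum(w_i Z_i) / sqrt(sum(w_i^2)) with
    w_i = df_i; combined one-tailed P = 1 - Phi(Z_w). One-tailed P values of
    exactly 0 or 1 are clamped to P_EPSILON with a warning.
    """
    if not components:
        raise ValueError("need at least one component")
    zs = []
    for c in components:
        p1 = c.p_one
        if p1 <= 0 or p1 >= 1:
            warnings.warn(
                f"one-tailed P {p1} clamped to [{P_EPSILON}, {1 - P_EPSILON}]",
                stacklevel=2,
            )
            p1 = min(max(p1, P_EPSILON), 1 - P_EPSILON)
        zs.append(float(stats.norm.isf(p1)))
    w = np.array([c.df for c in components], dtype=float)
    z = np.array(zs)
    z_w = float(w @ z / math.sqrt(float(w @ w)))
    p = float(stats.norm.sf(z_w))
    return WeightedZResult(hypothesis, list(components), z_w, p)


#: default assumed one-tailed directions per hypothesis family
DEFAULT_DIRECTIONS = {
    ("clade_size", "T"): "positive",
    ("clade_size", "dN"): "positive",
    ("clade_size", "dS"): "positive",
    ("clade_size", "body_mass"): "negative",
    ("T", "body_mass"): "negative",
    ("dN", "body_mass"): "negative",
    ("dS", "body_mass"): "negative",
}


def hypothesis_families(
    results: list[RegressionResult],
    genome_of: dict[str, str] | None = None,
    split_dn_body: bool = True,
) -> dict[str, list[RegressionResult]]:
    """Group regression results into (response, predictor) families across
    datasets.

    The dN ~ body-mass family is additionally split into nuclear-only and
    mitochondrial-only subgroups (keyed ``"dN~body_mass/nuclear"`` etc.) when
    ``genome_of`` maps dataset labels to ``"nuclear"``/``"mitochondrial"``.
    """
    fams: dict[str, list[RegressionResult]] = {}
    for r in results:
        key = f"{r.response}~{r.predictor}"
        fams.setdefault(key, []).append(r)
        if (
            split_dn_body
            and genome_of is not None
            and r.response == "dN"
            and r.predictor == "body_mass"
        ):
            genome = genome_of.get(r.dataset)
            if genome:
                fams.setdefault(f"{key}/{genome}", []).append(r)
    for key, members in fams.items():
        if not members:
            raise ValueError(f"empty family {key!r}")
    return fams
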