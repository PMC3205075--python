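"""Sister-pair contrasts: representative selection, ln-differences and
divergence standardization, with explicit exclusion bookkeeping.

Each sister pair contributes, per variable, a raw contrast ln(V_A) - ln(V_B)
standardized by the square root of the pair's total divergence,
(T_A + T_B)^0.5, which equalizes contrast variance across pairs of different
depths. Excluded contrasts carry a single primary exclusion reason and never
enter regressions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

EXCLUSION_REASONS = ("saturated", "shallow", "missing", "diagnostic")


@dataclass
class ContrastRow:
    """One pair's contrast for one variable."""

    pair_id: str
    variable: str
    raw: float | None
    weight: float | None
    standardized: float | None
    included: bool
    reason: str | None = None


@dataclass
class CladeRecord:
    """One clade of a sister pair.

    ``species_count`` comes from taxonomy (it need not match the subtree's tip
    count); ``tips_with_data`` marks the tips for which sequence data exist.
    """

    name: str
    species_count: int
    subtree: dendropy.Tree
    tips_with_data: set[str]
    representative: str | None = None

    def __post_init__(self) -> None:
        if self.species_count < 1:
            raise ValueError("species count must be >= 1")


def count_internal_nodes(subtree: dendropy.Tree, tip: str) -> int:
    """Number of internal nodes strictly between the clade's basal node and
    ``tip`` (both endpoints excluded)."""
    node = next(
        (leaf for leaf in subtree.leaf_node_iter() if leaf.taxon and leaf.taxon.label == tip),
        None,
    )
    if node is None:
        raise KeyError(f"tip {tip!r} not in subtree")
    count = -1  # excludes the basal (seed) node
    node = node.parent_node
    while node is not None:
        count += 1
        node = node.parent_node
    return max(count, 0)


def select_representative(clade: CladeRecord, role: str) -> str:
    """Choose the clade's representative tip by the node-count rule.

    In the more speciose clade the tip with the greatest number of intervening
    internal nodes is chosen (maximizing cladogenetic events represented on
    shared internal branches); in the less speciose clade, the fewest. Ties
    break to the lexicographically smallest taxon label.
    """
    if role not in ("more_speciose", "less_speciose"):
        raise ValueError("role must be 'more_speciose' or 'less_speciose'")
    candidates = sorted(clade.tips_with_data)
    if not candidates:
        raise ValueError(f"no tip with data in clade {clade.name!r}")
    # single traversal: node depth in internal-node counts
    depth = {}
    counts = {}
    for nd in clade.subtree.preorder_node_iter():
        depth[id(nd)] = 0 if nd.parent_node is None else depth[id(nd.parent_node)] + 1
        if nd.is_leaf() and nd.taxon is not None and nd.taxon.label in clade.tips_with_data:
            counts[nd.taxon.label] = max(depth[id(nd)] - 1, 0)
    missing = set(candidates) - set(counts)
    if missing:
        raise KeyError(f"tips {sorted(missing)} not in subtree")
    sign = -1 if role == "more_speciose" else 1
    return min(candidates, key=lambda t: (sign * counts[t], t))


def make_contrast(
    v_a: float, v_b: float, t_a: float, t_b: float, variable: str, pair_id: str = ""
) -> ContrastRow:
    """Raw ln(V_A) - ln(V_B) contrast, standardized by (T_A + T_B)^0.5.

    Non-positive variable values cannot be log-contrasted; the row is
    excluded with reason "missing".
    """
    if t_a < 0 or t_b < 0:
        raise ValueError("branch lengths must be non-negative")
    if v_a is None or v_b is None or v_a <= 0 or v_b <= 0:
        return ContrastRow(pair_id, variable, None, None, None, False, "missing")
    raw = math.log(v_a) - math.log(v_b)
    weight = math.sqrt(t_a + t_b)
    if weight == 0:
        return ContrastRow(pair_id, variable, raw, 0.0, None, False, "shallow")
    return ContrastRow(pair_id, variable, raw, weight, raw / weight, True)


@dataclass
class DiagnosticResult:
    slope: float
    p_value: float
    passed: bool
    n: int


def garland_diagnostic(rows: list[ContrastRow]) -> DiagnosticResult:
    """Standardization adequacy check: ordinary regression of the absolute
    standardized contrast on the standardization weight.

    An adequate standardization leaves contrast magnitude unrelated to pair
    divergence, so the check passes iff the slope's two-tailed P > 0.05.
    Degenerate weights (all equal) trivially pass.
    """
    inc = [r for r in rows if r.included]
    if len(inc) < 5:
        raise ValueError("need at least 5 included contrasts for the diagnostic")
    x = np.array([r.weight for r in inc])
    y = np.abs([r.standardized for r in inc])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DiagnosticResult(0.0, 1.0, True, len(inc))
    res = stats.linregress(x, y)
    return DiagnosticResult(
        float(res.slope), float(res.pvalue), bool(res.pvalue > 0.05), len(inc)
    )


def freckleton_diagnostic(rows: list[ContrastRow]) -> DiagnosticResult:
    """Transformation check: the same absolute-value regression applied to
    the unstandardized (log-scale) contrasts."""
    inc = [r for r in rows if r.included]
    if len(inc) < 5:
        raise ValueError("need at least 5 included contrasts for the diagnostic")
    x = np.array([r.weight for r in inc])
    y = np.abs([r.raw for r in inc])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return DiagnosticResult(0.0, 1.0, True, len(inc))
    res = stats.linregress(x, y)
    return DiagnosticResult(
        float(res.slope), float(res.pvalue), bool(res.pvalue > 0.05), len(inc)
    )


# ---------------------------------------------------------------------------
# Chimeric representatives and mitochondrial overlap trimming
# ---------------------------------------------------------------------------


@dataclass
class ChimericSequence:
    sequence: str
    provenance: list[tuple[str, str, int, int]]  # gene, species, start/end codon (1-based)


def assemble_representative(
    gene_sequences: dict[str, tuple[str, str]], gene_order: list[str]
) -> ChimericSequence:
    """Concatenate per-gene sequences (possibly from different species within
    one clade) into a chimeric representative, in a fixed gene order.

    ``gene_sequences`` maps gene -> (species, in-frame nucleotide sequence).
    Provenance records each segment's source species and codon interval.
    """
    missing = [g for g in gene_order if g not in gene_sequences]
    if missing:
        raise ValueError(f"missing gene(s): {missing}")
    parts = []
    provenance = []
    codon = 1
    for gene in gene_order:
        species, seq = gene_sequences[gene]
        if len(seq) % 3 != 0:
            raise ValueError(f"gene {gene!r} length {len(seq)} violates frame")
        n_codons = len(seq) // 3
        parts.append(seq)
        provenance.append((gene, species, codon, codon + n_codons - 1))
        codon += n_codons
    return ChimericSequence("".join(parts), provenance)


@dataclass
class GeneInterval:
    """1-based inclusive nucleotide coordinates of one gene on a strand."""

    gene: str
    start: int
    end: int
    flagged: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def trim_overlaps(
    intervals: list[GeneInterval],
    overlap_pairs: list[tuple[str, str]] | None = None,
) -> list[GeneInterval]:
    """Remove coding overlap between gene pairs from the downstream gene.

    For each (upstream, downstream) pair whose intervals intersect, the
    downstream gene's start is advanced past the shared region to its first
    codon-complete position (relative to the downstream gene's own frame), so
    one intact copy of every overlapped codon is kept and every output gene
    remains frame-consistent. A gene whose overlap cannot be resolved to a
    codon boundary within its extent is flagged rather than emitted mangled.
    """
    by_name = {iv.gene: GeneInterval(iv.gene, iv.start, iv.end) for iv in intervals}
    if overlap_pairs is None:
        ordered = sorted(intervals, key=lambda iv: iv.start)
        overlap_pairs = [
            (a.gene, b.gene)
            for a, b in zip(ordered, ordered[1:])
            if b.start <= a.end
        ]
    for up_name, down_name in overlap_pairs:
        up, down = by_name[up_name], by_name[down_name]
        if up.flagged or down.flagged or down.start > up.end:
            continue
        shift = up.end + 1 - down.start  # nucleotides shared
        shift = 3 * math.ceil(shift / 3)  # pad cut to downstream codon boundary
        new_start = down.start + shift
        if new_start + 2 > down.end:
            down.flagged = True
            continue
        down.start = new_start
    originals = {iv.gene: iv.start for iv in intervals}
    out = [by_name[iv.gene] for iv in intervals]
    for iv in out:
        # a trimmed gene's cut must sit on its own codon boundary
        if not iv.flagged and (iv.start - originals[iv.gene]) % 3 != 0:
            raise AssertionError(f"gene {iv.gene} left out of frame after trimming")
    return out


def contrast_table_tsv(rows: list[ContrastRow]) -> str:
    lines = ["pair_id\tvariable\traw\tweight\tstandardized\tincluded\treason"]
    for r in rows:
        fmt = lambda v: "NA" if v is None else f"{v:.6g}"
        lines.append(
            f"{r.pair_id}\t{r.variable}\t{fmt(r.raw)}\t{fmt(r.weight)}\t"
            f"{fmt(r.standardized)}\t{int(r.included)}\t{r.reason or ''}"
        )
    return "\n".join(lines) + "\n"
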