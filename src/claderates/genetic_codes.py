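"""Genetic codes restricted to sense codons.

Codon substitution models operate on the sense codons only: stop codons are
excluded from the state space, and data containing in-frame stops are rejected
at parse time. Two codes are supported, the standard nuclear code and the
vertebrate mitochondrial code (61 and 60 sense codons respectively).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: code_id -> NCBI translation table id
_CODE_IDS = {"standard": 1, "vertebrate_mitochondrial": 2}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code over the sense (non-stop) codons.

    Attributes
    ----------
    code_id:
        ``"standard"`` or ``"vertebrate_mitochondrial"``.
    sense_codons:
        Ordered tuple of sense codons (alphabetical over ACGT alphabet).
    codon_to_aa:
        Mapping from sense codon to one-letter amino acid.
    """

    code_id: str
    sense_codons: tuple[str, ...]
    codon_to_aa: dict[str, str]
    stop_codons: frozenset[str]
    index: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {c: i for i, c in enumerate(self.sense_codons)}
        )

    @property
    def n_states(self) -> int:
        return len(self.sense_codons)

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        return self.codon_to_aa[codon_a] == self.codon_to_aa[codon_b]


def get_genetic_code(code_id: str = "standard") -> GeneticCode:
    """Return a :class:`GeneticCode` by name.

    The standard code has 61 sense codons; the vertebrate mitochondrial code
    has 60 (TGA codes for Trp, ATA for Met, and AGA/AGG are stops).
    """
    try:
        table_id = _CODE_IDS[code_id]
    except KeyError:
        raise ValueError(
            f"unknown genetic code {code_id!r}; choose from {sorted(_CODE_IDS)}"
        ) from None
    table = CodonTable.unambiguous_dna_by_id[table_id]
    stops = frozenset(table.stop_codons)
    sense = tuple(
        "".join(c) for c in product(NUCLEOTIDES, repeat=3) if "".join(c) not in stops
    )
    codon_to_aa = {c: table.forward_table[c] for c in sense}
    return GeneticCode(code_id, sense, codon_to_aa, stops)
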