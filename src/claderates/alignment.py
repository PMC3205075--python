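"""In-frame codon alignments.

A :class:`CodonAlignment` holds a stop-free codon matrix over named taxa.
Entries are indices into the genetic code's sense codons, or ``MISSING`` for
gapped/ambiguous codons (treated as fully ambiguous in the likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .genetic_codes import NUCLEOTIDES, GeneticCode, get_genetic_code

#: sentinel state index for a missing/ambiguous codon
MISSING = -1


class AlignmentError(ValueError):
    """Raised for frame violations, in-frame stops, or ragged alignments."""


@dataclass
class CodonAlignment:
    """Codon alignment over named taxa.

    Attributes
    ----------
    taxa:
        Taxon labels, in input order.
    codons:
        ``(n_taxa, n_codons)`` int array of sense-codon indices, ``MISSING``
        for ambiguous entries.
    code:
        The :class:`GeneticCode` defining the state space.
    partitions:
        Optional mapping of gene name to half-open codon interval
        ``(start, stop)``; intervals must be nested within the alignment.
    """

    taxa: list[str]
    codons: np.ndarray
    code: GeneticCode
    partitions: dict[str, tuple[int, int]] | None = None
    _row: dict[str, int] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon labels")
        if self.partitions is not None:
            for gene, (lo, hi) in self.partitions.items():
                if not (0 <= lo < hi <= self.n_codons):
                    raise AlignmentError(
                        f"partition {gene!r} [{lo}, {hi}) outside alignment "
                        f"of {self.n_codons} codons"
                    )
        self._row = {t: i for i, t in enumerate(self.taxa)}

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.codons[self._row[taxon]]

    def subset(self, taxa: list[str]) -> "CodonAlignment":
        rows = [self._row[t] for t in taxa]
        return CodonAlignment(list(taxa), self.codons[rows], self.code, self.partitions)

    def extract_gene(self, gene: str) -> "CodonAlignment":
        if not self.partitions or gene not in self.partitions:
            raise AlignmentError(f"no partition named {gene!r}")
        lo, hi = self.partitions[gene]
        return CodonAlignment(list(self.taxa), self.codons[:, lo:hi], self.code)

    def positional_frequencies(self, pseudocount: float = 1.0) -> np.ndarray:
        """Empirical 3x4 positional nucleotide frequencies (F3x4).

        Counts nucleotides at each codon position over all non-missing codons,
        with a small pseudocount so no frequency is exactly zero.
        """
        counts = np.full((3, 4), pseudocount, dtype=float)
        sense = self.code.sense_codons
        flat = self.codons[self.codons >= 0]
        for idx in flat:
            codon = sense[idx]
            for p in range(3):
                counts[p, NUCLEOTIDES.index(codon[p])] += 1
        return counts / counts.sum(axis=1, keepdims=True)

    def to_fasta(self, path) -> None:
        sense = self.code.sense_codons
        with open(path, "w") as fh:
            for i, taxon in enumerate(self.taxa):
                seq = "".join(
                    sense[s] if s >= 0 else "---" for s in self.codons[i]
                )
                fh.write(f">{taxon}\n{seq}\n")


def encode_sequence(seq: str, code: GeneticCode, label: str = "") -> np.ndarray:
    """Encode a nucleotide string into sense-codon indices.

    Raises :class:`AlignmentError` on frame violations or in-frame stop codons,
    reporting the offending codon coordinate (1-based, in codons).
    """
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise AlignmentError(
            f"sequence {label!r} length {len(seq)} not divisible by 3"
        )
    out = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(len(out)):
        codon = seq[3 * k : 3 * k + 3]
        if codon in code.stop_codons:
            raise AlignmentError(
                f"in-frame stop codon {codon} at codon {k + 1} of {label!r}"
            )
        out[k] = code.index.get(codon, MISSING)
    return out


def read_codon_fasta(
    path,
    code: GeneticCode | str = "standard",
    partitions: dict[str, tuple[int, int]] | None = None,
) -> CodonAlignment:
    """Read an in-frame codon alignment from FASTA.

    Gaps (``-``) and ``?``/``N`` containing codons are treated as missing.
    All rows must have equal length divisible by 3; in-frame stops are
    rejected with their coordinate.
    """
    if isinstance(code, str):
        code = get_genetic_code(code)
    taxa: list[str] = []
    rows: list[np.ndarray] = []
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"row {rec.id!r} length {len(seq)} != first row length {length}"
            )
        taxa.append(rec.id)
        rows.append(encode_sequence(seq, code, label=rec.id))
    if not rows:
        raise AlignmentError(f"no sequences in {path}")
    return CodonAlignment(taxa, np.vstack(rows), code, partitions)
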