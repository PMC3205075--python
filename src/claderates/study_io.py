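"""Read a study directory written by :func:`claderates.synthetic_data.write_study`.

A study directory contains per-pair codon alignments (FASTA), pair trees and
clade subtrees (newick), a pair table (``pairs.tsv``) and a trait table
(``traits.tsv``); the same formats the pipeline emits, so studies round-trip
through the package's own readers.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd

from .alignment import read_codon_fasta
from .sister_contrasts import CladeRecord
from .synthetic_data import SimConfig, SyntheticPair, SyntheticStudy


def _read_clade(outdir: Path, name: str, count: int, rep: str) -> CladeRecord:
    tree = dendropy.Tree.get(
        path=str(outdir / f"{name}_subtree.nwk"), schema="newick",
        preserve_underscores=True
    )
    tips = {nd.taxon.label for nd in tree.leaf_node_iter() if nd.taxon is not None}
    return CladeRecord(name, count, tree, tips, representative=rep)


def read_study(path: str | Path, genetic_code: str = "standard") -> SyntheticStudy:
    outdir = Path(path)
    pairs_df = pd.read_csv(outdir / "pairs.tsv", sep="\t")
    traits = pd.read_csv(outdir / "traits.tsv", sep="\t")
    log_masses_all = dict(zip(traits["species"], traits["log_mass"]))
    pairs = []
    for row in pairs_df.itertuples():
        aln = read_codon_fasta(outdir / f"{row.pair_id}_alignment.fasta", genetic_code)
        newick = (outdir / f"{row.pair_id}_pairtree.nwk").read_text().strip()
        clade_a = _read_clade(outdir, row.clade_a, int(row.n_a), row.rep_a)
        clade_b = _read_clade(outdir, row.clade_b, int(row.n_b), row.rep_b)
        masses = {
            sp: lm
            for sp, lm in log_masses_all.items()
            if sp.startswith(row.clade_a) or sp.startswith(row.clade_b)
        }
        pairs.append(
            SyntheticPair(
                row.pair_id, clade_a, clade_b, newick, {}, aln, masses, truth={}
            )
        )
    return SyntheticStudy(SimConfig(n_pairs=len(pairs)), pairs)
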