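"""Bundled per-dataset regression summaries for the meta-analysis stage.

The package ships the published summary statistics (through-origin slope,
uncentered R^2, residual df and two-tailed P) of seven mammalian sister-pair
regression datasets — four mitochondrial (family-level, deep, shallow, and an
independent re-analysis of a published mitochondrial dataset) and three
nuclear (all mammals, Eutheria only, Metatheria only). These summaries are
the inputs of the weighted-Z combination stage, which needs only each test's
two-tailed P, slope sign and df.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

DATASETS = (
    "mito_family",
    "mito_deep",
    "mito_shallow",
    "mito_reanalysis",
    "nuc_mammalia",
    "nuc_eutheria",
    "nuc_metatheria",
)


def load_regression_summaries() -> pd.DataFrame:
    """Summary table with columns dataset, genome, response, predictor,
    coefficient, r_squared, df, p_two."""
    with resources.files("claderates.data").joinpath(
        "regression_summaries.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["df"] = df["df"].astype(int)
    return df


def genome_map(df: pd.DataFrame | None = None) -> dict[str, str]:
    if df is None:
        df = load_regression_summaries()
    return dict(df.drop_duplicates("dataset")[["dataset", "genome"]].values)
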