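"""End-to-end study pipeline: estimate -> contrast -> regress -> combine.

A study is a set of sister pairs, each with a codon alignment on a fixed
representative-pair topology, clade sizes, clade subtrees and tip body
masses. The pipeline fits branch-specific rates per pair, builds standardized
ln contrasts with explicit exclusions (saturated / shallow / missing), runs
the through-origin regressions of the standard hypothesis set, and combines
hypothesis families across datasets with the df-weighted Z procedure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import (
    DEFAULT_DIRECTIONS,
    RegressionResult,
    WeightedZComponent,
    regress_through_origin,
    weighted_z,
)
from .rate_estimation import (
    BranchRateEstimates,
    FitConfig,
    PairTree,
    fit_pair,
    flag_saturation,
    terminal_estimates,
)
from .sister_contrasts import ContrastRow, make_contrast
from .synthetic_data import SimConfig, SyntheticStudy, generate_study
from .trait_contrasts import TraitContrast, mle_contrast, variance_homogeneity

#: regression hypothesis set: (response, predictor) on standardized contrasts
DEFAULT_HYPOTHESES = (
    ("clade_size", "dN"),
    ("clade_size", "T"),
    ("clade_size", "dS"),
    ("clade_size", "omega"),
    ("clade_size", "body_mass"),
    ("dN", "body_mass"),
    ("T", "body_mass"),
    ("dS", "body_mass"),
    ("omega", "body_mass"),
)

RATE_MEASURES = ("T", "dN", "dS", "omega")


@dataclass
class RunConfig:
    """Pipeline configuration: exactly one of ``simulation`` or ``input_dir``.

    ``directions`` maps (response, predictor) to an assumed one-tailed
    direction; rate ~ clade-size families default positive and * ~ body-mass
    families negative, while omega families have no default and are combined
    only when a direction is supplied explicitly.
    """

    simulation: SimConfig | None = None
    input_dir: str | None = None
    fit: FitConfig = field(default_factory=FitConfig)
    hypotheses: tuple = DEFAULT_HYPOTHESES
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    dataset_label: str = "study"
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulation or input_dir must be set")


@dataclass
class StudyReport:
    regressions: pd.DataFrame
    families: pd.DataFrame
    contrasts: pd.DataFrame
    exclusions: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "regressions": self.regressions.to_dict(orient="records"),
            "families": self.families.to_dict(orient="records"),
            "exclusions": self.exclusions.to_dict(orient="records"),
        }
        return json.dumps(payload, indent=1, sort_keys=True, allow_nan=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.regressions.to_csv(outdir / "regressions.tsv", sep="\t", index=False)
        self.families.to_csv(outdir / "families.tsv", sep="\t", index=False)
        self.contrasts.to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
        self.exclusions.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(self.to_json())


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def estimate_rates(
    study: SyntheticStudy, fit_config: FitConfig
) -> dict[str, list[BranchRateEstimates]]:
    """Fit each pair tree and retain terminal-branch estimates."""
    out = {}
    for p in study.pairs:
        tree = PairTree.from_newick(
            p.pair_id,
            p.pair_tree_newick,
            p.clade_a.representative,
            p.clade_b.representative,
        )
        fit = fit_pair(p.alignment, tree, fit_config)
        out[p.pair_id] = terminal_estimates(fit)
    return out


def _pair_variables(pair, ests, shallow_floor) -> tuple[dict, dict, float]:
    """Per-pair variable values for clades A and B plus exclusion reasons."""
    est_a, est_b = ests
    t_sum = est_a.T + est_b.T
    reasons: dict[str, str | None] = {}
    values = {}
    for m in RATE_MEASURES:
        va = getattr(est_a, m if m != "omega" else "omega")
        vb = getattr(est_b, m if m != "omega" else "omega")
        fa, fb = flag_saturation(est_a)[m], flag_saturation(est_b)[m]
        if t_sum < shallow_floor:
            reasons[m] = "shallow"
        elif not (fa[0] and fb[0]):
            reasons[m] = fa[1] or fb[1]
        elif va is None or vb is None:
            reasons[m] = "missing"
        else:
            reasons[m] = None
        values[m] = (va, vb)
    values["clade_size"] = (pair.clade_a.species_count, pair.clade_b.species_count)
    reasons["clade_size"] = "shallow" if t_sum < shallow_floor else None
    return values, reasons, t_sum


def build_contrasts(
    study: SyntheticStudy,
    estimates: dict[str, list[BranchRateEstimates]],
    fit_config: FitConfig,
    include_traits: bool = True,
) -> tuple[list[ContrastRow], list[TraitContrast]]:
    """Standardized contrasts for every variable of every pair, with one
    primary exclusion reason each; body-mass contrasts use the BM
    time-averaged estimator on the clade subtrees."""
    rows: list[ContrastRow] = []
    traits: list[TraitContrast] = []
    for p in study.pairs:
        ests = estimates[p.pair_id]
        values, reasons, t_sum = _pair_variables(p, ests, fit_config.shallow_floor)
        weight = float(np.sqrt(t_sum))
        for var, (va, vb) in values.items():
            row = make_contrast(
                va if va is not None else -1.0,
                vb if vb is not None else -1.0,
                ests[0].T,
                ests[1].T,
                var,
                p.pair_id,
            )
            if reasons[var] is not None:
                row.included = False
                row.reason = reasons[var]
            rows.append(row)
        if not include_traits:
            continue
        # body mass: the BM contrast is already a log-scale difference
        logs_a = {k: v for k, v in p.log_masses.items() if k.startswith(p.clade_a.name)}
        logs_b = {k: v for k, v in p.log_masses.items() if k.startswith(p.clade_b.name)}
        try:
            raw = mle_contrast(
                p.clade_a.subtree,
                p.clade_b.subtree,
                {
                    k: _LogTrait(k, v)
                    for k, v in {**logs_a, **logs_b}.items()
                },
                p.pair_id,
            )
            hom = variance_homogeneity(list(logs_a.values()), list(logs_b.values()))
            geo = float(np.mean(list(logs_a.values())) - np.mean(list(logs_b.values())))
            traits.append(
                TraitContrast(p.pair_id, raw, geo, hom.passed, hom.note)
            )
            if reasons["clade_size"] == "shallow" or weight == 0:
                rows.append(
                    ContrastRow(p.pair_id, "body_mass", raw, weight, None, False, "shallow")
                )
            else:
                rows.append(
                    ContrastRow(
                        p.pair_id, "body_mass", raw, weight, raw / weight, True
                    )
                )
        except ValueError:
            rows.append(
                ContrastRow(p.pair_id, "body_mass", None, weight, None, False, "missing")
            )
    return rows, traits


class _LogTrait:
    """Adapter presenting an already-log-transformed value as a TraitRecord."""

    def __init__(self, species: str, log_mass: float):
        self.species = species
        self.log_mass = log_mass


def run_regressions(
    rows: list[ContrastRow], hypotheses, dataset: str
) -> list[RegressionResult | None]:
    by_var: dict[str, dict[str, float]] = {}
    for r in rows:
        if r.included:
            by_var.setdefault(r.variable, {})[r.pair_id] = r.standardized
    out = []
    for response, predictor in hypotheses:
        ys = by_var.get(response, {})
        xs = by_var.get(predictor, {})
        shared = sorted(set(ys) & set(xs))
        if len(shared) < 3:
            out.append(
                RegressionResult(response, predictor, np.nan, np.nan, 0, np.nan,
                                 len(shared), dataset)
            )
            continue
        out.append(
            regress_through_origin(
                [xs[p] for p in shared],
                [ys[p] for p in shared],
                response,
                predictor,
                dataset,
            )
        )
    return out


def combine_from_summary(
    summary: pd.DataFrame,
    directions: dict | None = None,
    split_dn_body: bool = True,
) -> pd.DataFrame:
    """df-weighted Z combination straight from per-dataset summary rows.

    ``summary`` needs columns dataset, response, predictor, coefficient, df,
    p_two (and genome, for the dN ~ body-mass nuclear/mitochondrial split).
    Families whose assumed direction is not supplied (omega families by
    default) are skipped.
    """
    directions = dict(DEFAULT_DIRECTIONS) if directions is None else dict(directions)
    groups: dict[tuple, pd.DataFrame] = {}
    for (resp, pred), g in summary.groupby(["response", "predictor"], sort=False):
        groups[(resp, pred, "all")] = g
        if split_dn_body and resp == "dN" and pred == "body_mass" and "genome" in g:
            for genome, gg in g.groupby("genome", sort=False):
                groups[(resp, pred, genome)] = gg
    records = []
    for (resp, pred, subgroup), g in groups.items():
        direction = directions.get((resp, pred))
        if direction is None:
            records.append(
                {"response": resp, "predictor": pred, "subgroup": subgroup,
                 "n": len(g), "z_combined": np.nan, "p_combined": np.nan,
                 "note": "no assumed direction"}
            )
            continue
        comps = [
            WeightedZComponent(
                row.dataset, float(row.p_two), float(np.sign(row.coefficient)),
                float(row.df), assumed_direction=direction,
            )
            for row in g.itertuples()
        ]
        res = weighted_z(comps, f"{resp}~{pred}/{subgroup}")
        records.append(
            {"response": resp, "predictor": pred, "subgroup": subgroup,
             "n": res.n_tests, "z_combined": res.z_combined,
             "p_combined": res.p_combined, "note": ""}
        )
    return pd.DataFrame.from_records(records)


def run(config: RunConfig) -> StudyReport:
    """Execute the full pipeline and return a machine-readable report.

    Deterministic given the seeds in the configuration; rerunning with the
    same configuration reproduces the report byte for byte.
    """
    if config.simulation is not None:
        study = generate_study(config.simulation)
    else:
        from .study_io import read_study

        study = read_study(config.input_dir)
    estimates = estimate_rates(study, config.fit)
    need_traits = any("body_mass" in h for h in config.hypotheses)
    rows, traits = build_contrasts(
        study, estimates, config.fit, include_traits=need_traits
    )
    regs = run_regressions(rows, config.hypotheses, config.dataset_label)

    reg_df = pd.DataFrame.from_records(
        [
            {"dataset": r.dataset, "response": r.response, "predictor": r.predictor,
             "coefficient": r.slope, "r_squared": r.r_squared, "df": r.df,
             "p_two": r.p_value, "n": r.n}
            for r in regs
        ]
    )
    valid = reg_df.dropna(subset=["p_two"])
    fam_df = combine_from_summary(valid, config.directions) if len(valid) else (
        pd.DataFrame(columns=["response", "predictor", "subgroup", "n",
                              "z_combined", "p_combined", "note"])
    )
    con_df = pd.DataFrame.from_records(
        [
            {"pair_id": r.pair_id, "variable": r.variable, "raw": r.raw,
             "weight": r.weight, "standardized": r.standardized,
             "included": r.included, "reason": r.reason or ""}
            for r in rows
        ]
    )
    exc_df = (
        con_df[~con_df.included]
        .groupby(["variable", "reason"], dropna=False)
        .size()
        .reset_index(name="n_pairs")
    )
    cfg_src = asdict(config.simulation) if config.simulation else {"input_dir": config.input_dir}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_src, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "n_pairs": len(study.pairs),
        "dataset": config.dataset_label,
    }
    report = StudyReport(reg_df, fam_df, con_df, exc_df, provenance)
    if config.output_dir:
        report.write(config.output_dir)
    return report
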