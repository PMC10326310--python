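"""File formats, variable construction, deflation, and the report pipeline.

All inputs and outputs are plain delimited text:

* panel: ``unit,year,<variables...>`` (long format, one row per unit-year);
* adjacency: two columns, one contiguous pair per line, ``#`` comments allowed;
* coordinates: ``unit,x,y`` planar points;
* regions: ``unit,region``;
* weight matrix export: dense CSV with unit ids as header row/column plus a
  sidecar ``<file>.meta.json``-style YAML record (kind, style).

Variable construction for the default application: the outcome FME is the
ratio of per-capita medical expenditure to per-capita disposable income;
monetary covariates enter as natural logs (lnRTI, lnPS, lnRLG, lnRPC); rates
and densities (RH, REF, RMI) pass through. Nominal series can first be
deflated to constant base-year prices with a per-unit price index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .esda import yearly_moran_table
from .impacts import impact_inference
from .panel import PanelDataset
from .panel_model import (
    SDMSpec,
    fit_spatial_panel,
    hausman_test,
    lr_test,
    wald_reduction_tests,
)
from .regional import RegionPartition, all_pairs_table, intra_regional_run
from .weights import (
    SpatialWeightMatrix,
    contiguity_from_adjacency,
    inverse_distance_from_coords,
    row_standardize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig", "load_panel", "write_panel", "load_adjacency", "load_coords",
    "load_regions", "write_weight_matrix", "load_weight_matrix", "deflate",
    "build_model_frame", "descriptive_table", "run_pipeline",
]

#: raw-variable -> model-frame construction rules for the default application
LOG_VARS = {"RTI": "lnRTI", "PS": "lnPS", "RLG": "lnRLG", "RPC": "lnRPC"}
PASSTHROUGH_VARS = ("RH", "REF", "RMI")
MONETARY_VARS = ("RTI", "PS", "RLG", "RPC", "expenditure", "income")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_panel(path) -> PanelDataset:
    """Read a long-format CSV panel (``unit,year,...``) and validate balance."""
    df = pd.read_csv(path, comment="#")
    required = {"unit", "year"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file must have columns {sorted(required)}")
    df["unit"] = df["unit"].astype(str)
    value_cols = [c for c in df.columns if c not in ("unit", "year")]
    for c in value_cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"non-numeric value {row[c]!r} for variable {c!r} at "
                f"unit={row['unit']!r}, year={row['year']!r}"
            )
        df[c] = pd.to_numeric(df[c])
    return PanelDataset(df.set_index(["unit", "year"]))


def write_panel(panel: PanelDataset, path) -> None:
    panel.df.reset_index().to_csv(path, index=False)


def load_adjacency(path) -> list:
    """Two-column pair list; '#' comments and blank lines ignored."""
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.replace(",", " ").split()]
        if len(parts) != 2:
            raise ValueError(f"bad adjacency line: {line!r}")
        pairs.append((parts[0], parts[1]))
    return pairs


def load_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    if not {"unit", "x", "y"}.issubset(df.columns):
        raise ValueError("coordinates file must have columns unit,x,y")
    df["unit"] = df["unit"].astype(str)
    return df.set_index("unit")[["x", "y"]].astype(float)


def load_regions(path) -> RegionPartition:
    df = pd.read_csv(path, comment="#")
    if not {"unit", "region"}.issubset(df.columns):
        raise ValueError("region file must have columns unit,region")
    return RegionPartition.from_mapping(
        dict(zip(df["unit"].astype(str), df["region"].astype(str))))


def write_weight_matrix(swm: SpatialWeightMatrix, path) -> None:
    path = Path(path)
    pd.DataFrame(swm.W, index=list(swm.unit_ids),
                 columns=list(swm.unit_ids)).to_csv(path)
    meta = {"kind": swm.kind, "style": swm.style}
    path.with_suffix(path.suffix + ".meta").write_text(json.dumps(meta))


def load_weight_matrix(path) -> SpatialWeightMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".meta").read_text())
    return SpatialWeightMatrix(df.to_numpy(), tuple(df.columns),
                               style=meta["style"], kind=meta["kind"])


# ---------------------------------------------------------------------------
# variable construction
# ---------------------------------------------------------------------------

def deflate(panel: PanelDataset, variables, base_year,
            deflator_variable: str = "deflator") -> PanelDataset:
    """Convert nominal series to constant base-year prices.

    Divides each listed variable by the per-unit price index normalized to 1
    at ``base_year`` (so base-year values are unchanged).
    """
    if deflator_variable not in panel.variables:
        raise KeyError(f"deflator variable {deflator_variable!r} not in panel")
    if base_year not in panel.periods:
        raise ValueError(f"base year {base_year} not in panel periods")
    dfl = panel.df[deflator_variable]
    if (dfl <= 0).any():
        cell = dfl[dfl <= 0].index[0]
        raise ValueError(f"nonpositive deflator at (unit, year)={cell}")
    base = dfl.unstack(level=1)[base_year]
    norm = dfl / base.reindex(dfl.index.get_level_values(0)).to_numpy()
    df = panel.df.copy()
    tr = dict(panel.transforms)
    for v in variables:
        if v not in df.columns:
            raise KeyError(f"variable {v!r} not in panel")
        df[v] = df[v] / norm
        tr[v] = "deflated"
    return PanelDataset(df, tr)


def build_model_frame(panel: PanelDataset) -> PanelDataset:
    """Construct the estimation variables from raw panel series.

    FME = expenditure / income; natural logs of RTI, PS, RLG, RPC; RH, REF,
    RMI pass through. Nonpositive values under a log or denominator abort
    with the offending cells named (no silent offsets or imputation).
    """
    df = panel.df
    needed = ["expenditure", "income", *LOG_VARS, *PASSTHROUGH_VARS]
    missing = [v for v in needed if v not in df.columns]
    if missing:
        raise KeyError(f"panel lacks raw variables: {missing}")
    problems = []
    for v in ("income", *LOG_VARS):
        bad = df.index[df[v] <= 0]
        problems += [f"{v} <= 0 at {cell}" for cell in bad[:5]]
    if problems:
        raise ValueError("cannot build model frame: " + "; ".join(problems))
    out = pd.DataFrame(index=df.index)
    out["FME"] = df["expenditure"] / df["income"]
    tr = {"FME": "ratio"}
    for raw, name in LOG_VARS.items():
        out[name] = np.log(df[raw])
        tr[name] = "log"
    for v in PASSTHROUGH_VARS:
        out[v] = df[v]
        tr[v] = "none"
    return PanelDataset(out, tr)


def descriptive_table(panel: PanelDataset) -> pd.DataFrame:
    """Mean / SD / min / max per variable (descriptive-statistics table)."""
    stats_df = panel.df.agg(["mean", "std", "min", "max"]).T
    stats_df.columns = ["mean", "sd", "min", "max"]
    stats_df.index.name = "variable"
    return stats_df


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration (paths, model, options)."""

    panel_path: str
    adjacency_path: str | None = None
    coords_path: str | None = None
    regions_path: str | None = None
    outcome: str = "FME"
    covariates: tuple = ("lnRTI", "lnPS", "RH", "REF", "RMI", "lnRLG", "lnRPC")
    weight_kinds: tuple = ("contiguity", "inverse_distance")
    build_frame: bool = False
    base_year: int | None = None
    impact_draws: int = 1000
    seed: int = 0
    output_dir: str = "reports"
    regional: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("covariates", "weight_kinds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def validate(self) -> None:
        for p in (self.panel_path, self.adjacency_path, self.coords_path,
                  self.regions_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if "contiguity" in self.weight_kinds and self.adjacency_path is None:
            raise ValueError("contiguity weights requested without adjacency file")
        if "inverse_distance" in self.weight_kinds and self.coords_path is None:
            raise ValueError("distance weights requested without coordinates file")
        if self.regional and self.regions_path is None:
            raise ValueError("regional stage requested without a region file")


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format="%.6f")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write one report file per stage.

    For each requested weight matrix: yearly Moran table, FE + RE SDM with
    Hausman/LR/Wald specification tests, impact decomposition with simulated
    standard errors; then intra-regional blocks and inter-regional pairs if a
    region file is given. Deterministic given config + seed.

    Returns a dict of the in-memory report tables keyed by file stem.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel_path)
    if config.build_frame:
        if config.base_year is not None:
            panel = deflate(panel, [v for v in MONETARY_VARS
                                    if v in panel.variables], config.base_year)
        panel = build_model_frame(panel)

    matrices = {}
    if "contiguity" in config.weight_kinds:
        adj = load_adjacency(config.adjacency_path)
        matrices["contiguity"] = row_standardize(
            contiguity_from_adjacency(adj, panel.unit_ids))
    if "inverse_distance" in config.weight_kinds:
        coords = load_coords(config.coords_path).loc[list(panel.unit_ids)]
        matrices["inverse_distance"] = row_standardize(
            inverse_distance_from_coords(coords.to_numpy(), panel.unit_ids))

    partition = load_regions(config.regions_path) if config.regions_path else None
    reports: dict[str, pd.DataFrame] = {}
    reports["descriptives"] = descriptive_table(panel)

    for kind, W in matrices.items():
        stage = f"moran_{kind}"
        logger.info("stage %s", stage)
        blocks = []
        for var in (config.covariates[0], config.outcome):
            tab = yearly_moran_table(panel, var, W)
            tab.columns = pd.MultiIndex.from_product([[var], tab.columns])
            blocks.append(tab)
        reports[stage] = pd.concat(blocks, axis=1)

        stage = f"sdm_{kind}"
        logger.info("stage %s", stage)
        spec = SDMSpec(config.outcome, config.covariates, W, "fixed", "SDM")
        fe = fit_spatial_panel(panel, spec)
        re = fit_spatial_panel(
            panel, SDMSpec(config.outcome, config.covariates, W, "random", "SDM"))
        slm = fit_spatial_panel(
            panel, SDMSpec(config.outcome, config.covariates, W, "fixed", "SLM"))
        sem = fit_spatial_panel(
            panel, SDMSpec(config.outcome, config.covariates, W, "fixed", "SEM"))
        w_lag, w_err = wald_reduction_tests(fe)
        lr_lag = lr_test(fe, slm)
        lr_err = lr_test(fe, sem)
        haus = hausman_test(fe, re)
        tab = pd.concat(
            {"FE": fe.summary()[["estimate", "se", "stars"]],
             "RE": re.summary()[["estimate", "se", "stars"]]}, axis=1)
        extra = pd.DataFrame(
            {
                ("FE", "estimate"): [fe.sigma2, fe.R2, fe.loglik,
                                     w_err.statistic, w_lag.statistic,
                                     lr_err.statistic, lr_lag.statistic,
                                     haus.statistic],
                ("RE", "estimate"): [re.sigma2, re.R2, re.loglik,
                                     np.nan, np.nan, np.nan, np.nan, haus.p],
            },
            index=["sigma2", "R2", "loglik", "Wald-err", "Wald-lag",
                   "LR-err", "LR-lag", "Hausman"],
        )
        reports[stage] = pd.concat([tab, extra])

        stage = f"impacts_{kind}"
        logger.info("stage %s", stage)
        dec = impact_inference(fe, D=config.impact_draws, seed=config.seed)
        reports[stage] = dec.to_report()

        if partition is not None:
            stage = f"regional_intra_{kind}"
            logger.info("stage %s", stage)
            blocks = {}
            for region in partition.regions:
                _, rdec = intra_regional_run(
                    panel, spec, partition, region,
                    D=config.impact_draws, seed=config.seed)
                blocks[region] = rdec.to_report().T
            reports[stage] = pd.concat(blocks, names=["region", "effect"])

            stage = f"regional_inter_{kind}"
            logger.info("stage %s", stage)
            # sparse contiguity graphs can lack links between distant regions;
            # such pairs are reported as NaN rows rather than aborting the run
            reports[stage] = all_pairs_table(panel, spec, partition,
                                             on_missing="nan")

    for name, df in reports.items():
        _fmt(df, outdir / f"{name}.csv")
    (outdir / "run_config.yaml").write_text(
        yaml.safe_dump({**config.__dict__,
                        "covariates": list(config.covariates),
                        "weight_kinds": list(config.weight_kinds)}))
    return reports
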