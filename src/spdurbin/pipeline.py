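"""Config-driven end-to-end analysis pipeline.

Reproduces the standard flow of an ecological spatial study: descriptive
statistics, composite-index construction, collinearity screen (VIF), global
Moran's I, spatial Durbin fit, impact decomposition, and the neighbor-order
spatial profile — writing each artifact to the output directory with
provenance (seed, weights checksum, package version) stamped on every table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .esda import morans_i, quintile_classes
from .impacts import partition_impacts, summarize_impacts
from .indices import pca_index, vif
from .model import SpatialDurbin
from .weights import SpatialWeights, read_gal


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Everything one analysis run needs; see ``from_yaml`` for file form."""

    table: str                      # area table CSV path
    weights: str                    # GAL file path
    outcome: str
    covariates: list[str]
    outdir: str
    id_col: str = "id"
    indices: list[dict] = field(default_factory=list)
    # each: {"name": ..., "inputs": [...], "anchor": ...}
    model_form: str = "durbin"
    Q: int = 4
    draws: int = 1000
    seed: int = 0
    permutations: int = 999

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        return cls(**cfg)


def descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Min/max/mean/SD (ddof=1) per numeric column; non-numeric skipped."""
    rows = {}
    for col in table.columns:
        s = table[col]
        if not pd.api.types.is_numeric_dtype(s):
            warnings.warn(f"skipping non-numeric column {col!r}", UserWarning,
                          stacklevel=2)
            continue
        v = s.to_numpy(dtype=float)
        rows[col] = {
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)),
        }
    return pd.DataFrame(rows).T[["min", "max", "mean", "sd"]]


def load_inputs(config: RunConfig) -> tuple[pd.DataFrame, SpatialWeights]:
    """Read the area table and weights, aligning table rows to weight order."""
    df = pd.read_csv(config.table, comment="#")
    w = read_gal(config.weights)
    if config.id_col not in df.columns:
        raise PipelineError(f"id column {config.id_col!r} not in table")
    df[config.id_col] = df[config.id_col].astype(str)
    if set(df[config.id_col]) != set(w.ids):
        raise PipelineError("table ids and weights ids do not match")
    df = df.set_index(config.id_col).loc[w.ids].reset_index()
    return df, w.row_standardize()


def _write_table(df: pd.DataFrame, path: Path, provenance: dict,
                 index_label: str = "variable") -> None:
    header = "".join(f"# {k}={v}\n" for k, v in provenance.items())
    path.write_text(header + df.to_csv(index_label=index_label))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the mapping of artifact names to paths.

    Any stage failure aborts with :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    df, w = stage("load")(lambda: load_inputs(config))
    provenance = {
        "package": f"spdurbin {__version__}",
        "seed": config.seed,
        "n": w.n,
        "w_checksum": w.checksum(),
    }

    def build_indices():
        for spec in config.indices:
            idx = pca_index(df[spec["inputs"]], sign_anchor=spec.get("anchor"))
            df[spec["name"]] = idx.scores
        return config.indices
    stage("indices")(build_indices)

    missing = [c for c in [config.outcome, *config.covariates] if c not in df.columns]
    if missing:
        raise PipelineError(f"stage 'validate' failed: missing columns {missing}")

    def do_descriptives():
        desc = descriptives(df[[config.outcome, *config.covariates]])
        p = outdir / "descriptives.csv"
        _write_table(desc, p, provenance)
        artifacts["descriptives"] = str(p)
    stage("descriptives")(do_descriptives)

    def do_vif():
        v = vif(df[config.covariates])
        p = outdir / "vif.csv"
        _write_table(v.to_frame("vif"), p, provenance)
        artifacts["vif"] = str(p)
    stage("vif")(do_vif)

    def do_esda():
        res = morans_i(df[config.outcome], w, permutations=config.permutations,
                       seed=config.seed)
        p = outdir / "moran.json"
        p.write_text(json.dumps({**provenance, **res.to_dict()}, indent=2))
        artifacts["moran"] = str(p)
        df[f"{config.outcome}_quintile"] = quintile_classes(df[config.outcome])
        pt = outdir / "table_with_classes.csv"
        pt.write_text(
            "".join(f"# {k}={v}\n" for k, v in provenance.items()) + df.to_csv(index=False)
        )
        artifacts["table_with_classes"] = str(pt)
    stage("esda")(do_esda)

    def do_fit():
        model = SpatialDurbin.from_dataframe(
            df, config.outcome, config.covariates, w, model_form=config.model_form
        )
        return model.fit()
    results = stage("fit")(do_fit)

    def write_fit():
        p = outdir / "fit.json"
        p.write_text(json.dumps({**provenance, **results.to_dict()}, indent=2))
        artifacts["fit"] = str(p)
        coefs = pd.DataFrame({
            "coef": results.params[results.vcov.index],
            "std_err": results.bse,
            "z": results.zvalues,
            "p_value": results.pvalues,
        })
        pc = outdir / "coefficients.csv"
        _write_table(coefs, pc, provenance, index_label="parameter")
        artifacts["coefficients"] = str(pc)
    stage("fit_report")(write_fit)

    def do_impacts():
        imp = summarize_impacts(results, draws=config.draws, seed=config.seed)
        p = outdir / "effects.csv"
        _write_table(imp.table(), p, provenance)
        artifacts["effects"] = str(p)
        pf = outdir / "effects_full.csv"
        _write_table(imp.frame, pf, provenance)
        artifacts["effects_full"] = str(pf)
    stage("impacts")(do_impacts)

    def do_partition():
        part = partition_impacts(results, Q=config.Q, draws=config.draws,
                                 seed=config.seed)
        p = outdir / "partition.csv"
        _write_table(part.table(), p, provenance)
        artifacts["partition"] = str(p)
    stage("partition")(do_partition)

    def do_log():
        p = outdir / "run_log.json"
        p.write_text(json.dumps({
            **provenance,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "config": {k: getattr(config, k) for k in (
                "table", "weights", "outcome", "covariates", "model_form",
                "Q", "draws", "seed", "permutations")},
            "artifacts": artifacts,
        }, indent=2))
        artifacts["run_log"] = str(p)
    stage("log")(do_log)

    return artifacts
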