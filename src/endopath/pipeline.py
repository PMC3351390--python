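"""End-to-end analysis: prepare data, screen phylogenetic signal, fit the
model zoo, bootstrap the winner, and write the report bundle.

Outputs mirror the standard artifacts of a comparative path analysis: a
model-selection table (chi-square, df, P, BIC, RMSEA, explained R_max
variance), a fitted-equations report, a phylogenetic-signal table with a
correction advisory, bootstrap intervals for the best model, and a JSON run
manifest sufficient to reproduce every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .models import ZOO_IDS, model_zoo
from .phylo import Phylogeny, correction_advised, read_newick, signal_frame, signal_table
from .rmax import AbundanceSeries, estimate_rmax
from .sem import (
    FitOptions,
    TraitTable,
    bootstrap_ci,
    equations_report,
    fit_ml,
    model_selection_table,
    prepare,
)

__all__ = ["PipelineConfig", "PipelineError", "run_full_analysis"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration for :func:`run_full_analysis`.

    ``traits`` is a CSV path or a :class:`~endopath.sem.TraitTable`;
    ``tree`` an optional Newick path/string or :class:`Phylogeny`;
    ``timeseries`` an optional mapping of species to abundance-series CSV
    paths (used to fill in missing R_max values is out of scope here — the
    estimates are written alongside for reference).
    """

    traits: object
    out_dir: str | Path
    tree: object | None = None
    timeseries: dict[str, str] | None = None
    models: tuple[str, ...] = ZOO_IDS
    b3: str = "reciprocal"
    log_columns: tuple[str, ...] = ("mb", "BMR", "MMR")
    bootstrap_reps: int = 1999
    seed: int = 0
    n_restarts: int = 10


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("load")
def _load(config: PipelineConfig):
    if isinstance(config.traits, TraitTable):
        table = config.traits
    else:
        table = TraitTable.from_csv(config.traits)
    tree = None
    if config.tree is not None:
        if isinstance(config.tree, Phylogeny):
            tree = config.tree
        else:
            src = str(config.tree)
            if Path(src).exists():
                src = Path(src).read_text()
            tree = read_newick(src)
    return table, tree


def run_full_analysis(config: PipelineConfig) -> dict:
    """Run the full comparative analysis and write the report bundle.

    Returns a dict of output paths.  Any stage failure removes partial
    outputs and raises :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        table, tree = _load(config)

        prepared = _stage("prepare")(prepare)(
            table, frozenset(c for c in config.log_columns if c in table.columns)
        )

        # phylogenetic-signal screen (advisory only)
        if tree is not None:
            results = _stage("signal")(signal_table)(prepared, tree)
            sig = signal_frame(results)
            sig_path = out / "signal.csv"
            sig.to_csv(sig_path, index=False)
            written.append(sig_path)
            advisory = correction_advised(results)
        else:
            advisory = None

        # R_max estimates from any provided abundance series
        if config.timeseries:
            rows = []
            for sp, path in sorted(config.timeseries.items()):
                series = AbundanceSeries.from_csv(path, species=sp)
                rows.append(
                    {"species": sp, "R_max_estimate": estimate_rmax(series)}
                )
            rmax_path = out / "rmax_estimates.csv"
            pd.DataFrame(rows).to_csv(rmax_path, index=False)
            written.append(rmax_path)

        # fit the candidate models
        opts = FitOptions(n_restarts=config.n_restarts, seed=config.seed)
        models = {mid: model_zoo(mid, b3=config.b3) for mid in config.models}
        fits = []
        fit_stage = _stage("fit")(fit_ml)
        for mid in config.models:
            fits.append(fit_stage(models[mid], prepared, opts))

        selection = _stage("selection")(model_selection_table)(fits)
        sel_path = out / "selection.csv"
        selection.to_csv(sel_path, index=False)
        written.append(sel_path)

        eq_path = out / "equations.txt"
        eq_path.write_text(equations_report(fits, models))
        written.append(eq_path)

        # bootstrap the best model
        best_id = str(selection.iloc[0]["model_id"])
        boot = _stage("bootstrap")(bootstrap_ci)(
            models[best_id],
            prepared,
            n_replicates=config.bootstrap_reps,
            seed=config.seed,
        )
        boot_path = out / "bootstrap.csv"
        boot.to_frame().to_csv(boot_path, index=False)
        written.append(boot_path)

        manifest = {
            "endopath_version": __version__,
            "seed": config.seed,
            "config": {
                "models": list(config.models),
                "b3": config.b3,
                "log_columns": list(config.log_columns),
                "bootstrap_reps": config.bootstrap_reps,
                "n_restarts": config.n_restarts,
            },
            "n_species": prepared.n,
            "best_model": best_id,
            "phylogenetic_correction_advised": advisory,
            "bootstrap_unreliable": boot.unreliable,
            "warnings": [
                f"model {f.model_id}: Heywood case" for f in fits if f.heywood
            ]
            + [f"model {f.model_id}: not converged" for f in fits if not f.converged],
            "output_sha256": {},
        }
        for p in written:
            manifest["output_sha256"][p.name] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(man_path)
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return {p.stem if p.suffix != ".json" else "manifest": str(p) for p in written}
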