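"""End-to-end orchestration: simulate -> index -> rates -> smooth -> regress.

Every stage draws its randomness from a named substream of the single config
seed, outputs are written with fixed numeric formatting, and the manifest
records input hashes and convergence summaries — a rerun under an identical
config reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from ._rng import child_seed
from .bym import BYMModel, fit_bym, smoothed_rates
from .config import RunConfig
from .deprivation import compute_index
from .graph import AdjacencyGraph, TractSet
from .io import (
    grid_polygons,
    read_counts,
    read_gal,
    read_indicators,
    read_polygons,
    write_choropleth,
    write_city,
)
from .mcmc import MCMCConfig, gelman_rubin
from .rates import crude_rate
from .regression import run_stratified_analysis
from .synthetic import simulate_city

logger = logging.getLogger("fertimap")

__all__ = ["run_all", "PipelineError"]

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence(child_seed(seed, "stage", stage)).generate_state(1, np.uint32)[0]
        % (2**31)
    )


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute the full pipeline; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "inputs": {},
        "outputs": {},
        "convergence": {},
        "unconverged": False,
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, exc) from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            logger.info("stage %s done in %.2fs", name, manifest["stages"][name]["seconds"])

        return deco

    state: dict[str, Any] = {}

    @stage("simulate")
    def _simulate():
        if config.simulate is None:
            state["counts_path"] = Path(config.counts)
            state["indicators_path"] = Path(config.indicators)
            state["adjacency_path"] = Path(config.adjacency)
            return
        opts = dict(config.simulate)
        rows, cols = opts.pop("rows"), opts.pop("cols")
        city = simulate_city(rows, cols, seed=_stage_seed(config.seed, "simulate"), **opts)
        paths = write_city(city, out / "data")
        state["counts_path"] = Path(paths["counts"])
        state["indicators_path"] = Path(paths["indicators"])
        state["adjacency_path"] = Path(paths["adjacency"])
        state["city"] = city
        manifest["outputs"]["truth"] = paths["truth"]

    @stage("load")
    def _load():
        ids, graph = read_gal(state["adjacency_path"])
        if "city" in state:
            tracts = state["city"].tracts
        else:
            tracts = TractSet(tract_id=tuple(ids))
        state["tracts"], state["graph"] = tracts, graph
        state["counts"] = read_counts(state["counts_path"])
        state["indicators"] = read_indicators(state["indicators_path"])
        if config.polygons:
            state["polygons"] = read_polygons(config.polygons)
        elif "city" in state:
            state["polygons"] = grid_polygons(tracts)
        for key in ("counts_path", "indicators_path", "adjacency_path"):
            manifest["inputs"][key.removesuffix("_path")] = {
                "path": str(state[key]),
                "sha256": _sha256(state[key]),
            }

    @stage("index")
    def _index():
        index = compute_index(state["indicators"])
        state["index"] = index
        path = out / "index.csv"
        index.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"]["index"] = str(path)
        manifest["index"] = {
            "variance_explained": round(index.variance_explained, 6),
            "q5": round(index.q5, 6),
            "q95": round(index.q95, 6),
        }
        if "polygons" in state:
            cpath = out / "deprivation_septiles.geojson"
            write_choropleth(
                dict(zip(index.tract_id, index.x)), state["polygons"], "septile", cpath
            )
            manifest["outputs"]["deprivation_map"] = str(cpath)

    @stage("rates")
    def _rates():
        rates = crude_rate(state["counts"])
        path = out / "crude_rates.csv"
        rates.to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"]["crude_rates"] = str(path)

    @stage("smooth")
    def _smooth():
        counts, graph, tracts = state["counts"], state["graph"], state["tracts"]
        results = []
        for nat in config.smooth_nationalities:
            for age in config.smooth_age_groups:
                for period in config.periods:
                    sub = counts[
                        (counts["age_group"] == age)
                        & (counts["nationality"] == nat)
                        & (counts["period"] == period)
                    ]
                    if sub.empty:
                        raise ValueError(f"no counts for smooth stratum {age}/{nat}/{period}")
                    agg = sub.groupby("tract_id", sort=False)[["births", "women"]].sum()
                    agg = agg.reindex(list(tracts.tract_id), fill_value=0)
                    model = BYMModel(
                        graph=graph,
                        O=agg["births"].to_numpy(),
                        N=agg["women"].to_numpy(),
                        tau_u_prior=config.tau_u_prior,
                        tau_v_prior=config.tau_v_prior,
                    )
                    key = f"smooth/{age}/{nat}/{period}"
                    cfg = MCMCConfig(seed=_stage_seed(config.seed, key), **config.mcmc)
                    draws = fit_bym(model, cfg)
                    rhats = gelman_rubin(draws) if cfg.n_chains >= 2 else {}
                    manifest["convergence"][key] = {
                        k: round(v, 4) for k, v in rhats.items()
                    }
                    sm = smoothed_rates(draws, model).to_frame(tracts.tract_id)
                    sm.insert(1, "period", period)
                    sm.insert(1, "nationality", nat)
                    sm.insert(1, "age_group", age)
                    results.append(sm)
        path = out / "smoothed_rates.csv"
        pd.concat(results, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"]["smoothed_rates"] = str(path)

    @stage("regress")
    def _regress():
        cfg = MCMCConfig(seed=_stage_seed(config.seed, "regress"), **config.mcmc)
        table = run_stratified_analysis(
            state["counts"],
            state["index"],
            state["graph"],
            cfg,
            age_groups=config.regress_age_groups,
            nationalities=config.regress_nationalities,
            periods=tuple(config.periods),
            shared_fields=config.shared_fields,
        )
        path = out / "rr_table.csv"
        table.to_csv(path, index=False, float_format=_FLOAT_FMT)
        manifest["outputs"]["rr_table"] = str(path)
        for key in manifest["convergence"].values():
            if any(v > 1.1 for v in key.values()):
                manifest["unconverged"] = True
        if np.nanmax(table["max_rhat"].to_numpy()) > 1.1:
            manifest["unconverged"] = True

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest["outputs"]["manifest"] = str(manifest_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
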