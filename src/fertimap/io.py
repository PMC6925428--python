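"""File interchange: GAL spatial weights, counts/indicator CSVs, GeoJSON maps.

GAL is the de-facto plain-text format for contiguity weights: a header line
with the number of areal units, then for each unit a line ``id n_neighbors``
followed by a line listing the neighbour ids.  No spatial-weights library is
assumed; the format is simple enough to read and write directly.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping, shape

from .deprivation import DeprivationIndex, assign_septiles
from .graph import AdjacencyGraph, TractSet
from .rates import COUNT_COLUMNS, validate_counts
from .synthetic import SyntheticCity

logger = logging.getLogger("fertimap")

__all__ = [
    "read_gal",
    "write_gal",
    "read_counts",
    "write_counts",
    "read_indicators",
    "write_indicators",
    "write_index",
    "write_choropleth",
    "grid_polygons",
    "write_city",
]

_FLOAT_FMT = "%.10g"  # deterministic CSV formatting


def read_gal(path: str | Path) -> tuple[list[str], AdjacencyGraph]:
    """Read a GAL file; returns the tract ids (file order) and the graph.

    Asymmetric listings (i names j but not vice versa) are symmetrized with a
    logged warning; a neighbour id that never appears as a unit is an error
    reported with its line number.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty GAL file")
    header = lines[0].split()
    # header is either "n" or the 4-token "0 n file var" variant
    n_declared = int(header[1] if len(header) >= 2 else header[0])

    ids: list[str] = []
    listed: dict[str, list[tuple[str, int]]] = {}
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        parts = lines[i].split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{i + 1}: expected 'id n_neighbors', got {lines[i]!r}")
        tid, k = parts[0], int(parts[1])
        ids.append(tid)
        nbs: list[str] = []
        if k > 0:
            i += 1
            if i >= len(lines):
                raise ValueError(f"{path}:{i}: missing neighbour line for {tid}")
            nbs = lines[i].split()
            if len(nbs) != k:
                raise ValueError(f"{path}:{i + 1}: {tid} declares {k} neighbours, lists {len(nbs)}")
        listed[tid] = [(nb, i + 1) for nb in nbs]
        i += 1
    if len(ids) != n_declared:
        raise ValueError(f"{path}: header declares {n_declared} units, file lists {len(ids)}")

    pos = {t: k for k, t in enumerate(ids)}
    pairs: set[tuple[int, int]] = set()
    directed: set[tuple[int, int]] = set()
    for tid, nbs in listed.items():
        for nb, lineno in nbs:
            if nb not in pos:
                raise ValueError(f"{path}:{lineno}: neighbour id {nb!r} is not a listed unit")
            a, b = pos[tid], pos[nb]
            directed.add((a, b))
            pairs.add((min(a, b), max(a, b)))
    asym = [(a, b) for a, b in directed if (b, a) not in directed]
    if asym:
        msg = f"{path}: {len(asym)} asymmetric neighbour entries symmetrized"
        logger.warning(msg)
        warnings.warn(msg, UserWarning)
    edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    return ids, AdjacencyGraph(n=len(ids), edges=edges)


def write_gal(path: str | Path, tracts: TractSet, graph: AdjacencyGraph) -> None:
    nbs = graph.neighbor_lists()
    out = [str(tracts.n_tracts)]
    for i, tid in enumerate(tracts.tract_id):
        out.append(f"{tid} {len(nbs[i])}")
        if nbs[i]:
            out.append(" ".join(tracts.tract_id[j] for j in nbs[i]))
    Path(path).write_text("\n".join(out) + "\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tract_id": str})
    return validate_counts(df)


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    validate_counts(counts)[COUNT_COLUMNS].to_csv(path, index=False)


def read_indicators(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tract_id": str})


def write_indicators(path: str | Path, indicators: pd.DataFrame) -> None:
    indicators.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_index(path: str | Path, index: DeprivationIndex) -> None:
    index.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def grid_polygons(tracts: TractSet) -> dict[str, object]:
    """Unit-square polygons for a synthetic lattice (planar grid coordinates)."""
    if tracts.rows is None or tracts.cols is None:
        raise ValueError("tract set has no grid coordinates")
    return {
        tid: box(c, -float(r) - 1.0, c + 1.0, -float(r))
        for tid, r, c in zip(tracts.tract_id, tracts.rows, tracts.cols)
    }


def write_choropleth(
    values: Mapping[str, float] | pd.Series,
    polygons: Mapping[str, object],
    classing: str,
    path: str | Path,
) -> None:
    """Write a GeoJSON FeatureCollection of per-tract values.

    ``classing`` is ``"septile"`` (classes from the deprivation septile rule
    applied to the values) or ``"continuous"`` (no class property beyond the
    value itself).  Feature order follows the order of ``values`` and
    missing polygons are an error, so output is deterministic.
    """
    if isinstance(values, pd.Series):
        values = values.to_dict()
    ids = list(values)
    missing = [t for t in ids if t not in polygons]
    if missing:
        raise ValueError(f"no polygon for tract(s): {missing[:5]}")
    if classing not in ("septile", "continuous"):
        raise ValueError("classing must be 'septile' or 'continuous'")
    vals = np.array([float(values[t]) for t in ids])
    classes = assign_septiles(vals) if classing == "septile" else [None] * len(ids)

    features = []
    for k, tid in enumerate(ids):
        geom = polygons[tid]
        geom_json = mapping(geom) if hasattr(geom, "geom_type") else dict(geom)
        props = {"tract_id": tid, "value": float(vals[k])}
        if classing == "septile":
            props["class"] = int(classes[k])
        features.append({"type": "Feature", "geometry": geom_json, "properties": props})
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def read_choropleth(path: str | Path) -> pd.DataFrame:
    """Values (and classes) back out of a written choropleth."""
    fc = json.loads(Path(path).read_text())
    rows = [f["properties"] for f in fc["features"]]
    return pd.DataFrame(rows)


def read_polygons(path: str | Path) -> dict[str, object]:
    """tract_id -> shapely geometry from a GeoJSON FeatureCollection."""
    fc = json.loads(Path(path).read_text())
    return {f["properties"]["tract_id"]: shape(f["geometry"]) for f in fc["features"]}


def write_city(city: SyntheticCity, outdir: str | Path) -> dict[str, str]:
    """Persist a synthetic city: counts, indicators, GAL adjacency, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.csv",
        "indicators": outdir / "indicators.csv",
        "adjacency": outdir / "adjacency.gal",
        "truth": outdir / "truth.json",
    }
    write_counts(paths["counts"], city.counts)
    write_indicators(paths["indicators"], city.indicators)
    write_gal(paths["adjacency"], city.tracts, city.graph)
    truth = {key: t.to_dict() for key, t in city.truths.items()}
    paths["truth"].write_text(json.dumps({"seed": city.seed, "strata": truth}, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
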