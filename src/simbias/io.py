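"""Readers and writers for the package's plain-text formats.

All tabular output is TSV; run metadata (seed, parameters, package version)
travels as a JSON sidecar next to every table so any result file can be
regenerated.  Genotype files hold one binary genome string per line with
'#' comments; structure lists hold one dot-bracket or abstract shape per
line; time series are two-column CSV (t, value); interaction graphs are
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .polyomino import Genotype
from .rna import validate_dotbracket, validate_level5
from .sampling import FrequencyTable, serialize_key
from .timeseries import TimeSeries
from .topology import InteractionGraph, Interface


def read_genotypes(path, n_tiles: int, bits_per_color: int) -> list:
    """Genotype file: one binary string per line, '#' starts a comment."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(Genotype(line, n_tiles, bits_per_color))
    return out


def write_genotypes(path, genotypes, header: str | None = None) -> None:
    lines = [f"# {header}"] if header else []
    lines += [g.bits if isinstance(g, Genotype) else str(g)
              for g in genotypes]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tileset(path) -> np.ndarray:
    """Tile-set TSV with columns tile_index, N, E, S, W."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("tile_index")
    return df[["N", "E", "S", "W"]].to_numpy(dtype=np.int64)


def write_tileset(path, colors: np.ndarray) -> None:
    df = pd.DataFrame(np.asarray(colors), columns=["N", "E", "S", "W"])
    df.insert(0, "tile_index", np.arange(len(df)))
    df.to_csv(path, sep="\t", index=False)


def write_frequency_table(path, table: FrequencyTable,
                          complexities: dict | None = None) -> None:
    """Frequency TSV (phenotype, count, probability[, complexity]) plus a
    JSON metadata sidecar (same stem, .meta.json)."""
    df = table.to_dataframe()
    if complexities is not None:
        lookup = {serialize_key(k): float(v) for k, v in
                  complexities.items()}
        df["complexity"] = [lookup.get(p) for p in df["phenotype"]]
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    meta = {"n_samples": table.n_samples, "n_und": table.n_und,
            "seed": table.seed}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n")


def read_structures(path) -> list:
    """Structure list: one dot-bracket or level-5 shape per line."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if set(line) <= {"[", "]"} or line == "_":
            out.append(validate_level5(line))
        else:
            out.append(validate_dotbracket(line))
    return out


def read_timeseries_csv(path, dt: float | None = None) -> TimeSeries:
    """Two-column CSV (t, value); dt inferred from t spacing if not given."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if dt is None:
        dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return TimeSeries(tuple(v), dt)


def write_timeseries_csv(path, series: TimeSeries) -> None:
    n = len(series)
    pd.DataFrame({"t": np.arange(n) * series.dt,
                  "value": series.array}).to_csv(path, index=False)


def graph_from_dict(data: dict) -> InteractionGraph:
    edges = tuple(Interface(int(e["a"]), int(e["b"]), int(e["interface_id"]),
                            str(e["kind"])) for e in data.get("edges", []))
    return InteractionGraph(tuple(data["node_types"]), edges)


def graph_to_dict(g: InteractionGraph) -> dict:
    return {"node_types": list(g.node_types),
            "edges": [{"a": e.a, "b": e.b, "interface_id": e.interface_id,
                       "kind": e.kind} for e in g.edges]}


def read_graphs_json(path) -> list:
    """JSON file holding one graph object or a list of them."""
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [graph_from_dict(d) for d in data]


def write_graphs_json(path, graphs) -> None:
    Path(path).write_text(json.dumps([graph_to_dict(g) for g in graphs],
                                     indent=2) + "\n")


def write_run_metadata(path, **fields) -> None:
    """JSON run metadata written alongside every CLI artifact."""
    from . import __version__

    payload = {"simbias_version": __version__, **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
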