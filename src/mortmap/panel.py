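"""Areal panel and adjacency-graph containers with plain-text I/O.

The panel holds observed counts ``O`` (areas x time periods), optional
denominators ``P``, optional expected counts ``E`` and an optional
area-level covariate table ``X``.  The adjacency graph encodes the
contiguity structure used by the intrinsic CAR priors.  Both objects are
read from and written to small text formats:

* counts CSV with header ``area_id,time_id,observed[,population]``,
  one row per (area, time) cell;
* covariates CSV with header ``area_id,<name1>,...,<nameK>``;
* graph file: first line ``n``, then ``n`` lines
  ``<i> <n_i> <j1> ... <j n_i>`` with 1-based indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ArealPanel",
    "AdjacencyGraph",
    "read_panel",
    "write_panel",
    "read_graph",
    "write_graph",
    "write_report",
]


@dataclass
class AdjacencyGraph:
    """Symmetric neighbour structure over ``n`` areas.

    ``neighbors`` follows the common adjacency-file convention: one sorted
    list of 1-based neighbour indices per area.  Zero-based views used
    internally are exposed as properties.  Islands (areas with no
    neighbours) are permitted but reported via :attr:`islands`.
    """

    n: int
    neighbors: list

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("graph must have at least one node")
        if len(self.neighbors) != self.n:
            raise ValueError(
                f"expected {self.n} neighbor lists, got {len(self.neighbors)}"
            )
        clean = []
        for i, nbr in enumerate(self.neighbors, start=1):
            nbr = [int(j) for j in nbr]
            for j in nbr:
                if not 1 <= j <= self.n:
                    raise ValueError(f"node {i}: neighbor index {j} outside 1..{self.n}")
                if j == i:
                    raise ValueError(f"node {i} lists itself as a neighbor")
            if len(set(nbr)) != len(nbr):
                dup = sorted(j for j in set(nbr) if nbr.count(j) > 1)
                raise ValueError(f"node {i} lists duplicate neighbor(s) {dup}")
            clean.append(sorted(nbr))
        for i, nbr in enumerate(clean, start=1):
            for j in nbr:
                if i not in clean[j - 1]:
                    raise ValueError(
                        f"asymmetric adjacency: node {i} lists {j} "
                        f"but node {j} does not list {i}"
                    )
        self.neighbors = clean

    # -- zero-based views -------------------------------------------------
    @cached_property
    def neighbors0(self):
        return [np.array([j - 1 for j in nbr], dtype=int) for nbr in self.neighbors]

    @cached_property
    def degrees(self) -> np.ndarray:
        return np.array([len(nbr) for nbr in self.neighbors], dtype=int)

    @cached_property
    def edges(self) -> np.ndarray:
        """Edge list as an (n_edges, 2) array of 0-based pairs with i < j."""
        out = [
            (i, j - 1)
            for i, nbr in enumerate(self.neighbors)
            for j in nbr
            if j - 1 > i
        ]
        return np.array(out, dtype=int).reshape(-1, 2)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def islands(self) -> list:
        """1-based indices of areas without neighbours."""
        return [i + 1 for i in range(self.n) if not self.neighbors[i]]

    @cached_property
    def components(self) -> list:
        """Connected components as sorted 0-based index arrays."""
        seen = np.zeros(self.n, dtype=bool)
        comps = []
        for start in range(self.n):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.append(v)
                for w in self.neighbors0[v]:
                    if not seen[w]:
                        seen[w] = True
                        stack.append(w)
            comps.append(np.array(sorted(comp), dtype=int))
        return comps

    @property
    def n_components(self) -> int:
        return len(self.components)

    def is_connected(self) -> bool:
        return self.n_components == 1

    def color_classes(self) -> list:
        """Greedy proper colouring; nodes in one class share no edge.

        Used to vectorise single-site Metropolis updates: within a class the
        full conditionals do not depend on each other.  Islands are excluded.
        """
        color = -np.ones(self.n, dtype=int)
        for v in range(self.n):
            if not self.neighbors[v]:
                continue
            used = {color[w] for w in self.neighbors0[v] if color[w] >= 0}
            c = 0
            while c in used:
                c += 1
            color[v] = c
        return [np.where(color == c)[0] for c in range(color.max() + 1)] if (color >= 0).any() else []

    def neighbor_sums(self, x: np.ndarray) -> np.ndarray:
        """For each area, the sum of ``x`` over its neighbours."""
        out = np.zeros(self.n, dtype=float)
        if self.n_edges:
            a, b = self.edges[:, 0], self.edges[:, 1]
            np.add.at(out, a, x[b])
            np.add.at(out, b, x[a])
        return out


@dataclass
class ArealPanel:
    """Counts panel over N areas and T time periods.

    ``O`` holds observed integer counts (a mortality ratio per 100,000
    live births is itself treated as a Poisson count).  ``P`` and ``E``
    are optional positive denominators / expected counts; ``X`` is an
    optional area-level, time-constant covariate table indexed like
    ``area_ids``.
    """

    area_ids: list
    time_ids: list
    O: np.ndarray
    P: np.ndarray | None = None
    X: pd.DataFrame | None = None
    E: np.ndarray | None = None

    def __post_init__(self):
        self.area_ids = list(self.area_ids)
        self.time_ids = list(self.time_ids)
        N, T = len(self.area_ids), len(self.time_ids)
        if N < 2:
            raise ValueError("panel needs at least 2 areas")
        if T < 1:
            raise ValueError("panel needs at least 1 time period")
        if len(set(self.area_ids)) != N:
            raise ValueError("area_ids must be unique")
        if len(set(self.time_ids)) != T:
            raise ValueError("time_ids must be unique")
        O = np.asarray(self.O)
        if O.shape != (N, T):
            raise ValueError(f"O must have shape {(N, T)}, got {O.shape}")
        if not np.all(np.isfinite(O.astype(float))):
            raise ValueError("O contains missing or non-finite cells")
        if np.any(O.astype(float) != np.floor(O.astype(float))):
            raise ValueError("observed counts must be integers (no rounding is applied)")
        if np.any(O.astype(float) < 0):
            raise ValueError("observed counts must be non-negative")
        self.O = O.astype(np.int64)
        for name in ("P", "E"):
            M = getattr(self, name)
            if M is not None:
                M = np.asarray(M, dtype=float)
                if M.shape != (N, T):
                    raise ValueError(f"{name} must have shape {(N, T)}")
                if not np.all(M > 0):
                    raise ValueError(f"all {name} entries must be positive")
                setattr(self, name, M)
        if self.X is not None:
            X = self.X
            if not isinstance(X, pd.DataFrame):
                raise ValueError("X must be a pandas DataFrame keyed by area_id")
            if list(X.index) != self.area_ids:
                X = X.reindex(self.area_ids)
                if X.isna().any().any():
                    missing = [a for a in self.area_ids if a not in self.X.index]
                    raise ValueError(f"covariates missing for area(s) {missing}")
            self.X = X.astype(float)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_times(self) -> int:
        return len(self.time_ids)

    @property
    def covariate_names(self) -> list:
        return [] if self.X is None else list(self.X.columns)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.area_ids):
            for t, tt in enumerate(self.time_ids):
                row = {"area_id": a, "time_id": tt, "observed": int(self.O[i, t])}
                if self.P is not None:
                    row["population"] = self.P[i, t]
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_panel(counts_path, covariates_path=None) -> ArealPanel:
    """Read a counts CSV (plus optional covariate CSV) into an :class:`ArealPanel`.

    Areas keep their first-appearance order in the counts file; time ids are
    sorted ascending.  Every (area, time) cell must be present exactly once.
    """
    df = pd.read_csv(counts_path, comment="#")
    required = {"area_id", "time_id", "observed"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts file must have columns {sorted(required)}")
    area_ids = list(pd.unique(df["area_id"]))
    time_ids = sorted(pd.unique(df["time_id"]))

    dup = df.duplicated(["area_id", "time_id"])
    if dup.any():
        pairs = df.loc[dup, ["area_id", "time_id"]].values.tolist()
        raise ValueError(f"duplicate (area,time) rows: {pairs[:10]}")
    present = set(zip(df["area_id"], df["time_id"]))
    missing = [(a, t) for a in area_ids for t in time_ids if (a, t) not in present]
    if missing:
        raise ValueError(f"missing (area,time) cells: {missing[:10]}")

    obs = pd.to_numeric(df["observed"], errors="coerce")
    bad = obs.isna()
    if bad.any():
        raise ValueError(f"non-numeric observed values at rows {list(df.index[bad])[:10]}")
    neg = obs < 0
    if neg.any():
        raise ValueError(f"negative observed values at rows {list(df.index[neg])[:10]}")
    nonint = obs != np.floor(obs)
    if nonint.any():
        raise ValueError(
            f"non-integer observed values at rows {list(df.index[nonint])[:10]}; "
            "counts are not rounded implicitly"
        )

    ai = {a: i for i, a in enumerate(area_ids)}
    ti = {t: j for j, t in enumerate(time_ids)}
    O = np.zeros((len(area_ids), len(time_ids)), dtype=np.int64)
    for a, t, o in zip(df["area_id"], df["time_id"], obs):
        O[ai[a], ti[t]] = int(o)

    P = None
    if "population" in df.columns:
        pop = pd.to_numeric(df["population"], errors="coerce")
        if pop.isna().any() or (pop <= 0).any():
            raise ValueError("population column must be positive and numeric")
        P = np.zeros_like(O, dtype=float)
        for a, t, p in zip(df["area_id"], df["time_id"], pop):
            P[ai[a], ti[t]] = p

    X = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path, comment="#")
        if "area_id" not in cov.columns:
            raise ValueError("covariates file must have an area_id column")
        unknown = [a for a in cov["area_id"] if a not in ai]
        if unknown:
            raise ValueError(f"covariate area_id(s) not in panel: {unknown}")
        absent = [a for a in area_ids if a not in set(cov["area_id"])]
        if absent:
            raise ValueError(f"panel area(s) missing from covariates: {absent}")
        X = cov.set_index("area_id").reindex(area_ids)

    return ArealPanel(area_ids, time_ids, O, P=P, X=X)


def write_panel(panel: ArealPanel, counts_path, covariates_path=None, header=None):
    """Write a panel back to the counts/covariates CSV formats."""
    df = panel.to_long_frame()
    with open(counts_path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        df.to_csv(fh, index=False)
    if covariates_path is not None and panel.X is not None:
        with open(covariates_path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            panel.X.reset_index(names="area_id").to_csv(fh, index=False)


def read_graph(path) -> AdjacencyGraph:
    """Parse and validate an adjacency-list file (1-based indices)."""
    with open(path) as fh:
        tokens = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
    if not tokens:
        raise ValueError("empty graph file")
    try:
        n = int(tokens[0][0])
    except (ValueError, IndexError):
        raise ValueError("first line must be the number of nodes") from None
    if len(tokens) != n + 1:
        raise ValueError(f"expected {n} node lines, got {len(tokens) - 1}")
    neighbors = [None] * n
    for parts in tokens[1:]:
        i, k = int(parts[0]), int(parts[1])
        nbr = [int(p) for p in parts[2:]]
        if len(nbr) != k:
            raise ValueError(f"node {i}: declared {k} neighbors but listed {len(nbr)}")
        if not 1 <= i <= n:
            raise ValueError(f"node index {i} outside 1..{n}")
        if neighbors[i - 1] is not None:
            raise ValueError(f"node {i} listed twice")
        neighbors[i - 1] = nbr
    if any(v is None for v in neighbors):
        missing = [i + 1 for i, v in enumerate(neighbors) if v is None]
        raise ValueError(f"no line for node(s) {missing}")
    return AdjacencyGraph(n, neighbors)


def write_graph(graph: AdjacencyGraph, path, header=None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(f"{graph.n}\n")
        for i, nbr in enumerate(graph.neighbors, start=1):
            fh.write(" ".join(map(str, [i, len(nbr)] + list(nbr))) + "\n")


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _sig6(v):
    if isinstance(v, float):
        if math.isfinite(v):
            return float(f"{v:.6g}")
        return v
    if isinstance(v, dict):
        return {k: _sig6(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_sig6(x) for x in v]
    if isinstance(v, (np.floating,)):
        return _sig6(float(v))
    if isinstance(v, (np.integer,)):
        return int(v)
    return v


def _report_frame(report) -> pd.DataFrame:
    if isinstance(report, pd.DataFrame):
        return report
    if hasattr(report, "to_frame") and callable(report.to_frame):
        return report.to_frame()
    if hasattr(report, "__dataclass_fields__"):
        d = {f.name: getattr(report, f.name) for f in dc_fields(report)}
        return pd.DataFrame([d])
    if isinstance(report, dict):
        return pd.DataFrame([report])
    raise ValueError(f"cannot serialise report of type {type(report).__name__}")


def write_report(report, path, format="csv", header=None):
    """Write a result table (risk report, posterior summary, DIC stats, trend
    fits) to CSV or JSON with floats at 6 significant digits."""
    if format not in ("csv", "json"):
        raise ValueError(f"unknown report format {format!r}; use 'csv' or 'json'")
    frame = _report_frame(report)
    if format == "csv":
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            frame.to_csv(fh, index=False, float_format="%.6g")
    else:
        records = [_sig6(rec) for rec in frame.to_dict(orient="records")]
        payload = records[0] if len(records) == 1 else records
        if header:
            payload = {"_meta": header, "records": records} if isinstance(payload, list) else {
                "_meta": header, **payload}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_sig6)
            fh.write("\n")
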