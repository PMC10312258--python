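"""File formats and run configuration.

Canonical interchange formats are delimited text (time series, matrices,
occupancy tables), GraphML (networks, with a JSON manifest of construction
parameters), and JSON (cycles, comparison reports).  Configuration files
are YAML mirroring the model parameter names (tau_E, gamma_E, ...).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .attractors import AttractorRepertoire, SymbolicSequence
from .hemo import BoldSeries, HemodynamicParameters
from .model import ModelParameters, NeuralTrajectory
from .network import TransitionNetwork
from .timeseries import MultivariateTimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_matrix",
    "write_matrix",
    "write_trajectory",
    "read_trajectory",
    "write_bold",
    "write_network",
    "read_network",
    "write_repertoire",
    "write_symbols",
    "read_symbols",
    "RunConfig",
]

_RESERVED = {"time", "epoch", "label"}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_timeseries(path) -> MultivariateTimeSeries:
    """Read a delimited time series with a header row.

    Channel columns are all numeric columns except the reserved names
    ``time`` (time stamps), ``epoch`` (run labels) and ``label``
    (per-sample annotations).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path))
    except Exception as exc:  # pragma: no cover - pandas message carries context
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    channels = [c for c in df.columns if c not in _RESERVED]
    for c in channels:
        if not np.issubdtype(df[c].dtype, np.number):
            bad = df.index[pd.to_numeric(df[c], errors="coerce").isna()][0]
            raise ValueError(
                f"non-numeric value in column {c!r} at data line {bad + 2} of {path}"
            )
    times = (
        df["time"].to_numpy(float)
        if "time" in df.columns
        else np.arange(len(df), dtype=float)
    )
    return MultivariateTimeSeries(
        X=df[channels].to_numpy(float),
        times=times,
        epochs=df["epoch"].to_numpy() if "epoch" in df.columns else None,
        labels=df["label"].to_numpy(str) if "label" in df.columns else None,
        channel_names=channels,
    )


def write_timeseries(ts: MultivariateTimeSeries, path) -> None:
    path = Path(path)
    cols = {"time": ts.times}
    names = ts.channel_names or [f"ch{i}" for i in range(ts.n_channels)]
    for i, name in enumerate(names):
        cols[name] = ts.X[:, i]
    if ts.epochs is not None and len(np.unique(ts.epochs)) > 1:
        cols["epoch"] = ts.epochs
    if ts.labels is not None:
        cols["label"] = ts.labels
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


def read_matrix(path) -> np.ndarray:
    """Headerless delimited numeric matrix."""
    return np.loadtxt(path, delimiter=_sep_for(path))


def write_matrix(M: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(M), delimiter=_sep_for(path))


def write_trajectory(traj: NeuralTrajectory, path) -> None:
    """Time column, G trace, then S_E and S_I columns per region."""
    N = traj.n_regions
    cols = {"time": traj.times, "G": traj.G_trace}
    for i in range(N):
        cols[f"SE_{i}"] = traj.S_E[:, i]
    for i in range(N):
        cols[f"SI_{i}"] = traj.S_I[:, i]
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


def read_trajectory(path) -> NeuralTrajectory:
    df = pd.read_csv(path, sep=_sep_for(path))
    se = sorted((c for c in df.columns if c.startswith("SE_")), key=lambda c: int(c[3:]))
    si = sorted((c for c in df.columns if c.startswith("SI_")), key=lambda c: int(c[3:]))
    times = df["time"].to_numpy(float)
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.001
    return NeuralTrajectory(
        times=times,
        S_E=df[se].to_numpy(float),
        S_I=df[si].to_numpy(float),
        G_trace=df["G"].to_numpy(float),
        dt=dt,
    )


def write_bold(bold: BoldSeries, path) -> None:
    cols = {"time": bold.times}
    for i in range(bold.n_regions):
        cols[f"bold_{i}"] = bold.bold[:, i]
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


def write_network(net: TransitionNetwork, path, manifest: dict | None = None) -> None:
    """GraphML with node attributes plus a JSON manifest of parameters."""
    path = Path(path)
    g = nx.DiGraph()
    for n in net.node_order():
        attrs = {
            "members": ",".join(map(str, net.members[n].tolist())),
            "measure": float(net.graph.nodes[n].get("measure", 0.0)),
        }
        for key in ("mean_rank", "mean_activation", "dominant_label"):
            if key in net.graph.nodes[n]:
                attrs[key] = net.graph.nodes[n][key]
        g.add_node(str(n), **attrs)
    for u, v in net.graph.edges:
        g.add_edge(str(u), str(v))
    nx.write_graphml(g, path)
    man = {
        "n_samples": net.n_samples,
        "n_nodes": net.n_nodes,
        "version": _version,
        **{k: v for k, v in net.params.items()},
        **(manifest or {}),
    }
    Path(str(path) + ".manifest.json").write_text(json.dumps(man, indent=2, default=str))


def read_network(path) -> TransitionNetwork:
    path = Path(path)
    g_raw = nx.read_graphml(path)
    manifest_path = Path(str(path) + ".manifest.json")
    params = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}

    def _key(n):
        try:
            return int(n)
        except ValueError:
            return n

    g = nx.DiGraph()
    members = {}
    for n, data in g_raw.nodes(data=True):
        key = _key(n)
        members[key] = np.array(
            [int(x) for x in str(data.get("members", "")).split(",") if x != ""]
        )
        attrs = {k: v for k, v in data.items() if k != "members"}
        g.add_node(key, **attrs)
    for u, v in g_raw.edges:
        g.add_edge(_key(u), _key(v))
    n_samples = int(sum(len(m) for m in members.values()))
    return TransitionNetwork(graph=g, members=members, n_samples=n_samples, params=params)


def write_repertoire(rep: AttractorRepertoire, path) -> None:
    """One row per attractor point: G, state coordinates, branch id, max
    eigenvalue real part; plus a JSON summary next to it."""
    path = Path(path)
    rows = []
    for fp, b in zip(rep.points, rep.branch_id):
        rows.append(
            {
                "G": fp.G,
                **{f"x{i}": v for i, v in enumerate(fp.state)},
                "branch": int(b),
                "max_re_eig": float(np.max(fp.eigenvalues.real))
                if fp.eigenvalues is not None
                else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)
    summary = {
        "n_points": len(rep.points),
        "n_branches": rep.n_branches,
        "G_min": float(np.min(rep.G_grid)),
        "G_max": float(np.max(rep.G_grid)),
        "G_scaling": rep.scaling,
    }
    Path(str(path) + ".summary.json").write_text(json.dumps(summary, indent=2))


def write_symbols(sym: SymbolicSequence, path) -> None:
    pd.DataFrame({"time": sym.times, "symbol": sym.symbols}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_symbols(path) -> SymbolicSequence:
    df = pd.read_csv(path, sep=_sep_for(path))
    return SymbolicSequence(
        symbols=df["symbol"].to_numpy(int), times=df["time"].to_numpy(float)
    )


_MAPPER_KEYS = {"k", "delta", "p_norm"}
_SIM_KEYS = {"duration", "dt", "TR", "record_every"}


@dataclass
class RunConfig:
    """Validated run configuration; round-trips losslessly through YAML.

    Precedence elsewhere in the package: CLI flag > config file > built-in
    defaults.  Unknown keys anywhere in the file are rejected.
    """

    model: ModelParameters = field(default_factory=ModelParameters)
    hemodynamics: HemodynamicParameters = field(default_factory=HemodynamicParameters)
    protocol: list = field(default_factory=list)  # [(time, G), ...]
    mapper: dict = field(default_factory=lambda: {"k": 16, "delta": 10, "p_norm": 2})
    simulation: dict = field(
        default_factory=lambda: {"duration": 60.0, "dt": 0.001, "TR": 0.72, "record_every": 1}
    )
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

        def check(section, keys, allowed_keys):
            bad = set(keys) - allowed_keys
            if bad:
                raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")

        model_kw = raw.get("model", {}) or {}
        check("model", model_kw, {f.name for f in dataclasses.fields(ModelParameters)})
        hemo_kw = raw.get("hemodynamics", {}) or {}
        check("hemodynamics", hemo_kw, {f.name for f in dataclasses.fields(HemodynamicParameters)})
        mapper_kw = raw.get("mapper", {}) or {}
        check("mapper", mapper_kw, _MAPPER_KEYS)
        sim_kw = raw.get("simulation", {}) or {}
        check("simulation", sim_kw, _SIM_KEYS)
        cfg = cls(
            model=ModelParameters(**model_kw),
            hemodynamics=HemodynamicParameters(**hemo_kw),
            protocol=[tuple(map(float, bp)) for bp in raw.get("protocol", [])],
            mapper={**cls().mapper, **mapper_kw},
            simulation={**cls().simulation, **sim_kw},
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", ".")),
        )
        return cfg

    def to_yaml(self, path) -> None:
        data = {
            "model": dataclasses.asdict(self.model),
            "hemodynamics": dataclasses.asdict(self.hemodynamics),
            "protocol": [list(bp) for bp in self.protocol],
            "mapper": dict(self.mapper),
            "simulation": dict(self.simulation),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
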