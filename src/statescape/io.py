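"""Serialization of analysis results (JSON) and run provenance."""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, is_dataclass

import numpy as np

from .meanshift import ClusterResult, MeanShiftParams

__all__ = [
    "write_clusters",
    "read_clusters",
    "write_json",
    "provenance_record",
]


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if is_dataclass(o):
            return asdict(o)
        return super().default(o)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, cls=_NumpyEncoder, indent=1)


def write_clusters(result: ClusterResult, path) -> None:
    write_json(
        {
            "centroids": result.centroids,
            "masses": result.masses,
            "assignments": result.assignments,
            "params": asdict(result.params) if result.params else None,
            "converged": result.converged,
        },
        path,
    )


def read_clusters(path) -> ClusterResult:
    with open(path) as fh:
        d = json.load(fh)
    params = MeanShiftParams(**d["params"]) if d.get("params") else None
    return ClusterResult(
        np.array(d["centroids"], dtype=np.int8),
        np.array(d["masses"], dtype=np.int64),
        np.array(d["assignments"], dtype=np.int64),
        params,
        bool(d.get("converged", True)),
    )


def provenance_record(stage: str, seed: int, params: dict) -> dict:
    """Machine-readable record of what produced a run directory."""
    import statescape

    return {
        "stage": stage,
        "seed": seed,
        "params": params,
        "package_version": statescape.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
    }
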