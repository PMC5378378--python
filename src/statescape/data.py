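"""Shared data containers and their plain-text serialization.

All state-space analyses in this package operate on time-ordered matrices of
binary (+/-1) network states.  A row is the instantaneous configuration of the
N recorded units (binary neurons, or binarized Up/Down states of neural
modules); rows are successive time bins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryStateSeries",
    "read_state_series",
    "write_state_series",
]


def _as_pm1(states: np.ndarray) -> np.ndarray:
    arr = np.asarray(states)
    if arr.ndim != 2:
        raise ValueError(f"states must be a 2-D (time x units) array, got shape {arr.shape}")
    if arr.size and not np.isin(np.unique(arr), (-1, 1)).all():
        raise ValueError("state entries must be +1 or -1")
    return np.ascontiguousarray(arr, dtype=np.int8)


@dataclass
class BinaryStateSeries:
    """Time-ordered matrix of +/-1 network states.

    Parameters
    ----------
    states : (T, N) array of int8
        One row per time bin, entries in {-1, +1}.
    bin_duration : float
        Duration of one row in the natural time unit of the source
        (1 Monte Carlo sweep for binary-network samples, milliseconds for
        binarized spiking activity).
    origin : str
        Free-text provenance tag.
    """

    states: np.ndarray
    bin_duration: float = 1.0
    origin: str = ""

    def __post_init__(self) -> None:
        self.states = _as_pm1(self.states)
        if self.states.shape[0] < 1:
            raise ValueError("a state series needs at least one row")

    @property
    def n_samples(self) -> int:
        return self.states.shape[0]

    @property
    def n_units(self) -> int:
        return self.states.shape[1]

    def __len__(self) -> int:
        return self.n_samples


def write_state_series(series: BinaryStateSeries, path) -> None:
    """Write a series as TSV: one row per time bin, with a `# N=.. bin=..` header."""
    header = f"# N={series.n_units} bin={series.bin_duration} origin={json.dumps(series.origin)}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, series.states, fmt="%d", delimiter="\t")


def read_state_series(path) -> BinaryStateSeries:
    bin_duration, origin = 1.0, ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            body = first[1:].strip()
            if "origin=" in body:
                body, _, origin_json = body.partition("origin=")
                origin = json.loads(origin_json)
            for tok in body.split():
                if tok.startswith("bin="):
                    bin_duration = float(tok[4:])
            states = np.loadtxt(fh, dtype=np.int8, delimiter="\t", ndmin=2)
        else:
            fh.seek(0)
            states = np.loadtxt(fh, dtype=np.int8, delimiter="\t", ndmin=2)
    return BinaryStateSeries(states, bin_duration=bin_duration, origin=origin)


def write_matrix_tsv(matrix: np.ndarray, path, meta: dict | None = None) -> None:
    """TSV matrix with a one-line JSON header comment (patterns, couplings)."""
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta or {}) + "\n")
        np.savetxt(fh, np.atleast_2d(matrix), delimiter="\t")


def read_matrix_tsv(path) -> tuple[np.ndarray, dict]:
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first[1:]) if first.startswith("#") else {}
        if not first.startswith("#"):
            fh.seek(0)
        matrix = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return matrix, meta
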