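"""Suspend/resume: training state as a versioned JSON text container.

Everything needed to continue a run bit-identically is stored: the
specification, parameters (with explicit shape metadata), the hidden
assignment, the log-likelihood trace, the RNG state and the configuration.
"""
from __future__ import annotations

import dataclasses
import json

import numpy as np

from .core import SequenceBatch
from .errors import SerializationError
from .formats import spec_from_dict, spec_to_dict
from .learning import EMConfig, TrainingState
from .params import DBNParams

FORMAT_VERSION = 1


def _hidden_to_json(hidden):
    return [
        [None if arr is None else np.asarray(arr).tolist() for arr in per_node]
        for per_node in hidden
    ]


def _hidden_from_json(h):
    return [
        [None if arr is None else np.asarray(arr, dtype=np.int64)
         for arr in per_node]
        for per_node in h
    ]


def state_to_dict(state: TrainingState) -> dict:
    return {
        "format": "seqdbn-state",
        "version": FORMAT_VERSION,
        "spec": spec_to_dict(state.params.spec),
        "iteration": state.iteration,
        "params": state.params.to_dict(),
        "params_avg": None if state.params_avg is None else state.params_avg.to_dict(),
        "snapshots": [p.to_dict() for p in state._snapshots],
        "hidden": _hidden_to_json(state.hidden),
        "trace": state.trace,
        "rng_state": _jsonable(state.rng_state),
        "config": None if state.config is None else dataclasses.asdict(state.config),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def state_from_dict(d: dict) -> TrainingState:
    try:
        if d.get("format") != "seqdbn-state":
            raise SerializationError("not a seqdbn state file")
        version = d.get("version")
        if version != FORMAT_VERSION:
            raise SerializationError(
                f"unsupported state-file version {version!r} "
                f"(this build reads version {FORMAT_VERSION})"
            )
        spec = spec_from_dict(d["spec"])
        params = DBNParams.from_dict(spec, d["params"])
        params_avg = (None if d.get("params_avg") is None
                      else DBNParams.from_dict(spec, d["params_avg"]))
        snapshots = [DBNParams.from_dict(spec, p) for p in d.get("snapshots", [])]
        config = None if d.get("config") is None else EMConfig(**d["config"])
        rng_state = d["rng_state"]
        return TrainingState(
            iteration=int(d["iteration"]),
            params=params,
            hidden=_hidden_from_json(d["hidden"]),
            trace=list(d["trace"]),
            rng_state=rng_state,
            config=config,
            params_avg=params_avg,
            _snapshots=snapshots,
        )
    except SerializationError:
        raise
    except (KeyError, TypeError, ValueError, IndexError) as exc:
        raise SerializationError(f"malformed state file: {exc}") from exc


def save_state(state: TrainingState, path) -> None:
    """Write a training state; ``load_state`` restores it bit-faithfully."""
    with open(path, "w") as fh:
        json.dump(state_to_dict(state), fh)


def load_state(path) -> TrainingState:
    """Read a state file; raises :class:`SerializationError` on truncated or
    corrupted input and on version mismatch, leaving no partial state."""
    try:
        with open(path) as fh:
            d = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise SerializationError(f"cannot parse state file {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise SerializationError(f"{path}: not a state document")
    return state_from_dict(d)
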