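"""Text file formats: DBN specification (YAML) and sequence data (TSV).

Sequence files carry one record per (sequence, slice) with tab-separated
per-node fields; vector components within a field are comma-separated and
hidden entries are written as the literal token ``?``.  The header names every
node and its family so a file is self-describing.
"""
from __future__ import annotations

import numpy as np
import yaml

from .core import (
    DBNSpec,
    INT_FAMILIES,
    NodeSpec,
    Sequence,
    SequenceBatch,
    VECTOR_FAMILIES,
)
from .errors import DataError, SpecError

HIDDEN_TOKEN = "?"


# ---------------------------------------------------------------------------
# DBN specification files
# ---------------------------------------------------------------------------

def spec_to_dict(spec: DBNSpec) -> dict:
    return {
        "nodes": [
            {
                "name": nd.name,
                "family": nd.family,
                "size": nd.size,
                "hidden": nd.hidden_allowed,
            }
            for nd in spec.nodes
        ],
        "intra_edges": [list(e) for e in spec.intra_edges],
        "inter_edges": [list(e) for e in spec.inter_edges],
    }


def spec_from_dict(d: dict) -> DBNSpec:
    try:
        nodes = tuple(
            NodeSpec(
                name=str(nd["name"]),
                family=str(nd["family"]),
                size=int(nd["size"]),
                hidden_allowed=bool(nd.get("hidden", False)),
            )
            for nd in d["nodes"]
        )
        intra = tuple(tuple(e) for e in d.get("intra_edges") or ())
        inter = tuple(tuple(e) for e in d.get("inter_edges") or ())
    except (KeyError, TypeError) as exc:
        raise SpecError(f"malformed spec document: {exc}") from exc
    return DBNSpec(nodes=nodes, intra_edges=intra, inter_edges=inter)


def write_spec(spec: DBNSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def read_spec(path) -> DBNSpec:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise SpecError(f"{path}: not a spec document")
    return spec_from_dict(d)


# ---------------------------------------------------------------------------
# Sequence data files
# ---------------------------------------------------------------------------

def _format_value(node: NodeSpec, value, hidden: bool) -> str:
    if hidden:
        return HIDDEN_TOKEN
    if node.family in INT_FAMILIES:
        if node.family in VECTOR_FAMILIES:
            return ",".join(str(int(x)) for x in value)
        return str(int(value))
    if node.family in VECTOR_FAMILIES:
        return ",".join(repr(float(x)) for x in value)
    return repr(float(value))


def _parse_value(node: NodeSpec, text: str):
    if node.family in VECTOR_FAMILIES:
        parts = text.split(",")
        if len(parts) != node.size:
            raise DataError(
                f"node {node.name!r}: expected {node.size} components, got {len(parts)}"
            )
        if node.family in INT_FAMILIES:
            return [int(p) for p in parts]
        return [float(p) for p in parts]
    if node.family in INT_FAMILIES:
        return int(text)
    return float(text)


def write_sequences(batch: SequenceBatch, path) -> None:
    spec = batch.spec
    header = ["seq", "slice"] + [f"{nd.name}:{nd.family}" for nd in spec.nodes]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for s, seq in enumerate(batch.sequences):
            for t in range(seq.length):
                fields = [str(s), str(t)]
                for i, nd in enumerate(spec.nodes):
                    fields.append(
                        _format_value(nd, seq.values[i][t], bool(seq.mask[i][t]))
                    )
                fh.write("\t".join(fields) + "\n")


def write_posterior(freq, spec: DBNSpec, path) -> None:
    """Posterior state-frequency tables as delimited text.

    ``freq`` is the structure returned by :func:`seqdbn.gibbs_infer`:
    ``freq[sequence][node]`` an (L, size) table or None.  One row per
    (sequence, slice, node, state) with the empirical frequency.
    """
    with open(path, "w") as fh:
        fh.write("seq\tslice\tnode\tstate\tfrequency\n")
        for s, per_node in enumerate(freq):
            for i, table in enumerate(per_node):
                if table is None:
                    continue
                name = spec.nodes[i].name
                for t in range(table.shape[0]):
                    for k in range(table.shape[1]):
                        fh.write(f"{s}\t{t}\t{name}\t{k}\t{float(table[t, k])!r}\n")


def read_sequences(path, spec: DBNSpec) -> SequenceBatch:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty sequence file")
    header = lines[0].split("\t")
    want = ["seq", "slice"] + [f"{nd.name}:{nd.family}" for nd in spec.nodes]
    if header != want:
        raise DataError(
            f"{path}: header {header!r} does not match spec (expected {want!r})"
        )
    # group rows by sequence id, slices in file order
    rows: dict[int, list[list[str]]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) != len(want):
            raise DataError(f"{path}: row with {len(fields)} fields, expected {len(want)}")
        rows.setdefault(int(fields[0]), []).append(fields)
    per_sequence = []
    for sid in sorted(rows):
        recs = sorted(rows[sid], key=lambda f: int(f[1]))
        length = len(recs)
        if [int(f[1]) for f in recs] != list(range(length)):
            raise DataError(f"{path}: sequence {sid} has non-contiguous slices")
        values, mask = [], []
        for i, nd in enumerate(spec.nodes):
            col = [f[2 + i] for f in recs]
            m = np.array([c == HIDDEN_TOKEN for c in col], dtype=bool)
            if nd.family in VECTOR_FAMILIES:
                fill = [0] * nd.size
            else:
                fill = 0
            vals = [fill if hid else _parse_value(nd, c) for c, hid in zip(col, m)]
            values.append(vals)
            mask.append(m)
        per_sequence.append((values, mask))
    return SequenceBatch.from_arrays(spec, per_sequence)
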