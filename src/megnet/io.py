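"""Readers and writers for recordings, flag tables, edge lists and metrics.

Formats:

* recording, text: ``<prefix>.tsv`` (one row per sample, one column per
  node) plus ``<prefix>.meta.yaml`` sidecar (fs, labels, roles, annotations);
* recording, binary: ``<prefix>.vsb`` — three ASCII header lines
  (``shape: n m``, ``dtype: <np dtype>``, ``fs: <Hz>``) followed by the raw
  C-order array bytes; same yaml sidecar for labels/annotations;
* flagged intervals: 3-column TSV (start_s, end_s, kind);
* thresholded network: TSV edge list (node_i, node_j, weight, sign, tp)
  with a ``#`` header comment carrying N, K, band, alpha;
* metrics: TSV, one row per subject x band.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ThresholdedNetwork
from .synthetic_meg import VirtualSensorRecording

__all__ = [
    "write_recording_text",
    "read_recording_text",
    "write_recording_binary",
    "read_recording_binary",
    "write_flags",
    "read_flags",
    "write_network",
    "read_network",
    "write_metrics",
    "read_metrics",
]


def _write_sidecar(rec: VirtualSensorRecording, path: Path) -> None:
    meta = {
        "fs": float(rec.fs),
        "node_labels": list(rec.node_labels),
        "node_roles": list(rec.node_roles),
        "annotations": [[float(a), float(b), str(k)] for a, b, k in rec.annotations],
    }
    path.write_text(yaml.safe_dump(meta, sort_keys=False))


def _read_sidecar(path: Path) -> dict:
    return yaml.safe_load(path.read_text())


def write_recording_text(rec: VirtualSensorRecording, prefix: str | Path) -> Path:
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), rec.data, delimiter="\t", fmt="%.10g")
    _write_sidecar(rec, prefix.with_suffix(".meta.yaml"))
    return prefix.with_suffix(".tsv")


def read_recording_text(prefix: str | Path) -> VirtualSensorRecording:
    prefix = Path(prefix)
    data = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    meta = _read_sidecar(prefix.with_suffix(".meta.yaml"))
    return VirtualSensorRecording(
        data=data,
        fs=meta["fs"],
        node_labels=meta["node_labels"],
        node_roles=meta.get("node_roles", []),
        annotations=[tuple(a) for a in meta.get("annotations", [])],
    )


def write_recording_binary(rec: VirtualSensorRecording, prefix: str | Path) -> Path:
    prefix = Path(prefix)
    path = prefix.with_suffix(".vsb")
    arr = np.ascontiguousarray(rec.data, dtype=np.float64)
    header = f"shape: {arr.shape[0]} {arr.shape[1]}\ndtype: {arr.dtype.name}\nfs: {rec.fs}\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(arr.tobytes())
    _write_sidecar(rec, prefix.with_suffix(".meta.yaml"))
    return path


def read_recording_binary(prefix: str | Path) -> VirtualSensorRecording:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".vsb"), "rb") as fh:
        lines = [fh.readline().decode("ascii").strip() for _ in range(3)]
        shape = tuple(int(v) for v in lines[0].split(":")[1].split())
        dtype = np.dtype(lines[1].split(":")[1].strip())
        fs = float(lines[2].split(":")[1])
        data = np.frombuffer(fh.read(), dtype=dtype).reshape(shape)
    meta = _read_sidecar(prefix.with_suffix(".meta.yaml"))
    return VirtualSensorRecording(
        data=data.copy(),
        fs=fs,
        node_labels=meta["node_labels"],
        node_roles=meta.get("node_roles", []),
        annotations=[tuple(a) for a in meta.get("annotations", [])],
    )


def write_flags(flags: list[tuple[float, float, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start_s\tend_s\tkind\n")
        for lo, hi, kind in flags:
            fh.write(f"{lo:.6f}\t{hi:.6f}\t{kind}\n")


def read_flags(path: str | Path) -> list[tuple[float, float, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(float(r.start_s), float(r.end_s), str(r.kind)) for r in df.itertuples()]


def write_network(net: ThresholdedNetwork, path: str | Path) -> None:
    band = net.band.name if hasattr(net.band, "name") else str(net.band)
    with open(path, "w") as fh:
        fh.write(f"# N={net.N} K={net.K} band={band} alpha={net.alpha} tp_crit={net.tp_crit:.6g}\n")
        fh.write(f"# roles={','.join(net.node_roles)}\n")
        fh.write("node_i\tnode_j\tweight\tsign\ttp\n")
        for i, j, w, sign, tp in net.edges:
            fh.write(f"{net.node_labels[i]}\t{net.node_labels[j]}\t{w:.10g}\t{'+' if sign > 0 else '-'}\t{tp:.10g}\n")


def read_network(path: str | Path) -> ThresholdedNetwork:
    with open(path) as fh:
        head = fh.readline().strip().lstrip("# ").split()
        fields = dict(kv.split("=") for kv in head)
        roles_line = fh.readline().strip().lstrip("# ")
        roles = roles_line.split("=", 1)[1].split(",") if "=" in roles_line else []
        df = pd.read_csv(fh, sep="\t")
    n = int(fields["N"])
    labels = sorted(set(df["node_i"]) | set(df["node_j"]))
    # rebuild a full label list if the edge list does not mention every node
    if len(labels) < n:
        labels = labels + [f"node_{k}" for k in range(n - len(labels))]
    index = {lab: k for k, lab in enumerate(labels)}
    edges = [
        (
            min(index[r.node_i], index[r.node_j]),
            max(index[r.node_i], index[r.node_j]),
            float(r.weight),
            1 if r.sign == "+" else -1,
            float(r.tp),
        )
        for r in df.itertuples()
    ]
    return ThresholdedNetwork(
        N=n,
        edges=sorted(edges),
        tp_crit=float(fields["tp_crit"]),
        alpha=float(fields["alpha"]),
        K=int(fields["K"]),
        band=fields["band"],
        node_labels=labels,
        node_roles=roles if len(roles) == n else [],
    )


def write_metrics(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
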