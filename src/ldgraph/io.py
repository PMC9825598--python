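"""Readers and writers for the pipeline's on-disk artifacts.

Masks and maps travel as NIfTI (nibabel), behaviour tables as CSV (pandas),
group graphs as GraphML (networkx) plus a TSV edge list, node tables as CSV
with voxel indices and mm coordinates, and run metadata as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import networkx as nx

from .cohort import LesionMask, PatientRecord, SubstrateMap
from .grid import GridSpec, make_grid
from .graphs import EdgeSet, LesionGraph, NodeTable


def write_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine())
    nib.save(img, str(path))


def read_mask(path, patient_id: Optional[str] = None) -> LesionMask:
    img = nib.load(str(path))
    aff = img.affine
    grid = make_grid(img.shape[:3], tuple(np.abs(np.diag(aff)[:3])),
                     tuple(aff[:3, 3]))
    data = (np.asanyarray(img.dataobj) > 0.5).astype(np.uint8)
    return LesionMask(patient_id or Path(path).stem.split(".")[0], data, grid)


def write_map(m: SubstrateMap, path) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.float32), m.grid.affine()), str(path))


def write_behaviour(records: Sequence[PatientRecord], path) -> None:
    pd.DataFrame([{"patient_id": r.patient_id, "score": r.score, "nart": r.nart,
                   "age": r.age, "aetiology": r.aetiology}
                  for r in records]).to_csv(path, index=False)


def read_behaviour(path) -> list[PatientRecord]:
    df = pd.read_csv(path)
    return [PatientRecord(str(row.patient_id), float(row.score), float(row.nart),
                          float(row.age), str(row.aetiology))
            for row in df.itertuples()]


def write_node_table(nodes: NodeTable, path) -> None:
    mm = nodes.grid.index_to_mm(nodes.voxel_indices)
    pd.DataFrame({"node_id": np.arange(len(nodes)),
                  "i": nodes.voxel_indices[:, 0], "j": nodes.voxel_indices[:, 1],
                  "k": nodes.voxel_indices[:, 2],
                  "x_mm": mm[:, 0], "y_mm": mm[:, 1], "z_mm": mm[:, 2]}
                 ).to_csv(path, index=False)


def write_graphml(g: LesionGraph, path) -> None:
    G = nx.Graph()
    for nid, vi in enumerate(g.nodes.voxel_indices):
        G.add_node(int(nid), i=int(vi[0]), j=int(vi[1]), k=int(vi[2]))
    for (a, b), c, w in zip(g.edges.pairs, g.cooccurrence, g.deficit_weight):
        G.add_edge(int(a), int(b), cooccurrence=int(c), deficit_weight=float(w))
    nx.write_graphml(G, str(path))


def read_graphml(path, grid: GridSpec) -> LesionGraph:
    G = nx.read_graphml(str(path), node_type=int)
    order = sorted(G.nodes)
    vi = np.array([[G.nodes[n]["i"], G.nodes[n]["j"], G.nodes[n]["k"]]
                   for n in order])
    nodes = NodeTable(vi, grid)
    pairs, cooc, w = [], [], []
    for a, b, d in G.edges(data=True):
        lo, hi = (a, b) if a < b else (b, a)
        pairs.append((lo, hi))
        cooc.append(int(d["cooccurrence"]))
        w.append(float(d["deficit_weight"]))
    idx = np.argsort([p[0] * len(order) + p[1] for p in pairs])
    pairs = np.asarray(pairs)[idx]
    return LesionGraph(nodes, EdgeSet(pairs, "spatial_adjacency"),
                       np.asarray(cooc)[idx], np.asarray(w)[idx])


def write_edge_tsv(g: LesionGraph, path) -> None:
    pd.DataFrame({"source": g.edges.pairs[:, 0], "target": g.edges.pairs[:, 1],
                  "cooccurrence": g.cooccurrence,
                  "deficit_weight": g.deficit_weight}
                 ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
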