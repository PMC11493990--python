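"""Deterministic layouts and network serialization.

Two layouts are provided: a layered trans-omics view (horizontal bands in a
fixed layer order) and a pathway layout that places reaction and metabolite
nodes at user-supplied per-pathway coordinates in the style of the familiar
KEGG global-map drawings, with enzyme mRNAs offset from their reaction.
Serialization targets GraphML, node-link JSON and a flat TSV; each format
round-trips the node set, edge multiset and all attributes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import pandas as pd

from .graph_core import (
    Compartment,
    Direction,
    EdgeType,
    Layer,
    Molecule,
    RegulationEdge,
    Sign,
    TransOmicsNetwork,
)

__all__ = [
    "assign_layered_layout",
    "assign_pathway_layout",
    "export_graph",
    "import_graph",
    "EXPORT_FORMATS",
]

PathLike = Union[str, Path]

EXPORT_FORMATS = ("graphml", "node-link-json", "edge-tsv")

#: fixed top-to-bottom band order of the layered view
_BANDS = (
    (Layer.TF, Layer.MIRNA),
    (Layer.MRNA, Layer.PROTEIN),
    (Layer.REACTION, Layer.TRANSPORTER),
    (Layer.METABOLITE,),  # tissue
    (Layer.METABOLITE,),  # blood
)

_BAND_HEIGHT = 100.0
_CANVAS_WIDTH = 1000.0
_MRNA_OFFSET = (12.0, 24.0)

_LAYOUT_COLUMNS = [
    "node_id", "layer", "compartment", "band", "x", "y", "pathway_id", "placed_by",
]


def _band_index(mol: Molecule) -> int:
    if mol.layer in (Layer.TF, Layer.MIRNA):
        return 0
    if mol.layer in (Layer.MRNA, Layer.PROTEIN):
        return 1
    if mol.layer in (Layer.REACTION, Layer.TRANSPORTER):
        return 2
    # metabolites: tissue above blood
    return 3 if mol.compartment is not Compartment.BLOOD else 4


def assign_layered_layout(net: TransOmicsNetwork) -> pd.DataFrame:
    """Band-per-layer layout: nodes grouped into horizontal bands in fixed
    order (TF/miRNA, mRNA/protein, reaction/transporter, tissue
    metabolites, blood metabolites), ordered by id within a band and evenly
    spaced.  A pure function of the network."""
    rows = []
    by_band: dict[int, list[Molecule]] = {}
    for mol in net.nodes:
        by_band.setdefault(_band_index(mol), []).append(mol)
    for band, members in sorted(by_band.items()):
        members.sort(key=lambda m: (m.id, m.compartment.value))
        step = _CANVAS_WIDTH / (len(members) + 1)
        for i, mol in enumerate(members, start=1):
            rows.append(
                {
                    "node_id": mol.id,
                    "layer": mol.layer.value,
                    "compartment": mol.compartment.value,
                    "band": band,
                    "x": round(i * step, 6),
                    "y": band * _BAND_HEIGHT,
                    "pathway_id": mol.pathway_id or "",
                    "placed_by": "layered",
                }
            )
    return pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)


def assign_pathway_layout(net: TransOmicsNetwork, coords_path: PathLike) -> pd.DataFrame:
    """Place nodes at user-supplied pathway coordinates.

    ``coords_path`` is a TSV with columns (pathway_id, node_id, x, y).
    Reaction and metabolite nodes found there are placed exactly; mRNA
    nodes attached to a placed reaction sit at a fixed offset from it;
    everything else falls back to the layered layout and is flagged.
    """
    coords = pd.read_csv(coords_path, sep="\t", dtype=str, keep_default_na=False)
    required = ["pathway_id", "node_id", "x", "y"]
    missing = [c for c in required if c not in coords.columns]
    if missing:
        raise ValueError(f"pathway coordinate file missing column(s): {', '.join(missing)}")
    try:
        positions = {
            str(r["node_id"]): (float(r["x"]), float(r["y"]), str(r["pathway_id"]))
            for _, r in coords.iterrows()
        }
    except ValueError as exc:
        raise ValueError("pathway coordinate file has non-numeric x/y") from exc

    fallback = assign_layered_layout(net).set_index(["node_id", "layer", "compartment"])
    rows = []
    placed_reactions: dict = {}
    for mol in net.nodes:
        if mol.layer in (Layer.REACTION, Layer.METABOLITE, Layer.TRANSPORTER) and mol.id in positions:
            x, y, pw = positions[mol.id]
            placed_reactions[mol.key] = (x, y)
            rows.append(
                {
                    "node_id": mol.id,
                    "layer": mol.layer.value,
                    "compartment": mol.compartment.value,
                    "band": -1,
                    "x": x,
                    "y": y,
                    "pathway_id": pw or (mol.pathway_id or ""),
                    "placed_by": "pathway",
                }
            )
    for mol in net.nodes:
        if mol.key in placed_reactions:
            continue
        anchor = None
        if mol.layer in (Layer.MRNA, Layer.PROTEIN):
            for edge in net.edges_incident(mol.key):
                other = edge.target if edge.source == mol.key else edge.source
                if other in placed_reactions:
                    anchor = placed_reactions[other]
                    break
        if anchor is not None:
            rows.append(
                {
                    "node_id": mol.id,
                    "layer": mol.layer.value,
                    "compartment": mol.compartment.value,
                    "band": -1,
                    "x": anchor[0] + _MRNA_OFFSET[0],
                    "y": anchor[1] + _MRNA_OFFSET[1],
                    "pathway_id": mol.pathway_id or "",
                    "placed_by": "reaction_offset",
                }
            )
        else:
            fb = fallback.loc[(mol.id, mol.layer.value, mol.compartment.value)]
            rows.append(
                {
                    "node_id": mol.id,
                    "layer": mol.layer.value,
                    "compartment": mol.compartment.value,
                    "band": int(fb["band"]),
                    "x": float(fb["x"]),
                    "y": float(fb["y"]),
                    "pathway_id": mol.pathway_id or "",
                    "placed_by": "fallback",
                }
            )
    out = pd.DataFrame(rows, columns=_LAYOUT_COLUMNS)
    return out.sort_values(["node_id", "layer", "compartment"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _node_token(key) -> str:
    ident, layer, compartment = key
    return f"{ident}|{Layer(layer).value}|{Compartment(compartment).value}"


def _parse_token(token: str):
    ident, layer, compartment = token.rsplit("|", 2)
    return ident, Layer(layer), Compartment(compartment)


def _sorted_nodes(net: TransOmicsNetwork) -> list[Molecule]:
    return sorted(net.nodes, key=lambda m: (m.id, m.layer.value, m.compartment.value))


def _sorted_edges(net: TransOmicsNetwork) -> list[RegulationEdge]:
    return sorted(
        net.edges,
        key=lambda e: (
            _node_token(e.source),
            _node_token(e.target),
            e.edge_type.value,
        ),
    )


def export_graph(
    net: TransOmicsNetwork,
    path: PathLike,
    fmt: str = "graphml",
    layout: Optional[pd.DataFrame] = None,
) -> Path:
    """Serialize a network (plus optional layout coordinates) to
    ``graphml``, ``node-link-json`` or ``edge-tsv``.

    Outputs are deterministically ordered, so exporting the same network
    twice yields byte-identical files.  The TSV format is a single flat
    file with a ``record`` discriminator column ("node" / "edge") so that
    isolated nodes survive the round trip.
    """
    path = Path(path)
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    coords = {}
    if layout is not None:
        for _, r in layout.iterrows():
            coords[(str(r["node_id"]), str(r["layer"]), str(r["compartment"]))] = (
                float(r["x"]),
                float(r["y"]),
            )

    if fmt == "graphml":
        g = nx.MultiDiGraph()
        for mol in _sorted_nodes(net):
            attrs = {
                "layer": mol.layer.value,
                "compartment": mol.compartment.value,
                "direction": mol.direction.value,
                "pathway_id": mol.pathway_id or "",
            }
            xy = coords.get((mol.id, mol.layer.value, mol.compartment.value))
            if xy:
                attrs["x"], attrs["y"] = xy
            g.add_node(_node_token(mol.key), **attrs)
        for edge in _sorted_edges(net):
            g.add_edge(
                _node_token(edge.source),
                _node_token(edge.target),
                key=edge.edge_type.value,
                edge_type=edge.edge_type.value,
                sign=edge.sign.value,
                evidence=edge.evidence,
            )
        nx.write_graphml(g, path)
        return path

    if fmt == "node-link-json":
        doc = {
            "directed": True,
            "multigraph": True,
            "nodes": [
                {
                    "id": _node_token(mol.key),
                    "layer": mol.layer.value,
                    "compartment": mol.compartment.value,
                    "direction": mol.direction.value,
                    "pathway_id": mol.pathway_id or "",
                    **(
                        dict(zip(("x", "y"), coords[(mol.id, mol.layer.value, mol.compartment.value)]))
                        if (mol.id, mol.layer.value, mol.compartment.value) in coords
                        else {}
                    ),
                }
                for mol in _sorted_nodes(net)
            ],
            "links": [
                {
                    "source": _node_token(edge.source),
                    "target": _node_token(edge.target),
                    "edge_type": edge.edge_type.value,
                    "sign": edge.sign.value,
                    "evidence": edge.evidence,
                }
                for edge in _sorted_edges(net)
            ],
        }
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
        return path

    # edge-tsv
    rows = []
    for mol in _sorted_nodes(net):
        xy = coords.get((mol.id, mol.layer.value, mol.compartment.value), ("", ""))
        rows.append(
            {
                "record": "node",
                "source": _node_token(mol.key),
                "target": "",
                "edge_type": "",
                "sign": "",
                "evidence": "",
                "direction": mol.direction.value,
                "pathway_id": mol.pathway_id or "",
                "x": xy[0],
                "y": xy[1],
            }
        )
    for edge in _sorted_edges(net):
        rows.append(
            {
                "record": "edge",
                "source": _node_token(edge.source),
                "target": _node_token(edge.target),
                "edge_type": edge.edge_type.value,
                "sign": edge.sign.value,
                "evidence": edge.evidence,
                "direction": "",
                "pathway_id": "",
                "x": "",
                "y": "",
            }
        )
    columns = ["record", "source", "target", "edge_type", "sign", "evidence",
               "direction", "pathway_id", "x", "y"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path


def import_graph(path: PathLike, fmt: str = "graphml") -> TransOmicsNetwork:
    """Inverse of :func:`export_graph` (coordinates are not re-imported)."""
    path = Path(path)
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown export format {fmt!r}; choose from {EXPORT_FORMATS}")
    net = TransOmicsNetwork()

    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        for token, data in g.nodes(data=True):
            ident, layer, compartment = _parse_token(token)
            net.add_molecule(
                Molecule(
                    ident,
                    layer,
                    compartment,
                    Direction(data.get("direction", "unknown")),
                    pathway_id=data.get("pathway_id") or None,
                )
            )
        for u, v, data in g.edges(data=True):
            net.add_edge(
                RegulationEdge(
                    _parse_token(u),
                    _parse_token(v),
                    EdgeType(data["edge_type"]),
                    Sign(data.get("sign", "unsigned")),
                    data.get("evidence", ""),
                )
            )
        return net

    if fmt == "node-link-json":
        doc = json.loads(path.read_text())
        for node in doc["nodes"]:
            ident, layer, compartment = _parse_token(node["id"])
            net.add_molecule(
                Molecule(
                    ident,
                    layer,
                    compartment,
                    Direction(node.get("direction", "unknown")),
                    pathway_id=node.get("pathway_id") or None,
                )
            )
        for link in doc["links"]:
            net.add_edge(
                RegulationEdge(
                    _parse_token(link["source"]),
                    _parse_token(link["target"]),
                    EdgeType(link["edge_type"]),
                    Sign(link.get("sign", "unsigned")),
                    link.get("evidence", ""),
                )
            )
        return net

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for _, row in df.iterrows():
        if row["record"] == "node":
            ident, layer, compartment = _parse_token(row["source"])
            net.add_molecule(
                Molecule(
                    ident,
                    layer,
                    compartment,
                    Direction(row["direction"] or "unknown"),
                    pathway_id=row["pathway_id"] or None,
                )
            )
        else:
            net.add_edge(
                RegulationEdge(
                    _parse_token(row["source"]),
                    _parse_token(row["target"]),
                    EdgeType(row["edge_type"]),
                    Sign(row["sign"] or "unsigned"),
                    row["evidence"],
                )
            )
    return net
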