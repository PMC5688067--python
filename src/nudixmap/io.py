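"""Plain-text readers and writers for every pipeline artifact.

Viability panels and phase fractions travel as TSV, fusion collections as a
JSON manifest plus one TSV per relation, trees as newick, and ground truth as
JSON — all deterministic round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epistasis import CellCycleTable, KnockdownPanel, canonical_pair
from .fusion import FusionGraph, Relation
from .simulate import TruthSet

__all__ = [
    "write_panel",
    "read_panel",
    "write_cellcycle",
    "read_cellcycle",
    "write_fusion",
    "read_fusion",
    "write_truth",
    "read_truth",
]


def write_panel(panel: KnockdownPanel, path: str | Path) -> None:
    """Viability TSV: one row per knockdown (gene_b empty for singles/control)."""
    rows = []

    def row(a, b, vec):
        return {"knockdown": f"{a}+{b}" if b else a, "gene_a": a, "gene_b": b,
                **{f"replicate_{i + 1}": v for i, v in enumerate(vec)}}

    if panel.control_viability is not None:
        rows.append(row(panel.control_label, "", panel.control_viability))
    for g in sorted(panel.single_viability):
        rows.append(row(g, "", panel.single_viability[g]))
    for (a, b) in sorted(panel.double_viability):
        rows.append(row(a, b, panel.double_viability[(a, b)]))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel(path: str | Path, control_label: str = "control", cell_line: str = "") -> KnockdownPanel:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    rep_cols = [c for c in df.columns if c.startswith("replicate_")]
    df["gene_b"] = df["gene_b"].fillna("")
    singles, doubles, control = {}, {}, None
    for _, r in df.iterrows():
        vec = r[rep_cols].to_numpy(dtype=float)
        if r["gene_a"] == control_label and not r["gene_b"]:
            control = vec
        elif not r["gene_b"]:
            singles[r["gene_a"]] = vec
        else:
            doubles[canonical_pair(r["gene_a"], r["gene_b"])] = vec
    return KnockdownPanel(
        genes=sorted(singles),
        single_viability=singles,
        double_viability=doubles,
        control_label=control_label,
        cell_line=cell_line,
        control_viability=control,
    )


def write_cellcycle(table: CellCycleTable, path: str | Path) -> None:
    """Phase-fraction TSV: knockdown id x phase."""
    rows = []
    for key in sorted(table.fractions, key=lambda k: (isinstance(k, tuple), k)):
        kid = "+".join(key) if isinstance(key, tuple) else key
        rows.append({"knockdown": kid, **dict(zip(table.phases, table.fractions[key]))})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_cellcycle(path: str | Path, control_label: str = "control") -> CellCycleTable:
    df = pd.read_csv(path, sep="\t")
    phases = [c for c in df.columns if c != "knockdown"]
    fractions = {}
    for _, r in df.iterrows():
        kid = r["knockdown"]
        key = tuple(kid.split("+")) if "+" in kid else kid
        fractions[key] = r[phases].to_numpy(dtype=float)
    return CellCycleTable(phases=phases, fractions=fractions, control_label=control_label)


def write_fusion(graph: FusionGraph, directory: str | Path) -> None:
    """JSON manifest (types, objects, relation files) + one TSV per relation."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"object_types": graph.object_types, "relations": []}
    for rel in graph.relations:
        fname = f"{rel.name}.tsv"
        pd.DataFrame(
            rel.matrix,
            index=graph.object_types[rel.type_i],
            columns=graph.object_types[rel.type_j],
        ).to_csv(directory / fname, sep="\t", float_format="%.10g")
        manifest["relations"].append({"name": rel.name, "type_i": rel.type_i, "type_j": rel.type_j, "file": fname})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def read_fusion(directory: str | Path) -> FusionGraph:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    relations = []
    for spec in manifest["relations"]:
        mat = pd.read_csv(directory / spec["file"], sep="\t", index_col=0)
        relations.append(Relation(name=spec["name"], type_i=spec["type_i"], type_j=spec["type_j"], matrix=mat.to_numpy()))
    return FusionGraph(object_types=manifest["object_types"], relations=relations)


def write_truth(truth: TruthSet, path: str | Path) -> None:
    payload = {
        "planted_interactions": [
            {"pair": list(p), "class": cls, "effect_size": eps} for p, cls, eps in truth.planted_interactions
        ],
        "planted_blocks": truth.planted_blocks,
        "planted_de_genes": [{"gene": g, "log2fc": fc} for g, fc in truth.planted_de_genes],
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    return TruthSet(
        planted_interactions=[
            (tuple(e["pair"]), e["class"], float(e["effect_size"])) for e in payload["planted_interactions"]
        ],
        planted_blocks={t: {o: int(b) for o, b in m.items()} for t, m in payload.get("planted_blocks", {}).items()},
        planted_de_genes=[(e["gene"], float(e["log2fc"])) for e in payload.get("planted_de_genes", [])],
        seed=int(payload.get("seed", 0)),
    )
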