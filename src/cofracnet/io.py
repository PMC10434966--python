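"""Readers and writers for the plain-text formats of the pipeline.

All inputs and outputs are UTF-8 TSV with '.' decimal separator:

* profile matrix — header row of fraction labels, first column ``protein``;
  empty numeric cells are read as 0 abundance;
* interaction-score matrix — square TSV with identical row/column identifier
  sets (columns are reordered to row order when permuted);
* orthology — headerless two-column TSV of identifier pairs;
* reference complexes — ``name<TAB>member;member;...`` or GMT
  (``name<TAB>description<TAB>member<TAB>member...``);
* sample sheet — columns dataset_id, collection_id, species_id, path, type
  with type in {profile, scores}.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    Collection,
    HyperNetwork,
    InteractionMatrix,
    OrthologyMap,
    ProfileDataset,
    ReferenceComplexSet,
    SuperCluster,
    ValidationError,
)

__all__ = [
    "load_profile_dataset",
    "load_score_matrix",
    "load_orthology",
    "load_reference_complexes",
    "load_sample_sheet",
    "write_profile_dataset",
    "write_orthology",
    "write_cluster_tables",
]


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0].lower() != "protein":
        raise ValidationError(
            f"{path}: first column header must be 'protein', got "
            f"{df.columns[0]!r}"
        )
    return df


def _to_float(cell: str, path, row: str, col: str) -> float:
    if cell.strip() == "":
        return 0.0
    try:
        return float(cell)
    except ValueError:
        raise ValidationError(
            f"{path}: malformed numeric cell {cell!r} at row {row!r}, "
            f"column {col!r}"
        ) from None


def load_profile_dataset(path, dataset_id: str, collection_id: str,
                         species_id: str) -> ProfileDataset:
    """Read a protein x fraction abundance TSV into a :class:`ProfileDataset`."""
    df = _read_table(path)
    proteins = df.iloc[:, 0].tolist()
    cols = list(df.columns[1:])
    values = np.array(
        [[_to_float(df.iat[i, j + 1], path, proteins[i], cols[j])
          for j in range(len(cols))]
         for i in range(len(proteins))],
        dtype=float,
    ).reshape(len(proteins), len(cols))
    return ProfileDataset(dataset_id, collection_id, species_id,
                          proteins, values, fractions=cols)


def load_score_matrix(path, dataset_id: str, collection_id: str,
                      species_id: str) -> InteractionMatrix:
    """Read a square symmetric interaction-score TSV.

    Row and column identifier sets must be equal; permuted columns are
    reordered to row order before the symmetry check.
    """
    df = _read_table(path)
    proteins = df.iloc[:, 0].tolist()
    cols = list(df.columns[1:])
    if set(cols) != set(proteins) or len(cols) != len(proteins):
        raise ValidationError(
            f"{path}: row and column identifier sets differ "
            f"({len(proteins)} rows vs {len(cols)} columns)"
        )
    body = df.set_index(df.columns[0]).iloc[:, :]
    body = body.loc[proteins, proteins]  # reorder columns to row order
    values = np.array(
        [[_to_float(body.iat[i, j], path, proteins[i], proteins[j])
          for j in range(len(proteins))]
         for i in range(len(proteins))],
        dtype=float,
    )
    np.fill_diagonal(values, np.nan)  # diagonal is never consulted
    return InteractionMatrix(dataset_id, collection_id, species_id,
                             proteins, values)


def load_orthology(path, species_a: str, species_b: str) -> OrthologyMap:
    """Read a headerless two-column TSV of one-to-one orthologous pairs."""
    pairs: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            pairs.add((parts[0], parts[1]))
    return OrthologyMap((species_a, species_b), pairs)


def load_reference_complexes(path) -> ReferenceComplexSet:
    """Read reference complexes from 2-column TSV or GMT lines."""
    complexes: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                members = [m for m in parts[1].split(";") if m.strip()]
            elif len(parts) >= 3:
                # GMT: name, description, then one member per column
                members = [m for m in parts[2:] if m.strip()]
            else:
                raise ValidationError(
                    f"{path}:{lineno}: expected >=2 tab-separated columns"
                )
            name = parts[0]
            if name in complexes:
                raise ValidationError(
                    f"{path}:{lineno}: duplicate complex name {name!r}"
                )
            if not members:
                warnings.warn(
                    f"{path}:{lineno}: complex {name!r} has no members; dropped"
                )
                continue
            complexes[name] = frozenset(members)
    return ReferenceComplexSet(complexes)


def load_sample_sheet(path):
    """Read the sample sheet; returns (records, collections).

    ``records`` is a list of dicts with keys dataset_id, collection_id,
    species_id, path, type; ``collections`` maps collection_id to
    :class:`Collection`. Relative paths are resolved against the sheet's
    directory.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["dataset_id", "collection_id", "species_id", "path", "type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: sample sheet missing columns {missing}")
    base = Path(path).parent
    records = []
    for _, row in df.iterrows():
        if row["type"] not in ("profile", "scores"):
            raise ValidationError(
                f"{path}: dataset {row['dataset_id']}: type must be "
                f"'profile' or 'scores', got {row['type']!r}"
            )
        p = Path(row["path"])
        records.append({
            "dataset_id": row["dataset_id"],
            "collection_id": row["collection_id"],
            "species_id": row["species_id"],
            "path": p if p.is_absolute() else base / p,
            "type": row["type"],
        })
    ids = [r["dataset_id"] for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate dataset_id in sample sheet")
    collections: dict[str, Collection] = {}
    for cid in dict.fromkeys(r["collection_id"] for r in records):
        members = [r for r in records if r["collection_id"] == cid]
        species = {r["species_id"] for r in members}
        if len(species) != 1:
            raise ValidationError(
                f"{path}: collection {cid} spans multiple species {species}"
            )
        collections[cid] = Collection(cid, species.pop(),
                                      [r["dataset_id"] for r in members])
    return records, collections


def write_profile_dataset(ds: ProfileDataset, path) -> None:
    cols = ds.fractions or [f"F{i + 1}" for i in range(ds.n_fractions)]
    df = pd.DataFrame(ds.abundances, columns=cols)
    df.insert(0, "protein", ds.proteins)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def write_orthology(om: OrthologyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(om.pairs):
            fh.write(f"{a}\t{b}\n")


def _node_id(element) -> str:
    return f"{element[0]}::{element[1]}"


def write_cluster_tables(superclusters: list[SuperCluster],
                         network: HyperNetwork | None,
                         out_dir) -> dict[str, str]:
    """Write the member table, cluster summary and hypernetwork edge list.

    Row order is deterministic: cluster id, then collection, then FrC
    descending, then identifier. Returns a mapping of table name to path.
    """
    out = Path(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "members": str(out / "cluster_members.tsv"),
        "summary": str(out / "cluster_summary.tsv"),
        "edges": str(out / "hypernetwork_edges.tsv"),
    }

    member_rows = []
    summary_rows = []
    for sc in sorted(superclusters, key=lambda s: s.cluster_id):
        for cid in sorted(sc.subclusters):
            sub = sc.subclusters[cid]
            for prot in sorted(sub.members,
                               key=lambda p: (-sub.members[p], p)):
                member_rows.append({
                    "supercluster_id": sc.cluster_id,
                    "collection_id": cid,
                    "protein": prot,
                    "frc": round(sub.members[prot], 6),
                    "best_guess": int(prot in sub.best_guess),
                })
        summary_rows.append({
            "supercluster_id": sc.cluster_id,
            "n_subclusters": len(sc.subclusters),
            "actual_matches": sc.actual_matches,
            "possible_matches": sc.possible_matches,
            "coherence": round(sc.coherence, 6),
            "passed_filter": int(sc.passed_filter),
            "annotation": sc.annotation or "",
        })
    pd.DataFrame(
        member_rows,
        columns=["supercluster_id", "collection_id", "protein", "frc",
                 "best_guess"],
    ).to_csv(paths["members"], sep="\t", index=False)
    pd.DataFrame(
        summary_rows,
        columns=["supercluster_id", "n_subclusters", "actual_matches",
                 "possible_matches", "coherence", "passed_filter",
                 "annotation"],
    ).to_csv(paths["summary"], sep="\t", index=False)

    edge_rows = []
    if network is not None:
        for ea, eb, w in network.edges:
            edge_rows.append({"node_a": _node_id(ea), "node_b": _node_id(eb),
                              "weight": round(w, 6)})
    pd.DataFrame(
        edge_rows, columns=["node_a", "node_b", "weight"]
    ).to_csv(paths["edges"], sep="\t", index=False)
    return paths
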