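"""Readers and writers for the package's TSV/CSV formats.

Feature matrices: first column = drug ID, header row = feature IDs, cells
0/1.  Pair lists: two drug-ID columns plus an optional label column.  CYP
annotations: pair columns plus a semicolon-separated isoform list.
Delimiter is inferred from the extension (``.csv`` -> comma, else tab).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cyp_annotation import validate_isoforms
from .errors import (
    DuplicateDrugError,
    LabelConflictError,
    NonBinaryValueError,
    SelfPairError,
)
from .pul_profiling import NegativeSet, NodeProfile, profiles_to_frame
from .similarity import (
    POSITIVE,
    UNLABELED,
    DrugFeatureMatrix,
    PairFeatureTable,
    PairKey,
    PairIndex,
    pair_key,
)

logger = logging.getLogger("gsompul")


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_feature_matrix(path, source_name: str | None = None) -> DrugFeatureMatrix:
    """Read a binary drug x feature table; errors name offending cells."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=str)
    drug_ids = [str(d) for d in df.index]
    feature_ids = [str(c) for c in df.columns]
    if len(set(drug_ids)) != len(drug_ids):
        raise DuplicateDrugError(f"duplicate drug ids in {path}")
    values = np.zeros(df.shape, dtype=np.uint8)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell not in ("0", "1"):
                raise NonBinaryValueError(
                    f"{path}: non-binary cell {cell!r} at drug "
                    f"{drug_ids[i]!r}, feature {feature_ids[j]!r}"
                )
            values[i, j] = int(cell)
    return DrugFeatureMatrix(
        source_name=source_name or path.stem,
        drug_ids=tuple(drug_ids),
        feature_ids=tuple(feature_ids),
        values=values,
    )


def write_feature_matrix(matrix: DrugFeatureMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.values, index=list(matrix.drug_ids), columns=list(matrix.feature_ids)
    )
    df.index.name = "drug_id"
    df.to_csv(path, sep=_sep(path))


def read_pair_labels(
    path, known_drugs: Iterable[str] | None = None, default_label: str = POSITIVE
) -> dict[PairKey, str]:
    """Read a two-column pair list (optional third label column).

    Pair keys are canonicalized; duplicate rows with the same label warn,
    conflicting labels raise.  Pairs naming a drug outside ``known_drugs``
    (when given) are dropped with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    known = set(known_drugs) if known_drugs is not None else None
    out: dict[PairKey, str] = {}
    for row in df.itertuples(index=False):
        a, b = str(row[0]).strip(), str(row[1]).strip()
        if a == b:
            raise SelfPairError(f"{path}: self-pair {a!r}")
        label = str(row[2]).strip() if df.shape[1] > 2 and not pd.isna(row[2]) else default_label
        if label not in (POSITIVE, UNLABELED):
            raise ValueError(f"{path}: unknown label {label!r}")
        if known is not None and (a not in known or b not in known):
            logger.warning("dropping pair (%s, %s): drug not in loaded matrices", a, b)
            continue
        key = pair_key(a, b)
        if key in out:
            if out[key] != label:
                raise LabelConflictError(f"{path}: conflicting labels for pair {key}")
            logger.warning("duplicate pair row for %s", key)
        out[key] = label
    return out


def write_pairs(pairs: Iterable[PairKey], path, extra: Mapping[PairKey, str] | None = None) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(pairs):
            if extra is not None:
                fh.write(f"{a}\t{b}\t{extra[(a, b)]}\n")
            else:
                fh.write(f"{a}\t{b}\n")


def read_cyp_annotations(path, allow_extra_isoforms: bool = False) -> dict[PairKey, frozenset[str]]:
    """Pair -> isoform set from a TSV with a semicolon-separated isoform column."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected drug_a, drug_b, isoform columns")
    out: dict[PairKey, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        key = pair_key(str(row[0]).strip(), str(row[1]).strip())
        cell = "" if pd.isna(row[2]) else str(row[2]).strip()
        names = [n for n in cell.split(";") if n]
        out[key] = validate_isoforms(names, allow_extra=allow_extra_isoforms)
    return out


def write_cyp_annotations(annotations: Mapping[PairKey, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        for (a, b), iso in sorted(annotations.items()):
            fh.write(f"{a}\t{b}\t{';'.join(sorted(iso))}\n")


def write_pair_feature_table(table: PairFeatureTable, path, metadata_path=None) -> None:
    """Pair table as TSV (canonical key columns first) + JSON sidecar metadata."""
    df = pd.DataFrame(table.vectors, columns=[f"f{j}" for j in range(table.n_features)])
    df.insert(0, "drug_a", [p[0] for p in table.pairs])
    df.insert(1, "drug_b", [p[1] for p in table.pairs])
    df.insert(2, "label", list(table.labels))
    df.to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        meta = {
            "representation": table.representation,
            "source_names": list(table.source_names),
            "source_dims": list(table.source_dims),
            "n_pairs": len(table.pairs),
            "n_features": table.n_features,
        }
        with open(metadata_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_pair_feature_table(path, metadata_path=None) -> PairFeatureTable:
    df = pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})
    pairs = PairIndex(tuple(zip(df["drug_a"], df["drug_b"])))
    labels = tuple(df["label"])
    vectors = df.drop(columns=["drug_a", "drug_b", "label"]).to_numpy(dtype=float)
    meta = {}
    if metadata_path is not None and Path(metadata_path).exists():
        with open(metadata_path) as fh:
            meta = json.load(fh)
    return PairFeatureTable(
        representation=meta.get("representation", "SFR1"),
        pairs=pairs,
        vectors=vectors,
        labels=labels,
        source_names=tuple(meta.get("source_names", ())),
        source_dims=tuple(meta.get("source_dims", ())),
    )


def write_negative_set(negatives: NegativeSet, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(negatives.pairs):
            fh.write(f"{a}\t{b}\t{negatives.provenance}\n")


def read_negative_set(path) -> NegativeSet:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    pairs = frozenset(pair_key(str(r[0]), str(r[1])) for r in df.itertuples(index=False))
    provenance = str(df.iloc[0, 2]) if df.shape[1] > 2 and len(df) else "unknown"
    return NegativeSet(pairs=pairs, provenance=provenance)


def write_node_profiles(profiles: Sequence[NodeProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)
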