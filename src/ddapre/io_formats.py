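"""Readers/writers for on-disk artifacts and the pair-space enumerator.

File dialect: UTF-8 CSV/TSV with a header row; the delimiter is inferred
from the file extension (``.tsv`` -> tab, anything else -> comma).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

_TREE_NUMBER_RE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")


class FormatError(ValueError):
    """Malformed file: missing columns, ragged rows, bad dialect."""


class ValidationError(ValueError):
    """Well-formed file with invalid content: duplicates, dangling ids."""


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by an opaque key with a SMILES structure string."""

    drug_id: str
    smiles: str


@dataclass(frozen=True)
class DiseaseRecord:
    """A disease with one or more MeSH TreeNumber codes.

    TreeNumbers are dotted hierarchical codes (e.g. ``C10.228.140``);
    truncating trailing segments yields ancestor concepts.
    """

    disease_id: str
    tree_numbers: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tree_numbers:
            raise ValidationError(
                f"disease {self.disease_id!r} has no tree numbers"
            )
        for code in self.tree_numbers:
            if not _TREE_NUMBER_RE.match(code):
                raise ValidationError(
                    f"disease {self.disease_id!r}: malformed tree number {code!r}"
                )


@dataclass
class AssociationTable:
    """(drug_id, disease_id, label) triples; the sample universe.

    ``provenance`` records whether the rows were observed (a curated
    positive list) or enumerated (the full drug x disease pair space).
    """

    drug_ids: list[str]
    disease_ids: list[str]
    labels: np.ndarray
    provenance: str = "observed"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.drug_ids) == len(self.disease_ids) == len(self.labels)):
            raise ValidationError("association table columns have unequal lengths")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")
        pairs = set(zip(self.drug_ids, self.disease_ids))
        if len(pairs) != len(self.drug_ids):
            raise ValidationError("duplicate (drug_id, disease_id) pairs")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.drug_ids, self.disease_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": self.drug_ids,
                "disease_id": self.disease_ids,
                "label": self.labels,
            }
        )


@dataclass
class EmbeddingTable:
    """Mapping from entity id to a fixed-length real vector."""

    vectors: dict[str, np.ndarray]
    dimension: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.dimension < 0:
            if not self.vectors:
                raise ValidationError("empty embedding table needs explicit dimension")
            self.dimension = len(next(iter(self.vectors.values())))
        clean = {}
        for key, vec in self.vectors.items():
            arr = np.asarray(vec, dtype=np.float64)
            if arr.shape != (self.dimension,):
                raise ValidationError(
                    f"id {key!r}: vector length {arr.shape} != declared {self.dimension}"
                )
            if not np.isfinite(arr).all():
                raise ValidationError(f"id {key!r}: non-finite values")
            clean[key] = arr
        self.vectors = clean

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.vectors[key]

    def __contains__(self, key: str) -> bool:
        return key in self.vectors

    def ids(self) -> list[str]:
        return list(self.vectors)

    def matrix(self, order: list[str] | None = None) -> np.ndarray:
        keys = order if order is not None else self.ids()
        return np.stack([self.vectors[k] for k in keys])


def _delimiter(path: str | Path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_frame(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_delimiter(path), dtype=str)
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return frame


def read_drug_table(
    path: str | Path, invalid_smiles: str = "reject"
) -> list[DrugRecord]:
    """Read a drug table (columns ``drug_id, smiles``).

    ``invalid_smiles`` controls what happens to rows whose SMILES does not
    parse: ``reject`` raises with a per-row report, ``drop`` removes them
    (reported via the returned records simply omitting them), ``keep-raw``
    keeps the record with the unparsed string.
    """
    if invalid_smiles not in ("reject", "drop", "keep-raw"):
        raise ValueError(f"unknown invalid-SMILES policy {invalid_smiles!r}")
    frame = _read_frame(path, ["drug_id", "smiles"])
    if frame["drug_id"].duplicated().any():
        dupes = frame["drug_id"][frame["drug_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate drug ids: {dupes}")
    records, bad = [], []
    for row in frame.itertuples(index=True):
        if not row.drug_id:
            raise ValidationError(f"row {row.Index}: empty drug_id")
        mol = Chem.MolFromSmiles(row.smiles) if isinstance(row.smiles, str) else None
        if mol is None and invalid_smiles != "keep-raw":
            bad.append((row.Index, row.drug_id, row.smiles))
            continue
        records.append(DrugRecord(row.drug_id, row.smiles))
    if bad and invalid_smiles == "reject":
        report = "; ".join(f"row {i} ({d!r}): {s!r}" for i, d, s in bad)
        raise ValidationError(f"unparseable SMILES: {report}")
    return records


def read_disease_table(path: str | Path) -> list[DiseaseRecord]:
    """Read a disease table (columns ``disease_id, tree_numbers``).

    Multiple TreeNumbers are ``|``-separated within the cell.
    """
    frame = _read_frame(path, ["disease_id", "tree_numbers"])
    if frame["disease_id"].duplicated().any():
        dupes = frame["disease_id"][frame["disease_id"].duplicated()].tolist()
        raise ValidationError(f"duplicate disease ids: {dupes}")
    records = []
    for row in frame.itertuples(index=True):
        codes = tuple(c for c in str(row.tree_numbers).split("|") if c)
        records.append(DiseaseRecord(row.disease_id, codes))
    return records


def read_association_table(
    path: str | Path, provenance: str = "observed"
) -> AssociationTable:
    """Read an association list (columns ``drug_id, disease_id, label``)."""
    frame = _read_frame(path, ["drug_id", "disease_id", "label"])
    return AssociationTable(
        frame["drug_id"].tolist(),
        frame["disease_id"].tolist(),
        frame["label"].astype(int).to_numpy(),
        provenance=provenance,
    )


def enumerate_pair_space(
    drugs: list[DrugRecord],
    diseases: list[DiseaseRecord],
    positives: AssociationTable,
) -> AssociationTable:
    """Enumerate the full combinatorial drug x disease pair space.

    Every pair appearing in ``positives`` (all of whose rows must carry
    label 1 and reference known ids) is labeled 1; every other pair is
    labeled 0, forming the unverified negative pool. Output ordering is
    drug-major then disease, both in input order.
    """
    drug_ids = [d.drug_id for d in drugs]
    disease_ids = [d.disease_id for d in diseases]
    known_drugs, known_diseases = set(drug_ids), set(disease_ids)
    pos_pairs = set()
    for dr, di, lab in zip(
        positives.drug_ids, positives.disease_ids, positives.labels
    ):
        if dr not in known_drugs or di not in known_diseases:
            raise ValidationError(f"positive pair ({dr!r}, {di!r}) references unknown id")
        if lab != 1:
            raise ValidationError("positives table must carry label 1 on every row")
        pos_pairs.add((dr, di))
    out_drugs, out_diseases, out_labels = [], [], []
    for dr in drug_ids:
        for di in disease_ids:
            out_drugs.append(dr)
            out_diseases.append(di)
            out_labels.append(1 if (dr, di) in pos_pairs else 0)
    return AssociationTable(
        out_drugs, out_diseases, np.array(out_labels), provenance="enumerated"
    )


def write_embedding_table(table: EmbeddingTable, path: str | Path) -> None:
    """Write an embedding table as TSV: id column + ``dimension`` numeric columns."""
    path = Path(path)
    cols = [f"dim_{i}" for i in range(table.dimension)]
    frame = pd.DataFrame(
        [table.vectors[k] for k in table.ids()], columns=cols, index=table.ids()
    )
    frame.index.name = "id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_embedding_table(path: str | Path) -> EmbeddingTable:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="id")
    try:
        values = frame.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric embedding values") from exc
    if values.ndim != 2:
        raise FormatError(f"{path}: ragged rows")
    return EmbeddingTable(
        {str(idx): values[i] for i, idx in enumerate(frame.index)},
        dimension=values.shape[1],
    )


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep=_delimiter(path), index=False)
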