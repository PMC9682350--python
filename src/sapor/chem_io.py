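"""Reading, standardizing and deduplicating SMILES-labelled compounds.

Input tables pair a SMILES string with a binary taste label (bitter or
sweet).  Before any descriptor is computed the structures are standardized
(sanitization, salt/solvent stripping to the parent molecule, canonical
SMILES) so that two spellings of the same compound collapse to one record,
and duplicate structures with conflicting taste labels are removed outright:
a structure that is both "bitter" and "sweet" in the sources is ambiguous
training signal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

__all__ = [
    "LABEL_ENCODING",
    "CompoundRecord",
    "CuratedDataset",
    "StandardizationResult",
    "read_compound_table",
    "standardize_compound",
    "standardize_dataset",
    "deduplicate_compounds",
    "curate",
]

#: Fixed label encoding: bitter -> 0, sweet -> 1.
LABEL_ENCODING = {"bitter": 0, "sweet": 1}

RDLogger.DisableLog("rdApp.*")


@dataclass(frozen=True)
class CompoundRecord:
    """A single compound: id, SMILES, taste label and provenance tag."""

    compound_id: str
    smiles: str
    taste: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.taste not in LABEL_ENCODING:
            raise ValueError(
                f"record {self.compound_id!r}: taste {self.taste!r} is not one of "
                f"{sorted(LABEL_ENCODING)}"
            )

    @property
    def label(self) -> int:
        return LABEL_ENCODING[self.taste]


@dataclass
class CuratedDataset:
    """Ordered collection of compound records with the fixed label encoding."""

    records: list[CompoundRecord] = field(default_factory=list)
    label_encoding: dict[str, int] = field(default_factory=lambda: dict(LABEL_ENCODING))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles_standardized", "taste", "label"])
            for r in self.records:
                w.writerow([r.compound_id, r.smiles, r.taste, r.label])


@dataclass(frozen=True)
class StandardizationResult:
    """Outcome of standardizing one SMILES: a canonical parent or a rejection."""

    ok: bool
    smiles: str | None = None
    reason: str | None = None


def read_compound_table(
    path: str | Path,
    fmt: str | None = None,
    smiles_column: str = "smiles",
    taste_column: str = "taste",
    id_column: str | None = None,
) -> CuratedDataset:
    """Read a compound table from CSV or whitespace-delimited ``.smi``.

    Records are returned in file order and are *not* yet standardized or
    deduplicated.  Unknown taste labels are rejected with the offending row
    number.  Missing compound ids are generated as zero-padded ordinals.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt is None:
        fmt = "smi" if path.suffix.lower() == ".smi" else "csv"
    if fmt not in ("csv", "smi"):
        raise ValueError(f"unsupported format {fmt!r}")

    records: list[CompoundRecord] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            for col in (smiles_column, taste_column):
                if col not in header:
                    raise KeyError(f"column {col!r} not found in {path} (header: {header})")
            if id_column is not None and id_column not in header:
                raise KeyError(f"id column {id_column!r} not found in {path}")
            for i, row in enumerate(reader):
                taste = row[taste_column].strip().lower()
                if taste not in LABEL_ENCODING:
                    raise ValueError(
                        f"{path}, data row {i + 1}: taste {taste!r} is not one of "
                        f"{sorted(LABEL_ENCODING)}"
                    )
                cid = row[id_column].strip() if id_column else f"{i:06d}"
                records.append(
                    CompoundRecord(cid, row[smiles_column].strip(), taste, source=str(path.name))
                )
    else:
        with open(path) as fh:
            i = 0
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) < 2:
                    raise ValueError(f"{path}, line {i + 1}: expected 'SMILES label [id]'")
                taste = parts[1].strip().lower()
                if taste not in LABEL_ENCODING:
                    raise ValueError(
                        f"{path}, line {i + 1}: taste {taste!r} is not one of "
                        f"{sorted(LABEL_ENCODING)}"
                    )
                cid = parts[2] if len(parts) > 2 else f"{i:06d}"
                records.append(CompoundRecord(cid, parts[0], taste, source=str(path.name)))
                i += 1
    return CuratedDataset(records=records)


def standardize_compound(smiles: str) -> StandardizationResult:
    """Standardize one SMILES to its canonical parent-molecule form.

    Sanitizes the structure, strips salts/solvents down to the parent
    fragment and emits a canonical SMILES, so that any two spellings of the
    same structure map to identical output.  Unparseable input yields a
    rejection (not an exception): the caller logs and drops it.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return StandardizationResult(False, reason=f"unparseable SMILES: {smiles!r}")
    try:
        mol = rdMolStandardize.Cleanup(mol)
        # parent = largest organic fragment, neutralized (salts/solvents stripped)
        mol = rdMolStandardize.ChargeParent(mol)
        out = Chem.MolToSmiles(mol)
    except Exception as exc:  # pragma: no cover - backend-internal failures
        return StandardizationResult(False, reason=f"standardization failed: {exc}")
    if not out:
        return StandardizationResult(False, reason=f"empty parent for {smiles!r}")
    return StandardizationResult(True, smiles=out)


def standardize_dataset(dataset: CuratedDataset) -> tuple[CuratedDataset, list[dict]]:
    """Standardize every record; rejected SMILES are dropped and reported."""
    kept: list[CompoundRecord] = []
    rejected: list[dict] = []
    for r in dataset.records:
        res = standardize_compound(r.smiles)
        if res.ok:
            kept.append(CompoundRecord(r.compound_id, res.smiles, r.taste, r.source))
        else:
            rejected.append({"compound_id": r.compound_id, "smiles": r.smiles, "reason": res.reason})
    return CuratedDataset(records=kept), rejected


def deduplicate_compounds(dataset: CuratedDataset) -> tuple[CuratedDataset, dict]:
    """Collapse duplicate structures; drop label-conflicting groups entirely.

    Records are grouped by their (already standardized) SMILES.  A group
    whose members all carry the same taste keeps its first occurrence; a
    group with conflicting tastes is removed completely.  The report counts
    records kept, collapsed and removed.
    """
    groups: dict[str, list[CompoundRecord]] = {}
    order: list[str] = []
    for r in dataset.records:
        if r.smiles not in groups:
            groups[r.smiles] = []
            order.append(r.smiles)
        groups[r.smiles].append(r)

    kept: list[CompoundRecord] = []
    n_collapsed = 0
    removed_conflicting: list[str] = []
    for smi in order:
        members = groups[smi]
        tastes = {m.taste for m in members}
        if len(tastes) == 1:
            kept.append(members[0])
            n_collapsed += len(members) - 1
        else:
            removed_conflicting.extend(m.compound_id for m in members)
    report = {
        "n_in": len(dataset.records),
        "n_kept": len(kept),
        "n_collapsed_duplicates": n_collapsed,
        "n_removed_conflicting": len(removed_conflicting),
        "removed_conflicting_ids": removed_conflicting,
    }
    return CuratedDataset(records=kept), report


def curate(dataset: CuratedDataset) -> tuple[CuratedDataset, dict]:
    """Standardize then deduplicate; returns the curated dataset and a report."""
    std, rejected = standardize_dataset(dataset)
    dedup, report = deduplicate_compounds(std)
    report = {"n_rejected_smiles": len(rejected), "rejected": rejected, **report}
    return dedup, report


def write_curation_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def from_smiles_labels(
    smiles: Sequence[str], tastes: Iterable[str], source: str = "memory"
) -> CuratedDataset:
    """Build an (uncurated) dataset from parallel SMILES / taste sequences."""
    records = [
        CompoundRecord(f"{i:06d}", s, t, source) for i, (s, t) in enumerate(zip(smiles, tastes))
    ]
    return CuratedDataset(records=records)
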