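"""2D molecular descriptor computation and feature-table assembly.

Descriptors are purely topological/compositional (no conformer generation):
RDKit's 2D descriptor collection (~210 names) and, when the openbabel
Python bindings are importable, pybel's 25 descriptors.  A descriptor the
backend cannot compute for a given structure is recorded as missing — never
as zero — because such failures are caused by the structure itself
(missing-not-at-random), e.g. a distance-edge descriptor undefined when the
relevant atom pair is absent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors

from .chem_io import CuratedDataset

__all__ = ["FeatureTable", "available_backends", "compute_descriptor_vector", "build_feature_table"]

try:  # optional second backend; 25 whole-molecule descriptors
    from openbabel import pybel as _pybel
except Exception:  # pragma: no cover - depends on install
    _pybel = None


@dataclass
class FeatureTable:
    """Compounds x descriptors matrix with explicit missing values.

    ``X`` is a float DataFrame indexed by compound id (NaN marks a missing
    descriptor value); ``y`` is the aligned 0/1 taste target (bitter=0,
    sweet=1); ``source_tags`` maps each column to the backend it came from.
    """

    X: pd.DataFrame
    y: pd.Series
    source_tags: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("target length must equal number of rows")
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-column fraction of missing values, in [0, 1]."""
        if self.n_rows == 0:
            return pd.Series(0.0, index=self.X.columns)
        return self.X.isna().mean()

    def column_meta(self) -> pd.DataFrame:
        mf = self.missing_fraction()
        return pd.DataFrame(
            {
                "source_tag": [self.source_tags.get(c, "") for c in self.X.columns],
                "missing_fraction": mf.values,
            },
            index=self.X.columns,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.X.copy(), self.y.copy(), dict(self.source_tags))

    def subset_columns(self, columns: list[str]) -> "FeatureTable":
        return FeatureTable(
            self.X[columns].copy(), self.y.copy(),
            {c: self.source_tags.get(c, "") for c in columns},
        )

    def to_csv(self, path) -> None:
        out = self.X.copy()
        out["target"] = self.y
        out.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, target_column: str = "target") -> "FeatureTable":
        df = pd.read_csv(path, index_col=0)
        y = df.pop(target_column).astype(int)
        return cls(df.astype(float), y)


def available_backends() -> list[str]:
    backends = ["rdkit"]
    if _pybel is not None:
        backends.append("obabel")
    return backends


def _rdkit_vector(mol: Chem.Mol) -> dict[str, float]:
    # CalcMolDescriptors returns the full registered 2D descriptor set;
    # per-descriptor failures come back as NaN/None rather than raising.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = Descriptors.CalcMolDescriptors(mol, missingVal=math.nan)
    return {f"rdkit.{k}": v for k, v in raw.items()}


# string-valued entries of pybel's calcdesc (canonical SMILES, formula, ...)
# come back as NaN floats; they are identifiers, not descriptors
_OBABEL_NON_NUMERIC = {"cansmi", "cansmiNS", "formula", "InChI", "InChIKey",
                       "smarts", "title", "s", "L5"}


def _obabel_vector(smiles: str) -> dict[str, float]:
    try:
        m = _pybel.readstring("smi", smiles)
        raw = m.calcdesc()
    except Exception:
        return {}
    out = {}
    for k, v in raw.items():
        if k not in _OBABEL_NON_NUMERIC and isinstance(v, (int, float)):
            out[f"obabel.{k}"] = float(v)
    return out


def compute_descriptor_vector(smiles: str, backends: list[str] | None = None) -> pd.Series:
    """Compute all 2D descriptors for one standardized SMILES.

    Returns a named float Series; a descriptor whose computation fails for
    this molecule is NaN.  Non-finite backend outputs are coerced to NaN.
    """
    if backends is None:
        backends = available_backends()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    values: dict[str, float] = {}
    if "rdkit" in backends:
        values.update(_rdkit_vector(mol))
    if "obabel" in backends:
        if _pybel is None:
            raise RuntimeError("openbabel backend requested but not importable")
        values.update(_obabel_vector(smiles))
    vec = pd.Series(values, dtype=float)
    vec[~np.isfinite(vec.to_numpy(dtype=float, na_value=np.nan))] = np.nan
    return vec


def build_feature_table(
    dataset: CuratedDataset, backends: list[str] | None = None
) -> FeatureTable:
    """One row per curated compound; columns are the descriptor-name union.

    Column order is determined by sorted descriptor names (input-order
    invariant); the target comes from the fixed bitter=0 / sweet=1 encoding.
    """
    if len(dataset) == 0:
        raise ValueError("curated dataset is empty")
    rows = {}
    for rec in dataset.records:
        rows[rec.compound_id] = compute_descriptor_vector(rec.smiles, backends=backends)
    X = pd.DataFrame.from_dict(rows, orient="index")
    X = X.reindex(columns=sorted(X.columns)).astype(float)
    X = X.loc[[r.compound_id for r in dataset.records]]
    y = pd.Series([r.label for r in dataset.records], index=X.index, name="target", dtype=int)
    tags = {c: c.split(".", 1)[0] for c in X.columns}
    return FeatureTable(X, y, tags)
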