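"""Fingerprint-similarity applicability domain.

A query molecule is inside the model's applicability domain when it is
structurally close to the training chemistry: its Morgan fingerprint
(1024 bits, radius 2) is compared with every training fingerprint by
Tanimoto similarity and the mean of the 5 highest scores is taken.  The
inside/outside threshold is calibrated from the score distributions of a
train/validation split (default: 5th percentile of the validation scores,
so almost all molecules of training-like chemistry remain inside).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator
from sklearn.model_selection import train_test_split

__all__ = [
    "N_BITS",
    "RADIUS",
    "fingerprint",
    "tanimoto",
    "average_top_k_similarity",
    "ADModel",
    "ApplicabilityDomain",
    "calibrate_threshold",
    "in_domain",
]

N_BITS = 1024
RADIUS = 2

_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=RADIUS, fpSize=N_BITS)


def fingerprint(smiles: str):
    """1024-bit radius-2 circular (Morgan) fingerprint of one SMILES."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return _GEN.GetFingerprint(mol)


def tanimoto(a, b) -> float:
    """|a AND b| / |a OR b|; two empty fingerprints give 0 with a warning."""
    if a.GetNumBits() != b.GetNumBits():
        raise ValueError(f"fingerprint length mismatch: {a.GetNumBits()} vs {b.GetNumBits()}")
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        warnings.warn("both fingerprints are empty; Tanimoto defined as 0")
        return 0.0
    return float(DataStructs.TanimotoSimilarity(a, b))


def average_top_k_similarity(query, reference: list, k: int = 5, exclude_self: bool = False) -> float:
    """Mean Tanimoto similarity to the k most similar reference fingerprints.

    With ``exclude_self`` one perfect match (the query itself, when scoring a
    member of the reference set) is removed before averaging.  Fewer than k
    references: average over what exists.
    """
    if not reference:
        raise ValueError("reference fingerprint collection is empty")
    sims = sorted((tanimoto(query, r) for r in reference), reverse=True)
    if exclude_self:
        sims = sims[1:]
        if not sims:
            raise ValueError("reference contains only the query itself")
    return float(np.mean(sims[:k]))


@dataclass
class ADModel:
    """Calibrated domain: training fingerprints, threshold, score distributions."""

    train_fingerprints: list
    threshold: float
    train_scores: np.ndarray
    validation_scores: np.ndarray
    k: int = 5
    percentile: float = 5.0

    def to_json(self, path) -> None:
        payload = {
            "threshold": self.threshold,
            "k": self.k,
            "percentile": self.percentile,
            "train_scores": self.train_scores.tolist(),
            "validation_scores": self.validation_scores.tolist(),
            "train_fingerprints": [fp.ToBitString() for fp in self.train_fingerprints],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ADModel":
        with open(path) as fh:
            payload = json.load(fh)
        fps = []
        for bits in payload["train_fingerprints"]:
            fp = DataStructs.CreateFromBitString(bits)
            fps.append(fp)
        return cls(
            train_fingerprints=fps,
            threshold=payload["threshold"],
            train_scores=np.asarray(payload["train_scores"]),
            validation_scores=np.asarray(payload["validation_scores"]),
            k=payload["k"],
            percentile=payload["percentile"],
        )


class ApplicabilityDomain(BaseEstimator):
    """Estimator interface: fit on SMILES, predict inside/outside + score.

    ``fit`` splits the input 90:10 (stratified when labels are given) into
    reference and calibration sets, scores both against the reference
    fingerprints (training members score with self-exclusion) and sets the
    threshold at the ``percentile``-th percentile of the validation scores.
    Boundary convention: a score equal to the threshold is inside.
    """

    def __init__(self, k: int = 5, percentile: float = 5.0,
                 validation_fraction: float = 0.1, random_state: int = 0):
        self.k = k
        self.percentile = percentile
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, smiles: list[str], y=None):
        if len(smiles) < 2:
            raise ValueError("need at least two compounds to calibrate")
        idx = np.arange(len(smiles))
        tr, va = train_test_split(
            idx, test_size=self.validation_fraction,
            random_state=self.random_state,
            stratify=None if y is None else np.asarray(y),
        )
        train_smiles = [smiles[i] for i in tr]
        val_smiles = [smiles[i] for i in va]
        self.model_ = calibrate_threshold(
            train_smiles, val_smiles, k=self.k, percentile=self.percentile
        )
        return self

    def score_samples(self, smiles: list[str]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "model_")
        m = self.model_
        return np.array(
            [
                average_top_k_similarity(fingerprint(s), m.train_fingerprints, k=m.k)
                for s in smiles
            ]
        )

    def predict(self, smiles: list[str]) -> np.ndarray:
        """True = inside the applicability domain."""
        scores = self.score_samples(smiles)
        return scores >= self.model_.threshold


def calibrate_threshold(
    train_smiles: list[str],
    validation_smiles: list[str],
    k: int = 5,
    percentile: float = 5.0,
) -> ADModel:
    """Build the domain from explicit train/validation compound sets.

    Training compounds are scored against the training references with
    self-exclusion (otherwise every training score is trivially 1);
    validation compounds are scored against the full training reference.
    Threshold = ``percentile``-th percentile of the validation scores.
    """
    if not train_smiles or not validation_smiles:
        raise ValueError("train and validation sets must be non-empty")
    train_fps = [fingerprint(s) for s in train_smiles]
    val_fps = [fingerprint(s) for s in validation_smiles]
    train_scores = np.array(
        [average_top_k_similarity(fp, train_fps, k=k, exclude_self=True) for fp in train_fps]
    )
    val_scores = np.array(
        [average_top_k_similarity(fp, train_fps, k=k) for fp in val_fps]
    )
    threshold = float(np.percentile(val_scores, percentile))
    return ADModel(
        train_fingerprints=train_fps,
        threshold=threshold,
        train_scores=train_scores,
        validation_scores=val_scores,
        k=k,
        percentile=percentile,
    )


def in_domain(smiles: str, model: ADModel) -> tuple[bool, float]:
    """Inside/outside verdict plus the average-top-k similarity score."""
    fp = fingerprint(smiles)
    if fp.GetNumOnBits() == 0:
        warnings.warn(f"empty fingerprint for {smiles!r}; treated as outside the domain")
        return False, 0.0
    score = average_top_k_similarity(fp, model.train_fingerprints, k=model.k)
    return score >= model.threshold, score
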