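"""Feature encoding and F-score feature ranking.

Each protein is represented by the concatenation of

* its amino-acid composition — the 20 residue frequencies, normalized by
  sequence length, in fixed alphabetical order (A, C, D, ..., Y);
* binary presence/absence indicators for every functional-domain identifier
  in a frozen registry built from the training set;
* optionally the 400 overlapping-dipeptide frequencies (off by default; it
  adds dimensionality without discriminative gain for this task).

The registry is the lexicographically sorted union of domain identifiers
over the whole training set (both classes), frozen before any scan: domains
first seen at scan time contribute nothing, keeping the vector dimension
well-defined.

Features are ranked by the F-score used by libsvm's feature-selection tool:
for feature i with class means x̄⁺, x̄⁻, overall mean x̄ and class sample
variances s⁺², s⁻²,

    F(i) = [(x̄⁺ − x̄)² + (x̄⁻ − x̄)²] / (s⁺² + s⁻²)

A zero denominator with a nonzero numerator is a perfectly separating
constant-within-class feature (F = +inf); zero over zero is F = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from protint.seqdata import AMINO_ACIDS, ProteinRecord

if TYPE_CHECKING:  # pragma: no cover
    from protint.dataset import LabeledDataset

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
#: All 400 dipeptides in row-major alphabetical order (AA, AC, ..., YY).
DIPEPTIDES: tuple[str, ...] = tuple(a + b for a, b in product(AMINO_ACIDS, AMINO_ACIDS))
_DIPEP_INDEX = {dp: i for i, dp in enumerate(DIPEPTIDES)}


@dataclass(frozen=True)
class FeatureSpace:
    """Frozen vector layout: 20 amino acids + domain registry (+ dipeptides)."""

    domain_registry: tuple[str, ...]
    include_dipeptides: bool = False

    def __post_init__(self) -> None:
        if len(set(self.domain_registry)) != len(self.domain_registry):
            raise ValueError("domain_registry contains duplicates")
        object.__setattr__(self, "domain_registry", tuple(self.domain_registry))

    @property
    def dimension(self) -> int:
        return 20 + len(self.domain_registry) + (400 if self.include_dipeptides else 0)

    def feature_names(self) -> list[str]:
        names = [f"aa_{a}" for a in AMINO_ACIDS]
        names += [f"dom_{d}" for d in self.domain_registry]
        if self.include_dipeptides:
            names += [f"dp_{d}" for d in DIPEPTIDES]
        return names

    def domain_feature_indices(self, domains: Iterable[str]) -> list[int]:
        """Feature indices of the given domain identifiers (registry members only)."""
        lookup = {d: 20 + i for i, d in enumerate(self.domain_registry)}
        return [lookup[d] for d in domains if d in lookup]


@dataclass(frozen=True)
class FeatureVector:
    """Encoded protein with provenance accession."""

    accession: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


@dataclass(frozen=True)
class FeatureScore:
    feature_index: int
    f_score: float
    rank: int  # 1-based, descending f_score


def build_space(
    training_records: Iterable[ProteinRecord], include_dipeptides: bool = False
) -> FeatureSpace:
    """Freeze the feature layout from the training records (both classes).

    The domain registry is the lexicographically sorted union of all domain
    identifiers seen in training.  Empty collections are a hard error.
    """
    records = list(training_records)
    if not records:
        raise ValueError("build_space: training collection is empty")
    registry = sorted(set().union(*(r.domains for r in records)))
    return FeatureSpace(tuple(registry), include_dipeptides=include_dipeptides)


def aa_composition(sequence: str) -> np.ndarray:
    """20-vector of residue frequencies; sums to 1. Length 0 is a hard error."""
    if not sequence:
        raise ValueError("aa_composition: empty sequence")
    counts = np.zeros(20)
    for ch in sequence:
        counts[_AA_INDEX[ch]] += 1
    return counts / len(sequence)


def dipeptide_composition(sequence: str) -> np.ndarray:
    """400-vector of overlapping dipeptide frequencies over (length − 1)."""
    if len(sequence) < 2:
        raise ValueError("dipeptide_composition: need at least 2 residues")
    counts = np.zeros(400)
    for i in range(len(sequence) - 1):
        counts[_DIPEP_INDEX[sequence[i : i + 2]]] += 1
    return counts / (len(sequence) - 1)


def encode(record: ProteinRecord, space: FeatureSpace) -> FeatureVector:
    """Encode a record in the frozen space.

    Layout: [composition | domain indicators in registry order | dipeptides].
    Domains absent from the registry are ignored.
    """
    blocks = [aa_composition(record.sequence)]
    dom = np.zeros(len(space.domain_registry))
    for i, d in enumerate(space.domain_registry):
        if d in record.domains:
            dom[i] = 1.0
    blocks.append(dom)
    if space.include_dipeptides:
        blocks.append(dipeptide_composition(record.sequence))
    return FeatureVector(record.accession, np.concatenate(blocks))


def encode_matrix(records: Sequence[ProteinRecord], space: FeatureSpace) -> np.ndarray:
    """Stack encodings of ``records`` into an (n, dimension) matrix."""
    return np.vstack([encode(r, space).values for r in records])


def f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature F-score for a binary-labelled matrix (labels 0/1).

    Requires at least two samples per class (sample variance needs n−1 ≥ 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos = X[y == 1]
    neg = X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("f_scores: need >= 2 samples in each class")
    overall = X.mean(axis=0)
    num = (pos.mean(axis=0) - overall) ** 2 + (neg.mean(axis=0) - overall) ** 2
    denom = pos.var(axis=0, ddof=1) + neg.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / denom
    f[(denom == 0) & (num > 0)] = np.inf
    f[(denom == 0) & (num == 0)] = 0.0
    return f


def f_score_rank(dataset: "LabeledDataset") -> list[FeatureScore]:
    """Rank all features by descending F-score (ties by ascending index)."""
    f = f_scores(dataset.X, dataset.y)
    order = sorted(range(len(f)), key=lambda i: (-f[i], i))
    return [
        FeatureScore(feature_index=i, f_score=float(f[i]), rank=r + 1)
        for r, i in enumerate(order)
    ]


def top_feature_indices(X: np.ndarray, y: np.ndarray, n_features: int) -> np.ndarray:
    """Indices of the ``n_features`` best features, ascending for stable slicing.

    ``n_features`` of 0 (or >= dimension) selects everything.
    """
    d = X.shape[1]
    if n_features <= 0 or n_features >= d:
        return np.arange(d)
    f = f_scores(X, y)
    order = sorted(range(d), key=lambda i: (-f[i], i))
    return np.array(sorted(order[:n_features]))
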