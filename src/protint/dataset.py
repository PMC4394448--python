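"""Labeled training-set construction.

Positives are the redundancy-reduced known partners of the target protein.
Negatives are drawn uniformly at random, without replacement, from the
background proteome after removing (i) the positives themselves and (ii)
any protein with more than ``identity_threshold`` global-alignment identity
to a positive — the standard homology-safe negative-sampling protocol when
true non-interactors are unknown.  Positives may be upsampled by an integer
factor (exact duplication); by default duplicated replicates are kept in the
same cross-validation fold (see :mod:`protint.model`), which avoids the
optimistic bias of letting copies of one protein straddle folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

from protint import features as ft
from protint import redundancy
from protint.seqdata import ProteinRecord, Proteome

#: Separator between a source accession and its replicate tag after upsampling.
REPLICATE_SEP = ".rep"


@dataclass(frozen=True)
class SamplingConfig:
    """Negative-sampling and upsampling parameters."""

    n_negatives: int | None = None  # None -> match number of positives
    identity_threshold: float = 0.70
    upsample_factor: int = 1
    n_repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.n_negatives is not None and self.n_negatives < 1:
            raise ValueError("n_negatives must be >= 1")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def source_accession(accession: str) -> str:
    """Accession of the original record behind a (possibly replicated) id."""
    return accession.split(REPLICATE_SEP, 1)[0]


@dataclass
class LabeledDataset:
    """Encoded feature matrix with binary labels and provenance.

    ``groups`` carries the source accession of every row so replicate copies
    produced by upsampling can be held together during cross-validation.
    """

    X: np.ndarray
    y: np.ndarray
    accessions: list[str]
    space: ft.FeatureSpace
    seed: int | None = None
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y) or len(self.X) != len(self.accessions):
            raise ValueError("X, y and accessions must have equal length")
        if not self.groups:
            self.groups = [source_accession(a) for a in self.accessions]
        if set(np.unique(self.y)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_positives(self) -> int:
        return int(self.y.sum())

    @property
    def n_negatives(self) -> int:
        return int(len(self.y) - self.y.sum())

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            accessions=[self.accessions[i] for i in idx],
            space=self.space,
            seed=self.seed,
            groups=[self.groups[i] for i in idx],
        )

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.svmlight`` (sparse ``label index:value``) and
        ``<prefix>.accessions.tsv`` (row order sidecar)."""
        prefix = Path(prefix)
        with open(f"{prefix}.svmlight", "wb") as fh:
            dump_svmlight_file(self.X, self.y, fh, zero_based=False)
        pd.DataFrame(
            {"accession": self.accessions, "label": self.y, "group": self.groups}
        ).to_csv(f"{prefix}.accessions.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, prefix: str | Path, space: ft.FeatureSpace) -> "LabeledDataset":
        prefix = Path(prefix)
        X, y = load_svmlight_file(f"{prefix}.svmlight", n_features=space.dimension)
        side = pd.read_csv(f"{prefix}.accessions.tsv", sep="\t")
        return cls(
            X=np.asarray(X.todense()),
            y=y.astype(int),
            accessions=side["accession"].tolist(),
            space=space,
            groups=side["group"].tolist(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Dense TSV-ready frame: accession, label, one column per feature."""
        df = pd.DataFrame(self.X, columns=self.space.feature_names())
        df.insert(0, "label", self.y)
        df.insert(0, "accession", self.accessions)
        return df


def sample_negatives(
    proteome: Proteome,
    positives: Sequence[ProteinRecord],
    config: SamplingConfig,
) -> list[ProteinRecord]:
    """Uniform seeded sample of eligible non-interacting proteins.

    Eligible = proteome minus positive accessions minus anything with more
    than ``identity_threshold`` identity to any positive.  The sample is
    drawn without replacement and returned sorted by accession.  If fewer
    eligible proteins exist than requested, a hard error reports the count.
    """
    n = config.n_negatives if config.n_negatives is not None else len(positives)
    pos_accessions = {p.accession for p in positives}
    pool = [r for r in proteome if r.accession not in pos_accessions]
    id_config = redundancy.IdentityConfig(threshold=config.identity_threshold)
    eligible = redundancy.cross_filter(pool, list(positives), id_config)
    if len(eligible) < n:
        raise ValueError(
            f"sample_negatives: only {len(eligible)} eligible proteins "
            f"for {n} requested negatives"
        )
    rng = np.random.default_rng(config.seed)
    chosen = rng.choice(len(eligible), size=n, replace=False)
    return sorted((eligible[i] for i in chosen), key=lambda r: r.accession)


def upsample_positives(positives: Sequence[ProteinRecord], factor: int) -> list[ProteinRecord]:
    """Duplicate each positive ``factor`` times (exact copies).

    Replicates get provenance ids ``<accession>.rep2`` ... so their common
    source remains recoverable; factor 1 is the identity.
    """
    if factor < 1:
        raise ValueError("upsample factor must be >= 1")
    if factor == 1:
        return list(positives)
    out: list[ProteinRecord] = []
    for rec in positives:
        out.append(rec)
        for i in range(2, factor + 1):
            out.append(rec.with_accession(f"{rec.accession}{REPLICATE_SEP}{i}"))
    return out


def assemble(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    space: ft.FeatureSpace,
    seed: int | None = None,
) -> LabeledDataset:
    """Encode positives (label 1) and negatives (label 0) into a dataset.

    Stable ordering: positives first, then negatives, each sorted by
    accession.  Any accession appearing in both classes is a hard error.
    """
    if not positives or not negatives:
        raise ValueError("assemble: both classes must be non-empty")
    overlap = {source_accession(p.accession) for p in positives} & {
        source_accession(n.accession) for n in negatives
    }
    if overlap:
        raise ValueError(f"assemble: accessions in both classes: {sorted(overlap)}")
    pos = sorted(positives, key=lambda r: r.accession)
    neg = sorted(negatives, key=lambda r: r.accession)
    X = ft.encode_matrix(list(pos) + list(neg), space)
    y = np.array([1] * len(pos) + [0] * len(neg))
    accessions = [r.accession for r in pos] + [r.accession for r in neg]
    return LabeledDataset(X=X, y=y, accessions=accessions, space=space, seed=seed)
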