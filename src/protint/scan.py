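"""Proteome-wide scanning for new interaction partners and GOslim summaries.

The calling threshold is derived from the training set: the minimum
calibrated probability (of the assigned class) among correctly classified
training samples, floored at 0.5 so a badly calibrated model cannot call
majority-negative scores positive.  Ranking of scan hits uses the
probability of the positive class; proteins without any domain annotation
are scored on composition alone (domain block all zeros) rather than
skipped, so the scan covers the whole proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from protint.features import encode_matrix
from protint.model import TrainedModel
from protint.seqdata import Proteome

if TYPE_CHECKING:  # pragma: no cover
    from protint.dataset import LabeledDataset


@dataclass(frozen=True)
class Prediction:
    accession: str
    probability: float  # positive-class probability
    call: bool          # probability >= threshold


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    n_correct: int      # correctly classified training samples
    n_below_floor: int  # correct samples whose probability fell below 0.5


def threshold_from_probabilities(correct_probs: Sequence[float]) -> ThresholdResult:
    """Minimum assigned-class probability over correct samples, floored at 0.5."""
    probs = np.asarray(correct_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("derive_threshold: no correctly classified samples")
    below = int((probs < 0.5).sum())
    return ThresholdResult(
        threshold=float(max(0.5, probs.min())),
        n_correct=int(probs.size),
        n_below_floor=below,
    )


def derive_threshold(model: TrainedModel, training: "LabeledDataset") -> ThresholdResult:
    """Probability call threshold from the model's own training set.

    Scores every training sample, keeps the correctly classified ones, and
    returns the minimum calibrated probability of the assigned class (with
    the 0.5 floor), alongside how many correct samples sat below the floor.
    """
    pred = model.predict(training.X)
    correct = pred == training.y
    assigned = model.assigned_probability(training.X)
    return threshold_from_probabilities(assigned[correct])


def scan_proteome(
    model: TrainedModel,
    proteome: Proteome,
    exclude: Iterable[str] = (),
    threshold: float = 0.96,
) -> list[Prediction]:
    """Score every non-excluded protein; rank by descending probability.

    The threshold only sets the boolean call — the full ranked list is always
    returned.  Ties in probability break by ascending accession.  An empty
    proteome after exclusion is a hard error.
    """
    excluded = set(exclude)
    records = [r for r in proteome if r.accession not in excluded]
    if not records:
        raise ValueError("scan_proteome: no proteins left after exclusion")
    probs = model.positive_probability(encode_matrix(records, model.space))
    preds = [
        Prediction(rec.accession, float(p), bool(p >= threshold))
        for rec, p in zip(records, probs)
    ]
    preds.sort(key=lambda pr: (-pr.probability, pr.accession))
    return preds


def predictions_to_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"accession": p.accession, "probability": p.probability, "call": p.call}
         for p in predictions]
    )


@dataclass
class GoSlimTable:
    """Per-category protein counts over one accession list.

    ``fractions`` are over mapped proteins; with multi-category mappings the
    counts can exceed the number of proteins (``multi_mapped`` flags this).
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    n_proteins: int
    n_mapped: int
    unmapped: int
    multi_mapped: bool

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": c, "count": n, "fraction_of_mapped": self.fractions[c]}
            for c, n in sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        return pd.DataFrame(rows, columns=["category", "count", "fraction_of_mapped"])


def goslim_summary(
    accessions: Sequence[str],
    category_map: Mapping[str, Iterable[str]],
) -> GoSlimTable:
    """Tabulate GOslim (or any coarse) categories over an accession list.

    A protein mapped to several categories contributes to each count;
    proteins with no mapping are counted as unmapped.
    """
    counts: dict[str, int] = {}
    n_mapped = 0
    multi = False
    for acc in accessions:
        cats = set(category_map.get(acc, ()))
        if not cats:
            continue
        n_mapped += 1
        if len(cats) > 1:
            multi = True
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    fractions = {c: (n / n_mapped if n_mapped else 0.0) for c, n in counts.items()}
    return GoSlimTable(
        counts=counts,
        fractions=fractions,
        n_proteins=len(accessions),
        n_mapped=n_mapped,
        unmapped=len(accessions) - n_mapped,
        multi_mapped=multi,
    )


def goslim_side_by_side(
    known: Sequence[str],
    predicted: Sequence[str],
    category_map: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Known-vs-predicted category table for comparing functional profiles."""
    t_known = goslim_summary(known, category_map)
    t_pred = goslim_summary(predicted, category_map)
    cats = sorted(set(t_known.counts) | set(t_pred.counts))
    return pd.DataFrame(
        {
            "category": cats,
            "known_count": [t_known.counts.get(c, 0) for c in cats],
            "known_fraction": [t_known.fractions.get(c, 0.0) for c in cats],
            "predicted_count": [t_pred.counts.get(c, 0) for c in cats],
            "predicted_fraction": [t_pred.fractions.get(c, 0.0) for c in cats],
        }
    )
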