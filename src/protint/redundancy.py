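"""Sequence-identity redundancy removal (CD-HIT-style, exact alignment).

Training sets built around a single target protein are prone to homology
bias: near-identical partners inflate cross-validation estimates.  This
module removes sequences above an identity threshold within one set
(``dedupe_within``, the CD-HIT role) and filters candidate sets against a
reference set (``cross_filter``, the CD-HIT-2D role).

Identity convention (CD-HIT's documented one): the number of identical
aligned residue pairs in an optimal global alignment, divided by the length
of the shorter sequence.  Alignments are scored with match +1, mismatch −1,
gap −1 (linear gaps) and solved exactly by Needleman–Wunsch; among
score-optimal alignments the one with the most identities defines the
identity.  No k-mer prefilter or banding is used — exactness over speed at
desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from protint.seqdata import ProteinRecord


@dataclass(frozen=True)
class IdentityConfig:
    """Identity threshold and global-alignment scoring."""

    threshold: float = 0.70
    match: int = 1
    mismatch: int = -1
    gap: int = -1

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")


DEFAULT_IDENTITY_CONFIG = IdentityConfig()


@njit(nogil=True)
def _align_stats(a, b, match, mismatch, gap):  # pragma: no cover - jit kernel
    """Needleman–Wunsch over (score, identities), lexicographic maximum.

    Both objectives are additive along an alignment path, so the
    lexicographic comparison has optimal substructure.
    """
    n = a.shape[0]
    m = b.shape[0]
    prev_s = np.empty(m + 1, dtype=np.int64)
    prev_i = np.empty(m + 1, dtype=np.int64)
    cur_s = np.empty(m + 1, dtype=np.int64)
    cur_i = np.empty(m + 1, dtype=np.int64)
    for j in range(m + 1):
        prev_s[j] = gap * j
        prev_i[j] = 0
    for i in range(1, n + 1):
        cur_s[0] = gap * i
        cur_i[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                bs = prev_s[j - 1] + match
                bi = prev_i[j - 1] + 1
            else:
                bs = prev_s[j - 1] + mismatch
                bi = prev_i[j - 1]
            us = prev_s[j] + gap
            if us > bs or (us == bs and prev_i[j] > bi):
                bs = us
                bi = prev_i[j]
            ls = cur_s[j - 1] + gap
            if ls > bs or (ls == bs and cur_i[j - 1] > bi):
                bs = ls
                bi = cur_i[j - 1]
            cur_s[j] = bs
            cur_i[j] = bi
        prev_s, cur_s = cur_s, prev_s
        prev_i, cur_i = cur_i, prev_i
    return prev_s[m], prev_i[m]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def pairwise_identity(a: str, b: str, config: IdentityConfig = DEFAULT_IDENTITY_CONFIG) -> float:
    """Fraction of identical aligned pairs over the shorter sequence length.

    Symmetric in its arguments; in [0, 1].  Empty sequences are a hard error.
    """
    if not a or not b:
        raise ValueError("pairwise_identity: sequences must be non-empty")
    _, identities = _align_stats(
        _encode(a), _encode(b), config.match, config.mismatch, config.gap
    )
    return identities / min(len(a), len(b))


def dedupe_within(
    records: Iterable[ProteinRecord],
    config: IdentityConfig = DEFAULT_IDENTITY_CONFIG,
) -> list[ProteinRecord]:
    """Greedy longest-first clustering; returns cluster representatives.

    Records are sorted by descending sequence length (ties by accession);
    each unclaimed record becomes a representative and claims every remaining
    record with identity strictly above the threshold.  Deterministic output
    order (the sort order restricted to survivors).
    """
    pool = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    claimed = [False] * len(pool)
    reps: list[ProteinRecord] = []
    for i, rep in enumerate(pool):
        if claimed[i]:
            continue
        reps.append(rep)
        for j in range(i + 1, len(pool)):
            if claimed[j]:
                continue
            if pairwise_identity(rep.sequence, pool[j].sequence, config) > config.threshold:
                claimed[j] = True
    return reps


def cross_filter(
    candidates: Iterable[ProteinRecord],
    reference: Sequence[ProteinRecord],
    config: IdentityConfig = DEFAULT_IDENTITY_CONFIG,
) -> list[ProteinRecord]:
    """Drop candidates with identity strictly above threshold to any reference.

    "More than" is strict: a candidate whose maximum identity equals the
    threshold exactly is retained.  Candidate order is preserved.
    """
    ref_seqs = [r.sequence for r in reference]
    kept = []
    for cand in candidates:
        if all(
            pairwise_identity(cand.sequence, s, config) <= config.threshold
            for s in ref_seqs
        ):
            kept.append(cand)
    return kept
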