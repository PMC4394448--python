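"""Synthetic proteomes with planted interaction signal.

The generator emulates the four inputs of a real study — a background
proteome FASTA, a protein→domain annotation table, a positive (interacting)
accession list, and an optional category map — without any database
downloads.  Positive-class signal is planted the way real partner sets
differ from the background: a multiplicative tilt on selected residue
frequencies (renormalized, so composition vectors stay on the simplex) and
a set of "enriched" domain identifiers that are far more prevalent among
positives than in the background.

Background residue frequencies default to the UniProt/Swiss-Prot average
composition.  Three named presets cover the interesting regimes:

* ``null`` — no tilt, identical domain rates in both classes; any
  downstream classifier should be at chance.
* ``weak`` — mild cysteine tilt (×1.5) and moderately enriched domains
  (0.30 vs 0.05).
* ``strong`` — cysteine frequency ×3 in positives and five enriched
  domains at 0.80 vs 0.05 background prevalence; the pipeline should
  recover the planted signal.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from protint.seqdata import AMINO_ACIDS, ProteinRecord, Proteome, write_fasta

#: Average amino-acid frequencies in UniProt/Swiss-Prot (fractions).
UNIPROT_FREQUENCIES: dict[str, float] = {
    "A": 0.0825, "C": 0.0138, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0707, "H": 0.0227, "I": 0.0591, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0393, "R": 0.0553,
    "S": 0.0663, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for one synthetic study."""

    n_positives: int = 60
    n_background: int = 400
    length_range: tuple[int, int] = (80, 200)
    background_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(UNIPROT_FREQUENCIES)
    )
    composition_tilt: Mapping[str, float] = field(default_factory=dict)
    domain_universe_size: int = 40
    n_enriched_domains: int = 5
    enriched_presence: float = 0.8    # per enriched domain, in positives
    background_presence: float = 0.05  # per domain, in background (and for
                                       # non-enriched domains in positives)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positives < 1 or self.n_background < 1:
            raise ValueError("both classes must be non-empty")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length range {self.length_range}")
        if not (0.0 <= self.enriched_presence <= 1.0) or not (
            0.0 <= self.background_presence <= 1.0
        ):
            raise ValueError("domain presence probabilities must be in [0, 1]")
        if self.n_enriched_domains > self.domain_universe_size:
            raise ValueError("enriched set must be a subset of the domain universe")
        if any(v < 0 for v in self.background_frequencies.values()):
            raise ValueError("background frequencies must be non-negative")
        if any(v < 0 for v in self.composition_tilt.values()):
            raise ValueError("composition tilt must be non-negative")

    @property
    def domain_universe(self) -> tuple[str, ...]:
        return tuple(f"IPR{i:06d}" for i in range(1, self.domain_universe_size + 1))

    @property
    def enriched_domains(self) -> tuple[str, ...]:
        return self.domain_universe[: self.n_enriched_domains]


PRESETS: dict[str, SyntheticConfig] = {
    "null": SyntheticConfig(
        n_positives=50, n_background=200,
        composition_tilt={}, enriched_presence=0.05, background_presence=0.05,
    ),
    "weak": SyntheticConfig(
        n_positives=60, n_background=400,
        composition_tilt={"C": 1.5}, enriched_presence=0.30, background_presence=0.05,
    ),
    "strong": SyntheticConfig(
        n_positives=60, n_background=400,
        composition_tilt={"C": 3.0}, enriched_presence=0.80, background_presence=0.05,
    ),
}


def preset(name: str, seed: int | None = None) -> SyntheticConfig:
    """Named preset; optionally override its seed."""
    try:
        config = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    return config


@dataclass
class SyntheticResult:
    proteome: Proteome          # positives + background, domains attached
    positives: list[str]        # positive accessions
    truth: pd.DataFrame         # per-record ground truth
    params: dict                # every generation parameter
    enriched_domains: tuple[str, ...]


def _frequency_vector(freqs: Mapping[str, float]) -> np.ndarray:
    vec = np.array([freqs.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
    total = vec.sum()
    if total <= 0:
        raise ValueError("frequency vector must have positive mass")
    return vec / total


def _tilted(base: np.ndarray, tilt: Mapping[str, float]) -> np.ndarray:
    mult = np.array([tilt.get(a, 1.0) for a in AMINO_ACIDS], dtype=float)
    vec = base * mult
    return vec / vec.sum()


def generate_proteome(config: SyntheticConfig) -> SyntheticResult:
    """Draw a synthetic proteome; deterministic for a fixed config (incl. seed).

    Background sequences are i.i.d. draws from the background frequencies
    with per-domain Bernoulli presence at the background rate; positives use
    the tilted frequencies and the enriched rates for the enriched domains.
    """
    rng = np.random.default_rng(config.seed)
    bg_freq = _frequency_vector(config.background_frequencies)
    pos_freq = _tilted(bg_freq, config.composition_tilt)
    universe = config.domain_universe
    enriched = set(config.enriched_domains)
    bg_p = np.full(len(universe), config.background_presence)
    pos_p = np.array(
        [config.enriched_presence if d in enriched else config.background_presence
         for d in universe]
    )
    aa = np.array(list(AMINO_ACIDS))
    lo, hi = config.length_range

    def draw(n: int, prefix: str, freq: np.ndarray, dom_p: np.ndarray) -> list[ProteinRecord]:
        records = []
        for i in range(1, n + 1):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(aa[rng.choice(20, size=length, p=freq)])
            present = rng.random(len(universe)) < dom_p
            domains = frozenset(d for d, keep in zip(universe, present) if keep)
            records.append(ProteinRecord(f"{prefix}{i:04d}", seq, domains))
        return records

    pos_records = draw(config.n_positives, "POS", pos_freq, pos_p)
    bg_records = draw(config.n_background, "BKG", bg_freq, bg_p)
    proteome = Proteome(pos_records + bg_records)
    truth = pd.DataFrame(
        [
            {
                "accession": r.accession,
                "is_positive": int(r.accession.startswith("POS")),
                "length": len(r.sequence),
                "n_domains": len(r.domains),
                "enriched_domains_present": sum(d in enriched for d in r.domains),
            }
            for r in proteome
        ]
    )
    params = dataclasses.asdict(config)
    params["background_frequencies"] = dict(config.background_frequencies)
    params["composition_tilt"] = dict(config.composition_tilt)
    params["enriched_domains"] = list(config.enriched_domains)
    return SyntheticResult(
        proteome=proteome,
        positives=[r.accession for r in pos_records],
        truth=truth,
        params=params,
        enriched_domains=config.enriched_domains,
    )


def write_synthetic(result: SyntheticResult, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA, domain TSV, positives list, truth TSV and params JSON.

    Byte-identical for the same config and seed (no timestamps).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "proteome.fasta",
        "domains": out / "domains.tsv",
        "positives": out / "positives.txt",
        "truth": out / "truth.tsv",
        "params": out / "params.json",
    }
    write_fasta(result.proteome, paths["fasta"])
    with open(paths["domains"], "w") as fh:
        for rec in result.proteome:
            for dom in sorted(rec.domains):
                fh.write(f"{rec.accession}\t{dom}\n")
    with open(paths["positives"], "w") as fh:
        for acc in result.positives:
            fh.write(acc + "\n")
    result.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["params"], "w") as fh:
        json.dump(result.params, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
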