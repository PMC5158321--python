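"""Synthetic two-set motif-hit generator with planted band effects.

Emulates the structure of a two-set promoter comparison: each promoter is
a -2000..+500 window (2500 bp) carrying motif occurrences, and the two
classes differ only in the rate of a few planted (motif, band) features.
Per promoter and motif, a background number of hits is drawn from a
Poisson with mean ``background_rate`` and placed uniformly along the
promoter; each planted effect adds Poisson(``rate_delta``) extra hits to
promoters of its enriched class, placed uniformly within the planted band.
Band counts are therefore Poisson, so planted effects are analytically
checkable.

Defaults describe the simulated study: 100 promoters per class, 20 motifs,
50-bp bands, five planted effects of size 3.0 split across the classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motif_io import MotifHit, write_motif_hits
from .psmm import BandScheme

__all__ = [
    "PlantedEffect",
    "SynthConfig",
    "SynthTruth",
    "default_planted",
    "generate_sets",
    "write_labels",
    "read_labels",
]


@dataclass(frozen=True)
class PlantedEffect:
    """One class-specific enrichment: extra hits of one motif in one band."""

    motif_id: str
    band_index: int
    enriched_class: str
    rate_delta: float

    def __post_init__(self) -> None:
        if self.rate_delta < 0:
            raise ValueError("rate_delta must be >= 0")
        if self.enriched_class not in ("A", "B"):
            raise ValueError("enriched_class must be 'A' or 'B'")


def _motif_vocabulary(n_motifs: int) -> tuple[str, ...]:
    # JASPAR-style accessions for realistic fixtures
    return tuple(f"MA{i:04d}.1" for i in range(1, n_motifs + 1))


def default_planted(
    n_motifs: int = 20, n_effects: int = 5, rate_delta: float = 3.0
) -> tuple[PlantedEffect, ...]:
    """Five spread-out planted effects alternating between the classes."""
    vocab = _motif_vocabulary(n_motifs)
    effects = []
    for i in range(n_effects):
        effects.append(
            PlantedEffect(
                motif_id=vocab[(i * max(1, n_motifs // n_effects)) % n_motifs],
                band_index=3 + 9 * i,
                enriched_class="A" if i % 2 == 0 else "B",
                rate_delta=rate_delta,
            )
        )
    return tuple(effects)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; the defaults are the simulated study design."""

    n_per_class: int = 100
    promoter_length: int = 2500
    band_width: int = 50
    n_motifs: int = 20
    background_rate: float = 1.0
    planted: tuple[PlantedEffect, ...] = field(default_factory=default_planted)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.n_per_class < 1 or self.n_motifs < 1:
            raise ValueError("n_per_class and n_motifs must be >= 1")
        scheme = self.scheme
        vocab = set(self.motif_ids)
        for eff in self.planted:
            if eff.band_index >= scheme.n_bands:
                raise ValueError(
                    f"planted band {eff.band_index} >= n_bands {scheme.n_bands}"
                )
            if eff.motif_id not in vocab:
                raise ValueError(f"planted motif {eff.motif_id!r} not in vocabulary")

    @property
    def scheme(self) -> BandScheme:
        return BandScheme(self.promoter_length, self.band_width)

    @property
    def motif_ids(self) -> tuple[str, ...]:
        return _motif_vocabulary(self.n_motifs)


@dataclass(frozen=True)
class SynthTruth:
    """Ground truth of a generated benchmark: planted features and labels."""

    planted_features: tuple[str, ...]
    effects: tuple[PlantedEffect, ...]
    labels: dict[str, str]


def generate_sets(
    config: SynthConfig,
) -> tuple[dict[str, list[MotifHit]], dict[str, list[MotifHit]], SynthTruth]:
    """Generate the two promoter sets' hits plus the ground truth.

    Returns (set_a, set_b, truth): insertion-ordered promoter -> hits
    mappings for classes A and B.  Identical configs (including seed) give
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme
    vocab = config.motif_ids
    sets: dict[str, dict[str, list[MotifHit]]] = {"A": {}, "B": {}}
    labels: dict[str, str] = {}
    for cls in ("A", "B"):
        effects = [e for e in config.planted if e.enriched_class == cls]
        for i in range(config.n_per_class):
            pid = f"prom{cls}{i:04d}"
            labels[pid] = cls
            hits: list[MotifHit] = []
            for motif in vocab:
                n_bg = rng.poisson(config.background_rate)
                for start in rng.integers(0, config.promoter_length, size=n_bg):
                    hits.append(MotifHit(pid, motif, int(start)))
            for eff in effects:
                lo = eff.band_index * config.band_width
                hi = min(lo + config.band_width, config.promoter_length)
                n_extra = rng.poisson(eff.rate_delta)
                for start in rng.integers(lo, hi, size=n_extra):
                    hits.append(MotifHit(pid, eff.motif_id, int(start)))
            sets[cls][pid] = hits
    planted_names = tuple(
        f"{e.motif_id}:{scheme.band_label(e.band_index)}" for e in config.planted
    )
    truth = SynthTruth(
        planted_features=planted_names, effects=config.planted, labels=labels
    )
    return sets["A"], sets["B"], truth


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("promoter_id\tclass\n")
        for pid, cls in labels.items():
            fh.write(f"{pid}\t{cls}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["promoter_id", "class"]:
            raise ValueError("labels file must have columns promoter_id, class")
        for line in fh:
            if line.strip():
                pid, cls = line.rstrip("\n").split("\t")[:2]
                labels[pid] = cls
    return labels


def write_hit_files(
    set_a: dict[str, list[MotifHit]],
    set_b: dict[str, list[MotifHit]],
    out_dir: str | Path,
) -> tuple[Path, Path, Path]:
    """Write the two sets' hits and the label file under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    a_path, b_path = out / "set_a_hits.tsv", out / "set_b_hits.tsv"
    write_motif_hits([h for hits in set_a.values() for h in hits], a_path)
    write_motif_hits([h for hits in set_b.values() for h in hits], b_path)
    labels = {pid: "A" for pid in set_a} | {pid: "B" for pid in set_b}
    labels_path = out / "labels.tsv"
    write_labels(labels, labels_path)
    return a_path, b_path, labels_path
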