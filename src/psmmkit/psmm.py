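"""Position Specific Motif Matrices (PSMMs) and the two-set feature matrix.

A promoter is summarised as a matrix of motif occurrence counts by
positional band: rows are motifs, columns are fixed-width bands of the
promoter (50 bp by default, so a -2000..+500 window gives 50 bands).
Flattening the PSMM row-by-row gives the promoter's feature vector;
stacking the feature vectors of two labelled promoter sets gives the
feature matrix that feature selection and classification consume.

Bands are half-open intervals [b*w, (b+1)*w) and a hit is assigned to the
band containing its start position; the last band may be shorter when the
band width does not divide the promoter length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_io import MotifHit

__all__ = [
    "BandScheme",
    "PSMM",
    "FeatureSpace",
    "FeatureMatrix",
    "build_psmm",
    "flatten_psmm",
    "build_feature_matrix",
]


@dataclass(frozen=True)
class BandScheme:
    """Partition of a promoter into fixed-width positional bands."""

    promoter_length: int
    band_width: int = 50

    def __post_init__(self) -> None:
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be >= 1")

    @property
    def n_bands(self) -> int:
        return math.ceil(self.promoter_length / self.band_width)

    def band_of(self, start: int) -> int:
        """Band index containing a hit start; raises if out of range."""
        if not 0 <= start < self.promoter_length:
            raise ValueError(
                f"start {start} outside promoter [0, {self.promoter_length})"
            )
        return start // self.band_width

    def band_label(self, band: int) -> str:
        lo = band * self.band_width
        hi = min((band + 1) * self.band_width, self.promoter_length)
        return f"{lo}-{hi}"


@dataclass(frozen=True)
class PSMM:
    """Per-promoter motif x band occurrence-count matrix."""

    promoter_id: str
    motif_ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape[0] != len(self.motif_ids):
            raise ValueError("counts rows must match motif_ids")
        if (counts < 0).any():
            raise ValueError("PSMM counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total_hits(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FeatureSpace:
    """Ordered (motif_id, band_index) feature axis.

    Motifs are ordered lexicographically and bands ascending within each
    motif, so the axis is a deterministic function of the motif vocabulary
    and the band scheme.
    """

    motif_ids: tuple[str, ...]
    scheme: BandScheme

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.motif_ids))
        if len(set(ordered)) != len(ordered):
            raise ValueError("duplicate motif ids in feature space")
        object.__setattr__(self, "motif_ids", ordered)

    def __len__(self) -> int:
        return len(self.motif_ids) * self.scheme.n_bands

    @property
    def pairs(self) -> list[tuple[str, int]]:
        return [
            (motif, band)
            for motif in self.motif_ids
            for band in range(self.scheme.n_bands)
        ]

    @property
    def names(self) -> list[str]:
        return [
            f"{motif}:{self.scheme.band_label(band)}" for motif, band in self.pairs
        ]

    def index_of(self, motif_id: str, band: int) -> int:
        try:
            row = self.motif_ids.index(motif_id)
        except ValueError:
            raise KeyError(f"motif {motif_id!r} not in feature space") from None
        if not 0 <= band < self.scheme.n_bands:
            raise KeyError(f"band {band} outside 0..{self.scheme.n_bands - 1}")
        return row * self.scheme.n_bands + band


@dataclass
class FeatureMatrix:
    """Samples x (motif, band) count matrix with binary class labels."""

    sample_ids: list[str]
    labels: list[str]
    space: FeatureSpace
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if n != len(self.sample_ids) or n != len(self.labels):
            raise ValueError("rows must match sample_ids and labels")
        if p != len(self.space):
            raise ValueError("columns must match the feature space")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.labels)) > 2:
            raise ValueError("at most two class labels supported")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen

    def class_rows(self, label: str) -> np.ndarray:
        return np.array([i for i, lab in enumerate(self.labels) if lab == label])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.space.names)
        df.insert(0, "class", self.labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, band_width: int = 50) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        names = list(df.columns[2:])
        motifs = []
        promoter_length = 0
        for name in names:
            motif, band = name.rsplit(":", 1)
            if motif not in motifs:
                motifs.append(motif)
            promoter_length = max(promoter_length, int(band.split("-")[1]))
        scheme = BandScheme(promoter_length, band_width)
        space = FeatureSpace(tuple(motifs), scheme)
        if space.names != names:
            raise ValueError("feature columns are not in canonical order")
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            labels=df["class"].astype(str).tolist(),
            space=space,
            values=df[names].to_numpy(dtype=np.int64),
        )


def build_psmm(
    hits: Iterable[MotifHit],
    scheme: BandScheme,
    motif_ids: Sequence[str],
    promoter_id: str | None = None,
    strict: bool = True,
) -> PSMM:
    """Tally one promoter's hits into a motif x band count matrix.

    Each hit increments the cell (its motif, the band containing its start).
    In strict mode a start at or beyond the promoter length is an error;
    otherwise such hits are dropped.
    """
    motif_ids = tuple(motif_ids)
    row = {m: i for i, m in enumerate(motif_ids)}
    counts = np.zeros((len(motif_ids), scheme.n_bands), dtype=np.int64)
    pid = promoter_id
    for hit in hits:
        if pid is None:
            pid = hit.promoter_id
        if hit.motif_id not in row:
            raise ValueError(f"unknown motif {hit.motif_id!r} for {hit.promoter_id}")
        if hit.start >= scheme.promoter_length:
            if strict:
                raise ValueError(
                    f"hit at {hit.start} outside promoter {hit.promoter_id} "
                    f"(length {scheme.promoter_length})"
                )
            continue
        counts[row[hit.motif_id], scheme.band_of(hit.start)] += 1
    return PSMM(promoter_id=pid or "", motif_ids=motif_ids, counts=counts)


def flatten_psmm(psmm: PSMM, space: FeatureSpace) -> np.ndarray:
    """Concatenate PSMM rows into the promoter's feature vector.

    Motifs in the space but absent from the PSMM contribute zeros, so every
    promoter maps onto the same axis.
    """
    if psmm.counts.shape[1] != space.scheme.n_bands:
        raise ValueError("PSMM band count does not match feature space")
    vec = np.zeros(len(space), dtype=np.int64)
    n_bands = space.scheme.n_bands
    for i, motif in enumerate(psmm.motif_ids):
        j = space.motif_ids.index(motif) if motif in space.motif_ids else -1
        if j < 0:
            raise ValueError(f"motif {motif!r} absent from feature space")
        vec[j * n_bands : (j + 1) * n_bands] = psmm.counts[i]
    return vec


def build_feature_matrix(
    set_a: Mapping[str, list[MotifHit]],
    set_b: Mapping[str, list[MotifHit]],
    scheme: BandScheme,
    labels: tuple[str, str] = ("A", "B"),
    motif_ids: Sequence[str] | None = None,
    strict: bool = True,
) -> FeatureMatrix:
    """Stack two promoter sets' flattened PSMMs into one labelled matrix.

    The feature space is the union of motifs observed in either set unless
    ``motif_ids`` pins the vocabulary.  Rows appear set A first, preserving
    each set's input order.
    """
    if not set_a or not set_b:
        raise ValueError("two non-empty promoter sets required")
    overlap = set(set_a) & set(set_b)
    if overlap:
        raise ValueError(f"promoter ids shared across sets: {sorted(overlap)[:3]}")
    if motif_ids is None:
        observed: set[str] = set()
        for hits in list(set_a.values()) + list(set_b.values()):
            observed.update(h.motif_id for h in hits)
        motif_ids = sorted(observed)
    space = FeatureSpace(tuple(motif_ids), scheme)
    rows, sample_ids, row_labels = [], [], []
    for label, promoters in zip(labels, (set_a, set_b)):
        for pid, hits in promoters.items():
            psmm = build_psmm(hits, scheme, space.motif_ids, pid, strict=strict)
            rows.append(flatten_psmm(psmm, space))
            sample_ids.append(pid)
            row_labels.append(label)
    return FeatureMatrix(
        sample_ids=sample_ids,
        labels=row_labels,
        space=space,
        values=np.vstack(rows),
    )
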