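"""I/O for motif hits, promoter FASTA, and JASPAR position-frequency matrices.

Motif occurrences ("hits") are the unit of input for the whole pipeline:
one transcription-factor binding-site match at one position of one promoter.
They normally come from an external over-representation scanner, so the hit
table is treated as the stable interchange format; a simple log-odds scanner
is provided for convenience when only sequences and JASPAR profiles are at
hand.

Hit-table dialect: tab-separated with header
``promoter_id  motif_id  start  strand  score``, 0-based forward-strand
starts, strand in ``{+, -, .}``, empty score field for scoreless hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "MotifHit",
    "PFM",
    "MotifFileFormatError",
    "read_motif_hits",
    "write_motif_hits",
    "read_promoters",
    "read_jaspar_pfms",
    "scan_promoters",
]

HIT_COLUMNS = ("promoter_id", "motif_id", "start", "strand", "score")
REQUIRED_COLUMNS = ("promoter_id", "motif_id", "start")
STRANDS = ("+", "-", ".")

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class MotifFileFormatError(ValueError):
    """A hit table or PFM file violates its dialect."""


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on one promoter.

    ``start`` is a 0-based offset from the promoter's 5' end in bp, always
    in forward-strand coordinates regardless of the strand matched.
    """

    promoter_id: str
    motif_id: str
    start: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.promoter_id:
            raise ValueError("promoter_id must be non-empty")
        if not self.motif_id:
            raise ValueError("motif_id must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")


@dataclass(frozen=True)
class PFM:
    """A position-frequency matrix: 4 x L counts over rows A, C, G, T."""

    motif_id: str
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError("PFM counts must be a 4 x L matrix with L >= 1")
        if (counts < 0).any():
            raise ValueError("PFM counts must be non-negative")
        if not (counts.sum(axis=0) > 0).all():
            raise ValueError("every PFM column must have positive sum")
        object.__setattr__(self, "counts", counts)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def reverse_complement(self) -> "PFM":
        # reverse columns and swap A<->T, C<->G rows
        return PFM(self.motif_id, self.counts[::-1, ::-1].copy())


def read_motif_hits(path: str | Path) -> dict[str, list[MotifHit]]:
    """Read a hit table, grouping hits by promoter in file order.

    Returns an insertion-ordered mapping promoter_id -> hits.  Promoters
    with zero hits do not appear (they are representable via the label
    file downstream).
    """
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line:
            raise MotifFileFormatError(f"{path}: empty file, expected a header row")
        header = header_line.rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for required in REQUIRED_COLUMNS:
            if required not in col:
                raise MotifFileFormatError(
                    f"{path}: missing required column {required!r}"
                )
        grouped: dict[str, list[MotifHit]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(header):
                raise MotifFileFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            raw_start = fields[col["start"]]
            try:
                start = int(raw_start)
            except ValueError:
                raise MotifFileFormatError(
                    f"{path}:{lineno}: non-integer start {raw_start!r}"
                ) from None
            if start < 0:
                raise MotifFileFormatError(f"{path}:{lineno}: negative start {start}")
            strand = fields[col["strand"]] if "strand" in col else "."
            score: float | None = None
            if "score" in col and fields[col["score"]] != "":
                score = float(fields[col["score"]])
            try:
                hit = MotifHit(
                    promoter_id=fields[col["promoter_id"]],
                    motif_id=fields[col["motif_id"]],
                    start=start,
                    strand=strand,
                    score=score,
                )
            except ValueError as exc:
                raise MotifFileFormatError(f"{path}:{lineno}: {exc}") from None
            grouped.setdefault(hit.promoter_id, []).append(hit)
    return grouped


def write_motif_hits(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write hits in the tab-separated dialect; re-readable without loss."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for hit in hits:
            score = "" if hit.score is None else repr(hit.score)
            fh.write(
                f"{hit.promoter_id}\t{hit.motif_id}\t{hit.start}\t{hit.strand}\t{score}\n"
            )


def flatten_hits(grouped: Mapping[str, list[MotifHit]]) -> list[MotifHit]:
    """Concatenate grouped hits back into one list, preserving order."""
    return [hit for hits in grouped.values() for hit in hits]


def read_promoters(path: str | Path) -> dict[str, str]:
    """Read promoter sequences from a plain multi-record FASTA file."""
    return {
        record.id: str(record.seq).upper() for record in SeqIO.parse(str(path), "fasta")
    }


def read_jaspar_pfms(path: str | Path) -> list[PFM]:
    """Read JASPAR-format position-frequency matrices.

    Accepts the JASPAR text format: a ``>MA0041.1 NAME`` header followed by
    four labeled count rows (A, C, G, T).
    """
    with Path(path).open() as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pfms = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        motif_id = m.matrix_id if getattr(m, "matrix_id", None) else m.name
        pfms.append(PFM(motif_id=motif_id, counts=counts))
    return pfms


def _log_odds(pfm: PFM, pseudocount: float = 0.01) -> np.ndarray:
    """Per-cell log-odds against a uniform 0.25 background, in nats."""
    counts = pfm.counts + pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    return np.log(probs / 0.25)


def _encode(sequence: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N) to -1."""
    out = np.full(len(sequence), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(sequence))


def _scan_one_strand(
    encoded: np.ndarray, lods: np.ndarray, threshold: float
) -> list[tuple[int, float]]:
    """All window starts whose log-odds score meets the threshold.

    Windows containing any non-ACGT base never match.
    """
    L = lods.shape[1]
    n = encoded.size
    if L > n:
        return []
    out = []
    for start in range(n - L + 1):
        window = encoded[start : start + L]
        if (window < 0).any():
            continue
        score = float(lods[window, np.arange(L)].sum())
        if score >= threshold - 1e-12:
            out.append((start, score))
    return out


def scan_promoters(
    sequences: Mapping[str, str],
    pfms: Iterable[PFM],
    score_fraction: float,
    pseudocount: float = 0.01,
) -> list[MotifHit]:
    """Scan promoter sequences with PFMs on both strands.

    A hit is emitted at every window whose log-odds score (uniform 0.25
    background, ``pseudocount`` added to every PFM cell) reaches
    ``score_fraction`` times the maximum attainable score for that PFM.
    Reverse-strand matches are reported by their start on the forward
    coordinate system.
    """
    if not 0.0 <= score_fraction <= 1.0:
        raise ValueError(f"score_fraction must be in [0, 1], got {score_fraction}")
    hits: list[MotifHit] = []
    encoded_seqs = {pid: _encode(seq) for pid, seq in sequences.items()}
    for pfm in pfms:
        lods_fwd = _log_odds(pfm, pseudocount)
        lods_rev = _log_odds(pfm.reverse_complement(), pseudocount)
        max_score = float(lods_fwd.max(axis=0).sum())
        threshold = score_fraction * max_score
        for pid, encoded in encoded_seqs.items():
            for start, score in _scan_one_strand(encoded, lods_fwd, threshold):
                hits.append(MotifHit(pid, pfm.motif_id, start, "+", score))
            for start, score in _scan_one_strand(encoded, lods_rev, threshold):
                hits.append(MotifHit(pid, pfm.motif_id, start, "-", score))
    return hits
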