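"""Motif and promoter input/output.

Establishes the identifier and coordinate conventions used by the whole
pipeline: JASPAR-format position frequency matrices become :class:`PWM`
objects (counts -> probabilities with a per-cell pseudocount), and promoters
are held as a 1:1 ``gene_id -> sequence`` map with optional BED-style
(0-based, half-open) genomic coordinates.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

logger = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
UNIFORM_BACKGROUND = np.full(4, 0.25)

_ALLOWED = frozenset("ACGTN")


class MotifParseError(ValueError):
    """Raised when a motif file cannot be parsed into valid count matrices."""


def _open_text(path) -> IO[str]:
    """Open a possibly gzip-compressed text file for reading."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _check_background(background) -> np.ndarray:
    bg = np.asarray(
        UNIFORM_BACKGROUND if background is None else background, dtype=float
    )
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9) or (bg <= 0).any():
        raise ValueError("background must be 4 positive probabilities summing to 1")
    return bg


@dataclass
class PWM:
    """Position probability matrix for one transcription factor.

    ``probs`` has one row per motif position over columns (A, C, G, T); every
    row sums to 1 and all entries are strictly positive (guaranteed by the
    pseudocount).  ``counts`` keeps the original count matrix when the PWM was
    built from one, so count output round-trips.
    """

    tf_id: str
    probs: np.ndarray
    pseudocount: float = 1.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    counts: Optional[np.ndarray] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = _check_background(self.background)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"PWM {self.tf_id!r}: probs must be a width x 4 matrix")
        if self.pseudocount < 0:
            raise ValueError(f"PWM {self.tf_id!r}: pseudocount must be nonnegative")
        if (self.probs <= 0).any():
            raise ValueError(f"PWM {self.tf_id!r}: all probabilities must be positive")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.tf_id!r}: rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=1))

    @classmethod
    def from_counts(
        cls,
        tf_id: str,
        counts,
        pseudocount: float = 1.0,
        background=None,
        name: str = "",
    ) -> "PWM":
        """Build a PWM from a 4-column count matrix, add-then-normalize."""
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise MotifParseError(f"record {tf_id!r}: counts must be width x 4")
        if (counts < 0).any():
            raise MotifParseError(f"record {tf_id!r}: negative counts")
        padded = counts + pseudocount
        row_sums = padded.sum(axis=1)
        if (row_sums == 0).any():
            raise MotifParseError(
                f"record {tf_id!r}: zero-count column with zero pseudocount"
            )
        return cls(
            tf_id=tf_id,
            probs=padded / row_sums[:, None],
            pseudocount=pseudocount,
            background=background,
            counts=counts,
            name=name,
        )

    def to_counts(self) -> np.ndarray:
        """Recover a count matrix: probabilities scaled back to the original
        per-position totals with the pseudocount removed."""
        if self.counts is not None:
            totals = self.counts.sum(axis=1) + 4 * self.pseudocount
        else:
            totals = np.full(self.width, 100.0)
        return self.probs * totals[:, None] - self.pseudocount

    def log_odds(self, background=None) -> np.ndarray:
        """width x 4 matrix of ln(p / background)."""
        bg = _check_background(self.background if background is None else background)
        return np.log(self.probs) - np.log(bg)[None, :]

    def reverse_complement(self) -> "PWM":
        rc_probs = self.probs[::-1, ::-1].copy()
        rc_counts = None if self.counts is None else self.counts[::-1, ::-1].copy()
        return PWM(
            tf_id=self.tf_id,
            probs=rc_probs,
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
            counts=rc_counts,
            name=self.name,
        )


def read_jaspar(path, pseudocount: float = 1.0, background=None) -> list[PWM]:
    """Read JASPAR-format PFM records (one or many) into PWMs.

    Counts are converted to probabilities with ``pseudocount`` added to every
    cell before row normalization; record order is preserved and the id is the
    first header token.
    """
    with _open_text(path) as handle:
        text = handle.read()
    n_headers = sum(1 for line in text.splitlines() if line.startswith(">"))
    import io

    try:
        records = bio_motifs.parse(io.StringIO(text), "jaspar")
    except Exception as exc:  # biopython raises bare Exception on ragged rows
        raise MotifParseError(f"{path}: {exc}") from exc
    if n_headers != len(records):
        raise MotifParseError(
            f"{path}: {n_headers} headers but {len(records)} parseable matrices "
            "(malformed record, e.g. wrong row count)"
        )
    pwms = []
    for rec in records:
        tf_id = rec.matrix_id or rec.name
        counts = np.array([rec.counts[b] for b in BASES], dtype=float).T
        pwms.append(
            PWM.from_counts(
                tf_id,
                counts,
                pseudocount=pseudocount,
                background=background,
                name=rec.name or "",
            )
        )
    ids = [p.tf_id for p in pwms]
    if len(set(ids)) != len(ids):
        raise MotifParseError(f"{path}: duplicate motif ids")
    return pwms


def write_jaspar(pwms: Iterable[PWM], path) -> None:
    """Write PWMs back to JASPAR count form (bracketed rows)."""
    with open(path, "wt") as out:
        for pwm in pwms:
            counts = pwm.to_counts()
            out.write(f">{pwm.tf_id} {pwm.name or pwm.tf_id}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{c:.2f}".rstrip("0").rstrip(".") for c in counts[:, bi])
                out.write(f"{base} [ {row} ]\n")


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"gene {self.gene_id!r}: non-ACGTN characters {sorted(bad)!r}"
            )
        if self.start is not None and self.end is not None:
            if self.end - self.start != len(self.sequence):
                raise ValueError(
                    f"gene {self.gene_id!r}: coordinate span does not match "
                    "sequence length"
                )


@dataclass
class PromoterSet:
    """Mapping of gene id to promoter sequence (unique ids, uppercase)."""

    records: dict[str, PromoterRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    @property
    def gene_ids(self) -> list[str]:
        return list(self.records)

    def sequence(self, gene_id: str) -> str:
        return self.records[gene_id].sequence

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "PromoterSet":
        return cls(
            records={g: PromoterRecord(g, s) for g, s in sequences.items()}
        )

    @classmethod
    def from_fasta(cls, path) -> "PromoterSet":
        records: dict[str, PromoterRecord] = {}
        with _open_text(path) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                if rec.id in records:
                    logger.warning("duplicate gene id %s in %s: first wins", rec.id, path)
                    continue
                records[rec.id] = PromoterRecord(rec.id, str(rec.seq))
        return cls(records=records)

    def to_fasta(self, path) -> None:
        with open(path, "wt") as out:
            for rec in self.records.values():
                out.write(f">{rec.gene_id}\n{rec.sequence}\n")


def _parse_bed6(path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with _open_text(path) as handle:
        for ln, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{ln}: BED6 needs 6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in "+-":
                raise ValueError(f"{path}:{ln}: strand must be + or -")
            rows.append((chrom, int(start), int(end), name, strand))
    return rows


def extract_promoters(
    genome,
    tss_bed,
    upstream: int = 500,
    downstream: int = 0,
) -> PromoterSet:
    """Extract promoter windows around TSSs from a genome FASTA.

    The BED start coordinate is taken as the TSS.  Plus-strand genes get the
    window ``[tss - upstream, tss + downstream)``; minus-strand genes get the
    mirrored window ``[tss - downstream, tss + upstream)`` reverse-complemented
    so that position 0 of the output is farthest upstream.  Windows past a
    contig boundary are truncated with a warning; genes on contigs absent from
    the genome are skipped with a warning; duplicate gene ids keep the first
    occurrence.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be nonnegative")
    from pyfaidx import Fasta

    fa = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
    records: dict[str, PromoterRecord] = {}
    for chrom, bed_start, _bed_end, gene_id, strand in _parse_bed6(tss_bed):
        if gene_id in records:
            logger.warning("duplicate gene id %s in %s: first wins", gene_id, tss_bed)
            continue
        if chrom not in fa:
            logger.warning("gene %s: contig %s absent from genome, skipped", gene_id, chrom)
            continue
        contig_len = len(fa[chrom])
        tss = bed_start
        if strand == "+":
            lo, hi = tss - upstream, tss + downstream
        else:
            lo, hi = tss - downstream, tss + upstream
        clo, chi = max(lo, 0), min(hi, contig_len)
        if (clo, chi) != (lo, hi):
            logger.warning(
                "gene %s: window [%d, %d) truncated to [%d, %d)", gene_id, lo, hi, clo, chi
            )
        if chi <= clo:
            logger.warning("gene %s: empty window after truncation, skipped", gene_id)
            continue
        seq = str(fa[chrom][clo:chi])
        if strand == "-":
            seq = reverse_complement(seq)
        records[gene_id] = PromoterRecord(
            gene_id, seq, chrom=chrom, start=clo, end=chi, strand=strand
        )
    return PromoterSet(records=records)
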