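"""Biophysical promoter-affinity scoring and per-factor gene ranking.

Each promoter/motif pair gets a continuous occupancy score: the sum over all
sequence windows on both strands of ``R*K_w / (1 + R*K_w)`` where
``K_w = exp((llr_w - llr_max) / lam)``, ``llr_w`` is the log-likelihood ratio
of the window under the motif versus the background, and ``llr_max`` is the
consensus (best-window) log-likelihood ratio.  ``K_w`` is the mismatch
penalty relative to the consensus site -- the scale on which the
width-derived default ``R`` is calibrated -- and no hard site/non-site cut is
made.  Scores are accumulated through the logistic function of
``ln(R) + (llr_w - llr_max) / lam``, so strong sites cannot overflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from tfcobind.motifs import PWM, PromoterSet

logger = logging.getLogger(__name__)

# sentinel log-ratio for N: forces the occupancy of any window touching an N
# to underflow to exactly 0 after the logistic
_N_PENALTY = -1e9


@dataclass
class AffinityParams:
    """Configuration of the occupancy model.

    ``lam`` scales the mismatch energy; ``r0`` is the binding constant at the
    consensus-neutral point.  When ``r0`` is None it is derived from the motif
    width as ``exp(0.584 * width - 5.66)``.  These defaults are conventional
    choices, configurable throughout.
    """

    lam: float = 0.7
    r0: Optional[float] = None
    background: Optional[np.ndarray] = None

    def r_for(self, pwm: PWM) -> float:
        if self.r0 is not None:
            if self.r0 <= 0:
                raise ValueError("r0 must be positive")
            return float(self.r0)
        return math.exp(0.584 * pwm.width - 5.66)


_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_ENCODE[ord("N")] = 4


def encode_sequence(seq: str) -> np.ndarray:
    """Map an ACGTN string to integer codes 0..4."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains non-ACGTN characters")
    return arr


def _llr5(pwm: PWM, background) -> np.ndarray:
    """width x 5 log-ratio lookup with the N column set to a hard penalty."""
    lo = pwm.log_odds(background)
    out = np.full((pwm.width, 5), _N_PENALTY, dtype=float)
    out[:, :4] = lo
    return out


def _window_llrs(enc: np.ndarray, llr5: np.ndarray) -> np.ndarray:
    """Log-likelihood ratio of every window of ``len(llr5)`` along ``enc``."""
    w = llr5.shape[0]
    n_win = enc.size - w + 1
    acc = np.zeros(n_win)
    for i in range(w):
        acc += llr5[i, enc[i : i + n_win]]
    return acc


def _consensus_llr(pwm: PWM, background) -> float:
    """Log-likelihood ratio of the best (consensus) window."""
    return float(pwm.log_odds(background).max(axis=1).sum())


def _occupancy_sum(enc: np.ndarray, pwm: PWM, params: AffinityParams) -> float:
    w = pwm.width
    if enc.size < w:
        return 0.0
    bg = params.background if params.background is not None else pwm.background
    log_r = math.log(params.r_for(pwm))
    llr_max = _consensus_llr(pwm, bg)
    total = 0.0
    for m in (pwm, pwm.reverse_complement()):
        llrs = _window_llrs(enc, _llr5(m, bg))
        total += float(expit(log_r + (llrs - llr_max) / params.lam).sum())
    return total


def score_affinity(
    promoters: PromoterSet, pwm: PWM, params: Optional[AffinityParams] = None
) -> dict[str, float]:
    """Occupancy score of every promoter for one motif (both strands).

    Windows containing N contribute 0; promoters shorter than the motif get
    score 0 with a warning.
    """
    params = params or AffinityParams()
    scores: dict[str, float] = {}
    warned_short = 0
    for gene_id, rec in promoters.records.items():
        enc = encode_sequence(rec.sequence)
        if enc.size < pwm.width:
            warned_short += 1
            scores[gene_id] = 0.0
            continue
        scores[gene_id] = _occupancy_sum(enc, pwm, params)
    if warned_short:
        logger.warning(
            "motif %s: %d promoters shorter than width %d scored 0",
            pwm.tf_id,
            warned_short,
            pwm.width,
        )
    return scores


@dataclass
class AffinityTable:
    """genes x factors matrix of nonnegative affinity scores."""

    genes: list[str]
    tfs: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.tfs)):
            raise ValueError("values shape must be (len(genes), len(tfs))")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.tfs)) != len(self.tfs):
            raise ValueError("duplicate tf ids")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("affinities must be finite and nonnegative")

    def column(self, tf_id: str) -> dict[str, float]:
        j = self.tfs.index(tf_id)
        return dict(zip(self.genes, self.values[:, j]))

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.genes, columns=self.tfs)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "AffinityTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            tfs=[str(t) for t in df.columns],
            values=df.to_numpy(dtype=float),
        )


def score_matrix(
    promoters: PromoterSet,
    pwms: Sequence[PWM],
    params: Optional[AffinityParams] = None,
) -> AffinityTable:
    """Score every promoter with every motif.

    Vectorized across promoters: sequences are padded with N (which can only
    lower nothing -- padded windows touch an N and score exactly 0), so one
    matrix pass per motif and strand suffices.
    """
    params = params or AffinityParams()
    genes = promoters.gene_ids
    seqs = [promoters.sequence(g) for g in genes]
    max_len = max((len(s) for s in seqs), default=0)
    enc_mat = np.full((len(genes), max_len), 4, dtype=np.int8)
    for i, s in enumerate(seqs):
        enc_mat[i, : len(s)] = encode_sequence(s)

    values = np.zeros((len(genes), len(pwms)))
    for j, pwm in enumerate(pwms):
        w = pwm.width
        if max_len < w:
            logger.warning("motif %s wider than every promoter; all scores 0", pwm.tf_id)
            continue
        bg = params.background if params.background is not None else pwm.background
        log_r = math.log(params.r_for(pwm))
        llr_max = _consensus_llr(pwm, bg)
        n_win = max_len - w + 1
        for m in (pwm, pwm.reverse_complement()):
            llr5 = _llr5(m, bg)
            acc = np.zeros((len(genes), n_win))
            for i in range(w):
                acc += llr5[i, enc_mat[:, i : i + n_win]]
            values[:, j] += expit(log_r + (acc - llr_max) / params.lam).sum(axis=1)
        short = [g for g, s in zip(genes, seqs) if len(s) < w]
        if short:
            logger.warning(
                "motif %s: %d promoters shorter than width %d scored 0",
                pwm.tf_id,
                len(short),
                w,
            )
    return AffinityTable(genes=genes, tfs=[p.tf_id for p in pwms], values=values)


@dataclass
class RankedTargets:
    """Genes ordered by decreasing affinity for one factor.

    Ties are broken lexicographically by gene id, so the ordering is a pure
    function of the score mapping.
    """

    tf_id: str
    genes: list[str]
    affinities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.affinities = np.asarray(self.affinities, dtype=float)
        if len(self.genes) != self.affinities.size:
            raise ValueError("genes and affinities must be parallel")
        if (np.diff(self.affinities) > 0).any():
            raise ValueError("affinities must be non-increasing")

    def top(self, k: int) -> list[str]:
        return self.genes[:k]


def rank_targets(tf_id: str, scores: Mapping[str, float]) -> RankedTargets:
    items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedTargets(
        tf_id=tf_id,
        genes=[g for g, _ in items],
        affinities=np.array([v for _, v in items]),
    )


def build_ranked_lists(table: AffinityTable) -> dict[str, RankedTargets]:
    """One ranked target list per factor; deterministic across input orders."""
    out = {}
    for j, tf_id in enumerate(table.tfs):
        out[tf_id] = rank_targets(tf_id, dict(zip(table.genes, table.values[:, j])))
    return out


def ranked_lists_to_tsv(lists: Mapping[str, RankedTargets], path) -> None:
    rows = []
    for tf_id in sorted(lists):
        rt = lists[tf_id]
        for rank, (g, a) in enumerate(zip(rt.genes, rt.affinities), 1):
            rows.append((tf_id, rank, g, a))
    df = pd.DataFrame(rows, columns=["tf_id", "rank", "gene_id", "affinity"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def ranked_lists_from_tsv(path) -> dict[str, RankedTargets]:
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str, "gene_id": str})
    out = {}
    for tf_id, grp in df.groupby("tf_id", sort=True):
        grp = grp.sort_values("rank")
        out[str(tf_id)] = RankedTargets(
            tf_id=str(tf_id),
            genes=[str(g) for g in grp["gene_id"]],
            affinities=grp["affinity"].to_numpy(),
        )
    return out
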