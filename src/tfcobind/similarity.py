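"""Motif-motif similarity and the similar-motif confounder filter.

Two near-identical motifs produce near-identical ranked target lists, so
their rank overlap is an artifact rather than evidence of cooperation.  The
similarity score used here is a log-odds-of-overlap statistic: each motif is
given a score threshold reaching a fixed per-window hit probability under the
background, and the statistic is the maximum over relative offsets and strand
combinations of

    ln P(motif A hits at 0  and  motif B hits at offset s)
       ----------------------------------------------------
              P(A hits) * P(B hits)

with offsets limited to |s| <= (width_a + width_b) / 2.  Hit probabilities
are computed by exact enumeration when the combined width allows it and by
seeded Monte Carlo otherwise.  Identical motifs score ln(1 / hit_p); motifs
whose hits are independent at some offset score ~0.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from tfcobind.motifs import PWM, _check_background

logger = logging.getLogger(__name__)

# exact enumeration bounds: per-motif 4^w score tables and combined width
_MAX_EXACT_WIDTH = 10
_MAX_EXACT_TOTAL = 16

# hit events are "score >= threshold" on discrete score distributions where
# ties carry real mass; all comparisons use this slack so that differently
# rounded partial sums classify tied words identically
_SCORE_TOL = 1e-9


def _enumerate_scores(lo: np.ndarray, bg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores and background probabilities of all 4^w words, in a fixed
    accumulation order so equal partial sums are bit-identical elsewhere."""
    scores = np.zeros(1)
    weights = np.ones(1)
    for row in lo:
        scores = (scores[:, None] + row[None, :]).ravel()
        weights = (weights[:, None] * bg[None, :]).ravel()
    return scores, weights


def _tail_function(scores: np.ndarray, weights: np.ndarray):
    """Return f(x) = P(score >= x) as a vectorized callable."""
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    suffix = np.concatenate([np.cumsum(weights[order][::-1])[::-1], [0.0]])

    def tail(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(s_sorted, np.asarray(x) - _SCORE_TOL, side="left")
        return suffix[idx]

    return tail


def _hit_threshold(
    scores: np.ndarray, weights: np.ndarray, hit_p: float
) -> tuple[float, float]:
    """Smallest threshold whose inclusive tail probability is <= hit_p.

    Returns (threshold, actual tail probability); the actual tail is what the
    statistic's denominator uses, so discreteness never biases the ratio.
    """
    uv, inv = np.unique(scores, return_inverse=True)
    uw = np.zeros(uv.size)
    np.add.at(uw, inv, weights)
    tails = np.cumsum(uw[::-1])[::-1]  # tails[j] = P(score >= uv[j])
    ok = np.nonzero(tails <= hit_p)[0]
    j = int(ok[0]) if ok.size else int(uv.size - 1)
    return float(uv[j]), float(tails[j])


@dataclass
class _Channel:
    """One motif read on one strand: log-odds rows, threshold, hit prob."""

    lo: np.ndarray
    threshold: float
    hit_p: float
    exact: bool


def _make_channels(
    pwm: PWM, bg: np.ndarray, hit_p: float, n_mc: int, rng: np.random.Generator
) -> dict[str, _Channel]:
    if (pwm.probs >= 1 - 1e-12).any():
        logger.warning("motif %s: degenerate column (entry ~1), proceeding", pwm.tf_id)
    channels = {}
    for strand, m in (("+", pwm), ("-", pwm.reverse_complement())):
        lo = np.log(m.probs) - np.log(bg)[None, :]
        if pwm.width <= _MAX_EXACT_WIDTH:
            scores, weights = _enumerate_scores(lo, bg)
            t, p = _hit_threshold(scores, weights, hit_p)
            channels[strand] = _Channel(lo, t, p, exact=True)
        else:
            words = rng.choice(4, size=(n_mc, pwm.width), p=bg)
            scores = lo[np.arange(pwm.width)[None, :], words].sum(axis=1)
            t, p = _hit_threshold(scores, np.full(n_mc, 1.0 / n_mc), hit_p)
            channels[strand] = _Channel(lo, t, p, exact=False)
    return channels


def _exact_joint(ca: _Channel, cb: _Channel, shift: int, bg: np.ndarray) -> float:
    """Exact P(A hits at 0 and B hits at `shift`) for overlapping footprints.

    Factorizes over the shared bases: enumerate the overlap region, and fold
    in the tail distribution of each motif's private positions.
    """
    wa, wb = ca.lo.shape[0], cb.lo.shape[0]
    lo_ov, hi_ov = max(0, shift), min(wa, shift + wb)
    ov_a = ca.lo[lo_ov:hi_ov]
    ov_b = cb.lo[lo_ov - shift : hi_ov - shift]
    qa, wts = _enumerate_scores(ov_a, bg)
    qb, _ = _enumerate_scores(ov_b, bg)

    rest_a = np.concatenate([ca.lo[:lo_ov], ca.lo[hi_ov:]])
    rest_b = np.concatenate([cb.lo[: lo_ov - shift], cb.lo[hi_ov - shift :]])
    tail_a = _tail_function(*_enumerate_scores(rest_a, bg))
    tail_b = _tail_function(*_enumerate_scores(rest_b, bg))
    return float(np.sum(wts * tail_a(ca.threshold - qa) * tail_b(cb.threshold - qb)))


def _mc_joint(
    ca: _Channel,
    cb: _Channel,
    shift: int,
    bg: np.ndarray,
    n_mc: int,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Monte Carlo P(A hits at 0 and B hits at `shift`); returns (p_hat, hits)."""
    wa, wb = ca.lo.shape[0], cb.lo.shape[0]
    start, stop = min(0, shift), max(wa, shift + wb)
    span = stop - start
    mat = rng.choice(4, size=(n_mc, span), p=bg)
    idx_a = np.arange(wa)
    idx_b = np.arange(wb)
    sa = ca.lo[idx_a[None, :], mat[:, -start : -start + wa]].sum(axis=1)
    sb = cb.lo[idx_b[None, :], mat[:, shift - start : shift - start + wb]].sum(axis=1)
    hits = int(
        np.count_nonzero(
            (sa >= ca.threshold - _SCORE_TOL) & (sb >= cb.threshold - _SCORE_TOL)
        )
    )
    return hits / n_mc, hits


def smax_similarity(
    a: PWM,
    b: PWM,
    background=None,
    hit_p: float = 0.01,
    method: str = "auto",
    n_mc: int = 200_000,
    seed: int = 0,
    return_se: bool = False,
):
    """Log-odds-of-overlapping-hits similarity of two motifs (both strands).

    ``method`` is "auto" (exact when combined width <= 16, Monte Carlo
    otherwise), "exact", or "mc".  The value is symmetric in (a, b) and
    invariant under reverse-complementing both motifs.  With ``return_se`` a
    ``(value, se)`` tuple is returned; the se is 0 for exact evaluation.
    """
    if not 0 < hit_p < 0.5:
        raise ValueError("hit_p must lie in (0, 0.5)")
    if a.tf_id > b.tf_id:  # canonical order: keeps MC estimates symmetric
        a, b = b, a
    bg = _check_background(background)
    exact = {"auto": a.width + b.width <= _MAX_EXACT_TOTAL, "exact": True, "mc": False}[
        method
    ]
    if exact and (a.width > _MAX_EXACT_WIDTH or b.width > _MAX_EXACT_WIDTH):
        raise ValueError("motifs too wide for exact enumeration; use method='mc'")
    rng = np.random.default_rng(
        [seed, zlib.crc32(a.tf_id.encode()), zlib.crc32(b.tf_id.encode())]
    )
    chan_a = _make_channels(a, bg, hit_p, n_mc, rng)
    chan_b = _make_channels(b, bg, hit_p, n_mc, rng)

    d = (a.width + b.width) // 2
    best = -np.inf
    best_hits = None
    for shift in range(-d, d + 1):
        disjoint = shift >= a.width or shift + b.width <= 0
        for ca, cb in itertools.product(chan_a.values(), chan_b.values()):
            if disjoint:
                p_joint, hits = ca.hit_p * cb.hit_p, None
            elif exact:
                p_joint, hits = _exact_joint(ca, cb, shift, bg), None
            else:
                p_joint, hits = _mc_joint(ca, cb, shift, bg, n_mc, rng)
            if p_joint <= 0:
                continue
            val = float(np.log(p_joint / (ca.hit_p * cb.hit_p)))
            if val > best:
                best, best_hits = val, hits
    if return_se:
        se = 0.0
        if best_hits is not None and best_hits > 0:
            se = float(np.sqrt((1 - best_hits / n_mc) / best_hits))
        elif best_hits == 0:
            se = float("inf")
        return best, se
    return best


@dataclass
class SimilarityMatrix:
    """Symmetric factor-by-factor similarity values."""

    tfs: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.tfs)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over tfs")
        if len(set(self.tfs)) != n:
            raise ValueError("duplicate tf ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        diag = np.diag(self.values)
        if (self.values > diag[:, None] + 1e-9).any():
            raise ValueError("self-similarity must be the row maximum")

    def value(self, tf_a: str, tf_b: str) -> float:
        try:
            i, j = self.tfs.index(tf_a), self.tfs.index(tf_b)
        except ValueError as exc:
            raise ValueError(f"tf missing from similarity matrix: {exc}") from exc
        return float(self.values[i, j])

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.tfs), k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.tfs, columns=self.tfs)
        df.index.name = "tf_id"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(tfs=[str(t) for t in df.columns], values=df.to_numpy(dtype=float))


def build_similarity_matrix(
    pwms: Sequence[PWM],
    background=None,
    hit_p: float = 0.01,
    method: str = "auto",
    n_mc: int = 200_000,
    seed: int = 0,
) -> SimilarityMatrix:
    n = len(pwms)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            values[i, j] = values[j, i] = smax_similarity(
                pwms[i],
                pwms[j],
                background=background,
                hit_p=hit_p,
                method=method,
                n_mc=n_mc,
                seed=seed,
            )
    return SimilarityMatrix(tfs=[p.tf_id for p in pwms], values=values)


def filter_by_similarity(pairs, sim: SimilarityMatrix, cutoff: float = 4.0):
    """Split pair results into (kept, flagged) by motif similarity.

    Kept pairs have similarity strictly below ``cutoff``; the rest are
    returned annotated, never dropped.  Every result comes back as a copy with
    its ``similarity`` and ``similar_flag`` fields filled in.
    """
    missing = {t for p in pairs for t in (p.tf_a, p.tf_b) if t not in sim.tfs}
    if missing:
        raise ValueError(f"tf(s) missing from similarity matrix: {sorted(missing)}")
    kept, flagged = [], []
    for p in pairs:
        s = sim.value(p.tf_a, p.tf_b)
        annotated = replace(p, similarity=s, similar_flag=bool(s >= cutoff))
        (flagged if s >= cutoff else kept).append(annotated)
    return kept, flagged


def quantile_cutoff(sim: SimilarityMatrix, q: float) -> float:
    """Empirical q-quantile of off-diagonal similarities (linear interpolation)."""
    if not 0 < q < 1:
        raise ValueError("q must lie strictly in (0, 1)")
    if len(sim.tfs) < 2:
        raise ValueError("need at least 2 tfs")
    return float(np.quantile(sim.upper_triangle(), q))
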