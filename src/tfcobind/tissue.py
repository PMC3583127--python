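"""Tissue-coupled co-targeting test in 2x2x2 contingency tables.

Genes are cross-classified by membership in the top-L target set of each of
two factors (X, Y) and in a tissue-specific gene set (Z).  The null of
interest is partial independence of the composite XY from Z: expected counts
are ``mu_hat[x, y, z] = mu[+, +, z] * mu[x, y, +] / n``, and the G-statistic

    G = 2 * sum mu * ln(mu / mu_hat)

is referred to chi-square with 3 degrees of freedom.  A pair is only *called*
in a tissue when the triple-positive cell exceeds its expectation, matching
the directional question being asked; the omnibus statistic itself is left
untouched.

Mutual-independence (df 4) and conditional-independence (df 2) variants of
the same G-test are provided for completeness but are not used for calling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from tfcobind.affinity import RankedTargets
from tfcobind.pairscan import enumerate_pairs
from tfcobind.similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)

# array axis convention: index 0 = "in" (top-ranked / tissue-specific),
# index 1 = "out"; mu[0, 0, 0] is the triple-positive cell
_IN, _OUT = 0, 1


@dataclass
class ThreeWayTable:
    """2x2x2 counts over (top-L1 membership, top-L2 membership, tissue)."""

    mu: np.ndarray
    labels: tuple[str, str, str] = ("tf_a", "tf_b", "tissue")

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu)
        if self.mu.shape != (2, 2, 2):
            raise ValueError("mu must be a 2x2x2 array")
        if (self.mu < 0).any() or not np.issubdtype(self.mu.dtype, np.integer):
            raise ValueError("mu must hold nonnegative integer counts")
        self.mu = self.mu.astype(np.int64)

    @property
    def n(self) -> int:
        return int(self.mu.sum())

    @property
    def xy_marginal(self) -> np.ndarray:
        return self.mu.sum(axis=2)

    @property
    def z_marginal(self) -> np.ndarray:
        return self.mu.sum(axis=(0, 1))

    @property
    def observed_111(self) -> int:
        return int(self.mu[_IN, _IN, _IN])

    def swapped(self) -> "ThreeWayTable":
        """Table with the two factor axes exchanged."""
        return ThreeWayTable(
            mu=self.mu.transpose(1, 0, 2).copy(),
            labels=(self.labels[1], self.labels[0], self.labels[2]),
        )


def build_table(
    top_a: Iterable[str],
    top_b: Iterable[str],
    tissue_genes: Iterable[str],
    universe: Iterable[str],
    labels: tuple[str, str, str] = ("tf_a", "tf_b", "tissue"),
) -> ThreeWayTable:
    """Cross-classify every universe gene by the three memberships.

    Tissue genes absent from the universe are dropped with a logged count;
    top sets must be subsets of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    top_a, top_b, tissue = set(top_a), set(top_b), set(tissue_genes)
    for name, s in (("top_a", top_a), ("top_b", top_b)):
        extra = s - universe
        if extra:
            raise ValueError(f"{name} contains {len(extra)} genes outside the universe")
    dropped = tissue - universe
    if dropped:
        logger.warning(
            "tissue %s: %d gene(s) outside the universe dropped", labels[2], len(dropped)
        )
        tissue &= universe
    mu = np.zeros((2, 2, 2), dtype=np.int64)
    for g in universe:
        x = _IN if g in top_a else _OUT
        y = _IN if g in top_b else _OUT
        z = _IN if g in tissue else _OUT
        mu[x, y, z] += 1
    return ThreeWayTable(mu=mu, labels=labels)


def expected_partial_independence(t: ThreeWayTable) -> np.ndarray:
    """Expected cell counts under independence of the composite XY from Z.

    Exactly preserves the total, every xy two-way marginal, and the z
    marginal of the observed table.
    """
    n = t.n
    if n <= 0:
        raise ValueError("table total must be positive")
    return t.xy_marginal[:, :, None] * t.z_marginal[None, None, :] / n


def _g_statistic(mu: np.ndarray, mu_hat: np.ndarray) -> float:
    mask = mu > 0
    if (mu_hat[mask] <= 0).any():
        raise RuntimeError(
            "internal inconsistency: observed count in a cell with zero expectation"
        )
    return float(2.0 * np.sum(mu[mask] * np.log(mu[mask] / mu_hat[mask])))


@dataclass
class TissueTestResult:
    """Outcome of one 2x2x2 independence test."""

    labels: tuple[str, str, str]
    g_stat: float
    df: int
    log10_p: float
    observed_111: int
    expected_111: float
    enriched: bool
    similarity: Optional[float] = None
    similar_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.g_stat < -1e-12:
            raise ValueError("g_stat must be nonnegative")
        if self.log10_p > 0:
            raise ValueError("log10 p must be <= 0")
        if self.enriched and self.observed_111 <= self.expected_111:
            raise ValueError("enriched requires observed_111 > expected_111")

    @property
    def tf_a(self) -> str:
        return self.labels[0]

    @property
    def tf_b(self) -> str:
        return self.labels[1]

    @property
    def tissue(self) -> str:
        return self.labels[2]


def _finish_test(t: ThreeWayTable, mu_hat: np.ndarray, df: int) -> TissueTestResult:
    g = max(0.0, _g_statistic(t.mu, mu_hat))
    log10_p = min(0.0, float(chi2.logsf(g, df)) / _LN10)
    expected_111 = float(mu_hat[_IN, _IN, _IN])
    observed_111 = t.observed_111
    return TissueTestResult(
        labels=t.labels,
        g_stat=g,
        df=df,
        log10_p=log10_p,
        observed_111=observed_111,
        expected_111=expected_111,
        enriched=bool(observed_111 > expected_111),
    )


def partial_independence_test(t: ThreeWayTable) -> TissueTestResult:
    """G-test of the composite XY against Z; chi-square, 3 degrees of freedom."""
    return _finish_test(t, expected_partial_independence(t), df=3)


def mutual_independence_test(t: ThreeWayTable) -> TissueTestResult:
    """G-test of full mutual independence of X, Y, Z (df 4).  Not used for
    interaction calling."""
    n = t.n
    mx = t.mu.sum(axis=(1, 2))
    my = t.mu.sum(axis=(0, 2))
    mz = t.z_marginal
    mu_hat = mx[:, None, None] * my[None, :, None] * mz[None, None, :] / n**2
    return _finish_test(t, mu_hat, df=4)


def conditional_independence_test(t: ThreeWayTable) -> TissueTestResult:
    """G-test of X independent of Y within each Z layer (df 2).  Not used for
    interaction calling."""
    mxz = t.mu.sum(axis=1)  # (x, z)
    myz = t.mu.sum(axis=0)  # (y, z)
    mz = t.z_marginal.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_hat = mxz[:, None, :] * myz[None, :, :] / mz[None, None, :]
    mu_hat = np.nan_to_num(mu_hat)
    return _finish_test(t, mu_hat, df=2)


def permutation_p(
    t: ThreeWayTable, n_perm: int = 2000, seed: int = 0
) -> float:
    """Seeded permutation p-value for the partial-independence G-statistic,
    shuffling the Z labels against the fixed XY classification.  Intended for
    small universes where the chi-square asymptotics are doubtful."""
    rng = np.random.default_rng(seed)
    observed = _g_statistic(t.mu, expected_partial_independence(t))
    xy_flat = np.repeat(np.arange(4), t.xy_marginal.ravel())
    z_flat = np.repeat([0, 1], t.z_marginal)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(z_flat)
        mu = np.zeros((4, 2), dtype=np.int64)
        np.add.at(mu, (xy_flat, z_flat), 1)
        table = ThreeWayTable(mu.reshape(2, 2, 2), labels=t.labels)
        g = _g_statistic(table.mu, expected_partial_independence(table))
        if g >= observed - 1e-12:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def read_tissue_sets(path) -> dict[str, set[str]]:
    """Load tissue gene sets from a two-column (tissue, gene) TSV or from a
    directory of one-gene-per-line ``<tissue>.txt`` files."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            genes = {ln.strip() for ln in f.read_text().splitlines() if ln.strip()}
            out[f.stem] = genes
    else:
        df = pd.read_csv(path, sep="\t", header=None, names=["tissue", "gene"], dtype=str)
        for tissue, grp in df.groupby("tissue", sort=True):
            out[str(tissue)] = set(grp["gene"])
    if not out:
        raise ValueError(f"no tissue gene sets found at {path}")
    return out


def write_tissue_sets(tissues: Mapping[str, Iterable[str]], path) -> None:
    rows = [(t, g) for t in sorted(tissues) for g in sorted(tissues[t])]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def tissue_scan(
    lists: Mapping[str, RankedTargets],
    tissues: Mapping[str, Iterable[str]],
    L: int = 1000,
    sim: Optional[SimilarityMatrix] = None,
    cutoff: float = 4.0,
) -> list[TissueTestResult]:
    """Partial-independence test for every (tissue, factor pair).

    Top-L sets are fixed (default 1000) rather than grid-scanned.  Results are
    ordered by (tissue, tf_a, tf_b) and annotated with motif similarity when a
    similarity matrix is supplied.
    """
    tf_ids = sorted(lists)
    universe = set(lists[tf_ids[0]].genes)
    if L > len(universe):
        raise ValueError(f"L={L} exceeds universe size {len(universe)}")
    for tf_id in tf_ids:
        if set(lists[tf_id].genes) != universe:
            raise ValueError(f"ranked list for {tf_id} covers a different universe")
    # boolean membership vectors over a fixed gene order; per-pair tables are
    # then one bincount instead of a python loop over the universe
    gene_order = sorted(universe)
    gene_index = {g: i for i, g in enumerate(gene_order)}
    in_top = {}
    for tf_id in tf_ids:
        vec = np.zeros(len(gene_order), dtype=np.int64)
        vec[[gene_index[g] for g in lists[tf_id].top(L)]] = 1
        in_top[tf_id] = vec
    pairs = enumerate_pairs(tf_ids)
    results = []
    for tissue in sorted(tissues):
        tissue_genes = set(tissues[tissue])
        dropped = tissue_genes - universe
        if dropped:
            logger.warning(
                "tissue %s: %d gene(s) outside the universe dropped", tissue, len(dropped)
            )
        in_z = np.zeros(len(gene_order), dtype=np.int64)
        in_z[[gene_index[g] for g in tissue_genes & universe]] = 1
        for a, b in pairs:
            code = (1 - in_top[a]) * 4 + (1 - in_top[b]) * 2 + (1 - in_z)
            mu = np.bincount(code, minlength=8).reshape(2, 2, 2)
            table = ThreeWayTable(mu=mu, labels=(a, b, tissue))
            res = partial_independence_test(table)
            if sim is not None:
                s = sim.value(a, b)
                res = replace(res, similarity=s, similar_flag=bool(s >= cutoff))
            results.append(res)
    return results


def results_to_tsv(results: Sequence[TissueTestResult], path) -> None:
    df = pd.DataFrame(
        [
            {
                "tissue": r.tissue,
                "tf_a": r.tf_a,
                "tf_b": r.tf_b,
                "mu_111": r.observed_111,
                "expected_111": r.expected_111,
                "g_stat": r.g_stat,
                "log10_p": r.log10_p,
                "similarity": r.similarity,
                "similar_flag": r.similar_flag,
                "enriched": r.enriched,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def results_from_tsv(path) -> list[TissueTestResult]:
    df = pd.read_csv(path, sep="\t", dtype={"tissue": str, "tf_a": str, "tf_b": str})
    out = []
    for row in df.itertuples(index=False):
        sim = None if pd.isna(row.similarity) else float(row.similarity)
        flag = None if pd.isna(row.similar_flag) else bool(row.similar_flag)
        out.append(
            TissueTestResult(
                labels=(row.tf_a, row.tf_b, row.tissue),
                g_stat=float(row.g_stat),
                df=3,
                log10_p=float(row.log10_p),
                observed_111=int(row.mu_111),
                expected_111=float(row.expected_111),
                enriched=bool(row.enriched),
                similarity=sim,
                similar_flag=flag,
            )
        )
    return out
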