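"""Seeded synthetic fixtures with known ground truth.

Generates everything the pipeline consumes -- promoter FASTA, JASPAR motifs,
tissue gene lists, a PPI edge list -- plus a JSON manifest of what was
planted: factor pairs whose motifs were co-inserted into a shared set of
promoters, and tissue gene sets partially drawn from those shared targets.
Identical seeds reproduce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from tfcobind.motifs import BASES, PWM, PromoterSet, PromoterRecord, write_jaspar
from tfcobind.tissue import ThreeWayTable, write_tissue_sets


@dataclass
class PlantedPair:
    """Co-insert the motifs of factors ``tf_i`` and ``tf_j`` (indices) into
    ``n_shared_targets`` common promoters.  ``site_strength`` is the
    per-position probability of mutating a planted site away from consensus."""

    tf_i: int
    tf_j: int
    n_shared_targets: int
    site_strength: float = 0.05


@dataclass
class TissueSpec:
    """``coupling`` is the fraction of the tissue's specific genes drawn from
    a planted pair's shared targets (pairs used round-robin)."""

    name: str
    n_specific: int
    coupling: float


@dataclass
class FixtureSpec:
    n_genes: int = 5000
    n_tfs: int = 20
    motif_width: int = 8
    promoter_length: int = 500
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    tissues: list[TissueSpec] = field(default_factory=list)
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_pairs = [
            p if isinstance(p, PlantedPair) else PlantedPair(*p) for p in self.planted_pairs
        ]
        self.tissues = [
            t if isinstance(t, TissueSpec) else TissueSpec(*t) for t in self.tissues
        ]
        if self.n_genes < 1 or self.n_tfs < 1:
            raise ValueError("n_genes and n_tfs must be positive")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must lie in (0, 1)")
        for p in self.planted_pairs:
            if not 0 <= p.tf_i < self.n_tfs or not 0 <= p.tf_j < self.n_tfs:
                raise ValueError("planted pair indexes a missing factor")
            if p.tf_i == p.tf_j:
                raise ValueError("planted pair must involve two distinct factors")
            if p.n_shared_targets > self.n_genes:
                raise ValueError("n_shared_targets exceeds n_genes")
            if not 0 <= p.site_strength < 1:
                raise ValueError("site_strength must lie in [0, 1)")
        if 2 * self.motif_width > self.promoter_length:
            raise ValueError(
                "two non-overlapping sites cannot fit in promoter_length"
            )
        for t in self.tissues:
            if not 0 <= t.coupling <= 1:
                raise ValueError("coupling must lie in [0, 1]")
            if t.n_specific > self.n_genes:
                raise ValueError("n_specific exceeds n_genes")


@dataclass
class Fixture:
    promoters: PromoterSet
    pwms: list[PWM]
    tissue_sets: dict[str, set[str]]
    ppi_edges: set[tuple[str, str]]
    manifest: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.promoters.to_fasta(outdir / "promoters.fa")
        write_jaspar(self.pwms, outdir / "motifs.jaspar")
        write_tissue_sets(self.tissue_sets, outdir / "tissues.tsv")
        with open(outdir / "ppi.tsv", "wt") as out:
            for a, b in sorted(self.ppi_edges):
                out.write(f"{a}\t{b}\n")
        with open(outdir / "manifest.json", "wt") as out:
            json.dump(self.manifest, out, indent=2, sort_keys=True)
            out.write("\n")


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def _tf_id(i: int) -> str:
    return f"TF{i:02d}"


def _random_pwm(width: int, rng: np.random.Generator, tf_id: str) -> PWM:
    """High-information motif: one dominant base per position."""
    counts = np.ones((width, 4))
    consensus = rng.integers(0, 4, size=width)
    dominance = rng.uniform(0.80, 0.95, size=width)
    total = 100.0
    for i in range(width):
        counts[i] = (1 - dominance[i]) * total / 3
        counts[i, consensus[i]] = dominance[i] * total
    return PWM.from_counts(tf_id, counts, pseudocount=1.0)


def _mutate_site(consensus: str, strength: float, rng: np.random.Generator) -> str:
    out = []
    for b in consensus:
        if rng.random() < strength:
            out.append(BASES[rng.integers(0, 4)])
        else:
            out.append(b)
    return "".join(out)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def generate(spec: FixtureSpec) -> Fixture:
    """Generate the full fixture described by ``spec`` (deterministic in seed)."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    pwms = [_random_pwm(spec.motif_width, rng, _tf_id(i)) for i in range(spec.n_tfs)]
    seq_codes = rng.choice(4, size=(spec.n_genes, spec.promoter_length), p=base_p)
    seqs = ["".join(BASES[c] for c in row) for row in seq_codes]

    available = list(range(spec.n_genes))
    manifest_pairs = []
    w = spec.motif_width
    for pp in spec.planted_pairs:
        if len(available) < pp.n_shared_targets:
            raise ValueError("not enough unplanted genes left for planted pair")
        chosen = rng.choice(len(available), size=pp.n_shared_targets, replace=False)
        targets = sorted(available[i] for i in chosen)
        available = [g for g in available if g not in set(targets)]
        cons_i = pwms[pp.tf_i].consensus
        cons_j = pwms[pp.tf_j].consensus
        for g in targets:
            # non-overlapping placement: site for tf_i in the left half-range,
            # site for tf_j to its right
            max_a = spec.promoter_length - 2 * w
            pos_a = int(rng.integers(0, max_a + 1))
            pos_b = int(rng.integers(pos_a + w, spec.promoter_length - w + 1))
            seq = seqs[g]
            for pos, cons in ((pos_a, cons_i), (pos_b, cons_j)):
                site = _mutate_site(cons, pp.site_strength, rng)
                if rng.random() < 0.5:
                    site = "".join(_COMP[b] for b in reversed(site))
                seq = seq[:pos] + site + seq[pos + w :]
            seqs[g] = seq
        manifest_pairs.append(
            {
                "tf_a": _tf_id(min(pp.tf_i, pp.tf_j)),
                "tf_b": _tf_id(max(pp.tf_i, pp.tf_j)),
                "targets": [_gene_id(g) for g in targets],
            }
        )

    tissue_sets: dict[str, set[str]] = {}
    manifest_tissues = {}
    for ti, ts in enumerate(spec.tissues):
        coupled: list[int] = []
        if spec.planted_pairs and ts.coupling > 0:
            pair = manifest_pairs[ti % len(manifest_pairs)]
            pool = [int(g[1:]) for g in pair["targets"]]
            n_coupled = min(round(ts.coupling * ts.n_specific), len(pool))
            idx = rng.choice(len(pool), size=n_coupled, replace=False)
            coupled = sorted(pool[i] for i in idx)
        n_random = ts.n_specific - len(coupled)
        others = np.setdiff1d(np.arange(spec.n_genes), np.array(coupled, dtype=int))
        idx = rng.choice(others.size, size=n_random, replace=False)
        random_part = sorted(int(others[i]) for i in idx)
        genes = sorted(set(coupled) | set(random_part))
        tissue_sets[ts.name] = {_gene_id(g) for g in genes}
        manifest_tissues[ts.name] = {
            "genes": [_gene_id(g) for g in genes],
            "coupled": [_gene_id(g) for g in coupled],
        }

    ppi_edges = {(p["tf_a"], p["tf_b"]) for p in manifest_pairs}
    planted = set(ppi_edges)
    n_decoys = max(3, len(planted))
    guard = 0
    while len(ppi_edges) < len(planted) + n_decoys and guard < 1000:
        i, j = rng.choice(spec.n_tfs, size=2, replace=False)
        edge = (_tf_id(min(i, j)), _tf_id(max(i, j)))
        if edge not in planted:
            ppi_edges.add(edge)
        guard += 1

    promoters = PromoterSet(
        records={
            _gene_id(i): PromoterRecord(_gene_id(i), seqs[i]) for i in range(spec.n_genes)
        }
    )
    manifest = {
        "seed": spec.seed,
        "spec": asdict(spec),
        "planted_pairs": manifest_pairs,
        "tissues": manifest_tissues,
        "ppi_decoys": sorted(e for e in ppi_edges if e not in planted),
    }
    return Fixture(
        promoters=promoters,
        pwms=pwms,
        tissue_sets=tissue_sets,
        ppi_edges=ppi_edges,
        manifest=manifest,
    )


def null_tables(
    n_tables: int, n: int, seed: int = 0, labels=("tf_a", "tf_b", "tissue")
) -> list[ThreeWayTable]:
    """Tables simulated under partial independence of (X, Y) from Z.

    Per table, a nonuniform joint (X, Y) distribution is drawn from a
    Dirichlet and an independent Z probability from U(0.2, 0.5); cell
    probabilities factorize as p_xy * p_z, so the partial-independence null
    holds exactly.  The concentration keeps expected cells large enough for
    the chi-square asymptotics at the intended n >= 2000.
    """
    if n < 8:
        raise ValueError("n must be at least 8")
    rng = np.random.default_rng(seed)
    tables = []
    for _ in range(n_tables):
        p_xy = rng.dirichlet([5.0, 5.0, 5.0, 5.0])
        p_z = rng.uniform(0.2, 0.5)
        probs = np.outer(p_xy, [p_z, 1 - p_z]).reshape(2, 2, 2)
        mu = rng.multinomial(n, probs.ravel()).reshape(2, 2, 2)
        tables.append(ThreeWayTable(mu=mu, labels=labels))
    return tables
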