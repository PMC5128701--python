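"""Diversity statistics of a clone library: coverage, Shannon, rarefaction.

Good's coverage C = (1 - n/N) x 100 estimates the fraction of the community
captured by the library, with n the number of singleton OTUs and N the
total clone count.  The Shannon index H = -sum p_i ln p_i (natural log) is
bounded above by ln S for S OTUs.  Rarefaction is the exact hypergeometric
expectation E[S_m] of the number of OTUs seen in a random subsample of m
clones (Hurlbert's formulation, as implemented by the classic Analytical
Rarefaction tool); a seeded Monte-Carlo subsampler is provided for
cross-checking only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .otu import AbundanceTable, singleton_count

__all__ = [
    "DiversityStats",
    "RarefactionCurve",
    "coverage",
    "shannon",
    "rarefy",
    "rarefy_monte_carlo",
    "summarize",
]


@dataclass(frozen=True)
class DiversityStats:
    coverage_pct: float
    shannon_nats: float
    richness: int
    singletons: int
    total_clones: int


@dataclass(frozen=True)
class RarefactionCurve:
    points: tuple[tuple[int, float], ...]
    total: int
    richness: int

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("m\texpected_otus\n")
            for m, e in self.points:
                fh.write(f"{m}\t{e:.6f}\n")


def coverage(table: AbundanceTable) -> float:
    """Good's coverage (1 - singletons/N) x 100, full precision."""
    n = singleton_count(table)
    return (1.0 - n / table.total) * 100.0


def shannon(table: AbundanceTable) -> float:
    """Shannon entropy -sum p_i ln p_i in nats."""
    counts = np.asarray(table.abundances(), dtype=float)
    if counts.size == 0:
        raise ValueError("empty abundance table")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def rarefy(table: AbundanceTable, depths: Sequence[int]) -> RarefactionCurve:
    """Exact expected OTU richness at each subsampling depth.

    E[S_m] = sum_i [1 - C(N - N_i, m) / C(N, m)], evaluated with exact
    integer binomials so no overflow or cancellation occurs.
    """
    counts = table.abundances()
    n_total = table.total
    points: list[tuple[int, float]] = []
    for m in depths:
        if not 1 <= m <= n_total:
            raise ValueError(f"depth {m} outside [1, {n_total}]")
        denom = math.comb(n_total, m)
        expected = sum(
            1.0 - math.comb(n_total - c, m) / denom if n_total - c >= m else 1.0
            for c in counts
        )
        points.append((int(m), float(expected)))
    return RarefactionCurve(points=tuple(points), total=n_total, richness=table.richness)


def rarefy_monte_carlo(
    table: AbundanceTable, depths: Sequence[int], n_draws: int = 10_000, seed: int = 0
) -> RarefactionCurve:
    """Monte-Carlo estimate of the rarefaction curve (cross-check mode)."""
    labels = np.repeat(np.arange(table.richness), table.abundances())
    rng = np.random.default_rng(seed)
    points = []
    for m in depths:
        if not 1 <= m <= table.total:
            raise ValueError(f"depth {m} outside [1, {table.total}]")
        seen = [
            np.unique(rng.choice(labels, size=m, replace=False)).size
            for _ in range(n_draws)
        ]
        points.append((int(m), float(np.mean(seen))))
    return RarefactionCurve(points=tuple(points), total=table.total, richness=table.richness)


def summarize(table: AbundanceTable) -> DiversityStats:
    return DiversityStats(
        coverage_pct=coverage(table),
        shannon_nats=shannon(table),
        richness=table.richness,
        singletons=singleton_count(table),
        total_clones=table.total,
    )


def plot_rarefaction(curve: RarefactionCurve, path: str | Path) -> None:
    """Save a rarefaction plot (clones subsampled vs expected OTUs)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ms = [m for m, _ in curve.points]
    es = [e for _, e in curve.points]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ms, es, "-", color="tab:blue")
    ax.set_xlabel("clones sampled")
    ax.set_ylabel("expected OTUs")
    ax.set_title(f"Rarefaction (N={curve.total}, S={curve.richness})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
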