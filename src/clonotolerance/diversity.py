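"""Repertoire diversity: Shannon entropy and Gini index of clone-size
distributions under repeated fixed-depth downsampling.

Each group's cells are repeatedly subsampled without replacement to a
common depth; clone sizes are rebuilt from the sampled cells and both
indices are computed per replicate.  Entropy is reported in bits.  The
default depth is floor(0.95 x smallest group's paired-cell count),
overridable with an explicit integer; the depth actually used is always
recorded on the results.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .stats_util import KruskalDunnResult, kruskal_dunn


@dataclass
class CloneSizeDistribution:
    sizes: list[int]
    group: str = ""

    def __post_init__(self):
        if any(s < 1 for s in self.sizes):
            raise ValueError("clone sizes must be positive")


def shannon_entropy(dist: CloneSizeDistribution | list[int]) -> float:
    """H = -sum p_i log2 p_i over clone frequencies, in bits."""
    sizes = dist.sizes if isinstance(dist, CloneSizeDistribution) else list(dist)
    if not sizes:
        raise ValueError("empty clone-size distribution")
    return float(st.entropy(np.asarray(sizes, dtype=float), base=2))


def gini_index(dist: CloneSizeDistribution | list[int], corrected: bool = False) -> float:
    """G = sum_i (2i - n - 1) x_(i) / (n sum x) over ascending-sorted sizes.

    0 for uniform sizes, increasing under concentration of cells into few
    clones.  ``corrected`` applies the small-sample n/(n-1) factor.
    """
    sizes = dist.sizes if isinstance(dist, CloneSizeDistribution) else list(dist)
    if not sizes:
        raise ValueError("empty clone-size distribution")
    x = np.sort(np.asarray(sizes, dtype=float))
    n = len(x)
    if n == 1:
        return 0.0
    i = np.arange(1, n + 1)
    g = float(((2 * i - n - 1) * x).sum() / (n * x.sum()))
    if corrected:
        g *= n / (n - 1)
    return g


@dataclass
class DiversityResult:
    group: str
    depth: int
    shannon: np.ndarray  # one value per replicate
    gini: np.ndarray

    def percentile_frame(self) -> pd.DataFrame:
        rows = []
        for name, vals in (("shannon", self.shannon), ("gini", self.gini)):
            q25, q50, q75 = np.percentile(vals, [25, 50, 75])
            rows.append({"group": self.group, "index": name, "depth": self.depth,
                         "p25": q25, "median": q50, "p75": q75})
        return pd.DataFrame(rows)


def default_depth(group_sizes: dict[str, int], fraction: float = 0.95) -> int:
    """floor(fraction x smallest group's cell count)."""
    return math.floor(fraction * min(group_sizes.values()))


def downsampled_diversity(
    cells: dict[str, list[str]],
    depth: int | None = None,
    reps: int = 1000,
    seed: int = 0,
) -> list[DiversityResult]:
    """Fixed-depth downsampled Shannon/Gini replicates per group.

    ``cells`` maps group label -> list of per-cell clonotype ids.  Each
    replicate draws ``depth`` cells without replacement and recomputes
    clone sizes.  The seed fixes the full replicate stream.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    sizes = {g: len(ids) for g, ids in cells.items()}
    if depth is None:
        depth = default_depth(sizes)
    for g, n in sizes.items():
        if depth > n:
            raise ValueError(f"depth {depth} exceeds group {g!r} size {n}")
    rng = np.random.default_rng(seed)
    out = []
    for group in cells:
        ids = np.asarray(cells[group], dtype=object)
        shannon = np.empty(reps)
        gini = np.empty(reps)
        for r in range(reps):
            take = rng.choice(len(ids), size=depth, replace=False)
            clone_sizes = list(Counter(ids[take]).values())
            shannon[r] = shannon_entropy(clone_sizes)
            gini[r] = gini_index(clone_sizes)
        out.append(DiversityResult(group=group, depth=depth, shannon=shannon, gini=gini))
    return out


@dataclass
class ComparisonReport:
    shannon: KruskalDunnResult
    gini: KruskalDunnResult


def compare_diversity(
    results: list[DiversityResult],
    adjust: str = "bonferroni",
) -> ComparisonReport:
    """Kruskal-Wallis across groups per index, with Dunn's all-pairs post hoc
    comparison (Bonferroni-adjusted by default)."""
    if len(results) < 2:
        raise ValueError("need results for at least 2 groups")
    return ComparisonReport(
        shannon=kruskal_dunn({r.group: r.shannon for r in results}, adjust),
        gini=kruskal_dunn({r.group: r.gini for r in results}, adjust),
    )


def replicates_frame(results: list[DiversityResult]) -> pd.DataFrame:
    frames = []
    for r in results:
        frames.append(pd.DataFrame({
            "group": r.group, "replicate": np.arange(len(r.shannon)),
            "depth": r.depth, "shannon": r.shannon, "gini": r.gini,
        }))
    return pd.concat(frames, ignore_index=True)
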