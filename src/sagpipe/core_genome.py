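"""Combinatorial conserved single-copy core-gene analysis.

Given a genome x ortholog-cluster copy-number matrix, this module counts,
for subsets of genomes, the clusters present in exactly one copy in every
subset member ("single-copy core"), summarizes the distribution of that
count over all (or a sample of) subsets of each size, and fits a power law
with an additive asymptote

    y(k) = c + a * k**b        (b < 0 expected)

to the decay of core-set size with subset size k.  The asymptote ``c`` is
the projected conserved core of the clade; the exhaustive single-copy core
over all genomes is reported alongside it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DEFAULT_MAX_COMBINATIONS = 10_000

_CHUNK = 2048  # subsets per vectorized block


@dataclass
class OrthologMatrix:
    """Genome x cluster copy-number table (non-negative integers)."""

    table: pd.DataFrame  # index: genome ids; columns: cluster ids

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < 0).any():
            raise ValueError("copy numbers must be non-negative")

    @classmethod
    def from_assignments(cls, gene_table: pd.DataFrame, assignments: pd.DataFrame) -> "OrthologMatrix":
        """Build the matrix from a gene table and (gene_id, cluster_id) assignments."""
        merged = gene_table[["gene_id", "genome_id"]].merge(assignments, on="gene_id", how="inner")
        if len(merged) < len(assignments):
            raise ValueError("some assigned genes are missing from the gene table")
        table = pd.crosstab(merged["genome_id"], merged["cluster_id"])
        table = table.sort_index().sort_index(axis=1)
        return cls(table=table)

    @property
    def genomes(self) -> list[str]:
        return list(self.table.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.table.columns)

    def single_copy_mask(self) -> np.ndarray:
        """Boolean genome x cluster array: copy number exactly 1."""
        return self.table.to_numpy() == 1


def count_single_copy_core(matrix: OrthologMatrix, subset: set[str] | list[str]) -> int:
    """Number of clusters with copy number exactly 1 in *every* genome of ``subset``."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = [g for g in subset if g not in matrix.table.index]
    if unknown:
        raise ValueError(f"unknown genome ids: {unknown}")
    block = matrix.table.loc[subset].to_numpy()
    return int((block == 1).all(axis=0).sum())


@dataclass
class CorePoint:
    """Distribution of single-copy core counts over genome subsets of one size."""

    k: int
    counts: np.ndarray  # core count per enumerated/sampled subset
    exhaustive: bool
    n_subsets: int
    seed: int | None
    mode_tie: bool

    @property
    def mean(self) -> float:
        return float(np.mean(self.counts))

    @property
    def sd(self) -> float:
        """Population standard deviation of the subset counts."""
        return float(np.std(self.counts))

    @property
    def mode(self) -> int:
        """Most frequent count; ties resolved toward the smaller count."""
        freq = np.bincount(self.counts)
        return int(np.argmax(freq))


@dataclass
class CoreCurve:
    """Core-count distribution per subset size, plus sampling metadata."""

    points: list[CorePoint] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.k, p.n_subsets, p.exhaustive, p.mean, p.mode, p.sd, p.mode_tie)
                for p in self.points
            ],
            columns=["k", "n_subsets", "exhaustive", "mean", "mode", "sd", "mode_tie"],
        )

    @property
    def ks(self) -> np.ndarray:
        return np.array([p.k for p in self.points])

    @property
    def means(self) -> np.ndarray:
        return np.array([p.mean for p in self.points])


def _subset_counts(single_copy: np.ndarray, subsets: np.ndarray) -> np.ndarray:
    """Core count for each row of ``subsets`` (indices into the genome axis)."""
    k = subsets.shape[1]
    out = np.empty(len(subsets), dtype=np.int64)
    for lo in range(0, len(subsets), _CHUNK):
        block = single_copy[subsets[lo : lo + _CHUNK]]  # (chunk, k, n_clusters)
        out[lo : lo + _CHUNK] = block.all(axis=1).sum(axis=1)
    return out


def core_distribution(
    matrix: OrthologMatrix,
    k: int,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
    seed: int = 0,
) -> CorePoint:
    """Distribution of single-copy core counts over genome subsets of size ``k``.

    Enumeration is exhaustive when C(n, k) <= ``max_combinations``;
    otherwise ``max_combinations`` distinct subsets are sampled uniformly
    without replacement using ``seed``.
    """
    n = len(matrix.genomes)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    total = comb(n, k)
    single_copy = matrix.single_copy_mask()
    if total <= max_combinations:
        subsets = np.array(list(itertools.combinations(range(n), k)), dtype=np.intp)
        exhaustive = True
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        chosen: set[tuple[int, ...]] = set()
        while len(chosen) < max_combinations:
            chosen.add(tuple(sorted(rng.choice(n, size=k, replace=False).tolist())))
        subsets = np.array(sorted(chosen), dtype=np.intp)
        exhaustive = False
        used_seed = seed
    counts = _subset_counts(single_copy, subsets)
    freq = np.bincount(counts)
    mode_tie = int((freq == freq.max()).sum()) > 1
    return CorePoint(
        k=k,
        counts=counts,
        exhaustive=exhaustive,
        n_subsets=len(subsets),
        seed=used_seed,
        mode_tie=mode_tie,
    )


def core_curve(
    matrix: OrthologMatrix,
    ks: list[int] | None = None,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
    seed: int = 0,
) -> CoreCurve:
    """Core-count distributions for each subset size (default 1..n genomes)."""
    if ks is None:
        ks = list(range(1, len(matrix.genomes) + 1))
    return CoreCurve(
        points=[core_distribution(matrix, k, max_combinations=max_combinations, seed=seed) for k in ks]
    )


class PowerLawFitError(RuntimeError):
    """Raised when the asymptotic power-law fit fails to converge.

    Carries the best iterate found so the caller can inspect it.
    """

    def __init__(self, message: str, params: tuple[float, float, float], rss: float):
        super().__init__(message)
        self.params = params
        self.rss = rss


@dataclass
class PowerLawFit:
    """Least-squares fit of y = c + a * k**b.

    ``c`` (the asymptote, constrained non-negative) is the projected
    conserved core size; ``b`` is expected negative for a decaying curve.
    """

    a: float
    b: float
    c: float
    rss: float
    n_points: int

    def predict(self, k):
        k = np.asarray(k, dtype=float)
        return self.c + self.a * k**self.b


def fit_power_law(ks, ys) -> PowerLawFit:
    """Fit y = c + a*k**b by trust-region least squares.

    Initialization is fixed and documented so the fit is deterministic:
    c0 = min(y), b0 = -1, a0 = (y[0] - c0) * k[0] (i.e. the amplitude that
    passes through the first point at b0).  Requires >= 4 strictly
    positive k values; raises :class:`PowerLawFitError` on non-convergence.
    """
    ks = np.asarray(ks, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(ks) != len(ys):
        raise ValueError("ks and ys must have equal length")
    if len(ks) < 4:
        raise ValueError("need at least 4 points to fit three parameters")
    if (ks <= 0).any():
        raise ValueError("ks must be strictly positive")

    c0 = float(np.min(ys))
    b0 = -1.0
    a0 = float((ys[0] - c0) * ks[0])

    def residuals(theta):
        a, b, c = theta
        return c + a * np.power(ks, b) - ys

    result = least_squares(
        residuals,
        x0=[a0, b0, c0],
        bounds=([-np.inf, -50.0, 0.0], [np.inf, 50.0, np.inf]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=10_000,
    )
    a, b, c = (float(v) for v in result.x)
    rss = float(np.sum(result.fun**2))
    if not result.success:
        raise PowerLawFitError(
            f"power-law fit did not converge: {result.message}", (a, b, c), rss
        )
    fitted = c + a * np.power(ks, b)
    if not np.isfinite(fitted).all():
        raise PowerLawFitError("fitted values not finite over the input range", (a, b, c), rss)
    return PowerLawFit(a=a, b=b, c=c, rss=rss, n_points=len(ks))


@dataclass
class MarkerCatalog:
    """The conserved single-copy marker set with per-genome coordinates.

    ``clusters`` is fixed to lexicographic cluster-id order; ``coords``
    maps cluster id -> genome id -> (contig_id, start, end, strand).
    """

    clusters: list[str]
    coords: dict[str, dict[str, tuple[str, int, int, str]]]

    def __len__(self) -> int:
        return len(self.clusters)

    def markers_for(self, genome_id: str) -> dict[str, tuple[str, int, int, str]]:
        return {c: self.coords[c][genome_id] for c in self.clusters}


def marker_catalog(
    matrix: OrthologMatrix, gene_table: pd.DataFrame, assignments: pd.DataFrame
) -> MarkerCatalog:
    """Build the catalog of clusters single-copy in every genome of the matrix.

    Raises ``ValueError`` when a core cluster has no coordinates in some
    genome (the gene table and the matrix disagree).
    """
    core = [
        c
        for c, ok in zip(matrix.clusters, (matrix.table.to_numpy() == 1).all(axis=0))
        if ok
    ]
    core = sorted(core)
    merged = gene_table.merge(assignments, on="gene_id", how="inner")
    coords: dict[str, dict[str, tuple[str, int, int, str]]] = {}
    for cluster in core:
        rows = merged[merged["cluster_id"] == cluster]
        per_genome: dict[str, tuple[str, int, int, str]] = {}
        for genome in matrix.genomes:
            sub = rows[rows["genome_id"] == genome]
            if len(sub) != 1:
                raise ValueError(
                    f"core cluster {cluster!r} has {len(sub)} coordinate records in "
                    f"genome {genome!r}; expected exactly 1"
                )
            r = sub.iloc[0]
            per_genome[genome] = (r["contig_id"], int(r["start"]), int(r["end"]), r["strand"])
        coords[cluster] = per_genome
    return MarkerCatalog(clusters=core, coords=coords)
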