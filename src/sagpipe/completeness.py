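"""Rolling-window marker-recovery simulation and SAG completeness estimation.

The estimator works as follows.  Each reference genome is concatenated
into a single circular sequence carrying the positions of the conserved
single-copy markers.  For every fraction f on a grid and every one of
``n_starts`` evenly spaced window starts, the window of length
round(f * L) is slid over the circle and the markers fully contained in
it are counted.  Pooling the resulting (marker count k, fraction f) pairs
over all reference genomes gives, for every observable k, a conditional
distribution of genome fraction recovered.  A SAG with k observed markers
is then assigned the median of that distribution as its estimated
fraction complete, with the first and third quartiles as spread, and its
estimated genome size is assembly length / fraction, with the uncertainty
obtained by propagating the quartile fractions through the same division.

Because markers are not evenly spaced in real genomes, the estimate is
deliberately *not* k/M: clustered markers make small observed counts
compatible with large recovered fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sagpipe.core_genome import MarkerCatalog
from sagpipe.io import HitTable, SagAssembly
from sagpipe.recruitment import best_hit

DEFAULT_FRACTION_GRID = np.round(np.arange(0.01, 1.001, 0.01), 2)
DEFAULT_N_STARTS = 1000
DEFAULT_MARKER_EVALUE = 1e-10


@dataclass
class GenomeLayout:
    """A concatenated (circular by default) genome with marker spans."""

    genome_id: str
    length: int
    markers: dict[str, tuple[int, int]]  # cluster id -> (start, end) on the concatenation
    circular: bool = True

    def __post_init__(self) -> None:
        for cid, (s, e) in self.markers.items():
            if not (0 <= s < e <= self.length):
                raise ValueError(f"marker {cid!r} span ({s}, {e}) outside [0, {self.length})")

    @property
    def marker_count(self) -> int:
        return len(self.markers)


def build_layout(
    assembly: SagAssembly,
    catalog: MarkerCatalog,
    contig_order: list[str] | None = None,
    circular: bool = True,
) -> GenomeLayout:
    """Concatenate contigs (in the given order) and offset marker coordinates.

    Raises ``ValueError`` naming the cluster when a catalog marker is
    missing from this genome.
    """
    lengths = assembly.contig_lengths()
    order = contig_order if contig_order is not None else assembly.contig_ids
    unknown = [c for c in order if c not in lengths]
    if unknown:
        raise ValueError(f"contig order names unknown contigs: {unknown}")
    offsets: dict[str, int] = {}
    pos = 0
    for cid in order:
        offsets[cid] = pos
        pos += lengths[cid]

    markers: dict[str, tuple[int, int]] = {}
    for cluster in catalog.clusters:
        per_genome = catalog.coords[cluster]
        if assembly.id not in per_genome:
            raise ValueError(f"catalog marker {cluster!r} missing from genome {assembly.id!r}")
        contig, start, end, _strand = per_genome[assembly.id]
        if contig not in offsets:
            raise ValueError(
                f"marker {cluster!r} lies on contig {contig!r} absent from the contig order"
            )
        markers[cluster] = (offsets[contig] + start, offsets[contig] + end)
    return GenomeLayout(genome_id=assembly.id, length=pos, markers=markers, circular=circular)


def uniform_marker_layout(
    length: int, n_markers: int, marker_length: int = 1000, genome_id: str = "uniform"
) -> GenomeLayout:
    """Layout with ``n_markers`` evenly spaced markers on a circular genome."""
    if n_markers * marker_length > length:
        raise ValueError("markers do not fit on the genome")
    spacing = length / n_markers
    markers = {
        f"m{i:04d}": (int(i * spacing), int(i * spacing) + marker_length) for i in range(n_markers)
    }
    return GenomeLayout(genome_id=genome_id, length=length, markers=markers)


def clustered_marker_layout(
    length: int,
    n_markers: int,
    cluster_span: float = 0.1,
    marker_length: int = 1000,
    genome_id: str = "clustered",
) -> GenomeLayout:
    """Layout with all markers packed into the first ``cluster_span`` of the genome."""
    span = int(length * cluster_span)
    if n_markers * marker_length > span:
        raise ValueError("markers do not fit in the clustered span")
    spacing = span / n_markers
    markers = {
        f"m{i:04d}": (int(i * spacing), int(i * spacing) + marker_length) for i in range(n_markers)
    }
    return GenomeLayout(genome_id=genome_id, length=length, markers=markers)


@dataclass
class RecoveryDistribution:
    """Conditional distribution of genome fraction recovered given marker count.

    ``samples[k]`` holds every pooled fraction observed together with
    marker count k.  ``summary()`` reports box statistics per k: median,
    quartiles, IQR x 1.5 whisker bounds (whiskers drawn at the extreme
    data points inside the bounds) and the number of outliers beyond them.
    """

    m: int  # total markers in the catalog
    samples: dict[int, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, arr in self.samples.items():
            if not 0 <= k <= self.m:
                raise ValueError(f"marker count {k} outside [0, {self.m}]")
            if len(arr) and (arr.min() < 0 or arr.max() > 1):
                raise ValueError("recovered fractions must be in [0, 1]")

    def observed_counts(self) -> list[int]:
        return sorted(k for k, arr in self.samples.items() if len(arr))

    def median_fraction(self, k: int) -> float:
        return float(np.median(self.samples[k]))

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in self.observed_counts():
            arr = np.sort(self.samples[k])
            q1, med, q3 = np.percentile(arr, [25, 50, 75])
            iqr = q3 - q1
            lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = arr[(arr >= lo_bound) & (arr <= hi_bound)]
            rows.append(
                (
                    k,
                    len(arr),
                    med,
                    q1,
                    q3,
                    inside.min() if len(inside) else np.nan,
                    inside.max() if len(inside) else np.nan,
                    int(((arr < lo_bound) | (arr > hi_bound)).sum()),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["k", "n", "median", "q1", "q3", "whisker_lo", "whisker_hi", "n_outliers"],
        )


def window_marker_counts(layout: GenomeLayout, window_length: int, starts: np.ndarray) -> np.ndarray:
    """Markers fully contained in the circular window [s, s + window_length) per start."""
    if not layout.markers:
        return np.zeros(len(starts), dtype=np.int64)
    if window_length >= layout.length:
        # the window covers the whole circle; every marker is inside
        return np.full(len(starts), len(layout.markers), dtype=np.int64)
    mstarts = np.array([s for s, _ in layout.markers.values()])
    mlens = np.array([e - s for s, e in layout.markers.values()])
    rel = (mstarts[None, :] - starts[:, None]) % layout.length
    return (rel + mlens[None, :] <= window_length).sum(axis=1)


def simulate_recovery(
    layouts: list[GenomeLayout],
    fraction_grid: np.ndarray | None = None,
    n_starts: int = DEFAULT_N_STARTS,
) -> RecoveryDistribution:
    """Rolling-window recovery simulation pooled over reference layouts.

    For every layout, fraction f in the grid and evenly spaced start, the
    markers fully contained in the window of length round(f * L) are
    counted; the (k, f) pairs are pooled over all layouts.
    """
    if fraction_grid is None:
        fraction_grid = DEFAULT_FRACTION_GRID
    fraction_grid = np.asarray(fraction_grid, dtype=float)
    if fraction_grid.size == 0:
        raise ValueError("fraction grid must be non-empty")
    if (fraction_grid <= 0).any() or (fraction_grid > 1).any():
        raise ValueError("fractions must lie in (0, 1]")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if not layouts:
        raise ValueError("need at least one layout")
    m = layouts[0].marker_count
    for layout in layouts[1:]:
        if layout.marker_count != m:
            raise ValueError("all layouts must carry the same marker catalog")

    pooled: dict[int, list[np.ndarray]] = {}
    for layout in layouts:
        starts = np.floor(np.arange(n_starts) * layout.length / n_starts).astype(np.int64)
        for f in fraction_grid:
            w = round(f * layout.length)
            ks = window_marker_counts(layout, w, starts)
            for k in np.unique(ks):
                pooled.setdefault(int(k), []).append(np.full(int((ks == k).sum()), f))
    samples = {k: np.concatenate(chunks) for k, chunks in pooled.items()}
    return RecoveryDistribution(
        m=m,
        samples=samples,
        provenance={
            "genomes": [layout.genome_id for layout in layouts],
            "fraction_grid": [float(f) for f in fraction_grid],
            "n_starts": n_starts,
        },
    )


def estimate_completeness(k_observed: int, dist: RecoveryDistribution) -> tuple[float, tuple[float, float]]:
    """Median recovered fraction at the observed marker count, with quartile spread."""
    if not 0 <= k_observed <= dist.m:
        raise ValueError(f"observed marker count must be in [0, {dist.m}]")
    arr = dist.samples.get(k_observed)
    if arr is None or len(arr) == 0:
        raise ValueError(
            f"no simulated samples with {k_observed} markers; "
            "rerun the recovery simulation with a denser fraction grid or more starts"
        )
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), (float(q1), float(q3))


@dataclass
class CompletenessEstimate:
    """A Table-style completeness / genome-size row for one SAG."""

    sag_id: str
    k: int
    fraction: float
    q1: float
    q3: float
    assembly_length: int
    size: float
    uncertainty: float
    method: dict = field(default_factory=dict)


def estimate_genome_size(
    assembly_length: int,
    fraction: float,
    quartiles: tuple[float, float] | None = None,
    sag_id: str = "",
    k: int = 0,
) -> CompletenessEstimate:
    """Genome size = assembly length / estimated fraction complete.

    The uncertainty is the half-width of assembly_length / f evaluated at
    the (Q1, Q3) fraction bounds; 0 when no quartiles are supplied or
    Q1 == Q3.
    """
    if fraction <= 0:
        raise ValueError("fraction must be > 0; size is undefined at 0")
    size = assembly_length / fraction
    if quartiles is None:
        q1 = q3 = fraction
        uncertainty = 0.0
    else:
        q1, q3 = quartiles
        if not 0 < q1 <= q3 <= 1:
            raise ValueError("quartiles must satisfy 0 < q1 <= q3 <= 1")
        uncertainty = (assembly_length / q1 - assembly_length / q3) / 2.0
    return CompletenessEstimate(
        sag_id=sag_id,
        k=k,
        fraction=fraction,
        q1=q1,
        q3=q3,
        assembly_length=assembly_length,
        size=size,
        uncertainty=uncertainty,
        method={"estimator": "median of rolling-window recovery distribution"},
    )


def count_markers_in_sag(hits: HitTable, evalue_cutoff: float = DEFAULT_MARKER_EVALUE) -> int:
    """Distinct catalog clusters identified in a SAG from a gene-vs-catalog hit table.

    Hits above the e-value cutoff are discarded, each SAG gene keeps only
    its best remaining hit (highest bitscore, ties by lower e-value then
    subject id), and the distinct clusters hit are counted; a cluster hit
    by several genes counts once.
    """
    passing = [h for h in hits if h.evalue <= evalue_cutoff]
    by_query: dict[str, list] = {}
    for h in passing:
        by_query.setdefault(h.query, []).append(h)
    clusters = {best_hit(rows).subject for rows in by_query.values()}
    return len(clusters)


def layout_to_dict(layout: GenomeLayout) -> dict:
    return {
        "genome_id": layout.genome_id,
        "length": layout.length,
        "circular": layout.circular,
        "markers": {c: [s, e] for c, (s, e) in layout.markers.items()},
    }


def layout_from_dict(d: dict) -> GenomeLayout:
    return GenomeLayout(
        genome_id=d["genome_id"],
        length=int(d["length"]),
        markers={c: (int(s), int(e)) for c, (s, e) in d["markers"].items()},
        circular=bool(d.get("circular", True)),
    )
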