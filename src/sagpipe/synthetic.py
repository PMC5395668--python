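"""Seeded generators for pangenomes, fragmented SAGs, paralog families and read sets.

Every generator takes an explicit integer seed and is byte-reproducible.
The defaults of :class:`PangenomeSpec` mirror the reference-genome
collection the estimator was designed around: 25 genomes of ~3 Mbp with a
designated core of 71 single-copy gene clusters conserved in every genome.

Genomes are circular for all window placement (matching the completeness
module), and a marker counts as recovered only when its full span lies
inside a window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sagpipe.io import SagAssembly

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA_STR = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(_AA_STR.encode(), dtype=np.uint8)

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return _NT[rng.integers(0, 4, size=length)]


@dataclass
class PangenomeSpec:
    """Parameters of a synthetic genome collection with a designated core.

    Defaults describe the study conditions the pipeline targets: a
    25-genome collection, each genome ~3 Mbp, sharing 71 single-copy core
    clusters.  ``duplication_rate`` is the per-genome probability that a
    core cluster carries a second copy (a duplicated cluster is no longer
    single-copy there); it defaults to 0 so the realized exhaustive core
    equals the designated core.
    """

    n_genomes: int = 25
    core_size: int = 71
    accessory_pool: int = 500
    accessory_retention: float = 0.30
    duplication_rate: float = 0.0
    genome_length: int = 3_000_000
    gene_length: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if self.core_size < 1:
            raise ValueError("core_size must be >= 1")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        for name in ("accessory_retention", "duplication_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        # worst case every core gene duplicated and every accessory retained
        worst = (2 * self.core_size + self.accessory_pool) * self.gene_length
        if worst > self.genome_length:
            raise ValueError(
                f"genome_length {self.genome_length} cannot hold up to "
                f"{worst} bp of genes without overlap"
            )


@dataclass
class Pangenome:
    """Output of :func:`generate_pangenome`: assemblies plus truth tables."""

    spec: PangenomeSpec
    assemblies: dict[str, SagAssembly]
    gene_table: pd.DataFrame
    assignments: pd.DataFrame  # columns: gene_id, cluster_id
    core_clusters: list[str]
    accessory_clusters: list[str]
    duplicated: dict[str, set[str]]  # genome id -> core clusters duplicated there

    @property
    def genome_ids(self) -> list[str]:
        return sorted({g for g in self.gene_table["genome_id"]})


def generate_pangenome(spec: PangenomeSpec, with_sequences: bool = True) -> Pangenome:
    """Generate a genome collection with known gene placement and orthology.

    Every designated core cluster is present in every genome, in exactly
    one copy except where a duplication fired; accessory clusters are
    retained per independent Bernoulli draws.  Genes are placed without
    overlap, separated by multinomially drawn intergenic gaps, so placement
    is uniform up to the no-overlap constraint.  With ``with_sequences``
    each cluster has a reference gene sequence embedded verbatim in each
    carrying genome (background is random DNA).
    """
    root = np.random.SeedSequence(spec.seed)
    cluster_ss, accessory_ss, *genome_ss = root.spawn(2 + spec.n_genomes)

    core_ids = [f"core{i:04d}" for i in range(spec.core_size)]
    acc_ids = [f"acc{i:04d}" for i in range(spec.accessory_pool)]

    # accessory presence drawn per cluster; a column retained by chance in
    # every genome is cleared in one, so the designated core IS the realized
    # exhaustive single-copy core whenever duplication_rate is 0
    arng = np.random.default_rng(accessory_ss)
    presence = arng.random((spec.n_genomes, spec.accessory_pool)) < spec.accessory_retention
    if spec.n_genomes > 1:
        for j in np.nonzero(presence.all(axis=0))[0]:
            presence[int(arng.integers(0, spec.n_genomes)), j] = False

    cluster_seqs: dict[str, np.ndarray] = {}
    if with_sequences:
        crng = np.random.default_rng(cluster_ss)
        for cid in core_ids + acc_ids:
            cluster_seqs[cid] = _random_dna(crng, spec.gene_length)

    gene_rows = []
    assign_rows = []
    assemblies: dict[str, SagAssembly] = {}
    duplicated: dict[str, set[str]] = {}

    for gi in range(spec.n_genomes):
        rng = np.random.default_rng(genome_ss[gi])
        genome_id = f"G{gi:03d}"
        contig_id = f"{genome_id}_c0"

        placements: list[str] = []
        dups: set[str] = set()
        for cid in core_ids:
            placements.append(cid)
            if spec.duplication_rate and rng.random() < spec.duplication_rate:
                placements.append(cid)
                dups.add(cid)
        for j, cid in enumerate(acc_ids):
            if presence[gi, j]:
                placements.append(cid)
        duplicated[genome_id] = dups

        order = rng.permutation(len(placements))
        placements = [placements[i] for i in order]

        n_genes = len(placements)
        total_gene = n_genes * spec.gene_length
        if total_gene > spec.genome_length:
            raise ValueError(f"cannot pack {n_genes} genes into {spec.genome_length} bp")
        gaps = rng.multinomial(spec.genome_length - total_gene, [1.0 / n_genes] * n_genes)

        if with_sequences:
            seq_arr = _random_dna(rng, spec.genome_length)

        pos = 0
        for j, cid in enumerate(placements):
            pos += int(gaps[j])
            start, end = pos, pos + spec.gene_length
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"{genome_id}_g{j:05d}"
            gene_rows.append((gene_id, genome_id, contig_id, start, end, strand))
            assign_rows.append((gene_id, cid))
            if with_sequences:
                seq_arr[start:end] = cluster_seqs[cid]
            pos = end

        if with_sequences:
            assemblies[genome_id] = SagAssembly(
                id=genome_id, contigs=[(contig_id, seq_arr.tobytes().decode("ascii"))]
            )

    gene_table = pd.DataFrame(
        gene_rows, columns=["gene_id", "genome_id", "contig_id", "start", "end", "strand"]
    )
    assignments = pd.DataFrame(assign_rows, columns=["gene_id", "cluster_id"])
    return Pangenome(
        spec=spec,
        assemblies=assemblies,
        gene_table=gene_table,
        assignments=assignments,
        core_clusters=core_ids,
        accessory_clusters=acc_ids,
        duplicated=duplicated,
    )


@dataclass
class SyntheticSag:
    """A simulated partial genome: windows cut from a circular source genome."""

    source_genome: str
    true_fraction: float
    windows: list[tuple[int, int]]  # (start, length) on the circular source
    marker_count: int
    assembly: SagAssembly | None = None

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def recovered_length(self) -> int:
        return sum(length for _, length in self.windows)


def _markers_in_windows(
    markers: dict[str, tuple[int, int]], windows: list[tuple[int, int]], genome_length: int
) -> int:
    """Count markers whose full span lies inside one window (circular)."""
    count = 0
    for mstart, mend in markers.values():
        mlen = mend - mstart
        for wstart, wlen in windows:
            if wlen >= genome_length or (mstart - wstart) % genome_length + mlen <= wlen:
                count += 1
                break
    return count


def generate_sag(
    genome_length: int,
    markers: dict[str, tuple[int, int]],
    true_fraction: float,
    n_windows: int = 1,
    seed: int = 0,
    sequence: str | None = None,
    source_genome: str = "genome",
) -> SyntheticSag:
    """Cut ``n_windows`` non-overlapping windows totalling ``true_fraction``
    of a circular genome and report the markers fully recovered.

    ``markers`` maps marker id to its (start, end) span on the genome.
    ``true_fraction`` 0 yields an empty SAG; a total window length smaller
    than ``n_windows`` bases is an error.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    rng = np.random.default_rng(seed)
    total = round(true_fraction * genome_length)
    if total == 0:
        return SyntheticSag(source_genome, true_fraction, [], 0, SagAssembly(id=f"{source_genome}_sag", contigs=[]))
    if total < n_windows:
        raise ValueError(
            f"true_fraction x genome_length = {total} bases cannot fill {n_windows} windows"
        )

    # split total bases into n_windows positive parts
    if n_windows == 1:
        lengths = [total]
    else:
        cuts = np.sort(rng.choice(np.arange(1, total), size=n_windows - 1, replace=False))
        bounds = np.concatenate(([0], cuts, [total]))
        lengths = list(np.diff(bounds).astype(int))

    # distribute the slack into n_windows inter-window gaps, then roll
    slack = genome_length - total
    gaps = rng.multinomial(slack, [1.0 / n_windows] * n_windows) if slack else np.zeros(n_windows, dtype=int)
    offset = int(rng.integers(0, genome_length))
    windows: list[tuple[int, int]] = []
    pos = offset
    for wlen, gap in zip(lengths, gaps):
        windows.append((pos % genome_length, int(wlen)))
        pos += int(wlen) + int(gap)

    marker_count = _markers_in_windows(markers, windows, genome_length)
    assembly = None
    if sequence is not None:
        contigs = []
        for i, (start, wlen) in enumerate(windows):
            if start + wlen <= genome_length:
                s = sequence[start : start + wlen]
            else:
                s = sequence[start:] + sequence[: (start + wlen) % genome_length]
            contigs.append((f"{source_genome}_w{i}", s))
        assembly = SagAssembly(id=f"{source_genome}_sag", contigs=contigs)
    return SyntheticSag(source_genome, true_fraction, windows, marker_count, assembly)


def generate_paralog_families(
    n_families: int,
    sizes: int | list[int],
    target_identity: float | list[float],
    length: int = 300,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate protein families with controlled within-family identity.

    Each family descends from an independent random ancestor; members are
    mutated independently per site (substitutions only, no indels) with
    probability ``p = 1 - sqrt(t)``, so the expected pairwise identity
    between two members is ``(1-p)^2 + p^2/19 ~= t``.  Between-family
    sequences are unrelated.  Returns a frame with columns
    ``seq_id, family_id, sequence``.
    """
    if isinstance(sizes, int):
        sizes = [sizes] * n_families
    if isinstance(target_identity, float):
        target_identity = [target_identity] * n_families
    if len(sizes) != n_families or len(target_identity) != n_families:
        raise ValueError("sizes and target_identity must have one entry per family")
    for t in target_identity:
        if not 0.0 <= t <= 1.0:
            raise ValueError("target identities must be in [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    for fi in range(n_families):
        fam_id = f"fam{fi:03d}"
        ancestor = _AA[rng.integers(0, 20, size=length)]
        p = 1.0 - math.sqrt(target_identity[fi])
        for mi in range(sizes[fi]):
            member = ancestor.copy()
            if p > 0:
                mask = rng.random(length) < p
                n_mut = int(mask.sum())
                if n_mut:
                    # substitute with a uniformly chosen *different* residue
                    shift = rng.integers(1, 20, size=n_mut)
                    old_idx = np.searchsorted(_AA, member[mask])
                    member[mask] = _AA[(old_idx + shift) % 20]
            rows.append((f"{fam_id}_m{mi:02d}", fam_id, member.tobytes().decode("ascii")))
    return pd.DataFrame(rows, columns=["seq_id", "family_id", "sequence"])


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each position independently with probability ``rate``.

    Substitutions go to a uniformly chosen different nucleotide; returns
    the mutated sequence and the number of substituted sites.
    """
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    n_mut = int(mask.sum())
    if n_mut:
        old_idx = np.searchsorted(_NT, arr[mask])
        shift = rng.integers(1, 4, size=n_mut)
        arr[mask] = _NT[(old_idx + shift) % 4]
    return arr.tobytes().decode("ascii"), n_mut


def generate_readset(
    genomes: dict[str, str],
    depths: list[float],
    reads_per_depth: int,
    read_length: int,
    mutation_rate: float | dict[float, float],
    seed: int = 0,
    sample: str = "sample1",
    source_weights: dict[str, float] | None = None,
    both_strands: bool = True,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw depth-stratified reads from a set of circular genomes.

    ``mutation_rate`` is a single substitution rate or a per-depth mapping;
    the read's true source genome is drawn uniformly (or per
    ``source_weights``) for every read.  Returns the reads as (id,
    sequence) pairs plus a truth table with columns ``read_id, source,
    sample, depth, identity`` where identity is the realized fraction of
    unmutated sites.
    """
    names = sorted(genomes)
    for name in names:
        if read_length > len(genomes[name]):
            raise ValueError(f"read_length {read_length} exceeds genome {name}")
    weights = np.array([source_weights.get(n, 0.0) if source_weights else 1.0 for n in names], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("source weights must have positive total")
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    truth_rows = []
    for depth in depths:
        rate = mutation_rate[depth] if isinstance(mutation_rate, dict) else mutation_rate
        for ri in range(reads_per_depth):
            src = names[int(rng.choice(len(names), p=weights))]
            genome = genomes[src]
            start = int(rng.integers(0, len(genome)))
            if start + read_length <= len(genome):
                frag = genome[start : start + read_length]
            else:
                frag = genome[start:] + genome[: (start + read_length) % len(genome)]
            frag, n_mut = mutate_sequence(frag, rate, rng)
            if both_strands and rng.random() < 0.5:
                frag = reverse_complement(frag)
            read_id = f"{sample}_d{depth:g}_r{ri:05d}"
            reads.append((read_id, frag))
            truth_rows.append((read_id, src, sample, depth, 1.0 - n_mut / read_length))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "source", "sample", "depth", "identity"])
    return reads, truth
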