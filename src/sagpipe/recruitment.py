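"""Reciprocal best-hit recruitment of metagenomic fragments.

A fragment (read or contig) is recruited to a focal genome in two stages:

1. it must hit the focal scaffolds at all (stage 1), passing a candidate
   filter of e-value <= 1e-5 and alignment length >= 50 by default; and
2. when searched against a combined reference set containing the focal
   scaffolds *and* decoy genomes (stage 2), its single best hit — highest
   bitscore, ties broken by lower e-value, then lexicographic subject id —
   must land on a focal scaffold.

Recruitment is summarized per (sample, depth) as relative recruitment
(percent of reads recruited) together with the mean percent identity of
the recruited fragments.

The module consumes standard tabular hit tables; :func:`align_reads` is a
small built-in semi-global aligner (edlib-backed) used by the synthetic
pipeline to produce such tables without an external search step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from sagpipe.io import Hit, HitTable

DEFAULT_STAGE1_EVALUE = 1e-5
DEFAULT_STAGE1_MIN_LENGTH = 50

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def best_hit(rows) -> Hit | None:
    """The single best hit among rows sharing a query.

    Highest bitscore wins; ties go to the lower e-value, then to the
    lexicographically smaller subject id.  Returns None for no rows;
    raises if the rows mix queries.
    """
    rows = list(rows)
    if not rows:
        return None
    queries = {r.query for r in rows}
    if len(queries) > 1:
        raise ValueError(f"best_hit expects rows for a single query, got {sorted(queries)}")
    return min(rows, key=lambda r: (-r.bitscore, r.evalue, r.subject))


@dataclass
class RbbResult:
    """Outcome of reciprocal best-hit recruitment for one focal genome."""

    focal_ids: set[str]
    candidates: set[str]  # reads passing the stage-1 filter
    recruited: dict[str, Hit]  # read id -> its stage-2 best hit (a focal subject)

    @property
    def recruited_ids(self) -> set[str]:
        return set(self.recruited)


def rbb_recruit(
    stage1: HitTable,
    stage2: HitTable,
    focal_ids: set[str] | list[str],
    evalue_cutoff: float = DEFAULT_STAGE1_EVALUE,
    min_length: int = DEFAULT_STAGE1_MIN_LENGTH,
) -> RbbResult:
    """Two-stage reciprocal best-hit recruitment.

    ``stage1`` holds hits of reads against the focal scaffolds only;
    ``stage2`` holds hits of the stage-1 candidates against the combined
    reference (focal + decoys).  A read is recruited iff it passes the
    stage-1 filter and its stage-2 best hit's subject is a focal scaffold.
    A candidate absent from stage 2 is an error listing the reads.
    """
    focal_ids = set(focal_ids)
    candidates = {
        h.query for h in stage1 if h.evalue <= evalue_cutoff and h.length >= min_length
    }
    stage2_by_query: dict[str, list[Hit]] = {}
    for h in stage2:
        stage2_by_query.setdefault(h.query, []).append(h)
    missing = sorted(candidates - set(stage2_by_query))
    if missing:
        raise ValueError(
            f"{len(missing)} stage-1 candidate reads missing from stage-2 results: {missing[:10]}"
        )
    recruited: dict[str, Hit] = {}
    for read in sorted(candidates):
        best = best_hit(stage2_by_query[read])
        if best is not None and best.subject in focal_ids:
            recruited[read] = best
    return RbbResult(focal_ids=focal_ids, candidates=candidates, recruited=recruited)


def relative_recruitment(recruited: int, total: int) -> float:
    """Relative recruitment as a percentage: 100 x recruited / total."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    if recruited > total:
        raise ValueError("recruited count cannot exceed the total")
    return 100.0 * recruited / total


@dataclass
class RecruitmentProfile:
    """Per-(sample, depth) recruitment summary for one focal genome.

    ``per_depth`` columns: sample, depth, total, recruited, relative_pct,
    mean_pident.  ``reads`` holds one row per recruited read with its
    percent identity, alignment length and subject scaffold.
    """

    focal_genome: str
    per_depth: pd.DataFrame
    reads: pd.DataFrame

    @property
    def mean_identity(self) -> float:
        """Unweighted mean percent identity of all recruited reads (ANI-style)."""
        return float(self.reads["pident"].mean()) if len(self.reads) else float("nan")

    def length_weighted_identity(self) -> float:
        if not len(self.reads):
            return float("nan")
        w = self.reads["length"].to_numpy(dtype=float)
        if w.sum() == 0:
            return self.mean_identity
        return float(np.average(self.reads["pident"], weights=w))


def recruitment_summary(
    result: RbbResult,
    read_meta: pd.DataFrame,
    focal_genome: str = "focal",
) -> RecruitmentProfile:
    """Summarize an RBB result against read metadata.

    ``read_meta`` must have columns ``read_id, sample, depth`` covering
    every read searched (recruited or not); totals per (sample, depth) are
    taken from it.
    """
    for col in ("read_id", "sample", "depth"):
        if col not in read_meta.columns:
            raise ValueError(f"read metadata missing column {col!r}")
    meta = read_meta.set_index("read_id")
    rows = []
    for read_id, hit in result.recruited.items():
        if read_id not in meta.index:
            raise ValueError(f"recruited read {read_id!r} absent from read metadata")
        rows.append(
            (
                read_id,
                meta.at[read_id, "sample"],
                meta.at[read_id, "depth"],
                hit.pident,
                hit.length,
                hit.subject,
            )
        )
    reads = pd.DataFrame(rows, columns=["read_id", "sample", "depth", "pident", "length", "subject"])

    totals = read_meta.groupby(["sample", "depth"], sort=True).size()
    per_rows = []
    for (sample, depth), total in totals.items():
        sub = reads[(reads["sample"] == sample) & (reads["depth"] == depth)]
        per_rows.append(
            (
                sample,
                depth,
                int(total),
                len(sub),
                relative_recruitment(len(sub), int(total)),
                float(sub["pident"].mean()) if len(sub) else float("nan"),
            )
        )
    per_depth = pd.DataFrame(
        per_rows, columns=["sample", "depth", "total", "recruited", "relative_pct", "mean_pident"]
    )
    return RecruitmentProfile(focal_genome=focal_genome, per_depth=per_depth, reads=reads)


def identity_depth_table(profile: RecruitmentProfile) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy (depth, percent identity) pairs plus the mean identity per depth.

    The tidy table feeds recruitment plots (identity vs depth); an empty
    profile yields empty tables.
    """
    if not len(profile.reads):
        tidy = pd.DataFrame(columns=["depth", "pident"])
        means = pd.DataFrame(columns=["depth", "mean_pident", "n"])
        return tidy, means
    tidy = profile.reads[["depth", "pident"]].copy().reset_index(drop=True)
    means = (
        tidy.groupby("depth", sort=True)["pident"]
        .agg(mean_pident="mean", n="size")
        .reset_index()
    )
    return tidy, means


def _hit_from_alignment(
    read_id: str, read_len: int, subject: str, edit_distance: int, db_size: int
) -> Hit:
    matches = max(read_len - edit_distance, 0)
    bitscore = 2.0 * matches
    # Karlin-Altschul-style search-space scaling; a proxy adequate for ranking
    evalue = float(db_size) * float(read_len) * 2.0 ** (-bitscore)
    pident = 100.0 * matches / read_len
    return Hit(
        query=read_id,
        subject=subject,
        pident=pident,
        length=read_len,
        bitscore=bitscore,
        evalue=evalue,
    )


def align_reads(
    reads: list[tuple[str, str]],
    references: list[tuple[str, str]],
    min_identity: float = 0.5,
    both_strands: bool = True,
) -> HitTable:
    """Semi-global alignment of each read against each reference sequence.

    A deterministic, edlib-backed stand-in for an external search tool:
    for every (read, reference) pair the best infix alignment (both
    strands when ``both_strands``) is scored, and a hit is emitted when
    its identity — (read length - edit distance) / read length — reaches
    ``min_identity``.  Bitscore is 2 x matched bases and the e-value is a
    search-space-scaled score transform, adequate for best-hit ranking.
    """
    db_size = sum(len(seq) for _, seq in references)
    hits: list[Hit] = []
    for read_id, read in reads:
        rc = read.translate(_COMPLEMENT)[::-1] if both_strands else None
        for ref_id, ref in references:
            dist = edlib.align(read, ref, mode="HW", task="distance")["editDistance"]
            if rc is not None:
                dist_rc = edlib.align(rc, ref, mode="HW", task="distance")["editDistance"]
                dist = min(dist, dist_rc)
            hit = _hit_from_alignment(read_id, len(read), ref_id, dist, db_size)
            if hit.pident >= 100.0 * min_identity:
                hits.append(hit)
    return HitTable(hits)
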