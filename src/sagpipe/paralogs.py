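"""Paralog profiling, greedy centroid dereplication and family assignment.

Identity between two sequences is computed from a global alignment
(match +1, mismatch -1, gap open -5, gap extend -1 by default) as
identical columns / alignment length, so gaps dilute identity.  The same
metric underlies both the paralog-fraction profile (the fraction of a
proteome's genes with an intragenome match at or above a threshold) and
the dereplication of sequence sets into consensus lineages.

Dereplication is a deterministic greedy centroid pass: sequences are
processed in canonical order (length descending, id ascending) and each
joins the first existing centroid it matches at or above the clustering
threshold, otherwise founds a new cluster.  Consensus sequences are
called per centroid column by strict majority, ties resolved to the
centroid's residue; insertions relative to the centroid carry no columns.

Lineage clusters are then labeled with protein families by majority
rules: the family hit by the most member sequences wins, ties resolved to
the lexicographically smallest family id and flagged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import warnings

import pandas as pd
from Bio import Align

from sagpipe.io import Hit, HitTable

UNASSIGNED = "unassigned"

DEFAULT_SCORING = {
    "match_score": 1.0,
    "mismatch_score": -1.0,
    "open_gap_score": -5.0,
    "extend_gap_score": -1.0,
}


def _make_aligner(scoring: dict | None = None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    for key, value in (scoring or DEFAULT_SCORING).items():
        setattr(aligner, key, value)
    return aligner


def _align(aligner: Align.PairwiseAligner, seq_a: str, seq_b: str):
    return next(iter(aligner.align(seq_a, seq_b)))


def pairwise_identity(seq_a: str, seq_b: str, scoring: dict | None = None) -> float:
    """Global-alignment identity: identical columns / alignment length.

    Symmetric; empty sequences are an error.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot compute identity of an empty sequence")
    aligner = _make_aligner(scoring)
    aln = _align(aligner, seq_a, seq_b)
    counts = aln.counts()
    return counts.identities / aln.length


@dataclass
class ParalogProfile:
    """Fraction of a proteome's genes with an intragenome paralog, per threshold."""

    genome_id: str
    thresholds: list[float]
    fraction_with_paralog: list[float]
    best_identity: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genome_id": self.genome_id,
                "threshold": self.thresholds,
                "fraction_with_paralog": self.fraction_with_paralog,
            }
        )


def paralog_fraction(
    proteome: dict[str, str],
    thresholds: list[float],
    genome_id: str = "genome",
    scoring: dict | None = None,
) -> ParalogProfile:
    """Profile paralog content of one proteome across identity thresholds.

    Each gene's best intragenome identity (excluding self) is computed
    once from all-vs-all global alignments; the fraction at threshold t is
    the share of genes whose best identity reaches t.  The fractions are
    non-increasing in t by construction (asserted).  A single-gene
    proteome warns and reports 0 everywhere.
    """
    thresholds = list(thresholds)
    if any(t2 < t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be sorted ascending")
    ids = sorted(proteome)
    if len(ids) < 2:
        warnings.warn(f"proteome {genome_id!r} has < 2 genes; paralog fractions are all 0")
        return ParalogProfile(genome_id, thresholds, [0.0] * len(thresholds), {i: 0.0 for i in ids})

    aligner = _make_aligner(scoring)
    best: dict[str, float] = {i: 0.0 for i in ids}
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            aln = _align(aligner, proteome[id_a], proteome[id_b])
            ident = aln.counts().identities / aln.length
            if ident > best[id_a]:
                best[id_a] = ident
            if ident > best[id_b]:
                best[id_b] = ident

    n = len(ids)
    fractions = [sum(1 for v in best.values() if v >= t) / n for t in thresholds]
    assert all(f2 <= f1 for f1, f2 in zip(fractions, fractions[1:])), "paralog fractions must be non-increasing"
    return ParalogProfile(genome_id, thresholds, fractions, best)


@dataclass
class LineageCluster:
    """One dereplicated sequence lineage."""

    lineage_id: str
    centroid_id: str
    member_ids: list[str]
    consensus: str
    family_votes: dict[str, int] = field(default_factory=dict)
    assigned_family: str | None = None
    tie: bool = False


def _consensus(
    aligner: Align.PairwiseAligner,
    centroid_seq: str,
    member_seqs: list[str],
) -> str:
    """Centroid-anchored consensus: per centroid column, strict majority of
    aligned member residues; ties (or no majority winner) resolve to the
    centroid's residue."""
    columns: list[Counter] = [Counter() for _ in centroid_seq]
    for mseq in member_seqs:
        if mseq == centroid_seq:
            for i, res in enumerate(centroid_seq):
                columns[i][res] += 1
            continue
        aln = _align(aligner, centroid_seq, mseq)
        target_blocks, query_blocks = aln.aligned
        for (ts, te), (qs, _qe) in zip(target_blocks, query_blocks):
            for off in range(te - ts):
                columns[ts + off][mseq[qs + off]] += 1
    out = []
    for i, counter in enumerate(columns):
        if not counter:
            out.append(centroid_seq[i])
            continue
        top = counter.most_common()
        best_count = top[0][1]
        winners = [res for res, cnt in top if cnt == best_count]
        out.append(winners[0] if len(winners) == 1 else centroid_seq[i])
    return "".join(out)


def dereplicate(
    sequences: dict[str, str],
    identity_threshold: float,
    scoring: dict | None = None,
) -> list[LineageCluster]:
    """Greedy centroid dereplication at the given identity threshold.

    Sequences are processed in canonical order (length descending, then id
    ascending).  Each sequence joins the first existing centroid (in
    founding order) with identity >= threshold, else founds a new
    centroid.  The result is a partition: every input sequence belongs to
    exactly one cluster.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = _make_aligner(scoring)
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    centroids: list[tuple[str, str]] = []  # (centroid id, centroid seq) in founding order
    members: dict[str, list[str]] = {}
    for sid in order:
        seq = sequences[sid]
        placed = False
        for cid, cseq in centroids:
            if seq == cseq:
                ident = 1.0
            else:
                aln = _align(aligner, cseq, seq)
                ident = aln.counts().identities / aln.length
            if ident >= identity_threshold:
                members[cid].append(sid)
                placed = True
                break
        if not placed:
            centroids.append((sid, seq))
            members[sid] = [sid]

    clusters = []
    for idx, (cid, cseq) in enumerate(centroids):
        mem = members[cid]
        consensus = _consensus(aligner, cseq, [sequences[m] for m in mem])
        clusters.append(
            LineageCluster(
                lineage_id=f"lineage{idx:04d}",
                centroid_id=cid,
                member_ids=mem,
                consensus=consensus,
            )
        )
    return clusters


def majority_rules_assign(
    cluster: LineageCluster, member_family_hits: dict[str, str]
) -> str:
    """Assign a lineage to the family hit by the most of its members.

    ``member_family_hits`` maps member sequence id to its family; members
    without an entry cast no vote.  Ties go to the lexicographically
    smallest family id and set the tie flag; a lineage whose members are
    all unlabeled is assigned ``"unassigned"``.  Updates the cluster in
    place and returns the assigned family.
    """
    votes = Counter(
        member_family_hits[m] for m in cluster.member_ids if m in member_family_hits
    )
    cluster.family_votes = dict(votes)
    if not votes:
        cluster.assigned_family = UNASSIGNED
        cluster.tie = False
        return UNASSIGNED
    best_count = max(votes.values())
    winners = sorted(f for f, c in votes.items() if c == best_count)
    cluster.assigned_family = winners[0]
    cluster.tie = len(winners) > 1
    return cluster.assigned_family


def recruit_by_models(
    hit_tables: dict[str, HitTable],
    evalue_cutoff: float = 1e-5,
    bitscore_cutoff: float | None = None,
) -> dict[str, str]:
    """Recruit sequences by a set of profile models and assign each its best model.

    ``hit_tables`` maps model id to that model's hit table (rows: sequence
    as query).  A sequence is recruited when any model hit passes the
    cutoffs; its assigned model is the one with the highest bitscore, ties
    broken by model id.  Returns sequence id -> best model id.
    """
    best: dict[str, tuple[float, str]] = {}
    for model_id in sorted(hit_tables):
        for h in hit_tables[model_id]:
            if h.evalue > evalue_cutoff:
                continue
            if bitscore_cutoff is not None and h.bitscore < bitscore_cutoff:
                continue
            current = best.get(h.query)
            candidate = (h.bitscore, model_id)
            if current is None or candidate[0] > current[0]:
                best[h.query] = candidate
            # equal bitscore: keep the earlier (lexicographically smaller) model
    return {seq: model for seq, (_score, model) in best.items()}


def lineage_table(clusters: list[LineageCluster]) -> pd.DataFrame:
    """Tidy per-lineage table: members, votes, assignment, tie flag."""
    return pd.DataFrame(
        [
            (
                c.lineage_id,
                c.centroid_id,
                len(c.member_ids),
                ";".join(c.member_ids),
                c.assigned_family,
                c.tie,
                ";".join(f"{f}:{n}" for f, n in sorted(c.family_votes.items())),
            )
            for c in clusters
        ],
        columns=["lineage_id", "centroid_id", "n_members", "members", "assigned_family", "tie", "votes"],
    )
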