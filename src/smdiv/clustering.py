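"""Pairwise identity and greedy centroid OTU clustering.

Clustering follows the UCLUST-style greedy scheme: sequences are visited in
(size desc, length desc, id asc) order; each sequence joins the first
centroid (in creation order) within the identity threshold, else seeds a
new centroid. The scheme is order-dependent, so the ordering is part of the
contract and results are deterministic.

Identity comes from a global alignment (match +1, mismatch -1, gap open -2,
gap extend -1) computed by Bio.Align.PairwiseAligner; identity = matches /
alignment columns with terminal-gap columns excluded, so slightly ragged
fragment ends do not dilute the estimate. Internal gaps count as
non-matching columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .seqprep import AmpliconRead

logger = logging.getLogger("smdiv")


def _make_aligner(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner

_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two DNA sequences in [0, 1].

    Terminal gap columns are excluded from the column count; an alignment
    reduced to nothing but terminal gaps has identity 0.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if a == b:
        return 1.0
    # canonical argument order: co-optimal alignments can differ between
    # (a, b) and (b, a), and identity must be symmetric
    if a > b:
        a, b = b, a
    aln = _ALIGNER.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    lo, hi = 0, len(sa)
    while lo < hi and (sa[lo] == "-" or sb[lo] == "-"):
        lo += 1
    while hi > lo and (sa[hi - 1] == "-" or sb[hi - 1] == "-"):
        hi -= 1
    if hi == lo:
        return 0.0
    matches = sum(1 for x, y in zip(sa[lo:hi], sb[lo:hi]) if x == y and x != "-")
    return matches / (hi - lo)


def alignment_score(a: str, b: str) -> float:
    """Optimal global alignment score under the module's scoring scheme."""
    return float(_ALIGNER.align(a, b).score)


@dataclass
class Cluster:
    """A centroid-labelled OTU at a fixed identity threshold."""

    cluster_id: str
    centroid_id: str
    centroid_seq: str
    members: list[AmpliconRead] = field(default_factory=list)
    identity_threshold: float = 0.97
    origin_flags: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return sum(m.size for m in self.members)


def _kmers(seq: str, k: int = 8) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def greedy_cluster(
    seqs: list[AmpliconRead],
    threshold: float,
    origins: dict[str, str] | None = None,
    prescreen: bool = False,
    prescreen_min_share: float = 0.3,
) -> list[Cluster]:
    """Greedy centroid clustering at a fixed identity threshold.

    ``origins`` optionally maps read ids to provenance labels (e.g.
    ``query``/``reference``) recorded on each cluster. The optional 8-mer
    prescreen only aligns against centroids sharing at least
    ``prescreen_min_share`` of the query's 8-mers; switch it off to keep
    the exact contract.
    """
    origins = origins or {}
    ordered = sorted(seqs, key=lambda r: (-r.size, -len(r.sequence), r.id))
    clusters: list[Cluster] = []
    kmer_cache: list[set[str]] = []
    for read in ordered:
        placed = False
        query_kmers = _kmers(read.sequence) if prescreen else None
        for idx, cl in enumerate(clusters):
            if prescreen:
                shared = len(query_kmers & kmer_cache[idx])
                if shared < prescreen_min_share * max(1, len(query_kmers)):
                    continue
            if pairwise_identity(read.sequence, cl.centroid_seq) >= threshold:
                cl.members.append(read)
                if read.id in origins:
                    cl.origin_flags.add(origins[read.id])
                placed = True
                break
        if not placed:
            cl = Cluster(
                cluster_id=f"OTU_{len(clusters) + 1}",
                centroid_id=read.id,
                centroid_seq=read.sequence,
                members=[read],
                identity_threshold=threshold,
            )
            if read.id in origins:
                cl.origin_flags.add(origins[read.id])
            clusters.append(cl)
            if prescreen:
                kmer_cache.append(_kmers(read.sequence))
    logger.info(
        "greedy_cluster: %d sequences -> %d clusters at %.2f",
        len(seqs), len(clusters), threshold,
    )
    return clusters


def build_otu_table(clusters: list[Cluster], sample_ids: list[str] | None = None) -> pd.DataFrame:
    """OTU x sample count matrix; cells sum member sizes per sample.

    Rows are ordered by total abundance descending (ties by cluster id).
    """
    if not clusters:
        return pd.DataFrame(columns=sample_ids or [])
    counts: dict[str, dict[str, int]] = {}
    seen_samples: list[str] = []
    for cl in clusters:
        row: dict[str, int] = {}
        for m in cl.members:
            per_sample = m.sample_sizes or ({m.sample_id: m.size} if m.sample_id else {})
            for s, n in per_sample.items():
                row[s] = row.get(s, 0) + n
                if s not in seen_samples:
                    seen_samples.append(s)
        counts[cl.cluster_id] = row
    cols = sample_ids if sample_ids is not None else sorted(seen_samples)
    table = pd.DataFrame(
        [[counts[c].get(s, 0) for s in cols] for c in counts],
        index=list(counts),
        columns=cols,
        dtype=int,
    )
    order = table.sum(axis=1).sort_values(ascending=False, kind="stable").index
    return table.loc[order]


def pick_representatives(
    clusters: list[Cluster], metadata: pd.DataFrame | None = None
) -> list[tuple[str, str]]:
    """Centroid sequence per cluster with annotated FASTA headers.

    Headers carry cluster id, total size and the majority site and stage
    (from per-sample member counts and the metadata); ties in the majority
    vote break by label order. Headers contain no whitespace so they
    round-trip through FASTA readers.
    """
    site_of, stage_of = {}, {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            site_of[str(row["sample_id"])] = str(row["site"])
            stage_of[str(row["sample_id"])] = str(row["stage"])

    out = []
    for cl in clusters:
        site_votes: dict[str, int] = {}
        stage_votes: dict[str, int] = {}
        for m in cl.members:
            per_sample = m.sample_sizes or ({m.sample_id: m.size} if m.sample_id else {})
            for s, n in per_sample.items():
                if s in site_of:
                    site_votes[site_of[s]] = site_votes.get(site_of[s], 0) + n
                    stage_votes[stage_of[s]] = stage_votes.get(stage_of[s], 0) + n
        maj_site = min(sorted(site_votes), key=lambda k: -site_votes[k]) if site_votes else "NA"
        maj_stage = min(sorted(stage_votes), key=lambda k: -stage_votes[k]) if stage_votes else "NA"
        header = f"{cl.cluster_id};size={cl.size};site={maj_site};stage={maj_stage}"
        out.append((header, cl.centroid_seq))
    return out


def shared_with_reference(
    query: list[tuple[str, str]],
    reference: list[tuple[str, str]],
    thresholds: list[float],
) -> pd.DataFrame:
    """Pooled clustering of query and reference sets at several thresholds.

    For each threshold, clusters the union and reports how many clusters
    contain only query members, only reference members, or both (shared);
    the three counts partition the total.
    """
    reads = [
        AmpliconRead(id=f"q|{rid}", sequence=seq) for rid, seq in query
    ] + [AmpliconRead(id=f"r|{rid}", sequence=seq) for rid, seq in reference]
    origins = {r.id: ("query" if r.id.startswith("q|") else "reference") for r in reads}
    rows = []
    for t in thresholds:
        clusters = greedy_cluster(reads, t, origins=origins)
        shared = sum(1 for c in clusters if c.origin_flags == {"query", "reference"})
        q_only = sum(1 for c in clusters if c.origin_flags == {"query"})
        r_only = sum(1 for c in clusters if c.origin_flags == {"reference"})
        rows.append(
            {
                "threshold": t,
                "total": len(clusters),
                "query_only": q_only,
                "reference_only": r_only,
                "shared": shared,
            }
        )
    return pd.DataFrame(rows)
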