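"""Read preparation for 454-style amplicon data.

Mirrors the standard preprocessing of pyrosequenced amplicons: rolling
quality-window truncation (Q20 over 50 bp), barcode demultiplexing with
barcode+primer clipping, exact dereplication with singleton removal, a
simplified de-novo two-parent chimera test driven by the 1.9 abundance
skew, and trimming all retained reads to a common length.

The fixed stage order is quality_filter -> demultiplex -> dereplicate ->
flag_chimeras -> trim_to_common_length; total read mass is non-increasing
at every stage and each stage logs its input/output counts.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .primers import IUPAC

logger = logging.getLogger("smdiv")

_ACGT = set("ACGT")


@dataclass
class AmpliconRead:
    """A raw or processed amplicon read.

    ``size`` is the duplicate count after dereplication; ``sample_sizes``
    keeps per-sample duplicate counts so OTU tables retain sample
    resolution after pooled dereplication.
    """

    id: str
    sequence: str
    qualities: list[int] | None = None
    sample_id: str | None = None
    size: int = 1
    sample_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )
        if self.size < 1:
            raise ValueError(f"read {self.id}: size must be >= 1")


@dataclass(frozen=True)
class ChimeraParams:
    """Parameters of the simplified two-parent chimera test.

    ``min_crossover_gain`` is the identity improvement the two-parent
    model must show over the best single parent; ``vote_error_tolerance``
    is the fraction of contradicting (wrong-parent) sites tolerated per
    segment, absorbing sequencing errors.
    """

    abundance_skew: float = 1.9
    min_crossover_gain: float = 0.005
    vote_error_tolerance: float = 0.01
    max_parents: int = 32

    def __post_init__(self) -> None:
        if self.abundance_skew <= 1:
            raise ValueError("abundance_skew must be > 1")


def quality_filter(
    reads: list[AmpliconRead], q_cutoff: int = 20, window: int = 50
) -> list[AmpliconRead]:
    """Rolling-window quality truncation and ambiguity removal.

    Windows of ``window`` bases slide one base at a time; a read is
    truncated at the start of the first window whose mean quality falls
    below ``q_cutoff``. Reads shorter than ``window`` after truncation are
    dropped, as are reads containing any ambiguous (non-ACGT) base.
    """
    kept: list[AmpliconRead] = []
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"read {read.id}: quality_filter requires qualities")
        if set(read.sequence) - _ACGT:
            continue
        q = np.asarray(read.qualities, dtype=float)
        cut = len(q)
        if len(q) >= window:
            means = np.convolve(q, np.ones(window) / window, mode="valid")
            bad = np.nonzero(means < q_cutoff)[0]
            if bad.size:
                cut = int(bad[0])
        else:
            cut = 0
        if cut < window:
            continue
        kept.append(
            replace(read, sequence=read.sequence[:cut], qualities=read.qualities[:cut])
        )
    logger.info("quality_filter: %d -> %d reads", len(reads), len(kept))
    return kept


def demultiplex(
    reads: list[AmpliconRead],
    metadata,
    forward_primer: str | None = None,
) -> tuple[list[AmpliconRead], list[AmpliconRead]]:
    """Assign reads to samples by exact 5' barcode match; clip barcode+primer.

    Returns ``(assigned, unassigned)``. When ``forward_primer`` (IUPAC) is
    given it is clipped after the barcode if present at the expected
    offset; reads whose barcode matches no sample go to the unassigned bin.
    """
    barcodes: dict[str, str] = {}
    for _, row in metadata.iterrows():
        bc = row.get("barcode")
        if bc is None or (isinstance(bc, float) and np.isnan(bc)):
            raise ValueError(f"sample {row['sample_id']}: missing barcode")
        if bc in barcodes:
            raise ValueError(f"duplicate barcode {bc!r} in metadata")
        barcodes[str(bc)] = str(row["sample_id"])
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must have equal length")
    (bc_len,) = lengths

    assigned, unassigned = [], []
    for read in reads:
        tag = read.sequence[:bc_len]
        sample = barcodes.get(tag)
        if sample is None:
            unassigned.append(read)
            continue
        clip = bc_len
        if forward_primer is not None:
            k = len(forward_primer)
            rest = read.sequence[bc_len : bc_len + k]
            if len(rest) == k and all(
                base in IUPAC[ch] for ch, base in zip(forward_primer, rest)
            ):
                clip += k
        quals = None if read.qualities is None else read.qualities[clip:]
        assigned.append(
            replace(read, sequence=read.sequence[clip:], qualities=quals, sample_id=sample)
        )
    logger.info(
        "demultiplex: %d reads -> %d assigned, %d unassigned",
        len(reads), len(assigned), len(unassigned),
    )
    return assigned, unassigned


def dereplicate(reads: list[AmpliconRead], min_size: int = 2) -> list[AmpliconRead]:
    """Collapse exact duplicates across samples; drop groups below min_size.

    Dereplication is pooled across samples with per-sample bookkeeping in
    ``sample_sizes``. Output is sorted by size descending then sequence.
    """
    groups: dict[str, Counter] = defaultdict(Counter)
    first_id: dict[str, str] = {}
    for read in reads:
        groups[read.sequence][read.sample_id] += read.size
        first_id.setdefault(read.sequence, read.id)
    uniques = []
    for seq, per_sample in groups.items():
        size = sum(per_sample.values())
        if size < min_size:
            continue
        uniques.append(
            AmpliconRead(
                id=first_id[seq],
                sequence=seq,
                size=size,
                sample_sizes=dict(per_sample),
            )
        )
    uniques.sort(key=lambda r: (-r.size, r.sequence))
    logger.info(
        "dereplicate: %d reads -> %d uniques (min_size=%d)",
        len(reads), len(uniques), min_size,
    )
    return uniques


def _match_profile(query: str, parent: str) -> np.ndarray:
    """Positionwise equality of query vs parent, compared ungapped.

    Sequences are compared over their common prefix length; the chimera
    test runs after length trimming in practice, so an ungapped comparison
    is adequate and keeps the test O(n).
    """
    n = min(len(query), len(parent))
    a = np.frombuffer(query[:n].encode(), dtype=np.uint8)
    b = np.frombuffer(parent[:n].encode(), dtype=np.uint8)
    out = np.zeros(len(query), dtype=bool)
    out[:n] = a == b
    return out


def flag_chimeras(
    reads: list[AmpliconRead], params: ChimeraParams | None = None
) -> tuple[list[AmpliconRead], list[AmpliconRead]]:
    """Simplified de-novo two-parent chimera test on dereplicated reads.

    Queries are visited in ascending abundance; candidate parents are reads
    with size >= abundance_skew x query size. For each parent pair (A, B)
    sites are classified as A-votes (query agrees with A but not B) or
    B-votes (query agrees with B but not A). The query is flagged when
    some breakpoint yields at least one A-vote and essentially no B-votes
    in the prefix, at least one B-vote and essentially no A-votes in the
    suffix ("essentially" = up to ``vote_error_tolerance`` of the segment,
    absorbing sequencing errors), and the two-parent model's full-length
    identity beats the best single parent by ``min_crossover_gain``.
    Returns ``(clean, flagged)``.
    """
    params = params or ChimeraParams()
    g = params.min_crossover_gain
    tol = params.vote_error_tolerance
    order = sorted(reads, key=lambda r: (r.size, r.sequence))
    clean: list[AmpliconRead] = []
    flagged: list[AmpliconRead] = []
    for query in order:
        parents = [
            r
            for r in reads
            if r.size >= params.abundance_skew * query.size and r.sequence != query.sequence
        ]
        parents = sorted(parents, key=lambda r: (-r.size, r.sequence))[: params.max_parents]
        n = len(query.sequence)
        if len(parents) < 2 or n < 2:
            clean.append(query)
            continue
        profiles = np.stack([_match_profile(query.sequence, p.sequence) for p in parents])
        cum = np.cumsum(profiles, axis=1)  # matches in prefix [0, k)
        tot = cum[:, -1]
        best_single = float(tot.max()) / n
        ks = np.arange(1, n)
        tol_pref = np.floor(tol * ks)
        tol_suff = np.floor(tol * (n - ks))
        is_chimera = False
        for ai in range(len(parents)):
            for bi in range(len(parents)):
                if ai == bi:
                    continue
                votes_a = profiles[ai] & ~profiles[bi]
                votes_b = profiles[bi] & ~profiles[ai]
                ca = np.cumsum(votes_a)
                cb = np.cumsum(votes_b)
                qa = ca[:-1]                      # A-votes in prefix [0, k)
                na = cb[:-1]                      # contradicting B-votes there
                qb = cb[-1] - cb[:-1]             # B-votes in suffix
                nb = ca[-1] - ca[:-1]             # contradicting A-votes there
                model = (cum[ai, :-1] + tot[bi] - cum[bi, :-1]) / n
                hit = (
                    (qa >= 1) & (qb >= 1)
                    & (na <= tol_pref) & (nb <= tol_suff)
                    & (model >= best_single + g)
                )
                if bool(hit.any()):
                    is_chimera = True
                    break
            if is_chimera:
                break
        (flagged if is_chimera else clean).append(query)
    clean.sort(key=lambda r: (-r.size, r.sequence))
    flagged.sort(key=lambda r: (-r.size, r.sequence))
    logger.info(
        "flag_chimeras: %d uniques -> %d clean, %d flagged",
        len(reads), len(clean), len(flagged),
    )
    return clean, flagged


def trim_to_common_length(
    reads: list[AmpliconRead], floor: int = 0
) -> list[AmpliconRead]:
    """Cut all reads to the shortest retained length; drop reads below floor."""
    kept = [r for r in reads if len(r.sequence) >= floor]
    if not kept:
        return []
    target = min(len(r.sequence) for r in kept)
    out = [
        replace(
            r,
            sequence=r.sequence[:target],
            qualities=None if r.qualities is None else r.qualities[:target],
        )
        for r in kept
    ]
    logger.info(
        "trim_to_common_length: %d -> %d reads at %d bp", len(reads), len(out), target
    )
    return out


def total_read_mass(reads: list[AmpliconRead]) -> int:
    """Sum of duplicate counts; conserved or decreasing along the pipeline."""
    return sum(r.size for r in reads)
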