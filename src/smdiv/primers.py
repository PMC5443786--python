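"""IUPAC degenerate-primer arithmetic and in-silico PCR.

The bundled primer pairs target biosynthetic domains of secondary-metabolite
pathways: the NRPS adenylation domain (A3/A7R, ~700 bp product), the PKS
ketosynthase + methyl-malonyl-CoA transferase region (K1/M6R, ~1,400 bp) and
the Firmicutes PKS acyl carrier protein (Pks firmi_F/R, ~200 bp).

Matching is primer-anchored and ungapped: a mismatch is a target position
whose base is outside the primer's IUPAC set. Minus-strand hits are found by
scanning the reverse complement and are reported in forward coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product
from math import prod

logger = logging.getLogger("smdiv")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement with IUPAC-aware complement rules."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair, both primers written 5'->3'."""

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            _validate_iupac(primer)


@dataclass(frozen=True, order=True)
class PrimerHit:
    """An ungapped primer match on a target, in forward coordinates."""

    sequence_id: str
    start: int
    end: int
    strand: str
    mismatches: int


def _validate_iupac(primer: str) -> None:
    for i, ch in enumerate(primer):
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} at position {i}")


def expand_degenerate(primer: str) -> set[str]:
    """Enumerate all plain-DNA oligonucleotide variants of a primer."""
    _validate_iupac(primer)
    return {"".join(p) for p in product(*(IUPAC[ch] for ch in primer))}


def degeneracy(primer: str) -> int:
    """Number of plain variants, as the per-position degeneracy product."""
    _validate_iupac(primer)
    return prod(len(IUPAC[ch]) for ch in primer)


# The three pairs used for amplicon sequencing of biosynthetic domains.
BUNDLED_PAIRS: dict[str, PrimerPair] = {
    "AD": PrimerPair("A3/A7R", "GCSTACSYSATSTACACSTCSGG", "SASGTCVCCSGTSCGGTAS"),
    "KS": PrimerPair("K1/M6R", "TSAAGTCSAACATCGGBCA", "CGCAGGTTSCSGTACCAGTA"),
    "met-mal-CoA": PrimerPair("K1/M6R", "TSAAGTCSAACATCGGBCA", "CGCAGGTTSCSGTACCAGTA"),
    "ACP": PrimerPair(
        "Pks firmi_F/R", "GCNGGNCAYWSNYTNGGNGARTAYA", "CATRWANCKNSWRTGRAANGCNCC"
    ),
}


def _mismatches_at(primer: str, target: str, start: int) -> int:
    return sum(
        1
        for i, ch in enumerate(primer)
        if target[start + i] not in IUPAC[ch]
    )


def _scan_strand(primer: str, target: str, max_mismatch: int) -> list[tuple[int, int]]:
    k = len(primer)
    hits = []
    for start in range(len(target) - k + 1):
        mm = _mismatches_at(primer, target, start)
        if mm <= max_mismatch:
            hits.append((start, mm))
    return hits


def match_primer(
    primer: str,
    sequence: str,
    max_mismatch: int = 0,
    sequence_id: str = "seq",
    both_strands: bool = True,
) -> list[PrimerHit]:
    """Find ungapped primer matches on one or both strands.

    Minus-strand hits are located by scanning the reverse complement of the
    target and converted back to forward coordinates, so ``start:end``
    always slices the forward sequence.
    """
    _validate_iupac(primer)
    sequence = sequence.upper()
    k = len(primer)
    hits = [
        PrimerHit(sequence_id, s, s + k, "+", mm)
        for s, mm in _scan_strand(primer, sequence, max_mismatch)
    ]
    if both_strands:
        rc = reverse_complement(sequence)
        n = len(sequence)
        for s, mm in _scan_strand(primer, rc, max_mismatch):
            hits.append(PrimerHit(sequence_id, n - (s + k), n - s, "-", mm))
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.strand))
    return hits


@dataclass(frozen=True)
class Amplicon:
    sequence_id: str
    sequence: str
    orientation: str  # strand of the template carrying the forward primer
    start: int
    end: int
    multiple: bool = False  # template yielded several candidate amplicons


def extract_amplicons(
    pair: PrimerPair,
    sequences: list[tuple[str, str]],
    min_len: int = 0,
    max_len: int = 10**9,
    max_mismatch: int | None = None,
) -> list[Amplicon]:
    """In-silico PCR: pull out regions bounded by the primer pair.

    An amplicon runs from a forward-primer start to the end of the
    reverse-primer binding site (primers included), with the forward primer
    and the reverse-complemented reverse primer on the same strand. Both
    template orientations are scanned; output is re-oriented so the forward
    primer is 5'. Templates yielding more than one candidate have all
    candidates reported with ``multiple=True``.
    """
    mm = pair.max_mismatch if max_mismatch is None else max_mismatch
    out: list[Amplicon] = []
    for sid, seq in sequences:
        seq = seq.upper()
        candidates: list[Amplicon] = []
        for orient, template in (("+", seq), ("-", reverse_complement(seq))):
            f_hits = match_primer(pair.forward, template, mm, sid, both_strands=False)
            r_site = reverse_complement(pair.reverse)
            r_hits = match_primer(r_site, template, mm, sid, both_strands=False)
            for fh in f_hits:
                for rh in r_hits:
                    if rh.start < fh.end:
                        continue
                    length = rh.end - fh.start
                    if min_len <= length <= max_len:
                        candidates.append(
                            Amplicon(sid, template[fh.start : rh.end], orient, fh.start, rh.end)
                        )
        flag = len(candidates) > 1
        for amp in candidates:
            out.append(
                Amplicon(amp.sequence_id, amp.sequence, amp.orientation, amp.start, amp.end, flag)
            )
    logger.info("extract_amplicons: %d amplicons from %d templates", len(out), len(sequences))
    return out


def build_reference_db(
    candidates: list[tuple[str, str]],
    pair: PrimerPair,
    identity_threshold: float = 0.90,
) -> list[tuple[str, str]]:
    """Build a trimmed, dereplicated reference set from candidate sequences.

    A candidate is kept when both primers match ungapped over their full
    length at per-primer identity >= ``identity_threshold`` (identity =
    1 - mismatches/primer length); the retained region is the amplicon
    (primers included). Exact duplicates are removed and output is ordered
    by id for determinism.
    """
    def allowed(primer: str) -> int:
        return int((1.0 - identity_threshold) * len(primer))

    mm = max(allowed(pair.forward), allowed(pair.reverse))
    amps = extract_amplicons(pair, candidates, max_mismatch=mm)
    # re-check the per-primer identity (extract uses a shared mismatch cap)
    kept: dict[str, str] = {}
    seen: set[str] = set()
    for amp in sorted(amps, key=lambda a: (a.sequence_id, a.start)):
        fwd_mm = _mismatches_at(pair.forward, amp.sequence, 0)
        r_site = reverse_complement(pair.reverse)
        rev_mm = _mismatches_at(r_site, amp.sequence, len(amp.sequence) - len(r_site))
        if fwd_mm > allowed(pair.forward) or rev_mm > allowed(pair.reverse):
            continue
        if amp.sequence in seen:
            continue
        seen.add(amp.sequence)
        key = amp.sequence_id
        suffix = 0
        while key in kept:
            suffix += 1
            key = f"{amp.sequence_id}.{suffix}"
        kept[key] = amp.sequence
    result = sorted(kept.items())
    logger.info(
        "build_reference_db: %d/%d candidates retained", len(result), len(candidates)
    )
    return result


def load_primer_tsv(path) -> dict[str, PrimerPair]:
    """Load primer pairs from a TSV with columns name, forward, reverse."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return {
        str(r["name"]): PrimerPair(str(r["name"]), str(r["forward"]), str(r["reverse"]))
        for _, r in df.iterrows()
    }
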