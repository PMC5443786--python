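"""Synthetic amplicon communities with ground truth.

The generator emulates the study design the pipeline targets: three sites,
two vegetation stages, three biological replicates, per-domain gene
families with controlled between-site overlap, lognormal abundances with
stage-dependent shifts for a fraction of families, exact primer binding
sites flanking each family's domain region, 454-like errors (substitutions
plus homopolymer indels at a ~5% aggregate rate) and optional two-parent
chimeras. Every emitted read has exactly one row in the truth table, so
clustering, diversity, sharing and chimera-flagging results can all be
scored against known answers.

Site membership is built so that (a) exactly round(overlap x n) families
are shared by all sites and (b) the alpha/gamma effective-species overlap
statistic of the true per-site family counts equals the overlap parameter:
the pooled family count is tuned to 3n/(1+2*overlap) by additionally
sharing families between pairs of sites.

Family sequences radiate from one ancestor per community on a star
phylogeny: each family applies its own point mutations to the ancestral
core at a rate placing inter-family identity below the clustering
threshold minus a margin, while reads within a family differ from it only
by sequencing error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .primers import BUNDLED_PAIRS, IUPAC, PrimerPair, reverse_complement
from .seqprep import AmpliconRead

logger = logging.getLogger("smdiv")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic amplicon community.

    Defaults mirror the targeted study design: 3 sites x 2 stages x 3
    replicates, ~200 bp ACP-like amplicons, a 5% aggregate error rate. The
    seed fully determines all output.
    """

    n_sites: int = 3
    n_stages: int = 2
    n_replicates: int = 3
    n_families_per_site: int = 20
    between_site_overlap: float = 0.3
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    reads_per_sample: int = 500
    error_rate: float = 0.05
    homopolymer_indel_weight: float = 0.3
    chimera_rate: float = 0.02
    amplicon_length: int = 200
    domain: str = "ACP"
    cluster_identity: float = 0.95
    identity_margin: float = 0.08
    stage_shift: float = 0.3
    stage_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "between_site_overlap", "error_rate", "homopolymer_indel_weight",
            "chimera_rate", "stage_shift",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.amplicon_length <= 0 or self.reads_per_sample < 0:
            raise ValueError("lengths and read counts must be positive")

    @property
    def sites(self) -> list[str]:
        return [f"P{i+1}" for i in range(self.n_sites)]

    @property
    def stages(self) -> list[str]:
        return ["emergence", "senescence"][: self.n_stages]


def _concrete(primer: str, rng: np.random.Generator) -> str:
    """One plain-DNA realisation of a degenerate primer."""
    return "".join(IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in primer)


def _mutate_core(core: str, n_mut: int, rng: np.random.Generator) -> str:
    seq = np.array(list(core))
    pos = rng.choice(len(seq), size=min(n_mut, len(seq)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = choices[rng.integers(3)]
    return "".join(seq)


@dataclass
class SyntheticCommunity:
    spec: CommunitySpec
    families: list[tuple[str, str]]
    site_membership: dict[str, list[str]]
    metadata: pd.DataFrame = None
    reads: dict[str, list[AmpliconRead]] = field(default_factory=dict)
    truth: pd.DataFrame = None


def generate_families(spec: CommunitySpec) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Family sequences plus per-site membership with controlled overlap.

    Raises if the clustering threshold minus margin falls below the
    identity floor of unrelated mutated sequences.
    """
    if spec.cluster_identity - spec.identity_margin < 0.65:
        raise ValueError(
            "infeasible identity band: threshold - margin below the "
            "random-identity floor (~0.65)"
        )
    rng = np.random.default_rng(spec.seed)
    pair: PrimerPair = BUNDLED_PAIRS[spec.domain]
    fwd = _concrete(pair.forward, rng)
    rev = _concrete(pair.reverse, rng)
    core_len = spec.amplicon_length - len(fwd) - len(rev)
    if core_len <= 0:
        raise ValueError("amplicon_length shorter than the primer pair")

    n = spec.n_families_per_site
    o = spec.between_site_overlap
    sites = spec.sites
    n_shared_all = round(o * n)
    if spec.n_sites == 3:
        gamma_target = 3 * n / (1.0 + 2.0 * o)
        n_pairs = max(0, round(3 * n - 2 * n_shared_all - gamma_target))
    else:
        n_pairs = 0
    per_pair = {}
    if n_pairs:
        site_pairs = list(combinations(sites, 2))
        for idx in range(n_pairs):
            p = site_pairs[idx % len(site_pairs)]
            per_pair[p] = per_pair.get(p, 0) + 1

    membership: dict[str, list[str]] = {s: [] for s in sites}
    families: list[tuple[str, str]] = []
    ancestor = "".join(_BASES[rng.integers(4, size=core_len)])
    # per-family divergence from the star ancestor: inter-family identity
    # ~= 1 - 2*d_frac must sit below threshold - margin
    d_frac = (1.0 - (spec.cluster_identity - spec.identity_margin)) / 2.0
    n_mut = max(1, int(round(d_frac * core_len)))

    def new_family(tag: str) -> str:
        fid = f"fam_{len(families) + 1:04d}_{tag}"
        core = _mutate_core(ancestor, n_mut, rng)
        families.append((fid, fwd + core + reverse_complement(rev)))
        return fid

    for _ in range(n_shared_all):
        fid = new_family("all")
        for s in sites:
            membership[s].append(fid)
    for (sa, sb), count in sorted(per_pair.items()):
        for _ in range(count):
            fid = new_family(f"{sa}{sb}")
            membership[sa].append(fid)
            membership[sb].append(fid)
    for s in sites:
        while len(membership[s]) < n:
            membership[s].append(new_family(s))
        if len(membership[s]) > n:
            raise ValueError(
                "infeasible overlap configuration: pair-sharing exceeds "
                "per-site family budget"
            )
    logger.info(
        "generate_families: %d families (%d shared by all sites)",
        len(families), n_shared_all,
    )
    return families, membership


def _make_metadata(spec: CommunitySpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    barcodes: set[str] = set()
    for site in spec.sites:
        for stage in spec.stages:
            for rep in range(1, spec.n_replicates + 1):
                while True:
                    bc = "".join(_BASES[rng.integers(4, size=10)])
                    if bc not in barcodes:
                        barcodes.add(bc)
                        break
                rows.append(
                    {
                        "sample_id": f"{site}_{stage[:3]}_{rep}",
                        "site": site,
                        "stage": stage,
                        "replicate": rep,
                        "barcode": bc,
                    }
                )
    return pd.DataFrame(rows)


def _homopolymer_runs(seq: str, min_run: int = 3) -> np.ndarray:
    """Boolean mask of positions inside homopolymer runs >= min_run."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mask = np.zeros(len(arr), dtype=bool)
    i = 0
    while i < len(arr):
        j = i
        while j < len(arr) and arr[j] == arr[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def _apply_errors(seq: str, spec: CommunitySpec, rng: np.random.Generator) -> str:
    """Per-base errors: substitutions, with homopolymer-aware indels.

    Each base errs with probability ``error_rate``; inside homopolymer
    runs of length >= 3 the error is realised as a one-base insertion or
    deletion with probability ``homopolymer_indel_weight``, otherwise as a
    substitution.
    """
    if spec.error_rate == 0:
        return seq
    hp = _homopolymer_runs(seq)
    out: list[str] = []
    errs = rng.random(len(seq)) < spec.error_rate
    kinds = rng.random(len(seq))
    ins_or_del = rng.random(len(seq))
    subs = rng.integers(3, size=len(seq))
    for i, base in enumerate(seq):
        if not errs[i]:
            out.append(base)
            continue
        if hp[i] and kinds[i] < spec.homopolymer_indel_weight:
            if ins_or_del[i] < 0.5:
                out.append(base + base)  # insertion extends the run
            # else deletion: emit nothing
        else:
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[subs[i]])
    return "".join(out)


def sample_reads(
    spec: CommunitySpec,
    families: list[tuple[str, str]],
    site_membership: dict[str, list[str]],
) -> tuple[pd.DataFrame, dict[str, list[AmpliconRead]], pd.DataFrame]:
    """Draw per-sample reads; returns (metadata, reads by sample, truth table).

    Family abundances are lognormal per site (shared across that site's
    samples); a ``stage_shift`` fraction of each site's families have
    their abundance multiplied by ``stage_factor`` at senescence. Errors
    and chimeras are applied per read; every read gets one truth row.
    """
    rng = np.random.default_rng(spec.seed + 1)
    seq_of = dict(families)
    metadata = _make_metadata(spec, rng)
    reads: dict[str, list[AmpliconRead]] = {}
    truth_rows = []

    for site in spec.sites:
        fams = site_membership[site]
        abundance = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, len(fams))
        n_shift = int(round(spec.stage_shift * len(fams)))
        shifted = set(rng.choice(len(fams), size=n_shift, replace=False).tolist())
        for stage in spec.stages:
            ab = abundance.copy()
            if stage == "senescence":
                for k in shifted:
                    ab[k] *= spec.stage_factor
            probs = ab / ab.sum()
            for rep in range(1, spec.n_replicates + 1):
                sample_id = f"{site}_{stage[:3]}_{rep}"
                sample_reads_list: list[AmpliconRead] = []
                if spec.reads_per_sample == 0:
                    logger.warning("sample %s: reads_per_sample=0", sample_id)
                counts = rng.multinomial(spec.reads_per_sample, probs)
                parents = np.repeat(np.arange(len(fams)), counts)
                rng.shuffle(parents)
                for i, fam_idx in enumerate(parents):
                    rid = f"{sample_id}_r{i:05d}"
                    fid = fams[fam_idx]
                    template = seq_of[fid]
                    parent_b = ""
                    is_chimera = False
                    if (
                        spec.chimera_rate > 0
                        and len(set(parents.tolist())) >= 2
                        and rng.random() < spec.chimera_rate
                    ):
                        others = [f for f in sorted(set(parents.tolist())) if f != fam_idx]
                        fb = fams[others[rng.integers(len(others))]]
                        sb = seq_of[fb]
                        cut = int(rng.integers(1, min(len(template), len(sb))))
                        template = template[:cut] + sb[cut:]
                        parent_b = fb
                        is_chimera = True
                    seq = _apply_errors(template, spec, rng)
                    sample_reads_list.append(
                        AmpliconRead(
                            id=rid,
                            sequence=seq,
                            qualities=[40] * len(seq),
                            sample_id=sample_id,
                        )
                    )
                    truth_rows.append(
                        {
                            "read_id": rid,
                            "family_id": fid,
                            "site": site,
                            "stage": stage,
                            "replicate": rep,
                            "is_chimera": is_chimera,
                            "parent_b": parent_b,
                        }
                    )
                reads[sample_id] = sample_reads_list
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "family_id", "site", "stage", "replicate", "is_chimera", "parent_b"],
    )
    logger.info(
        "sample_reads: %d reads over %d samples", len(truth), len(reads)
    )
    return metadata, reads, truth


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """End-to-end generation: families, metadata, reads and truth table."""
    families, membership = generate_families(spec)
    metadata, reads, truth = sample_reads(spec, families, membership)
    return SyntheticCommunity(spec, families, membership, metadata, reads, truth)


def pooled_reads(community: SyntheticCommunity) -> list[AmpliconRead]:
    """All reads with sample barcodes prepended, for the demultiplex path."""
    bc = community.metadata.set_index("sample_id")["barcode"]
    pooled = []
    for sample_id, rlist in sorted(community.reads.items()):
        tag = str(bc.loc[sample_id])
        for r in rlist:
            pooled.append(
                AmpliconRead(
                    id=r.id,
                    sequence=tag + r.sequence,
                    qualities=[40] * len(tag) + (r.qualities or []),
                )
            )
    return pooled
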