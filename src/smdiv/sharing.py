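"""Replicate-consistency filtering and shared/specific clade accounting.

A cluster counts as present in a (site, stage) group only when it is seen
in at least ``min_replicates`` of that group's biological replicates; this
filter precedes all sharing comparisons. Venn-style region counts then
partition the filtered clusters by which groups they occur in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

logger = logging.getLogger("smdiv")


@dataclass
class VennReport:
    threshold: float | None
    grouping: str
    region_counts: dict[frozenset, int]
    percentages: dict[frozenset, float]
    total: int


def replicate_consistent(
    otu_table: pd.DataFrame, metadata: pd.DataFrame, min_replicates: int = 2
) -> dict[tuple[str, str], set[str]]:
    """Clusters with replicate-consistent presence per (site, stage) group.

    Returns a map (site, stage) -> set of cluster ids present (nonzero) in
    at least ``min_replicates`` replicates of that group. A cluster is
    retained globally if it passes in at least one group.
    """
    meta = metadata.set_index("sample_id")
    groups: dict[tuple[str, str], list[str]] = {}
    for sample in otu_table.columns:
        if sample not in meta.index:
            raise ValueError(f"sample {sample!r} missing from metadata")
        key = (str(meta.loc[sample, "site"]), str(meta.loc[sample, "stage"]))
        groups.setdefault(key, []).append(sample)
    out: dict[tuple[str, str], set[str]] = {}
    for key, samples in sorted(groups.items()):
        if len(samples) < min_replicates:
            raise ValueError(
                f"group {key} has {len(samples)} replicates, fewer than "
                f"min_replicates={min_replicates}"
            )
        present = (otu_table[samples] > 0).sum(axis=1)
        out[key] = set(present.index[present >= min_replicates])
    kept = set().union(*out.values()) if out else set()
    logger.info(
        "replicate_consistent: %d/%d clusters pass in >=1 group",
        len(kept), len(otu_table),
    )
    return out


def venn_regions(
    sets: dict[str, set], threshold: float | None = None, grouping: str = "by_site"
) -> VennReport:
    """Exact Venn region counts for up to five sets.

    Each element of the union is assigned to exactly one region, the
    non-empty subset of groups containing it; percentages are relative to
    the union size, one decimal.
    """
    if len(sets) < 2:
        raise ValueError("venn_regions requires at least two groups")
    if len(sets) > 5:
        raise ValueError("more than 5 groups: request a combinatorial report instead")
    names = sorted(sets)
    universe = set().union(*sets.values())
    counts: dict[frozenset, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            region = frozenset(combo)
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) if len(combo) < len(names) else set()
            counts[region] = len(inside - outside)
    total = len(universe)
    pct = {
        k: round(100.0 * v / total, 1) if total else 0.0 for k, v in counts.items()
    }
    return VennReport(threshold, grouping, counts, pct, total)


def site_sharing_report(
    otu_table: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float | None = None,
    min_replicates: int = 2,
) -> VennReport:
    """Venn report of clusters across sites, pooling stages after filtering."""
    groups = replicate_consistent(otu_table, metadata, min_replicates)
    by_site: dict[str, set] = {}
    for (site, _stage), clusters in groups.items():
        by_site.setdefault(site, set()).update(clusters)
    return venn_regions(by_site, threshold, "by_site")


def stage_sharing_report(
    tables: dict[float, pd.DataFrame],
    metadata: pd.DataFrame,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Percentage of clusters shared between stages, per site and threshold.

    ``tables`` maps identity threshold -> OTU table clustered at that
    threshold. A cluster is "shared" in a site when it has
    replicate-consistent presence at both emergence and senescence there.
    Per-threshold averages across sites are included as site ``mean``.
    """
    rows = []
    for threshold, table in sorted(tables.items()):
        groups = replicate_consistent(table, metadata, min_replicates)
        sites = sorted({site for site, _ in groups})
        pcts = []
        for site in sites:
            stage_sets = {
                stage: clusters
                for (s, stage), clusters in groups.items()
                if s == site
            }
            if len(stage_sets) < 2:
                raise ValueError(f"site {site!r} lacks both stages")
            union = set().union(*stage_sets.values())
            inter = set.intersection(*stage_sets.values())
            pct = round(100.0 * len(inter) / len(union), 1) if union else 0.0
            pcts.append(pct)
            rows.append(
                {
                    "threshold": threshold,
                    "site": site,
                    "shared": len(inter),
                    "total": len(union),
                    "shared_pct": pct,
                }
            )
        rows.append(
            {
                "threshold": threshold,
                "site": "mean",
                "shared": sum(r["shared"] for r in rows if r["threshold"] == threshold and r["site"] in sites),
                "total": sum(r["total"] for r in rows if r["threshold"] == threshold and r["site"] in sites),
                "shared_pct": round(sum(pcts) / len(pcts), 1) if pcts else 0.0,
            }
        )
    return pd.DataFrame(rows)
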