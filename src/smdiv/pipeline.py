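"""End-to-end pipeline orchestration.

Stages run in a fixed order (simulate -> prep -> cluster -> diversity ->
sharing -> phylo -> stats -> annotate); each stage writes plain files into
the run directory and records its input/output counts in a JSON manifest,
so read-mass accounting can be audited after the fact. Reruns with the
same configuration and seed are byte-identical apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import clustering, diversity, function_annot, io_formats, phylo, seqprep, sharing, stats
from .primers import BUNDLED_PAIRS
from .synthetic_data import CommunitySpec, generate_community, pooled_reads

logger = logging.getLogger("smdiv")

DEFAULT_CONFIG: dict = {
    # CommunitySpec overrides for the bundled demo. The demo lowers the
    # per-base error to 1% (typical pyrosequencing substitution+indel rate)
    # so that exact-duplicate dereplication with singleton removal retains
    # read mass at desk scale; at the generator's 5% aggregate default
    # nearly every read is unique and the singleton filter removes all of
    # them, which is worth knowing but makes a poor demonstration.
    "simulate": {"error_rate": 0.01},
    "prep": {"q_cutoff": 20, "window": 50, "min_size": 2, "abundance_skew": 1.9,
             "length_floor": 0},
    "cluster": {"thresholds": [0.97, 0.90, 0.85, 0.75]},
    "diversity": {},
    "sharing": {"min_replicates": 2},
    "phylo": {"threshold": 0.85, "max_leaves": 200},
    "stats": {"n_boot": 199, "nmds_threshold": 0.97},
    "annotate": {},
}


def _merge(base: dict, override: dict) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None, outdir: str | Path, seed: int = 0) -> dict:
    """Run all stages on a (by default synthetic) community; return manifest."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("pipeline %s: %s", stage, counts)

    # --- simulate -----------------------------------------------------------
    sim_kwargs = dict(cfg["simulate"])
    sim_kwargs["seed"] = seed
    spec = CommunitySpec(**sim_kwargs)
    community = generate_community(spec)
    io_formats.write_metadata(community.metadata, outdir / "metadata.tsv")
    io_formats.write_fasta(community.families, outdir / "families.fasta")
    community.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    raw = pooled_reads(community)
    io_formats.write_fastq(raw, outdir / "reads.fastq")
    record("simulate", families=len(community.families), reads=len(raw))

    # --- prep ---------------------------------------------------------------
    p = cfg["prep"]
    filtered = seqprep.quality_filter(raw, p["q_cutoff"], p["window"])
    fwd = BUNDLED_PAIRS[spec.domain].forward
    assigned, unassigned = seqprep.demultiplex(filtered, community.metadata, fwd)
    uniques = seqprep.dereplicate(assigned, p["min_size"])
    clean, flagged = seqprep.flag_chimeras(
        uniques, seqprep.ChimeraParams(abundance_skew=p["abundance_skew"])
    )
    trimmed = seqprep.trim_to_common_length(clean, p["length_floor"])
    with open(outdir / "prep.fasta", "w") as fh:
        for r in trimmed:
            fh.write(f">{r.id};size={r.size}\n{r.sequence}\n")
    record(
        "prep",
        raw=len(raw), quality_filtered=len(filtered), assigned=len(assigned),
        unassigned=len(unassigned), uniques=len(uniques),
        chimeras_flagged=len(flagged), retained=len(trimmed),
        retained_mass=seqprep.total_read_mass(trimmed),
    )

    # --- cluster ------------------------------------------------------------
    thresholds = list(cfg["cluster"]["thresholds"])
    sample_ids = list(community.metadata["sample_id"])
    tables: dict[float, pd.DataFrame] = {}
    clusters_by_t = {}
    for t in thresholds:
        cls = clustering.greedy_cluster(trimmed, t)
        clusters_by_t[t] = cls
        table = clustering.build_otu_table(cls, sample_ids)
        tables[t] = table
        io_formats.write_otu_table(table, outdir / f"otu_table_{int(round(t*100))}.tsv")
    record("cluster", **{f"clusters_{int(round(t*100))}": len(clusters_by_t[t]) for t in thresholds})

    # --- diversity ----------------------------------------------------------
    t_hi = max(thresholds)
    table = tables[t_hi]
    meta = community.metadata.set_index("sample_id")
    per_site = {}
    for site in sorted(meta["site"].unique()):
        cols = [s for s in table.columns if meta.loc[s, "site"] == site]
        per_site[site] = table[cols].sum(axis=1).tolist()
    pooled = table.sum(axis=1).tolist()
    report = diversity.site_overlap_report(per_site, pooled)
    div_rows = [
        {
            "site": s,
            "observed": r.observed,
            "chao1": round(r.chao1, 1),
            "coverage_pct": r.coverage_pct,
        }
        for s, r in report["per_site"].items()
    ]
    div_rows.append(
        {
            "site": "pooled",
            "observed": report["pooled"].observed,
            "chao1": round(report["pooled"].chao1, 1),
            "coverage_pct": report["pooled"].coverage_pct,
        }
    )
    pd.DataFrame(div_rows).to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    record(
        "diversity",
        mean_alpha=report["mean_alpha"],
        overlap_pct=report["overlap_pct"],
    )

    # --- sharing ------------------------------------------------------------
    sh = cfg["sharing"]
    stage_rep = sharing.stage_sharing_report(
        {t: tables[t] for t in thresholds if t >= 0.85},
        community.metadata,
        sh["min_replicates"],
    )
    stage_rep.to_csv(outdir / "stage_sharing.tsv", sep="\t", index=False)
    site_rep = sharing.site_sharing_report(
        tables[t_hi], community.metadata, t_hi, sh["min_replicates"]
    )
    venn_rows = [
        {
            "region": "+".join(sorted(k)),
            "count": v,
            "percent": site_rep.percentages[k],
        }
        for k, v in sorted(site_rep.region_counts.items(), key=lambda kv: sorted(kv[0]))
    ]
    pd.DataFrame(venn_rows).to_csv(outdir / "site_venn.tsv", sep="\t", index=False)
    record("sharing", site_regions=len(site_rep.region_counts), filtered_total=site_rep.total)

    # --- phylo --------------------------------------------------------------
    ph = cfg["phylo"]
    t_phy = ph["threshold"]
    cls = clusters_by_t.get(t_phy) or clustering.greedy_cluster(trimmed, t_phy)
    reps = clustering.pick_representatives(cls, community.metadata)[: ph["max_leaves"]]
    if len(reps) >= 3:
        dm = phylo.distance_matrix(reps)
        tree = phylo.neighbor_joining(dm)
        (outdir / "representatives.nwk").write_text(phylo.write_newick(tree) + "\n")
        record("phylo", leaves=len(reps))
    else:
        record("phylo", leaves=len(reps), skipped=True)

    # --- stats --------------------------------------------------------------
    st = cfg["stats"]
    table97 = tables.get(st["nmds_threshold"], table)
    nonzero = table97.loc[:, table97.sum(axis=0) > 0]
    D = stats.bray_curtis_matrix(nonzero)
    ordination = stats.nmds(D, seed=seed)
    ordination.coordinates.to_csv(outdir / "nmds_coordinates.tsv", sep="\t")
    diff = stats.fit_differential(
        nonzero, community.metadata, ("site", "stage"), n_boot=st["n_boot"], seed=seed
    )
    diff.per_otu.to_csv(outdir / "differential.tsv", sep="\t")
    record(
        "stats",
        stress=round(ordination.stress, 4),
        shepard_r=round(ordination.shepard_r, 4),
        **{
            f"p_{f}": diff.multivariate[f]["p"] for f in diff.multivariate
        },
    )

    # --- annotate -----------------------------------------------------------
    reps100 = clustering.pick_representatives(clustering.greedy_cluster(trimmed, 1.0))
    fixture = function_annot.make_synthetic_domain_fixture()
    assignments, summary = function_annot.assign_functions(reps100, fixture)
    pd.DataFrame([dataclasses.asdict(a) for a in assignments]).to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )
    record(
        "annotate",
        n_searched=summary.n_searched,
        n_passing=summary.n_passing,
        fraction_linked=round(summary.fraction_linked, 4),
    )

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
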