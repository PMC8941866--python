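"""End-to-end orchestration: profiles -> trophic stats -> classification ->
networks -> association statistics, with input validation and a deterministic
result bundle on disk."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import interactions as inter
from . import io, networks, stats, synthetic, trophic
from .errors import ConfigError, TrophnetError


@dataclass
class PipelineConfig:
    """One run's settings. Exactly one of (input paths, generator) is active."""

    metadata_path: str | None = None
    resource_assay_path: str | None = None
    biofilm_assay_path: str | None = None
    generator: synthetic.GeneratorConfig | None = None
    seed: int = 0
    growth_threshold: float = trophic.GROWTH_THRESHOLD
    overlap_mode: str = "jaccard"
    alpha: float = inter.DEFAULT_ALPHA
    pooling: str = "bio_means"
    on_missing: str = "error"
    modularity_seed: int = 0
    out_dir: str | None = None
    graph_formats: tuple[str, ...] = ("graphml", "gexf")

    def validate(self) -> None:
        paths = (self.metadata_path, self.resource_assay_path, self.biofilm_assay_path)
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.generator is not None and some_paths:
            raise ConfigError("give either input paths or a generator config, not both")
        if self.generator is None and not has_paths:
            raise ConfigError("all three input paths are required without a generator")


@dataclass
class ValidationReport:
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file: str, line, field_name: str, message: str) -> None:
        self.violations.append({"file": file, "line": line,
                                "field": field_name, "message": message})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.violations, columns=["file", "line", "field", "message"])


def validate_inputs(metadata_path, resource_assay_path, biofilm_assay_path) -> ValidationReport:
    """Schema/consistency check of an input bundle; report-only, never raises
    for content problems (line numbers are 1-based including the header)."""
    report = ValidationReport()
    try:
        meta = io.read_strain_metadata(metadata_path)
    except TrophnetError as exc:
        report.add(str(metadata_path), None, "-", str(exc))
        return report
    known = set(meta["strain_id"])

    try:
        res = io.read_resource_assays(resource_assay_path)
    except TrophnetError as exc:
        report.add(str(resource_assay_path), None, "-", str(exc))
        res = None
    if res is not None:
        rfile = str(resource_assay_path)
        for pos, row in enumerate(res.itertuples(index=False), start=2):
            if row.strain_id not in known:
                report.add(rfile, pos, "strain_id", f"unknown strain {row.strain_id!r}")
            if not np.isfinite(row.od600) or row.od600 < 0:
                report.add(rfile, pos, "od600", f"invalid OD reading {row.od600!r}")
        dup = res.duplicated(["strain_id", "resource_id", "replicate"])
        for pos in (dup[dup].index + 2):
            report.add(rfile, int(pos), "replicate", "duplicate (strain, resource, replicate) well")
        resources = pd.unique(res["resource_id"])
        have = set(zip(res["strain_id"], res["resource_id"]))
        for sid in meta["strain_id"]:
            for rid in resources:
                if (sid, rid) not in have:
                    report.add(rfile, None, "resource_id",
                               f"missing assay cell (strain={sid!r}, resource={rid!r})")

    try:
        bio = io.read_biofilm_assays(biofilm_assay_path)
    except TrophnetError as exc:
        report.add(str(biofilm_assay_path), None, "-", str(exc))
        bio = None
    if bio is not None:
        bfile = str(biofilm_assay_path)
        for pos, row in enumerate(bio.itertuples(index=False), start=2):
            for col, sid in (("strain_a", row.strain_a), ("strain_b", row.strain_b)):
                if sid and sid not in known:
                    report.add(bfile, pos, col, f"unknown strain {sid!r}")
            if not np.isfinite(row.a590) or row.a590 < 0:
                report.add(bfile, pos, "a590", f"invalid A590 reading {row.a590!r}")
        mono = bio[bio["strain_b"] == ""]
        counts = mono.groupby("strain_a").size()
        for sid, cnt in counts.items():
            if cnt < 2:
                report.add(bfile, None, "bio_rep",
                           f"monoculture {sid!r} has {cnt} replicate(s); >= 2 required")
        for sid in known - set(mono["strain_a"]):
            report.add(bfile, None, "strain_a", f"no monoculture assay for strain {sid!r}")
    return report


def _load_inputs(config: PipelineConfig):
    if config.generator is not None:
        community = synthetic.generate_community(config.generator, config.seed)
        assays = synthetic.generate_biofilm_assays(community, config.generator, config.seed)
        return community.metadata, community.resource_assays, assays.biofilm
    return (io.read_strain_metadata(config.metadata_path),
            io.read_resource_assays(config.resource_assay_path),
            io.read_biofilm_assays(config.biofilm_assay_path))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and (optionally) write the result bundle.

    Returns a dict of result tables/objects keyed by stage; with
    ``config.out_dir`` set, every table is also written as TSV plus graph
    exports and a deterministic run log.
    """
    config.validate()
    metadata, resource_assays, biofilm = _load_inputs(config)

    profile = trophic.build_profile_matrix(resource_assays,
                                           strain_ids=list(metadata["strain_id"]),
                                           threshold=config.growth_threshold)
    breadth = trophic.breadth_table(profile)
    overlaps = trophic.pairwise_overlap_table(profile)

    # communities: one per treatment plus one per (treatment, fraction) cell
    communities: dict[str, list[str]] = {}
    for treatment, grp in metadata.groupby("treatment", sort=False):
        communities[str(treatment)] = list(grp["strain_id"])
    for (treatment, fraction), grp in metadata.groupby(["treatment", "fraction"], sort=False):
        communities[f"{treatment}_{fraction}"] = list(grp["strain_id"])

    summaries = []
    for cid, members in communities.items():
        s = trophic.community_summary(profile.loc[members], cid)
        summaries.append({"community_id": cid, "S": s.S, "L": s.L,
                          "connectance": s.connectance, "nestedness": s.nestedness})
    community_summaries = pd.DataFrame(summaries)

    interactions = inter.classify_all(biofilm, metadata, alpha=config.alpha,
                                      pooling=config.pooling,
                                      on_missing=config.on_missing)
    counts_treatment = inter.summarize_counts(interactions, metadata, by=("treatment",))
    counts_fraction = inter.summarize_counts(interactions, metadata,
                                             by=("treatment", "fraction"))

    graphs: dict[str, object] = {}
    metric_rows = []
    for treatment in pd.unique(metadata["treatment"]):
        G = networks.build_network(interactions, metadata, str(treatment))
        networks.annotate_breadth(G, breadth)
        graphs[str(treatment)] = G
        metric_rows.append(networks.topology_metrics(G, seed=config.modularity_seed))
        for fraction in pd.unique(metadata.loc[metadata["treatment"] == treatment,
                                               "fraction"]):
            Gf = networks.build_network(interactions, metadata, str(treatment),
                                        str(fraction))
            networks.annotate_breadth(Gf, breadth) if Gf.number_of_nodes() else None
            graphs[f"{treatment}_{fraction}"] = Gf
            if Gf.number_of_nodes():
                metric_rows.append(networks.topology_metrics(Gf, seed=config.modularity_seed))
    network_metrics = networks.metrics_table(metric_rows)

    reg_tables = stats.build_regression_tables(community_summaries, network_metrics,
                                               interactions, overlaps)
    fits = []
    table_a = reg_tables["connectance_vs_positive"]
    if len(table_a) >= 3 and np.ptp(table_a["connectance"]) > 0:
        fits.append(stats.fit_linear_model(table_a["connectance"], table_a["positive_pct"],
                                           "connectance", "positive_pct"))
    for name, xcol, resp in (("nestedness_vs_intensity", "nestedness", "intensity"),
                             ("overlap_vs_intensity", "niche_overlap_pct", "intensity")):
        tbl = reg_tables[name]
        for sign in ("positive", "negative"):
            sub = tbl[tbl["sign"] == sign]
            if len(sub) >= 3 and np.ptp(sub[xcol]) > 0:
                fits.append(stats.fit_linear_model(sub[xcol], sub[resp],
                                                   xcol, f"{resp}_{sign}"))
    model_fits = stats.fits_table(fits)

    # group comparisons of per-pair niche overlap and per-network trophic stats
    comparisons = []
    treat_map = metadata.set_index("strain_id")["treatment"]
    frac_map = metadata.set_index("strain_id")["fraction"]
    ov = overlaps.copy()
    ov["treatment"] = ov["strain_a"].map(treat_map)
    same_treat = ov["treatment"] == ov["strain_b"].map(treat_map)
    within_t = ov[same_treat]
    if within_t["treatment"].nunique() >= 2:
        comparisons.append(stats.anova_tukey(within_t["overlap_jaccard_pct"],
                                             within_t["treatment"],
                                             "niche_overlap~treatment"))
    ov["fraction"] = ov["strain_a"].map(frac_map)
    same_frac = ov["fraction"] == ov["strain_b"].map(frac_map)
    within_f = ov[same_frac]
    if within_f["fraction"].nunique() >= 2:
        comparisons.append(stats.anova_tukey(within_f["overlap_jaccard_pct"],
                                             within_f["fraction"],
                                             "niche_overlap~fraction"))
    cs = community_summaries.copy()
    cs["treatment"] = cs["community_id"].str.split("_").str[0]
    cs["fraction"] = cs["community_id"].str.split("_").str[1]
    if cs.groupby("treatment").size().min() >= 2 and cs["treatment"].nunique() >= 2:
        comparisons.append(stats.anova_tukey(cs["connectance"], cs["treatment"],
                                             "connectance~treatment"))
    sub = cs.dropna(subset=["fraction"])
    if len(sub) and sub.groupby("fraction").size().min() >= 2 and sub["fraction"].nunique() >= 2:
        comparisons.append(stats.anova_tukey(sub["connectance"], sub["fraction"],
                                             "connectance~fraction"))

    results = {
        "metadata": metadata, "profile_matrix": profile, "breadth": breadth,
        "overlaps": overlaps, "community_summaries": community_summaries,
        "interactions": interactions, "counts_treatment": counts_treatment,
        "counts_fraction": counts_fraction, "graphs": graphs,
        "network_metrics": network_metrics, "regression_tables": reg_tables,
        "model_fits": model_fits, "group_comparisons": comparisons,
    }
    if config.out_dir is not None:
        _write_bundle(results, config)
    return results


def _write_bundle(results: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io.write_tsv(results["metadata"], out / "strain_metadata.tsv")
    io.write_tsv(results["profile_matrix"], out / "profile_matrix.tsv", index=True)
    io.write_tsv(results["breadth"], out / "breadth_classes.tsv")
    io.write_tsv(results["overlaps"], out / "pair_overlaps.tsv")
    io.write_tsv(results["community_summaries"], out / "community_trophic.tsv")
    io.write_tsv(results["interactions"], out / "interactions.tsv")
    io.write_tsv(results["counts_treatment"], out / "interaction_counts_treatment.tsv")
    io.write_tsv(results["counts_fraction"], out / "interaction_counts_fraction.tsv")
    io.write_tsv(results["network_metrics"], out / "network_metrics.tsv")
    io.write_tsv(results["model_fits"], out / "model_fits.tsv")
    for name, tbl in results["regression_tables"].items():
        io.write_tsv(tbl, out / f"regression_{name}.tsv")
    comp_rows = []
    for comp in results["group_comparisons"]:
        for row in comp.table.itertuples(index=False):
            comp_rows.append({"grouping": comp.grouping, "group": row.group,
                              "n": row.n, "mean": row.mean, "letters": row.letters,
                              "F": comp.f_statistic, "p_value": comp.p_value})
    io.write_tsv(pd.DataFrame(comp_rows,
                              columns=["grouping", "group", "n", "mean",
                                       "letters", "F", "p_value"]),
                 out / "group_comparisons.tsv")
    gdir = out / "graphs"
    gdir.mkdir(exist_ok=True)
    for name, G in results["graphs"].items():
        safe = name.replace("+", "").replace(" ", "_")
        for fmt in config.graph_formats:
            networks.export_graph(G, gdir / f"{safe}.{fmt}", fmt)
    log_lines = ["trophnet pipeline run", f"seed={config.seed}",
                 f"growth_threshold={config.growth_threshold}",
                 f"overlap_mode={config.overlap_mode}", f"alpha={config.alpha}",
                 f"pooling={config.pooling}", f"modularity_seed={config.modularity_seed}",
                 f"n_strains={len(results['metadata'])}",
                 f"n_pairs_classified={len(results['interactions'])}",
                 f"n_networks={len(results['graphs'])}"]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
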