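"""Association statistics linking trophic patterns to interaction outcomes.

Three families of simple linear models relate community connectance to the
fraction of positive edges (one point per network), and community nestedness
or pairwise niche overlap to interaction intensity (one point per resolved
pair, fitted separately within positive and negative pairs). Group
differences in trophic patterns across fertilizer treatments or aggregate
fractions are assessed by one-way ANOVA with Tukey HSD post hoc comparisons
summarised as a compact letter display.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import (AssemblyError, DegenerateFitError, InsufficientDataError,
                     InvalidInputError)


@dataclass(frozen=True)
class ModelFit:
    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass(frozen=True)
class GroupComparison:
    grouping: str
    f_statistic: float
    p_value: float
    table: pd.DataFrame = field(repr=False)  # group, n, mean, letters


def fit_linear_model(x, y, predictor: str = "x", response: str = "y") -> ModelFit:
    """Ordinary least squares of ``y`` on ``x`` with slope test.

    Returns slope, intercept, R^2 and the two-sided p-value of the slope.
    A response with zero variance yields a flat fit (slope 0, R^2 0, p 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("model fit requires finite values")
    n = x.size
    if n < 3:
        raise DegenerateFitError(f"need >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor has zero variance")
    if np.ptp(y) == 0:
        return ModelFit(predictor, response, 0.0, float(y[0]), 0.0, 1.0, n)
    res = sps.linregress(x, y)
    return ModelFit(predictor, response, float(res.slope), float(res.intercept),
                    float(res.rvalue) ** 2, float(res.pvalue), n)


def fits_table(fits: list[ModelFit]) -> pd.DataFrame:
    return pd.DataFrame([{"predictor": f.predictor, "response": f.response,
                          "n": f.n, "slope": f.slope, "intercept": f.intercept,
                          "r_squared": f.r_squared, "p_value": f.p_value}
                         for f in fits])


def build_regression_tables(community_summaries: pd.DataFrame,
                            network_metrics: pd.DataFrame,
                            interactions: pd.DataFrame,
                            overlaps: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Assemble the three model-input tables.

    * ``connectance_vs_positive`` — one row per network: community
      connectance against the network's positive-edge percentage.
    * ``nestedness_vs_intensity`` — one row per resolved pair: the NODF of
      the pair's treatment community, intensity, and edge sign.
    * ``overlap_vs_intensity`` — one row per resolved pair: the pair's
      Jaccard niche overlap, intensity, and edge sign.
    """
    for col in ("community_id", "connectance", "nestedness"):
        if col not in community_summaries.columns:
            raise AssemblyError(f"community summary lacks column {col!r}")
    merged = community_summaries.merge(
        network_metrics, left_on="community_id", right_on="network_id", how="inner")
    missing = set(network_metrics["network_id"]) - set(community_summaries["community_id"])
    if missing:
        raise AssemblyError(f"no trophic summary for networks: {sorted(missing)}")
    table_a = merged[["community_id", "connectance", "positive_pct"]].dropna()

    resolved = interactions[interactions["regime"].isin(("positive", "negative"))].copy()
    if resolved.empty:
        empty_b = pd.DataFrame(columns=["strain_a", "strain_b", "nestedness",
                                        "intensity", "sign"])
        empty_c = pd.DataFrame(columns=["strain_a", "strain_b", "niche_overlap_pct",
                                        "intensity", "sign"])
        return {"connectance_vs_positive": table_a,
                "nestedness_vs_intensity": empty_b,
                "overlap_vs_intensity": empty_c}

    nodf_by_treatment = community_summaries.set_index("community_id")["nestedness"]
    unknown = set(resolved["treatment"]) - set(nodf_by_treatment.index)
    if unknown:
        raise AssemblyError(f"no community nestedness for treatments: {sorted(unknown)}")
    table_b = pd.DataFrame({
        "strain_a": resolved["strain_a"], "strain_b": resolved["strain_b"],
        "nestedness": resolved["treatment"].map(nodf_by_treatment).to_numpy(),
        "intensity": resolved["intensity"], "sign": resolved["regime"]})

    key = ["strain_a", "strain_b"]
    ov = overlaps.copy()
    ov_swapped = ov.rename(columns={"strain_a": "strain_b", "strain_b": "strain_a"})
    ov_both = pd.concat([ov, ov_swapped], ignore_index=True)
    table_c = resolved.merge(ov_both[key + ["overlap_jaccard_pct"]], on=key, how="left")
    if table_c["overlap_jaccard_pct"].isna().any():
        bad = table_c[table_c["overlap_jaccard_pct"].isna()][key].head()
        raise AssemblyError(f"pairs without overlap values:\n{bad}")
    table_c = pd.DataFrame({
        "strain_a": table_c["strain_a"], "strain_b": table_c["strain_b"],
        "niche_overlap_pct": table_c["overlap_jaccard_pct"],
        "intensity": table_c["intensity"], "sign": table_c["regime"]})
    return {"connectance_vs_positive": table_a,
            "nestedness_vs_intensity": table_b,
            "overlap_vs_intensity": table_c}


def _compact_letters(groups: list[str], means: dict[str, float],
                     nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display from pairwise non-significance relations.

    Groups that are not significantly different must share a letter; groups
    with no shared letter differ. Letters are assigned to the maximal cliques
    of the non-significance graph, ordered by descending clique mean.
    """
    G = nx.Graph()
    G.add_nodes_from(groups)
    G.add_edges_from((a, b) for a, b in (tuple(p) for p in nonsig_pairs if len(p) == 2))
    cliques = [sorted(c) for c in nx.find_cliques(G)]
    cliques.sort(key=lambda c: (-max(means[g] for g in c), c))
    letters: dict[str, str] = {g: "" for g in groups}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for g in clique:
            letters[g] += letter
    return letters


def anova_tukey(values, groups, grouping: str = "group",
                alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with Tukey HSD post hoc grouping.

    Returns the overall F and p plus a per-group table with mean, n and the
    compact letter display at ``alpha``: groups sharing no letter differ.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise InvalidInputError("values and groups must align")
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise InsufficientDataError("need >= 2 groups")
    arrays = {g: values[groups == g] for g in names}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise InsufficientDataError(f"group {g!r} has {arr.size} value(s); >= 2 required")
    f_stat, p = sps.f_oneway(*arrays.values())

    tukey = pairwise_tukeyhsd(values, groups, alpha=alpha)
    nonsig: set[frozenset] = set()
    summary = tukey.summary().data[1:]
    for row in summary:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[-1])
        if not reject:
            nonsig.add(frozenset((g1, g2)))
    means = {g: float(arr.mean()) for g, arr in arrays.items()}
    letters = _compact_letters([str(g) for g in names],
                               {str(g): m for g, m in means.items()},
                               nonsig)
    table = pd.DataFrame({
        "group": [str(g) for g in names],
        "n": [arrays[g].size for g in names],
        "mean": [means[g] for g in names],
        "letters": [letters[str(g)] for g in names]})
    return GroupComparison(grouping, float(f_stat), float(p), table)
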