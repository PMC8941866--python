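"""Trophic patterns from carbon-source utilisation assays.

A strain's metabolic profile is the binary vector of carbon sources it can
grow on, called from endpoint OD600 readings of single-resource minimal-medium
cultures. From the strains x resources binary matrix this module derives every
community-level trophic pattern used downstream:

* resource-breadth classes (specialist / intermediate / generalist),
* pairwise niche overlap (Jaccard or total-panel percentage),
* connectance ``C = L / S**2`` where ``L`` sums each species' used resources
  and ``S`` is species richness,
* nestedness as NODF (Nestedness metric based on Overlap and Decreasing Fill)
  on a 0-100 scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidInputError, SchemaError

#: Endpoint OD600 above which a well is scored as growth.
GROWTH_THRESHOLD = 0.05
#: Strains using strictly less than this fraction of the panel are specialists.
SPECIALIST_MAX_FRACTION = 0.25
#: Strains using strictly more than this fraction of the panel are generalists.
GENERALIST_MIN_FRACTION = 0.50

OVERLAP_MODES = ("jaccard", "total")


@dataclass(frozen=True)
class TrophicBreadthClass:
    strain_id: str
    n_used: int
    breadth_fraction: float
    class_label: str


@dataclass(frozen=True)
class PairTrophicStats:
    strain_a: str
    strain_b: str
    niche_overlap_pct: float
    shared_count: int
    union_count: int


@dataclass(frozen=True)
class CommunityTrophicSummary:
    community_id: str
    S: int
    L: int
    connectance: float
    nestedness: float | None = None


def call_growth(readings: Iterable[float], threshold: float = GROWTH_THRESHOLD) -> int:
    """Score a single (strain, resource) well series as growth (1) or not (0).

    The replicate readings are averaged and growth is called when the mean is
    strictly greater than ``threshold``.
    """
    values = [float(v) for v in readings]
    if not values:
        raise InvalidInputError("growth call requires at least one OD reading")
    if threshold < 0:
        raise InvalidInputError(f"negative OD threshold: {threshold}")
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError("OD readings must be finite and >= 0")
    # exact rational mean: boundary cases (mean == threshold) must resolve
    # on the correct side of the strict inequality
    mean = sum(Fraction(v) for v in values) / len(values)
    return int(mean > Fraction(threshold))


def build_profile_matrix(
    assays: pd.DataFrame,
    strain_ids: Sequence[str] | None = None,
    resource_ids: Sequence[str] | None = None,
    threshold: float = GROWTH_THRESHOLD,
) -> pd.DataFrame:
    """Build the binary strains x resources profile matrix from long-format assays.

    Parameters
    ----------
    assays:
        Long-format table with columns ``strain_id``, ``resource_id`` and
        ``od600`` (one row per replicate well).
    strain_ids, resource_ids:
        Expected row/column orders. Default: order of first appearance.
        Every (strain, resource) cell in the cross product must be present.
    """
    required = {"strain_id", "resource_id", "od600"}
    missing_cols = required - set(assays.columns)
    if missing_cols:
        raise SchemaError(f"resource assay table missing columns: {sorted(missing_cols)}")
    if strain_ids is None:
        strain_ids = list(pd.unique(assays["strain_id"]))
    if resource_ids is None:
        resource_ids = list(pd.unique(assays["resource_id"]))
    if len(set(strain_ids)) != len(strain_ids):
        raise SchemaError("duplicate strain identifiers")
    if len(set(resource_ids)) != len(resource_ids):
        raise SchemaError("duplicate resource identifiers")

    grouped = assays.groupby(["strain_id", "resource_id"], sort=False)["od600"]
    cells = {key: vals.tolist() for key, vals in grouped}
    extra = set(cells) - set(itertools.product(strain_ids, resource_ids))
    if extra:
        raise SchemaError(f"unexpected assay cells: {sorted(extra)[:5]}")

    matrix = np.zeros((len(strain_ids), len(resource_ids)), dtype=np.int8)
    for i, sid in enumerate(strain_ids):
        for j, rid in enumerate(resource_ids):
            try:
                readings = cells[(sid, rid)]
            except KeyError:
                raise SchemaError(f"missing assay cell (strain={sid!r}, resource={rid!r})") from None
            matrix[i, j] = call_growth(readings, threshold)
    return pd.DataFrame(matrix, index=pd.Index(strain_ids, name="strain_id"),
                        columns=pd.Index(resource_ids, name="resource_id"))


def classify_trophic_breadth(row: Sequence[int], strain_id: str = "",
                             n_resources: int | None = None) -> TrophicBreadthClass:
    """Classify one strain's resource breadth.

    Specialist: uses < 25% of the panel. Generalist: > 50%. Everything in the
    closed band [25%, 50%] is intermediate. Both cuts are strict inequalities.
    """
    arr = np.asarray(row, dtype=int)
    if n_resources is None:
        n_resources = arr.size
    if n_resources < 1 or arr.size != n_resources:
        raise InvalidInputError(
            f"profile row length {arr.size} != panel size {n_resources}")
    n_used = int(arr.sum())
    frac = n_used / n_resources
    if frac < SPECIALIST_MAX_FRACTION:
        label = "specialist"
    elif frac > GENERALIST_MIN_FRACTION:
        label = "generalist"
    else:
        label = "intermediate"
    return TrophicBreadthClass(strain_id, n_used, frac, label)


def breadth_table(profile: pd.DataFrame) -> pd.DataFrame:
    """Breadth class of every strain in a profile matrix, as a table."""
    records = [classify_trophic_breadth(profile.loc[sid].to_numpy(), sid)
               for sid in profile.index]
    return pd.DataFrame(
        {"strain_id": [r.strain_id for r in records],
         "n_used": [r.n_used for r in records],
         "breadth_fraction": [r.breadth_fraction for r in records],
         "class_label": [r.class_label for r in records]})


def niche_overlap(row_a: Sequence[int], row_b: Sequence[int],
                  mode: str = "jaccard",
                  strain_a: str = "A", strain_b: str = "B") -> PairTrophicStats:
    """Pairwise niche overlap between two binary profiles, as a percentage.

    ``jaccard`` divides the shared-resource count by the union of both
    strains' resource sets; ``total`` divides by the full panel size.
    """
    a = np.asarray(row_a, dtype=bool)
    b = np.asarray(row_b, dtype=bool)
    if a.shape != b.shape:
        raise InvalidInputError(f"profile length mismatch: {a.size} vs {b.size}")
    if mode not in OVERLAP_MODES:
        raise InvalidInputError(f"unknown overlap mode {mode!r}")
    shared = int(np.sum(a & b))
    union = int(np.sum(a | b))
    if mode == "jaccard":
        pct = 0.0 if union == 0 else 100.0 * shared / union
    else:
        pct = 100.0 * shared / a.size
    return PairTrophicStats(strain_a, strain_b, pct, shared, union)


def pairwise_overlap_table(profile: pd.DataFrame) -> pd.DataFrame:
    """All unordered strain pairs with overlap under both modes (vectorised)."""
    M = profile.to_numpy(dtype=bool)
    n, n_res = M.shape
    inter = (M.astype(np.int32) @ M.astype(np.int32).T)
    totals = M.sum(axis=1)
    iu, ju = np.triu_indices(n, k=1)
    shared = inter[iu, ju]
    union = totals[iu] + totals[ju] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, 100.0 * shared / union, 0.0)
    ids = profile.index.to_numpy()
    return pd.DataFrame(
        {"strain_a": ids[iu], "strain_b": ids[ju],
         "shared_count": shared, "union_count": union,
         "overlap_jaccard_pct": jac,
         "overlap_total_pct": 100.0 * shared / n_res})


def connectance(profile: pd.DataFrame, community_id: str = "") -> CommunityTrophicSummary:
    """Community connectance ``C = L / S**2``.

    ``L`` is the total number of species-resource links (sum over species of
    resources used) and ``S`` the species richness. Under this definition C
    can exceed 1 when the resource panel is larger than the community.
    """
    if profile.shape[0] < 1:
        raise InvalidInputError("connectance requires at least one species")
    S = int(profile.shape[0])
    L = int(profile.to_numpy().sum())
    return CommunityTrophicSummary(community_id, S, L, L / S**2)


def _nodf_axis_contributions(M: np.ndarray) -> np.ndarray:
    """Paired NODF contributions over all unordered row pairs of ``M``."""
    totals = M.sum(axis=1)
    inter = M @ M.T
    iu, ju = np.triu_indices(M.shape[0], k=1)
    ti, tj = totals[iu], totals[ju]
    smaller = np.minimum(ti, tj)
    with np.errstate(invalid="ignore", divide="ignore"):
        paired = np.where((ti != tj) & (smaller > 0),
                          100.0 * inter[iu, ju] / np.maximum(smaller, 1), 0.0)
    return paired


def nestedness_nodf(matrix: pd.DataFrame | np.ndarray) -> float:
    """NODF nestedness of a binary matrix, in [0, 100].

    For every unordered pair of rows with strictly different marginal totals
    the paired overlap is ``100 * |intersection| / (smaller total)``; ties
    contribute 0, as do pairs whose smaller total is zero (the convention of
    the original decreasing-fill definition, shared by the R implementations,
    which keeps empty rows/columns in the pair count). Column pairs are
    treated symmetrically. The score is the mean over all row pairs and
    column pairs, which makes it invariant under any permutation of rows or
    columns.
    """
    M = np.asarray(matrix, dtype=np.int64)
    if M.ndim != 2:
        raise InvalidInputError("NODF requires a 2-D binary matrix")
    if not np.isin(M, (0, 1)).all():
        raise InvalidInputError("NODF matrix cells must be 0 or 1")
    if (M.sum(axis=1) > 0).sum() < 2 or (M.sum(axis=0) > 0).sum() < 2:
        raise DegenerateInputError(
            "NODF needs >= 2 non-empty rows and >= 2 non-empty columns")
    row_pairs = _nodf_axis_contributions(M)
    col_pairs = _nodf_axis_contributions(M.T)
    return float((row_pairs.sum() + col_pairs.sum()) / (row_pairs.size + col_pairs.size))


def community_summary(profile: pd.DataFrame, community_id: str,
                      compute_nodf: bool = True) -> CommunityTrophicSummary:
    """S, L, connectance and (when the matrix allows it) NODF for one community."""
    base = connectance(profile, community_id)
    nodf: float | None = None
    if compute_nodf:
        try:
            nodf = nestedness_nodf(profile)
        except DegenerateInputError:
            nodf = None
    return CommunityTrophicSummary(community_id, base.S, base.L, base.connectance, nodf)
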