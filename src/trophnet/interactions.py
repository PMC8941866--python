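"""Classification of pairwise coculture outcomes from biofilm yields.

Every strain pair within a treatment is cocultured and its biofilm yield
(crystal-violet A590) compared with the two monocultures under a three-regime
scheme:

* **positive** — the coculture produces significantly more biofilm than the
  best monoculture producer;
* **negative** — the coculture produces significantly less than the average
  of the two monocultures;
* **unresolved** — neither criterion is met (the buffer between the average
  and the best monoculture absorbs ambiguous pairs).

Because ``best >= average`` always holds, the two regimes are mutually
exclusive. Significance is assessed on replicate yields: a one-sided Welch
two-sample t-test against the best monoculture's replicates for the positive
call, and a one-sided one-sample t-test against the monoculture average for
the negative call. With ``alpha = 1`` the classifier degenerates to the pure
threshold rule on the means, which is also how planted truth regimes are
defined by the synthetic generator.

Interaction intensity is the mean coculture yield itself and later becomes
the network edge weight.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateInputError, InsufficientReplicationError,
                     InvalidInputError, LabelingError, PairingError, SchemaError)

REGIMES = ("positive", "negative", "unresolved")
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PairInteraction:
    strain_a: str
    strain_b: str
    regime: str
    intensity: float
    p_positive: float
    p_negative: float
    co_mean: float
    best_mono_mean: float
    avg_mono_mean: float


def enumerate_pairs(strain_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered strain pairs, in input order."""
    ids = list(strain_ids)
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate strain identifiers")
    if len(ids) < 2:
        raise DegenerateInputError("pair enumeration needs >= 2 strains")
    return list(itertools.combinations(ids, 2))


def _check_replicates(values: Sequence[float], label: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientReplicationError(
            f"{label}: {arr.size} replicate(s); >= 2 required for testing")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise InvalidInputError(f"{label}: A590 replicates must be finite and >= 0")
    return arr


def _exact_mean(values: np.ndarray) -> float:
    """Replicate mean with a single rounding; exact for constant arrays."""
    return float(sum(Fraction(float(v)) for v in values) / len(values))


def _p_greater_two_sample(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Welch p-value for mean(x) > mean(y); exact in the
    zero-variance limit so noise-free data resolves by the means alone."""
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 0.0 if _exact_mean(x) > _exact_mean(y) else 1.0
    res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    p = float(res.pvalue)
    if np.isnan(p):
        return 0.0 if _exact_mean(x) > _exact_mean(y) else 1.0
    return p


def _p_less_one_sample(x: np.ndarray, null_value: float) -> float:
    """One-sided one-sample p-value for mean(x) < null_value."""
    if np.ptp(x) == 0:
        return 0.0 if _exact_mean(x) < null_value else 1.0
    res = stats.ttest_1samp(x, null_value, alternative="less")
    p = float(res.pvalue)
    if np.isnan(p):
        return 0.0 if _exact_mean(x) < null_value else 1.0
    return p


def classify_pair(mono_a: Sequence[float], mono_b: Sequence[float],
                  co: Sequence[float], alpha: float = DEFAULT_ALPHA,
                  strain_a: str = "A", strain_b: str = "B") -> PairInteraction:
    """Classify one coculture against its two monocultures.

    ``mono_a``, ``mono_b`` and ``co`` are replicate A590 yields (biological
    means by convention; any >= 2 replicates work). A monoculture-mean tie is
    broken by pooling both monocultures' replicates for the positive test.
    """
    if not 0 < alpha <= 1:
        raise InvalidInputError(f"alpha must be in (0, 1], got {alpha}")
    a = _check_replicates(mono_a, f"monoculture {strain_a}")
    b = _check_replicates(mono_b, f"monoculture {strain_b}")
    c = _check_replicates(co, f"coculture {strain_a}-{strain_b}")

    # replicate means computed exactly then rounded once, so the strict
    # regime thresholds resolve ties as ties in the zero-noise limit
    # (np.mean of identical values is not always that value)
    mean_a = _exact_mean(a)
    mean_b = _exact_mean(b)
    co_mean = _exact_mean(c)
    best = max(mean_a, mean_b)
    avg = (mean_a + mean_b) / 2
    if mean_a == mean_b:
        best_reps = np.concatenate([a, b])
    else:
        best_reps = a if mean_a > mean_b else b

    p_pos = _p_greater_two_sample(c, best_reps)
    p_neg = _p_less_one_sample(c, avg)

    if p_pos < alpha and co_mean > best:
        regime = "positive"
    elif p_neg < alpha and co_mean < avg:
        regime = "negative"
    else:
        regime = "unresolved"
    return PairInteraction(strain_a, strain_b, regime, float(co_mean),
                           p_pos, p_neg, float(co_mean), float(best), float(avg))


def _replicate_values(df: pd.DataFrame, pooling: str) -> np.ndarray:
    """Collapse one assay's wells to the replicate values used for testing."""
    if pooling == "bio_means":
        return df.groupby("bio_rep")["a590"].mean().to_numpy()
    if pooling == "wells":
        return df["a590"].to_numpy()
    raise InvalidInputError(f"unknown replicate pooling {pooling!r}")


def classify_all(biofilm: pd.DataFrame, metadata: pd.DataFrame,
                 alpha: float = DEFAULT_ALPHA, pooling: str = "bio_means",
                 on_missing: str = "error") -> pd.DataFrame:
    """Classify every within-treatment pair present in the metadata.

    Parameters
    ----------
    biofilm:
        Long-format assay table with columns ``strain_a``, ``strain_b``
        (empty/NaN for monocultures), ``bio_rep``, ``tech_rep``, ``a590``.
    metadata:
        Strain table with columns ``strain_id``, ``treatment`` (and usually
        ``fraction``). Pairs are enumerated within each treatment.
    pooling:
        ``"bio_means"`` (default) averages technical wells within each
        biological replicate before testing, avoiding pseudo-replication;
        ``"wells"`` uses every well.
    on_missing:
        ``"error"`` raises listing the missing assays; ``"skip"`` drops pairs
        without assays.

    Returns a table with one row per classified pair (regime, intensity,
    p-values, mean summaries, treatment label).
    """
    for col in ("strain_a", "strain_b", "bio_rep", "a590"):
        if col not in biofilm.columns:
            raise SchemaError(f"biofilm table missing column {col!r}")
    if on_missing not in ("error", "skip"):
        raise InvalidInputError(f"on_missing must be 'error' or 'skip', got {on_missing!r}")

    meta = metadata.set_index("strain_id")
    known = set(meta.index)
    b = biofilm.copy()
    b["strain_b"] = b["strain_b"].replace("", np.nan)
    referenced = set(b["strain_a"]) | set(b["strain_b"].dropna())
    orphans = referenced - known
    if orphans:
        raise LabelingError(f"biofilm assays reference unknown strains: {sorted(orphans)[:5]}")

    is_mono = b["strain_b"].isna()
    mono_reps: dict[str, np.ndarray] = {
        sid: _replicate_values(grp, pooling)
        for sid, grp in b[is_mono].groupby("strain_a")}
    co_reps: dict[frozenset, np.ndarray] = {}
    for (sa, sb), grp in b[~is_mono].groupby(["strain_a", "strain_b"]):
        if sa == sb:
            raise PairingError(f"coculture assay lists the same strain twice: {sa}")
        key = frozenset((sa, sb))
        if key in co_reps:  # A-B and B-A rows for the same pair
            co_reps[key] = np.concatenate([co_reps[key], _replicate_values(grp, pooling)])
        else:
            co_reps[key] = _replicate_values(grp, pooling)

    rows, missing = [], []
    for treatment, grp in meta.groupby("treatment", sort=False):
        strains = list(grp.index)
        if len(strains) < 2:
            continue
        for sa, sb in enumerate_pairs(strains):
            key = frozenset((sa, sb))
            if sa not in mono_reps or sb not in mono_reps or key not in co_reps:
                missing.append((sa, sb))
                continue
            res = classify_pair(mono_reps[sa], mono_reps[sb], co_reps[key],
                                alpha=alpha, strain_a=sa, strain_b=sb)
            rows.append({"strain_a": sa, "strain_b": sb, "treatment": treatment,
                         "regime": res.regime, "intensity": res.intensity,
                         "p_positive": res.p_positive, "p_negative": res.p_negative,
                         "co_mean": res.co_mean, "best_mono_mean": res.best_mono_mean,
                         "avg_mono_mean": res.avg_mono_mean})
    if missing and on_missing == "error":
        raise SchemaError(
            f"{len(missing)} pair(s) lack mono/co assays, e.g. {missing[:5]}")
    return pd.DataFrame(rows, columns=["strain_a", "strain_b", "treatment", "regime",
                                       "intensity", "p_positive", "p_negative",
                                       "co_mean", "best_mono_mean", "avg_mono_mean"])


def summarize_counts(interactions: pd.DataFrame, metadata: pd.DataFrame | None = None,
                     by: Sequence[str] = ("treatment",)) -> pd.DataFrame:
    """Regime count table per group, mirroring a treatments x regimes layout.

    Grouping by ``fraction`` labels a pair by its shared aggregate fraction;
    cross-fraction pairs are labelled ``"mixed"``.
    """
    if interactions.empty:
        return pd.DataFrame(columns=[*by, "positive", "negative", "unresolved", "total"])
    df = interactions.copy()
    if "fraction" in by:
        if metadata is None:
            raise LabelingError("fraction grouping requires strain metadata")
        frac = metadata.set_index("strain_id")["fraction"]
        missing = (set(df["strain_a"]) | set(df["strain_b"])) - set(frac.index)
        if missing:
            raise LabelingError(f"strains without metadata: {sorted(missing)[:5]}")
        fa = df["strain_a"].map(frac)
        fb = df["strain_b"].map(frac)
        df["fraction"] = np.where(fa == fb, fa, "mixed")
    counts = (df.groupby([*by, "regime"], sort=False).size()
              .unstack("regime", fill_value=0))
    for regime in REGIMES:
        if regime not in counts.columns:
            counts[regime] = 0
    counts = counts[list(REGIMES)]
    counts["total"] = counts.sum(axis=1)
    return counts.reset_index()
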