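"""Seeded synthetic communities with planted trophic and interaction structure.

The generator emulates a culture-collection study design: 122 strains spread
over 3 fertilizer treatments (CK, M, NPK) x 3 soil-aggregate fractions,
profiled on a 46-carbon-source panel and cocultured pairwise within each
treatment with 3 biological x 4 technical biofilm replicates. Everything is
drawn from a single integer seed and emitted together with a truth table
(planted profiles, pairwise overlaps, planted coculture means and regimes)
so recovery can be tested exactly in the noise-free limit.

Planted structure:

* per-strain resource-use probability = class base (specialist /
  intermediate / generalist) + treatment shift + fraction shift, so mean
  niche overlap is ordered NPK > M > CK and macro > micro > silt by default;
* monoculture biofilm means are lognormal;
* each planted coculture mean deviates from the average-monoculture null by
  ``synergy_base + interaction_effect_slope * overlap_fraction`` plus
  pair-level noise, so high-overlap pairs tend toward antagonism;
* truth regimes apply the pure threshold rule (positive above the best
  monoculture, negative below the monoculture average) to planted means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from . import trophic

TREATMENTS = ("CK", "M", "NPK")
FRACTIONS = ("macroaggregates", "microaggregates", "silt+clays")

#: Strain counts per (treatment, fraction) cell; totals 35 + 46 + 41 = 122.
DEFAULT_CELL_COUNTS: dict[tuple[str, str], int] = {
    ("CK", "macroaggregates"): 8, ("CK", "microaggregates"): 11, ("CK", "silt+clays"): 16,
    ("M", "macroaggregates"): 12, ("M", "microaggregates"): 18, ("M", "silt+clays"): 16,
    ("NPK", "macroaggregates"): 16, ("NPK", "microaggregates"): 12, ("NPK", "silt+clays"): 13,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study; defaults reflect the emulated design."""

    cell_counts: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CELL_COUNTS))
    n_resources: int = 46
    specialist_fraction: float = 9 / 122
    generalist_fraction: float = 27 / 122
    # resource-use probability by breadth class
    specialist_use_p: float = 0.15
    intermediate_use_p: float = 0.40
    generalist_use_p: float = 0.62
    # additive shifts to use probability: encode NPK > M > CK, macro > micro > silt
    treatment_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"CK": -0.08, "M": 0.0, "NPK": 0.08})
    fraction_shifts: Mapping[str, float] = field(
        default_factory=lambda: {"macroaggregates": 0.08, "microaggregates": 0.0,
                                 "silt+clays": -0.08})
    # OD600 emission around the growth threshold
    growth_threshold: float = trophic.GROWTH_THRESHOLD
    od_positive_mean: float = 0.30
    od_negative_mean: float = 0.01
    od_noise_sd: float = 0.01
    n_od_replicates: int = 3
    # monoculture biofilm yields (lognormal on A590 scale)
    mono_yield_mean: float = 0.5
    mono_yield_cv: float = 0.3
    # planted coculture deviation from the average-monoculture null
    synergy_base: float = 0.12
    interaction_effect_slope: float = -0.5  # per unit overlap fraction (0..1)
    pair_noise_sd: float = 0.12
    # replicate noise on A590 (biological and technical levels)
    noise_sd: float = 0.05
    n_bio_reps: int = 3
    n_tech_reps: int = 4

    def validate(self) -> None:
        if self.specialist_fraction + self.generalist_fraction > 1:
            raise ConfigError("specialist_fraction + generalist_fraction must be <= 1")
        for name in ("specialist_fraction", "generalist_fraction", "specialist_use_p",
                     "intermediate_use_p", "generalist_use_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.n_resources < 1 or min(self.cell_counts.values()) < 1:
            raise ConfigError("counts must be >= 1")
        for name in ("od_noise_sd", "noise_sd", "pair_noise_sd", "mono_yield_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_od_replicates < 1 or self.n_bio_reps < 1 or self.n_tech_reps < 1:
            raise ConfigError("replicate counts must be >= 1")

    def noise_free(self) -> "GeneratorConfig":
        """Copy with every replicate-level noise source switched off."""
        return replace(self, od_noise_sd=0.0, noise_sd=0.0)


@dataclass
class SyntheticCommunity:
    metadata: pd.DataFrame          # strain_id, treatment, fraction
    resource_assays: pd.DataFrame   # strain_id, resource_id, replicate, od600
    truth_profiles: pd.DataFrame    # binary strains x resources matrix
    truth_strains: pd.DataFrame     # strain_id, planted class, use probability
    truth_group_overlap: pd.DataFrame  # group level mean planted overlap


@dataclass
class SyntheticAssays:
    biofilm: pd.DataFrame           # strain_a, strain_b, bio_rep, tech_rep, a590
    truth_pairs: pd.DataFrame       # per-pair planted means, overlap, regime


def _community_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, 11])


def _assay_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, 23])


def generate_community(config: GeneratorConfig, seed: int) -> SyntheticCommunity:
    """Draw strains, their planted profiles, and the OD600 assay table."""
    config.validate()
    rng = _community_rng(seed)

    rows = []
    for (treatment, fraction), count in config.cell_counts.items():
        for _ in range(count):
            rows.append({"treatment": treatment, "fraction": fraction})
    meta = pd.DataFrame(rows)
    meta.insert(0, "strain_id", [f"S{i + 1:03d}" for i in range(len(meta))])
    n = len(meta)

    p_int = 1.0 - config.specialist_fraction - config.generalist_fraction
    classes = rng.choice(["specialist", "intermediate", "generalist"], size=n,
                         p=[config.specialist_fraction, p_int, config.generalist_fraction])
    base = {"specialist": config.specialist_use_p,
            "intermediate": config.intermediate_use_p,
            "generalist": config.generalist_use_p}
    use_p = np.array([
        base[c] + config.treatment_shifts[t] + config.fraction_shifts[f]
        for c, t, f in zip(classes, meta["treatment"], meta["fraction"])])
    use_p = np.clip(use_p, 0.0, 1.0)

    profiles = (rng.random((n, config.n_resources)) < use_p[:, None]).astype(np.int8)
    resource_ids = [f"C{j + 1:02d}" for j in range(config.n_resources)]
    truth_profiles = pd.DataFrame(profiles,
                                  index=pd.Index(meta["strain_id"], name="strain_id"),
                                  columns=pd.Index(resource_ids, name="resource_id"))

    # OD readings: planted mean well above/below the threshold, jittered
    means = np.where(profiles == 1, config.od_positive_mean, config.od_negative_mean)
    reps = config.n_od_replicates
    noise = rng.normal(0.0, config.od_noise_sd, size=(n, config.n_resources, reps)) \
        if config.od_noise_sd > 0 else np.zeros((n, config.n_resources, reps))
    readings = np.clip(means[:, :, None] + noise, 0.0, None)
    assay = pd.DataFrame({
        "strain_id": np.repeat(meta["strain_id"].to_numpy(), config.n_resources * reps),
        "resource_id": np.tile(np.repeat(resource_ids, reps), n),
        "replicate": np.tile(np.arange(1, reps + 1), n * config.n_resources),
        "od600": readings.reshape(-1)})

    truth_strains = pd.DataFrame({
        "strain_id": meta["strain_id"], "treatment": meta["treatment"],
        "fraction": meta["fraction"], "planted_class": classes,
        "use_probability": use_p,
        "n_used": profiles.sum(axis=1)})

    overlaps = trophic.pairwise_overlap_table(truth_profiles)
    frac_map = meta.set_index("strain_id")["fraction"]
    treat_map = meta.set_index("strain_id")["treatment"]
    ta = overlaps["strain_a"].map(treat_map)
    tb = overlaps["strain_b"].map(treat_map)
    fa = overlaps["strain_a"].map(frac_map)
    fb = overlaps["strain_b"].map(frac_map)
    group_rows = []
    for t in TREATMENTS:
        mask = (ta == t) & (tb == t)
        if mask.any():
            group_rows.append({"grouping": "treatment", "group": t,
                               "mean_overlap_jaccard_pct":
                                   float(overlaps.loc[mask, "overlap_jaccard_pct"].mean())})
    for f in FRACTIONS:
        mask = (fa == f) & (fb == f)
        if mask.any():
            group_rows.append({"grouping": "fraction", "group": f,
                               "mean_overlap_jaccard_pct":
                                   float(overlaps.loc[mask, "overlap_jaccard_pct"].mean())})
    truth_group = pd.DataFrame(group_rows)

    return SyntheticCommunity(meta, assay, truth_profiles, truth_strains, truth_group)


def generate_biofilm_assays(community: SyntheticCommunity,
                            config: GeneratorConfig, seed: int) -> SyntheticAssays:
    """Draw monoculture and within-treatment coculture biofilm replicates."""
    config.validate()
    rng = _assay_rng(seed)
    meta = community.metadata
    profiles = community.truth_profiles

    # lognormal monoculture means with the requested mean and CV
    cv2 = config.mono_yield_cv ** 2
    sigma = np.sqrt(np.log1p(cv2))
    mu = np.log(config.mono_yield_mean) - sigma**2 / 2
    mono_means = pd.Series(rng.lognormal(mu, sigma, size=len(meta)),
                           index=meta["strain_id"].to_numpy())

    pair_rows = []
    for treatment in pd.unique(meta["treatment"]):
        strains = meta.loc[meta["treatment"] == treatment, "strain_id"].tolist()
        for i in range(len(strains)):
            for j in range(i + 1, len(strains)):
                pair_rows.append((strains[i], strains[j], treatment))
    pairs = pd.DataFrame(pair_rows, columns=["strain_a", "strain_b", "treatment"])

    prof = profiles.to_numpy(dtype=bool)
    idx = {sid: k for k, sid in enumerate(profiles.index)}
    ia = pairs["strain_a"].map(idx).to_numpy()
    ib = pairs["strain_b"].map(idx).to_numpy()
    shared = (prof[ia] & prof[ib]).sum(axis=1)
    union = (prof[ia] | prof[ib]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        overlap_pct = np.where(union > 0, 100.0 * shared / union, 0.0)

    ma = mono_means.loc[pairs["strain_a"]].to_numpy()
    mb = mono_means.loc[pairs["strain_b"]].to_numpy()
    avg = (ma + mb) / 2
    best = np.maximum(ma, mb)
    pair_noise = rng.normal(0.0, config.pair_noise_sd, size=len(pairs)) \
        if config.pair_noise_sd > 0 else np.zeros(len(pairs))
    planted_co = np.clip(
        avg + config.synergy_base
        + config.interaction_effect_slope * (overlap_pct / 100.0) + pair_noise,
        0.0, None)
    truth_regime = np.where(planted_co > best, "positive",
                            np.where(planted_co < avg, "negative", "unresolved"))

    truth_pairs = pd.DataFrame({
        "strain_a": pairs["strain_a"], "strain_b": pairs["strain_b"],
        "treatment": pairs["treatment"], "overlap_jaccard_pct": overlap_pct,
        "mono_mean_a": ma, "mono_mean_b": mb, "avg_mono_mean": avg,
        "best_mono_mean": best, "planted_co_mean": planted_co,
        "truth_regime": truth_regime})

    def _replicates(planted: np.ndarray) -> np.ndarray:
        """(n_assays, bio, tech) replicate readings, truncated at 0."""
        n = planted.shape[0]
        if config.noise_sd > 0:
            bio = rng.normal(0.0, config.noise_sd, size=(n, config.n_bio_reps, 1))
            tech = rng.normal(0.0, config.noise_sd,
                              size=(n, config.n_bio_reps, config.n_tech_reps))
        else:
            bio = np.zeros((n, config.n_bio_reps, 1))
            tech = np.zeros((n, config.n_bio_reps, config.n_tech_reps))
        return np.clip(planted[:, None, None] + bio + tech, 0.0, None)

    def _long(sa, sb, readings) -> pd.DataFrame:
        n = len(sa)
        nb, nt = config.n_bio_reps, config.n_tech_reps
        return pd.DataFrame({
            "strain_a": np.repeat(np.asarray(sa, dtype=object), nb * nt),
            "strain_b": np.repeat(np.asarray(sb, dtype=object), nb * nt),
            "bio_rep": np.tile(np.repeat(np.arange(1, nb + 1), nt), n),
            "tech_rep": np.tile(np.arange(1, nt + 1), n * nb),
            "a590": readings.reshape(-1)})

    mono_readings = _replicates(mono_means.to_numpy())
    co_readings = _replicates(planted_co)
    biofilm = pd.concat([
        _long(mono_means.index.to_numpy(), np.full(len(mono_means), "", dtype=object),
              mono_readings),
        _long(pairs["strain_a"].to_numpy(), pairs["strain_b"].to_numpy(), co_readings),
    ], ignore_index=True)
    return SyntheticAssays(biofilm, truth_pairs)


def write_fixture_bundle(community: SyntheticCommunity, assays: SyntheticAssays,
                         directory, config: GeneratorConfig, seed: int) -> dict[str, Path]:
    """Write pipeline input TSVs, truth TSVs and a flat manifest; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "metadata": directory / "metadata.tsv",
        "resource_assays": directory / "resource_assays.tsv",
        "biofilm_assays": directory / "biofilm_assays.tsv",
        "truth_profiles": directory / "truth_profiles.tsv",
        "truth_strains": directory / "truth_strains.tsv",
        "truth_pairs": directory / "truth_pairs.tsv",
        "truth_group_overlap": directory / "truth_group_overlap.tsv",
        "manifest": directory / "manifest.txt",
    }
    community.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    community.resource_assays.to_csv(paths["resource_assays"], sep="\t", index=False)
    assays.biofilm.to_csv(paths["biofilm_assays"], sep="\t", index=False)
    community.truth_profiles.to_csv(paths["truth_profiles"], sep="\t")
    community.truth_strains.to_csv(paths["truth_strains"], sep="\t", index=False)
    assays.truth_pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    community.truth_group_overlap.to_csv(paths["truth_group_overlap"], sep="\t", index=False)

    lines = [f"seed={int(seed)}"]
    for key, value in asdict(config).items():
        if isinstance(value, dict):
            for k, v in value.items():
                kk = "|".join(k) if isinstance(k, tuple) else str(k)
                lines.append(f"{key}.{kk}={v}")
        else:
            lines.append(f"{key}={value}")
    paths["manifest"].write_text("\n".join(lines) + "\n")
    return paths


def generate_bundle(config: GeneratorConfig, seed: int, directory) -> dict[str, Path]:
    """Generate a full community + assay bundle and write it in one call."""
    community = generate_community(config, seed)
    assays = generate_biofilm_assays(community, config, seed)
    return write_fixture_bundle(community, assays, directory, config, seed)
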