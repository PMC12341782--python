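"""Synthetic data generators with known ground truth.

Every other module is testable offline through these generators. They
emulate the three data shapes the pipeline consumes:

* a reference aging cohort — an array-like beta matrix where methylation
  drifts linearly with age plus truncated-Gaussian measurement noise;
* a two-cell-type atlas sample set with strongly separated marker CpGs plus
  null sites, and the matching ground-truth atlas of generating means;
* long-read fragments — binary Bernoulli methylation calls drawn from the
  true cell type's marker means (and optionally from a reference model's
  age-dependent sites, for end-to-end pipeline runs).

All generators are deterministic under their seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .reference import ReferenceAgingModel
from .types import (
    AtlasSampleSet,
    Fragment,
    MethylationProfile,
    ReferenceAgingDataset,
    sites_index,
)


@dataclasses.dataclass
class SimulationConfig:
    """Knobs for the synthetic generators.

    Defaults mirror the study conditions being emulated: a 519-sample
    reference cohort with a broad even age distribution, array-scale beta
    noise (sd 0.02), a myeloid/lymphocyte fragment mixture of 75/25 with a
    5% unassignable tail, marker means separated by 0.5, and 5 CpG calls
    per fragment (the minimum overlap the assignment filter demands).
    """

    seed: int = 0
    # reference aging cohort
    n_reference_samples: int = 519
    n_sites: int = 2000
    age_range: tuple[float, float] = (0.0, 100.0)
    slope_max: float = 0.005  # slopes drawn uniform on [-slope_max, slope_max]
    null_site_fraction: float = 0.2  # fraction of sites with zero age slope
    noise_sd: float = 0.02
    reference_chroms: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
    # cell-type atlas + fragments
    cell_types: tuple[str, str] = ("myeloid", "lymphocyte")
    n_markers: int = 200
    n_null_sites: int = 900
    marker_mean_separation: float = 0.5
    atlas_samples_per_type: int = 5
    atlas_within_sd: float = 0.05
    atlas_coverage: int = 30
    mixture_proportions: tuple[float, ...] = (0.75, 0.25)
    n_fragments: int = 1000
    cpgs_per_read: int = 5
    ineligible_fraction: float = 0.05
    age_sites_per_read: int = 0  # extra age-informative calls per fragment
    reads_per_site: int = 10  # pileup depth for profile simulation

    def __post_init__(self) -> None:
        if abs(sum(self.mixture_proportions) - 1.0) > 1e-9:
            raise ValueError("mixture_proportions must sum to 1")
        if len(self.mixture_proportions) != len(self.cell_types):
            raise ValueError("one mixture proportion per cell type")
        lo, hi = self.age_range
        if not (0 <= lo < hi <= 120):
            raise ValueError("age_range must be within [0, 120] with low < high")
        for name in ("noise_sd", "atlas_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ------------------------------------------------------------------ helpers
def _reference_sites(config: SimulationConfig) -> pd.MultiIndex:
    chroms = config.reference_chroms
    tuples = [
        (chroms[i % len(chroms)], 1_000_000 + 50 * (i // len(chroms)))
        for i in range(config.n_sites)
    ]
    return sites_index(tuples)


MARKER_BASE = 5_000_000  # marker CpGs occupy their own chr1 position block
NULL_BASE = 8_000_000


def _marker_sites(config: SimulationConfig) -> pd.MultiIndex:
    return sites_index([("chr1", MARKER_BASE + 2 * i) for i in range(config.n_markers)])


def _null_sites(config: SimulationConfig) -> pd.MultiIndex:
    return sites_index([("chr1", NULL_BASE + 2 * i) for i in range(config.n_null_sites)])


# ----------------------------------------------------------- reference data
def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceAgingDataset, pd.DataFrame]:
    """Cohort beta matrix with linear age trends; returns (dataset, truth).

    ``truth`` holds the generating slope and intercept per site. Betas are
    ``clip(intercept + slope * age + N(0, noise_sd), 0, 1)``; a
    ``null_site_fraction`` of sites receives slope 0.
    """
    rng = np.random.default_rng(config.seed)
    sites = _reference_sites(config)
    n, m = config.n_reference_samples, config.n_sites

    ages = rng.uniform(*config.age_range, size=n)
    slopes = rng.uniform(-config.slope_max, config.slope_max, size=m)
    null = rng.random(m) < config.null_site_fraction
    slopes[null] = 0.0
    # anchor each site's beta at mid-age inside (0.15, 0.85) so the linear
    # trend rarely saturates over the age range
    mid = 0.5 * (config.age_range[0] + config.age_range[1])
    base = rng.uniform(0.15, 0.85, size=m)
    intercepts = base - slopes * mid

    clean = intercepts[None, :] + slopes[None, :] * ages[:, None]
    noisy = clean + rng.normal(0.0, config.noise_sd, size=(n, m)) if config.noise_sd > 0 else clean
    betas = pd.DataFrame(
        np.clip(noisy, 0.0, 1.0),
        index=[f"S{i:04d}" for i in range(n)],
        columns=sites,
    )
    dataset = ReferenceAgingDataset(
        betas=betas, ages=pd.Series(ages, index=betas.index, name="age")
    )
    truth = pd.DataFrame({"slope": slopes, "intercept": intercepts}, index=sites)
    return dataset, truth


# ------------------------------------------------------- atlas and fragments
def simulate_atlas_samples(
    config: SimulationConfig,
) -> tuple[AtlasSampleSet, pd.DataFrame]:
    """Per-sample atlas betas and the ground-truth mean table.

    Marker sites have per-type means ``0.5 +/- separation/2`` (which type is
    hyper-methylated alternates at random); null sites share one mean across
    types. Within-type sample noise is truncated Gaussian.
    """
    rng = np.random.default_rng(config.seed + 1)
    t_a, t_b = config.cell_types
    markers = _marker_sites(config)
    nulls = _null_sites(config)
    all_sites = markers.append(nulls)

    lo = 0.5 - config.marker_mean_separation / 2.0
    hi = 0.5 + config.marker_mean_separation / 2.0
    a_high = rng.random(len(markers)) < 0.5
    mean_a = np.where(a_high, hi, lo)
    mean_b = np.where(a_high, lo, hi)
    null_means = rng.uniform(0.2, 0.8, size=len(nulls))

    means = {
        t_a: np.concatenate([mean_a, null_means]),
        t_b: np.concatenate([mean_b, null_means]),
    }
    k = config.atlas_samples_per_type
    rows, labels, sample_ids = [], [], []
    for ct in (t_a, t_b):
        for j in range(k):
            noise = rng.normal(0.0, config.atlas_within_sd, size=len(all_sites))
            rows.append(np.clip(means[ct] + noise, 0.0, 1.0))
            labels.append(ct)
            sample_ids.append(f"{ct}_{j}")
    betas = pd.DataFrame(rows, index=sample_ids, columns=all_sites)
    coverage = pd.DataFrame(
        config.atlas_coverage, index=sample_ids, columns=all_sites, dtype=int
    )
    samples = AtlasSampleSet(
        betas=betas, coverage=coverage, labels=pd.Series(labels, index=sample_ids)
    )
    truth = pd.DataFrame({t_a: means[t_a][: len(markers)], t_b: means[t_b][: len(markers)]},
                         index=markers)
    truth.index.names = ["chrom", "pos"]
    return samples, truth


def simulate_fragments(
    config: SimulationConfig,
    atlas: pd.DataFrame,
    reference_model: ReferenceAgingModel | None = None,
    age: float | None = None,
) -> tuple[list[Fragment], list[str]]:
    """Fragments with binary Bernoulli calls from the true type's atlas means.

    Each fragment carries calls at ``cpgs_per_read`` marker CpGs sampled
    without replacement. An ``ineligible_fraction`` of fragments is made to
    fail the eligibility filters (alternating low MAPQ / sex-chromosome
    placement). When a fitted ``reference_model`` and an ``age`` are given,
    each eligible fragment additionally carries ``age_sites_per_read`` calls
    at model sites on its chromosome, drawn Bernoulli from the model's
    age-``age`` prediction — this is the end-to-end hook that lets assigned
    fragments be piled up and age-predicted.
    """
    rng = np.random.default_rng(config.seed + 2)
    types = list(config.cell_types)
    marker_pos = {ct: np.asarray([p for _, p in atlas.index]) for ct in types}
    atlas_means = {ct: atlas[ct].to_numpy(dtype=float) for ct in types}

    age_pos = age_p = None
    if reference_model is not None and age is not None and config.age_sites_per_read > 0:
        tab = reference_model.model_
        on_chr1 = tab.loc[tab.index.get_level_values("chrom") == "chr1"]
        age_pos = on_chr1.index.get_level_values("pos").to_numpy()
        age_p = np.clip(
            on_chr1["slope"].to_numpy() * age + on_chr1["intercept"].to_numpy(),
            1e-3,
            1.0 - 1e-3,
        )

    fragments: list[Fragment] = []
    true_labels: list[str] = []
    labels_idx = rng.choice(len(types), size=config.n_fragments, p=config.mixture_proportions)
    bad = rng.random(config.n_fragments) < config.ineligible_fraction
    for i in range(config.n_fragments):
        ct = types[labels_idx[i]]
        pick = rng.choice(len(marker_pos[ct]), size=config.cpgs_per_read, replace=False)
        probs = atlas_means[ct][pick]
        calls = {
            int(marker_pos[ct][pick[j]]): float(rng.random() < probs[j])
            for j in range(config.cpgs_per_read)
        }
        chrom, mapq = "chr1", 60
        if bad[i]:
            if i % 2 == 0:
                mapq = 5
            else:
                chrom = "chrX"
        elif age_pos is not None and len(age_pos):
            k = min(config.age_sites_per_read, len(age_pos))
            apick = rng.choice(len(age_pos), size=k, replace=False)
            for j in apick:
                calls[int(age_pos[j])] = float(rng.random() < age_p[j])
        fragments.append(Fragment(read_id=f"read_{i:06d}", chrom=chrom, mapq=mapq, calls=calls))
        true_labels.append(ct)
    return fragments, true_labels


def simulate_atlas_and_fragments(
    config: SimulationConfig,
    reference_model: ReferenceAgingModel | None = None,
    age: float | None = None,
) -> tuple[AtlasSampleSet, pd.DataFrame, list[Fragment], list[str]]:
    """One-call generator: atlas sample set, true atlas, fragments, labels."""
    samples, truth = simulate_atlas_samples(config)
    fragments, labels = simulate_fragments(config, truth, reference_model, age)
    return samples, truth, fragments, labels


# ----------------------------------------------------------------- profiles
def simulate_profile_at_age(
    model: ReferenceAgingModel,
    age: float,
    sites: pd.MultiIndex,
    reads_per_site: int,
    seed: int,
    exact: bool = False,
) -> MethylationProfile:
    """Binomial pileup profile at the model's predicted methylation.

    Per site, beta is the success fraction of ``reads_per_site`` Bernoulli
    draws at probability ``clamp(slope * age + intercept)``; ``exact=True``
    bypasses sampling and sets beta to the prediction itself (the
    infinite-depth limit used by self-consistency checks).
    """
    rng = np.random.default_rng(seed)
    p = model.predict_beta(sites, age)
    if exact:
        beta = p
    else:
        beta = rng.binomial(reads_per_site, p).astype(float) / reads_per_site
    return MethylationProfile(
        beta=pd.Series(beta, index=sites),
        coverage=pd.Series(reads_per_site, index=sites, dtype=int),
    )
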