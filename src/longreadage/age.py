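"""Grid-search epigenetic age prediction for sparse methylation profiles.

For a query profile m over the selected age-informative CpGs, the predictor
evaluates, at every age A on a grid (0 to 100 years, step 0.1 by default),
the Bernoulli log-probability of observing the profile given the reference
model's predicted methylation p_k(A) = clamp(slope_k * A + intercept_k):

    P(A) = sum_k [ m_k * log p_k(A) + (1 - m_k) * log(1 - p_k(A)) ]

The grid age maximizing P is the sample's epigenetic age. Fractional m_k
(aggregated beta values) enter the score verbatim; clamping p_k into
[eps, 1 - eps] keeps every term finite.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import InsufficientSitesError, NoSharedSitesError
from .reference import ReferenceAgingModel
from .types import AgePrediction, MethylationProfile

logger = logging.getLogger(__name__)

#: clamp applied to predicted methylation so log terms stay finite
DEFAULT_EPS = 1e-3


def predicted_methylation(
    model: ReferenceAgingModel, site: tuple[str, int], age: float, eps: float = DEFAULT_EPS
) -> float:
    """Model-predicted methylation at one site, clamped into [eps, 1-eps]."""
    if site not in model.model_.index:
        raise KeyError(f"site not in model: {site[0]}:{site[1]}")
    row = model.model_.loc[site]
    return float(np.clip(row["slope"] * age + row["intercept"], eps, 1.0 - eps))


def score_profile(
    profile: MethylationProfile,
    model: ReferenceAgingModel,
    sites: pd.MultiIndex,
    age: float,
    eps: float = DEFAULT_EPS,
) -> float:
    """Log-probability score of the profile at one age over the given sites."""
    scores = _score_grid(profile, model, sites, np.asarray([age], dtype=float), eps)
    return float(scores[0])


def _score_grid(
    profile: MethylationProfile,
    model: ReferenceAgingModel,
    sites: pd.MultiIndex,
    ages: np.ndarray,
    eps: float,
) -> np.ndarray:
    """Vectorized score over an age vector: one matrix pass per profile."""
    if len(sites) == 0:
        raise ValueError("site list is empty")
    missing = sites.difference(model.model_.index)
    if len(missing):
        raise KeyError(f"{len(missing)} sites not in model")
    missing = sites.difference(profile.sites)
    if len(missing):
        raise KeyError(f"{len(missing)} sites not in profile")

    sub = model.model_.loc[sites]
    m = profile.beta.loc[sites].to_numpy(dtype=float)
    # p: (n_sites, n_ages)
    p = sub["slope"].to_numpy()[:, None] * ages[None, :] + sub["intercept"].to_numpy()[:, None]
    np.clip(p, eps, 1.0 - eps, out=p)
    return m @ np.log(p) + (1.0 - m) @ np.log1p(-p)


def age_grid(age_min: float = 0.0, age_max: float = 100.0, age_step: float = 0.1) -> np.ndarray:
    """Inclusive age grid; values rounded to the step's decimals so grid
    points are exact (0.1 increments yield exact multiples of 0.1)."""
    n = int(round((age_max - age_min) / age_step))
    decimals = max(0, -int(np.floor(np.log10(age_step))))
    return np.round(age_min + age_step * np.arange(n + 1), decimals)


class LongReadAgePredictor(BaseEstimator, RegressorMixin):
    """Epigenetic age estimator for sparsely intersecting methylation profiles.

    Fitting builds the per-site reference aging model; prediction selects,
    per profile, the CpGs with the highest |Pearson r| in the
    profile/reference intersection and maximizes the Bernoulli
    log-probability score over the age grid.

    Parameters
    ----------
    selection_mode : {"percentile", "fixed_number"}, default "percentile"
        How many top age-correlating CpGs to use per profile: the top
        ``selection_value`` percent of the intersection, or a fixed count.
    selection_value : float, default 1.0
        Percentile (0, 100] or fixed site count, per ``selection_mode``.
    min_sites : int, default 1
        Profiles with fewer usable sites raise
        :class:`~longreadage.exceptions.InsufficientSitesError`; set to 300
        for cell-free DNA workflows where sparse intersections are unreliable.
    age_min, age_max, age_step : float
        Grid bounds and step in years (default 0 to 100 by 0.1).
    eps : float, default 1e-3
        Clamp for predicted methylation.
    min_samples : int, default 3
        Passed to the underlying :class:`ReferenceAgingModel`.

    Attributes
    ----------
    reference_model_ : ReferenceAgingModel
        The fitted site-wise regression table.
    """

    def __init__(
        self,
        selection_mode: str = "percentile",
        selection_value: float = 1.0,
        min_sites: int = 1,
        age_min: float = 0.0,
        age_max: float = 100.0,
        age_step: float = 0.1,
        eps: float = DEFAULT_EPS,
        min_samples: int = 3,
    ):
        self.selection_mode = selection_mode
        self.selection_value = selection_value
        self.min_sites = min_sites
        self.age_min = age_min
        self.age_max = age_max
        self.age_step = age_step
        self.eps = eps
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, y) -> "LongReadAgePredictor":
        """Fit the reference model on a samples x sites beta matrix and ages."""
        self.reference_model_ = ReferenceAgingModel(min_samples=self.min_samples).fit(X, y)
        return self

    def set_reference(self, model: ReferenceAgingModel) -> "LongReadAgePredictor":
        """Adopt an already-fitted reference model (e.g. loaded from TSV)."""
        self.reference_model_ = model
        return self

    def predict_one(self, profile: MethylationProfile) -> AgePrediction:
        """Full grid-search prediction for one profile.

        Ties in the maximal score resolve to the lowest age (the grid is
        scanned in ascending order).
        """
        if len(profile) == 0:
            raise NoSharedSitesError("profile is empty")
        model = self.reference_model_
        try:
            sites = model.select_sites(
                profile.sites, mode=self.selection_mode, value=self.selection_value
            )
        except NoSharedSitesError:
            raise InsufficientSitesError(0, max(self.min_sites, 1))
        if len(sites) < self.min_sites:
            raise InsufficientSitesError(len(sites), self.min_sites)

        grid = age_grid(self.age_min, self.age_max, self.age_step)
        scores = _score_grid(profile, model, sites, grid.astype(float), self.eps)
        best = int(np.argmax(scores))  # first (lowest-age) argmax on ties
        curve = pd.Series(scores, index=grid, name="score")
        return AgePrediction(
            age_estimate=float(grid[best]),
            score_at_max=float(scores[best]),
            n_sites_used=len(sites),
            score_curve=curve,
        )

    def predict(self, X: list[MethylationProfile]) -> np.ndarray:
        """Vector of age estimates, one per profile."""
        return np.asarray([self.predict_one(p).age_estimate for p in X])


def predict_age(
    profile: MethylationProfile,
    model: ReferenceAgingModel,
    selection_mode: str = "percentile",
    selection_value: float = 1.0,
    min_sites: int = 1,
    age_min: float = 0.0,
    age_max: float = 100.0,
    age_step: float = 0.1,
    eps: float = DEFAULT_EPS,
) -> AgePrediction:
    """Functional wrapper: grid-search age prediction with a prefitted model."""
    est = LongReadAgePredictor(
        selection_mode=selection_mode,
        selection_value=selection_value,
        min_sites=min_sites,
        age_min=age_min,
        age_max=age_max,
        age_step=age_step,
        eps=eps,
    ).set_reference(model)
    return est.predict_one(profile)


def age_deviation(prediction: AgePrediction, chronological_age: float) -> float:
    """Predicted epigenetic age minus chronological age, in years."""
    return prediction.deviation(chronological_age)
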