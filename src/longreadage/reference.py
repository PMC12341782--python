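"""Per-CpG linear age-methylation reference models.

The reference aging model fits, for every CpG site in a cohort methylation
matrix, an ordinary least-squares regression of methylation beta on
chronological age, together with the Pearson correlation between the two.
Sites are later ranked by |r| to pick the most age-informative CpGs, either
as a percentile of the intersection with a query profile (top 1% by default)
or as a fixed number of sites.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import (
    ConstantAgesError,
    NoFittableSitesError,
    NoSharedSitesError,
)
from .types import MethylationProfile, ReferenceAgingDataset

logger = logging.getLogger(__name__)

#: columns of the fitted per-site model table
MODEL_COLUMNS = ["slope", "intercept", "pearson_r", "n_samples"]


class ReferenceAgingModel(BaseEstimator):
    """Site-wise OLS of methylation on age, with Pearson-r site ranking.

    Parameters
    ----------
    min_samples : int, default 3
        Minimum number of complete (age, beta) pairs a site needs to be fit.
        Below 3 the regression and correlation are not meaningful.

    Attributes
    ----------
    model_ : pandas.DataFrame
        One row per retained site, indexed by (chrom, pos), columns
        ``slope`` (beta units / year), ``intercept`` (beta units),
        ``pearson_r`` in [-1, 1] and ``n_samples``. Sites with fewer than
        ``min_samples`` complete pairs, zero beta variance, or zero age
        variance on their pairs are dropped.
    n_sites_ : int
        Number of retained sites.
    """

    def __init__(self, min_samples: int = 3):
        self.min_samples = min_samples

    # ------------------------------------------------------------------ fit
    def fit(self, X: pd.DataFrame, y=None) -> "ReferenceAgingModel":
        """Fit per-site regressions.

        ``X`` is a samples x sites beta matrix (NaN = missing) with a
        (chrom, pos) column MultiIndex; ``y`` the per-sample ages in years.
        Each site is fit on its own complete pairs only.
        """
        if y is None:
            raise ValueError("ages (y) are required")
        if self.min_samples < 3:
            raise ValueError("min_samples must be >= 3")
        ages = np.asarray(y, dtype=float)
        if X.shape[0] != ages.shape[0]:
            raise ValueError("X and y must have one age per sample")
        if X.shape[1] == 0 or X.shape[0] == 0:
            raise NoFittableSitesError("empty reference dataset")
        if np.ptp(ages) == 0:
            raise ConstantAgesError("all reference ages identical; correlation undefined")

        B = X.to_numpy(dtype=float)
        mask = np.isfinite(B)
        n = mask.sum(axis=0).astype(float)

        # per-site sums over each site's own complete pairs
        Bz = np.where(mask, B, 0.0)
        a = ages[:, None]
        sum_a = (a * mask).sum(axis=0)
        sum_a2 = (a**2 * mask).sum(axis=0)
        sum_b = Bz.sum(axis=0)
        sum_b2 = (Bz**2).sum(axis=0)
        sum_ab = (Bz * a).sum(axis=0)

        with np.errstate(invalid="ignore", divide="ignore"):
            s_aa = sum_a2 - sum_a**2 / n
            s_bb = sum_b2 - sum_b**2 / n
            s_ab = sum_ab - sum_a * sum_b / n
            slope = s_ab / s_aa
            intercept = (sum_b - slope * sum_a) / n
            r = s_ab / np.sqrt(s_aa * s_bb)

        # numerical floor: a site whose betas are constant has s_bb ~ 0 up to
        # rounding; scale the tolerance by the magnitude of the sums involved
        tol_b = 1e-12 * np.maximum(sum_b2, 1.0)
        tol_a = 1e-12 * np.maximum(sum_a2, 1.0)
        keep = (n >= self.min_samples) & (s_bb > tol_b) & (s_aa > tol_a)
        keep &= np.isfinite(r)
        if not keep.any():
            raise NoFittableSitesError(
                "no fittable sites: every site has <"
                f"{self.min_samples} complete pairs or zero variance"
            )

        self.model_ = pd.DataFrame(
            {
                "slope": slope[keep],
                "intercept": intercept[keep],
                "pearson_r": np.clip(r[keep], -1.0, 1.0),
                "n_samples": n[keep].astype(int),
            },
            index=X.columns[keep],
        )
        self.model_.index.names = ["chrom", "pos"]
        self.n_sites_ = int(keep.sum())
        return self

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "ReferenceAgingModel":
        """Rehydrate a fitted model from its per-site table (e.g. from TSV)."""
        est = cls()
        missing = [c for c in MODEL_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"model table lacks columns {missing}")
        est.model_ = table[MODEL_COLUMNS].copy()
        est.model_.index.names = ["chrom", "pos"]
        est.n_sites_ = len(table)
        return est

    # ----------------------------------------------------------- prediction
    def predict_beta(self, sites: pd.MultiIndex, age: float, eps: float = 1e-3) -> np.ndarray:
        """Predicted methylation ``clamp(slope*age + intercept, eps, 1-eps)``."""
        sub = self.model_.loc[sites]
        raw = sub["slope"].to_numpy() * age + sub["intercept"].to_numpy()
        return np.clip(raw, eps, 1.0 - eps)

    # ------------------------------------------------------- site selection
    def select_sites(
        self,
        candidate_sites: pd.MultiIndex,
        mode: str = "percentile",
        value: float = 1.0,
    ) -> pd.MultiIndex:
        """Rank the candidate/model intersection by |Pearson r| and truncate.

        ``percentile`` mode keeps the top ``value`` percent (count rounded up,
        so any positive value keeps at least one site); ``fixed_number`` mode
        keeps ``min(value, pool)`` sites. Ties in |r| break by (chrom, pos)
        ascending for reproducibility.
        """
        if mode not in ("percentile", "fixed_number"):
            raise ValueError(f"unknown selection mode {mode!r}")
        pool = self.model_.index.intersection(candidate_sites)
        if len(pool) == 0:
            raise NoSharedSitesError("no shared sites between candidates and model")
        if mode == "percentile":
            if not (0 < value <= 100):
                raise ValueError("percentile value must be in (0, 100]")
            count = math.ceil(value / 100.0 * len(pool))
        else:
            if value < 1 or value != int(value):
                raise ValueError("fixed_number value must be a positive integer")
            count = min(int(value), len(pool))

        sub = self.model_.loc[pool]
        order = (
            sub.assign(abs_r=sub["pearson_r"].abs())
            .sort_values(
                by=["abs_r", "chrom", "pos"],
                ascending=[False, True, True],
                kind="mergesort",
            )
            .index[:count]
        )
        return pd.MultiIndex.from_tuples(order, names=["chrom", "pos"])

    def selection_count(self, candidate_sites: pd.MultiIndex, percentile: float) -> int:
        """Number of sites percentile-mode selection would keep."""
        pool = self.model_.index.intersection(candidate_sites)
        if len(pool) == 0:
            raise NoSharedSitesError("no shared sites between candidates and model")
        return math.ceil(percentile / 100.0 * len(pool))

    def fixed_number_from_cohort(
        self, profiles: list[MethylationProfile], percentile: float = 1.0
    ) -> int:
        """Two-step cutoff: mean per-profile percentile-mode site count.

        Profiles with an empty intersection are excluded with a warning; the
        mean over the rest is rounded to the nearest integer.
        """
        if not profiles:
            raise ValueError("at least one profile required")
        counts = []
        for i, prof in enumerate(profiles):
            try:
                counts.append(self.selection_count(prof.sites, percentile))
            except NoSharedSitesError:
                logger.warning(
                    "profile %d shares no sites with the reference model; excluded", i
                )
        if not counts:
            raise NoSharedSitesError("every profile had an empty intersection")
        return int(round(float(np.mean(counts))))


# ------------------------------------------------------- functional wrappers
def fit_reference(dataset: ReferenceAgingDataset, min_samples: int = 3) -> ReferenceAgingModel:
    """Fit the site-wise reference aging model on a cohort dataset."""
    return ReferenceAgingModel(min_samples=min_samples).fit(dataset.betas, dataset.ages)


def select_sites(
    model: ReferenceAgingModel,
    candidate_sites: pd.MultiIndex,
    mode: str = "percentile",
    value: float = 1.0,
) -> pd.MultiIndex:
    return model.select_sites(candidate_sites, mode=mode, value=value)


def fixed_number_from_cohort(
    model: ReferenceAgingModel,
    profiles: list[MethylationProfile],
    percentile: float = 1.0,
) -> int:
    return model.fixed_number_from_cohort(profiles, percentile)
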