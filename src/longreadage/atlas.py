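"""Differentially methylated marker discovery and the cell-type atlas.

Given per-sample methylation of two leukocyte groups (e.g. myeloid vs
lymphocyte), a CpG site becomes a marker when it passes four filters:
adequate coverage in every sample, a large between-group mean beta
difference, a small Welch t-test p-value, and quantile separation (the
groups' central quantile ranges must not overlap). The atlas records each
marker's mean beta per cell type; these means are the c_k vector that
fragment deconvolution scores against.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import NoMarkersError
from .types import AtlasSampleSet

logger = logging.getLogger(__name__)


class CellTypeMarkerFinder(BaseEstimator):
    """Two-group differential methylation filter bank.

    Parameters
    ----------
    min_mean_diff : float, default 0.4
        Minimum |group mean beta difference| at a marker.
    max_p : float, default 0.001
        Welch two-sample t-test p-value cutoff.
    min_coverage : int, default 10
        Every sample must reach this read coverage at the site.
    quantile_gap : float, default 0.25
        Separation requirement: the (1 - quantile_gap) quantile of the
        lower-methylated group must lie strictly below the quantile_gap
        quantile of the higher group. Smaller values are stricter.
    fdr_bh : bool, default False
        Apply Benjamini-Hochberg correction to the t-test p-values before
        the ``max_p`` cutoff.

    Attributes
    ----------
    atlas_ : pandas.DataFrame
        Markers x cell types table of group mean betas, indexed (chrom, pos).
    cell_types_ : list of str
    diagnostics_ : dict
        Sites passing each filter individually, plus the total tested.
    """

    def __init__(
        self,
        min_mean_diff: float = 0.4,
        max_p: float = 0.001,
        min_coverage: int = 10,
        quantile_gap: float = 0.25,
        fdr_bh: bool = False,
    ):
        self.min_mean_diff = min_mean_diff
        self.max_p = max_p
        self.min_coverage = min_coverage
        self.quantile_gap = quantile_gap
        self.fdr_bh = fdr_bh

    def fit(self, X: AtlasSampleSet, y=None) -> "CellTypeMarkerFinder":
        """Apply the four filters site-by-site and record surviving markers."""
        groups = X.cell_types
        if len(groups) != 2:
            raise ValueError(f"exactly two cell-type groups required, got {groups}")
        idx_a = X.labels[X.labels == groups[0]].index
        idx_b = X.labels[X.labels == groups[1]].index
        if len(idx_a) < 2 or len(idx_b) < 2:
            raise ValueError("each group needs >= 2 samples for the differential test")

        beta_a = X.betas.loc[idx_a].to_numpy(dtype=float)
        beta_b = X.betas.loc[idx_b].to_numpy(dtype=float)
        cov = X.coverage.to_numpy()

        pass_cov = (cov >= self.min_coverage).all(axis=0)

        mean_a = beta_a.mean(axis=0)
        mean_b = beta_b.mean(axis=0)
        pass_diff = np.abs(mean_a - mean_b) >= self.min_mean_diff

        with np.errstate(invalid="ignore", divide="ignore"):
            pvals = stats.ttest_ind(beta_a, beta_b, axis=0, equal_var=False).pvalue
        pvals = np.where(np.isfinite(pvals), pvals, 1.0)
        if self.fdr_bh:
            pvals = multipletests(pvals, method="fdr_bh")[1]
        pass_p = pvals <= self.max_p

        # quantile separation: upper tail of the low group below the lower
        # tail of the high group
        q = self.quantile_gap
        lo_hi = np.where(
            mean_a[None, :] <= mean_b[None, :],
            np.stack(
                [
                    np.quantile(beta_a, 1 - q, axis=0),
                    np.quantile(beta_b, q, axis=0),
                ]
            ),
            np.stack(
                [
                    np.quantile(beta_b, 1 - q, axis=0),
                    np.quantile(beta_a, q, axis=0),
                ]
            ),
        )
        pass_quant = lo_hi[0] < lo_hi[1]

        keep = pass_cov & pass_diff & pass_p & pass_quant
        self.diagnostics_ = {
            "n_sites": int(X.betas.shape[1]),
            "pass_coverage": int(pass_cov.sum()),
            "pass_mean_diff": int(pass_diff.sum()),
            "pass_p_value": int(pass_p.sum()),
            "pass_quantile": int(pass_quant.sum()),
            "markers": int(keep.sum()),
        }
        if not keep.any():
            raise NoMarkersError(self.diagnostics_)

        self.cell_types_ = groups
        self.atlas_ = pd.DataFrame(
            {groups[0]: mean_a[keep], groups[1]: mean_b[keep]},
            index=X.betas.columns[keep],
        )
        self.atlas_.index.names = ["chrom", "pos"]
        logger.info(
            "marker discovery: %d/%d sites retained (%s)",
            int(keep.sum()),
            X.betas.shape[1],
            self.diagnostics_,
        )
        return self


def find_markers(
    samples: AtlasSampleSet,
    min_mean_diff: float = 0.4,
    max_p: float = 0.001,
    min_coverage: int = 10,
    quantile_gap: float = 0.25,
    fdr_bh: bool = False,
) -> pd.DataFrame:
    """Functional wrapper returning the marker atlas table."""
    finder = CellTypeMarkerFinder(
        min_mean_diff=min_mean_diff,
        max_p=max_p,
        min_coverage=min_coverage,
        quantile_gap=quantile_gap,
        fdr_bh=fdr_bh,
    ).fit(samples)
    return finder.atlas_
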