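"""End-to-end convenience: raw deployment to labeled dive table and model.

Chains detection, phase segmentation with shoulder correction, location
assignment, movement metrics, the 12-variable metric table, transforms, and
the PCA + Ward typing fit.  Analysis drivers, tests, and the acceptance
script all run through this module so they measure the same computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .budgets import activity_budget
from .classify import DiveTypeModel, NamingThresholds, fit_dive_type_model
from .extraction import DepthSeries, DetectionConfig, extract_dive_table
from .geolocation import BathymetryGrid, add_movement_metrics, assign_locations
from .metrics import (TransformSpec, apply_transforms, compute_dive_metrics,
                      flag_outliers)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    dives: pd.DataFrame        # extracted + located + movement columns
    metrics: pd.DataFrame      # 12 variables, row-aligned with dives
    transformed: pd.DataFrame
    model: DiveTypeModel
    used_index: pd.Index       # rows (into dives/metrics) used in the fit
    labeled: pd.DataFrame      # used rows with type_name attached

    @property
    def type_names(self) -> dict:
        return self.model.type_names


def run_pipeline(series: DepthSeries, fixes: pd.DataFrame,
                 grid: BathymetryGrid | None = None,
                 detection: DetectionConfig = DetectionConfig(),
                 transforms: TransformSpec = TransformSpec(),
                 k_clusters: int = 6, variance_target: float = 0.85,
                 thresholds: NamingThresholds = NamingThresholds(),
                 outlier_n_mad: float | None = None) -> PipelineResult:
    """Run the full archive analysis on one deployment.

    Dives lacking complete movement metrics (record ends, invalid
    locations) are excluded from the typing fit, mirroring the exclusion
    of dives far from any fix.  Setting ``outlier_n_mad`` additionally
    drops univariate outliers (n-MAD rule) before the fit; this is off by
    default because a univariate rule on multimodal dive data can flag
    entire legitimate behavior types, where an analyst's manual screen
    would remove only isolated artifacts.
    """
    dives = extract_dive_table(series, detection)
    located = assign_locations(dives, fixes)
    located = add_movement_metrics(located, grid)
    metrics = compute_dive_metrics(series, located)
    transformed = apply_transforms(metrics, transforms)
    fit_table = transformed
    if outlier_n_mad is not None:
        fit_table, _ = flag_outliers(transformed, n_mad=outlier_n_mad)
    model, used = fit_dive_type_model(fit_table, metrics.loc[fit_table.index],
                                      k_clusters, variance_target, thresholds)
    labeled = located.loc[used].reset_index(drop=True).copy()
    labeled["type_name"] = [model.type_names[c] for c in model.labels]
    labeled["PDI"] = metrics.loc[used, "PDI"].to_numpy()
    labeled["MaxDepth"] = metrics.loc[used, "MaxDepth"].to_numpy()
    return PipelineResult(dives=located, metrics=metrics, transformed=transformed,
                          model=model, used_index=used, labeled=labeled)
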