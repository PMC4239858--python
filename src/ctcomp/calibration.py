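"""Method-comparison statistics and experiment drivers.

CT-derived masses are compared against a reference channel (QMR-style truth
tables) by ordinary least squares, with the reference on the x-axis and the
CT measurement on the y-axis.  Under that convention a slope of 1 and
intercept of 0 mean the CT pipeline is fully quantitative with respect to the
reference; R² measures linearity (sufficient for tracking *relative* changes
even when the slope is off).  No errors-in-variables correction is applied —
this mirrors standard practice for these calibrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .quantify import (
    DensityTable,
    background_subtract,
    body_composition,
    mask_volume,
    mass_from_volume,
)
from .segmentation import (
    ADIPOSE,
    ADIPOSE_NARROW,
    HUWindow,
    TissueMask,
    auto_body_voi,
    resample_to,
    segment_window,
)
from .synth import PhantomSpec, TruthRecord, simulate_empty_tube, simulate_phantom
from .core import VoxelGrid

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """Slope/intercept/R² summary of a method-comparison fit."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float
    intercept_se: float
    residuals: np.ndarray
    max_abs_deviation: float

    def to_dict(self) -> dict:
        d = {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "max_abs_deviation": self.max_abs_deviation,
        }
        return d


@dataclass
class ReplicateSummary:
    """Mean and standard error of the mean over replicate measurements."""

    mean: float
    sem: float
    n_replicates: int


def replicate_summary(values) -> ReplicateSummary:
    """Arithmetic mean and SEM (sample sd with n−1 denominator over √n)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("replicate_summary needs at least 2 values")
    return ReplicateSummary(
        mean=float(values.mean()),
        sem=float(values.std(ddof=1) / np.sqrt(values.size)),
        n_replicates=int(values.size),
    )


def ols_fit(x, y) -> RegressionResult:
    """Ordinary least-squares fit of measured *y* on reference *x*."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if x.size < 3:
        raise ValueError("a reported fit needs n >= 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; slope is undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    residuals = np.asarray(model.resid)
    return RegressionResult(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n=int(x.size),
        slope_se=float(model.bse[1]),
        intercept_se=float(model.bse[0]),
        residuals=residuals,
        max_abs_deviation=float(np.abs(residuals).max()),
    )


def compare_methods(measured: pd.Series, reference: pd.DataFrame, column: str = "fat_mass_g") -> RegressionResult:
    """Regress CT-derived per-specimen masses on a reference-table column.

    *measured* is a Series indexed by specimen id; rows are joined by id, so
    row order is irrelevant.  Unmatched ids on either side are a hard error.
    """
    ref = reference.set_index("specimen_id")[column]
    measured = pd.Series(measured, dtype=float)
    missing_ref = sorted(set(measured.index) - set(ref.index))
    missing_meas = sorted(set(ref.index) - set(measured.index))
    if missing_ref or missing_meas:
        raise ValueError(
            f"unmatched specimen ids: missing from reference {missing_ref}, "
            f"missing from measurements {missing_meas}"
        )
    ref = ref.loc[measured.index]
    return ols_fit(ref.to_numpy(), measured.to_numpy())


@dataclass
class PhantomExperimentReport:
    """Per-dilution summaries plus the calibration fit of a phantom series."""

    fit: RegressionResult
    table: pd.DataFrame  # oil_mass_g, measured_mean_g, measured_sem_g, n


def measure_phantom_oil_mass(
    grid: VoxelGrid,
    empty_grid: VoxelGrid,
    densities: DensityTable = DensityTable(),
    window: HUWindow = ADIPOSE,
) -> float:
    """Oil mass (g) from one phantom scan and its paired empty-tube scan.

    Adipose-window volume of the filled tube, minus the plastic background
    volume of the empty tube, times the soybean-oil density.
    """
    sample_vol = mask_volume(segment_window(grid, window))
    empty_vol = mask_volume(segment_window(empty_grid, window))
    return mass_from_volume(
        background_subtract(sample_vol, empty_vol), densities.soybean_oil
    )


def run_phantom_experiment(
    oil_masses_g=(0.0, 3.0, 6.0, 9.0, 12.0, 15.0, 18.0),
    replicates: int = 3,
    edge_um: float = 250.0,
    noise_sd_hu: float | None = None,
    seeds=(1, 2, 3),
    supersample: int = 4,
    base_spec: PhantomSpec | None = None,
) -> PhantomExperimentReport:
    """Run the in vitro oil/water dilution series end to end.

    For every oil mass × replicate: simulate the filled phantom and its
    paired empty tube (replicate *i* uses ``seeds[i]``, with the noise stream
    further decorrelated across dilution points), segment the adipose window,
    subtract the plastic background, convert to mass at 0.926 g/mL; then
    summarize replicates and fit measured means against true masses.
    """
    oil_masses_g = tuple(float(m) for m in oil_masses_g)
    if len(set(oil_masses_g)) < 3:
        raise ValueError("need at least 3 distinct oil masses for a fit")
    if replicates < 1 or len(seeds) < replicates:
        raise ValueError("need one seed per replicate")
    base = base_spec if base_spec is not None else PhantomSpec()
    if noise_sd_hu is None:
        noise_sd_hu = base.noise_sd_hu

    rows = []
    for i_mass, oil in enumerate(oil_masses_g):
        measures = []
        for rep in range(replicates):
            # independent noise per (dilution, replicate), reproducible per seed
            seed = int(
                np.random.SeedSequence([int(seeds[rep]), i_mass]).generate_state(1)[0]
                % (2**31 - 1)
            )
            spec = dc_replace(
                base, oil_mass_g=oil, noise_sd_hu=noise_sd_hu, seed=seed
            )
            grid, truth = simulate_phantom(spec, edge_um, supersample)
            empty = simulate_empty_tube(spec, edge_um, supersample)
            measures.append(measure_phantom_oil_mass(grid, empty))
        row = {"oil_mass_g": oil, "n": replicates}
        if replicates >= 2:
            summ = replicate_summary(measures)
            row["measured_mean_g"] = summ.mean
            row["measured_sem_g"] = summ.sem
        else:
            row["measured_mean_g"] = float(measures[0])
        rows.append(row)
    table = pd.DataFrame(rows)
    fit = ols_fit(table["oil_mass_g"], table["measured_mean_g"])
    return PhantomExperimentReport(fit=fit, table=table)


def run_parameter_sweep(
    cohort,
    reference: pd.DataFrame | None = None,
    edges_um=(125.0, 250.0, 500.0),
    windows=(ADIPOSE, ADIPOSE_NARROW),
    median_mms=(None, 1.0),
    densities: DensityTable = DensityTable(),
) -> pd.DataFrame:
    """Fit CT adipose mass against the reference for every analysis setting.

    *cohort* is a list of ``(VoxelGrid, TruthRecord)`` pairs as produced by
    ``make_cohort``; each grid must be at the finest requested resolution
    (coarser settings are emulated by mean-pool resampling, like re-running
    the reconstruction at a larger voxel).  When *reference* is None the fit
    uses the TruthRecord adipose masses.  Returns one row per combination
    with slope, intercept, R² and max |residual|.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    base_edge = cohort[0][0].edge_um
    rows = []
    for edge in edges_um:
        # resample + VOI once per specimen and resolution, reused across
        # window/filter combinations
        prepared = []
        for grid, truth in cohort:
            g = resample_to(grid, edge) if edge != base_edge else grid
            voi = auto_body_voi(g, tail_crop=_scaled_tail_crop(g, base_edge, edge))
            prepared.append((g, voi, truth))
        for window, median_mm in product(windows, median_mms):
            measured = {}
            for g, voi, truth in prepared:
                comp = body_composition(
                    g, voi=voi, densities=densities, median_mm=median_mm,
                    adipose_window=window, specimen_id=truth.specimen_id,
                )
                measured[truth.specimen_id or f"s{len(measured)}"] = comp.masses_g["adipose"]
            measured = pd.Series(measured)
            if reference is not None:
                fit = compare_methods(measured, reference, "fat_mass_g")
            else:
                truth_masses = pd.Series(
                    {t.specimen_id or f"s{i}": t.masses_g["adipose"]
                     for i, (_, t) in enumerate(cohort)}
                ).loc[measured.index]
                fit = ols_fit(truth_masses.to_numpy(), measured.to_numpy())
            rows.append(
                {
                    "edge_um": edge,
                    "window_lo": window.lo,
                    "window_hi": window.hi,
                    "median_mm": np.nan if median_mm is None else median_mm,
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "max_abs_deviation": fit.max_abs_deviation,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


def _scaled_tail_crop(grid: VoxelGrid, base_edge: float, edge: float):
    """Rescale the simulator's tail z-crop to a resampled voxel size."""
    crop = grid.meta.get("tail_crop")
    if crop is None:
        return None
    factor = edge / base_edge
    if factor == 1:
        return tuple(crop)
    return (int(crop[0] // factor), int(np.ceil(crop[1] / factor)))
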