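"""Rate-constant estimation by constrained weighted least squares.

The 29 fractional clearance constants are fitted to a whole-body tracer
dataset by minimizing a weighted squared distance between the simulated
trajectory and the observed organ means.  Weights are the inverse of the
measurement standard deviation (not the variance, which over-emphasizes
small values); an inverse-variance mode is kept as a sensitivity switch.

Two structural devices keep the problem identifiable:

* the 13 plasma-exit constants are renormalized inside the model to a set
  total plasma clearance (20 pool turnovers per day by default), because
  the first observation at 12 h cannot resolve the fast clearance scale;
* each compartment keeps a single exit route (reflux or body loss), never
  both, so that only the identifiable sum is estimated.

Optimization runs in log-parameter space (rates span three orders of
magnitude) with bounded least squares from multiple seeded random starts.
Parameter uncertainty is quantified by Monte-Carlo resampling of the
dataset followed by sextile-truncated empirical bounds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .compartment_model import (
    RateConstants,
    Topology,
    TracerTrajectory,
    build_topology,
    rate_matrix,
    _propagate,
)
from .observation_processing import TracerDataset

__all__ = [
    "FitResult",
    "ResampleEnsemble",
    "ParameterBounds",
    "IdentifiabilityReport",
    "floor_sds",
    "weighted_distance",
    "fit",
    "resample_fit",
    "parameter_bounds",
    "identifiability_scan",
]

DEFAULT_TOTAL_CLEARANCE = 20.0
DEFAULT_RATE_BOUNDS = (1e-4, 50.0)
WEIGHTING_MODES = ("inverse_sd", "inverse_variance")


@dataclass(frozen=True)
class FitResult:
    """Point estimate with its fit criteria and reproducibility metadata."""

    rates: RateConstants
    fval_chi_sqr: float
    fit_quality: float
    n_starts: int
    converged: bool
    seed: int
    weighting: str = "inverse_sd"

    def __post_init__(self):
        if self.fval_chi_sqr < 0 or self.fit_quality < 0:
            raise ValueError("fit criteria must be non-negative")

    def to_dict(self) -> dict:
        return {
            "rates": dict(self.rates.values),
            "fval_chi_sqr": self.fval_chi_sqr,
            "fit_quality": self.fit_quality,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "seed": self.seed,
            "weighting": self.weighting,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FitResult":
        return cls(rates=RateConstants(doc["rates"]),
                   fval_chi_sqr=doc["fval_chi_sqr"],
                   fit_quality=doc["fit_quality"],
                   n_starts=doc["n_starts"], converged=doc["converged"],
                   seed=doc["seed"], weighting=doc.get("weighting", "inverse_sd"))


@dataclass(frozen=True)
class ResampleEnsemble:
    """One refit per Monte-Carlo replicate of the dataset."""

    fits: tuple[FitResult, ...]
    n_replicates: int
    seed: int
    n_failed: int = 0

    def parameter_table(self) -> pd.DataFrame:
        """Replicate estimates, one row per replicate, one column per rate."""
        return pd.DataFrame([dict(f.rates.values) for f in self.fits])


@dataclass(frozen=True)
class ParameterBounds:
    """Sextile-truncated scatter interval per parameter."""

    lower: Mapping[str, float]
    upper: Mapping[str, float]

    def __post_init__(self):
        for p in self.lower:
            if self.lower[p] > self.upper[p]:
                raise ValueError(f"lower > upper for {p}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lower": dict(self.lower),
                             "upper": dict(self.upper)})


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Multi-start exploration of the acceptable-fit parameter domain."""

    best: FitResult
    retained: tuple[FitResult, ...]
    spread: Mapping[str, float]           # relative spread per parameter
    correlations: pd.DataFrame
    flagged_pairs: tuple[tuple[str, str], ...]
    acceptance_factor: float


def floor_sds(dataset: TracerDataset, frac: float = 0.01,
              min_floor: float = 1e-6) -> TracerDataset:
    """Floor each organ's SDs at ``frac`` of that organ's maximum mean.

    Prevents infinite weights from zero SDs (the source text is silent on
    this); cells already above the floor are untouched.
    """
    df = dataset.observations.copy()
    organ_max = df.groupby("organ")["mean_pct_dose"].transform("max")
    floor = np.maximum(frac * organ_max.clip(lower=0), min_floor)
    df["sd_pct_dose"] = np.maximum(df["sd_pct_dose"], floor)
    return dc_replace(dataset, observations=df)


def _aligned_predictions(dataset: TracerDataset,
                         trajectory: TracerTrajectory) -> np.ndarray:
    df = dataset.observations
    time_index = {float(t): i for i, t in enumerate(trajectory.times)}
    comp_index = {c: j for j, c in enumerate(trajectory.compartments)}
    preds = np.empty(len(df))
    for r, row in enumerate(df.itertuples()):
        ti = time_index.get(float(row.time_days))
        cj = comp_index.get(row.organ)
        if ti is None or cj is None:
            raise ValueError(
                f"trajectory lacks prediction for ({row.organ}, {row.time_days})")
        preds[r] = trajectory.content[ti, cj]
    return preds


def weighted_distance(dataset: TracerDataset, trajectory: TracerTrajectory,
                      weighting: str = "inverse_sd") -> tuple[float, float]:
    """Weighted criterion (fval) and its per-point quality measure.

    inverse_sd:        fval = sum (pred - mean)^2 / SD
    inverse_variance:  fval = sum (pred - mean)^2 / SD^2

    fit_quality = sqrt(fval / N), the root mean weighted squared deviation.
    All SDs must be positive (apply :func:`floor_sds` first).
    """
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {WEIGHTING_MODES}")
    df = dataset.observations
    sd = df["sd_pct_dose"].to_numpy(dtype=float)
    if np.any(sd <= 0):
        raise ValueError("all SDs must be > 0 after flooring")
    preds = _aligned_predictions(dataset, trajectory)
    dev2 = (preds - df["mean_pct_dose"].to_numpy(dtype=float)) ** 2
    w = sd if weighting == "inverse_sd" else sd ** 2
    fval = float(np.sum(dev2 / w))
    return fval, float(np.sqrt(fval / len(df)))


class _Objective:
    """Residual vector of the weighted criterion in log-parameter space."""

    def __init__(self, dataset: TracerDataset, topology: Topology,
                 total_clearance: float | None, weighting: str,
                 fixed: Mapping[str, float] | None):
        self.topology = topology
        self.params = list(topology.param_names)
        self.plasma_set = set(topology.plasma_exit_params)
        self.fixed = dict(fixed or {})
        unknown = set(self.fixed) - set(self.params)
        if unknown:
            raise ValueError(f"fixed parameters not in topology: {sorted(unknown)}")
        self.free = [p for p in self.params if p not in self.fixed]
        self.free_plasma_idx = np.array(
            [i for i, p in enumerate(self.free) if p in self.plasma_set], dtype=int)
        self.total_clearance = total_clearance
        if total_clearance is not None:
            fixed_plasma = sum(v for p, v in self.fixed.items()
                               if p in self.plasma_set)
            self.plasma_target = total_clearance - fixed_plasma
            if self.plasma_target < 0:
                raise ValueError("fixed plasma exits exceed total clearance")

        df = dataset.observations
        self.times = np.sort(df["time_days"].unique()).astype(float)
        t_idx = {t: i for i, t in enumerate(self.times)}
        c_idx = {c: j for j, c in enumerate(topology.compartments)}
        self.row_t = df["time_days"].map(lambda t: t_idx[float(t)]).to_numpy()
        self.row_c = df["organ"].map(c_idx).to_numpy()
        if np.any(pd.isna(self.row_c)):
            bad = df.loc[pd.isna(df["organ"].map(c_idx)), "organ"].unique()
            raise ValueError(f"dataset organs not in topology: {list(bad)}")
        self.row_c = self.row_c.astype(int)
        self.means = df["mean_pct_dose"].to_numpy(dtype=float)
        sd = df["sd_pct_dose"].to_numpy(dtype=float)
        if np.any(sd <= 0):
            raise ValueError("all SDs must be > 0 after flooring; "
                             "apply floor_sds first")
        self.scale = np.sqrt(sd) if weighting == "inverse_sd" else sd
        self.n_points = len(df)
        self.x0 = np.zeros(len(topology.compartments))
        self.x0[topology.index(topology.central)] = 100.0

    def rates_from_x(self, x: np.ndarray) -> RateConstants:
        k = dict(self.fixed)
        for p, v in zip(self.free, np.exp(x)):
            k[p] = float(v)
        if self.total_clearance is not None and len(self.free_plasma_idx):
            current = sum(k[p] for p in self.free
                          if p in self.plasma_set)
            if current > 0:
                factor = self.plasma_target / current
                for p in self.free:
                    if p in self.plasma_set:
                        k[p] *= factor
        return RateConstants(k)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        rates = self.rates_from_x(x)
        A = rate_matrix(self.topology, rates)
        X = _propagate(A, self.x0, self.times)
        preds = X[self.row_t, self.row_c]
        return (preds - self.means) / self.scale

    def criteria(self, x: np.ndarray) -> tuple[float, float]:
        r = self.residuals(x)
        fval = float(np.sum(r * r))
        return fval, float(np.sqrt(fval / self.n_points))


def fit(dataset: TracerDataset,
        topology: Topology | None = None,
        total_clearance: float | None = DEFAULT_TOTAL_CLEARANCE,
        n_starts: int = 50,
        seed: int = 0,
        fixed: Mapping[str, float] | None = None,
        weighting: str = "inverse_sd",
        rate_bounds: tuple[float, float] = DEFAULT_RATE_BOUNDS,
        sd_floor_frac: float = 0.01,
        heuristic_start: bool = True,
        least_squares_options: Mapping | None = None) -> FitResult:
    """Point-estimate the rate constants from a tracer dataset.

    The plasma-exit constants are parameterized as non-negative shares
    rescaled to ``total_clearance`` inside the model, so the constraint
    holds exactly in the returned estimate; pass ``total_clearance=None``
    to fit the fast scale freely (used by the identifiability scan).
    ``fixed`` pins a subset of rates; with all 29 pinned no search runs.
    Deterministic for identical (dataset, seed, n_starts).
    """
    if topology is None:
        topology = build_topology()
    if weighting not in WEIGHTING_MODES:
        raise ValueError(f"weighting must be one of {WEIGHTING_MODES}")
    if total_clearance is not None and total_clearance <= 0:
        raise ValueError("total_clearance must be > 0")
    dataset = floor_sds(dataset, frac=sd_floor_frac)
    obj = _Objective(dataset, topology, total_clearance, weighting, fixed)

    if not obj.free:  # fully pinned: evaluate only
        rates = obj.rates_from_x(np.empty(0))
        fval, quality = obj.criteria(np.empty(0))
        return FitResult(rates=rates, fval_chi_sqr=fval, fit_quality=quality,
                         n_starts=0, converged=True, seed=seed,
                         weighting=weighting)

    lo, hi = rate_bounds
    log_lo, log_hi = np.log(lo), np.log(hi)
    ls_opts = dict(method="trf", x_scale="jac",
                   xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=3000)
    ls_opts.update(least_squares_options or {})

    rng = np.random.default_rng(seed)
    starts = []
    if heuristic_start:
        starts.append(np.full(len(obj.free), np.log(0.5)))
    sample_lo, sample_hi = np.log(max(lo, 1e-2)), np.log(min(hi, 20.0))
    while len(starts) < max(n_starts, 1):
        starts.append(rng.uniform(sample_lo, sample_hi, size=len(obj.free)))
    starts = starts[:max(n_starts, 1)]

    best = None
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(obj.residuals, x0,
                                bounds=(log_lo, log_hi), **ls_opts)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(sol.cost):
            continue
        any_success = any_success or bool(sol.success)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("no start produced a finite criterion value")

    rates = obj.rates_from_x(best.x)
    fval, quality = obj.criteria(best.x)
    return FitResult(rates=rates, fval_chi_sqr=fval, fit_quality=quality,
                     n_starts=len(starts), converged=any_success, seed=seed,
                     weighting=weighting)


def resample_fit(dataset: TracerDataset,
                 n_replicates: int = 200,
                 seed: int = 0,
                 topology: Topology | None = None,
                 **fit_kwargs) -> ResampleEnsemble:
    """Monte-Carlo resampling of the dataset with a refit per replicate.

    Each replicate draws per-cell Gaussian noise with the observed mean
    and SD (negatives clipped to zero, mirroring the spleen handling) and
    runs the same estimation.  Fails if more than half the replicates
    error out.  Fully reproducible from ``seed``.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    base = dataset.observations
    means = base["mean_pct_dose"].to_numpy(dtype=float)
    sds = base["sd_pct_dose"].to_numpy(dtype=float)
    # draw replicate data and per-replicate seeds up front for determinism
    draws = rng.normal(means, sds, size=(n_replicates, len(means))).clip(min=0.0)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)

    fits: list[FitResult] = []
    n_failed = 0
    for r in range(n_replicates):
        df = base.copy()
        df["mean_pct_dose"] = draws[r]
        rep = dc_replace(dataset, observations=df)
        try:
            fits.append(fit(rep, topology=topology, seed=int(rep_seeds[r]),
                            **fit_kwargs))
        except (RuntimeError, ValueError):
            n_failed += 1
    if n_failed > n_replicates // 2:
        raise RuntimeError(
            f"{n_failed}/{n_replicates} replicate fits failed")
    return ResampleEnsemble(fits=tuple(fits), n_replicates=n_replicates,
                            seed=seed, n_failed=n_failed)


def parameter_bounds(ensemble: ResampleEnsemble) -> ParameterBounds:
    """Sextile-truncated scatter interval of the replicate estimates.

    Per parameter the 1/6 and 5/6 empirical quantiles (linear-interpolation
    convention, ``numpy.quantile(..., method="linear")``); for Gaussian
    scatter the interval width approaches 2 * 0.9674 sigma, i.e. roughly
    twice the standard deviation.
    """
    if not ensemble.fits:
        raise ValueError("ensemble is empty")
    table = ensemble.parameter_table()
    lo = table.quantile(1 / 6, interpolation="linear")
    hi = table.quantile(5 / 6, interpolation="linear")
    return ParameterBounds(lower=lo.to_dict(), upper=hi.to_dict())


def identifiability_scan(dataset: TracerDataset,
                         topology: Topology | None = None,
                         n_starts: int = 20,
                         seed: int = 0,
                         acceptance_factor: float = 1.05,
                         correlation_threshold: float = 0.9,
                         spread_threshold: float = 0.01,
                         **fit_kwargs) -> IdentifiabilityReport:
    """Explore the acceptable-fit domain by independent single-start fits.

    All local optima whose criterion lies within ``acceptance_factor`` of
    the best are retained; parameters whose relative spread across the
    retained set exceeds ``spread_threshold`` and whose pairwise
    correlation magnitude exceeds ``correlation_threshold`` are flagged as
    interdependent (a multi-start surrogate for a full conditional-
    expectation analysis).
    """
    if topology is None:
        topology = build_topology()
    rng = np.random.default_rng(seed)
    start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)
    fits = []
    for s in start_seeds:
        try:
            fits.append(fit(dataset, topology=topology, n_starts=1,
                            seed=int(s), heuristic_start=False, **fit_kwargs))
        except RuntimeError:
            continue
    if not fits:
        raise RuntimeError("no start produced a finite criterion value")
    best = min(fits, key=lambda f: f.fval_chi_sqr)
    cutoff = best.fval_chi_sqr * acceptance_factor
    retained = tuple(f for f in fits if f.fval_chi_sqr <= cutoff)

    table = pd.DataFrame([dict(f.rates.values) for f in retained])
    center = table.median()
    span = table.max() - table.min()
    denom = center.where(center > 0, 1.0)
    spread = (span / denom).to_dict()

    variable = [p for p in table.columns if spread[p] > spread_threshold]
    corr = table.corr() if len(retained) > 2 else pd.DataFrame(
        np.eye(len(table.columns)), index=table.columns, columns=table.columns)
    flagged = tuple(
        (a, b) for a, b in itertools.combinations(variable, 2)
        if abs(corr.loc[a, b]) > correlation_threshold)
    return IdentifiabilityReport(best=best, retained=retained, spread=spread,
                                 correlations=corr, flagged_pairs=flagged,
                                 acceptance_factor=acceptance_factor)
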