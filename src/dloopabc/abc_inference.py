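"""Rejection ABC over the two-deme model's four free parameters.

Parameters are drawn from independent uniform priors (N_D ~ U(1, 1000),
P ~ U(0, 1), M_E and M_L ~ U(0, 0.01)), a batch of coalescent simulations
produces one 32-element summary-statistic vector per draw, and plain
rejection retains the parameter sets whose standardized statistics lie
closest (Euclidean distance) to the observed vector.  Posterior summaries
use boundary-reflected Gaussian KDE with Silverman bandwidths; credible
intervals are highest-posterior-density intervals.

Per-row seeds derive from the master seed via
``np.random.SeedSequence(master_seed, spawn_key=(row,))`` so a batch is
reproducible regardless of execution order or parallel scheduling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import gaussian_kde

from .coalescent_sim import (
    DemographicModel,
    MutationModel,
    SamplingScheme,
    simulate_dataset,
)
from .popgen_stats import STAT_VECTOR_NAMES, abc_stat_vector

logger = logging.getLogger("dloopabc")

PARAM_NAMES = ("N_D", "P", "M_E", "M_L")


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors on the four free parameters."""

    n_d: tuple[float, float] = (1.0, 1_000.0)
    p: tuple[float, float] = (0.0, 1.0)
    m_early: tuple[float, float] = (0.0, 0.01)
    m_late: tuple[float, float] = (0.0, 0.01)

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "N_D": self.n_d,
            "P": self.p,
            "M_E": self.m_early,
            "M_L": self.m_late,
        }

    def contains(self, params: Sequence[float]) -> bool:
        return all(
            lo <= v <= hi
            for v, (lo, hi) in zip(params, self.bounds.values())
        )


def draw_prior_sample(
    prior: PriorSpec, n: int, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw n parameter rows from the prior, reproducible under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {
        name: rng.uniform(lo, hi, size=n)
        for name, (lo, hi) in prior.bounds.items()
    }
    return pd.DataFrame(cols)


def _row_rng(master_seed: int, row: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(row,)))


def run_simulation_batch(
    prior: PriorSpec,
    n_sims: int,
    scheme: SamplingScheme,
    mut: MutationModel | None = None,
    seed: int = 0,
    base_model: DemographicModel | None = None,
    group_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Simulate ``n_sims`` parameter draws and their statistic vectors.

    Row i uses the generator seeded by SeedSequence(seed, spawn_key=(i,)):
    parameter draw first, then the simulation, so the table is identical
    however rows are scheduled.  ``group_map`` maps scheme group labels to
    the four ABC sample groups; omit it when scheme labels already are the
    ABC groups.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    mut = mut if mut is not None else MutationModel()
    rows = np.empty((n_sims, 4 + len(STAT_VECTOR_NAMES)))
    bounds = list(prior.bounds.values())
    for i in range(n_sims):
        rng = _row_rng(seed, i)
        params = tuple(rng.uniform(lo, hi) for lo, hi in bounds)
        try:
            sample = simulate_dataset(
                params, scheme, mut, seed=rng, base_model=base_model
            )
            grouped = sample.by_group()
            if group_map is not None:
                merged: dict[str, list[np.ndarray]] = {}
                for label, mat in grouped.items():
                    merged.setdefault(group_map[label], []).append(mat)
                grouped = {g: np.vstack(m) for g, m in merged.items()}
            stats = abc_stat_vector(grouped)
        except Exception as err:  # pragma: no cover - defensive
            raise RuntimeError(f"simulation row {i} failed: {err}") from err
        rows[i, :4] = params
        rows[i, 4:] = stats.values
    return pd.DataFrame(rows, columns=list(PARAM_NAMES) + list(STAT_VECTOR_NAMES))


# ---------------------------------------------------------------------------
# rejection
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Accepted parameter sets from rejection ABC plus the scaling used."""

    accepted: pd.DataFrame
    tolerance: float
    distances: np.ndarray          # distances of accepted rows, ascending
    prior: PriorSpec
    dropped_stats: tuple[str, ...] = ()

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)


def rejection(
    observed: np.ndarray | Sequence[float],
    table: pd.DataFrame,
    tolerance: float,
    prior: PriorSpec | None = None,
    scale: str = "sd",
) -> PosteriorResult:
    """Plain rejection ABC.

    Each statistic is standardized by its spread across the whole table
    (``sd`` default, ``mad`` optional); statistics constant across the
    table are dropped (logged).  The ceil(tolerance x n) rows with the
    smallest Euclidean distance to the observed vector are retained, ties
    broken by row index (stable sort).
    """
    if not (0.0 < tolerance <= 1.0):
        raise ValueError("tolerance must be in (0, 1]")
    if len(table) == 0:
        raise ValueError("empty simulation table")
    observed = np.asarray(observed, dtype=float)
    stat_cols = [c for c in table.columns if c in STAT_VECTOR_NAMES]
    stats = table[stat_cols].to_numpy(dtype=float)
    if observed.shape[0] != stats.shape[1]:
        raise ValueError(
            f"observed vector length {observed.shape[0]} != table stats {stats.shape[1]}"
        )
    if scale == "sd":
        spread = stats.std(axis=0)
    elif scale == "mad":
        spread = np.median(np.abs(stats - np.median(stats, axis=0)), axis=0)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    keep = spread > 0
    dropped = tuple(np.asarray(stat_cols)[~keep])
    if dropped:
        logger.info("rejection: dropping constant statistics %s", dropped)
    z = (stats[:, keep] - observed[keep]) / spread[keep]
    dist = np.sqrt((z**2).sum(axis=1))
    n_keep = math.ceil(tolerance * len(table))
    order = np.argsort(dist, kind="stable")[:n_keep]
    return PosteriorResult(
        accepted=table.iloc[order].reset_index(drop=True),
        tolerance=tolerance,
        distances=dist[order],
        prior=prior if prior is not None else PriorSpec(),
        dropped_stats=dropped,
    )


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def _reflected_kde_1d(
    values: np.ndarray, bounds: tuple[float, float], grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE (Silverman bandwidth) reflected at the prior bounds."""
    lo, hi = bounds
    grid = np.linspace(lo, hi, grid_size)
    if np.ptp(values) == 0.0:
        dens = np.zeros(grid_size)
        dens[np.argmin(np.abs(grid - values[0]))] = 1.0
        dens /= np.trapezoid(dens, grid) or 1.0
        return grid, dens
    kde = gaussian_kde(values, bw_method="silverman")
    dens = kde(grid) + kde(2 * lo - grid) + kde(2 * hi - grid)
    dens /= np.trapezoid(dens, grid)
    return grid, dens


def posterior_mode_1d(
    values: Sequence[float],
    bounds: tuple[float, float],
    grid_size: int = 512,
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Marginal posterior mode via boundary-reflected KDE on a grid."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values")
    grid, dens = _reflected_kde_1d(values, bounds, grid_size)
    return float(grid[np.argmax(dens)]), (grid, dens)


def posterior_mode_2d(
    x: Sequence[float],
    y: Sequence[float],
    bounds_x: tuple[float, float],
    bounds_y: tuple[float, float],
    grid_size: int = 256,
) -> tuple[tuple[float, float], dict]:
    """Joint posterior mode of two parameters.

    The density is a product-kernel KDE realized as a fine 2-D histogram
    smoothed with a Gaussian filter (sigma = per-dimension Silverman
    bandwidth for d=2, h_i = sigma_i n^(-1/6)); the filter's reflect mode
    implements boundary reflection at the prior rectangle.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10 or x.size != y.size:
        raise ValueError("need >= 10 paired values")
    n = x.size
    hist, xe, ye = np.histogram2d(
        x, y, bins=grid_size, range=[bounds_x, bounds_y]
    )
    dx = xe[1] - xe[0]
    dy = ye[1] - ye[0]
    h_x = max(x.std(ddof=1) * n ** (-1.0 / 6.0), dx / 2)
    h_y = max(y.std(ddof=1) * n ** (-1.0 / 6.0), dy / 2)
    dens = gaussian_filter(hist, sigma=(h_x / dx, h_y / dy), mode="reflect")
    dens /= dens.sum() * dx * dy
    xi, yi = np.unravel_index(np.argmax(dens), dens.shape)
    xc = 0.5 * (xe[:-1] + xe[1:])
    yc = 0.5 * (ye[:-1] + ye[1:])
    surface = {"x": xc, "y": yc, "density": dens, "dx": dx, "dy": dy}
    return (float(xc[xi]), float(yc[yi])), surface


def density_contour_level(surface: Mapping, mass: float) -> float:
    """Density threshold whose superlevel set holds ``mass`` probability."""
    dens = np.asarray(surface["density"]).ravel()
    cell = surface["dx"] * surface["dy"]
    order = np.argsort(dens)[::-1]
    csum = np.cumsum(dens[order]) * cell
    idx = int(np.searchsorted(csum, mass))
    idx = min(idx, len(dens) - 1)
    return float(dens[order][idx])


def hpd_interval(
    values: Sequence[float],
    mass: float = 0.95,
    bounds: tuple[float, float] | None = None,
    grid_size: int = 512,
) -> tuple[float, float]:
    """Highest-posterior-density interval from the reflected KDE.

    Computed as the narrowest grid interval holding ``mass`` probability
    under the KDE; for a unimodal density this is the HPD interval and
    contains the mode.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values")
    if np.ptp(values) == 0.0:
        return float(values[0]), float(values[0])
    if bounds is None:
        bounds = (values.min(), values.max())
    grid, dens = _reflected_kde_1d(values, bounds, grid_size)
    dx = grid[1] - grid[0]
    cdf = np.concatenate([[0.0], np.cumsum(dens) * dx])
    cdf /= cdf[-1]
    # smallest [i, j) window with cdf[j] - cdf[i] >= mass
    j = np.searchsorted(cdf, cdf[: grid_size] + mass)
    valid = j <= grid_size
    widths = np.where(valid, (j - np.arange(grid_size + 1)[: grid_size]) * dx, np.inf)
    i = int(np.argmin(widths))
    return float(grid[i]), float(grid[min(int(j[i]), grid_size) - 1])


def accepted_param_correlation(
    result: PosteriorResult | pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations between accepted parameters, permutation p-values.

    p is two-sided: the proportion of column permutations with
    |r_perm| >= |r_obs|, with the (1+k)/(1+N) correction.  Constant
    columns yield NaN (flagged undefined).
    """
    df = result.accepted if isinstance(result, PosteriorResult) else result
    params = df[[c for c in PARAM_NAMES if c in df.columns]]
    if len(params) < 10:
        raise ValueError("need at least 10 accepted rows")
    cols = params.columns
    k = len(cols)
    rng = np.random.default_rng(seed)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    arr = params.to_numpy(dtype=float)
    for i in range(k):
        r[i, i] = 1.0
        for j in range(i + 1, k):
            x, y = arr[:, i], arr[:, j]
            if x.std() == 0 or y.std() == 0:
                continue
            r_obs = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = r_obs
            if n_perm > 0:
                count = 0
                for _ in range(n_perm):
                    r_perm = np.corrcoef(x, rng.permutation(y))[0, 1]
                    if abs(r_perm) >= abs(r_obs):
                        count += 1
                p[i, j] = p[j, i] = (1 + count) / (1 + n_perm)
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def parameter_recovery(
    truth: tuple[float, float, float, float],
    template=None,
    n_sims: int = 20_000,
    tolerance: float = 0.01,
    n_reps: int = 10,
    seed: int = 0,
    prior: PriorSpec | None = None,
) -> list[dict]:
    """End-to-end validation: infer known parameters from pseudo-observed data.

    One reference table of ``n_sims`` simulations is shared by ``n_reps``
    independently generated pseudo-observed datasets (the sampling scheme is
    part of the study design and is fixed once from ``seed``).  Returns the
    posterior summary of each repetition.
    """
    from .popgen_stats import abc_stat_vector as _stat_vector
    from .synthetic_data import StudyTemplate, build_study, by_abc_group

    template = template if template is not None else StudyTemplate(scale=0.1)
    prior = prior if prior is not None else PriorSpec()
    scheme, meta = build_study(template, seed=seed)
    group_map = {m.region_group: m.abc_group for m in meta}
    mut = MutationModel(seq_length=template.seq_length)
    table = run_simulation_batch(
        prior, n_sims, scheme, mut, seed=seed + 59, group_map=group_map
    )
    summaries = []
    for rep in range(n_reps):
        pod = simulate_dataset(truth, scheme, mut, seed=seed + 100_000 + rep)
        observed = _stat_vector(by_abc_group(pod, meta))
        result = rejection(observed.values, table, tolerance, prior=prior)
        summaries.append(summarize_posterior(result))
    return summaries


def summarize_posterior(
    result: PosteriorResult,
    masses: Sequence[float] = (0.5, 0.95),
    corr_perms: int = 0,
    seed: int | None = None,
) -> dict:
    """Modes, HPD intervals and the joint (N_D, P) mode as a JSON-able dict."""
    out: dict = {"tolerance": result.tolerance, "n_accepted": result.n_accepted}
    bounds = result.prior.bounds
    for name in PARAM_NAMES:
        vals = result.accepted[name].to_numpy()
        mode, _ = posterior_mode_1d(vals, bounds[name])
        entry = {"mode": mode, "mean": float(vals.mean())}
        for mass in masses:
            lo, hi = hpd_interval(vals, mass, bounds[name])
            entry[f"hpd_{int(mass * 100)}"] = [lo, hi]
        out[name] = entry
    (nd_mode, p_mode), _ = posterior_mode_2d(
        result.accepted["N_D"].to_numpy(),
        result.accepted["P"].to_numpy(),
        bounds["N_D"],
        bounds["P"],
    )
    out["joint_mode_ND_P"] = [nd_mode, p_mode]
    if corr_perms:
        r, p = accepted_param_correlation(result, n_perm=corr_perms, seed=seed)
        out["correlation_r"] = r.to_dict()
        out["correlation_p"] = p.to_dict()
    return out
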