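"""Kernel-density stochastic model of hour-to-hour insulin-sensitivity change.

From identified SI profiles, consecutive-interval pairs (SI_n, SI_{n+1})
restricted to 1-2 hourly measurement intervals are pooled into a conditional
density p(SI_{n+1} | SI_n) on a log-spaced grid, using Gaussian kernels whose
bandwidth scales with the SI value (variability in this parameter is
multiplicative).  Percentile bands of the conditional (5/25/50/75/95) give
the cohort's metabolic-variability fingerprint; two cohorts can be compared
band-by-band, and the conditional can be sampled to drive synthetic patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_GRID = (1e-5, 3e-3, 200)
#: central SI range where clinical data density is high, L/(mU*min)
CENTRAL_RANGE = (0.01e-3, 0.8e-3)
DEFAULT_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


@dataclass
class TransitionDataset:
    """Hourly-scale SI transition pairs admitted to stochastic-model fitting."""

    si_now: np.ndarray
    si_next: np.ndarray

    def __post_init__(self) -> None:
        self.si_now = np.asarray(self.si_now, dtype=float)
        self.si_next = np.asarray(self.si_next, dtype=float)
        if self.si_now.shape != self.si_next.shape or self.si_now.ndim != 1:
            raise InvalidInputError("si_now/si_next must be matching 1-D")
        if self.si_now.size and (np.any(self.si_now <= 0)
                                 or np.any(self.si_next <= 0)):
            raise InvalidInputError("SI transition values must be positive")

    @property
    def n(self) -> int:
        return int(self.si_now.size)

    @classmethod
    def from_profiles(cls, profiles, max_interval_h: float = 2.0
                      ) -> "TransitionDataset":
        """Pool transitions from identified profiles; 4-hourly data excluded."""
        xs, ys = [], []
        for p in profiles:
            a, b = p.transitions(max_interval_h=max_interval_h)
            xs.append(a)
            ys.append(b)
        if not xs:
            return cls(np.empty(0), np.empty(0))
        return cls(np.concatenate(xs), np.concatenate(ys))


@dataclass
class StochasticSIModel:
    """Row-stochastic conditional density of next-hour SI on a fixed grid."""

    grid: np.ndarray                 # SI evaluation grid, increasing
    conditional: np.ndarray          # (n_grid, n_grid); row i = p(. | grid[i])
    bandwidth_frac: float            # kernel sd as a fraction of SI value
    n_pairs: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.conditional = np.asarray(self.conditional, dtype=float)

    def _trapz_weights(self) -> np.ndarray:
        w = np.zeros_like(self.grid)
        d = np.diff(self.grid)
        w[:-1] += d / 2.0
        w[1:] += d / 2.0
        return w

    def row_integrals(self) -> np.ndarray:
        return self.conditional @ self._trapz_weights()

    def row_cdf(self, i: int) -> np.ndarray:
        """Cumulative trapezoid of row i, normalized to end at exactly 1."""
        row = self.conditional[i]
        mids = 0.5 * (row[:-1] + row[1:]) * np.diff(self.grid)
        cdf = np.concatenate([[0.0], np.cumsum(mids)])
        return cdf / cdf[-1]

    def row_index(self, si_now: float) -> int:
        if si_now < self.grid[0] or si_now > self.grid[-1]:
            logger.warning("SI %.3g outside grid [%.3g, %.3g]; clamped",
                           si_now, self.grid[0], self.grid[-1])
        return int(np.argmin(np.abs(self.grid - np.clip(
            si_now, self.grid[0], self.grid[-1]))))

    def save(self, path) -> None:
        np.savez(path, grid=self.grid, conditional=self.conditional,
                 bandwidth_frac=self.bandwidth_frac, n_pairs=self.n_pairs)

    @classmethod
    def load(cls, path) -> "StochasticSIModel":
        d = np.load(path)
        return cls(grid=d["grid"], conditional=d["conditional"],
                   bandwidth_frac=float(d["bandwidth_frac"]),
                   n_pairs=int(d["n_pairs"]))


def _make_grid(spec) -> np.ndarray:
    if isinstance(spec, (tuple, list)) and len(spec) == 3:
        lo, hi, n = spec
        if not (0 < lo < hi) or int(n) < 10:
            raise InvalidInputError(f"bad grid spec {spec}")
        return np.geomspace(lo, hi, int(n))
    g = np.asarray(spec, dtype=float)
    if g.ndim != 1 or g.size < 10 or np.any(np.diff(g) <= 0):
        raise InvalidInputError("grid must be increasing 1-D with >= 10 points")
    return g


def _loo_cv_bandwidth(x: np.ndarray, y: np.ndarray,
                      candidates=(0.10, 0.15, 0.20, 0.30, 0.40, 0.50),
                      max_points: int = 1000) -> float:
    """Leave-one-out conditional pseudo-likelihood over candidate fractions."""
    if x.size > max_points:
        idx = np.random.default_rng(0).choice(x.size, max_points, replace=False)
        x, y = x[idx], y[idx]
    best_c, best_ll = candidates[0], -np.inf
    for c in candidates:
        hx = c * x
        hy = c * y
        dx = (x[:, None] - x[None, :]) / hx[None, :]
        wy = np.exp(-0.5 * ((y[:, None] - y[None, :]) / hy[None, :]) ** 2) \
            / hy[None, :]
        wx = np.exp(-0.5 * dx ** 2)
        np.fill_diagonal(wx, 0.0)
        num = np.sum(wx * wy, axis=1)
        den = np.sum(wx, axis=1)
        ok = den > 0
        ll = float(np.sum(np.log(np.maximum(num[ok] / den[ok], 1e-300))))
        if ll > best_ll:
            best_ll, best_c = ll, c
    return best_c


def fit_stochastic_model(data: TransitionDataset, grid=DEFAULT_GRID,
                         bandwidth="cv", min_pairs: int = 30
                         ) -> StochasticSIModel:
    """Fit the conditional kernel density p(SI_{n+1} | SI_n).

    ``bandwidth`` is either a float (kernel sd as a fraction of the SI value)
    or ``"cv"`` to select it by leave-one-out pseudo-likelihood on the
    fitting data.  Rows are normalized to integrate to 1 on the grid.
    """
    if data.n < min_pairs:
        raise InsufficientDataError(
            f"need >= {min_pairs} transition pairs, have {data.n}")
    g = _make_grid(grid)
    x, y = data.si_now, data.si_next
    c = _loo_cv_bandwidth(x, y) if bandwidth == "cv" else float(bandwidth)
    if not 0 < c < 2:
        raise InvalidInputError(f"bandwidth fraction {c} out of range (0, 2)")
    hx = c * x
    hy = c * y
    # log-weight of datum j at conditioning point grid[i]; shifting each row
    # by its max exponent keeps far-from-data rows from underflowing to zero
    # (the conditional is row-normalized, so the shift cancels exactly)
    lw = -0.5 * ((g[:, None] - x[None, :]) / hx[None, :]) ** 2
    wx = np.exp(lw - lw.max(axis=1, keepdims=True))
    # kernel of datum j evaluated on the outcome grid
    ky = np.exp(-0.5 * ((y[:, None] - g[None, :]) / hy[:, None]) ** 2) \
        / (np.sqrt(2.0 * np.pi) * hy[:, None])
    cond = wx @ ky
    model = StochasticSIModel(grid=g, conditional=cond, bandwidth_frac=c,
                              n_pairs=data.n)
    integ = model.row_integrals()
    if np.any(integ <= 0):
        raise InsufficientDataError("a conditioning row received no density "
                                    "on the grid; widen the grid or the "
                                    "bandwidth")
    model.conditional = cond / integ[:, None]
    return model


@dataclass
class PercentileBands:
    """Conditional percentile curves of next-hour SI over the grid."""

    grid: np.ndarray
    quantiles: tuple
    bands: np.ndarray                # (len(quantiles), n_grid)

    def band(self, q: float) -> np.ndarray:
        return self.bands[self.quantiles.index(q)]

    @property
    def median(self) -> np.ndarray:
        return self.band(0.50)

    def to_frame(self):
        import pandas as pd
        d = {"si_now": self.grid}
        for q, row in zip(self.quantiles, self.bands):
            d[f"p{int(round(q * 100)):02d}"] = row
        return pd.DataFrame(d)


def percentile_bands(model: StochasticSIModel,
                     quantiles=DEFAULT_QUANTILES) -> PercentileBands:
    """Invert each row's conditional CDF at the requested probabilities."""
    qs = tuple(quantiles)
    out = np.empty((len(qs), model.grid.size))
    for i in range(model.grid.size):
        cdf = model.row_cdf(i)
        out[:, i] = np.interp(qs, cdf, model.grid)
    return PercentileBands(grid=model.grid, quantiles=qs, bands=out)


def sample_next_si(model: StochasticSIModel, si_now: float,
                   rng: np.random.Generator) -> float:
    """Draw next-hour SI from the conditional via inverse-CDF sampling."""
    i = model.row_index(si_now)
    cdf = model.row_cdf(i)
    u = rng.uniform()
    return float(np.interp(u, cdf, model.grid))


def band_overlap_summary(model_a: StochasticSIModel,
                         model_b: StochasticSIModel,
                         quantiles=DEFAULT_QUANTILES,
                         central_range: tuple[float, float] = CENTRAL_RANGE
                         ) -> dict:
    """Per-grid-point differences between two cohorts' percentile bands.

    If grids differ, B's bands are interpolated onto A's grid (warned).
    Summary medians are restricted to the configured central SI range, where
    clinical data density supports the comparison.
    """
    ba = percentile_bands(model_a, quantiles)
    bb = percentile_bands(model_b, quantiles)
    grid = ba.grid
    if not np.array_equal(model_a.grid, model_b.grid):
        logger.warning("grids differ; interpolating second model's bands")
        bb_bands = np.vstack([np.interp(grid, bb.grid, row)
                              for row in bb.bands])
    else:
        bb_bands = bb.bands
    absd = np.abs(ba.bands - bb_bands)
    reld = absd / np.maximum(np.abs(ba.bands), 1e-300)
    mask = (grid >= central_range[0]) & (grid <= central_range[1])
    out = {"grid": grid, "quantiles": tuple(quantiles),
           "abs_diff": absd, "rel_diff": reld,
           "central_median_rel_diff": {}}
    for j, q in enumerate(quantiles):
        out["central_median_rel_diff"][q] = float(np.median(reld[j, mask]))
    return out
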