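"""Temporal predation schedules and their pairwise Kolmogorov-Smirnov distances.

A schedule is a species x site predation-risk series over the deployment
calendar, normalized to unit mass so that comparisons reflect the *shape and
timing* of seasonal risk rather than its overall level (the convention of
the flowering-schedule comparison method this follows).  The KS distance is
the supremum absolute difference between the two cumulative schedules,
treated as right-continuous step functions on the date axis; it ranges from
0 (identical schedules) to 1 (temporally disjoint mass).

An un-normalized variant (cumulative raw risk, sensitive to level as well as
timing) is available via ``build_schedules(..., normalize=False)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import RiskTable

logger = logging.getLogger(__name__)

WEIGHT_SUM_TOL = 1e-12
METRIC_TOL = 1e-12


@dataclass(frozen=True)
class Schedule:
    """Unit-mass (or raw-risk) temporal distribution for one species x site."""

    species: str
    site: str
    dates: np.ndarray  # datetime64[D], strictly increasing
    weights: np.ndarray  # non-negative, sums to 1 when normalized
    observed: np.ndarray  # False where the risk value was interpolated
    normalized: bool = True

    def __post_init__(self):
        dates = np.asarray(self.dates, dtype="datetime64[D]")
        weights = np.asarray(self.weights, dtype=float)
        observed = np.asarray(self.observed, dtype=bool)
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "observed", observed)
        if not (len(dates) == len(weights) == len(observed)):
            raise ValueError("dates, weights and observed must have equal length")
        if np.any(np.diff(dates.astype("int64")) <= 0):
            raise ValueError("dates must be strictly increasing")
        if np.any(weights < 0):
            raise ValueError("weights must be non-negative")
        if self.normalized and abs(weights.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValueError(f"normalized weights must sum to 1, got {weights.sum()!r}")

    @property
    def label(self) -> tuple[str, str]:
        return (self.species, self.site)


def build_schedules(
    risks: RiskTable, normalize: bool = True, interpolate: bool = True
) -> list[Schedule]:
    """Convert a risk table into per-(species, site) schedules.

    Interior missing deployments are linearly interpolated on the date axis
    between the adjacent observed risks; gaps at the calendar boundaries take
    the nearest observed value.  Every fill is flagged (``observed=False``).
    Series with fewer than two observed deployments, or with all-zero risk,
    cannot define a temporal distribution and are excluded with a warning.
    """
    out: list[Schedule] = []
    tbl = risks.table
    for (site, species), grp in tbl.groupby(["site", "species"], sort=True):
        grp = grp.sort_values("date")
        dates = grp["date"].to_numpy(dtype="datetime64[D]")
        vals = grp["risk"].to_numpy(dtype=float)
        obs = ~np.isnan(vals)
        if obs.sum() < 2:
            logger.warning(
                "schedule (%s, %s) excluded: only %d observed deployments",
                species, site, int(obs.sum()),
            )
            continue
        if interpolate:
            x = dates.astype("int64").astype(float)
            # np.interp holds the boundary values flat, which is exactly the
            # nearest-observed rule for gaps at the calendar edges
            filled = np.interp(x, x[obs], vals[obs])
        else:
            filled = vals[obs]
            dates = dates[obs]
            obs = np.ones(obs.sum(), dtype=bool)
        if filled.sum() <= 0:
            logger.warning("schedule (%s, %s) excluded: all-zero risk series", species, site)
            continue
        weights = filled / filled.sum() if normalize else filled
        out.append(
            Schedule(
                species=species,
                site=site,
                dates=dates,
                weights=weights,
                observed=obs,
                normalized=normalize,
            )
        )
    return out


def _cdf_on_grid(sched: Schedule, grid: np.ndarray) -> np.ndarray:
    """Right-continuous cumulative schedule evaluated at the grid dates."""
    cum = np.concatenate(([0.0], np.cumsum(sched.weights)))
    idx = np.searchsorted(sched.dates, grid, side="right")
    return cum[idx]


def ks_distance(a: Schedule, b: Schedule) -> float:
    """sup |F_a - F_b| over the union of both schedules' date grids."""
    grid = np.union1d(a.dates, b.dates)
    return float(np.max(np.abs(_cdf_on_grid(a, grid) - _cdf_on_grid(b, grid))))


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix of pairwise KS statistics."""

    labels: list[tuple[str, str]]
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")

    def to_dataframe(self) -> pd.DataFrame:
        names = [f"{sp}@{site}" for sp, site in self.labels]
        return pd.DataFrame(self.D, index=names, columns=names)

    def to_csv(self, path, float_format: str = "%.12g") -> None:
        self.to_dataframe().to_csv(path, index_label="label", float_format=float_format)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        labels = [tuple(name.split("@", 1)) for name in df.index]
        return cls(labels=labels, D=df.to_numpy(dtype=float))

    def sites(self) -> dict[tuple[str, str], str]:
        """Label -> site grouping for dispersion analysis."""
        return {lab: lab[1] for lab in self.labels}


def ks_matrix(schedules: list[Schedule]) -> DistanceMatrix:
    """All pairwise KS distances among the given schedules."""
    if len(schedules) < 2:
        raise ValueError("need at least two schedules")
    labels = [s.label for s in schedules]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (species, site) labels")
    n = len(schedules)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = ks_distance(schedules[i], schedules[j])
    return DistanceMatrix(labels=labels, D=D)


@dataclass(frozen=True)
class MetricReport:
    """Outcome of the exhaustive triangle-inequality audit of a matrix."""

    triangle_inequality_ok: bool
    worst_violation: float
    n_triples_checked: int


def check_metric(dm: DistanceMatrix, tol: float = METRIC_TOL) -> MetricReport:
    """Exhaustively audit symmetry, non-negativity and the triangle inequality.

    ``worst_violation`` is the largest signed excess D[i,k] - D[i,j] - D[j,k]
    over all unordered triples of distinct points; non-positive means the
    inequality holds.
    """
    D = dm.D
    n = D.shape[0]
    if np.any(D < -tol):
        raise ValueError("distance matrix has negative entries")
    if np.max(np.abs(D - D.T)) > tol:
        raise ValueError("distance matrix is not symmetric")
    if np.max(np.abs(np.diag(D))) > tol:
        raise ValueError("distance matrix has a nonzero diagonal")
    worst = -np.inf
    for j in range(n):
        # excess[i, k] = D[i, k] - (D[i, j] + D[j, k]) for intermediate j
        excess = D - D[:, j][:, None] - D[j, :][None, :]
        mask = np.ones((n, n), dtype=bool)
        mask[j, :] = mask[:, j] = False
        np.fill_diagonal(mask, False)
        if mask.any():
            worst = max(worst, float(excess[mask].max()))
    n_triples = n * (n - 1) * (n - 2) // 6
    if n < 3:
        worst = 0.0
    return MetricReport(
        triangle_inequality_ok=bool(worst <= tol),
        worst_violation=worst,
        n_triples_checked=n_triples,
    )


def schedules_to_frame(schedules: list[Schedule]) -> pd.DataFrame:
    """Long-format export: one row per (species, site, date)."""
    rows = []
    for s in schedules:
        for d, w, o in zip(s.dates, s.weights, s.observed):
            rows.append(
                {
                    "species": s.species,
                    "site": s.site,
                    "date": pd.Timestamp(d),
                    "weight": float(w),
                    "provenance": "observed" if o else "interpolated",
                    "normalized": s.normalized,
                }
            )
    return pd.DataFrame(rows)


def schedules_from_frame(df: pd.DataFrame) -> list[Schedule]:
    """Rebuild schedules from the long-format export.

    Serialized weights are rounded for portability, so normalized schedules
    are re-normalized on read (a relative adjustment below 1e-11).
    """
    out = []
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    for (site, species), grp in df.groupby(["site", "species"], sort=True):
        grp = grp.sort_values("date")
        weights = grp["weight"].to_numpy(dtype=float)
        normalized = bool(grp["normalized"].iloc[0])
        if normalized:
            weights = weights / weights.sum()
        out.append(
            Schedule(
                species=species,
                site=site,
                dates=grp["date"].to_numpy(dtype="datetime64[D]"),
                weights=weights,
                observed=(grp["provenance"] == "observed").to_numpy(),
                normalized=normalized,
            )
        )
    return out
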