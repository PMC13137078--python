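"""Annual variability of predation risk and the habitat correlation battery.

Community-level predation risk at a site and deployment is the pooled
proportion of all tethered animals consumed, regardless of species:
sum(consumed) / sum(recovered).  Its sample standard deviation over the
site's deployments ("community SD") measures how seasonal predation is as a
community-level process; the analogous per-species SD measures each
species' own seasonality.  Pearson and Spearman correlations then relate
site dispersion (among-species variation), community SD, and habitat means.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import RiskTable
from .ordination import DispersionResult

logger = logging.getLogger(__name__)

#: the default site-level correlation battery: (x metric, y metric)
DEFAULT_SITE_BATTERY: tuple[tuple[str, str], ...] = (
    ("dispersion", "community_sd"),
    ("mean_eelgrass_cover", "dispersion"),
    ("mean_eelgrass_cover", "community_sd"),
    ("mean_shoot_density", "dispersion"),
    ("mean_shoot_density", "community_sd"),
    ("mean_bare_cover", "dispersion"),
    ("mean_bare_cover", "community_sd"),
    ("mean_macroalgae_cover", "dispersion"),
    ("mean_macroalgae_cover", "community_sd"),
)
#: habitat metrics each species' annual SD is correlated against
DEFAULT_SPECIES_HABITAT: tuple[str, ...] = ("mean_eelgrass_cover", "mean_shoot_density")


@dataclass
class VariabilityResult:
    """Community series + SD per site, and per-(species, site) SDs."""

    community_series: pd.DataFrame  # site, date, deployment, pooled_risk
    community_sd: pd.DataFrame  # site, community_sd, n_deployments
    species_sd: pd.DataFrame  # species, site, species_sd, n_observed


def community_variability(risks: RiskTable, pooled: bool = True) -> VariabilityResult:
    """Pooled community risk series and its per-site sample SD.

    With ``pooled=True`` (default) the community risk at a deployment is
    total consumed over total recovered across species; ``pooled=False``
    instead averages the species proportions unweighted (the "average of the
    colored lines" reading).  Deployments with no recovered tether are
    skipped.  Sites with fewer than two usable deployments get a missing SD.
    """
    series_rows = []
    sd_rows = []
    for site, grp in risks.table.groupby("site", sort=True):
        vals = []
        for (date, dep), g in grp.groupby(["date", "deployment"], sort=True):
            rec = g["n_recovered"].sum()
            if rec == 0:
                logger.warning("site %s deployment %s: nothing recovered; skipped", site, dep)
                continue
            if pooled:
                risk = float(g["n_consumed"].sum() / rec)
            else:
                sp_risk = g["risk"].dropna()
                risk = float(sp_risk.mean())
            vals.append(risk)
            series_rows.append(
                {"site": site, "date": date, "deployment": int(dep), "pooled_risk": risk}
            )
        if len(vals) < 2:
            logger.warning("site %s: <2 usable deployments; community SD missing", site)
            sd = np.nan
        else:
            sd = float(np.std(vals, ddof=1))
        sd_rows.append({"site": site, "community_sd": sd, "n_deployments": len(vals)})
    return VariabilityResult(
        community_series=pd.DataFrame(series_rows),
        community_sd=pd.DataFrame(sd_rows),
        species_sd=pd.DataFrame(columns=["species", "site", "species_sd", "n_observed"]),
    )


def species_variability(risks: RiskTable) -> pd.DataFrame:
    """Sample SD of each species' observed risk series (site by site).

    Only observed deployments enter: interpolated values exist solely to
    complete schedule grids for the KS comparison and are excluded here.
    """
    rows = []
    for (site, species), grp in risks.table.groupby(["site", "species"], sort=True):
        vals = grp["risk"].dropna().to_numpy()
        if len(vals) < 2:
            logger.warning("series (%s, %s): <2 observations; SD missing", species, site)
            sd = np.nan
        else:
            sd = float(np.std(vals, ddof=1))
        rows.append(
            {"species": species, "site": site, "species_sd": sd, "n_observed": len(vals)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    estimate: float
    df: int
    p_value: float
    n: int
    x_name: str = ""
    y_name: str = ""
    degenerate: bool = False


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (enumerates n! orders)."""
    n = len(xr)
    xs = (xr - xr.mean()) / xr.std()
    ys = (yr - yr.mean()) / yr.std()
    count = 0
    total = 0
    thresh = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        rho = float(np.dot(xs, ys[list(perm)])) / n
        if abs(rho) >= thresh:
            count += 1
        total += 1
    return count / total


def correlate(
    x, y, method: str = "pearson", x_name: str = "", y_name: str = ""
) -> CorrelationResult:
    """Correlation with pairwise-complete deletion and two-sided p-value.

    Pearson p comes from the t statistic r * sqrt(df / (1 - r^2)) with
    df = n - 2.  Spearman rho is Pearson on average ranks; its p is an exact
    all-permutations value for n <= 8 and the t approximation otherwise.
    Zero variance in either input leaves the estimate undefined (flagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < len(x):
        logger.info("dropped %d incomplete pair(s)", int(len(x) - ok.sum()))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    df = n - 2
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in %s or %s: correlation undefined", x_name, y_name)
        return CorrelationResult(method, np.nan, df, np.nan, n, x_name, y_name, True)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), df, float(p), n, x_name, y_name)
    if method == "spearman":
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        rho = float(stats.pearsonr(xr, yr)[0])
        if n <= 8:
            p = _spearman_exact_p(xr, yr, rho)
        elif abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt(df / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df))
        return CorrelationResult("spearman", rho, df, float(p), n, x_name, y_name)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class AnalysisReport:
    """Consolidated site table, species table and correlation battery."""

    site_table: pd.DataFrame
    species_table: pd.DataFrame
    correlations: pd.DataFrame
    n_tests: int = 0

    def to_dict(self) -> dict:
        return {
            "site_table": self.site_table.to_dict(orient="records"),
            "species_table": self.species_table.to_dict(orient="records"),
            "correlations": self.correlations.to_dict(orient="records"),
            "n_tests": self.n_tests,
        }


def association_report(
    dispersion: DispersionResult,
    variability: VariabilityResult,
    habitat: pd.DataFrame,
    site_battery: tuple[tuple[str, str], ...] | None = None,
    species_habitat: tuple[str, ...] | None = None,
    method: str = "pearson",
) -> AnalysisReport:
    """Correlation battery over per-site metrics plus per-species SD rows.

    No multiple-testing correction is applied; ``n_tests`` is reported so
    users can apply their own.  Sites missing any metric in a pair are
    dropped pairwise.
    """
    if site_battery is None:
        site_battery = DEFAULT_SITE_BATTERY
    if species_habitat is None:
        species_habitat = DEFAULT_SPECIES_HABITAT
    disp = dispersion.group_means.rename(columns={"group": "site"})[["site", "dispersion"]]
    site_table = disp.merge(variability.community_sd[["site", "community_sd"]],
                            on="site", how="outer")
    site_table = site_table.merge(habitat, on="site", how="outer").sort_values("site")
    usable = site_table.dropna(subset=["dispersion", "community_sd"])
    if len(usable) < 3:
        raise ValueError(f"need >=3 sites with complete core metrics, got {len(usable)}")

    species_table = variability.species_sd.merge(
        habitat[["site"] + [c for c in habitat.columns if c.startswith("mean_")]],
        on="site", how="left",
    )

    rows = []
    for x_name, y_name in site_battery:
        res = correlate(site_table[x_name], site_table[y_name], method=method,
                        x_name=x_name, y_name=y_name)
        rows.append(res)
    for species in sorted(species_table["species"].unique()):
        sub = species_table[species_table["species"] == species]
        for metric in species_habitat:
            n_complete = int((sub[metric].notna() & sub["species_sd"].notna()).sum())
            if n_complete < 3:
                logger.warning(
                    "species %s has %d complete site(s) for %s; correlation skipped",
                    species, n_complete, metric,
                )
                continue
            res = correlate(sub[metric], sub["species_sd"], method=method,
                            x_name=metric, y_name=f"species_sd[{species}]")
            rows.append(res)
    corr = pd.DataFrame(
        [
            {
                "x": r.x_name,
                "y": r.y_name,
                "method": r.method,
                "estimate": r.estimate,
                "df": r.df,
                "p_value": r.p_value,
                "n": r.n,
                "degenerate": r.degenerate,
            }
            for r in rows
        ]
    )
    return AnalysisReport(
        site_table=site_table.reset_index(drop=True),
        species_table=species_table,
        correlations=corr,
        n_tests=len(rows),
    )
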