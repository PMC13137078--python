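"""Synthetic tethering studies under three hypothesized seasonal regimes.

Each species' latent predation risk follows a Gaussian seasonal bump

    r_s(t) = baseline + amplitude * exp(-(t - peak_day)^2 / (2 width^2))

on a day axis counted from 1 January of the study's first year.  A per-site
mixing parameter ``gamma`` interpolates the species' peak days between two
regimes:

* ``gamma = 0`` — every species shares one seasonal peak, so community-level
  (pooled) risk is strongly seasonal while species schedules coincide;
* ``gamma = 1`` — peaks are evenly staggered through the deployment window
  with matched amplitudes, so species schedules differ maximally in timing
  while their summed risk is near-constant away from the window edges.

Flat-but-distinct species hierarchies (constant per-species levels) are the
degenerate case ``amplitude = 0`` with per-species baselines; note that
unit-mass schedule normalization collapses such series to identical uniform
schedules, which is why this case is kept separate in testing.

Counts are binomial: tethers recovered ~ Binomial(n, recovery_prob), prey
consumed ~ Binomial(recovered, r_s(t)).  One master seed deterministically
derives an independent random substream per (site, deployment, species), so
adding or removing a site never perturbs another site's draws.

The companion habitat generator produces quadrat surveys whose mean eelgrass
cover increases monotonically with ``gamma``, emulating the field gradient
from nearly bare sites (~2% cover) to dense beds (~50% cover).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .io import validate_habitat_table, validate_tether_table

#: four focal peracarid species; the Ampithoe-valida column is absent at the
#: three sites where the species does not occur
SPECIES_FOUR = ("A.lacertosa", "A.valida", "C.californica", "P.resecata")
SPECIES_THREE = ("A.lacertosa", "C.californica", "P.resecata")


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class RiskCurve:
    """Latent seasonal predation-risk curve for one species.

    Parameters are proportions except ``peak_day`` and ``width`` (days on
    the study-year axis; ``width`` is the Gaussian standard deviation).
    """

    species: str
    baseline: float = 0.1
    amplitude: float = 0.5
    peak_day: float = 258.0
    width: float = 35.0

    def __post_init__(self):
        if not 0.0 <= self.baseline + self.amplitude <= 1.0:
            raise ConfigError(
                f"{self.species}: baseline + amplitude = "
                f"{self.baseline + self.amplitude} outside [0, 1]"
            )
        if self.width <= 0:
            raise ConfigError(f"{self.species}: width must be positive")

    def risk(self, day):
        """Risk at day-of-study-year ``day`` (scalar or array)."""
        day = np.asarray(day, dtype=float)
        r = self.baseline + self.amplitude * np.exp(
            -((day - self.peak_day) ** 2) / (2.0 * self.width**2)
        )
        return r if r.ndim else float(r)


@dataclass(frozen=True)
class SiteDesign:
    site: str
    species: tuple[str, ...]
    gamma: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigError(f"{self.site}: gamma must lie in [0, 1]")


@dataclass(frozen=True)
class StudyDesign:
    """Field-study layout: sites, deployment calendar, effort and seed."""

    sites: tuple[SiteDesign, ...]
    deployments: tuple[date, ...]
    tethers_per_species: int = 20
    recovery_prob: float = 0.9
    seed: int = 0
    baseline: float = 0.1
    amplitude: float = 0.5
    width: float = 35.0
    shared_peak_day: float = 258.0  # mid-September: the early-fall maximum

    def __post_init__(self):
        if list(self.deployments) != sorted(set(self.deployments)):
            raise ConfigError("deployment dates must be strictly increasing")
        if not 0.0 <= self.recovery_prob <= 1.0:
            raise ConfigError("recovery_prob must lie in [0, 1]")

    @property
    def year0(self) -> int:
        return self.deployments[0].year

    def day_of_study_year(self, d: date) -> float:
        return float((d - date(self.year0, 1, 1)).days)


def default_design(seed: int = 0, gammas: tuple[float, ...] | None = None) -> StudyDesign:
    """Six-site, 16-deployment study spanning one year.

    Three sites carry all four focal species, three carry three (matching the
    Tomales Bay / Bodega Harbor split), giving 21 species x site series.
    Sites are ordered along the habitat gradient NC < MM < MP < CC < WP < BL
    with ``gamma`` spanning 0..1 by default.
    """
    if gammas is None:
        gammas = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    codes = ("NC", "MM", "MP", "CC", "WP", "BL")
    # four-species sites per the field design (the three Tomales Bay sites)
    four = {"NC", "MP", "BL"}
    sites = tuple(
        SiteDesign(code, SPECIES_FOUR if code in four else SPECIES_THREE, g)
        for code, g in zip(codes, gammas)
    )
    start = date(2022, 4, 15)
    deployments = tuple(start + timedelta(days=22 * k) for k in range(16))
    return StudyDesign(sites=sites, deployments=deployments, seed=seed)


def site_curves(design: StudyDesign, site: SiteDesign) -> list[RiskCurve]:
    """Per-species risk curves for one site under its gamma mix.

    Staggered peaks are evenly spaced over [first + 2w, last - 2w] of the
    deployment window so the Gaussian bumps stay clear of the window edges;
    each species' realized peak is the gamma-weighted blend of the shared
    peak and its staggered position.
    """
    t0 = design.day_of_study_year(design.deployments[0])
    t1 = design.day_of_study_year(design.deployments[-1])
    lo, hi = t0 + 2 * design.width, t1 - 2 * design.width
    if lo >= hi:
        raise ConfigError("deployment window too short for the curve width")
    n = len(site.species)
    staggered = np.linspace(lo, hi, n)
    curves = []
    for sp, pk in zip(site.species, staggered):
        peak = (1.0 - site.gamma) * design.shared_peak_day + site.gamma * pk
        curves.append(
            RiskCurve(sp, design.baseline, design.amplitude, float(peak), design.width)
        )
    return curves


def _substream(seed: int, *parts: str) -> np.random.Generator:
    """Independent generator keyed by a stable hash of the string parts."""
    key = zlib.crc32("|".join(parts).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def simulate_tethering(
    curves: list[RiskCurve], design: StudyDesign, site: str
) -> pd.DataFrame:
    """Draw one site's tether outcome table under the binomial model."""
    rows = []
    for d in design.deployments:
        t = design.day_of_study_year(d)
        for curve in curves:
            r = curve.risk(t)
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"{curve.species}: risk {r} at day {t} outside [0, 1]")
            rng = _substream(design.seed, "tether", site, d.isoformat(), curve.species)
            n_rec = int(rng.binomial(design.tethers_per_species, design.recovery_prob))
            n_con = int(rng.binomial(n_rec, r))
            rows.append(
                {
                    "site": site,
                    "date": pd.Timestamp(d),
                    "species": curve.species,
                    "n_deployed": design.tethers_per_species,
                    "n_recovered": n_rec,
                    "n_consumed": n_con,
                }
            )
    return validate_tether_table(pd.DataFrame(rows))


def _habitat_means(gamma: float) -> dict[str, float]:
    """Site-level habitat means along the gradient.

    Anchored to the field extremes: eelgrass cover 2..50%, shoot density
    1.15..34.8 per 0.25 m^2, bare ground 94..50.1% between the barest and
    densest sites.
    """
    return {
        "eelgrass": 2.0 + 48.0 * gamma,
        "shoots": 1.15 + 33.65 * gamma,
        "bare": 94.0 - 43.9 * gamma,
    }


def simulate_habitat(
    design: StudyDesign,
    site: SiteDesign,
    n_surveys: int = 11,
    n_quadrats: int = 5,
) -> pd.DataFrame:
    """Quadrat surveys for one site over the year after the tethering study."""
    means = _habitat_means(site.gamma)
    start = design.deployments[0] + timedelta(days=365)
    dates = [start + timedelta(days=32 * k) for k in range(n_surveys)]
    rng_site = _substream(design.seed, "habitat-site", site.site)
    macro_mean = float(rng_site.uniform(0.0, 20.0))
    rows = []
    for d in dates:
        doy = (d - date(d.year, 1, 1)).days
        # seasonal growth factor: summer maximum, winter minimum, annual mean ~1
        season = 1.0 + 0.6 * np.cos(2 * np.pi * (doy - 227) / 365.0)
        rng = _substream(design.seed, "habitat", site.site, d.isoformat())
        for q in range(1, n_quadrats + 1):
            eel = np.clip(
                rng.normal(means["eelgrass"] * season, 0.25 * means["eelgrass"] + 1.0),
                0.0, 100.0,
            )
            shoots = rng.poisson(max(means["shoots"] * season, 0.0))
            macro = np.clip(rng.normal(macro_mean, 4.0), 0.0, 100.0)
            sessile = np.clip(rng.normal(2.0, 2.0), 0.0, 100.0)
            bare = np.clip(
                rng.normal(means["bare"] - (season - 1.0) * means["eelgrass"], 5.0),
                0.0, 100.0,
            )
            rows.append(
                {
                    "site": site.site,
                    "date": pd.Timestamp(d),
                    "quadrat": q,
                    "eelgrass_cover_pct": float(eel),
                    "macroalgae_cover_pct": float(macro),
                    "sessile_invert_cover_pct": float(sessile),
                    "bare_cover_pct": float(bare),
                    "shoot_count": float(shoots),
                }
            )
    return validate_habitat_table(pd.DataFrame(rows))


def simulate_study(design: StudyDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full synthetic study: one tether table and one habitat table.

    Deterministic in ``design.seed``; per-(site, deployment, species)
    substreams make site blocks independent of each other.
    """
    tether_parts = []
    habitat_parts = []
    for site in design.sites:
        curves = site_curves(design, site)
        tether_parts.append(simulate_tethering(curves, design, site.site))
        habitat_parts.append(simulate_habitat(design, site))
    tethers = validate_tether_table(pd.concat(tether_parts, ignore_index=True))
    habitat = validate_habitat_table(pd.concat(habitat_parts, ignore_index=True))
    return tethers, habitat


def design_from_dict(cfg: dict, seed: int | None = None) -> StudyDesign:
    """Build a StudyDesign from a config mapping (YAML/JSON ``simulation`` block)."""
    if "sites" in cfg:
        sites = tuple(
            SiteDesign(s["site"], tuple(s["species"]), float(s.get("gamma", 0.0)))
            for s in cfg["sites"]
        )
        deployments = tuple(date.fromisoformat(str(d)) for d in cfg["deployments"])
        design = StudyDesign(
            sites=sites,
            deployments=deployments,
            tethers_per_species=int(cfg.get("tethers_per_species", 20)),
            recovery_prob=float(cfg.get("recovery_prob", 0.9)),
            seed=int(cfg.get("seed", 0)),
            baseline=float(cfg.get("baseline", 0.1)),
            amplitude=float(cfg.get("amplitude", 0.5)),
            width=float(cfg.get("width", 35.0)),
            shared_peak_day=float(cfg.get("shared_peak_day", 258.0)),
        )
    else:
        design = default_design(seed=int(cfg.get("seed", 0)))
        overrides = {
            k: cfg[k]
            for k in ("tethers_per_species", "recovery_prob", "baseline",
                      "amplitude", "width", "shared_peak_day")
            if k in cfg
        }
        if "gammas" in cfg:
            design = default_design(seed=int(cfg.get("seed", 0)),
                                    gammas=tuple(float(g) for g in cfg["gammas"]))
        if overrides:
            design = replace(design, **overrides)
    if seed is not None:
        design = replace(design, seed=int(seed))
    return design
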