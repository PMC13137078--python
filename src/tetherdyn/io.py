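"""Readers, writers and core tables for tethering-assay and habitat data.

A tethering assay records, for each site x deployment date x prey species,
how many tethered individuals were deployed, how many tethers were recovered
~24 h later, and how many recovered tethers had the prey missing (scored as
consumed).  Predation risk is the proportion of *recovered* tethers with
missing prey: lost tethers carry no information about consumption, so the
denominator is ``n_recovered``, not ``n_deployed``.

Habitat surveys record percent cover (eelgrass, macroalgae, sessile
invertebrates, bare ground) and eelgrass shoot counts in 0.25 m^2 quadrats.
Covers are layered substrates, so the per-quadrat total may exceed 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TETHER_COLUMNS = ["site", "date", "species", "n_deployed", "n_recovered", "n_consumed"]
HABITAT_COLUMNS = [
    "site",
    "date",
    "quadrat",
    "eelgrass_cover_pct",
    "macroalgae_cover_pct",
    "sessile_invert_cover_pct",
    "bare_cover_pct",
    "shoot_count",
]
HABITAT_METRICS = {
    "eelgrass_cover": "eelgrass_cover_pct",
    "shoot_density": "shoot_count",
    "bare_cover": "bare_cover_pct",
    "macroalgae_cover": "macroalgae_cover_pct",
    "sessile_invert_cover": "sessile_invert_cover_pct",
}


class ValidationError(ValueError):
    """A table violates a structural invariant (counts, duplicates, ranges)."""


class ParseError(ValueError):
    """A file row could not be parsed; the message names the offending line."""


def _rename_from_map(df: pd.DataFrame, column_map: dict[str, str] | None,
                     required: list[str], path) -> pd.DataFrame:
    """Map native file columns to standard names.

    ``column_map`` maps standard name -> column name in the file, so a
    deposit with its own header vocabulary can be ingested without editing
    the file.
    """
    if column_map:
        rename = {native: std for std, native in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _parse_dates(df: pd.DataFrame, path) -> pd.Series:
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: line {line}: unparseable date {df['date'][bad.idxmax()]!r}")
    if parsed.isna().any():
        line = int(parsed.isna().idxmax()) + 2
        raise ParseError(f"{path}: line {line}: empty date")
    return parsed


def _parse_counts(df: pd.DataFrame, cols: list[str], path) -> pd.DataFrame:
    out = df.copy()
    for col in cols:
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: line {line}: non-numeric {col}={out[col][bad.idxmax()]!r}")
        if not np.allclose(vals, np.round(vals)):
            line = int((~np.isclose(vals, np.round(vals))).idxmax()) + 2
            raise ParseError(f"{path}: line {line}: {col} must be an integer")
        out[col] = vals.round().astype(int)
    return out


def validate_tether_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check TetherRecord invariants; return the table sorted by site/date/species."""
    counts = ["n_deployed", "n_recovered", "n_consumed"]
    if (df[counts] < 0).any().any():
        raise ValidationError("tether counts must be non-negative")
    if (df["n_recovered"] > df["n_deployed"]).any():
        bad = df[df["n_recovered"] > df["n_deployed"]].iloc[0]
        raise ValidationError(
            f"n_recovered > n_deployed for ({bad['site']}, {bad['date'].date()}, {bad['species']})"
        )
    if (df["n_consumed"] > df["n_recovered"]).any():
        bad = df[df["n_consumed"] > df["n_recovered"]].iloc[0]
        raise ValidationError(
            f"n_consumed > n_recovered for ({bad['site']}, {bad['date'].date()}, {bad['species']})"
        )
    dup = df.duplicated(subset=["site", "date", "species"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate record for ({bad['site']}, {bad['date'].date()}, {bad['species']})"
        )
    return df.sort_values(["site", "date", "species"], kind="stable").reset_index(drop=True)


def read_tether_records(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a tethering outcome CSV into a validated table.

    Parameters
    ----------
    path
        CSV with header and columns site, date, species, n_deployed,
        n_recovered, n_consumed (or natives remapped via ``column_map``).
    column_map
        Optional mapping ``standard_name -> column name in the file``.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df = _rename_from_map(df, column_map, TETHER_COLUMNS, path)
    df = df[TETHER_COLUMNS].copy()
    df["date"] = _parse_dates(df, path)
    df = _parse_counts(df, ["n_deployed", "n_recovered", "n_consumed"], path)
    return validate_tether_table(df)


def write_tether_records(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[TETHER_COLUMNS].to_csv(path, index=False)


def validate_habitat_table(df: pd.DataFrame) -> pd.DataFrame:
    covers = [
        "eelgrass_cover_pct",
        "macroalgae_cover_pct",
        "sessile_invert_cover_pct",
        "bare_cover_pct",
    ]
    if (df[covers] < 0).any().any():
        raise ValidationError("percent covers must be non-negative")
    if (df["shoot_count"] < 0).any():
        raise ValidationError("shoot_count must be non-negative")
    # layered substrates: per-quadrat cover totals above 100% are legitimate
    return df.sort_values(["site", "date", "quadrat"], kind="stable").reset_index(drop=True)


def read_habitat_quadrats(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a habitat quadrat survey CSV into a validated table."""
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df = _rename_from_map(df, column_map, HABITAT_COLUMNS, path)
    df = df[HABITAT_COLUMNS].copy()
    df["date"] = _parse_dates(df, path)
    df = _parse_counts(df, ["quadrat"], path)
    for col in [
        "eelgrass_cover_pct",
        "macroalgae_cover_pct",
        "sessile_invert_cover_pct",
        "bare_cover_pct",
        "shoot_count",
    ]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.isna().idxmax()) + 2
            raise ParseError(f"{path}: line {line}: non-numeric {col}")
        df[col] = vals.astype(float)
    return validate_habitat_table(df)


def write_habitat_quadrats(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[HABITAT_COLUMNS].to_csv(path, index=False)


@dataclass
class RiskTable:
    """Species-level predation risk on the full site x deployment x species grid.

    ``table`` has one row per (site, deployment, species) for every species
    ever deployed at the site and every date in the site's deployment
    calendar; ``risk`` is ``n_consumed / n_recovered`` and is NaN (missing)
    exactly when the combination was not deployed or no tether was recovered.
    ``calendars`` holds each site's deployment dates in ascending order;
    deployment indices are 1-based positions in that calendar.
    """

    table: pd.DataFrame
    calendars: dict[str, list[pd.Timestamp]] = field(default_factory=dict)

    def site_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for site, grp in self.table.groupby("site", sort=True):
            out[site] = sorted(grp["species"].unique())
        return out


def compute_risk_table(tethers: pd.DataFrame) -> RiskTable:
    """Per-combination predation risk = consumed / recovered.

    Combinations with no recovered tether (or never deployed) are explicitly
    missing — never imputed as zero at this layer.
    """
    if len(tethers) == 0:
        raise ValidationError("empty tether table")
    rows = []
    calendars: dict[str, list[pd.Timestamp]] = {}
    for site, grp in tethers.groupby("site", sort=True):
        dates = sorted(grp["date"].unique())
        calendars[site] = [pd.Timestamp(d) for d in dates]
        species = sorted(grp["species"].unique())
        obs = grp.set_index(["date", "species"])
        for t, date in enumerate(dates, start=1):
            for sp in species:
                if (date, sp) in obs.index:
                    rec = obs.loc[(date, sp)]
                    n_rec = int(rec["n_recovered"])
                    n_con = int(rec["n_consumed"])
                    risk = n_con / n_rec if n_rec > 0 else np.nan
                    if n_rec == 0:
                        logger.info(
                            "no tethers recovered for (%s, %s, %s); risk marked missing",
                            site, pd.Timestamp(date).date(), sp,
                        )
                else:
                    n_rec, n_con, risk = 0, 0, np.nan
                rows.append(
                    {
                        "site": site,
                        "date": pd.Timestamp(date),
                        "deployment": t,
                        "species": sp,
                        "n_recovered": n_rec,
                        "n_consumed": n_con,
                        "risk": risk,
                    }
                )
    table = pd.DataFrame(rows)
    return RiskTable(table=table, calendars=calendars)


def write_risk_table(risks: RiskTable, path, float_format: str = "%.12g") -> None:
    out = risks.table.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format=float_format)


def read_risk_table(path) -> RiskTable:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    df["risk"] = pd.to_numeric(df["risk"], errors="coerce")
    calendars = {
        site: sorted(pd.Timestamp(d) for d in grp["date"].unique())
        for site, grp in df.groupby("site", sort=True)
    }
    return RiskTable(table=df, calendars=calendars)


def summarize_habitat(quadrats: pd.DataFrame) -> pd.DataFrame:
    """Per-site grand means and annual ranges for each habitat metric.

    The grand mean is the unweighted mean over all quadrat rows; with a
    balanced design (equal quadrats per survey) this equals the mean of the
    per-survey-date site means.  The annual range is (min, max) of the
    per-survey-date site means.
    """
    rows = []
    for site, grp in quadrats.groupby("site", sort=True):
        row: dict[str, object] = {"site": site}
        by_date = grp.groupby("date")
        for metric, col in HABITAT_METRICS.items():
            row[f"mean_{metric}"] = float(grp[col].mean())
            date_means = by_date[col].mean()
            row[f"{metric}_min"] = float(date_means.min())
            row[f"{metric}_max"] = float(date_means.max())
        rows.append(row)
    return pd.DataFrame(rows)
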