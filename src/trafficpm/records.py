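"""Reading, validation and curation of urban source-apportionment records.

One record is one reported measurement of annual-mean PM2.5 in a city,
together with the percentage of that concentration attributed to traffic
(tailpipe plus non-tailpipe) by the source-apportionment study, and
study-level covariates: publication year, city population, geographic
coordinates, site typology, whether a sea-salt contribution was reported,
and the estimation method.  The curated table adds the derived
traffic-related concentration (overall x share / 100) and the model
covariates: log population in millions, latitude / 10, a post-2005
publication dummy and a four-level location category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ConfigurationError",
    "ValidationError",
    "FitError",
    "REQUIRED_COLUMNS",
    "REGIONS",
    "LOCATION_CATEGORIES",
    "DEFAULT_REGRESSORS",
    "DesignMatrices",
    "read_records",
    "filter_records",
    "curate",
    "build_design",
    "descriptive_summary",
    "regressor_row",
]


class DataError(Exception):
    """The data itself makes the requested operation impossible."""


class ConfigurationError(Exception):
    """A config (dialect, regressor list, threshold...) is invalid."""


class ValidationError(Exception):
    """Records violate hard invariants; carries per-row problem messages."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} invalid record(s): " + "; ".join(self.problems[:5])
            + ("; ..." if len(self.problems) > 5 else "")
        )


class FitError(Exception):
    """Model fitting failed (rank deficiency, ill-posed input...)."""


#: Canonical column names; a dialect maps these to arbitrary source headers.
REQUIRED_COLUMNS = (
    "study_id",
    "city",
    "country",
    "region",
    "pub_year",
    "population",
    "latitude",
    "longitude",
    "site_type",
    "overall_pm25",
    "traffic_share_pct",
    "sea_salt_reported",
    "method",
)

#: The 12 geographic regions used to stratify the database.
REGIONS = (
    "Africa",
    "Central and Eastern Europe",
    "East Asia",
    "Middle East",
    "North America",
    "Northwestern Europe",
    "Oceania/Japan",
    "South/Central America",
    "Southeastern Asia",
    "Southern Asia",
    "Southwestern Europe",
    "Western Europe",
)

#: Four-level location grouping used in the regression (reference: rest_of_world).
LOCATION_CATEGORIES = ("NA_Oceania_Japan", "NW_W_Europe", "rest_of_Europe", "rest_of_world")

_REGION_TO_LOC = {
    "North America": "NA_Oceania_Japan",
    "Oceania/Japan": "NA_Oceania_Japan",
    "Northwestern Europe": "NW_W_Europe",
    "Western Europe": "NW_W_Europe",
    "Central and Eastern Europe": "rest_of_Europe",
    "Southwestern Europe": "rest_of_Europe",
}

#: Default regressor sets.  The traffic equation carries the post-2005 dummy;
#: the overall equation instead separates the rest of Europe from the rest of
#: the world.  Dummy reference groups: no sea salt reported, published on or
#: before 2005, rest of the world.
DEFAULT_REGRESSORS = {
    "traffic": [
        "ln_population",
        "lat10",
        "sea_salt_reported",
        "post2005",
        "loc_NA_Oceania_Japan",
        "loc_NW_W_Europe",
    ],
    "overall": [
        "ln_population",
        "lat10",
        "sea_salt_reported",
        "loc_NA_Oceania_Japan",
        "loc_NW_W_Europe",
        "loc_rest_of_Europe",
    ],
}

_KNOWN_REGRESSORS = (
    "ln_population",
    "lat10",
    "sea_salt_reported",
    "post2005",
    "loc_NA_Oceania_Japan",
    "loc_NW_W_Europe",
    "loc_rest_of_Europe",
)

_NUMERIC_COLUMNS = ("pub_year", "population", "latitude", "longitude",
                    "overall_pm25", "traffic_share_pct")

_BOOL_MAP = {"true": 1, "false": 0, "yes": 1, "no": 0, "1": 1, "0": 0,
             "1.0": 1, "0.0": 0}


def _coerce_bool(series: pd.Series) -> pd.Series:
    out = series.astype(str).str.strip().str.lower().map(_BOOL_MAP)
    return out


def read_records(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a CSV of source-apportionment records into the canonical schema.

    Parameters
    ----------
    path : str or Path
        CSV file with a header row, one record per row.
    dialect : dict, optional
        Mapping from canonical column name to the header used in the file.
        Omitted canonical names are assumed to appear verbatim.

    Returns
    -------
    DataFrame with the canonical columns, validated.  Rows violating hard
    invariants (non-positive concentration, latitude outside [-90, 90],
    traffic share outside (0, 100], implausible year) raise
    :class:`ValidationError` listing every offending row — they are never
    silently dropped.
    """
    dialect = dict(dialect or {})
    unknown = set(dialect) - set(REQUIRED_COLUMNS)
    if unknown:
        raise ConfigurationError(f"dialect maps unknown canonical columns: {sorted(unknown)}")
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    except pd.errors.EmptyDataError as e:
        raise DataError(f"no records in {path}") from e
    if raw.empty:
        raise DataError(f"no records in {path}")
    rename = {dialect.get(c, c): c for c in REQUIRED_COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s) in {path}: {missing}")
    df = raw.rename(columns=rename)[list(REQUIRED_COLUMNS)].copy()

    problems: list[str] = []
    for col in _NUMERIC_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & converted.isna()
        for i in df.index[bad]:
            problems.append(f"row {i}: unparseable {col} {df.loc[i, col]!r}")
        df[col] = converted
    ss = _coerce_bool(df["sea_salt_reported"])
    for i in df.index[ss.isna()]:
        problems.append(f"row {i}: unparseable sea_salt_reported {df.loc[i, 'sea_salt_reported']!r}")
    df["sea_salt_reported"] = ss

    def flag(mask: pd.Series, msg: str) -> None:
        for i in df.index[mask.fillna(False)]:
            problems.append(f"row {i}: {msg} ({df.loc[i, mask.name]})")

    flag((df["overall_pm25"] <= 0).rename("overall_pm25"), "overall_pm25 must be > 0")
    flag(df["overall_pm25"].isna().rename("overall_pm25"), "overall_pm25 missing")
    flag((~df["latitude"].between(-90, 90)).rename("latitude"), "latitude outside [-90, 90]")
    share = df["traffic_share_pct"]
    flag((share.notna() & ~((share > 0) & (share <= 100))).rename("traffic_share_pct"),
         "traffic_share_pct outside (0, 100]")
    flag((~df["pub_year"].between(1980, 2030)).rename("pub_year"), "pub_year outside 1980-2030")
    if problems:
        raise ValidationError(problems)

    df["sea_salt_reported"] = df["sea_salt_reported"].astype(int)
    df["pub_year"] = df["pub_year"].astype(int)
    return df.reset_index(drop=True)


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the urban / traffic-share inclusion rules.

    Keeps only records from urban sites (excluding industrial, rural and
    other typologies, for between-study comparability) that report the
    percentage traffic contribution.  Returns the retained records plus a
    retention log with the count removed under each rule.
    """
    site = records["site_type"].astype(str).str.strip().str.lower()
    is_urban = site == "urban"
    has_share = records["traffic_share_pct"].notna()
    kept = records[is_urban & has_share].reset_index(drop=True)
    log = {
        "n_input": int(len(records)),
        "n_removed_non_urban": int((~is_urban).sum()),
        "n_removed_no_traffic_share": int((is_urban & ~has_share).sum()),
        "n_retained": int(len(kept)),
    }
    if kept.empty:
        raise DataError("no records remain after the urban/traffic-share filter")
    return kept, log


def curate(records: pd.DataFrame, year_cut: int = 2005) -> tuple[pd.DataFrame, dict]:
    """Derive traffic-related PM2.5 and the model covariates.

    traffic_pm25 = overall_pm25 x traffic_share_pct / 100,
    ln_population = ln(population in millions), lat10 = latitude / 10,
    post2005 = 1 iff pub_year > ``year_cut`` ("published after"), and the
    four-level location category (Japan grouped with North America and
    Oceania as a high-income region with comparable concentrations).

    Records with a zero traffic share (log-transform undefined downstream)
    or with missing population/latitude (complete-case fitting) are dropped
    and itemised in the curation log.  A non-positive population is a hard
    validation error.
    """
    df = records.copy()
    if (df["population"].dropna() <= 0).any():
        bad = df.index[df["population"] <= 0].tolist()
        raise ValidationError([f"row {i}: population must be > 0" for i in bad])
    dropped: list[dict] = []

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        for i in df.index[mask]:
            dropped.append({"row": int(i), "city": str(df.loc[i, "city"]), "reason": reason})
        df = df[~mask]

    drop(df["traffic_share_pct"] == 0, "traffic_share_pct is 0 (ln undefined)")
    drop(df["population"].isna(), "population missing")
    drop(df["latitude"].isna(), "latitude missing")
    if df.empty:
        raise DataError("no records remain after curation")
    df = df.reset_index(drop=True)

    df["traffic_pm25"] = df["overall_pm25"] * df["traffic_share_pct"] / 100.0
    df["ln_population"] = np.log(df["population"] / 1e6)
    df["lat10"] = df["latitude"] / 10.0
    df["post2005"] = (df["pub_year"] > year_cut).astype(int)
    loc = df["region"].map(_REGION_TO_LOC).fillna("rest_of_world")
    # Japan is a high-income country with North-America-like concentrations;
    # grouped with North America / Oceania regardless of the region label.
    loc[df["country"].astype(str).str.strip().str.lower() == "japan"] = "NA_Oceania_Japan"
    df["loc_cat"] = loc
    log = {"n_input": int(len(records)), "n_dropped": len(dropped),
           "dropped": dropped, "n_curated": int(len(df)), "year_cut": year_cut}
    return df, log


@dataclass
class DesignMatrices:
    """Per-outcome regressor matrices and log outcomes for the joint model.

    ``y1``/``X1`` belong to the traffic equation, ``y2``/``X2`` to the
    overall equation.  Intercepts are not included in the matrices; the
    model adds them.
    """

    y1: np.ndarray
    y2: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    x1_names: list[str]
    x2_names: list[str]
    city_index: pd.Series = field(repr=False)

    @property
    def nobs(self) -> int:
        return len(self.y1)

    def __post_init__(self):
        n = len(self.y1)
        if not (len(self.y2) == self.X1.shape[0] == self.X2.shape[0] == n):
            raise ValueError("y1, y2, X1, X2 must have equal row counts")


def regressor_row(names: list[str], cov: dict) -> np.ndarray:
    """Expand one set of curated covariates into a regressor vector.

    ``cov`` holds ln_population, lat10, sea_salt_reported, post2005 and
    loc_cat; location dummies are derived from loc_cat.
    """
    vals = []
    for name in names:
        if name.startswith("loc_"):
            vals.append(1.0 if cov["loc_cat"] == name[4:] else 0.0)
        else:
            vals.append(float(cov[name]))
    return np.asarray(vals, dtype=float)


def build_design(curated: pd.DataFrame,
                 formula_cfg: dict[str, list[str]] | None = None) -> DesignMatrices:
    """Build the two regressor matrices and log-outcome vectors.

    ``formula_cfg`` maps ``"traffic"`` and ``"overall"`` to regressor name
    lists; defaults to :data:`DEFAULT_REGRESSORS`.
    """
    cfg = formula_cfg or DEFAULT_REGRESSORS
    for eq in ("traffic", "overall"):
        if eq not in cfg:
            raise ConfigurationError(f"formula config missing equation {eq!r}")
        bad = [r for r in cfg[eq] if r not in _KNOWN_REGRESSORS]
        if bad:
            raise ConfigurationError(f"unknown regressor(s) in {eq} equation: {bad}")
    cols = {name: curated[name].to_numpy(dtype=float)
            for name in ("ln_population", "lat10", "sea_salt_reported", "post2005")}
    for cat in LOCATION_CATEGORIES[:-1]:
        cols[f"loc_{cat}"] = (curated["loc_cat"] == cat).to_numpy(dtype=float)

    def matrix(names: list[str]) -> np.ndarray:
        if not names:
            return np.empty((len(curated), 0))
        return np.column_stack([cols[n] for n in names])

    return DesignMatrices(
        y1=np.log(curated["traffic_pm25"].to_numpy(dtype=float)),
        y2=np.log(curated["overall_pm25"].to_numpy(dtype=float)),
        X1=matrix(cfg["traffic"]),
        X2=matrix(cfg["overall"]),
        x1_names=list(cfg["traffic"]),
        x2_names=list(cfg["overall"]),
        city_index=curated["city"].astype(str).reset_index(drop=True),
    )


def descriptive_summary(curated: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Descriptive statistics of the curated sample.

    Returns three tables: covariate moments, regional frequencies (percent
    sums to 100) and concentration moments for overall and traffic PM2.5.
    """
    if curated.empty:
        raise DataError("cannot summarise an empty table")

    def moments(s: pd.Series) -> dict:
        x = s.to_numpy(dtype=float)
        return {"mean": x.mean(), "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                "min": x.min(), "max": x.max()}

    cov_rows = {
        "ln_population": moments(curated["ln_population"]),
        "latitude": moments(curated["latitude"]),
        "sea_salt_reported": moments(curated["sea_salt_reported"]),
        "post2005": moments(curated["post2005"]),
    }
    for cat in LOCATION_CATEGORIES[:-1]:
        cov_rows[f"loc_{cat}"] = moments((curated["loc_cat"] == cat).astype(float))
    covariates = pd.DataFrame(cov_rows).T

    counts = curated["region"].value_counts()
    regions = pd.DataFrame({"count": counts, "percent": 100.0 * counts / counts.sum()})

    conc = pd.DataFrame({
        "overall_pm25": moments(curated["overall_pm25"]),
        "traffic_pm25": moments(curated["traffic_pm25"]),
    }).T
    return {"covariates": covariates, "regions": regions, "concentrations": conc}
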