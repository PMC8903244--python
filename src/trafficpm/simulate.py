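"""Synthetic source-apportionment datasets and IER parameter draws.

The generator reads the joint meta-regression model forward: covariates are
drawn from distributions matching the urban records of the WHO source
apportionment database (log city population in millions, signed latitude,
sea-salt reporting, publication period, 12-region frequencies), the pair
(ln traffic PM2.5, ln overall PM2.5) is drawn from a bivariate normal with
known coefficients and covariance, and rows where the simulated traffic
concentration would exceed the overall concentration are redrawn so the
implied traffic share stays in (0, 100].  Every dataset ships with a truth
ledger holding the generating parameters and per-row latent means, so
parameter recovery can be scored without touching generator internals.

The packaged IER parameter laws are synthetic placeholders (NOT the GBD /
Burnett draws, which are an external input); their curve shapes are chosen
to be qualitatively realistic, in particular a diabetes-like law that is
flat above roughly 20 ug/m^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .records import REGIONS, ConfigurationError, DEFAULT_REGRESSORS, regressor_row

__all__ = [
    "GeneratorConfig",
    "simulate_dataset",
    "simulate_ier_draws",
    "make_fixture",
    "load_fixture",
    "ENDPOINTS",
    "AGE_SPECIFIC_ENDPOINTS",
    "SYNTHETIC_IER_LAWS",
    "FIXTURE_SEEDS",
]

# Covariate moments and regional sampling frequencies of the urban records
# in the source-apportionment database the generator emulates.
_COVARIATE_LAW = {
    "ln_population": {"mean": -0.13, "sd": 1.68},      # log millions
    "latitude": {"mean": 30.97, "sd": 23.61, "lo": -55.0, "hi": 70.0},
    "sea_salt_p": 0.50,
    "post2005_p": 0.742,
    "year_range_pre": (1987, 2005),
    "year_range_post": (2006, 2014),
}

_REGION_PERCENTS = {
    "Africa": 0.55,
    "Central and Eastern Europe": 1.65,
    "East Asia": 9.89,
    "Middle East": 2.75,
    "North America": 31.32,
    "Northwestern Europe": 6.59,
    "Oceania/Japan": 4.95,
    "South/Central America": 6.59,
    "Southeastern Asia": 4.95,
    "Southern Asia": 4.95,
    "Southwestern Europe": 21.43,
    "Western Europe": 4.40,
}

_REGION_COUNTRY = {
    "Africa": "Kenya",
    "Central and Eastern Europe": "Poland",
    "East Asia": "China",
    "Middle East": "Iran",
    "North America": "United States",
    "Northwestern Europe": "United Kingdom",
    "Oceania/Japan": "Australia",
    "South/Central America": "Brazil",
    "Southeastern Asia": "Thailand",
    "Southern Asia": "India",
    "Southwestern Europe": "Spain",
    "Western Europe": "Germany",
}

# True regression coefficients: intercepts and slopes on the default
# regressor sets, at realistic effect sizes for urban PM2.5 meta-regression.
_TRUE_ETA = (2.54, 3.63)
_TRUE_GAMMA1 = {
    "ln_population": 0.21, "lat10": 0.06, "sea_salt_reported": -0.29,
    "post2005": -0.36, "loc_NA_Oceania_Japan": -1.25, "loc_NW_W_Europe": -1.69,
}
_TRUE_GAMMA2 = {
    "ln_population": 0.08, "lat10": 0.13, "sea_salt_reported": -0.33,
    "loc_NA_Oceania_Japan": -1.11, "loc_NW_W_Europe": -1.49,
    "loc_rest_of_Europe": -0.41,
}


def _default_sigma(rho: float = 0.6, sd1: float = 0.5, sd2: float = 0.35) -> np.ndarray:
    return np.array([[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]])


@dataclass
class GeneratorConfig:
    """Parameters of the forward model used to simulate a dataset."""

    n_obs: int = 182
    n_cities: int = 117
    true_eta: tuple[float, float] = _TRUE_ETA
    true_gamma1: dict[str, float] = field(default_factory=lambda: dict(_TRUE_GAMMA1))
    true_gamma2: dict[str, float] = field(default_factory=lambda: dict(_TRUE_GAMMA2))
    true_sigma: np.ndarray = field(default_factory=_default_sigma)
    covariate_law: dict = field(default_factory=lambda: dict(_COVARIATE_LAW))
    region_percents: dict[str, float] = field(default_factory=lambda: dict(_REGION_PERCENTS))
    nonurban_frac: float = 0.0     # contamination for testing the urban filter
    missing_share_frac: float = 0.0  # records without a traffic share
    # The share cap (traffic <= overall) is a physical constraint of real
    # records; disable only for model-level checks that rely on the exact
    # MVN law (the resulting table may then violate record invariants).
    enforce_share_cap: bool = True
    seed: int = 0

    def validate(self) -> None:
        sig = np.asarray(self.true_sigma, dtype=float)
        if sig.shape != (2, 2) or not np.allclose(sig, sig.T):
            raise ConfigurationError("true_sigma must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(sig).min() <= 0:
            raise ConfigurationError("true_sigma must be positive definite")
        if self.n_cities > self.n_obs:
            raise ConfigurationError("n_cities cannot exceed n_obs")
        missing = set(self.region_percents) - set(REGIONS)
        if missing:
            raise ConfigurationError(f"unknown regions: {sorted(missing)}")


def _loc_cat(region: str, country: str) -> str:
    from .records import _REGION_TO_LOC  # single source of truth

    if country.strip().lower() == "japan":
        return "NA_Oceania_Japan"
    return _REGION_TO_LOC.get(region, "rest_of_world")


def simulate_dataset(cfg: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a source-record table plus its truth ledger.

    Returns a DataFrame in the canonical source dialect (round-trippable
    through :func:`trafficpm.records.read_records`) and a JSON-serialisable
    ledger with the true parameters, the per-row latent means and the
    number of share-cap rejections.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_cov, rng_out, rng_misc = (np.random.default_rng(s) for s in ss.spawn(3))
    law = cfg.covariate_law
    regions = list(cfg.region_percents)
    probs = np.array([cfg.region_percents[r] for r in regions], dtype=float)
    probs = probs / probs.sum()

    # City-level attributes; every city gets at least one observation.
    n_c = cfg.n_cities
    city_region = rng_cov.choice(regions, size=n_c, p=probs)
    city_country = np.array([_REGION_COUNTRY[r] for r in city_region], dtype=object)
    # a slice of the Oceania/Japan cities are Japanese
    jp = (city_region == "Oceania/Japan") & (rng_cov.random(n_c) < 0.5)
    city_country[jp] = "Japan"
    city_lnpop = rng_cov.normal(law["ln_population"]["mean"], law["ln_population"]["sd"], n_c)
    lat = law["latitude"]
    city_lat = rng_cov.normal(lat["mean"], lat["sd"], n_c)
    while True:  # truncate to the plausible urban band
        out = (city_lat < lat["lo"]) | (city_lat > lat["hi"])
        if not out.any():
            break
        city_lat[out] = rng_cov.normal(lat["mean"], lat["sd"], out.sum())
    city_lon = rng_cov.uniform(-180, 180, n_c)

    city_of = np.concatenate([np.arange(n_c),
                              rng_cov.integers(0, n_c, cfg.n_obs - n_c)])
    rng_cov.shuffle(city_of)

    n = cfg.n_obs
    post = rng_cov.random(n) < law["post2005_p"]
    lo_pre, hi_pre = law["year_range_pre"]
    lo_post, hi_post = law["year_range_post"]
    pub_year = np.where(post,
                        rng_cov.integers(lo_post, hi_post + 1, n),
                        rng_cov.integers(lo_pre, hi_pre + 1, n))
    sea_salt = (rng_cov.random(n) < law["sea_salt_p"]).astype(int)
    method = rng_cov.choice(["PMF", "CMB", "PCA"], size=n, p=[0.6, 0.3, 0.1])

    rows = []
    for i in range(n):
        c = city_of[i]
        rows.append({
            "region": city_region[c], "country": str(city_country[c]),
            "ln_population": city_lnpop[c], "lat10": city_lat[c] / 10.0,
            "sea_salt_reported": sea_salt[i], "post2005": int(post[i]),
            "loc_cat": _loc_cat(city_region[c], str(city_country[c])),
        })
    X1 = np.array([regressor_row(DEFAULT_REGRESSORS["traffic"], r) for r in rows])
    X2 = np.array([regressor_row(DEFAULT_REGRESSORS["overall"], r) for r in rows])
    g1 = np.array([cfg.true_gamma1[k] for k in DEFAULT_REGRESSORS["traffic"]])
    g2 = np.array([cfg.true_gamma2[k] for k in DEFAULT_REGRESSORS["overall"]])
    mu1 = cfg.true_eta[0] + X1 @ g1
    mu2 = cfg.true_eta[1] + X2 @ g2

    chol = np.linalg.cholesky(np.asarray(cfg.true_sigma, dtype=float))
    y = np.column_stack([mu1, mu2]) + rng_out.standard_normal((n, 2)) @ chol.T
    # share cap: redraw any row whose traffic would exceed its overall
    n_rejected = 0
    for _ in range(1000):
        over = (y[:, 0] > y[:, 1]) if cfg.enforce_share_cap else np.zeros(n, bool)
        if not over.any():
            break
        n_rejected += int(over.sum())
        y[over] = (np.column_stack([mu1[over], mu2[over]])
                   + rng_out.standard_normal((over.sum(), 2)) @ chol.T)
    else:
        raise ConfigurationError("share-cap rejection did not terminate; "
                                 "true_sigma/coefficients imply shares above 100%")

    overall = np.exp(y[:, 1])
    share = 100.0 * np.exp(y[:, 0] - y[:, 1])

    site_type = np.full(n, "urban", dtype=object)
    if cfg.nonurban_frac > 0:
        k = rng_misc.random(n) < cfg.nonurban_frac
        site_type[k] = rng_misc.choice(["industrial", "rural"], size=int(k.sum()))
    share_out = share.astype(object)
    if cfg.missing_share_frac > 0:
        share_out[rng_misc.random(n) < cfg.missing_share_frac] = np.nan

    df = pd.DataFrame({
        "study_id": [f"S{1 + i // 2:03d}" for i in range(n)],
        "city": [f"city_{city_of[i]:03d}" for i in range(n)],
        "country": [r["country"] for r in rows],
        "region": [r["region"] for r in rows],
        "pub_year": pub_year,
        "population": np.round(np.exp(city_lnpop[city_of]) * 1e6, 0).astype(np.int64),
        "latitude": np.round(city_lat[city_of], 4),
        "longitude": np.round(city_lon[city_of], 4),
        "site_type": site_type,
        "overall_pm25": np.round(overall, 4),
        "traffic_share_pct": [np.round(v, 4) if np.isfinite(float(v)) else "" for v in share_out],
        "sea_salt_reported": sea_salt,
        "method": method,
    })
    truth = {
        "seed": cfg.seed,
        "n_obs": n,
        "n_cities": n_c,
        "eta": list(cfg.true_eta),
        "gamma1": {k: cfg.true_gamma1[k] for k in DEFAULT_REGRESSORS["traffic"]},
        "gamma2": {k: cfg.true_gamma2[k] for k in DEFAULT_REGRESSORS["overall"]},
        "sigma": np.asarray(cfg.true_sigma, dtype=float).tolist(),
        "rho": float(cfg.true_sigma[0][1]
                     / np.sqrt(cfg.true_sigma[0][0] * cfg.true_sigma[1][1])),
        "mu1": mu1.tolist(),
        "mu2": mu2.tolist(),
        "city": df["city"].tolist(),
        "n_share_cap_rejections": n_rejected,
        "regressors": dict(DEFAULT_REGRESSORS),
    }
    return df, truth


# ---------------------------------------------------------------------------
# IER parameter draws

ENDPOINTS = ("IHD", "stroke", "COPD", "lung_cancer", "LRI", "diabetes")
AGE_SPECIFIC_ENDPOINTS = ("IHD", "stroke")

#: Synthetic central values and lognormal spreads for (theta, omega, delta).
#: NOT GBD/Burnett values — invented placeholders whose curve shapes are
#: qualitatively realistic (diabetes saturates by ~20 ug/m^3).
SYNTHETIC_IER_LAWS = {
    "IHD": {"theta": 1.4, "omega": 0.030, "delta": 0.70, "cv": 0.10},
    "stroke": {"theta": 1.2, "omega": 0.030, "delta": 0.70, "cv": 0.10},
    "COPD": {"theta": 0.6, "omega": 0.025, "delta": 1.10, "cv": 0.10},
    "lung_cancer": {"theta": 0.7, "omega": 0.020, "delta": 1.10, "cv": 0.10},
    "LRI": {"theta": 1.8, "omega": 0.040, "delta": 0.80, "cv": 0.10},
    "diabetes": {"theta": 0.45, "omega": 0.350, "delta": 1.00, "cv": 0.10},
}

X_BOUNDS = (2.4, 5.9)  # uncertain counterfactual threshold, ug/m^3


def simulate_ier_draws(endpoint: str, n_draws: int = 1000,
                       law: dict | None = None, seed: int = 0,
                       age_group: str | None = None) -> pd.DataFrame:
    """Draw a synthetic IER parameter table for one disease endpoint.

    Each draw is a (theta, omega, delta, x) quadruple: theta, omega, delta
    lognormal around the law's central values with coefficient of variation
    ``cv`` (``cv=0`` gives point masses), and x uniform on [2.4, 5.9].
    """
    if endpoint not in ENDPOINTS:
        raise ConfigurationError(f"unknown endpoint {endpoint!r}; one of {ENDPOINTS}")
    law = dict(law or SYNTHETIC_IER_LAWS[endpoint])
    if min(law["theta"], law["omega"], law["delta"]) <= 0:
        raise ConfigurationError("theta, omega, delta central values must be > 0")
    if age_group is None and endpoint in AGE_SPECIFIC_ENDPOINTS:
        age_group = "55-60"
    rng = np.random.default_rng(np.random.SeedSequence((seed, hash(endpoint) % 2**31)))
    cv = float(law.get("cv", 0.0))
    sd = np.sqrt(np.log1p(cv**2))

    def ln_draw(center: float) -> np.ndarray:
        if sd == 0:
            return np.full(n_draws, center)
        return center * np.exp(rng.normal(-0.5 * sd**2, sd, n_draws))

    return pd.DataFrame({
        "endpoint": endpoint,
        "age_group": age_group or "",
        "draw": np.arange(n_draws),
        "theta": ln_draw(law["theta"]),
        "omega": ln_draw(law["omega"]),
        "delta": ln_draw(law["delta"]),
        "x": rng.uniform(*X_BOUNDS, n_draws),
    })


def simulate_all_ier_draws(n_draws: int = 1000, seed: int = 0) -> pd.DataFrame:
    """All six endpoints stacked into one draw table."""
    return pd.concat([simulate_ier_draws(e, n_draws=n_draws, seed=seed)
                      for e in ENDPOINTS], ignore_index=True)


# ---------------------------------------------------------------------------
# Fixtures

FIXTURE_SEEDS = {"small": 20220308, "paper_scale": 20220309}
_FIXTURE_SIZES = {"small": (50, 30), "paper_scale": (182, 117)}


def make_fixture(name: str, outdir) -> dict[str, Path]:
    """Write a named deterministic fixture dataset to ``outdir``.

    ``small`` is a 50-row / 30-city dataset for fast end-to-end runs;
    ``paper_scale`` is 182 rows over 117 cities.  Each fixture comprises a
    records CSV, a truth-ledger JSON and a 1000-draw synthetic IER table.
    Regeneration with the packaged seeds is byte-identical.
    """
    if name not in FIXTURE_SEEDS:
        raise ConfigurationError(f"unknown fixture {name!r}; one of {sorted(FIXTURE_SEEDS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_obs, n_cities = _FIXTURE_SIZES[name]
    cfg = GeneratorConfig(n_obs=n_obs, n_cities=n_cities, seed=FIXTURE_SEEDS[name])
    records, truth = simulate_dataset(cfg)
    ier = simulate_all_ier_draws(n_draws=1000, seed=FIXTURE_SEEDS[name])
    paths = {
        "records": outdir / f"{name}_records.csv",
        "truth": outdir / f"{name}_truth.json",
        "ier": outdir / f"{name}_ier_draws.csv",
    }
    records.to_csv(paths["records"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    ier.to_csv(paths["ier"], index=False, float_format="%.8g")
    return paths


def load_fixture(name: str) -> tuple[pd.DataFrame, dict]:
    """Load a packaged fixture's records and truth ledger.

    The packaged copies were written by :func:`make_fixture` with the seeds
    in :data:`FIXTURE_SEEDS`; regenerating reproduces them exactly.
    """
    from importlib.resources import files

    from .records import read_records

    data = files("trafficpm") / "data"
    rec_path = data / f"{name}_records.csv"
    if not rec_path.is_file():
        raise ConfigurationError(f"no packaged fixture {name!r}")
    records = read_records(str(rec_path))
    truth = json.loads((data / f"{name}_truth.json").read_text())
    return records, truth
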