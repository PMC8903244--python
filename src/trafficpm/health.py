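"""IER relative risks and population attributable fractions.

The integrated exposure-response (IER) function gives the relative risk of
mortality from a disease endpoint at an annual-mean PM2.5 concentration:

    RR(pm) = 1 + theta * (1 - exp(-omega * z**delta)),   z = max(0, pm - x)

where theta, omega, delta are endpoint-specific parameters and x is the
uncertain counterfactual concentration below which no excess mortality is
assumed (uniform on [2.4, 5.9] ug/m^3).  Parameter uncertainty is carried
by a table of draws (1000 by default); the packaged draws are synthetic
stand-ins, and externally supplied GBD/Burnett draw files in the same CSV
layout are accepted verbatim.

The traffic-removal counterfactual compares the posterior-mean overall
concentration (baseline) with the baseline minus the posterior-mean
traffic concentration.  The population attributable fraction for one
parameter draw is PAF = 1 - RR(pm_cf) / RR(pm_baseline); the reported
value is the mean over draws, as a percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prediction import CityConcentrationDraws

__all__ = [
    "CounterfactualPair",
    "PAFResult",
    "relative_risk",
    "counterfactual_pair",
    "paf",
    "city_paf_mc",
    "benefit_curve",
    "plot_benefit_curve",
    "read_ier_draws",
]

_IER_COLUMNS = ("endpoint", "draw", "theta", "omega", "delta", "x")


def relative_risk(pm, theta, omega, delta, x):
    """IER relative risk; broadcasts over numpy array arguments.

    Equals 1 exactly whenever ``pm`` is at or below the counterfactual
    threshold ``x`` and approaches 1 + theta as ``pm`` grows.
    """
    pm = np.asarray(pm, dtype=float)
    if np.any(pm < 0):
        raise ValueError("PM2.5 concentration must be non-negative")
    z = np.maximum(0.0, pm - np.asarray(x, dtype=float))
    rr = 1.0 + np.asarray(theta) * (-np.expm1(-np.asarray(omega) * z ** np.asarray(delta)))
    return rr if rr.shape else float(rr)


@dataclass
class CounterfactualPair:
    """Baseline and traffic-removed PM2.5 for one city (ug/m^3)."""

    pm_baseline: float
    pm_cf: float
    city: str = ""
    floored: bool = False

    def __post_init__(self):
        if self.pm_baseline <= 0:
            raise ValueError("pm_baseline must be > 0")
        if not (0 <= self.pm_cf <= self.pm_baseline):
            raise ValueError("need 0 <= pm_cf <= pm_baseline")


def counterfactual_pair(city_draws: CityConcentrationDraws) -> CounterfactualPair:
    """Pair the posterior-mean overall with overall minus mean traffic.

    If the mean traffic concentration exceeds the mean overall (possible
    only in pathological fits), the counterfactual is floored at 0 with a
    warning.
    """
    if city_draws.overall.size == 0:
        raise ValueError("no draws")
    pm_b = float(city_draws.overall.mean())
    pm_cf = pm_b - float(city_draws.traffic.mean())
    floored = pm_cf < 0
    if floored:
        warnings.warn(f"{city_draws.city}: mean traffic exceeds mean overall; "
                      "counterfactual floored at 0", stacklevel=2)
        pm_cf = 0.0
    return CounterfactualPair(pm_baseline=pm_b, pm_cf=pm_cf,
                              city=city_draws.city, floored=floored)


def paf(pair: CounterfactualPair, draw) -> float:
    """Population attributable fraction for one IER parameter draw.

    ``draw`` is any mapping (e.g. a DataFrame row) with theta, omega,
    delta and x.
    """
    rr_b = relative_risk(pair.pm_baseline, draw["theta"], draw["omega"],
                         draw["delta"], draw["x"])
    rr_cf = relative_risk(pair.pm_cf, draw["theta"], draw["omega"],
                          draw["delta"], draw["x"])
    return 1.0 - rr_cf / rr_b


@dataclass
class PAFResult:
    """Monte-Carlo mean PAF (percent) for one city and endpoint."""

    city: str
    endpoint: str
    age_group: str
    mean_paf_pct: float
    n_draws: int
    paf_draws: np.ndarray | None = None


def city_paf_mc(pair: CounterfactualPair, draws: pd.DataFrame,
                keep_draws: bool = False) -> PAFResult:
    """Average the per-draw PAF over an IER parameter draw table.

    The table must contain a single endpoint (and a single age group for
    the age-specific endpoints).
    """
    missing = [c for c in _IER_COLUMNS if c not in draws.columns]
    if missing:
        raise ValueError(f"IER draw table missing column(s): {missing}")
    if len(draws) == 0:
        raise ValueError("empty IER draw table")
    endpoints = draws["endpoint"].unique()
    if len(endpoints) != 1:
        raise ValueError(f"one endpoint per call; got {sorted(endpoints)}")
    ages = draws["age_group"].fillna("").unique() if "age_group" in draws else [""]
    if len(ages) != 1:
        raise ValueError(f"one age group per call; got {sorted(ages)}")
    rr_b = relative_risk(pair.pm_baseline, draws["theta"].to_numpy(),
                         draws["omega"].to_numpy(), draws["delta"].to_numpy(),
                         draws["x"].to_numpy())
    rr_cf = relative_risk(pair.pm_cf, draws["theta"].to_numpy(),
                          draws["omega"].to_numpy(), draws["delta"].to_numpy(),
                          draws["x"].to_numpy())
    vals = 1.0 - rr_cf / rr_b
    return PAFResult(city=pair.city, endpoint=str(endpoints[0]),
                     age_group=str(ages[0]), mean_paf_pct=float(100.0 * vals.mean()),
                     n_draws=int(len(vals)),
                     paf_draws=vals if keep_draws else None)


def benefit_curve(cities: list[CounterfactualPair],
                  draws_by_endpoint: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Percent mortality reduction per city and endpoint.

    One row per city x endpoint, carrying the baseline concentration so
    the rise-then-flatten (and, for a saturating IER, declining) patterns
    can be plotted against pollution level.
    """
    if not cities or not draws_by_endpoint:
        raise ValueError("need at least one city and one endpoint")
    rows = []
    for pair in cities:
        for endpoint, draws in draws_by_endpoint.items():
            res = city_paf_mc(pair, draws)
            rows.append({"city": pair.city, "baseline_pm25": pair.pm_baseline,
                         "cf_pm25": pair.pm_cf, "endpoint": endpoint,
                         "age_group": res.age_group,
                         "pct_reduction": res.mean_paf_pct})
    out = pd.DataFrame(rows).sort_values(["endpoint", "baseline_pm25"], kind="stable")
    return out.reset_index(drop=True)


def read_ier_draws(path) -> dict[str, pd.DataFrame]:
    """Read an IER draw CSV and split it by endpoint."""
    df = pd.read_csv(path)
    missing = [c for c in _IER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"IER draw file {path} missing column(s): {missing}")
    if "age_group" not in df.columns:
        df["age_group"] = ""
    df["age_group"] = df["age_group"].fillna("")
    return {str(e): g.reset_index(drop=True) for e, g in df.groupby("endpoint")}


def plot_benefit_curve(table: pd.DataFrame, path=None):
    """Panel per endpoint: percent reduction vs baseline concentration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    endpoints = table["endpoint"].unique()
    ncol = min(len(endpoints), 3)
    nrow = -(-len(endpoints) // ncol)
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, endpoint in zip(axes.ravel(), endpoints):
        sub = table[table["endpoint"] == endpoint]
        ax.scatter(sub["baseline_pm25"], sub["pct_reduction"], s=12, alpha=0.7)
        ax.set_title(endpoint)
        ax.set_xlabel("baseline PM$_{2.5}$ ($\\mu$g/m$^3$)")
        ax.set_ylabel("% reduction in mortality")
    for ax in axes.ravel()[len(endpoints):]:
        ax.set_visible(False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
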