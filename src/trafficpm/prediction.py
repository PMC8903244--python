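"""Per-city posterior concentrations and guideline exceedance probabilities.

For a city with covariate vector X_c, each posterior draw (eta, gamma,
Sigma) yields expected log concentrations mu_k = eta_k + gamma_k . X_c for
the traffic and overall outcomes.  On the natural scale the "median"
transform uses exp(mu_k) (the median of the implied lognormal) and
"lognormal_mean" uses exp(mu_k + Sigma_kk / 2).  Non-traffic PM2.5 is the
per-draw difference overall - traffic; the exceedance probability is the
fraction of draws at or above a guideline threshold (default 5 ug/m^3,
the WHO annual guideline).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ConfigurationError, regressor_row
from .model import PosteriorDraws

__all__ = [
    "CityProfile",
    "CityConcentrationDraws",
    "profiles_from_curated",
    "predict_city",
    "exceedance_probability",
    "exceedance_curve",
    "plot_exceedance_curve",
]

TRANSFORMS = ("median", "lognormal_mean")


@dataclass
class CityProfile:
    """Covariates at which per-city concentrations are predicted."""

    city: str
    covariates: dict = field(default_factory=dict)

    _REQUIRED = ("ln_population", "lat10", "sea_salt_reported", "post2005", "loc_cat")

    def vector(self, names: list[str]) -> np.ndarray:
        # only require the fields the fitted design actually uses
        needed = {"loc_cat" if n.startswith("loc_") else n for n in names}
        missing = sorted(needed - set(self.covariates))
        if missing:
            raise ConfigurationError(
                f"profile for {self.city!r} is missing covariate(s): {missing}")
        return regressor_row(names, self.covariates)


@dataclass
class CityConcentrationDraws:
    """Per-draw expected concentrations for one city, natural scale."""

    city: str
    traffic: np.ndarray
    overall: np.ndarray
    transform: str

    @property
    def nontraffic(self) -> np.ndarray:
        return self.overall - self.traffic

    @property
    def n_negative_nontraffic(self) -> int:
        """Draws where traffic exceeded overall (kept, not clamped)."""
        return int((self.nontraffic < 0).sum())

    def summary(self, level: float = 0.95) -> dict:
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        out = {"city": self.city}
        for name, arr in (("traffic", self.traffic), ("overall", self.overall),
                          ("nontraffic", self.nontraffic)):
            qlo, qhi = np.percentile(arr, [lo, hi])
            out.update({f"{name}_mean": float(arr.mean()),
                        f"{name}_ci_low": float(qlo),
                        f"{name}_ci_high": float(qhi)})
        return out


def profiles_from_curated(curated: pd.DataFrame,
                          aggregation: str = "most_recent") -> list[CityProfile]:
    """One profile per city from its curated records.

    ``most_recent`` takes the covariates of the city's latest record
    (publication year, ties broken by row order); ``mean_of_records``
    averages the numeric covariates and takes the modal location category.
    """
    if aggregation not in ("most_recent", "mean_of_records"):
        raise ConfigurationError(f"unknown aggregation {aggregation!r}")
    profiles = []
    for city, grp in curated.groupby("city", sort=True):
        if aggregation == "most_recent":
            row = grp.loc[grp["pub_year"].idxmax()]
            cov = {k: row[k] for k in CityProfile._REQUIRED}
        else:
            cov = {k: float(grp[k].mean())
                   for k in ("ln_population", "lat10", "sea_salt_reported", "post2005")}
            cov["loc_cat"] = grp["loc_cat"].mode().iloc[0]
        profiles.append(CityProfile(city=str(city), covariates=cov))
    return profiles


def predict_city(draws: PosteriorDraws, profile: CityProfile,
                 transform: str = "median") -> CityConcentrationDraws:
    """Posterior draws of the city's expected traffic and overall PM2.5."""
    if transform not in TRANSFORMS:
        raise ConfigurationError(f"unknown transform {transform!r}; one of {TRANSFORMS}")
    x1 = profile.vector(draws.x1_names)
    x2 = profile.vector(draws.x2_names)
    mu1 = draws.eta[:, 0] + draws.gamma1 @ x1
    mu2 = draws.eta[:, 1] + draws.gamma2 @ x2
    if transform == "lognormal_mean":
        mu1 = mu1 + 0.5 * draws.sigma[:, 0, 0]
        mu2 = mu2 + 0.5 * draws.sigma[:, 1, 1]
    return CityConcentrationDraws(city=profile.city, traffic=np.exp(mu1),
                                  overall=np.exp(mu2), transform=transform)


def exceedance_probability(city_draws: CityConcentrationDraws,
                           threshold: float = 5.0) -> float:
    """Posterior probability that non-traffic PM2.5 is >= the threshold.

    Indicator convention: a draw exactly at the threshold counts as
    exceeding.  Draws with negative non-traffic concentration (traffic
    above overall) count as below the threshold.
    """
    if threshold <= 0:
        raise ConfigurationError("threshold must be positive")
    nt = city_draws.nontraffic
    if nt.size == 0:
        raise ValueError("no draws")
    return float((nt >= threshold).mean())


def exceedance_curve(draws: PosteriorDraws, profiles: list[CityProfile],
                     threshold: float = 5.0,
                     transform: str = "median") -> pd.DataFrame:
    """Per-city exceedance table, sorted by posterior-mean overall PM2.5."""
    if not profiles:
        raise ValueError("need at least one city profile")
    rows = []
    for prof in profiles:
        cd = predict_city(draws, prof, transform=transform)
        row = cd.summary()
        row["exceedance_probability"] = exceedance_probability(cd, threshold)
        row["n_negative_nontraffic"] = cd.n_negative_nontraffic
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("overall_mean", kind="stable")
    return out.reset_index(drop=True)


def plot_exceedance_curve(table: pd.DataFrame, threshold: float = 5.0, path=None):
    """Scatter of exceedance probability against mean overall PM2.5."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(table["overall_mean"], table["exceedance_probability"], s=14, alpha=0.7)
    ax.set_xlabel("posterior mean overall PM$_{2.5}$ ($\\mu$g/m$^3$)")
    ax.set_ylabel(f"P(non-traffic PM$_{{2.5}}$ $\\geq$ {threshold:g} $\\mu$g/m$^3$)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
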