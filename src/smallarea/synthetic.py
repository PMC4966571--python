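"""Synthetic multi-city mortality studies with known ground truth.

The generator mirrors the generative structure the hierarchical models
assume: per city ``j`` a 4-vector of regression coefficients
``b_kj ~ Normal(beta_k, sigma_bk^2)`` (intercept, deprivation slope, period
effect, deprivation x period interaction), per city-period an intrinsic-CAR
spatial field ``S`` and an exchangeable heterogeneous field ``H``, a latent
standard-normal deprivation score ``X`` per tract with five noisy indicator
variables loading on it, and Poisson death counts
``O ~ Poisson(pop * ref_rate * theta)`` with
``log theta = b1 + b2*X + b3*T + b4*X*T + S + H``.

Everything is driven by one :class:`numpy.random.Generator`, so a fixed
seed reproduces the study bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import connected_components, laplacian, make_city_lattice, node_order
from .reference import age_group_labels, default_reference, reference_rate_lookup

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticStudy",
    "sample_icar_field",
    "simulate_study",
    "lattice_shape",
]

#: standardized loading of each indicator on the latent deprivation score
INDICATOR_NOISE_SD = 0.3
#: location (percent) and scale of each synthetic census indicator
_INDICATOR_LOC = {
    "unemployment_pct": 15.0,
    "manual_workers_pct": 30.0,
    "temporary_workers_pct": 25.0,
    "low_education_pct": 20.0,
    "low_education_young_pct": 18.0,
}
_INDICATOR_SCALE = {
    "unemployment_pct": 6.0,
    "manual_workers_pct": 10.0,
    "temporary_workers_pct": 8.0,
    "low_education_pct": 8.0,
    "low_education_young_pct": 7.0,
}
INDICATOR_COLUMNS = list(_INDICATOR_LOC)

#: SD of the log-normal tract-size multiplier (tracts differ in population)
_TRACT_SIZE_LOG_SD = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and sizes for one synthetic study.

    ``beta_true`` are the population-level coefficients on the log-risk
    scale (intercept, deprivation slope, period effect, interaction);
    ``sigma_b_true`` the between-city SDs of the per-city coefficients;
    ``sigma_s_true`` / ``sigma_h_true`` the spatial and heterogeneous
    effect SDs shared by every city-period; ``base_population`` the average
    person-years per tract-age stratum.
    """

    n_cities: int = 8
    tracts_per_city: int = 100
    n_age_groups: int = 18
    periods: int = 2
    beta_true: tuple[float, float, float, float] = (0.0, 0.12, -0.15, -0.02)
    sigma_b_true: tuple[float, float, float, float] = (0.05, 0.03, 0.03, 0.01)
    sigma_s_true: float = 0.2
    sigma_h_true: float = 0.05
    base_population: float = 250.0
    sexes: tuple[str, ...] = ("men", "women")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cities < 1:
            raise ValueError("n_cities must be >= 1")
        if self.tracts_per_city < 4:
            raise ValueError("tracts_per_city must be >= 4")
        if self.n_age_groups < 1:
            raise ValueError("n_age_groups must be >= 1")
        if self.periods != 2:
            raise ValueError("the study design has exactly 2 periods")
        if len(self.beta_true) != 4 or len(self.sigma_b_true) != 4:
            raise ValueError("beta_true and sigma_b_true must have length 4")
        if min(self.sigma_b_true) < 0 or self.sigma_s_true < 0 or self.sigma_h_true < 0:
            raise ValueError("variance parameters must be >= 0")
        if self.base_population <= 0:
            raise ValueError("base_population must be > 0")
        if not self.sexes:
            raise ValueError("need at least one sex")


@dataclass
class GroundTruth:
    """Realized latent quantities of one simulated study.

    ``b_city`` has one row per city (columns b1..b4); ``table`` one row per
    (city, tract, period) with the latent deprivation score ``x``, spatial
    effect ``s``, heterogeneous effect ``h`` and relative risk ``theta``.
    """

    b_city: pd.DataFrame
    table: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)


@dataclass
class SyntheticStudy:
    """Container bundling every output of :func:`simulate_study`."""

    counts: pd.DataFrame
    indicators: pd.DataFrame
    graphs: dict[str, nx.Graph]
    truth: GroundTruth
    reference: pd.DataFrame


def lattice_shape(n_tracts: int) -> tuple[int, int]:
    """Most nearly square ``rows x cols`` factorization of ``n_tracts``."""
    if n_tracts < 1:
        raise ValueError("n_tracts must be >= 1")
    rows = int(np.floor(np.sqrt(n_tracts)))
    while rows > 1 and n_tracts % rows:
        rows -= 1
    return rows, n_tracts // rows


def sample_icar_field(
    graph: nx.Graph, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one intrinsic-CAR field subject to a sum-to-zero constraint.

    The improper ICAR density ``p(s) prop exp(-s' L s / (2 sigma^2))`` (L
    the graph Laplacian) is made proper by restricting it to the orthogonal
    complement of the constant vector: the draw is built from the non-null
    Laplacian eigenvectors with variances ``sigma^2 / lambda_i``, which
    gives covariance ``sigma^2 * pinv(L)`` and an exactly zero-sum field.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    n = graph.number_of_nodes()
    if len(connected_components(graph)) != 1:
        raise ValueError(
            "graph is disconnected: sample each connected component separately "
            "with its own sum-to-zero constraint"
        )
    if sigma == 0 or n == 1:
        return np.zeros(n)
    evals, evecs = np.linalg.eigh(laplacian(graph))
    keep = evals > 1e-10 * evals[-1]
    z = rng.standard_normal(keep.sum())
    s = evecs[:, keep] @ (sigma * z / np.sqrt(evals[keep]))
    return s - s.mean()  # exact zero sum (removes float residue)


def _city_names(n_cities: int) -> list[str]:
    return [f"city{j + 1:02d}" for j in range(n_cities)]


def _simulate_indicators(x: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Five census-style indicators loading equally on the latent score.

    Each indicator is ``x`` plus independent noise (SD 0.3 on the latent
    scale), rescaled to a percentage with its own location/scale and
    clipped to [0, 100].  Equal loadings mean the first principal component
    of the standardized indicators recovers near-equal weights.
    """
    cols = {}
    norm = np.sqrt(1.0 + INDICATOR_NOISE_SD**2)
    for name in INDICATOR_COLUMNS:
        z = (x + rng.normal(0.0, INDICATOR_NOISE_SD, size=x.size)) / norm
        cols[name] = np.clip(_INDICATOR_LOC[name] + _INDICATOR_SCALE[name] * z, 0.0, 100.0)
    return pd.DataFrame(cols)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate one full multi-city study (counts, indicators, graphs, truth)."""
    rng = np.random.default_rng(config.seed)
    cities = _city_names(config.n_cities)
    labels = age_group_labels(config.n_age_groups)
    reference = default_reference(config.n_age_groups, config.sexes)

    beta = np.asarray(config.beta_true, float)
    sigma_b = np.asarray(config.sigma_b_true, float)

    n_rows, n_cols = lattice_shape(config.tracts_per_city)
    a = np.arange(config.n_age_groups, dtype=float)
    age_profile = 0.93**a
    age_profile = age_profile / age_profile.mean()  # mean 1: avg stratum = base_population

    rates = {sex: reference_rate_lookup(reference, sex).to_numpy() for sex in config.sexes}

    graphs: dict[str, nx.Graph] = {}
    count_frames, indicator_frames, truth_frames, b_rows = [], [], [], []

    for city in cities:
        g = make_city_lattice(n_rows, n_cols)
        graphs[city] = g
        n = g.number_of_nodes()
        tracts = np.asarray(node_order(g))

        b_j = beta + sigma_b * rng.standard_normal(4)
        b_rows.append({"city": city, "b1": b_j[0], "b2": b_j[1], "b3": b_j[2], "b4": b_j[3]})

        x = rng.standard_normal(n)
        ind = _simulate_indicators(x, rng)
        ind.insert(0, "tract", tracts)
        ind.insert(0, "city", city)
        indicator_frames.append(ind)

        size_mult = np.exp(rng.normal(0.0, _TRACT_SIZE_LOG_SD, size=n))
        pop = np.rint(
            config.base_population * size_mult[:, None] * age_profile[None, :]
        ).astype(int)  # (tract, age)

        for t in range(config.periods):
            s_field = sample_icar_field(g, config.sigma_s_true, rng)
            h_field = (
                rng.normal(0.0, config.sigma_h_true, size=n)
                if config.sigma_h_true > 0
                else np.zeros(n)
            )
            t2 = float(t)  # period indicator: 0 first period, 1 second
            log_theta = b_j[0] + b_j[1] * x + b_j[2] * t2 + b_j[3] * x * t2 + s_field + h_field
            theta = np.exp(log_theta)
            truth_frames.append(
                pd.DataFrame(
                    {
                        "city": city,
                        "tract": tracts,
                        "period": t + 1,
                        "x": x,
                        "s": s_field,
                        "h": h_field,
                        "theta": theta,
                    }
                )
            )
            for sex in config.sexes:
                mean = pop * rates[sex][None, :] * theta[:, None]
                deaths = rng.poisson(mean)
                deaths[pop == 0] = 0
                count_frames.append(
                    pd.DataFrame(
                        {
                            "city": city,
                            "tract": np.repeat(tracts, config.n_age_groups),
                            "sex": sex,
                            "age_group": np.tile(labels, n),
                            "period": t + 1,
                            "deaths": deaths.ravel(),
                            "population": pop.ravel().astype(float),
                        }
                    )
                )

    truth = GroundTruth(
        b_city=pd.DataFrame(b_rows),
        table=pd.concat(truth_frames, ignore_index=True),
        config=config,
    )
    return SyntheticStudy(
        counts=pd.concat(count_frames, ignore_index=True),
        indicators=pd.concat(indicator_frames, ignore_index=True),
        graphs=graphs,
        truth=truth,
        reference=reference,
    )
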