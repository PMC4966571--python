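"""The three Bayesian hierarchical spatial models and their summaries.

* **Model 1** (disease mapping): per city-period BYM smoothing,
  ``log(theta) = b1 + S + H`` with expected counts standardized against the
  city's own first-period rates; yields smoothed SMRs
  ``exp(b1 + S + H) * 100``.
* **Model 2** (ecological regression): per city,
  ``log(theta) = b1 + b2*X + b3*T2 + b4*X*T2 + S + H`` with flat priors on
  the per-city coefficients and nationally standardized expected counts.
  ``exp(b2)`` is the first-period relative risk per unit deprivation,
  ``exp(b2 + b4)`` the second-period one, and ``Pr(b4 > 0)`` the
  probability that the association grew.
* **Model 3** (random coefficients): Model 2 with the per-city
  coefficients partially pooled, ``b_kj ~ Normal(beta_k, sigma_bk^2)``,
  which adds the global relative risks ``exp(beta2)`` and
  ``exp(beta2 + beta4)`` and the global trend probability ``Pr(beta4 > 0)``.

Every SD carries a Uniform(0, ``prior_sd_upper``) prior; flat priors are
implemented as genuinely improper flats.  Point estimates are posterior
means; all intervals are equal-tailed 2.5/97.5 posterior percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from . import diagnostics as diag
from .graphs import connected_components, laplacian, node_order
from .mcmc import BlockData, GibbsResult, run_sampler
from .standardization import expected_counts, validate_counts

__all__ = [
    "ModelSpec",
    "ModelFit",
    "RRSummary",
    "PR_BIN_LABELS",
    "icar_log_kernel",
    "categorize_pr",
    "fit_model1",
    "fit_model2",
    "fit_model3",
    "ssmr",
    "rr_and_trend",
]

PR_BIN_LABELS = [
    "[0.000, 0.025)",
    "[0.025, 0.050)",
    "[0.050, 0.950)",
    "[0.950, 0.975)",
    "[0.975, 1.000]",
]
_PR_BIN_EDGES = np.array([0.025, 0.050, 0.950, 0.975])


@dataclass(frozen=True)
class ModelSpec:
    """Sampler settings.  ``iterations`` is the total per chain; the
    retained sample is ``(iterations - burn_in) / thinning`` per chain."""

    model_id: int
    prior_sd_upper: float = 10.0
    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 5_000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")
        if self.prior_sd_upper <= 0:
            raise ValueError("prior_sd_upper must be > 0")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class ModelFit:
    """Posterior draws plus convergence diagnostics of one fitted model.

    ``draws`` maps names to chain-major arrays: ``b`` (chain, draw, block,
    coef), ``sigma_s``/``sigma_h`` (chain, draw, block, period), ``u``/``S``
    (chain, draw, stratum) and, for the hierarchical model, ``beta`` and
    ``sigma_b`` (chain, draw, coef).  ``stratum_index`` aligns the stratum
    axis with (city, tract, period).
    """

    model_id: int
    spec: ModelSpec
    sex: str
    block_labels: list
    draws: dict[str, np.ndarray]
    stratum_index: pd.DataFrame
    diagnostics: pd.DataFrame
    converged: bool
    offending: list[str] = field(default_factory=list)

    @property
    def cities(self) -> list[str]:
        return list(dict.fromkeys(self.stratum_index["city"]))


@dataclass
class RRSummary:
    """Relative risks per unit deprivation, by city and (Model 3) globally."""

    per_city: pd.DataFrame
    global_summary: pd.DataFrame | None = None


def icar_log_kernel(s, graph: nx.Graph, sigma: float) -> float:
    """Log-density kernel of the sum-to-zero intrinsic-CAR field.

    ``-(1/(2 sigma^2)) * sum_{i~j} (s_i - s_j)^2`` over undirected edges,
    plus the sigma-dependent normalization ``-(rank/2) log(sigma^2)`` of
    the constrained density (rank = nodes minus connected components).
    Constant terms free of ``s`` and ``sigma`` are dropped.  Invariant
    under adding a constant to ``s``.
    """
    s = np.asarray(s, dtype=float)
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if s.size != graph.number_of_nodes():
        raise ValueError(
            f"field length {s.size} != number of nodes {graph.number_of_nodes()}"
        )
    L = laplacian(graph)
    quad = float(s @ (L @ s))
    rank = graph.number_of_nodes() - len(connected_components(graph))
    return -0.5 * quad / sigma**2 - 0.5 * rank * np.log(sigma**2)


def categorize_pr(p: float) -> str:
    """Five-bin label of a trend-change probability ``Pr(dRR)`` in [0, 1]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p}")
    return PR_BIN_LABELS[int(np.searchsorted(_PR_BIN_EDGES, p, side="right"))]


# ---------------------------------------------------------------------------
# data preparation


def _aggregate(counts: pd.DataFrame, sex: str, expected: pd.DataFrame) -> pd.DataFrame:
    obs = (
        counts[counts["sex"] == sex]
        .groupby(["city", "tract", "period"], sort=True)["deaths"]
        .sum()
        .rename("observed")
        .reset_index()
    )
    if obs.empty:
        raise ValueError(f"no counts for sex={sex!r}")
    exp_sex = expected[expected["sex"] == sex][["city", "tract", "period", "expected"]]
    merged = obs.merge(exp_sex, on=["city", "tract", "period"], how="left")
    if merged["expected"].isna().any():
        raise ValueError("expected counts missing for some (city, tract, period)")
    return merged


def _graph_arrays(graph: nx.Graph):
    order = node_order(graph)
    isolated = [v for v in order if graph.degree(v) == 0]
    if isolated:
        warnings.warn(
            f"{len(isolated)} tract(s) have no neighbours; their spatial effect "
            "is fixed at 0 and the heterogeneous effect absorbs their variability",
            stacklevel=3,
        )
    return order, laplacian(graph), connected_components(graph)


def _period_vector(df: pd.DataFrame, order, period: int, col: str) -> np.ndarray:
    sub = df[df["period"] == period].set_index("tract")[col]
    try:
        return sub.loc[order].to_numpy(float)
    except KeyError as err:
        raise ValueError(f"missing tract data for period {period}: {err}") from None


def _index_x(index, city: str, order) -> np.ndarray:
    table = index.table if hasattr(index, "table") else index
    sub = table[table["city"] == city].set_index("tract")["x"]
    try:
        return sub.loc[order].to_numpy(float)
    except KeyError:
        raise ValueError(f"deprivation index missing tracts for city {city!r}") from None


# ---------------------------------------------------------------------------
# fitting


def _monitored(fit_draws, block_labels, model_id, periods) -> dict[str, np.ndarray]:
    mon: dict[str, np.ndarray] = {}
    b = fit_draws["b"]
    for j, lab in enumerate(block_labels):
        name = lab if isinstance(lab, str) else f"{lab[0]},p{lab[1]}"
        for k in range(b.shape[-1]):
            mon[f"b{k + 1}[{name}]"] = b[:, :, j, k]
        for t, per in enumerate(periods):
            suffix = name if model_id == 1 else f"{name},p{per}"
            mon[f"sigma_s[{suffix}]"] = fit_draws["sigma_s"][:, :, j, t]
            mon[f"sigma_h[{suffix}]"] = fit_draws["sigma_h"][:, :, j, t]
    if "beta" in fit_draws:
        for k in range(fit_draws["beta"].shape[-1]):
            mon[f"beta{k + 1}"] = fit_draws["beta"][:, :, k]
            mon[f"sigma_b{k + 1}"] = fit_draws["sigma_b"][:, :, k]
    return mon


def _finish(model_id, spec, sex, block_labels, result: GibbsResult, stratum_index, periods):
    draws = {"b": result.b, "sigma_s": result.sigma_s, "sigma_h": result.sigma_h}
    if result.beta is not None:
        draws["beta"] = result.beta
        draws["sigma_b"] = result.sigma_b
    if result.u is not None:
        draws["u"] = result.u
        draws["S"] = result.S
    mon = _monitored(draws, block_labels, model_id, periods)
    diagnostics = diag.diagnose(mon)
    offending = diagnostics.loc[~diagnostics["ok"], "parameter"].tolist()
    converged = not offending
    if not converged:
        warnings.warn(
            f"model {model_id} fit did not meet the convergence gate "
            f"(R-hat < {diag.RHAT_LIMIT}, n_eff > {diag.ESS_LIMIT:g}) for: "
            + ", ".join(offending[:10])
            + ("..." if len(offending) > 10 else ""),
            stacklevel=3,
        )
    return ModelFit(
        model_id=model_id,
        spec=spec,
        sex=sex,
        block_labels=block_labels,
        draws=draws,
        stratum_index=stratum_index,
        diagnostics=diagnostics,
        converged=converged,
        offending=offending,
    )


def fit_model1(
    counts: pd.DataFrame,
    graphs: dict[str, nx.Graph],
    spec: ModelSpec,
    sex: str = "men",
    expected: pd.DataFrame | None = None,
    store_fields: bool = True,
) -> ModelFit:
    """BYM smoothing per (city, period): free intercept + ICAR + heterogeneity.

    Expected counts default to indirect standardization against each
    city's own period-1 rates, so first-period smoothed SMRs are centred
    on 100 by construction.
    """
    if spec.model_id != 1:
        raise ValueError("spec.model_id must be 1")
    validate_counts(counts)
    if expected is None:
        expected = expected_counts(counts, mode="city_period1")
    data = _aggregate(counts, sex, expected)
    blocks, labels, idx_frames = [], [], []
    for city in sorted(graphs):
        order, L, comps = _graph_arrays(graphs[city])
        sub = data[data["city"] == city]
        for period in sorted(sub["period"].unique()):
            O = _period_vector(sub, order, period, "observed")
            E = _period_vector(sub, order, period, "expected")
            blocks.append(
                BlockData(
                    label=f"{city},p{period}", n=len(order), n_periods=1,
                    O=O, E=E, Z=np.ones((len(order), 1)), L=L, comps=comps,
                    periods=[period],
                )
            )
            labels.append((city, period))
            idx_frames.append(pd.DataFrame({"city": city, "tract": order, "period": period}))
    result = run_sampler(blocks, hierarchical=False, spec=spec, store_fields=store_fields)
    stratum_index = pd.concat(idx_frames, ignore_index=True)
    return _finish(1, spec, sex, labels, result, stratum_index, periods=[1])


def _fit_regression(counts, graphs, index, spec, sex, reference, expected, store_fields):
    validate_counts(counts)
    if expected is None:
        if reference is None:
            raise ValueError("provide either a national reference rate table or expected counts")
        expected = expected_counts(counts, reference=reference, mode="national")
    data = _aggregate(counts, sex, expected)
    blocks, labels, idx_frames = [], [], []
    for city in sorted(graphs):
        order, L, comps = _graph_arrays(graphs[city])
        sub = data[data["city"] == city]
        periods = sorted(sub["period"].unique())
        if periods != [1, 2]:
            raise ValueError(f"city {city!r}: both periods required, got {periods}")
        x = _index_x(index, city, order)
        n = len(order)
        O = np.concatenate([_period_vector(sub, order, p, "observed") for p in periods])
        E = np.concatenate([_period_vector(sub, order, p, "expected") for p in periods])
        t2 = np.concatenate([np.zeros(n), np.ones(n)])
        xx = np.concatenate([x, x])
        Z = np.column_stack([np.ones(2 * n), xx, t2, xx * t2])
        blocks.append(
            BlockData(label=city, n=n, n_periods=2, O=O, E=E, Z=Z, L=L,
                      comps=comps, periods=periods)
        )
        labels.append(city)
        idx_frames.append(
            pd.DataFrame(
                {"city": city, "tract": np.tile(order, 2),
                 "period": np.repeat(periods, n)}
            )
        )
    hierarchical = spec.model_id == 3
    result = run_sampler(blocks, hierarchical=hierarchical, spec=spec, store_fields=store_fields)
    stratum_index = pd.concat(idx_frames, ignore_index=True)
    return _finish(spec.model_id, spec, sex, labels, result, stratum_index, periods=[1, 2])


def fit_model2(
    counts, graphs, index, spec: ModelSpec, sex: str = "men",
    reference=None, expected=None, store_fields: bool = True,
) -> ModelFit:
    """Per-city ecological regression with period interaction (fixed effects)."""
    if spec.model_id != 2:
        raise ValueError("spec.model_id must be 2")
    return _fit_regression(counts, graphs, index, spec, sex, reference, expected, store_fields)


def fit_model3(
    counts, graphs, index, spec: ModelSpec, sex: str = "men",
    reference=None, expected=None, store_fields: bool = True,
) -> ModelFit:
    """Random-coefficients multilevel model pooling cities into global RRs."""
    if spec.model_id != 3:
        raise ValueError("spec.model_id must be 3")
    if len(graphs) < 3:
        raise ValueError(
            "the random-coefficients model needs >= 3 cities: the between-city "
            "variances are unidentifiable with fewer"
        )
    return _fit_regression(counts, graphs, index, spec, sex, reference, expected, store_fields)


# ---------------------------------------------------------------------------
# posterior summaries


def _summary(draws_flat: np.ndarray):
    return (
        float(draws_flat.mean()),
        float(np.percentile(draws_flat, 2.5)),
        float(np.percentile(draws_flat, 97.5)),
    )


def ssmr(fit: ModelFit) -> pd.DataFrame:
    """Smoothed SMRs ``exp(b1 + S + H) * 100`` per tract with 95% intervals.

    Uses the identity ``b1 + S + H = log(theta)``: the stored latent
    surface is exactly the log relative risk, so no reassembly is needed.
    """
    if fit.model_id != 1:
        raise ValueError("smoothed SMRs are defined for Model 1 fits only")
    if "u" not in fit.draws:
        raise ValueError("fit was run without stored latent fields")
    u = fit.draws["u"]  # (chain, draw, stratum)
    flat = u.reshape(-1, u.shape[-1])
    vals = np.exp(flat) * 100.0
    out = fit.stratum_index.copy()
    out["ssmr"] = vals.mean(axis=0)
    out["ssmr_lo"] = np.percentile(vals, 2.5, axis=0)
    out["ssmr_hi"] = np.percentile(vals, 97.5, axis=0)
    return out


def rr_and_trend(fit: ModelFit) -> RRSummary:
    """Relative risks per period, trend-change probability and its category."""
    if fit.model_id not in (2, 3):
        raise ValueError("relative-risk summaries are defined for Models 2 and 3")
    b = fit.draws["b"]  # (chain, draw, city, 4)
    rows = []
    for j, city in enumerate(fit.block_labels):
        b2 = b[:, :, j, 1].ravel()
        b4 = b[:, :, j, 3].ravel()
        rr1, lo1, hi1 = _summary(np.exp(b2))
        rr2, lo2, hi2 = _summary(np.exp(b2 + b4))
        pr = float((b4 > 0).mean())
        rows.append(
            {"city": city, "sex": fit.sex,
             "rr_p1": rr1, "rr_p1_lo": lo1, "rr_p1_hi": hi1,
             "rr_p2": rr2, "rr_p2_lo": lo2, "rr_p2_hi": hi2,
             "pr_delta": pr, "category": categorize_pr(pr)}
        )
    per_city = pd.DataFrame(rows)
    global_summary = None
    if fit.model_id == 3:
        beta = fit.draws["beta"]
        b2g = beta[:, :, 1].ravel()
        b4g = beta[:, :, 3].ravel()
        rr1, lo1, hi1 = _summary(np.exp(b2g))
        rr2, lo2, hi2 = _summary(np.exp(b2g + b4g))
        pr = float((b4g > 0).mean())
        global_summary = pd.DataFrame(
            [{"sex": fit.sex,
              "rrg_p1": rr1, "rrg_p1_lo": lo1, "rrg_p1_hi": hi1,
              "rrg_p2": rr2, "rrg_p2_lo": lo2, "rrg_p2_hi": hi2,
              "pr_delta_global": pr, "category": categorize_pr(pr)}]
        )
    return RRSummary(per_city=per_city, global_summary=global_summary)
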