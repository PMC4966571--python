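"""MCMC convergence diagnostics.

Thin wrappers around ArviZ's split potential-scale-reduction factor
(R-hat) and effective sample size, applied per monitored scalar parameter.
The convergence gate used throughout the package is the conventional
``R-hat < 1.1 and n_eff > 100`` for every monitored parameter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RHAT_LIMIT = 1.1
ESS_LIMIT = 100.0

__all__ = ["rhat", "ess", "RHAT_LIMIT", "ESS_LIMIT", "diagnose"]


def _as_chains(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("chains must be a 2-D array (n_chains, n_draws)")
    if arr.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    return arr


def rhat(chains) -> float:
    """Split R-hat (rank-normalized potential scale reduction) of one parameter."""
    import arviz as az

    return float(az.rhat(_as_chains(chains)))


def ess(chains) -> float:
    """Bulk effective sample size of one parameter across chains."""
    import arviz as az

    return float(az.ess(_as_chains(chains)))


def diagnose(draws: dict[str, np.ndarray]) -> pd.DataFrame:
    """Diagnostics table for a dict of per-parameter ``(chain, draw)`` arrays.

    Returns one row per parameter with ``rhat``, ``ess`` and an ``ok`` flag
    under the standard gate.
    """
    rows = []
    for name, arr in draws.items():
        r, e = rhat(arr), ess(arr)
        rows.append(
            {"parameter": name, "rhat": r, "ess": e,
             "ok": bool(r < RHAT_LIMIT and e > ESS_LIMIT)}
        )
    return pd.DataFrame(rows)
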