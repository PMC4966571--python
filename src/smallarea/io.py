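"""CSV and edge-list persistence of study inputs and outputs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .graphs import read_edgelist, write_edgelist
from .synthetic import SyntheticStudy

__all__ = [
    "write_study",
    "read_counts",
    "read_indicators",
    "read_reference",
    "read_graphs",
    "write_index",
    "read_index_table",
    "write_fit_draws",
]


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write a simulated study as plain-text files.

    Layout: ``counts.csv``, ``indicators.csv``, ``reference.csv``,
    ``truth.csv`` + ``truth_b_city.csv`` (generator ground truth for test
    harnesses) and one ``adjacency/<city>.txt`` edge list per city.
    """
    outdir = Path(outdir)
    (outdir / "adjacency").mkdir(parents=True, exist_ok=True)
    study.counts.to_csv(outdir / "counts.csv", index=False)
    study.indicators.to_csv(outdir / "indicators.csv", index=False)
    study.reference.to_csv(outdir / "reference.csv", index=False)
    study.truth.table.to_csv(outdir / "truth.csv", index=False)
    study.truth.b_city.to_csv(outdir / "truth_b_city.csv", index=False)
    for city, g in study.graphs.items():
        write_edgelist(g, outdir / "adjacency" / f"{city}.txt")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"city": str, "sex": str, "age_group": str})


def read_indicators(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"city": str})


def read_reference(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"sex": str, "age_group": str})


def read_graphs(adjacency_dir: str | Path) -> dict:
    adjacency_dir = Path(adjacency_dir)
    graphs = {}
    for f in sorted(adjacency_dir.glob("*.txt")):
        graphs[f.stem] = read_edgelist(f)
    if not graphs:
        raise ValueError(f"no edge-list files found under {adjacency_dir}")
    return graphs


def write_index(index, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write the deprivation index table plus a JSON metadata sidecar."""
    csv_path = Path(csv_path)
    index.table.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".meta.json")
    meta = {
        "loadings": [float(v) for v in index.loadings],
        "variance_explained": float(index.variance_explained),
        "correlations": {k: float(v) for k, v in index.correlations.items()},
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2) + "\n")


def read_index_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"city": str})


def write_fit_draws(fit, outdir: str | Path) -> None:
    """Persist monitored scalar draws and diagnostics of a fit.

    ``draws.csv`` is long format (parameter, chain, iteration, value) over
    the coefficient- and variance-level parameters (latent per-tract
    fields are summarised, not dumped); ``diagnostics.csv`` holds R-hat
    and effective sample sizes.
    """
    from .models import _monitored  # local import to avoid cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    periods = sorted(fit.stratum_index["period"].unique()) if fit.model_id != 1 else [1]
    mon = _monitored(fit.draws, fit.block_labels, fit.model_id, periods)
    frames = []
    for name, arr in mon.items():
        n_chain, n_draw = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "parameter": name,
                    "chain": [c for c in range(n_chain) for _ in range(n_draw)],
                    "iteration": list(range(n_draw)) * n_chain,
                    "value": arr.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(outdir / "draws.csv", index=False)
    fit.diagnostics.to_csv(outdir / "diagnostics.csv", index=False)
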