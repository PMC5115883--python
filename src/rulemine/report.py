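"""Results-style report tables.

The canonical outputs are plain CSV/JSON tables; figures are derived views
and live behind an optional plotting flag.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport

__all__ = ["render_report", "interaction_matrix", "rule_bin_grid", "report_to_json"]


def interaction_matrix(report: EvaluationReport) -> pd.DataFrame:
    """Square variable x variable matrix of 2D-rule co-selection counts.

    Lower triangle: first modality (renal failure); upper triangle: second
    modality.  Diagonal is zero (a rule's two variables are distinct).
    """
    inter = report.interaction_frequency
    variables = sorted({v for pairs in inter.values() for pair in pairs for v in pair})
    mat = pd.DataFrame(0, index=variables, columns=variables, dtype=int)
    lower, upper = _modality_order(report)
    for (a, b), count in inter.get(lower, {}).items():
        lo, hi = sorted((a, b))
        mat.loc[hi, lo] += count  # lower triangle
    for (a, b), count in inter.get(upper, {}).items():
        lo, hi = sorted((a, b))
        mat.loc[lo, hi] += count  # upper triangle
    return mat


def _modality_order(report: EvaluationReport):
    return report.modalities


def rule_bin_grid(report: EvaluationReport, pair: tuple, modality: str, n_bins: int = 10) -> np.ndarray:
    """Bin-grid frequency map for one variable pair and modality: entry
    (a, b) counts, over runs, the 2D rules whose box covers bin a of the
    first variable and bin b of the second."""
    grid = np.zeros((n_bins, n_bins), dtype=int)
    want = frozenset(pair)
    for run in report.per_run:
        if run["rules"] is None:
            continue
        for r in run["rules"]:
            if r.dimension != 2 or r.modality != modality or r.variables != want:
                continue
            by_var = {c.variable: c for c in r.conditions}
            ca, cb = by_var[pair[0]], by_var[pair[1]]
            grid[ca.lo - 1 : ca.hi, cb.lo - 1 : cb.hi] += 1
    return grid


def coverage_table(report: EvaluationReport, modality: str, n_bins: int = 10) -> pd.DataFrame:
    """Per-variable 1D-rule bin-coverage counts for one modality (rows:
    variables, columns: bin codes)."""
    rows = {}
    for (var, mod), counts in report.coverage_maps.items():
        if mod != modality:
            continue
        arr = np.zeros(n_bins, dtype=int)
        for code, c in counts.items():
            if 1 <= code <= n_bins:
                arr[code - 1] = c
        rows[var] = arr
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"bin_{i}" for i in range(1, n_bins + 1)])


def report_to_json(report: EvaluationReport) -> dict:
    cfg = report.config
    return {
        "model_type": report.model_type,
        "config": {
            "n_splits": cfg.n_splits,
            "test_fraction": cfg.test_fraction,
            "inner_repeats": cfg.inner_repeats,
            "inner_folds": cfg.inner_folds,
            "c_grid": list(cfg.c_grid),
            "n_permutations": cfg.n_permutations,
            "n_perm_splits": cfg.n_perm_splits,
            "seed": cfg.seed,
            "f1_average": cfg.f1_average,
            "min_modality_size": cfg.min_modality_size,
            "min_z": cfg.min_z,
        },
        "f1_mean": report.f1_mean,
        "f1_sd": report.f1_sd,
        "complexity_mean": report.complexity_mean,
        "c_star": report.c_star,
        "c_mode_frequency": report.c_mode_frequency,
        "stability_mean": report.stability_mean,
        "stability_sd": report.stability_sd,
        "permutation_p": report.permutation_p,
        "permutation_observed": report.permutation_observed,
        "per_run": [
            {
                "run": r["run"],
                "f1": r["f1"],
                "complexity": r["complexity"],
                "chosen_C": r["chosen_C"],
                "selected_variables": r["selected_variables"],
            }
            for r in report.per_run
        ],
        "feature_frequency": report.feature_frequency,
    }


def render_report(report: EvaluationReport, outdir, n_bins: int = 10, plots: bool = False, pair=None) -> list:
    """Write the report's canonical tables to ``outdir``.

    Emits a summary row (the headline table: F1, complexity, p-value,
    C (freq), stability), per-run metrics, variable selection frequencies,
    per-modality 1D rule coverage maps, interaction matrices, and — when a
    ``pair`` is given — its 2D rule bin grids.  Returns the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    summary = pd.DataFrame([report.summary_row()])
    p = outdir / f"summary_{report.model_type}.csv"
    summary.to_csv(p, index=False)
    written.append(p)

    p = outdir / f"report_{report.model_type}.json"
    with open(p, "w") as fh:
        json.dump(report_to_json(report), fh, indent=2)
    written.append(p)

    per_run = pd.DataFrame(
        [
            {"run": r["run"], "f1": r["f1"], "complexity": r["complexity"], "chosen_C": r["chosen_C"]}
            for r in report.per_run
        ]
    )
    p = outdir / f"per_run_{report.model_type}.csv"
    per_run.to_csv(p, index=False)
    written.append(p)

    freq = pd.Series(report.feature_frequency, dtype=int).sort_values(ascending=False)
    p = outdir / f"variable_frequency_{report.model_type}.csv"
    freq.rename_axis("variable").rename("frequency").to_csv(p)
    written.append(p)

    modalities = _modality_order(report)
    for modality in modalities:
        cov = coverage_table(report, modality, n_bins)
        p = outdir / f"coverage_{report.model_type}_{modality}.csv"
        cov.to_csv(p, index_label="variable")
        written.append(p)

    if report.interaction_frequency:
        mat = interaction_matrix(report)
        p = outdir / f"interactions_{report.model_type}.csv"
        mat.to_csv(p, index_label="variable")
        written.append(p)
        if pair is not None:
            for modality in modalities:
                grid = rule_bin_grid(report, tuple(pair), modality, n_bins)
                p = outdir / f"bingrid_{report.model_type}_{modality}.csv"
                pd.DataFrame(
                    grid,
                    index=[f"{pair[0]}_bin{i}" for i in range(1, n_bins + 1)],
                    columns=[f"{pair[1]}_bin{i}" for i in range(1, n_bins + 1)],
                ).to_csv(p)
                written.append(p)

    if plots:
        written += _plot(report, outdir)
    return written


def _plot(report: EvaluationReport, outdir: Path) -> list:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = []
    freq = pd.Series(report.feature_frequency, dtype=int).sort_values(ascending=False)
    fig, ax = plt.subplots(figsize=(10, 4))
    freq.plot.bar(ax=ax)
    ax.axhline(report.config.n_splits / 2, color="red", lw=1)
    ax.set_ylabel("selection frequency")
    fig.tight_layout()
    p = outdir / f"variable_frequency_{report.model_type}.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out.append(p)
    return out
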