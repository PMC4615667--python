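"""Report emission: stratum and model tables, machine-readable results, plots.

Human-readable tables mirror conventional epidemiology-report formatting (utility
means at 3 dp, coefficients and fit statistics at 4 dp, ages and percents at
1 dp); the machine-readable YAML always carries full precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .models import AnalysisResult, FitResult
from .strata import CorrelationRow, StratumSummary, summaries_to_frame


def write_stratum_table(
    summaries: list[StratumSummary],
    correlation: CorrelationRow | None,
    path: str | Path,
    sep: str = "\t",
) -> Path:
    """Write the stratum descriptives (plus the labelled Pearson row) as text."""
    path = Path(path)
    frame = summaries_to_frame(summaries, correlation)
    frame.to_csv(path, sep=sep, index=False, float_format="%.3f")
    return path


def _fit_row(number: int, fit: FitResult, rmsd: float | None) -> dict:
    fmt = lambda v: "" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.4f}"
    return {
        "analysis": number,
        "model": fit.model_id,
        "alpha": fmt(fit.alpha),
        "beta": fmt(fit.beta),
        "beta2": fmt(fit.beta2),
        "p_beta2": fmt(fit.p_beta2),
        "adj_r2": fmt(fit.adj_r2),
        "rmsd_ac": fmt(rmsd),
        "rmse": fmt(fit.rmse),
        "l1o_rmsr": fmt(fit.l1o_rmsr),
    }


def write_model_table(
    results: dict[int, AnalysisResult], path: str | Path, sep: str = "\t"
) -> Path:
    """Write the per-analysis model comparison table (4 dp) as delimited text."""
    path = Path(path)
    header = [
        "analysis", "model", "alpha", "beta", "beta2", "p_beta2",
        "adj_r2", "rmsd_ac", "rmse", "l1o_rmsr",
    ]
    lines = [sep.join(header)]
    for number in sorted(results):
        result = results[number]
        for fit, rmsd in (
            (result.fit_a, None),
            (result.fit_b, result.rmsd_ac),
            (result.fit_c, None),
        ):
            row = _fit_row(number, fit, rmsd)
            lines.append(sep.join(str(row[h]) for h in header))
    path.write_text("\n".join(lines) + "\n")
    return path


def _fit_record(fit: FitResult) -> dict:
    return {
        "model": fit.model_id,
        "alpha": float(fit.alpha),
        "beta": float(fit.beta),
        "beta2": None if fit.beta2 is None else float(fit.beta2),
        "p_beta2": None if fit.p_beta2 is None else float(fit.p_beta2),
        "adj_r2": float(fit.adj_r2),
        "rmse": float(fit.rmse),
        "l1o_rmsr": float(fit.l1o_rmsr),
        "fitted": [float(v) for v in fit.fitted],
    }


def results_to_records(results: dict[int, AnalysisResult]) -> dict:
    """Full-precision, YAML/JSON-serializable view of a set of analyses."""
    records = {}
    for number, result in sorted(results.items()):
        entry = {
            "instrument": result.series.instrument,
            "label": result.series.label,
            "x": [float(v) for v in result.series.x],
            "y": [float(v) for v in result.series.y],
            "w": [float(v) for v in result.series.w],
            "rmsd_ac": float(result.rmsd_ac),
            "fits": [
                _fit_record(result.fit_a),
                _fit_record(result.fit_b),
                _fit_record(result.fit_c),
            ],
        }
        for key in ("n_weighable_codes", "retained_pct", "reclassified_pct"):
            if key in result.info:
                entry[key] = (
                    int(result.info[key]) if key == "n_weighable_codes"
                    else float(result.info[key])
                )
        records[number] = entry
    return records


def write_results_yaml(results: dict[int, AnalysisResult], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(results_to_records(results), sort_keys=True))
    return path


def plot_analysis(result: AnalysisResult, path: str | Path, title: str = "") -> Path:
    """Observed stratum means with the three fitted curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    x = result.series.x
    grid = np.linspace(x.min(), x.max(), 200)
    a, b = result.fit_a.alpha, result.fit_a.beta
    qa, qb, qc = result.fit_b.alpha, result.fit_b.beta, result.fit_b.beta2
    ca, cb = result.fit_c.alpha, result.fit_c.beta

    fig, ax = plt.subplots(figsize=(6, 4))
    sizes = 200 * result.series.w / result.series.w.max()
    ax.scatter(x, result.series.y, s=sizes, color="k", alpha=0.6, zorder=3,
               label="stratum means (area ~ n)")
    ax.plot(grid, a + b * grid, label=f"A: {a:.4f} {b:+.4f}k")
    ax.plot(grid, qa + qb * grid + qc * grid**2, linestyle="--",
            label=f"B: quadratic (b2={qc:.4f})")
    ax.plot(grid, ca * cb**grid, linestyle=":", label=f"C: {ca:.4f}*{cb:.4f}^k")
    ax.set_xlabel("number of diagnoses (stratum)")
    ax.set_ylabel(f"mean {result.series.instrument or 'utility'}")
    ax.set_title(title or result.series.label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
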