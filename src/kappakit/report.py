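"""Analysis reports: per-comparison kappa blocks, JSON and text rendering.

A report block holds the contingency matrix with its marginal totals,
the three standard statistics (Cohen, linear weighted, quadratic
weighted) each with SE/CI/p-value and a qualitative verdict, plus any
reference-kappa metadata carried with the table.  JSON serialises at
full precision; the text rendering rounds to 2 decimals
(half away from zero), matching how agreement tables are printed.
"""

from __future__ import annotations

import datetime as _dt
import json
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from . import __version__
from .datasets import recist_comparisons
from .interpret import LANDIS_KOCH_BANDS
from .model import InterRaterModel
from .table import ContingencyTable

DEFAULT_STATS = ("cohen", "linear", "quadratic")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (0.375 -> 0.38, -0.005 -> -0.01)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round2(x: float) -> float:
    return round_half_away(x, 2)


def analyze_table(
    table: ContingencyTable,
    statistics: tuple[str, ...] = DEFAULT_STATS,
    ci: str = "asymptotic",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
    gate: bool = True,
    band_edges=LANDIS_KOCH_BANDS,
    reference_kappa: float | None = None,
) -> dict:
    """One report block: matrix, totals, and the requested statistics."""
    model = InterRaterModel.from_table(table)
    results = model.fit_family(
        statistics, ci=ci, alpha=alpha, n_boot=n_boot, seed=seed,
        gate_interpretation=gate, band_edges=band_edges,
    )
    block = {
        "table_id": table.table_id,
        "raters": list(table.rater_names),
        "labels": list(table.scale.labels),
        "counts": table.counts.tolist(),
        "row_totals": table.counts.sum(axis=1).tolist(),
        "col_totals": table.counts.sum(axis=0).tolist(),
        "n": table.n_subjects,
        "statistics": {name: res.to_dict() for name, res in results.items()},
    }
    if reference_kappa is not None:
        block["reference_kappa"] = reference_kappa
    return block


def build_report(blocks: list[dict], config: dict | None = None) -> dict:
    """Wrap report blocks with run metadata."""
    return {
        "generator": f"kappakit {__version__}",
        "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        "config": config or {},
        "comparisons": blocks,
    }


def recist_reanalysis(
    ci: str = "asymptotic",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict:
    """Full reanalysis of the six bundled RECIST response-assessment matrices.

    Recomputes Cohen's, linear-weighted and quadratic-weighted kappa with
    CIs and verdicts for every rater-vs-reference comparison; the
    originally reported kappa is attached as metadata, never recomputed.
    """
    blocks = []
    for comp in recist_comparisons():
        blocks.append(
            analyze_table(
                comp.table, ci=ci, alpha=alpha, n_boot=n_boot, seed=seed,
                reference_kappa=comp.kappa_star,
            )
        )
    return build_report(
        blocks,
        config={"ci": ci, "alpha": alpha, "n_boot": n_boot if ci == "bootstrap" else None,
                "seed": seed},
    )


def report_to_json(report: dict, indent: int = 2) -> str:
    return json.dumps(report, indent=indent)


def _fmt_ci(stat: dict) -> str:
    lo, hi = stat["ci"]
    return f"{round2(lo):.2f}–{round2(hi):.2f}"


def render_text(report: dict) -> str:
    """Plain-text rendering: one matrix-with-totals block per comparison."""
    out = []
    out.append(f"{report['generator']}  ({report['timestamp']})")
    for block in report["comparisons"]:
        labels = block["labels"]
        counts = np.asarray(block["counts"])
        title = block["table_id"] or f"{block['raters'][0]} vs {block['raters'][1]}"
        out.append("")
        out.append(f"== {title}: {block['raters'][0]} (rows) vs {block['raters'][1]} (cols) ==")
        width = max(6, max(len(s) for s in labels) + 1)
        head = " " * width + "".join(f"{lab:>{width}}" for lab in labels) + f"{'Total':>{width}}"
        out.append(head)
        for i, lab in enumerate(labels):
            row = f"{lab:>{width}}" + "".join(f"{c:>{width}d}" for c in counts[i])
            row += f"{block['row_totals'][i]:>{width}d}"
            out.append(row)
        total_row = f"{'Total':>{width}}" + "".join(
            f"{c:>{width}d}" for c in block["col_totals"]
        ) + f"{block['n']:>{width}d}"
        out.append(total_row)
        for name, stat in block["statistics"].items():
            sig = "<" if stat["p_value"] < stat["alpha"] else ">"
            out.append(
                f"  {name:<10s} kappa = {round2(stat['point']):.2f}  "
                f"(p {sig} {stat['alpha']:g}, "
                f"{(1 - stat['alpha']) * 100:.0f}% CI = {_fmt_ci(stat)})  "
                f"[{stat['interpretation']}]"
            )
        if "reference_kappa" in block:
            out.append(
                f"  originally reported kappa* = {block['reference_kappa']:.2f} "
                "(metadata; computation method unknown)"
            )
    return "\n".join(out)
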