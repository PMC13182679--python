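"""Aggregation of planning results into per-case and per-stratum reports.

Cases are stratified by target volume into the categories <1 cc, 1-2 cc,
2-20 cc and >20 cc (boundary volumes go to the finer category: 1 cc and
2 cc both belong to "1-2 cc").
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .metrics import PlanMetrics
from .planner import PlanningRun

__all__ = ["volume_category", "metrics_row", "write_report", "VOLUME_CATEGORIES"]

VOLUME_CATEGORIES = ("<1 cc", "1-2 cc", "2-20 cc", ">20 cc")


def volume_category(volume_cc: float) -> str:
    if volume_cc < 1.0:
        return VOLUME_CATEGORIES[0]
    if volume_cc <= 2.0:
        return VOLUME_CATEGORIES[1]
    if volume_cc <= 20.0:
        return VOLUME_CATEGORIES[2]
    return VOLUME_CATEGORIES[3]


def metrics_row(case_id: str, m: PlanMetrics) -> dict:
    return {
        "id": case_id,
        "volume_cc": m.tv_cc,
        "coverage_pct": 100.0 * m.coverage,
        "si": m.selectivity,
        "ci_rtog": m.ci_rtog,
        "ci_paddick": m.ci_paddick,
        "n_shots": m.n_shots,
    }


def write_report(
    runs: list[PlanningRun],
    out_csv: str | Path,
    out_json: str | Path | None = None,
    seed: int | None = None,
    cfg_hash: str = "",
) -> pd.DataFrame:
    """Write per-case rows plus volume-stratum aggregates; returns the rows.

    The JSON summary carries the stratum means together with the seed and
    configuration hash for provenance.
    """
    if not runs:
        raise ValueError("no runs to report")
    rows = pd.DataFrame([metrics_row(r.case_id, r.best_metrics) for r in runs])
    rows["category"] = rows["volume_cc"].map(volume_category)
    rows.to_csv(out_csv, index=False)

    agg = (
        rows.groupby("category")[["coverage_pct", "si", "ci_rtog", "ci_paddick", "n_shots"]]
        .mean()
        .reindex([c for c in VOLUME_CATEGORIES if c in set(rows["category"])])
    )
    summary = {
        "seed": seed,
        "config_hash": cfg_hash,
        "n_cases": int(len(rows)),
        "strata": {cat: {k: float(v) for k, v in row.items()} for cat, row in agg.iterrows()},
    }
    if out_json is not None:
        Path(out_json).write_text(json.dumps(summary, indent=2) + "\n")
    return rows
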