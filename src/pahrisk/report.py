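"""Assemble pipeline outputs into a reproducible report bundle."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .montecarlo import McResult
from .risk import RiskResult
from .summary import ComplianceReport, GroupSummaryTable


def _json_default(o: Any) -> Any:
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o).__name__)


def render_report(
    outdir: str | Path,
    summary: GroupSummaryTable | None = None,
    compliance_report: ComplianceReport | None = None,
    risk: RiskResult | None = None,
    mc: McResult | None = None,
    clusters: Mapping[str, int] | None = None,
    seed: int | None = None,
    config: Mapping[str, Any] | None = None,
) -> list[Path]:
    """Write every available stage output into ``outdir``.

    Missing stages are recorded as explicit gaps in ``metadata.json``
    rather than raising, so a deterministic-only run still yields a
    valid (partial) bundle.  Tables are written with fixed float
    formatting so identical inputs produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    missing: list[str] = []

    def emit_csv(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, float_format="%.6g")
        written.append(p)

    def emit_json(name: str, payload: Any) -> None:
        p = outdir / name
        p.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
        written.append(p)

    if summary is not None:
        emit_csv("group_summary.csv", summary.table)
        emit_csv("overall_summary.csv", summary.overall)
    else:
        missing.append("summary")

    if compliance_report is not None:
        emit_json(
            "compliance.json",
            {
                "limits_ug_per_kg": dict(compliance_report.limits),
                "all_compliant": compliance_report.all_compliant,
                "per_group": compliance_report.flags.to_dict(orient="index"),
            },
        )
    else:
        missing.append("compliance")

    if risk is not None:
        emit_json("risk_deterministic.json", dataclasses.asdict(risk))
    else:
        missing.append("risk")

    if mc is not None:
        emit_csv("edi_percentiles.csv", mc.edi)
        emit_json("ilcr_percentiles.json", {str(k): v for k, v in mc.ilcr.items()})
        draws = outdir / "ilcr_draws.txt"
        np.savetxt(draws, mc.ilcr_draws, fmt="%.8e")
        written.append(draws)
    else:
        missing.append("monte_carlo")

    if clusters is not None:
        emit_csv(
            "cluster_assignments.csv",
            pd.Series(dict(clusters), name="cluster").rename_axis("variable").to_frame(),
        )
    else:
        missing.append("clusters")

    config = dict(config or {})
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=_json_default).encode()
    ).hexdigest()[:16]
    emit_json(
        "metadata.json",
        {
            "pahrisk_version": __version__,
            "python": platform.python_version(),
            "seed": seed,
            "config": config,
            "config_sha256_16": cfg_hash,
            "missing_stages": missing,
        },
    )
    return written
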