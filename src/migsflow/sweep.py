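"""Scenario sweep engine and report writer.

Evaluates the lumped outflow model over a grid of devices × baseline IOPs ×
bleb pressures and renders the result as CSV (long form, one row per grid
point), JSON (rows plus parameter provenance) or a markdown table mirroring
the published layout (one IOP row and one efficacy row per device, bleb
pressures as columns, a dash where scarring drives the IOP above baseline).

Two efficacy rounding policies are supported: ``"unrounded"`` computes the
percent reduction from the exact postoperative IOP; ``"rounded"`` first
rounds the IOP to the reported precision, which is how summary percentages
such as a 76 % reduction at a baseline of 50 mmHg arise.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from . import __version__ as _pkg_version
from .hydraulics import (
    BlebState,
    EyeParameters,
    ImplantSpec,
    predict_outcome,
)
from .catalog import get_device, shorten
from .printed import REFERENCE_CELLS, PrintedCell

__all__ = [
    "SweepGrid",
    "SweepResult",
    "default_grid",
    "run_sweep",
    "write_report",
    "compare_to_printed",
    "device_row_label",
]

CSV_HEADER = ["device", "pg_mmHg", "pb_mmHg", "pc_mmHg", "qv_ul_min", "efficacy_pct"]


def device_row_label(spec: ImplantSpec) -> str:
    """Canonical row label, e.g. 'XEN 45-6mm'; idempotent for shortened variants."""
    if spec.name.endswith("mm"):
        return spec.name
    return f"{spec.name}-{spec.length_mm:g}mm"


@dataclass(frozen=True)
class SweepGrid:
    """Device × p_g × p_b evaluation grid.

    ``p_b_values`` is the default bleb-pressure axis; ``p_b_overrides`` maps a
    baseline IOP to a replacement axis (the published grid starts at
    p_b = 2 mmHg in the 30 mmHg block but at 0 elsewhere).
    """

    devices: Sequence[ImplantSpec]
    p_g_values: Sequence[float]
    p_b_values: Sequence[float]
    eye_defaults: Mapping[str, float] = field(
        default_factory=lambda: {
            "p_ev": 10.5,
            "Q_cb": 2.0,
            "uveoscleral_fraction": 0.15,
            "viscosity": 7e-4,
            "density": 998.2,
        }
    )
    p_b_overrides: Mapping[float, Sequence[float]] = field(default_factory=dict)
    efficacy_rounding: str = "unrounded"  # or "rounded"

    def __post_init__(self) -> None:
        if not self.devices or not self.p_g_values:
            raise ValueError("sweep grid axes must be non-empty")
        if not self.p_b_values and not self.p_b_overrides:
            raise ValueError("sweep grid axes must be non-empty")
        if self.efficacy_rounding not in ("unrounded", "rounded"):
            raise ValueError("efficacy_rounding must be 'unrounded' or 'rounded'")
        p_ev = self.eye_defaults["p_ev"]
        for p_g in self.p_g_values:
            if p_g <= p_ev:
                raise ValueError(f"baseline IOP {p_g} must exceed p_ev {p_ev}")

    def p_b_axis(self, p_g: float) -> Sequence[float]:
        return self.p_b_overrides.get(p_g, self.p_b_values)


@dataclass(frozen=True)
class SweepResult:
    """One row per grid point, plus the parameter provenance that produced it."""

    table: pd.DataFrame
    provenance: Dict[str, object]


def default_grid(efficacy_rounding: str = "unrounded") -> SweepGrid:
    """The study grid: three devices and their 1 mm-trimmed variants,
    baselines 25/30/50 mmHg, bleb pressures 0(2)/5/10/17/20/34 mmHg."""
    devices = []
    for name in ("XEN 45", "XEN 63", "PreserFlo"):
        spec = get_device(name)
        devices.append(spec)
        devices.append(shorten(spec, 1.0))
    return SweepGrid(
        devices=devices,
        p_g_values=[25.0, 30.0, 50.0],
        p_b_values=[0.0, 5.0, 10.0, 17.0, 20.0, 34.0],
        p_b_overrides={30.0: [2.0, 5.0, 10.0, 17.0, 20.0, 34.0]},
        efficacy_rounding=efficacy_rounding,
    )


def _efficacy(p_g: float, p_c: float, policy: str) -> float:
    p_eff = round(p_c) if policy == "rounded" else p_c
    return 100.0 * (p_g - p_eff) / p_g


def run_sweep(grid: SweepGrid) -> SweepResult:
    """Deterministic evaluation of the model at every grid point.

    Domain errors are attached to the offending cell (in an ``error``
    column) rather than aborting the whole sweep.
    """
    records: List[dict] = []
    any_error = False
    for device in grid.devices:
        label = device_row_label(device)
        for p_g in grid.p_g_values:
            for p_b in grid.p_b_axis(p_g):
                rec = {"device": label, "pg_mmHg": float(p_g), "pb_mmHg": float(p_b)}
                try:
                    eye = EyeParameters(p_g=p_g, **grid.eye_defaults)
                    out = predict_outcome(device, eye, BlebState.fixed(p_b))
                    rec.update(
                        pc_mmHg=out.p_c,
                        qv_ul_min=out.Q_v,
                        efficacy_pct=_efficacy(p_g, out.p_c, grid.efficacy_rounding),
                        error="",
                    )
                except ValueError as exc:
                    any_error = True
                    rec.update(
                        pc_mmHg=float("nan"),
                        qv_ul_min=float("nan"),
                        efficacy_pct=float("nan"),
                        error=str(exc),
                    )
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    if not any_error:
        df = df.drop(columns=["error"])
    provenance = {
        "package": "migsflow",
        "version": _pkg_version,
        "eye_defaults": dict(grid.eye_defaults),
        "efficacy_rounding": grid.efficacy_rounding,
        "devices": [
            {
                "name": device_row_label(d),
                "lumen_diameter_um": d.lumen_diameter_um,
                "length_mm": d.length_mm,
                "shape_factor": d.shape_factor,
            }
            for d in grid.devices
        ],
        "generated_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }
    return SweepResult(table=df, provenance=provenance)


def _format_csv(result: SweepResult) -> str:
    df = result.table.sort_values(["device", "pg_mmHg", "pb_mmHg"], kind="mergesort")
    buf = io.StringIO()
    buf.write(",".join(CSV_HEADER) + "\n")
    for _, row in df.iterrows():
        buf.write(
            f"{row['device']},{row['pg_mmHg']:g},{row['pb_mmHg']:g},"
            f"{row['pc_mmHg']:.6f},{row['qv_ul_min']:.6f},{row['efficacy_pct']:.6f}\n"
        )
    return buf.getvalue()


def _format_json(result: SweepResult) -> str:
    df = result.table.sort_values(["device", "pg_mmHg", "pb_mmHg"], kind="mergesort")
    payload = {
        "provenance": result.provenance,
        "rows": df.to_dict(orient="records"),
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _format_markdown(result: SweepResult) -> str:
    """Published-layout mirror: p_b columns, one IOP and one efficacy row per device."""
    df = result.table
    lines: List[str] = []
    for p_g in sorted(df["pg_mmHg"].unique()):
        block = df[df["pg_mmHg"] == p_g]
        p_bs = sorted(block["pb_mmHg"].unique())
        lines.append(f"### Baseline IOP p_g = {p_g:g} mmHg")
        lines.append("")
        lines.append("| device | " + " | ".join(f"p_b={pb:g}" for pb in p_bs) + " |")
        lines.append("|---" * (len(p_bs) + 1) + "|")
        for device in dict.fromkeys(df["device"]):
            rows = block[block["device"] == device].set_index("pb_mmHg")
            pc_cells = [f"{rows.loc[pb, 'pc_mmHg']:.1f}" for pb in p_bs]
            eff_cells = [
                "-" if rows.loc[pb, "efficacy_pct"] < 0
                else f"{rows.loc[pb, 'efficacy_pct']:.0f}"
                for pb in p_bs
            ]
            lines.append(f"| {device} | " + " | ".join(pc_cells) + " |")
            lines.append("| Efficacy (%) | " + " | ".join(eff_cells) + " |")
        lines.append("")
    return "\n".join(lines) + "\n"


_FORMATTERS = {"csv": _format_csv, "json": _format_json, "markdown": _format_markdown}


def write_report(result: SweepResult, format: str, path: Optional[str] = None) -> str:
    """Render (and optionally write) the sweep in a bit-stable format."""
    try:
        text = _FORMATTERS[format](result)
    except KeyError:
        raise ValueError(
            f"unknown format {format!r}; expected one of {sorted(_FORMATTERS)}"
        ) from None
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def compare_to_printed(
    result: SweepResult, printed: Optional[Sequence[PrintedCell]] = None
) -> pd.DataFrame:
    """Per-cell comparison of the sweep against the published reference grid.

    Returns a frame with the model IOP, the published value, their absolute
    difference, the reference's cfd_noise annotation, and a ``flagged``
    column marking cells that deviate by more than 0.5 mmHg.  Summary
    quantiles are attached as ``DataFrame.attrs['summary']``.
    """
    if printed is None:
        printed = REFERENCE_CELLS
    cols = ["device", "pg_mmHg", "pb_mmHg", "pc_model", "pc_printed",
            "abs_diff", "cfd_noise", "flagged"]
    if len(printed) == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs["summary"] = {}
        return out
    indexed = result.table.set_index(["device", "pg_mmHg", "pb_mmHg"])
    rows = []
    for cell in printed:
        key = (cell.device, float(cell.p_g), float(cell.p_b))
        try:
            model_pc = float(indexed.loc[key, "pc_mmHg"])
        except KeyError:
            raise ValueError(
                f"reference cell {key} is not covered by the sweep result"
            ) from None
        diff = abs(model_pc - cell.p_c)
        rows.append(
            dict(device=cell.device, pg_mmHg=cell.p_g, pb_mmHg=cell.p_b,
                 pc_model=model_pc, pc_printed=cell.p_c, abs_diff=diff,
                 cfd_noise=cell.cfd_noise, flagged=diff > 0.5)
        )
    out = pd.DataFrame(rows, columns=cols)
    out.attrs["summary"] = {
        "n_cells": len(out),
        "n_flagged": int(out["flagged"].sum()),
        "max_abs_diff": float(out["abs_diff"].max()),
        "quantiles_mmHg": {
            q: float(out["abs_diff"].quantile(q)) for q in (0.5, 0.9, 1.0)
        },
        "max_abs_diff_concordant": float(
            out.loc[~out["cfd_noise"], "abs_diff"].max()
        ) if (~out["cfd_noise"]).any() else float("nan"),
    }
    return out
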