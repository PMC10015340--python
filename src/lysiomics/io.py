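"""Delimited-text readers/writers for the pipeline's tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate.counts import SampleDesign
from .simulate.lysimeter import IrrigationPolicy, LysimeterSeries, SoilPotSpec

_EPOCH = pd.Timestamp("2019-10-15 00:00:00")  # nominal experiment start


def write_lysimeter_csv(series: LysimeterSeries, path) -> None:
    """Long-format CSV: pot, ISO timestamp, weight_g, vwc, vpd_kpa, par, irrigation_g."""
    ts = _EPOCH + pd.to_timedelta(series.hours, unit="h")
    irr = np.zeros(len(series.hours))
    for (h, v) in series.irrigation_events:
        idx = int(np.argmin(np.abs(series.hours - h)))
        irr[idx] += v
    pd.DataFrame({
        "pot": series.pot_id,
        "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S"),
        "weight_g": series.weight_g,
        "vwc": series.vwc,
        "vpd_kpa": series.vpd,
        "par": series.par,
        "irrigation_g": irr,
    }).to_csv(path, index=False)


def read_lysimeter_csv(path, policy: IrrigationPolicy | None = None,
                       pot: SoilPotSpec | None = None) -> LysimeterSeries:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    hours = (df["timestamp"] - df["timestamp"].iloc[0]).dt.total_seconds().to_numpy() / 3600.0
    res_min = float(np.round((hours[1] - hours[0]) * 60, 6))
    events = [(float(h), float(v)) for h, v in
              zip(hours[df["irrigation_g"] > 0], df.loc[df["irrigation_g"] > 0, "irrigation_g"])]
    return LysimeterSeries(
        pot_id=str(df["pot"].iloc[0]), species="", group="",
        hours=hours, weight_g=df["weight_g"].to_numpy(),
        vwc=df["vwc"].to_numpy(), vpd=df["vpd_kpa"].to_numpy(),
        par=df["par"].to_numpy(), light=df["par"].to_numpy() > 0,
        irrigation_events=events, resolution_min=res_min,
        policy=policy or IrrigationPolicy(), pot=pot or SoilPotSpec())


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_design_tsv(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_design_tsv(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t"))


def write_run_config(params: dict, path) -> None:
    """Echo generation parameters to JSON for provenance."""
    def _clean(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, np.ndarray):
            return v.tolist()
        if hasattr(v, "__dict__"):
            return {k: _clean(x) for k, x in vars(v).items()
                    if not isinstance(x, (np.ndarray, pd.DataFrame, pd.Series))}
        if isinstance(v, dict):
            return {k: _clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [_clean(x) for x in v]
        return v
    Path(path).write_text(json.dumps(_clean(params), indent=2, default=str))
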