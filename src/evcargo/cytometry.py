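"""Dead-cell gating of two-channel cytometry event tables.

The gate mirrors the viability assay: only Hoechst-positive events (nucleated
cells) enter the denominator; events positive in both the Hoechst and
YO-PRO-1 channels are scored dead.  "Positive" is strictly greater than the
channel threshold.  Thresholds are plain scalars; the defaults sit in the
valley between the synthetic generator's debris/live/dead populations
(log-normal mixtures), standing in for PMT gates set on single-stain
controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


class GateError(ValueError):
    """Gating cannot produce a defined percentage."""


@dataclass(frozen=True)
class GateConfig:
    hoechst_threshold: float = 1000.0
    yopro_threshold: float = 500.0

    def __post_init__(self) -> None:
        for v in (self.hoechst_threshold, self.yopro_threshold):
            if not (v > 0 and v < float("inf")):
                raise GateError("thresholds must be finite and positive")


DEFAULT_GATE = GateConfig()


@dataclass(frozen=True)
class DeathResult:
    condition: str
    n_events: int
    n_hoechst_pos: int
    n_double_pos: int

    @property
    def percent_dead(self) -> float:
        return 100.0 * self.n_double_pos / self.n_hoechst_pos


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"hoechst", "yopro"} - set(df.columns)
    if missing:
        raise GateError(f"{path}: missing channel column(s) {sorted(missing)}")
    return df


def gate(
    events: pd.DataFrame,
    config: GateConfig = DEFAULT_GATE,
    condition: str = "condition",
) -> DeathResult:
    """Score dead cells: double-positive / Hoechst-positive * 100."""
    hoechst = pd.to_numeric(events["hoechst"])
    yopro = pd.to_numeric(events["yopro"])
    h_pos = hoechst > config.hoechst_threshold
    double = h_pos & (yopro > config.yopro_threshold)
    n_h = int(h_pos.sum())
    if n_h == 0:
        raise GateError(f"{condition}: no Hoechst-positive events; percent undefined")
    return DeathResult(condition, len(events), n_h, int(double.sum()))


def compare_conditions(
    results: dict[str, DeathResult] | list[DeathResult],
    baseline: str,
) -> pd.DataFrame:
    """Per-condition percent dead, difference from baseline, and ratio to
    baseline (net increase normalised to the mock/untreated control)."""
    if isinstance(results, list):
        results = {r.condition: r for r in results}
    if baseline not in results:
        raise KeyError(f"baseline condition {baseline!r} missing")
    base = results[baseline].percent_dead
    rows = []
    for name, res in results.items():
        pct = res.percent_dead
        rows.append(
            {
                "condition": name,
                "percent_dead": pct,
                "difference_vs_baseline": pct - base,
                "ratio_vs_baseline": pct / base if base else float("inf"),
            }
        )
    return pd.DataFrame(
        rows, columns=["condition", "percent_dead", "difference_vs_baseline", "ratio_vs_baseline"]
    )


def dose_response(
    series: list[tuple[float, DeathResult]],
) -> tuple[pd.DataFrame, bool]:
    """Ordered dose table plus a monotonicity flag (non-decreasing percent
    dead with dose; reported, not enforced)."""
    if len(series) < 2:
        raise ValueError("need at least two doses")
    doses = [d for d, _r in series]
    if len(set(doses)) != len(doses):
        raise ValueError("duplicate dose values")
    ordered = sorted(series, key=lambda x: x[0])
    rows = [
        {
            "dose_pmol": d,
            "percent_dead": r.percent_dead,
            "n_events": r.n_events,
            "n_hoechst_pos": r.n_hoechst_pos,
            "n_double_pos": r.n_double_pos,
        }
        for d, r in ordered
    ]
    pct = [row["percent_dead"] for row in rows]
    monotone = all(b >= a for a, b in zip(pct, pct[1:]))
    return pd.DataFrame(rows), monotone


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class EvDose:
    """EVs delivered per recipient cell."""

    ev_yield: float
    recipient_cells: float

    @property
    def exact(self) -> float:
        return self.ev_yield / self.recipient_cells

    def reported(self, sig: int = 2) -> float:
        return round_sig(self.exact, sig)


def ev_dose(ev_yield: float, recipient_cells: float) -> EvDose:
    """EVs per treated cell, e.g. 4.8e9 EVs onto 2e5 cells -> 24,000."""
    if ev_yield <= 0 or recipient_cells <= 0:
        raise ValueError("yield and recipient count must be positive")
    return EvDose(ev_yield, recipient_cells)
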