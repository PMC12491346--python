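"""One-way deterministic sensitivity analysis and tornado tables.

One chance node is swept across an interval while every other input stays
at its base value; effectiveness (incremental effectiveness for the
two-strategy model) and the corresponding ICER/CER are recomputed at both
endpoints *through the same code path as the base case* — there is no
separate sensitivity evaluator.

Endpoints above 1 are legal and flagged ``theoretical`` (they arise when a
node whose base value is 1 is pushed upward); they are never clamped.
Endpoints where the effectiveness or the ratio is undefined carry an
explicit marker instead of a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import ModelSpec
from .errors import (
    ConfigError,
    UndefinedEffectivenessError,
    UndefinedRatioError,
    ValidationError,
)

__all__ = ["DsaInterval", "DsaRow", "one_way", "tornado_table", "default_intervals", "rows_to_frame", "tornado_plot"]


@dataclass(frozen=True)
class DsaInterval:
    """Sweep interval for one chance node (low > 0; high may exceed 1)."""

    node_id: str
    low: Real
    high: Real

    def __post_init__(self):
        if not self.low > 0:
            raise ValidationError(f"{self.node_id}: interval low must be > 0")
        if self.low > self.high:
            raise ValidationError(f"{self.node_id}: need low <= high")


@dataclass(frozen=True)
class DsaRow:
    """One-way result for one node: effectiveness and ratio at both endpoints.

    ``eff_*`` is the model's headline effectiveness (incremental
    effectiveness for a two-strategy model, plain effectiveness
    otherwise).  ``None`` in an ``eff``/``ratio`` slot means the quantity
    is undefined at that endpoint.  ``width`` is the absolute ratio range
    over the defined endpoints (the tornado bar length).
    """

    node_id: str
    low: Real
    high: Real
    eff_low: Real | None
    eff_high: Real | None
    ratio_low: Real | None
    ratio_high: Real | None
    width: Real
    theoretical: bool

    @property
    def undefined(self) -> bool:
        return None in (self.eff_low, self.eff_high, self.ratio_low, self.ratio_high)


def _evaluate_endpoint(spec: ModelSpec, node_id: str, value: Real):
    """(headline effectiveness, ratio, theoretical) at one endpoint."""
    varied = spec.with_node(node_id, value)
    try:
        result = varied.base_effectiveness()
        eff = result.incremental if varied.is_incremental else result.eff_by_strategy[varied.strategy_ids[0]]
    except UndefinedEffectivenessError:
        return None, None, not (0 <= value <= 1)
    try:
        ratio = varied.base_ratio()
    except UndefinedRatioError:
        ratio = None
    theoretical = result.theoretical or not (0 <= value <= 1)
    return eff, ratio, theoretical


def one_way(spec: ModelSpec, interval: DsaInterval) -> DsaRow:
    """Sweep one node over ``interval`` with all other inputs at base values."""
    if interval.node_id not in spec.nodes.values:
        raise ConfigError(f"model {spec.model_id} has no node {interval.node_id!r}")
    eff_lo, ratio_lo, theo_lo = _evaluate_endpoint(spec, interval.node_id, interval.low)
    eff_hi, ratio_hi, theo_hi = _evaluate_endpoint(spec, interval.node_id, interval.high)
    defined = [r for r in (ratio_lo, ratio_hi) if r is not None]
    width = abs(max(defined) - min(defined)) if len(defined) == 2 else 0
    return DsaRow(
        node_id=interval.node_id,
        low=interval.low,
        high=interval.high,
        eff_low=eff_lo,
        eff_high=eff_hi,
        ratio_low=ratio_lo,
        ratio_high=ratio_hi,
        width=width,
        theoretical=theo_lo or theo_hi,
    )


def tornado_table(spec: ModelSpec, intervals: Sequence[DsaInterval]) -> list[DsaRow]:
    """One-way rows sorted by descending ratio width (ties: node order)."""
    ids = [iv.node_id for iv in intervals]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ConfigError(f"duplicate node_id in DSA intervals: {dupes}")
    node_order = {n: i for i, n in enumerate(spec.nodes.node_ids)}
    rows = [one_way(spec, iv) for iv in intervals]
    return sorted(rows, key=lambda r: (-r.width, node_order[r.node_id]))


def default_intervals(spec: ModelSpec) -> list[DsaInterval]:
    """The intervals declared in the model spec's ``dsa`` block."""
    return [DsaInterval(node_id=n, low=lo, high=hi) for n, (lo, hi) in spec.dsa_bounds.items()]


def rows_to_frame(spec: ModelSpec, rows: Iterable[DsaRow]) -> pd.DataFrame:
    """Flat export table; base-case values echoed on every row."""
    base = spec.base_effectiveness()
    base_eff = base.incremental if spec.is_incremental else base.eff_by_strategy[spec.strategy_ids[0]]
    base_ratio = float(spec.base_ratio())
    out = []
    for r in rows:
        out.append(
            {
                "node_id": r.node_id,
                "low": float(r.low),
                "high": float(r.high),
                "eff_low": None if r.eff_low is None else float(r.eff_low),
                "eff_high": None if r.eff_high is None else float(r.eff_high),
                "ratio_low": None if r.ratio_low is None else float(r.ratio_low),
                "ratio_high": None if r.ratio_high is None else float(r.ratio_high),
                "width": float(r.width),
                "theoretical": r.theoretical,
                "undefined": r.undefined,
                "base_eff": float(base_eff),
                "base_ratio": base_ratio,
                "ratio_kind": spec.ratio_kind,
            }
        )
    return pd.DataFrame(out)


def tornado_plot(spec: ModelSpec, rows: Sequence[DsaRow], path: str | Path) -> Path:
    """Horizontal-bar tornado diagram with the base-case ratio marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    base_ratio = float(spec.base_ratio())
    plotted = [r for r in rows if not r.undefined]
    fig, ax = plt.subplots(figsize=(7, 0.6 * max(len(plotted), 3) + 1.2))
    labels, lefts, widths, colors = [], [], [], []
    for r in reversed(plotted):  # widest on top
        lo, hi = sorted((float(r.ratio_low), float(r.ratio_high)))
        labels.append(f"{r.node_id}{'*' if r.theoretical else ''}")
        lefts.append(lo)
        widths.append(hi - lo if hi > lo else base_ratio * 0.002)
        colors.append("#c44e52" if r.theoretical else "#4c72b0")
    ax.barh(labels, widths, left=lefts, color=colors, height=0.6)
    ax.axvline(base_ratio, color="black", lw=1, ls="--", label=f"base {spec.ratio_kind}")
    ax.set_xlabel(f"{spec.ratio_kind} (EUR per correctly identified TRC lesion)")
    ax.set_title(f"{spec.label}\none-way sensitivity of the {spec.ratio_kind}")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path)
    plt.close(fig)
    return path
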