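"""Probabilistic sensitivity analysis (Monte Carlo).

Each of ``n_draws`` (default 10,000) parameter sets samples every chance
node independently from a normal distribution — mean and SD from the model
spec — conditioned on being positive by *rejection* (redraw at <= 0, never
absolute value or clipping, so the normal shape is preserved where it has
mass).  Draws above 1 are retained and flagged theoretical.  The per-lesion
imaging cost is sampled from a gamma distribution with the model's cost
mean and a coefficient of variation of 0.5 (shape 1/cv^2 = 4, scale =
mean * cv^2).

Per draw, effectiveness is computed for each strategy through the decision
tree; the two-strategy model also records the within-draw incremental
effectiveness and per-draw ICER = cost / IE (single-strategy: CER =
cost / effectiveness).  Draws whose effectiveness denominator is within
tolerance of zero are excluded and counted; more than 1% exclusions is an
error.  The headline "mean ICER/CER" is the ratio of means
(mean cost / mean effectiveness); the mean of per-draw ratios is reported
alongside but is unstable whenever the denominator can approach zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ModelSpec
from .errors import PsaError, RejectionBudgetError, ValidationError
from .tree_model import STRATEGIES

__all__ = [
    "PsaConfig",
    "PsaSummary",
    "PsaResult",
    "draw_node_value",
    "draw_cost",
    "run_psa",
    "summarize_draws",
]

#: Summary statistics, in report order.
_STATS = ("mean", "sd", "minimum", "p2.5", "p10", "median", "p90", "p97.5", "maximum")
_PERCENTILES = {"p2.5": 2.5, "p10": 10.0, "median": 50.0, "p90": 90.0, "p97.5": 97.5}

_STRATEGY_NODES = {
    ("model1", "combined"): ("N1", "N3", "N4"),
    ("model1", "reference"): ("N2", "N5", "N6"),
    ("model2", "pet"): ("N1", "N2", "N3"),
}


@dataclass(frozen=True)
class PsaConfig:
    """Monte Carlo settings (defaults mirror the published analysis)."""

    seed: int
    n_draws: int = 10_000
    cost_cv: float | None = None  # None: take the model spec's value (0.5)
    denom_tol: float = 1e-9
    max_excluded_frac: float = 0.01
    max_rejection_rounds: int = 1000

    def __post_init__(self):
        if self.n_draws < 1:
            raise ValidationError("n_draws must be >= 1")
        if self.cost_cv is not None and self.cost_cv <= 0:
            raise ValidationError("cost_cv must be > 0")


@dataclass(frozen=True)
class PsaSummary:
    """Per-quantity Monte Carlo statistics plus headline ratios.

    ``table`` has one row per statistic (mean, sd, minimum, percentiles,
    maximum) and one column per quantity (per-strategy effectiveness,
    incremental effectiveness, cost).  ``summary_ratio`` is the
    paper-compatible ratio of means; ``mean_of_ratios`` averages the
    per-draw ratios over draws where they are defined.
    """

    model_id: str
    table: pd.DataFrame
    ratio_kind: str
    summary_ratio: float
    mean_of_ratios: float
    n_draws: int
    n_excluded: int
    n_ratio_undefined: int
    theoretical_fraction: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class PsaResult:
    draws: pd.DataFrame
    summary: PsaSummary
    config: PsaConfig


def _truncated_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator, max_rounds: int
) -> np.ndarray:
    """Normal(mean, sd) conditioned on > 0 by rejection; sd == 0 returns the mean."""
    if mean <= 0:
        raise ValidationError(f"truncated-normal mean must be > 0, got {mean}")
    if sd == 0:
        return np.full(size, float(mean))
    x = rng.normal(mean, sd, size)
    for _ in range(max_rounds):
        bad = x <= 0
        if not bad.any():
            return x
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise RejectionBudgetError(
        f"positive-truncation rejection budget exhausted for Normal({mean}, {sd})"
    )


def draw_node_value(
    mean: float, sd: float, rng: np.random.Generator, *, max_rounds: int = 1000
) -> float:
    """One positive chance-node draw; values above 1 are permitted."""
    return float(_truncated_normal(mean, sd, 1, rng, max_rounds)[0])


def draw_cost(mean: float, cv: float, rng: np.random.Generator, size: int | None = None):
    """Gamma cost draw(s): shape 1/cv^2, scale mean*cv^2 (strictly positive)."""
    mean = float(mean)
    if mean <= 0:
        raise ValidationError(f"cost mean must be > 0, got {mean}")
    if cv <= 0:
        raise ValidationError(f"cost cv must be > 0, got {cv}")
    shape = 1.0 / cv**2
    scale = mean * cv**2
    out = rng.gamma(shape, scale, size=size)
    return float(out) if size is None else out


def _effectiveness(p_rated, p_conf_rel, p_conf_trc, tol):
    num = (1.0 - p_rated) * p_conf_trc
    den = p_rated * (1.0 - p_conf_rel) + num
    valid = np.abs(den) >= tol
    eff = np.divide(num, den, out=np.full_like(den, np.nan), where=valid)
    return eff, valid


def run_psa(spec: ModelSpec, config: PsaConfig) -> PsaResult:
    """Full Monte Carlo analysis of one model.

    Node draw order is the model's canonical node order, then the cost, so
    a fixed seed reproduces the draw table bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_draws
    cv = spec.cost_cv if config.cost_cv is None else config.cost_cv

    node_draws = {
        node: _truncated_normal(
            float(spec.psa_means[node]),
            float(spec.nodes.sds[node]),
            n,
            rng,
            config.max_rejection_rounds,
        )
        for node in spec.nodes.node_ids
    }
    cost = draw_cost(float(spec.psa_cost_mean), cv, rng, size=n)

    strategies = STRATEGIES[spec.model_id]
    eff_cols: dict[str, np.ndarray] = {}
    valid = np.ones(n, dtype=bool)
    for strat in strategies:
        rating, conf_rel, conf_trc = _STRATEGY_NODES[(spec.model_id, strat)]
        eff, ok = _effectiveness(
            node_draws[rating], node_draws[conf_rel], node_draws[conf_trc], config.denom_tol
        )
        eff_cols[f"eff_{strat}"] = eff
        valid &= ok

    n_excluded = int((~valid).sum())
    if n_excluded > config.max_excluded_frac * n:
        raise PsaError(
            f"{n_excluded}/{n} draws had a near-zero effectiveness denominator "
            f"(> {config.max_excluded_frac:.0%} allowed); the model is degenerate"
        )

    table = pd.DataFrame({node.lower(): node_draws[node] for node in spec.nodes.node_ids})
    for col, eff in eff_cols.items():
        table[col] = eff
    if spec.is_incremental:
        first, second = strategies
        table["ie"] = table[f"eff_{first}"] - table[f"eff_{second}"]
        denom = table["ie"].to_numpy()
    else:
        denom = table[f"eff_{strategies[0]}"].to_numpy()
    table["cost_eur"] = cost
    ratio_ok = valid & (np.abs(denom) >= config.denom_tol)
    table["ratio"] = np.divide(cost, denom, out=np.full(n, np.nan), where=ratio_ok)
    eff_names = [f"eff_{s}" for s in strategies]
    table["theoretical"] = (table[eff_names] > 1).any(axis=1) | (table[eff_names] < 0).any(axis=1)

    table = table.loc[valid].reset_index(drop=True)
    n_ratio_undefined = int(table["ratio"].isna().sum())

    summary = summarize_draws(
        table,
        model_id=spec.model_id,
        ratio_kind=spec.ratio_kind,
        n_excluded=n_excluded,
    )
    return PsaResult(draws=table, summary=summary, config=config)


def summarize_draws(
    draws: pd.DataFrame,
    *,
    model_id: str,
    ratio_kind: str = "CER",
    n_excluded: int = 0,
) -> PsaSummary:
    """Exact order statistics (linear-interpolation percentiles) per quantity."""
    if len(draws) == 0:
        raise PsaError("no valid draws to summarize")
    strategies = STRATEGIES[model_id]
    quantities = [f"eff_{s}" for s in strategies[::-1]]  # comparator first, as published
    if "ie" in draws.columns:
        quantities.append("ie")
    quantities.append("cost_eur")

    stats = {}
    for q in quantities:
        x = draws[q].to_numpy(dtype=float)
        col = {
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            "minimum": float(np.min(x)),
            "maximum": float(np.max(x)),
        }
        for name, pct in _PERCENTILES.items():
            col[name] = float(np.percentile(x, pct))  # linear interpolation
        stats[q] = col
    table = pd.DataFrame(stats).reindex(index=list(_STATS))

    denom_col = "ie" if "ie" in draws.columns else f"eff_{strategies[0]}"
    mean_denom = float(draws[denom_col].mean())
    summary_ratio = float(draws["cost_eur"].mean()) / mean_denom if mean_denom != 0 else float("nan")
    ratios = draws["ratio"].to_numpy(dtype=float)
    mean_of_ratios = float(np.nanmean(ratios)) if np.isfinite(ratios).any() else float("nan")

    theoretical_fraction = {
        f"eff_{s}": float(((draws[f"eff_{s}"] > 1) | (draws[f"eff_{s}"] < 0)).mean())
        for s in strategies
    }
    return PsaSummary(
        model_id=model_id,
        table=table,
        ratio_kind=ratio_kind,
        summary_ratio=summary_ratio,
        mean_of_ratios=mean_of_ratios,
        n_draws=len(draws) + n_excluded,
        n_excluded=n_excluded,
        n_ratio_undefined=int(draws["ratio"].isna().sum()),
        theoretical_fraction=theoretical_fraction,
    )


def scatter_plot(result: PsaResult, spec: ModelSpec, path: str | Path) -> Path:
    """Effectiveness-vs-cost scatter of the Monte Carlo draws."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    eff_col = "ie" if spec.is_incremental else f"eff_{spec.strategy_ids[0]}"
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.draws[eff_col] * 100, result.draws["cost_eur"], s=4, alpha=0.25, rasterized=True)
    ax.set_xlabel(("incremental " if spec.is_incremental else "") + "effectiveness (%)")
    ax.set_ylabel("per-lesion PET imaging cost (EUR)")
    ax.set_title(f"{spec.label}\nMonte Carlo draws (n={len(result.draws)})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
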