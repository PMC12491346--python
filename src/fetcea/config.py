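"""Model specification files: chance nodes, sensitivity bounds, itemized costs.

A model spec is a YAML (or JSON — YAML is a superset) mapping with blocks
``nodes``, ``dsa``, ``costs`` and ``psa``.  Probabilities may be written as
exact count ratios (``"54/83"``) or decimals; fee amounts are strings
parsed as exact decimals.  The two bundled specs, ``model1.yaml`` and
``model2.yaml``, encode the published base cases:

* ``model1`` — PET+MRI vs MRI alone, 83 lesions / 92 scans;
* ``model2`` — PET alone after suspicious routine MRI, 22 lesions.

Each node carries its base ``value`` (canonical count ratio), the Monte
Carlo ``sd``, an optional ``psa_mean`` (the published rounded percentage,
used by the probabilistic analysis when present), and a one-way
sensitivity interval given either explicitly (``low``/``high``) or as a
half-width ``delta`` around the base value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from decimal import Decimal
from fractions import Fraction
from importlib import resources
from numbers import Real
from pathlib import Path
from typing import Mapping

import yaml

from .cost_model import CostProfile, FeeItem, cer, icer, per_lesion_cost, scan_cost
from .errors import ConfigError
from .tree_model import (
    MODEL_NODES,
    STRATEGIES,
    EffectivenessResult,
    NodeProbabilities,
    evaluate_model,
)

__all__ = ["ModelSpec", "load_model_spec", "packaged_model_path", "config_hash"]


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified decision-tree model: nodes, DSA bounds, costs."""

    model_id: str
    label: str
    nodes: NodeProbabilities
    psa_means: Mapping[str, float]
    dsa_bounds: Mapping[str, tuple[Real, Real]]
    cost_profile: CostProfile
    strategy_modalities: Mapping[str, tuple[str, ...]]
    strategy_labels: Mapping[str, str]
    cost_cv: float = 0.5

    # -- structure ------------------------------------------------------------

    @property
    def strategy_ids(self) -> tuple[str, ...]:
        return STRATEGIES[self.model_id]

    @property
    def is_incremental(self) -> bool:
        """True when the model compares two strategies (ICER), else CER."""
        return len(self.strategy_ids) == 2

    @property
    def ratio_kind(self) -> str:
        return "ICER" if self.is_incremental else "CER"

    def with_node(self, node_id: str, value: Real) -> "ModelSpec":
        """Copy with one chance node replaced (sensitivity context)."""
        return replace(self, nodes=self.nodes.with_value(node_id, value))

    # -- effectiveness ---------------------------------------------------------

    def base_effectiveness(self) -> EffectivenessResult:
        return evaluate_model(self.nodes)

    # -- costs -----------------------------------------------------------------

    def scan_cost(self, strategy: str) -> Decimal:
        items = []
        for modality in self.strategy_modalities[strategy]:
            items.extend(self.cost_profile.items_by_modality[modality])
        return scan_cost(items)

    def lesion_cost(self, strategy: str):
        return per_lesion_cost(
            self.scan_cost(strategy), self.cost_profile.n_scans, self.cost_profile.n_lesions
        )

    def incremental_cost(self):
        """Per-lesion cost difference, index strategy minus comparator."""
        first, second = self.strategy_ids
        return self.lesion_cost(first) - self.lesion_cost(second)

    @property
    def psa_cost_mean(self):
        """Gamma mean for the Monte Carlo cost draw: the per-lesion cost of
        the additional PET (incremental models) or of the single strategy."""
        if self.is_incremental:
            return self.incremental_cost()
        return self.lesion_cost(self.strategy_ids[0])

    def base_ratio(self):
        """Base-case ICER (two strategies) or CER (single strategy), exact."""
        result = self.base_effectiveness()
        if self.is_incremental:
            first, second = self.strategy_ids
            return icer(self.lesion_cost(first), self.lesion_cost(second), result.incremental)
        return cer(self.lesion_cost(self.strategy_ids[0]), result.eff_by_strategy[self.strategy_ids[0]])


# --- parsing ------------------------------------------------------------------

def _parse_prob(value, where: str) -> Fraction:
    try:
        if isinstance(value, str) and "/" in value:
            num, den = value.split("/")
            return Fraction(int(num), int(den))
        return Fraction(str(value))
    except (ValueError, ZeroDivisionError) as exc:
        raise ConfigError(f"{where}: cannot parse probability {value!r} ({exc})") from None


def _require(mapping, key, where: str):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ConfigError(f"{where}.{key}: missing required field")
    return mapping[key]


def load_model_spec(path: str | Path) -> ModelSpec:
    """Parse and validate a model specification file.

    Raises :class:`~fetcea.errors.ConfigError` naming the offending field
    path on any schema violation.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")

    model_id = _require(raw, "model", str(path))
    if model_id not in MODEL_NODES:
        raise ConfigError(f"model: unknown model {model_id!r}; expected one of {list(MODEL_NODES)}")
    label = raw.get("label", model_id)

    nodes_raw = _require(raw, "nodes", "")
    values: dict[str, Fraction] = {}
    sds: dict[str, float] = {}
    psa_means: dict[str, float] = {}
    for node in MODEL_NODES[model_id]:
        if node not in nodes_raw:
            raise ConfigError(f"nodes.{node}: missing required node for {model_id}")
        entry = nodes_raw[node]
        values[node] = _parse_prob(_require(entry, "value", f"nodes.{node}"), f"nodes.{node}.value")
        sd = float(_require(entry, "sd", f"nodes.{node}"))
        if sd < 0:
            raise ConfigError(f"nodes.{node}.sd: must be non-negative")
        sds[node] = sd
        psa_means[node] = float(entry.get("psa_mean", values[node]))
    extra = sorted(set(nodes_raw) - set(MODEL_NODES[model_id]))
    if extra:
        raise ConfigError(f"nodes: unexpected node(s) {extra} for {model_id}")
    nodes = NodeProbabilities(model_id=model_id, values=values, sds=sds)

    dsa_raw = raw.get("dsa", {})
    dsa_bounds: dict[str, tuple[Real, Real]] = {}
    for node, entry in dsa_raw.items():
        if node not in values:
            raise ConfigError(f"dsa.{node}: {model_id} has no such node")
        if "delta" in entry:
            delta = _parse_prob(entry["delta"], f"dsa.{node}.delta")
            low, high = values[node] - delta, values[node] + delta
        else:
            low = _parse_prob(_require(entry, "low", f"dsa.{node}"), f"dsa.{node}.low")
            high = _parse_prob(_require(entry, "high", f"dsa.{node}"), f"dsa.{node}.high")
        if not (0 < low <= high):
            raise ConfigError(f"dsa.{node}: need 0 < low <= high, got [{float(low)}, {float(high)}]")
        dsa_bounds[node] = (low, high)

    costs_raw = _require(raw, "costs", "")
    cohort = _require(costs_raw, "cohort", "costs")
    n_lesions = int(_require(cohort, "n_lesions", "costs.cohort"))
    n_scans = int(_require(cohort, "n_scans", "costs.cohort"))
    modalities_raw = _require(costs_raw, "modalities", "costs")
    items_by_modality = {}
    for modality, items in modalities_raw.items():
        parsed = []
        for i, item in enumerate(items):
            where = f"costs.modalities.{modality}[{i}]"
            parsed.append(
                FeeItem(
                    code=str(_require(item, "code", where)),
                    label=str(_require(item, "label", where)),
                    amount=Decimal(str(_require(item, "amount_eur", where))),
                )
            )
        items_by_modality[modality] = tuple(parsed)
    profile = CostProfile(items_by_modality=items_by_modality, n_scans=n_scans, n_lesions=n_lesions)

    strategies_raw = _require(costs_raw, "strategies", "costs")
    expected = STRATEGIES[model_id]
    if set(strategies_raw) != set(expected):
        raise ConfigError(
            f"costs.strategies: {model_id} requires exactly {sorted(expected)}, got {sorted(strategies_raw)}"
        )
    strategy_modalities = {}
    strategy_labels = {}
    for strat, entry in strategies_raw.items():
        mods = tuple(_require(entry, "modalities", f"costs.strategies.{strat}"))
        unknown = [m for m in mods if m not in items_by_modality]
        if unknown:
            raise ConfigError(f"costs.strategies.{strat}.modalities: unknown modality {unknown}")
        strategy_modalities[strat] = mods
        strategy_labels[strat] = str(entry.get("label", strat))

    cost_cv = float(raw.get("psa", {}).get("cost_cv", 0.5))
    if cost_cv <= 0:
        raise ConfigError("psa.cost_cv: must be > 0")

    return ModelSpec(
        model_id=model_id,
        label=label,
        nodes=nodes,
        psa_means=psa_means,
        dsa_bounds=dsa_bounds,
        cost_profile=profile,
        strategy_modalities=strategy_modalities,
        strategy_labels=strategy_labels,
        cost_cv=cost_cv,
    )


def packaged_model_path(name: str) -> Path:
    """Path of a bundled model spec, e.g. ``packaged_model_path("model1")``."""
    ref = resources.files("fetcea").joinpath("data", f"{name}.yaml")
    with resources.as_file(ref) as p:
        return Path(p)


def config_hash(path: str | Path) -> str:
    """SHA-256 of the raw config file bytes (stable across runs)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
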