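"""Decision-tree structures and the effectiveness statistic.

Two diagnostic decision trees for pretreated pediatric CNS tumor lesions:

* ``model1`` — simultaneous [18F]FET PET + MRI (``combined``) versus MRI
  alone (``reference``), six chance nodes N1–N6.
* ``model2`` — FET PET alone after a routine MRI suspicious for relapse
  (``pet``), three chance nodes N1–N3.

Rating nodes give the probability that a lesion is *rated* tumor relapse
(model1 N1: combined reading, N2: MRI reading; model2 N1: PET reading).
Confirmation nodes give the probability that the rating is confirmed by
neuropathology or clinicoradiological follow-up (model1 N3/N4 for the
combined arm's relapse/TRC calls, N5/N6 for the MRI arm's; model2 N2/N3).

The primary outcome ("effectiveness") is the probability that a lesion with
*confirmed* treatment-related changes (TRC) is correctly rated TRC — i.e.
recall on the confirmed-TRC stratum:

    eff = (1 - p_rated) * p_conf_trc
          -----------------------------------------------
          p_rated * (1 - p_conf_rel) + (1 - p_rated) * p_conf_trc

The numerator is the tree mass of lesions rated TRC and confirmed TRC; the
denominator adds the lesions rated relapse whose confirmation *failed*
(confirmed TRC despite a relapse call).  When every relapse call is
confirmed (p_conf_rel = 1) the statistic is identically 1, whatever the
rating split — which is why varying the rating node leaves a perfect
strategy's result unchanged.

All arithmetic is type-generic: feed :class:`fractions.Fraction` count
ratios and every result is an exact rational; feed floats and you get
floats.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from fractions import Fraction
from numbers import Real
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigError,
    NodeEstimationError,
    UndefinedEffectivenessError,
    ValidationError,
)

__all__ = [
    "Diagnosis",
    "MODEL_NODES",
    "STRATEGIES",
    "LesionRecord",
    "LesionDataset",
    "NodeProbabilities",
    "EffectivenessResult",
    "trc_identification_rate",
    "evaluate_model",
    "estimate_node",
    "estimate_nodes",
]


class Diagnosis(str, enum.Enum):
    """The two-level diagnosis used for ratings and confirmed outcomes."""

    RELAPSE = "relapse"
    TRC = "trc"  # treatment-related changes


#: Chance nodes per model, in canonical order.
MODEL_NODES: Mapping[str, tuple[str, ...]] = {
    "model1": ("N1", "N2", "N3", "N4", "N5", "N6"),
    "model2": ("N1", "N2", "N3"),
}

#: Strategy identifiers per model.  For ``model1`` the first entry is the
#: index strategy (PET+MRI) and the second the comparator (MRI alone).
STRATEGIES: Mapping[str, tuple[str, ...]] = {
    "model1": ("combined", "reference"),
    "model2": ("pet",),
}

#: (rating node, relapse-confirmation node, TRC-confirmation node) triple
#: feeding the effectiveness statistic, per model and strategy.
_STRATEGY_NODES: Mapping[tuple[str, str], tuple[str, str, str]] = {
    ("model1", "combined"): ("N1", "N3", "N4"),
    ("model1", "reference"): ("N2", "N5", "N6"),
    ("model2", "pet"): ("N1", "N2", "N3"),
}

_DENOM_TOL = 1e-12


def _as_diagnosis(value) -> Diagnosis:
    if isinstance(value, Diagnosis):
        return value
    try:
        return Diagnosis(str(value).strip().lower())
    except ValueError:
        raise ValidationError(
            f"diagnosis must be one of {[d.value for d in Diagnosis]}, got {value!r}"
        ) from None


@dataclass(frozen=True)
class LesionRecord:
    """One lesion: imaging rating(s), confirmed diagnosis, scans performed."""

    lesion_id: str
    confirmed: Diagnosis
    rating_combined: Diagnosis | None = None
    rating_reference: Diagnosis | None = None
    n_scans: int = 1

    def __post_init__(self):
        object.__setattr__(self, "confirmed", _as_diagnosis(self.confirmed))
        for attr in ("rating_combined", "rating_reference"):
            v = getattr(self, attr)
            if v is not None:
                object.__setattr__(self, attr, _as_diagnosis(v))
        if self.rating_combined is None and self.rating_reference is None:
            raise ValidationError(f"lesion {self.lesion_id}: at least one rating required")
        if not isinstance(self.n_scans, int) or self.n_scans < 1:
            raise ValidationError(f"lesion {self.lesion_id}: n_scans must be a positive integer")


_COLUMNS = ("lesion_id", "rating_combined", "rating_reference", "confirmed", "n_scans")
_LEVELS = {d.value for d in Diagnosis}


class LesionDataset:
    """Lesion-level table backed by a :class:`pandas.DataFrame`.

    Columns: ``lesion_id, rating_combined, rating_reference, confirmed,
    n_scans``.  Ratings are ``"relapse"``/``"trc"`` or missing (at least one
    present per lesion); ``confirmed`` is always present; ``n_scans >= 1``.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"lesion dataset missing columns: {missing}")
        frame = frame.loc[:, list(_COLUMNS)].reset_index(drop=True)
        for col in ("rating_combined", "rating_reference", "confirmed"):
            s = frame[col].astype("string").str.strip().str.lower()
            s = s.replace("", pd.NA)
            bad = s.dropna()[~s.dropna().isin(_LEVELS)]
            if len(bad):
                raise ValidationError(f"column {col}: invalid labels {sorted(bad.unique())}")
            frame[col] = s
        if frame["confirmed"].isna().any():
            raise ValidationError("confirmed diagnosis is required for every lesion")
        if (frame["rating_combined"].isna() & frame["rating_reference"].isna()).any():
            raise ValidationError("every lesion needs at least one imaging rating")
        n_scans = pd.to_numeric(frame["n_scans"], errors="raise")
        if (n_scans < 1).any() or (n_scans != n_scans.astype(int)).any():
            raise ValidationError("n_scans must be positive integers")
        frame["n_scans"] = n_scans.astype(int)
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def n_lesions(self) -> int:
        return len(self._frame)

    @property
    def total_scans(self) -> int:
        return int(self._frame["n_scans"].sum())

    @classmethod
    def from_records(cls, records: Iterable[LesionRecord]) -> "LesionDataset":
        rows = [
            {
                "lesion_id": r.lesion_id,
                "rating_combined": None if r.rating_combined is None else r.rating_combined.value,
                "rating_reference": None if r.rating_reference is None else r.rating_reference.value,
                "confirmed": r.confirmed.value,
                "n_scans": r.n_scans,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=_COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "LesionDataset":
        frame = pd.read_csv(path, dtype={"lesion_id": str}, keep_default_na=True)
        return cls(frame)

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    def __eq__(self, other) -> bool:
        if not isinstance(other, LesionDataset):
            return NotImplemented
        return self._frame.equals(other._frame)


@dataclass(frozen=True)
class NodeProbabilities:
    """Chance-node values (and optional SDs) for one decision-tree model.

    ``context="base"`` enforces values in [0, 1].  ``context="sensitivity"``
    only requires values > 0; values above 1 are legal there and flagged
    *theoretical* (they arise when varying a node whose base value is 1).
    """

    model_id: str
    values: Mapping[str, Real]
    sds: Mapping[str, float] | None = None
    context: str = "base"

    def __post_init__(self):
        if self.model_id not in MODEL_NODES:
            raise ConfigError(f"unknown model_id {self.model_id!r}; expected one of {list(MODEL_NODES)}")
        expected = MODEL_NODES[self.model_id]
        got = tuple(self.values)
        if set(got) != set(expected):
            missing = sorted(set(expected) - set(got))
            extra = sorted(set(got) - set(expected))
            raise ConfigError(
                f"{self.model_id} nodes mismatch: missing {missing}, unexpected {extra}"
            )
        object.__setattr__(self, "values", dict(sorted(self.values.items())))
        if self.sds is not None:
            if set(self.sds) != set(expected):
                raise ConfigError(f"{self.model_id} sds keys must match nodes {expected}")
            if any(sd < 0 for sd in self.sds.values()):
                raise ConfigError("node SDs must be non-negative")
            object.__setattr__(self, "sds", dict(sorted(self.sds.items())))
        for node, v in self.values.items():
            if self.context == "base":
                if not (0 <= v <= 1):
                    raise ConfigError(
                        f"nodes.{node}.value: base-case probability must lie in [0, 1], got {float(v)}"
                    )
            else:
                if not v > 0:
                    raise ConfigError(
                        f"nodes.{node}.value: sensitivity value must be > 0, got {float(v)}"
                    )

    @property
    def node_ids(self) -> tuple[str, ...]:
        return MODEL_NODES[self.model_id]

    @property
    def theoretical_nodes(self) -> tuple[str, ...]:
        """Nodes whose value exceeds 1 (possible only outside the base case)."""
        return tuple(n for n in self.node_ids if self.values[n] > 1)

    def with_value(self, node_id: str, value: Real, context: str = "sensitivity") -> "NodeProbabilities":
        if node_id not in self.values:
            raise ConfigError(f"model {self.model_id} has no node {node_id!r}")
        values = dict(self.values)
        values[node_id] = value
        return replace(self, values=values, context=context)


@dataclass(frozen=True)
class EffectivenessResult:
    """Per-strategy effectiveness plus the incremental difference.

    ``incremental`` (index minus comparator) is present exactly when the
    model has two strategies.  ``theoretical`` marks any effectiveness
    outside [0, 1], which can only happen with sensitivity-context inputs.
    """

    model_id: str
    eff_by_strategy: Mapping[str, Real]
    incremental: Real | None = None
    theoretical: bool = field(default=False)

    def display_pct(self, strategy: str) -> str:
        from .cost_model import format_pct  # local import to avoid cycle at module load

        return format_pct(self.eff_by_strategy[strategy])


def trc_identification_rate(
    p_rated_relapse: Real,
    p_confirm_relapse: Real,
    p_confirm_trc: Real,
    *,
    tol: float = _DENOM_TOL,
) -> Real:
    """Probability that a confirmed-TRC lesion is rated treatment-related changes.

    Parameters are one strategy's chance nodes: the probability a lesion is
    rated relapse, and the confirmation probabilities of the relapse and TRC
    calls.  Exact for :class:`~fractions.Fraction` inputs.

    Raises
    ------
    UndefinedEffectivenessError
        If the confirmed-TRC mass (the denominator) is within ``tol`` of
        zero — no confirmed treatment-related changes to identify.
    """
    num = (1 - p_rated_relapse) * p_confirm_trc
    den = p_rated_relapse * (1 - p_confirm_relapse) + num
    if abs(den) < tol:
        raise UndefinedEffectivenessError(
            "effectiveness undefined: probability mass of confirmed "
            f"treatment-related changes is {float(den)!r} (|den| < {tol})"
        )
    return num / den


def evaluate_model(nodes: NodeProbabilities) -> EffectivenessResult:
    """Evaluate per-strategy effectiveness (and incremental effectiveness).

    ``model1``: combined arm from (N1, N3, N4), MRI arm from (N2, N5, N6),
    incremental = combined − reference.  ``model2``: single PET arm from
    (N1, N2, N3); incremental absent.
    """
    strategies = STRATEGIES[nodes.model_id]
    eff = {}
    for strat in strategies:
        rating, conf_rel, conf_trc = _STRATEGY_NODES[(nodes.model_id, strat)]
        try:
            v = {k: nodes.values[k] for k in (rating, conf_rel, conf_trc)}
        except KeyError as exc:  # defensive; NodeProbabilities already validates
            raise ConfigError(f"model {nodes.model_id} is missing node {exc}") from None
        eff[strat] = trc_identification_rate(v[rating], v[conf_rel], v[conf_trc])
    incremental = None
    if len(strategies) == 2:
        incremental = eff[strategies[0]] - eff[strategies[1]]
    theoretical = any(not (0 <= e <= 1) for e in eff.values())
    return EffectivenessResult(
        model_id=nodes.model_id,
        eff_by_strategy=eff,
        incremental=incremental,
        theoretical=theoretical,
    )


# --- empirical node estimation ------------------------------------------------

def _proportion(num: int, den: int, node_id: str, what: str) -> Fraction:
    if den == 0:
        raise NodeEstimationError(
            f"cannot estimate {node_id}: empty conditioning subset ({what})"
        )
    return Fraction(int(num), int(den))


def estimate_node(dataset: LesionDataset, model_id: str, node_id: str) -> Fraction:
    """Empirical conditional proportion for one chance node.

    Ratings are lesion-level: a lesion scanned repeatedly still contributes
    once here (scan counts matter only to costs).
    """
    if model_id not in MODEL_NODES:
        raise ConfigError(f"unknown model_id {model_id!r}")
    if node_id not in MODEL_NODES[model_id]:
        raise ConfigError(f"model {model_id} has no node {node_id!r}")
    df = dataset.frame
    n = len(df)
    if n == 0:
        raise NodeEstimationError(f"cannot estimate {node_id}: empty dataset")

    # model2 ratings (PET alone) live in rating_combined; model1 N2/N5/N6
    # condition on the MRI-alone reading.
    if model_id == "model2" or node_id in ("N1", "N3", "N4"):
        rating_col = "rating_combined"
    else:
        rating_col = "rating_reference"
    rating = df[rating_col]
    if rating.isna().any():
        raise ValidationError(
            f"estimating {model_id} {node_id} needs column {rating_col} on every lesion"
        )
    rated_rel = rating == Diagnosis.RELAPSE.value
    conf_rel = df["confirmed"] == Diagnosis.RELAPSE.value

    if model_id == "model1":
        spec = {
            "N1": ("marginal", "rating_combined"),
            "N2": ("marginal", "rating_reference"),
            "N3": ("confirm_relapse", "rating_combined"),
            "N4": ("confirm_trc", "rating_combined"),
            "N5": ("confirm_relapse", "rating_reference"),
            "N6": ("confirm_trc", "rating_reference"),
        }[node_id]
    else:
        spec = {
            "N1": ("marginal", "rating_combined"),
            "N2": ("confirm_relapse", "rating_combined"),
            "N3": ("confirm_trc", "rating_combined"),
        }[node_id]

    kind, _ = spec
    if kind == "marginal":
        return _proportion(int(rated_rel.sum()), n, node_id, "all lesions")
    if kind == "confirm_relapse":
        sub = rated_rel
        return _proportion(int((conf_rel & sub).sum()), int(sub.sum()), node_id, "lesions rated relapse")
    sub = ~rated_rel
    return _proportion(int((~conf_rel & sub).sum()), int(sub.sum()), node_id, "lesions rated TRC")


def estimate_nodes(
    dataset: LesionDataset,
    model_id: str,
    nodes: Sequence[str] | None = None,
) -> NodeProbabilities | dict[str, Fraction]:
    """Estimate chance nodes from lesion-level data as exact count ratios.

    With ``nodes=None`` every node of the model is estimated and a
    :class:`NodeProbabilities` (SDs unset) is returned; a subset returns a
    plain dict, so nodes with empty conditioning subsets only raise when
    actually requested.
    """
    requested = MODEL_NODES[model_id] if nodes is None else tuple(nodes)
    est = {node: estimate_node(dataset, model_id, node) for node in requested}
    if nodes is None:
        return NodeProbabilities(model_id=model_id, values=est)
    return est
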