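"""Synthetic lesion cohorts and the exact study fixtures.

Two sources of lesion-level data:

* :func:`study_fixture` — the two deterministic cohorts whose integer
  counts underlie the base-case analyses: 83 pretreated lesions (92
  PET+MRI scans) for the two-strategy model, and 22 lesions (one PET scan
  each) for the PET-triage model.  The counts are reconstructed from the
  published rounded node percentages together with the headline
  effectiveness values; the reconstruction is unique and re-verified by a
  brute-force integer search in the test suite.

* :func:`generate_cohort` — binomial sampling through the tree.  For the
  two-strategy model both readings concern the *same* lesion, so a single
  latent confirmed diagnosis is drawn first and each strategy's rating is
  drawn conditionally on it; the conditional rating probabilities are
  back-solved from the requested chance-node values via Bayes' rule.
  Node sets admitting no valid joint distribution (mismatched implied
  prevalence, or back-solved conditionals outside [0, 1]) raise
  :class:`~fetcea.errors.InconsistentCohortError`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Real
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InconsistentCohortError, ValidationError
from .tree_model import MODEL_NODES, Diagnosis, LesionDataset, NodeProbabilities

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "study_fixture",
    "trc_prevalence",
    "nodes_from_latent",
    "load_cohort_spec",
]

_REL = Diagnosis.RELAPSE.value
_TRC = Diagnosis.TRC.value


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a random lesion cohort.

    ``scans`` is either a constant per-lesion scan count or an exact
    allocation ``{n_scans: n_lesions_with_that_count}`` summing to
    ``n_lesions`` (the study cohort allocates 2 scans to 9 of 83 lesions).
    """

    model_id: str
    n_lesions: int
    probabilities: NodeProbabilities
    scans: int | Mapping[int, int] = 1
    seed: int | None = None

    def __post_init__(self):
        if self.n_lesions < 1:
            raise ValidationError("n_lesions must be >= 1")
        if self.probabilities.model_id != self.model_id:
            raise ConfigError(
                f"probabilities are for {self.probabilities.model_id}, spec says {self.model_id}"
            )
        if any(not (0 <= v <= 1) for v in self.probabilities.values.values()):
            raise ValidationError("generating probabilities must lie in [0, 1]")
        if isinstance(self.scans, Mapping):
            if any(k < 1 or v < 0 for k, v in self.scans.items()):
                raise ValidationError("scan allocation needs counts >= 1 and non-negative sizes")
            if sum(self.scans.values()) != self.n_lesions:
                raise ValidationError("scan allocation must cover every lesion exactly once")
        elif self.scans < 1:
            raise ValidationError("scans per lesion must be >= 1")


def trc_prevalence(nodes: NodeProbabilities, strategy: str = "combined") -> Real:
    """Confirmed-TRC prevalence implied by one strategy's branch of the tree."""
    v = nodes.values
    if nodes.model_id == "model2":
        return v["N1"] * (1 - v["N2"]) + (1 - v["N1"]) * v["N3"]
    if strategy == "combined":
        return v["N1"] * (1 - v["N3"]) + (1 - v["N1"]) * v["N4"]
    return v["N2"] * (1 - v["N5"]) + (1 - v["N2"]) * v["N6"]


def _rating_conditionals(p_rated, p_conf_rel, prev_rel, prev_trc, arm: str):
    """P(rated relapse | truth) for one strategy, via Bayes on the node values."""
    # joint masses: rated-relapse ∧ truth-relapse, rated-relapse ∧ truth-TRC
    joint_rel = p_rated * p_conf_rel
    joint_trc = p_rated * (1 - p_conf_rel)
    q_rel = joint_rel / prev_rel if prev_rel > 0 else 0
    q_trc = joint_trc / prev_trc if prev_trc > 0 else 0
    for name, q in (("P(rated relapse | relapse)", q_rel), ("P(rated relapse | TRC)", q_trc)):
        if not (0 <= q <= 1):
            raise InconsistentCohortError(
                f"{arm}: back-solved {name} = {float(q):.4f} lies outside [0, 1]; "
                "the requested node probabilities admit no joint lesion distribution"
            )
    return q_rel, q_trc


def generate_cohort(spec: CohortSpec) -> LesionDataset:
    """Draw a lesion cohort whose chance-node structure matches ``spec``.

    The confirmed diagnosis is a single latent truth per lesion; ratings
    are conditionally independent given that truth.  Marginally each
    rating node is Bernoulli with its requested probability, and the
    confirmation nodes match by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_lesions
    v = {k: float(val) for k, val in spec.probabilities.values.items()}

    if spec.model_id == "model2":
        rated_rel = rng.random(n) < v["N1"]
        conf_rel = np.where(
            rated_rel,
            rng.random(n) < v["N2"],          # relapse call confirmed -> truth relapse
            ~(rng.random(n) < v["N3"]),       # TRC call confirmed -> truth TRC
        )
        frame = pd.DataFrame(
            {
                "lesion_id": [f"S{i + 1:06d}" for i in range(n)],
                "rating_combined": np.where(rated_rel, _REL, _TRC),
                "rating_reference": pd.NA,
                "confirmed": np.where(conf_rel, _REL, _TRC),
                "n_scans": _allocate_scans(spec, rng),
            }
        )
        return LesionDataset(frame)

    # model1: shared latent truth, two conditionally independent readings
    prev_trc_c = trc_prevalence(spec.probabilities, "combined")
    prev_trc_r = trc_prevalence(spec.probabilities, "reference")
    if abs(float(prev_trc_c) - float(prev_trc_r)) > 1e-9:
        raise InconsistentCohortError(
            "both strategies rate the same lesions, so they must imply the same "
            f"confirmed-TRC prevalence; got {float(prev_trc_c):.6f} (combined) vs "
            f"{float(prev_trc_r):.6f} (reference)"
        )
    prev_trc = float(prev_trc_c)
    prev_rel = 1.0 - prev_trc
    qc_rel, qc_trc = _rating_conditionals(v["N1"], v["N3"], prev_rel, prev_trc, "combined")
    qr_rel, qr_trc = _rating_conditionals(v["N2"], v["N5"], prev_rel, prev_trc, "reference")

    truth_rel = rng.random(n) < prev_rel
    p_comb = np.where(truth_rel, qc_rel, qc_trc)
    p_ref = np.where(truth_rel, qr_rel, qr_trc)
    comb_rel = rng.random(n) < p_comb
    ref_rel = rng.random(n) < p_ref
    frame = pd.DataFrame(
        {
            "lesion_id": [f"S{i + 1:06d}" for i in range(n)],
            "rating_combined": np.where(comb_rel, _REL, _TRC),
            "rating_reference": np.where(ref_rel, _REL, _TRC),
            "confirmed": np.where(truth_rel, _REL, _TRC),
            "n_scans": _allocate_scans(spec, rng),
        }
    )
    return LesionDataset(frame)


def _allocate_scans(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.scans, Mapping):
        counts = np.concatenate(
            [np.full(size, k, dtype=int) for k, size in sorted(spec.scans.items())]
        )
        return counts[::-1]  # higher scan counts on the first lesion ids
    return np.full(spec.n_lesions, int(spec.scans), dtype=int)


def nodes_from_latent(
    model_id: str,
    prevalence_trc: float,
    rated_relapse_given_relapse: tuple[float, ...],
    rated_relapse_given_trc: tuple[float, ...],
) -> NodeProbabilities:
    """Build a *consistent* node set from latent parameters.

    For ``model1`` pass one (sensitivity-like, false-call) pair per
    strategy, combined first.  Useful for simulation studies: any latent
    parameterisation yields node values that admit a joint distribution.
    """
    prev_trc = prevalence_trc
    prev_rel = 1 - prev_trc
    pairs = list(zip(rated_relapse_given_relapse, rated_relapse_given_trc))
    expected = 2 if model_id == "model1" else 1
    if len(pairs) != expected:
        raise ConfigError(f"{model_id} needs {expected} strategy conditional pair(s)")
    values: dict[str, float] = {}
    triples = [("N1", "N3", "N4"), ("N2", "N5", "N6")] if model_id == "model1" else [("N1", "N2", "N3")]
    for (rating, conf_rel, conf_trc), (q_rel, q_trc) in zip(triples, pairs):
        p_rated = prev_rel * q_rel + prev_trc * q_trc
        values[rating] = p_rated
        values[conf_rel] = (prev_rel * q_rel / p_rated) if p_rated > 0 else 1.0
        p_trc_call = 1 - p_rated
        values[conf_trc] = (prev_trc * (1 - q_trc) / p_trc_call) if p_trc_call > 0 else 1.0
    return NodeProbabilities(model_id=model_id, values=values)


# --- deterministic study fixtures --------------------------------------------

def study_fixture(model_id: str) -> LesionDataset:
    """The exact lesion table behind each base case (seed-independent).

    ``model1``: 83 lesions, 92 scans.  Combined reading: 54 rated relapse
    (all confirmed relapse), 29 rated TRC (21 confirmed TRC, 8 relapse).
    MRI-alone reading: 68 rated relapse (57 relapse, 11 TRC), 15 rated TRC
    (10 TRC, 5 relapse).  One shared confirmed label per lesion (62
    relapse, 21 TRC under both cross-tabulations).  The joint split of the
    two readings among confirmed-relapse lesions is not identified by
    those margins; the maximum-agreement assignment is used (it does not
    affect any node estimate or cost).  Nine lesions carry 2 scans
    (arbitrary choice of which; only the 92-scan total matters to costs).

    ``model2``: 22 lesions, one scan each: 10 rated relapse by PET (9
    confirmed relapse, 1 TRC), 12 rated TRC (9 TRC, 3 relapse).
    """
    if model_id == "model1":
        # (confirmed, rating_combined, rating_reference, count)
        blocks = [
            (_REL, _REL, _REL, 54),
            (_REL, _TRC, _REL, 3),
            (_REL, _TRC, _TRC, 5),
            (_TRC, _TRC, _REL, 11),
            (_TRC, _TRC, _TRC, 10),
        ]
        rows = []
        for confirmed, comb, ref, count in blocks:
            rows += [(comb, ref, confirmed)] * count
        frame = pd.DataFrame(rows, columns=["rating_combined", "rating_reference", "confirmed"])
        frame.insert(0, "lesion_id", [f"M1-{i + 1:03d}" for i in range(len(frame))])
        frame["n_scans"] = [2] * 9 + [1] * (len(frame) - 9)
        return LesionDataset(frame)
    if model_id == "model2":
        blocks = [(_REL, _REL, 9), (_REL, _TRC, 1), (_TRC, _TRC, 9), (_TRC, _REL, 3)]
        rows = []
        for rating, confirmed, count in blocks:
            rows += [(rating, confirmed)] * count
        frame = pd.DataFrame(rows, columns=["rating_combined", "confirmed"])
        frame.insert(0, "lesion_id", [f"M2-{i + 1:03d}" for i in range(len(frame))])
        frame["rating_reference"] = pd.NA
        frame["n_scans"] = 1
        return LesionDataset(frame)
    raise ConfigError(f"unknown model_id {model_id!r}; expected 'model1' or 'model2'")


def load_cohort_spec(path: str | Path, seed: int | None = None) -> CohortSpec:
    """Read a cohort recipe from YAML (keys: model, n_lesions, probabilities, scans)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        model_id = raw["model"]
        n_lesions = int(raw["n_lesions"])
        probs = raw["probabilities"]
    except KeyError as exc:
        raise ConfigError(f"{path}: missing required key {exc}") from None
    if model_id not in MODEL_NODES:
        raise ConfigError(f"{path}: model: unknown model {model_id!r}")
    values = {}
    for node in MODEL_NODES[model_id]:
        if node not in probs:
            raise ConfigError(f"{path}: probabilities.{node}: missing")
        values[node] = _parse_prob(probs[node], f"probabilities.{node}")
    nodes = NodeProbabilities(model_id=model_id, values=values)
    scans = raw.get("scans", 1)
    if isinstance(scans, dict):
        scans = {int(k): int(v) for k, v in scans.items()}
    else:
        scans = int(scans)
    if seed is None:
        seed = raw.get("seed")
    return CohortSpec(
        model_id=model_id, n_lesions=n_lesions, probabilities=nodes, scans=scans, seed=seed
    )


def _parse_prob(value, where: str) -> Fraction:
    try:
        if isinstance(value, str) and "/" in value:
            num, den = value.split("/")
            return Fraction(int(num), int(den))
        return Fraction(str(value))
    except (ValueError, ZeroDivisionError) as exc:
        raise ConfigError(f"{where}: cannot parse probability {value!r} ({exc})") from None
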