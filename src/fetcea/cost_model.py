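"""Imaging costs from fee-schedule items, and the ICER / CER ratios.

Costing follows the German statutory-health-insurance outpatient fee
schedule: a scan's cost is the exact sum of its itemized fees, held as
:class:`decimal.Decimal` (never binary floats — €1,566.33 must be exact).
Per-lesion cost multiplies the per-scan cost by the scans-per-lesion
factor (92/83 in the two-strategy cohort), carried as an exact
:class:`~fractions.Fraction`.  Cent rounding happens exactly once, in the
display helpers.

    ICER = (cost_combined − cost_reference) / (eff_combined − eff_reference)
    CER  = cost / effectiveness
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal, InvalidOperation
from fractions import Fraction
from numbers import Real
from typing import Iterable, Mapping

from .errors import UndefinedRatioError, ValidationError

__all__ = [
    "FeeItem",
    "CostProfile",
    "scan_cost",
    "per_lesion_cost",
    "icer",
    "cer",
    "format_eur",
    "format_pct",
    "round_eur",
]

_RATIO_TOL = 1e-9


@dataclass(frozen=True)
class FeeItem:
    """One fee-schedule entry: index number, label, amount in EUR.

    Tracer production has no fee-schedule code and uses a sentinel string.
    """

    code: str
    label: str
    amount: Decimal

    def __post_init__(self):
        if not str(self.code):
            raise ValidationError("fee item code must be non-empty")
        try:
            amount = Decimal(str(self.amount))
        except InvalidOperation:
            raise ValidationError(f"fee item {self.code}: invalid amount {self.amount!r}") from None
        if amount < 0:
            raise ValidationError(f"fee item {self.code}: amount must be non-negative, got {amount}")
        object.__setattr__(self, "amount", amount)


@dataclass(frozen=True)
class CostProfile:
    """Itemized fees per modality plus the cohort's scans-per-lesion factor."""

    items_by_modality: Mapping[str, tuple[FeeItem, ...]]
    n_scans: int
    n_lesions: int

    def __post_init__(self):
        object.__setattr__(
            self,
            "items_by_modality",
            {m: tuple(items) for m, items in self.items_by_modality.items()},
        )
        if self.n_lesions < 1:
            raise ValidationError("n_lesions must be >= 1")
        if self.n_scans < self.n_lesions:
            raise ValidationError("n_scans must be >= n_lesions (every lesion is scanned)")

    @property
    def scan_factor(self) -> Fraction:
        return Fraction(self.n_scans, self.n_lesions)

    def scan_cost(self, modality: str) -> Decimal:
        return scan_cost(self.items_by_modality[modality])


def scan_cost(items: Iterable[FeeItem]) -> Decimal:
    """Exact sum of fee items for one scan (cent precision preserved)."""
    total = Decimal("0.00")
    for item in items:
        total += item.amount
    return total


def per_lesion_cost(total_scan_cost, n_scans: int, n_lesions: int):
    """Per-lesion imaging cost: per-scan cost times ``n_scans / n_lesions``.

    Returns an exact :class:`~fractions.Fraction` for Decimal/Fraction/int
    input, a float for float input; rounding is left to display time.
    """
    if n_lesions < 1:
        raise ValidationError("n_lesions must be >= 1")
    if n_scans < 0:
        raise ValidationError("n_scans must be non-negative")
    return _exact(total_scan_cost) * n_scans / n_lesions


def icer(cost_combined, cost_reference, incremental_effectiveness, *, tol: float = _RATIO_TOL):
    """Incremental cost-effectiveness ratio.

    EUR per *additional* correctly identified treatment-related-change
    lesion.  Negative incremental effectiveness is allowed (the combined
    strategy would be dominated); the sign is preserved, never masked.
    """
    if abs(incremental_effectiveness) < tol:
        raise UndefinedRatioError(
            f"ICER undefined: |incremental effectiveness| = {float(incremental_effectiveness)!r} < {tol}"
        )
    return (_exact(cost_combined) - _exact(cost_reference)) / incremental_effectiveness


def cer(cost, effectiveness, *, tol: float = _RATIO_TOL):
    """Cost-effectiveness ratio: EUR per correctly identified TRC lesion."""
    if effectiveness <= tol:
        raise UndefinedRatioError(
            f"CER undefined: effectiveness = {float(effectiveness)!r} <= {tol}"
        )
    return _exact(cost) / effectiveness


# --- exact/display helpers ----------------------------------------------------

def _exact(x):
    """Lift exact numeric types to Fraction; leave floats as floats."""
    if isinstance(x, Decimal):
        return Fraction(x)
    if isinstance(x, (int, Fraction)):
        return Fraction(x)
    return x


def _to_decimal(x) -> Decimal:
    if isinstance(x, Decimal):
        return x
    if isinstance(x, Fraction):
        return Decimal(x.numerator) / Decimal(x.denominator)
    if isinstance(x, int):
        return Decimal(x)
    return Decimal(repr(float(x)))


def round_eur(x) -> Decimal:
    """Round to cents, half away from zero (the single rounding step)."""
    return _to_decimal(x).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)


def format_eur(x) -> str:
    """Euro display with thousands separators, e.g. ``€3,314.51``."""
    return f"€{round_eur(x):,.2f}"


def format_pct(x) -> str:
    """Whole-percent display (half-up), e.g. Fraction(10, 21) -> ``48``."""
    pct = (_to_decimal(x) * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    return str(pct)
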