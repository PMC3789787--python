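"""Phenotype classification and cofactor-sensitivity calls.

A variant is *nonfunctional* if it confers no growth even at the highest
pyridoxine dose (400 ng/mL), *sensitive* if its growth rate differs
significantly (Welch t-test, P < 0.01) from the major allele in at least
one pyridoxine dose, and *benign* otherwise.  Among sensitive variants a
few grow faster than the major allele; in the hem1-delta panel, variants
nearly unable to grow at high B6 but low heme precursor are called
dually cofactor-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .data_model import (
    AssayCondition,
    Category,
    GrowthResult,
    SigFlag,
    Substitution,
    VariantPanel,
    VariantRecord,
)

__all__ = [
    "Direction",
    "SignificanceResult",
    "PhenotypeCall",
    "compare_replicates",
    "classify",
    "classify_panel",
    "faster_set",
    "dual_sensitivity",
    "heme_saturation",
]

HIGH_B6 = 400.0   # ng/mL, the "high" pyridoxine dose
LOW_DALA = 5.0    # ug/mL, the limiting heme-precursor dose


class Direction(str, Enum):
    FASTER = "faster"
    SLOWER = "slower"
    NONE = "none"


@dataclass(frozen=True)
class SignificanceResult:
    condition: AssayCondition
    p_value: float
    flag: SigFlag
    direction: Direction

    def __post_init__(self) -> None:
        if self.flag is not SigFlag.NONE and self.direction is Direction.NONE:
            raise ValueError("a significant difference must have a direction")


@dataclass(frozen=True)
class PhenotypeCall:
    substitution: Substitution
    category: Category
    per_condition: tuple[SignificanceResult, ...] = ()
    faster_than_wt: bool = False
    dual_sensitive: bool | None = None   # None = not assessed


def _flag_for_p(p: float) -> SigFlag:
    if p < 0.001:
        return SigFlag.P001
    if p < 0.01:
        return SigFlag.P01
    return SigFlag.NONE


def compare_replicates(
    variant_ratios: np.ndarray,
    major_ratios: np.ndarray,
    condition: AssayCondition,
) -> SignificanceResult:
    """Welch two-sample t-test of variant vs major-allele replicate ratios.

    Replicate counts are small (>= 3 independent transformants) and
    variances differ between strains, so the unequal-variance form is
    used.  Identical zero-variance samples give p = 1 by convention.
    """
    v = np.asarray(variant_ratios, dtype=float)
    m = np.asarray(major_ratios, dtype=float)
    if v.size < 2 or m.size < 2:
        raise ValueError("need >= 2 replicates in each sample")
    if v.std() == 0 and m.std() == 0:
        p = 1.0 if v.mean() == m.mean() else 0.0
    else:
        p = float(stats.ttest_ind(v, m, equal_var=False).pvalue)
    flag = _flag_for_p(p)
    if flag is SigFlag.NONE:
        direction = Direction.NONE
    else:
        direction = Direction.FASTER if v.mean() > m.mean() else Direction.SLOWER
    return SignificanceResult(condition=condition, p_value=p, flag=flag,
                              direction=direction)


def _result_direction(res: GrowthResult) -> Direction:
    if res.sig_flag is SigFlag.NONE or res.relative_rate is None:
        return Direction.NONE
    return Direction.FASTER if res.relative_rate > 1.0 else Direction.SLOWER


def classify(record: VariantRecord,
             significance: tuple[SignificanceResult, ...] | None = None,
             ) -> PhenotypeCall:
    """Assign the three-way phenotype category from per-condition data.

    With ``significance`` given (recomputation mode for raw replicate
    data), its flags are used; otherwise the record's stored flags — the
    printed ones for the bundled fixtures — are authoritative.
    """
    try:
        high = record.result_at(AssayCondition(pyridoxine=HIGH_B6))
    except KeyError as exc:
        raise ValueError(
            f"{record.substitution}: no observation at the high (400 ng/mL) "
            "pyridoxine dose; cannot classify") from exc

    if high.relative_rate is None:
        return PhenotypeCall(substitution=record.substitution,
                             category=Category.NONFUNCTIONAL)

    if significance is not None:
        per_condition = significance
        flagged = [s for s in per_condition if s.flag is not SigFlag.NONE]
        directions = [s.direction for s in flagged]
    else:
        per_condition = ()
        flagged = [r for r in record.results if r.sig_flag is not SigFlag.NONE]
        directions = [_result_direction(r) for r in flagged]

    if flagged:
        faster = all(d is Direction.FASTER for d in directions)
        return PhenotypeCall(substitution=record.substitution,
                             category=Category.SENSITIVE,
                             per_condition=per_condition,
                             faster_than_wt=faster)
    return PhenotypeCall(substitution=record.substitution,
                         category=Category.BENIGN,
                         per_condition=per_condition)


def classify_panel(panel: VariantPanel) -> dict[Substitution, PhenotypeCall]:
    return {rec.substitution: classify(rec) for rec in panel}


def faster_set(panel: VariantPanel) -> set[Substitution]:
    """Sensitive variants all of whose significant differences are faster
    growth than the major allele."""
    return {
        sub for sub, call in classify_panel(panel).items()
        if call.category is Category.SENSITIVE and call.faster_than_wt
    }


def dual_sensitivity(table2_panel: VariantPanel,
                     rate_floor: float = 0.1) -> set[Substitution]:
    """Variants extremely sensitive to limiting heme despite high B6.

    Evaluated at 400 ng/mL pyridoxine with the low (5 ug/mL) d-ALA dose in
    the hem1-delta background: a variant is dually sensitive if it has no
    determinable rate there, or a relative rate below ``rate_floor``.
    """
    cond = AssayCondition(pyridoxine=HIGH_B6, dala=LOW_DALA, hem1_deleted=True)
    out: set[Substitution] = set()
    for rec in table2_panel:
        try:
            res = rec.result_at(cond)
        except KeyError as exc:
            raise ValueError(
                f"{rec.substitution}: missing the {cond.label()} condition") from exc
        if res.relative_rate is None or res.relative_rate < rate_floor:
            out.add(rec.substitution)
    return out


def heme_saturation(a430: float, a280: float) -> float:
    """Fraction of full heme incorporation from an absorbance spectrum.

    The heme Soret peak at 430 nm relative to the aromatic 280 nm peak is
    one-to-one for fully heme-loaded enzyme, so the ratio, clipped to
    [0, 1], reads out fractional incorporation.
    """
    if not a280 > 0:
        raise ValueError("aromatic (280 nm) absorbance must be positive")
    if a430 < 0:
        raise ValueError("430 nm absorbance must be non-negative")
    return float(min(1.0, a430 / a280))
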