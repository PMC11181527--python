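"""Published base-case inputs for the Thai random-breath-testing analysis.

These constants are the printed inputs of the analysis this package
implements: population denominators and programme costs, and the reported
per-arm lifetime outcomes for the 20-year-old male and female binge-drinker
cohorts.  The per-arm outcome values are *inputs* to the incremental
arithmetic (the transition parameters behind them were never published);
the package derives increments, ICERs and population totals from them with
the same operations it applies to its own model output.
"""

from __future__ import annotations

from .economics import ArmResult

__all__ = [
    "WTP_THRESHOLD_THB_PER_QALY",
    "THB_PER_USD",
    "published_arm_results",
    "PUBLISHED_ICER",
]

WTP_THRESHOLD_THB_PER_QALY = 160_000.0
THB_PER_USD = 35.0

# Reported lifetime outcomes per cohort member, by sex and strategy arm.
_ARM_VALUES = {
    ("male", "MEDIA_ONLY"): dict(
        life_years=73.04, disc_life_years=44.66, disc_qalys=41.99,
        lifetime_cost=692_780.0, disc_lifetime_cost=274_286.0),
    ("male", "RBT_PLUS_MEDIA"): dict(
        life_years=74.47, disc_life_years=45.16, disc_qalys=42.42,
        lifetime_cost=739_615.0, disc_lifetime_cost=298_772.0),
    ("female", "MEDIA_ONLY"): dict(
        life_years=77.30, disc_life_years=44.20, disc_qalys=33.48,
        lifetime_cost=713_890.0, disc_lifetime_cost=276_917.0),
    ("female", "RBT_PLUS_MEDIA"): dict(
        life_years=77.88, disc_life_years=44.36, disc_qalys=33.58,
        lifetime_cost=731_303.0, disc_lifetime_cost=287_392.0),
}

#: reported ICERs (THB per QALY).  These reflect unrounded model output;
#: dividing the printed rounded increments reproduces them to within ~1%.
PUBLISHED_ICER = {"male": 57_391.0, "female": 103_850.0}


def published_arm_results(sex: str, arm_label: str) -> ArmResult:
    """ArmResult built from the reported per-arm values for one sex/arm."""
    key = (sex, arm_label)
    if key not in _ARM_VALUES:
        raise KeyError(f"no published results for sex={sex!r}, arm={arm_label!r}")
    return ArmResult(label=arm_label, **_ARM_VALUES[key])
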