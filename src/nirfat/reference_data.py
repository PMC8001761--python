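"""Published summary statistics of the South African infant cohort.

These group-level means and standard deviations (one row per variable,
three age groups: all subjects 3-24 months, 3-6 months, 7-24 months) are
the inputs for the summary-statistics cross-checks: the one-way ANOVA and
Tukey-Kramer computations on mid-upper arm circumference, and the numeric
consistency check of the multi-compartment fat-mass model against the
printed group fat-mass column.

Skinfold values are in mm and "bone" is bone mineral content in kg; both
readings are validated numerically by the multi-compartment cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GroupSummary:
    """n / mean / SD triple for one variable in one age group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"group {self.label!r}: sd must be >= 0, got {self.sd}")


GROUP_LABELS = ("3-24", "3-6", "7-24")
GROUP_N = {"3-24": 164, "3-6": 105, "7-24": 59}

#: variable -> {group label -> (mean, sd)}
COHORT_SUMMARIES: dict[str, dict[str, tuple[float, float]]] = {
    "age_months": {"3-24": (7.1, 5.7), "3-6": (3.6, 1.5), "7-24": (13.3, 5.2)},
    "weight_g": {"3-24": (7561, 2015), "3-6": (6437, 1231), "7-24": (9562, 1530)},
    "length_cm": {"3-24": (65.8, 8.6), "3-6": (60.8, 4.3), "7-24": (74.8, 6.7)},
    "fm_dd_g": {"3-24": (2073, 878), "3-6": (1738, 677), "7-24": (2668, 880)},
    "fm_dxa_g": {"3-24": (2146, 861), "3-6": (1935, 797), "7-24": (2523, 843)},
    "fm_4c_g": {"3-24": (2117, 881), "3-6": (1783, 699), "7-24": (2712, 858)},
    "tbw_kg": {"3-24": (4.4, 1.1), "3-6": (3.8, 0.6), "7-24": (5.4, 0.9)},
    "bmc_kg": {"3-24": (0.15, 0.05), "3-6": (0.12, 0.03), "7-24": (0.20, 0.04)},
    "muac_cm": {"3-24": (14.2, 2.3), "3-6": (13.6, 2.0), "7-24": (15.2, 2.4)},
    "subscapular_mm": {"3-24": (9.3, 2.1), "3-6": (9.5, 1.9), "7-24": (8.9, 2.3)},
    "flank_mm": {"3-24": (11.0, 2.9), "3-6": (11.2, 2.8), "7-24": (10.7, 3.0)},
    "thigh_mm": {"3-24": (19.9, 3.8), "3-6": (20.1, 3.6), "7-24": (19.5, 4.0)},
    "triceps_mm": {"3-24": (9.6, 1.8), "3-6": (9.5, 1.7), "7-24": (9.6, 2.0)},
}

#: male fraction per group (printed as "Male (%)")
MALE_FRACTION = {"3-24": 0.4817, "3-6": 0.5048, "7-24": 0.4407}


def group_summaries(variable: str) -> list[GroupSummary]:
    """Return the three GroupSummary records for ``variable``."""
    per_group = COHORT_SUMMARIES[variable]
    return [
        GroupSummary(label=g, n=GROUP_N[g], mean=per_group[g][0], sd=per_group[g][1])
        for g in GROUP_LABELS
    ]
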