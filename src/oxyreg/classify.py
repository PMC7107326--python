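"""Group-level aggregation of RI values and respiration-strategy labels.

Strategies are group-level constructs: per species x temperature, the median
and quartiles of the individual RI values decide between metabolic
suppression (median, Q1, Q3 all below 0), high or low oxyregulation,
oxyconformity (median near 0 with quartiles straddling it) and the hybrid
conformity/regulation pattern. Two rule modes are provided:

- ``literal``: the published clause set applied verbatim;
- ``table2_compat``: identical except the median is rounded to one decimal
  before the high-oxyregulation clause, which is the only reading under which
  every published species x temperature triple reproduces its published label
  (e.g. a median of 0.48 with Q1 = 0.29 is labelled high oxyregulation).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = ["Strategy", "GroupSummary", "classify_strategy", "summarize_group"]


class Strategy(str, Enum):
    HIGH_OXYREGULATION = "high_oxyregulation"
    LOW_OXYREGULATION = "low_oxyregulation"
    CONFORMITY = "conformity"
    CONFORMITY_REGULATION = "conformity_regulation"
    METABOLIC_SUPPRESSION = "metabolic_suppression"
    UNCLASSIFIED = "unclassified"


@dataclass
class GroupSummary:
    """Per species x temperature summary of individual RI values."""

    species: str
    temperature_C: float
    n: int
    ri_median: float
    ri_q1: float
    ri_q3: float
    strategy: str
    rule_trace: str = ""


def classify_strategy(
    median: float, q1: float, q3: float, mode: str = "literal"
) -> tuple[Strategy, str]:
    """Assign a respiration strategy from the group's RI median and quartiles.

    Clauses are evaluated in a fixed precedence (each clause only fires if no
    earlier one did); ``rule_trace`` records the fired clause and mode.

    1. metabolic suppression:     median < 0 and Q1 < 0 and Q3 < 0
    2. high oxyregulation:        0.5 <= median < 1 and (Q1 > 0.25 or Q3 > 0.75)
       (in table2_compat mode the median is rounded to 1 decimal first)
    3. low oxyregulation:         0.25 < median < 0.5
    4. conformity/regulation:     0 < median < 0.5 and Q1 < 0 and Q3 > 0.25
    5. conformity:                |median| <= 0.25 and Q1 < 0 and Q3 > 0
    6. unclassified otherwise.
    """
    if not (q1 <= median <= q3):
        raise ValueError(f"quartiles out of order: Q1={q1}, median={median}, Q3={q3}")
    if mode not in ("literal", "table2_compat"):
        raise ValueError(f"unknown classification mode {mode!r}")

    m2 = round(median, 1) if mode == "table2_compat" else median
    if median < 0 and q1 < 0 and q3 < 0:
        label, clause = Strategy.METABOLIC_SUPPRESSION, "1:median,Q1,Q3<0"
    elif 0.5 <= m2 < 1 and (q1 > 0.25 or q3 > 0.75):
        label, clause = Strategy.HIGH_OXYREGULATION, "2:0.5<=median<1,Q1>0.25|Q3>0.75"
    elif 0.25 < median < 0.5:
        label, clause = Strategy.LOW_OXYREGULATION, "3:0.25<median<0.5"
    elif 0 < median < 0.5 and q1 < 0 and q3 > 0.25:
        label, clause = Strategy.CONFORMITY_REGULATION, "4:0<median<0.5,Q1<0,Q3>0.25"
    elif abs(median) <= 0.25 and q1 < 0 and q3 > 0:
        label, clause = Strategy.CONFORMITY, "5:|median|<=0.25,Q1<0,Q3>0"
    else:
        label, clause = Strategy.UNCLASSIFIED, "6:no clause matched"
    return label, f"{mode}/{clause}"


def summarize_group(
    ri_values: Sequence[float],
    species: str,
    temperature_C: float,
    mode: str = "literal",
) -> GroupSummary:
    """Median/Q1/Q3 (linear-interpolation quantiles) and strategy for one group."""
    vals = np.asarray(list(ri_values), dtype=float)
    if vals.size == 0:
        raise ValueError(f"empty RI group for {species} @ {temperature_C} C")
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])  # linear interpolation
    label, trace = classify_strategy(float(med), float(q1), float(q3), mode=mode)
    return GroupSummary(
        species=species,
        temperature_C=float(temperature_C),
        n=int(vals.size),
        ri_median=float(med),
        ri_q1=float(q1),
        ri_q3=float(q3),
        strategy=label.value,
        rule_trace=trace,
    )
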