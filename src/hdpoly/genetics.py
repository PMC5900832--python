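"""Genetic clock scores for Huntington's disease gene carriers.

The CAG repeat length of the expanded huntingtin allele, together with
current age, drives three scalar "clock" scores used throughout the
premanifest-HD literature:

* the disease burden score, ``age * (CAG - 35.5)``, a cumulative
  pathology-exposure index;
* the Langbehn model's expected years to clinical diagnosis,
  ``21.54 + exp(9.556 - 0.146 * CAG) - age``;
* the CAG-Age Product scaled (CAPs), ``age * (CAG - 33.66) / 432.3326``,
  normalised so a value of about 1 coincides with expected onset.

Only the deterministic point-estimate form of the Langbehn model is
implemented (the survival/penetrance form is out of scope here).
"""

from __future__ import annotations

import warnings
from statistics import median
from typing import Sequence

__all__ = [
    "disease_burden_score",
    "langbehn_years_to_dx",
    "langbehn_onset_age",
    "caps_score",
    "assign_subgroups",
    "CAGRangeWarning",
    "DegenerateSplitWarning",
]

#: CAG range over which the Langbehn onset model was fitted/validated.
LANGBEHN_CAG_RANGE = (36, 56)

#: CAPs scaling constants: CAPs = age * (CAG - CAPS_L) / CAPS_S, ~1 at onset.
CAPS_L = 33.66
CAPS_S = 432.3326


class CAGRangeWarning(UserWarning):
    """CAG repeat length outside the validated range of the onset model."""


class DegenerateSplitWarning(UserWarning):
    """Median split could not separate subjects (all values tied)."""


def disease_burden_score(age: float, cag: float) -> float:
    """Cumulative disease-burden score ``age * (CAG - 35.5)``.

    Parameters
    ----------
    age : float
        Current age in years, > 0.
    cag : float
        CAG repeat length of the expanded allele; must exceed 35.5
        (the score is undefined for non-expanded alleles).
    """
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    if cag < 35.5:
        raise ValueError(
            f"disease burden score undefined for CAG {cag} <= 35.5 (non-expanded allele)"
        )
    return age * (cag - 35.5)


def langbehn_onset_age(cag: float) -> float:
    """Expected age at clinical diagnosis, ``21.54 + exp(9.556 - 0.146*CAG)``."""
    import math

    if not (LANGBEHN_CAG_RANGE[0] <= cag <= LANGBEHN_CAG_RANGE[1]):
        warnings.warn(
            f"CAG {cag} outside the validated range {LANGBEHN_CAG_RANGE} of the "
            "Langbehn onset model; extrapolated estimate",
            CAGRangeWarning,
            stacklevel=2,
        )
    return 21.54 + math.exp(9.556 - 0.146 * cag)


def langbehn_years_to_dx(age: float, cag: float) -> float:
    """Estimated years to clinical diagnosis (may be negative if overdue)."""
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    return langbehn_onset_age(cag) - age


def caps_score(age: float, cag: float) -> float:
    """CAG-Age Product scaled: ``age * (CAG - 33.66) / 432.3326``.

    Scaled so that the score is approximately 1 at the Langbehn expected
    onset age for that CAG length.
    """
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    if not (LANGBEHN_CAG_RANGE[0] <= cag <= LANGBEHN_CAG_RANGE[1]):
        warnings.warn(
            f"CAG {cag} outside the validated range {LANGBEHN_CAG_RANGE}",
            CAGRangeWarning,
            stacklevel=2,
        )
    return age * (cag - CAPS_L) / CAPS_S


def assign_subgroups(subjects: Sequence) -> list:
    """Median-split gene carriers into 'near' and 'far' subgroups.

    The split is on estimated years to diagnosis over carriers only:
    subjects at or below the carrier median are labelled ``near``, the
    rest ``far``; controls pass through untouched.  With an odd number of
    carriers and distinct values this puts the median subject in the near
    group (e.g. 19 carriers -> 10 near / 9 far).

    Parameters
    ----------
    subjects : sequence of SubjectRecord
        Records; carriers must have ``est_years_to_dx`` set.

    Returns
    -------
    list of SubjectRecord
        New records (dataclass replace) with ``subgroup`` filled in.
    """
    from dataclasses import replace

    carriers = [s for s in subjects if s.group != "control"]
    if len(carriers) < 2:
        raise ValueError(f"need >= 2 gene carriers for a median split, got {len(carriers)}")
    values = []
    for s in carriers:
        if s.est_years_to_dx is None:
            raise ValueError(f"subject {s.subject_id} has no est_years_to_dx")
        values.append(s.est_years_to_dx)
    med = median(values)
    if max(values) == min(values):
        warnings.warn(
            "all carriers share the same estimated years to diagnosis; "
            "degenerate split assigns every carrier to 'near'",
            DegenerateSplitWarning,
            stacklevel=2,
        )
    out = []
    for s in subjects:
        if s.group == "control":
            out.append(s)
        else:
            out.append(replace(s, subgroup="near" if s.est_years_to_dx <= med else "far"))
    return out
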