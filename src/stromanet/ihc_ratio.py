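"""Ordinal IHC scoring and the epithelium:stroma protein Expression Ratio classifier.

TRIM28 nuclear staining is scored on a four-step ordinal scale per tissue
compartment (0 = absent, 1 = weak, 2 = moderate, 3 = strong).  A case is
assigned to the *high* epithelium:stroma ratio group when the epithelial
score exceeds the stromal score by at least two units; a signed difference
of one or zero units (including stroma-dominant cases) is *low*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

VALID_SCORES = (0, 1, 2, 3)

HIGH = "high"
LOW = "low"

#: 19 paired (epithelium, stroma) scores of the reference colorectal cohort,
#: reconstructed from the cohort's published score distribution: the high-ratio
#: cases are enumerated directly; the low-ratio pairs are the unique completion
#: consistent with the epithelial (8 strong / 9 moderate / 2 weak) and stromal
#: (2 moderate / 12 weak / 5 absent) marginals and the two described low-ratio
#: cases.  The pairing of low-ratio cases is a documented reconstruction, not a
#: per-case record.
REFERENCE_COHORT_PAIRS: tuple[tuple[int, int], ...] = (
    # high ratio: signed difference >= 2
    (3, 0),
    (3, 1), (3, 1), (3, 1), (3, 1), (3, 1), (3, 1),
    (2, 0), (2, 0), (2, 0),
    # low ratio: signed difference <= 1
    (3, 2),
    (2, 2),
    (2, 1), (2, 1), (2, 1), (2, 1), (2, 1),
    (1, 1),
    (1, 0),
)


class InvalidScoreError(ValueError):
    """An IHC score outside the ordinal scale {0, 1, 2, 3}."""


@dataclass(frozen=True)
class IHCCase:
    """One case's paired compartment scores and derived ratio group."""

    case_id: str
    epithelium_score: int
    stroma_score: int
    ratio_group: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "ratio_group",
            expression_ratio_class(self.epithelium_score, self.stroma_score),
        )


def _check_score(score: int, label: str) -> int:
    if isinstance(score, bool) or score not in VALID_SCORES:
        raise InvalidScoreError(
            f"{label} score must be an integer in {{0,1,2,3}}, got {score!r}"
        )
    return int(score)


def expression_ratio_class(epithelium_score: int, stroma_score: int) -> str:
    """Classify a score pair into the high or low expression-ratio group.

    The difference is signed: ``high`` iff ``epithelium_score - stroma_score
    >= 2``.  Stroma-dominant cases are therefore always ``low``.
    """
    e = _check_score(epithelium_score, "epithelium")
    s = _check_score(stroma_score, "stroma")
    return HIGH if e - s >= 2 else LOW


@dataclass(frozen=True)
class CohortGrouping:
    """Per-case ratio labels plus group counts for a classified cohort."""

    cases: tuple[IHCCase, ...]
    n_high: int
    n_low: int

    @property
    def labels(self) -> dict[str, str]:
        return {c.case_id: c.ratio_group for c in self.cases}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [c.case_id for c in self.cases],
                "epithelium_score": [c.epithelium_score for c in self.cases],
                "stroma_score": [c.stroma_score for c in self.cases],
                "ratio_group": [c.ratio_group for c in self.cases],
            }
        )


def classify_cohort(cases: Iterable[IHCCase | tuple[str, int, int]]) -> CohortGrouping:
    """Apply the expression-ratio rule to every case of a cohort.

    Accepts ``IHCCase`` objects or ``(case_id, epithelium_score,
    stroma_score)`` tuples.  Case ids must be unique and the cohort
    non-empty.
    """
    normalized: list[IHCCase] = []
    for c in cases:
        if isinstance(c, IHCCase):
            normalized.append(c)
        else:
            case_id, e, s = c
            normalized.append(IHCCase(str(case_id), e, s))
    if not normalized:
        raise ValueError("cohort is empty")
    counts = Counter(c.case_id for c in normalized)
    dupes = sorted(k for k, v in counts.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate case_id(s): {dupes}")
    n_high = sum(1 for c in normalized if c.ratio_group == HIGH)
    return CohortGrouping(tuple(normalized), n_high, len(normalized) - n_high)


def reference_cohort(case_ids: Sequence[str] | None = None) -> list[IHCCase]:
    """The 19-case reference cohort as ``IHCCase`` objects.

    High-ratio pairs come first (default ids C01..C10), then low-ratio pairs
    (C11..C19), matching the synthetic generator's group layout.
    """
    pairs = REFERENCE_COHORT_PAIRS
    if case_ids is None:
        case_ids = [f"C{i:02d}" for i in range(1, len(pairs) + 1)]
    if len(case_ids) != len(pairs):
        raise ValueError(f"expected {len(pairs)} case ids, got {len(case_ids)}")
    return [IHCCase(cid, e, s) for cid, (e, s) in zip(case_ids, pairs)]


def read_score_table(path) -> list[IHCCase]:
    """Read a ``case_id,epithelium_score,stroma_score`` CSV."""
    df = pd.read_csv(path)
    required = {"case_id", "epithelium_score", "stroma_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table missing column(s): {sorted(missing)}")
    return [
        IHCCase(str(r.case_id), int(r.epithelium_score), int(r.stroma_score))
        for r in df.itertuples()
    ]


def write_grouping(path, grouping: CohortGrouping) -> None:
    grouping.to_frame().to_csv(path, index=False)
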