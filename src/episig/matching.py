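"""Age- and sex-matched control selection.

Greedy nearest-neighbour matching without replacement: cases are
visited in sample-sheet order and each receives the ``ratio``
sex-identical pool members with the smallest absolute age gap, ties
broken by lexicographic control id so the result does not depend on
pool row order. The study design this reproduces used 4 controls per
case for single-cohort discovery and 2 per case for the pooled
multi-syndrome cohort; the ratio is therefore an explicit argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import pandas as pd

from .containers import validate_sample_sheet
from .errors import MatchingError


@dataclass
class MatchResult:
    """Matched case/control pairs. Each control is used at most once."""

    pairs: List[Tuple[str, str, float]]  # (case_id, control_id, age_gap_years)
    ratio: int

    @property
    def control_ids(self) -> List[str]:
        return [c for _, c, _ in self.pairs]

    @property
    def case_ids(self) -> List[str]:
        return sorted({c for c, _, _ in self.pairs})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.pairs, columns=["case_id", "control_id", "age_gap_years"]
        )


def match_controls(
    cases: pd.DataFrame, pool: pd.DataFrame, ratio: int = 4
) -> MatchResult:
    """Select ``ratio`` age/sex-matched controls per case, without replacement.

    Raises :class:`MatchingError` naming the first case for which the
    remaining pool has too few sex-compatible members.
    """
    validate_sample_sheet(cases)
    validate_sample_sheet(pool)
    if ratio < 1:
        raise MatchingError("matching ratio must be at least 1")
    available = {sid: (row["sex"], float(row["age_years"])) for sid, row in pool.iterrows()}
    pairs: List[Tuple[str, str, float]] = []
    for case_id, case in cases.iterrows():
        candidates = sorted(
            (
                (abs(age - float(case["age_years"])), cid)
                for cid, (sex, age) in available.items()
                if sex == case["sex"]
            ),
        )
        if len(candidates) < ratio:
            raise MatchingError(
                f"case {case_id!r} ({case['sex']}): only {len(candidates)} "
                f"sex-compatible controls left, {ratio} required"
            )
        for gap, cid in candidates[:ratio]:
            pairs.append((case_id, cid, gap))
            del available[cid]
    return MatchResult(pairs=pairs, ratio=ratio)


def audit_match(result: MatchResult, cases: pd.DataFrame, pool: pd.DataFrame) -> dict:
    """Summarise a matching: age-gap statistics and sex concordance."""
    gaps = [gap for _, _, gap in result.pairs]
    concordant = sum(
        1
        for case_id, control_id, _ in result.pairs
        if cases.loc[case_id, "sex"] == pool.loc[control_id, "sex"]
    )
    n = len(result.pairs)
    return {
        "n_pairs": n,
        "ratio": result.ratio,
        "max_age_gap_years": max(gaps) if gaps else 0.0,
        "mean_age_gap_years": sum(gaps) / n if n else 0.0,
        "sex_concordance": concordant / n if n else 1.0,
    }
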