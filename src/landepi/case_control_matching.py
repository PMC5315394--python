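"""Individual 6:1 control matching.

Each case receives ``ratio`` controls drawn uniformly without
replacement from pool members sharing its stratum (sex, birth year,
region).  Subjects whose geocoding failed are never selected — drawing
only from validly geocoded candidates is equivalent to drawing,
discarding invalid picks and redrawing replacements from the same
stratum, which mirrors how the registry study replaced its ~2% of
failed control geocodes.  No control serves two cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MatchedSet", "MatchingError", "match_controls", "matched_sets_frame"]


@dataclass
class MatchedSet:
    case_id: str
    control_ids: list[str]
    stratum: tuple  # (sex, birth_year, region)


class MatchingError(RuntimeError):
    def __init__(self, stratum, needed: int, available: int):
        self.stratum = stratum
        self.shortfall = needed - available
        super().__init__(
            f"stratum {stratum}: need {needed} eligible controls, "
            f"only {available} available (shortfall {self.shortfall})"
        )


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 6,
    seed: int = 0,
    year_window: int = 0,
) -> list[MatchedSet]:
    """Draw ``ratio`` matched controls per case, without reuse.

    Deterministic given inputs and seed: cases are processed in id
    order and draws use a single seeded generator.  ``year_window``
    relaxes birth-year matching to +/- that many years (default exact).
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    for col in ("sex", "birth_year", "region"):
        if col not in pool.columns or col not in cases.columns:
            raise ValueError(f"missing matching variable {col!r}")
    rng = np.random.default_rng(seed)
    eligible = pool[pool["geocode_valid"].astype(bool)]
    by_stratum: dict[tuple, list[str]] = {
        key: list(grp["id"])
        for key, grp in eligible.groupby(["sex", "birth_year", "region"], sort=True)
    }
    used: set[str] = set()
    sets: list[MatchedSet] = []
    for _, case in cases.sort_values("id").iterrows():
        stratum = (case["sex"], int(case["birth_year"]), case["region"])
        if year_window == 0:
            candidates = by_stratum.get(stratum, [])
        else:
            candidates = [
                cid
                for year in range(stratum[1] - year_window, stratum[1] + year_window + 1)
                for cid in by_stratum.get((stratum[0], year, stratum[2]), [])
            ]
        candidates = [c for c in candidates if c not in used and c != case["id"]]
        if len(candidates) < ratio:
            raise MatchingError(stratum, ratio, len(candidates))
        picks = rng.choice(len(candidates), size=ratio, replace=False)
        chosen = [candidates[i] for i in sorted(picks)]
        used.update(chosen)
        sets.append(MatchedSet(case_id=case["id"], control_ids=chosen, stratum=stratum))
    return sets


def matched_sets_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    """Long-format table of matched pairs (one row per control)."""
    rows = [
        {
            "case_id": s.case_id,
            "control_id": cid,
            "sex": s.stratum[0],
            "birth_year": s.stratum[1],
            "region": s.stratum[2],
        }
        for s in sets
        for cid in s.control_ids
    ]
    return pd.DataFrame(rows)
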