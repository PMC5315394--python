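"""Census-tract socioeconomic status assignment and quartiling.

Every residence inherits the socioeconomic value of the census tract
containing it (tracts partition the territory).  The continuous value is
categorised into quartiles for modelling; cut-points are the 25/50/75
linear-interpolation percentiles of a reference population (the matched
controls by default) and labelling uses half-open intervals, so Q2 =
[q25, q50) and Q4 contains the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import shapely

from .geoio import Landscape

__all__ = ["SesAssignment", "assign_ses", "assign_ses_bulk", "ses_quartiles", "quartile_labels"]

QUARTILE_LABELS = np.array(["Q1", "Q2", "Q3", "Q4"], dtype=object)


@dataclass
class SesAssignment:
    ses_value: float
    tract_id: str
    quartile: str | None = None


def _tract_layer(tracts):
    if isinstance(tracts, Landscape):
        return tracts.tracts, tracts.tract_ses, tracts.tract_id
    polys, ses, ids = tracts
    return (
        np.asarray(polys, dtype=object),
        np.asarray(ses, dtype=float),
        np.asarray(ids, dtype=object),
    )


def assign_ses(point, tracts) -> SesAssignment:
    """SES value of the tract containing one residence."""
    if isinstance(point, shapely.Geometry):
        pt = point
    else:
        pt = shapely.points(*point)
    df = assign_ses_bulk([pt], tracts)
    return SesAssignment(
        ses_value=float(df["ses_value"].iloc[0]), tract_id=str(df["tract_id"].iloc[0])
    )


def assign_ses_bulk(points, tracts) -> pd.DataFrame:
    """Vectorised tract join.

    Boundary points (in more than one tract's closure) resolve to the
    lowest tract index, deterministically.  A point in no tract raises,
    since tracts must partition the extent.
    """
    polys, ses, ids = _tract_layer(tracts)
    pts = np.asarray(points, dtype=object) if not isinstance(points, np.ndarray) else points
    tree = shapely.STRtree(polys)
    pi, ti = tree.query(pts, predicate="intersects")
    assignment = np.full(len(pts), -1, dtype=int)
    # reversed order so the lowest tract index wins ties
    order = np.lexsort((-ti, pi))
    assignment[pi[order]] = ti[order]
    missing = np.flatnonzero(assignment < 0)
    if len(missing):
        raise ValueError(
            f"{len(missing)} point(s) fall in no census tract (first: index {missing[0]})"
        )
    return pd.DataFrame({"ses_value": ses[assignment], "tract_id": ids[assignment]})


def ses_quartiles(
    values, status=None, reference: str = "controls"
) -> tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]:
    """Quartile cut-points and a labeller.

    ``values`` are subject-level SES values; when ``reference`` is
    ``"controls"``, ``status`` must be given and only control subjects
    define the cut-points (the study convention, which yields exactly
    equal control counts per quartile).  Returns the three cut-points and
    a function mapping values to labels Q1..Q4.
    """
    values = np.asarray(values, dtype=float)
    if reference == "controls":
        if status is None:
            raise ValueError("reference='controls' requires a status vector")
        ref = values[np.asarray(status) == "control"]
    elif reference == "all":
        ref = values
    else:
        raise ValueError(f"unknown reference {reference!r}")
    if len(np.unique(ref[np.isfinite(ref)])) < 4:
        raise ValueError("need at least 4 distinct reference SES values")
    cuts = np.percentile(ref[np.isfinite(ref)], [25, 50, 75], method="linear")

    def labeller(v) -> np.ndarray:
        return quartile_labels(v, cuts)

    return cuts, labeller


def quartile_labels(values, cuts) -> np.ndarray:
    """Label values into Q1..Q4 by half-open intervals [q25, q50) etc."""
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(np.asarray(cuts, dtype=float), values, side="right")
    out = QUARTILE_LABELS[idx]
    return np.where(np.isfinite(values), out, None)
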