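"""Recording-site statistics: variance-based dorsoventral border search.

Central-nucleus (CE, dorsal) units show more variable background firing
rates than basolateral/lateral (BL/L, ventral) units.  The border is found
by sliding a candidate depth in 0.2-mm steps and taking the depth with the
lowest two-sample F-test p-value for the dorsal-vs-ventral variance of
background firing rate.  The minimum p over candidates is reported
uncorrected for the search (a selection bias documented, matching the
procedure, not corrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class BorderResult:
    border_depth_mm: float
    p_value: float
    f_statistic: float
    variance_dorsal: float
    variance_ventral: float
    n_dorsal: int
    n_ventral: int
    candidate_grid: np.ndarray


def variance_f_test(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sample F-test of equal variances (two-sided).

    F = var(a)/var(b) with (n_a - 1, n_b - 1) df; identical variances give
    F = 1, p = 1.
    """
    # sort so the variance's summation order (and hence the result, to the
    # last ulp) is independent of unit ordering
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 values per side")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    if vb == 0 and va == 0:
        return {"F": 1.0, "p": 1.0, "df": (dfa, dfb),
                "var_a": 0.0, "var_b": 0.0}
    if vb == 0:
        return {"F": np.inf, "p": 0.0, "df": (dfa, dfb),
                "var_a": float(va), "var_b": 0.0}
    f = va / vb
    p = 2.0 * min(stats.f.sf(f, dfa, dfb), stats.f.cdf(f, dfa, dfb))
    return {"F": float(f), "p": float(min(p, 1.0)), "df": (dfa, dfb),
            "var_a": float(va), "var_b": float(vb)}


def dorsoventral_border(units, step: float = 0.2, min_per_side: int = 5,
                        alpha: float = 0.05) -> Optional[BorderResult]:
    """Search the depth grid for the background-FR variance border.

    For each candidate depth on the ``step``-mm grid with at least
    ``min_per_side`` units on each side, a two-sample F-test compares the
    variance of background firing rate dorsal (< candidate) vs ventral
    (>= candidate).  Returns the candidate with the lowest p (ties ->
    shallowest), or None when the best p >= alpha.  Deterministic and
    invariant to unit ordering.
    """
    depths = np.asarray([u.depth for u in units], dtype=float)
    frs = np.asarray([u.background_fr for u in units], dtype=float)
    if len(units) < 2 * min_per_side:
        raise InsufficientDataError(
            f"need >= {2 * min_per_side} units with depth and background FR")
    lo = np.ceil(depths.min() / step) * step
    hi = np.floor(depths.max() / step) * step
    grid = np.round(np.arange(lo, hi + step / 2, step), 10)
    best = None
    for cand in grid:
        dorsal = frs[depths < cand]
        ventral = frs[depths >= cand]
        if len(dorsal) < min_per_side or len(ventral) < min_per_side:
            continue
        res = variance_f_test(dorsal, ventral)
        if best is None or res["p"] < best[1]["p"]:
            best = (cand, res, len(dorsal), len(ventral))
    if best is None:
        raise InsufficientDataError("no candidate depth had enough units "
                                    "on both sides")
    cand, res, n_d, n_v = best
    if res["p"] >= alpha:
        return None
    return BorderResult(border_depth_mm=float(cand), p_value=res["p"],
                        f_statistic=res["F"],
                        variance_dorsal=res["var_a"],
                        variance_ventral=res["var_b"],
                        n_dorsal=n_d, n_ventral=n_v, candidate_grid=grid)


def assign_region(unit, border_depth_mm: Optional[float]) -> str:
    """Assign a unit to the dorsal (CE-like) or ventral (BL/L-like) region.

    Depth < border -> dorsal; ties (depth == border) -> dorsal.
    """
    if border_depth_mm is None:
        raise ValueError("border is undefined")
    return "dorsal" if unit.depth <= border_depth_mm else "ventral"


def region_variance_compare(units, border_depth_mm: float,
                            values: Optional[dict] = None,
                            metric: str = "background_fr") -> dict:
    """Two-sample F-test of a metric's variance dorsal vs ventral.

    ``metric`` is ``background_fr`` (read off the unit records) or any key
    into ``values`` (unit_id -> value), e.g. a per-context selectivity
    index in the free-viewing or fixation window.
    """
    dorsal, ventral = [], []
    for u in units:
        if metric == "background_fr":
            v = u.background_fr
        else:
            if values is None or u.unit_id not in values:
                continue
            v = values[u.unit_id]
        (dorsal if assign_region(u, border_depth_mm) == "dorsal"
         else ventral).append(v)
    if len(dorsal) < 2 or len(ventral) < 2:
        raise InsufficientDataError("need >= 2 units per side")
    res = variance_f_test(dorsal, ventral)
    res["n_dorsal"], res["n_ventral"] = len(dorsal), len(ventral)
    res["variance_dorsal"], res["variance_ventral"] = (res.pop("var_a"),
                                                       res.pop("var_b"))
    return res
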