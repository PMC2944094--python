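"""Distance-band risk tables and tests of risk variation across bands.

Given an area-to-band assignment, observed and expected counts are
aggregated per band and each band gets an SIR with CI.  Two tests, both
conditional on the overall ratio theta = sum(O)/sum(E):

homogeneity
    X^2 = sum_k (O_k - theta E_k)^2 / (theta E_k), chi-square on K-1 df —
    is risk constant across bands?

linear trend
    Poisson score test of slope zero in O_k ~ Poisson(E_k e^{b0 + b1 x_k}):
    U = sum x_k O_k - theta sum x_k E_k,
    V = theta [sum x_k^2 E_k - (sum x_k E_k)^2 / sum E_k],
    z = U / sqrt(V), two-sided normal p.

With K = 2 bands the two are the same test: X^2 = z^2 exactly.  Default
band scores are the band midpoint distances in km; band rank is available
for schemes whose distances are not meaningful scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import BandScheme
from .health import CountTable, PopulationTable
from .standardize import ReferenceRates, StandardizedResult, expected_count, indirect_ratio

__all__ = [
    "BandRiskTable",
    "BandTestResult",
    "band_risks",
    "homogeneity_test",
    "trend_test",
]


@dataclass
class BandTestResult:
    statistic: float
    df: int | None
    p_value: float
    test: str


@dataclass
class BandRiskTable:
    """Per-band observed, expected and SIR, plus the overall ratio."""

    table: pd.DataFrame  # columns: band, observed, expected, sir, ci_lower, ci_upper
    results: dict[int, StandardizedResult]
    overall: StandardizedResult
    excluded_bands: list[int]

    @property
    def observed(self) -> np.ndarray:
        return self.table["observed"].to_numpy()

    @property
    def expected(self) -> np.ndarray:
        return self.table["expected"].to_numpy()

    def tests(self, scores=None, scheme: BandScheme | None = None) -> dict[str, BandTestResult]:
        """Homogeneity and trend tests over the non-excluded bands."""
        if scores is None:
            if scheme is not None:
                mids = scheme.midpoints_km()
                scores = [mids[b - 1] for b in self.table["band"]]
            else:
                scores = self.table["band"].to_numpy(dtype=float)  # band rank
        return {
            "homogeneity": homogeneity_test(self.observed, self.expected),
            "trend": trend_test(self.observed, self.expected, scores),
        }


def band_risks(membership: dict[str, int | None], counts: CountTable,
               population: PopulationTable, ref: ReferenceRates,
               strata=None, level: float = 0.95) -> BandRiskTable:
    """Aggregate O and E over the member areas of each distance band.

    Areas mapped to ``None`` (outside all bands) are excluded.  Bands with
    zero expected count are flagged and left out of the test table.  The
    overall row pools every in-band area, so a single band containing all
    areas reproduces the whole-study SIR.
    """
    assigned = {a: b for a, b in membership.items() if b is not None}
    if not assigned:
        raise ValueError("no areas assigned to any band")

    e_by_area = expected_count(population, ref, strata=strata, by_area=True)
    o_by_area = counts.data.groupby("area_id")["events"].sum()

    rows = []
    results: dict[int, StandardizedResult] = {}
    excluded: list[int] = []
    for band in sorted(set(assigned.values())):
        areas = [a for a, b in assigned.items() if b == band]
        o = int(o_by_area.reindex(areas).fillna(0).sum())
        e = float(e_by_area.reindex(areas).fillna(0).sum())
        if e <= 0:
            warnings.warn(f"band {band} has zero expected count; excluded from tests",
                          stacklevel=2)
            excluded.append(band)
            continue
        res = indirect_ratio(o, e, level=level)
        results[band] = res
        rows.append({"band": band, "observed": o, "expected": e, "sir": res.ratio,
                     "ci_lower": res.ci[0], "ci_upper": res.ci[1]})

    if not rows:
        raise ValueError("every band has zero expected count")
    table = pd.DataFrame(rows)
    o_tot = int(table["observed"].sum())
    e_tot = float(table["expected"].sum())
    overall = indirect_ratio(o_tot, e_tot, level=level)
    return BandRiskTable(table=table, results=results, overall=overall,
                         excluded_bands=excluded)


def homogeneity_test(observed, expected) -> BandTestResult:
    """Chi-square test of a common ratio across bands, K-1 df."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if len(o) != len(e):
        raise ValueError("observed and expected differ in length")
    if len(o) < 2:
        raise ValueError("homogeneity test needs at least 2 bands")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    theta = o.sum() / e.sum()
    x2 = float(np.sum((o - theta * e) ** 2 / (theta * e)))
    df = len(o) - 1
    p = float(stats.chi2.sf(x2, df))
    return BandTestResult(statistic=x2, df=df, p_value=p, test="homogeneity")


def trend_test(observed, expected, scores) -> BandTestResult:
    """Poisson score test for a log-linear trend in risk across bands."""
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    x = np.asarray(scores, dtype=float)
    if not (len(o) == len(e) == len(x)):
        raise ValueError("observed, expected and scores differ in length")
    if len(o) < 2:
        raise ValueError("trend test needs at least 2 bands")
    if np.any(e <= 0):
        raise ValueError("all expected counts must be positive")
    theta = o.sum() / e.sum()
    u = float(np.sum(x * o) - theta * np.sum(x * e))
    v = float(theta * (np.sum(x**2 * e) - np.sum(x * e) ** 2 / np.sum(e)))
    if v <= 0:
        raise ValueError("degenerate scores (zero variance across bands)")
    z = u / np.sqrt(v)
    p = float(2 * stats.norm.sf(abs(z)))
    return BandTestResult(statistic=float(z), df=None, p_value=p, test="linear_trend")
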