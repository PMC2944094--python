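"""Direct and indirect standardization with confidence intervals.

Indirect standardization projects the sex- and age-specific rates of a
reference population onto the study population's stratum structure to give
expected counts E; the standardized incidence/mortality ratio is O/E with a
confidence interval from Byar's cube-root approximation to the exact
Poisson interval (the default, which reproduces published SIR tables at
2 dp) or from the chi-square inversion of the exact Poisson interval.

Direct standardization applies study-population stratum-specific rates to a
standard population's stratum weights; its CI uses the Fay-Feuer gamma
method.  A Carstairs-style deprivation index (sum of z-scores of male
unemployment, lack of car access, low social class and overcrowding) feeds
area-level covariate adjustment via quintiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .health import CountTable, PopulationTable, assign_quintiles

__all__ = [
    "ReferenceRates",
    "StandardizedResult",
    "DirectRateResult",
    "expected_count",
    "indirect_ratio",
    "direct_rate",
    "carstairs_index",
    "byar_ci",
    "exact_poisson_ci",
]

DEFAULT_STRATA = ("sex", "age_band")


@dataclass
class ReferenceRates:
    """Stratum-specific event rates of the reference population.

    ``data`` has the stratum columns plus ``rate`` (events per person-year).
    Build from raw reference counts + person-years with :meth:`from_tables`,
    or supply precomputed rates directly.
    """

    data: pd.DataFrame
    strata: tuple[str, ...] = DEFAULT_STRATA

    def __post_init__(self):
        self.strata = tuple(self.strata)
        missing = [c for c in self.strata + ("rate",) if c not in self.data.columns]
        if missing:
            raise ValueError(f"reference rates missing columns {missing}")
        if (self.data["rate"] < 0).any():
            raise ValueError("negative reference rate")
        if self.data.duplicated(subset=list(self.strata)).any():
            raise ValueError("duplicate reference strata")

    @classmethod
    def from_tables(cls, counts: CountTable, population: PopulationTable,
                    strata=DEFAULT_STRATA, exclude_areas=None) -> "ReferenceRates":
        """Aggregate raw reference counts and person-years into rates.

        ``exclude_areas`` removes the study areas from the reference (by
        default a whole-region reference includes them, as when a state's
        own rates are the comparison for districts within it).
        """
        strata = tuple(strata)
        cdf, pdf = counts.data, population.data
        if exclude_areas:
            excl = set(exclude_areas)
            cdf = cdf[~cdf["area_id"].isin(excl)]
            pdf = pdf[~pdf["area_id"].isin(excl)]
        o = cdf.groupby(list(strata), observed=True)["events"].sum()
        n = pdf.groupby(list(strata), observed=True)["person_years"].sum()
        merged = pd.concat([o, n], axis=1).fillna({"events": 0.0})
        if merged["person_years"].isna().any() or (merged["person_years"] == 0).any():
            zero = merged[~(merged["person_years"] > 0)].index.tolist()
            raise ValueError(f"reference strata with events but no person-years: {zero}")
        merged["rate"] = merged["events"] / merged["person_years"]
        return cls(merged.reset_index()[list(strata) + ["rate"]], strata=strata)


@dataclass
class StandardizedResult:
    """An indirectly standardized ratio (SIR or SMR) with its CI."""

    observed: int
    expected: float
    ci: tuple[float, float]
    level: float = 0.95
    kind: str = "SIR"
    method: str = "byar"
    adjustment: tuple[str, ...] = DEFAULT_STRATA

    @property
    def ratio(self) -> float:
        return self.observed / self.expected

    def rounded(self, dp: int = 2) -> tuple[float, float, float]:
        """(ratio, lower, upper) rounded half-even to ``dp`` places, the
        convention used for report tables; internal values are never rounded."""
        r = np.round([self.ratio, *self.ci], dp)
        return float(r[0]), float(r[1]), float(r[2])


@dataclass
class DirectRateResult:
    """A directly standardized rate per ``per`` person-years with gamma CI."""

    rate: float
    ci: tuple[float, float]
    per: float = 1e5
    level: float = 0.95
    standard_population: str = ""
    observed: int = 0


# ---------------------------------------------------------------------------
# Expected counts
# ---------------------------------------------------------------------------

def expected_count(study_pop: PopulationTable, ref: ReferenceRates,
                   strata=None, by_area: bool = False):
    """Expected events E = sum over strata of person-years x reference rate.

    With ``by_area`` the sum is returned per area as a Series (additive over
    disjoint area sets by construction); otherwise a single float.

    Raises
    ------
    ValueError
        Naming any study stratum that has person-years but no reference
        rate.
    """
    strata = tuple(strata) if strata is not None else ref.strata
    if set(strata) - set(ref.strata):
        raise ValueError(
            f"adjustment strata {strata} not all present in reference {ref.strata}"
        )
    rates = ref.data.groupby(list(strata), observed=True)["rate"].mean().rename("rate")
    pop = study_pop.data
    merged = pop.merge(rates.reset_index(), on=list(strata), how="left")
    missing = merged["rate"].isna() & (merged["person_years"] > 0)
    if missing.any():
        miss = merged.loc[missing, list(strata)].drop_duplicates()
        raise ValueError(
            "missing reference rate for study strata: "
            + "; ".join(str(tuple(r)) for r in miss.itertuples(index=False))
        )
    merged["rate"] = merged["rate"].fillna(0.0)
    merged["e"] = merged["person_years"] * merged["rate"]
    if by_area:
        return merged.groupby("area_id")["e"].sum()
    return float(merged["e"].sum())


# ---------------------------------------------------------------------------
# Confidence intervals on a Poisson count ratio
# ---------------------------------------------------------------------------

def byar_ci(observed: int, expected: float, level: float = 0.95) -> tuple[float, float]:
    """Byar's cube-root approximation to the exact Poisson CI on O/E.

    lower = O (1 - 1/(9O) - z/(3 sqrt(O)))^3 / E   (0 when O = 0)
    upper = (O+1)(1 - 1/(9(O+1)) + z/(3 sqrt(O+1)))^3 / E
    """
    z = stats.norm.ppf(0.5 + level / 2)
    o = float(observed)
    if o > 0:
        lower = o * (1 - 1 / (9 * o) - z / (3 * math.sqrt(o))) ** 3 / expected
    else:
        lower = 0.0
    op = o + 1
    upper = op * (1 - 1 / (9 * op) + z / (3 * math.sqrt(op))) ** 3 / expected
    return max(lower, 0.0), upper


def exact_poisson_ci(observed: int, expected: float,
                     level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson CI on O/E via chi-square inversion."""
    alpha = 1 - level
    o = int(observed)
    lower = 0.0 if o == 0 else stats.chi2.ppf(alpha / 2, 2 * o) / 2 / expected
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * (o + 1)) / 2 / expected
    return lower, upper


_CI_METHODS = {"byar": byar_ci, "exact_poisson": exact_poisson_ci}


def indirect_ratio(observed: int, expected: float, level: float = 0.95,
                   method: str = "byar", kind: str = "SIR",
                   adjustment=DEFAULT_STRATA) -> StandardizedResult:
    """Standardized incidence/mortality ratio O/E with Poisson CI."""
    if expected <= 0:
        raise ValueError(f"expected count must be positive, got {expected}")
    if observed < 0:
        raise ValueError(f"observed count must be non-negative, got {observed}")
    try:
        ci_fn = _CI_METHODS[method]
    except KeyError:
        raise ValueError(f"unknown CI method {method!r}; use byar or exact_poisson")
    ci = ci_fn(observed, expected, level)
    return StandardizedResult(observed=int(observed), expected=float(expected),
                              ci=ci, level=level, kind=kind, method=method,
                              adjustment=tuple(adjustment))


# ---------------------------------------------------------------------------
# Direct standardization
# ---------------------------------------------------------------------------

def direct_rate(study_counts: CountTable, study_pop: PopulationTable,
                standard_weights: pd.Series | dict, per: float = 1e5,
                level: float = 0.95, strata=DEFAULT_STRATA,
                label: str = "") -> DirectRateResult:
    """Directly standardized rate: per x sum_s w_s (o_s / n_s).

    ``standard_weights`` maps stratum keys (tuples over ``strata``, or a
    Series with a matching MultiIndex) to standard-population person-years
    or shares; they are normalized to sum to one.  The CI is the Fay-Feuer
    gamma interval on the weighted sum.
    """
    strata = list(strata)
    o = study_counts.data.groupby(strata, observed=True)["events"].sum()
    n = study_pop.data.groupby(strata, observed=True)["person_years"].sum()
    if isinstance(standard_weights, dict):
        w = pd.Series(standard_weights)
        if len(strata) > 1:
            w.index = pd.MultiIndex.from_tuples(w.index, names=strata)
    else:
        w = standard_weights.copy()
    w = w / w.sum()

    df = pd.concat([o.rename("o"), n.rename("n")], axis=1).fillna({"o": 0})
    bad = df[(df["o"] > 0) & ~(df["n"] > 0)]
    if len(bad):
        raise ValueError(f"strata with events but zero person-years: {bad.index.tolist()}")
    df = df[df["n"] > 0]
    w = w.reindex(df.index).fillna(0.0)

    rates = df["o"] / df["n"]
    x = float((w * rates).sum())
    v = float((w**2 * df["o"] / df["n"] ** 2).sum())
    alpha = 1 - level
    if x > 0 and v > 0:
        lower = stats.gamma.ppf(alpha / 2, a=x**2 / v, scale=v / x)
    else:
        lower = 0.0
    wm = float((w / df["n"]).max()) if len(df) else 0.0
    xm, vm = x + wm, v + wm**2
    upper = stats.gamma.ppf(1 - alpha / 2, a=xm**2 / vm, scale=vm / xm) if vm > 0 else 0.0
    return DirectRateResult(rate=per * x, ci=(per * lower, per * upper), per=per,
                            level=level, standard_population=label,
                            observed=int(df["o"].sum()))


# ---------------------------------------------------------------------------
# Carstairs deprivation index
# ---------------------------------------------------------------------------

CARSTAIRS_COMPONENTS = (
    "male_unemployment",
    "no_car_access",
    "low_social_class",
    "overcrowding",
)


def carstairs_index(inputs: pd.DataFrame) -> pd.Series:
    """Area deprivation index: sum of the four component z-scores.

    ``inputs`` is indexed by area_id with proportion columns
    ``male_unemployment, no_car_access, low_social_class, overcrowding``
    (car access entered as *lack* of access, so every component increases
    with deprivation).  Z-scores use the unweighted area-level mean and SD.
    A zero-variance component carries no information and is dropped with a
    warning.  Larger index = more deprived; quintiles then come from
    :func:`rifkit.health.assign_quintiles`.
    """
    missing = [c for c in CARSTAIRS_COMPONENTS if c not in inputs.columns]
    if missing:
        raise ValueError(f"missing Carstairs components: {missing}")
    if len(inputs) < 2:
        raise ValueError("need at least 2 areas to standardize components")
    vals = inputs[list(CARSTAIRS_COMPONENTS)].astype(float)
    if ((vals < 0) | (vals > 1)).any().any():
        raise ValueError("Carstairs components must be proportions in [0, 1]")
    index = pd.Series(0.0, index=inputs.index)
    for comp in CARSTAIRS_COMPONENTS:
        col = vals[comp]
        sd = col.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            warnings.warn(f"zero variance in {comp!r}; component dropped", stacklevel=2)
            continue
        index = index + (col - col.mean()) / sd
    return index


def carstairs_quintiles(inputs: pd.DataFrame) -> dict[str, int]:
    """Convenience: Carstairs index then quintile assignment (1 = least deprived)."""
    idx = carstairs_index(inputs)
    return assign_quintiles(idx.to_dict())
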