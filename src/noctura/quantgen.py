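"""Quantitative-genetic estimation for truncation-selection experiments.

Three estimators of the narrow-sense heritability of diurnal preference:

* **realized heritability** — the slope (through the origin) of cumulative
  selection response on cumulative selection differential over the cycles of
  an artificial-selection experiment, with a parametric-bootstrap variance
  for genetic drift;
* **mid-parent regression** — slope of mid-progeny phenotype on mid-parent
  phenotype, which estimates h^2 directly;
* **single-parent regression** — slope of offspring on one parent, doubled.

The selection differential for a male-only selection scheme with unselected
female mates charges both sexes equally:
``S = 1/2 (mean selected males - pop mean) + 1/2 (mean mates - pop mean)``,
using the mates' actual (realized) phenotypic deviation, which keeps the
realized-h^2 regression consistent conditional on the mates actually used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats


@dataclass
class SelectionCycleRecord:
    """Per-cycle bookkeeping of a selection experiment (phenotype units)."""

    cycle: int
    pop_mean: float
    pop_var: float
    selected_male_mean: float
    sibling_female_mean: float
    progeny_mean: float
    S: float
    R: float
    cum_S: float
    cum_R: float
    n_phenotyped: int
    n_selected: int

    def __post_init__(self) -> None:
        if self.n_selected > self.n_phenotyped:
            raise ValueError("n_selected cannot exceed n_phenotyped")


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float
    method: Literal["realized", "midparent", "single_parent"]
    drift_var: float | None = None
    pvalue: float | None = None

    @property
    def h2_percent(self) -> float:
        return 100.0 * self.h2


def selection_differential(
    pop_phenos: Sequence[float],
    selected_male_phenos: Sequence[float],
    sibling_female_phenos: Sequence[float],
) -> float:
    """Equal-sex-weight selection differential S.

    ``S = 1/2 (mean selected males - pop mean) + 1/2 (mean mates - pop mean)``.
    Mates drawn at random have zero expected deviation, so one-sex selection
    gives S = half the male differential in expectation.
    """
    pop = np.asarray(pop_phenos, dtype=float)
    males = np.asarray(selected_male_phenos, dtype=float)
    females = np.asarray(sibling_female_phenos, dtype=float)
    if males.size == 0 or females.size == 0:
        raise ValueError("selected sets must be non-empty")
    mu = pop.mean()
    return float(0.5 * (males.mean() - mu) + 0.5 * (females.mean() - mu))


def cumulate(records: Sequence[SelectionCycleRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(cum_S, cum_R) arrays from per-cycle records, verified as running sums."""
    cs = np.array([r.cum_S for r in records], dtype=float)
    cr = np.array([r.cum_R for r in records], dtype=float)
    s = np.array([r.S for r in records], dtype=float)
    r = np.array([r.R for r in records], dtype=float)
    if not (np.allclose(np.cumsum(s), cs) and np.allclose(np.cumsum(r), cr)):
        raise ValueError("cum_S/cum_R are not running sums of S/R")
    return cs, cr


def _origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope through the origin and its standard error."""
    sxx = float((x * x).sum())
    if sxx == 0.0:
        raise ValueError("no selection applied")
    b = float((x * y).sum() / sxx)
    n = x.size
    if n > 1:
        resid = y - b * x
        se = float(np.sqrt((resid @ resid) / (n - 1) / sxx))
    else:
        se = float("nan")
    return b, se


def realized_h2(
    cycles: Sequence[SelectionCycleRecord],
    n_boot: int = 0,
    rng: np.random.Generator | None = None,
) -> HeritabilityEstimate:
    """Realized heritability from a selection experiment.

    h^2 is the least-squares slope of cumulative response on cumulative
    selection differential with the intercept fixed at zero (zero cumulative
    selection must give zero expected response).  With ``n_boot > 0`` a
    parametric bootstrap re-simulates the same design (population size,
    number selected, number of cycles, phenotypic variance) at the estimated
    h^2 and reports the variance of the re-estimated slope as the drift
    variance of the estimate.
    """
    if len(cycles) < 2:
        raise ValueError("need at least two selection cycles")
    cs, cr = cumulate(cycles)
    if np.allclose(cs, 0.0):
        raise ValueError("no selection applied")
    b, se = _origin_slope(cs, cr)
    drift_var = None
    if n_boot > 0:
        from .synthetic_data import SimConfig, run_selection_experiment

        rng = np.random.default_rng() if rng is None else rng
        h2_sim = float(np.clip(b, 0.0, 1.0))
        direction = "nocturnal" if cs[-1] >= 0 else "diurnal"
        config = SimConfig(
            n_pop=cycles[0].n_phenotyped,
            n_selected=cycles[0].n_selected,
            n_cycles=len(cycles),
            h2=h2_sim,
            vp=float(np.mean([r.pop_var for r in cycles])),
        )
        slopes = np.empty(n_boot)
        for i in range(n_boot):
            rec, _ = run_selection_experiment(config, direction=direction, rng=rng)
            bs, br = cumulate(rec)
            slopes[i], _ = _origin_slope(bs, br)
        drift_var = float(slopes.var(ddof=1))
    return HeritabilityEstimate(h2=b, se=se, method="realized",
                                drift_var=drift_var)


def parent_offspring_h2(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    mode: Literal["midparent", "single_mother", "single_father"] = "midparent",
) -> HeritabilityEstimate:
    """Heritability from parent-offspring regression.

    ``pairs`` holds (parent predictor, offspring value) rows; the predictor is
    the mid-parent value for ``midparent`` mode or one parent's phenotype for
    the single-parent modes.  h^2 equals the OLS slope for mid-parent
    regression and twice the slope for single-parent regression (one parent
    transmits half the additive effects); the p-value is the two-sided test
    of zero slope.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (parent, offspring) rows")
    if arr.shape[0] < 3:
        raise ValueError("need at least three pairs")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in pairs")
    parent, offspring = arr[:, 0], arr[:, 1]
    if np.ptp(parent) == 0:
        raise ValueError("zero variance in parent predictor")
    res = stats.linregress(parent, offspring)
    factor = 1.0 if mode == "midparent" else 2.0
    if mode not in ("midparent", "single_mother", "single_father"):
        raise ValueError(f"unknown mode {mode!r}")
    return HeritabilityEstimate(
        h2=factor * float(res.slope),
        se=factor * float(res.stderr),
        method="midparent" if mode == "midparent" else "single_parent",
        pvalue=float(res.pvalue),
    )
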