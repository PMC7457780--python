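"""Simulator of heritable diurnal preference and its measurement.

Everything the downstream estimators consume can be generated here:

* an infinitesimal-model population with an additive nocturnality trait
  (breeding values Gaussian, offspring = mid-parent + Mendelian-sampling
  deviation of variance ``h2 * Vp / 2``);
* per-fly actograms — Poisson counts around a crepuscular two-bump (von
  Mises) activity template, entrained in LD, free-running at the fly's own
  period tau in DD, with light masking pulling the expressed night/day ratio
  in LD away from the endogenous one;
* multi-cycle truncation-selection experiments mirroring a design in which
  300 males are phenotyped per cycle and the 25 most extreme are each crossed
  to an unselected female;
* parent-offspring family tables for regression heritability;
* cross tables for the quantitative complementation test.

The trait is the ND ratio itself (night/day activity), floored at a small
positive value.  Masking is parameterised by ``masking_m >= 0``: the measured
log ND excess over the template's intrinsic ratio in constant darkness is the
LD excess divided by ``1 + masking_m``, so ``masking_m = 0`` means no masking
(the DD ratio matches the LD ratio in expectation) and large ``masking_m``
means the LD phenotype is mostly a direct light effect that vanishes in DD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .actogram_io import ActivitySeries, LightRegime, annotate_light
from .complementation import QCTTable
from .quantgen import SelectionCycleRecord

logger = logging.getLogger(__name__)

_T0_DEFAULT = pd.Timestamp("2017-08-08 08:00:00")  # lights-on, day 0


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the selection design being emulated: 300 males phenotyped
    per cycle, the 25 most extreme selected, 10 cycles.  The base population
    is crepuscular (mean ND ratio 1.0) with phenotypic variance 0.0225
    (sd 0.15 on the ratio scale) and a base-population heritability of 0.14.
    ``full_sib_mates`` controls whether a selected male's mate is modelled as
    his genetic full sister (literal sib mating) or as an unselected female
    genetically exchangeable with the population (the default, under which
    the realized-heritability regression is a consistent estimator of h2).
    """

    n_pop: int = 300
    n_selected: int = 25
    n_cycles: int = 10
    h2: float = 0.14
    nd_mean: float = 1.0
    vp: float = 0.0225
    total_activity_per_day: float = 1500.0
    masking_m: float = 1.0
    tau_mean: float = 24.0
    tau_sd: float = 0.2
    bump_phases: tuple[float, float] = (0.0, 12.0)
    bump_concentration: float = 2.0
    measurement_sd: float = 0.0
    full_sib_mates: bool = False
    nd_floor: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.n_selected > self.n_pop:
            raise ValueError("n_selected cannot exceed n_pop")
        if self.vp < 0 or self.total_activity_per_day <= 0:
            raise ValueError("vp must be >= 0 and total activity positive")
        if self.masking_m < 0:
            raise ValueError("masking_m must be >= 0")

    @property
    def va(self) -> float:
        return self.h2 * self.vp

    @property
    def ve(self) -> float:
        return (1.0 - self.h2) * self.vp

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimIndividual:
    id: str
    sex: Literal["M", "F"]
    g: float
    e: float
    true_nd: float
    tau: float
    family_id: str


def _floor_nd(values: np.ndarray | float, floor: float):
    return np.maximum(values, floor)


def simulate_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[SimIndividual]:
    """Draw a base population: one male and one female per full-sib family.

    Breeding values g ~ N(0, h2*Vp) and environmental deviations
    e ~ N(0, (1-h2)*Vp) are independent; ``true_nd = nd_mean + g + e`` floored
    at ``nd_floor``.  With ``full_sib_mates`` the two sibs share a family
    effect of variance Va/2 (full-sib additive correlation 1/2); otherwise
    individuals are genetically independent and families are labels only.
    """
    rng = config.rng() if rng is None else rng
    n = config.n_pop
    sd_a = np.sqrt(config.va)
    if config.full_sib_mates:
        fam = rng.normal(0.0, sd_a / np.sqrt(2.0), size=n)
        g_m = fam + rng.normal(0.0, sd_a / np.sqrt(2.0), size=n)
        g_f = fam + rng.normal(0.0, sd_a / np.sqrt(2.0), size=n)
    else:
        g_m = rng.normal(0.0, sd_a, size=n)
        g_f = rng.normal(0.0, sd_a, size=n)
    e_m = rng.normal(0.0, np.sqrt(config.ve), size=n)
    e_f = rng.normal(0.0, np.sqrt(config.ve), size=n)
    tau_m = rng.normal(config.tau_mean, config.tau_sd, size=n)
    tau_f = rng.normal(config.tau_mean, config.tau_sd, size=n)
    out: list[SimIndividual] = []
    for i in range(n):
        for sex, g, e, tau in (("M", g_m[i], e_m[i], tau_m[i]),
                               ("F", g_f[i], e_f[i], tau_f[i])):
            out.append(
                SimIndividual(
                    id=f"F{i:04d}{sex}",
                    sex=sex,
                    g=float(g),
                    e=float(e),
                    true_nd=float(_floor_nd(config.nd_mean + g + e,
                                            config.nd_floor)),
                    tau=float(tau),
                    family_id=f"F{i:04d}",
                )
            )
    return out


# ---------------------------------------------------------------------------
# actogram synthesis
# ---------------------------------------------------------------------------

def _template(phase_zt: np.ndarray, config: SimConfig) -> np.ndarray:
    """Two-bump crepuscular activity template on subjective ZT in [0, 24)."""
    m, e = config.bump_phases
    k = config.bump_concentration
    w = 2.0 * np.pi / 24.0
    return (np.exp(k * np.cos(w * (phase_zt - m)))
            + np.exp(k * np.cos(w * (phase_zt - e))))


def simulate_activity(
    ind: SimIndividual,
    regime: LightRegime,
    days: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    bin_minutes: int = 1,
    t0: pd.Timestamp | None = None,
) -> ActivitySeries:
    """Poisson actogram for one fly under the given light regime.

    The expected count profile is the crepuscular template evaluated at the
    fly's internal phase (clock-entrained in LD, free-running at ``ind.tau``
    after ``regime.dd_start``), with night-phase bins re-weighted so that the
    expected night/day ratio equals the fly's expressed ND ratio for that
    segment — ``true_nd`` in LD, relaxed toward the template's intrinsic
    ratio in DD according to ``masking_m`` — and the expected total equals
    ``total_activity_per_day`` per day.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if t0 is None:
        base = _T0_DEFAULT.normalize() + pd.Timedelta(hours=regime.lights_on_hour)
        t0 = base
    n_bins = days * (1440 // bin_minutes)
    bin_h = bin_minutes / 60.0
    t_mid_h = (np.arange(n_bins) + 0.5) * bin_h
    series = ActivitySeries(
        fly_id=ind.id, t0=t0, bin_minutes=bin_minutes,
        counts=np.zeros(n_bins, dtype=np.int64),
    )
    series = annotate_light(series, regime)
    flags = series.light_flags
    in_dd = np.array([f.startswith("subj") for f in flags])
    night = np.array([f in ("D", "subjD") for f in flags])

    # internal phase: entrained (24 h, locked to ZT) until dd_start, then
    # free-running at tau from the phase reached at release
    zt0 = regime.zt(t0)
    phase = (zt0 + t_mid_h) % 24.0
    if in_dd.any():
        dd_h = (regime.dd_start - t0) / pd.Timedelta(hours=1)
        rel = t_mid_h >= dd_h
        phase[rel] = (zt0 + dd_h + (t_mid_h[rel] - dd_h) * 24.0 / ind.tau) % 24.0
    lam = _template(phase, config)

    for seg in (~in_dd, in_dd):
        if not seg.any():
            continue
        is_dd_seg = bool(in_dd[seg][0])
        f_night = lam[seg & night].sum()
        f_day = lam[seg & ~night].sum()
        intrinsic = f_night / f_day if f_day > 0 else 1.0
        if is_dd_seg:
            target = intrinsic * (ind.true_nd / intrinsic) ** (
                1.0 / (1.0 + config.masking_m)
            )
        else:
            target = ind.true_nd
        if f_night > 0 and f_day > 0:
            beta = target * f_day / f_night
            lam[seg & night] *= beta
        seg_days = seg.sum() * bin_h / 24.0
        lam[seg] *= config.total_activity_per_day * seg_days / lam[seg].sum()

    counts = rng.poisson(lam)
    return replace(series, counts=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# selection experiment
# ---------------------------------------------------------------------------

def _measure_fast(
    true_nd: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    if config.measurement_sd > 0:
        noise = rng.normal(0.0, config.measurement_sd, size=true_nd.shape)
        return _floor_nd(true_nd + noise, config.nd_floor)
    return true_nd


def _measure_full(
    inds: Sequence[SimIndividual], config: SimConfig,
    rng: np.random.Generator, days: int, bin_minutes: int,
) -> np.ndarray:
    from .rhythm_metrics import nd_ratio

    regime = LightRegime(lights_on_hour=8.0, photoperiod_hours=12.0)
    out = np.empty(len(inds))
    for i, ind in enumerate(inds):
        s = simulate_activity(ind, regime, days, config, rng=rng,
                              bin_minutes=bin_minutes)
        out[i], _ = nd_ratio(s)
    return out


def run_selection_experiment(
    config: SimConfig,
    direction: Literal["nocturnal", "diurnal"] = "nocturnal",
    rng: np.random.Generator | None = None,
    phenotype_path: Literal["fast", "full"] = "fast",
    days: int = 5,
    bin_minutes: int = 30,
) -> tuple[list[SelectionCycleRecord], dict]:
    """Simulate a full truncation-selection experiment.

    Per cycle: phenotype ``n_pop`` males, rank them, take the ``n_selected``
    most extreme in ``direction``, mate each to an unselected female (a full
    sister when ``config.full_sib_mates``), and breed the next generation
    with offspring breeding values = mid-parent + Mendelian sampling of
    variance ``h2*Vp/2``.  Phenotypes come from the analytic fast path or the
    full Poisson-actogram path.  Returns the per-cycle records and the
    generating truth (h2, direction, per-generation mean breeding value).
    """
    if direction not in ("nocturnal", "diurnal"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = config.rng() if rng is None else rng
    n, k = config.n_pop, config.n_selected
    sd_a, sd_e = np.sqrt(config.va), np.sqrt(config.ve)
    sd_mend = np.sqrt(config.va / 2.0)

    if config.full_sib_mates:
        fam = rng.normal(0.0, sd_a / np.sqrt(2.0), size=n)
        g_m = fam + rng.normal(0.0, sd_a / np.sqrt(2.0), size=n)
        g_f = fam + rng.normal(0.0, sd_a / np.sqrt(2.0), size=n)
    else:
        g_m = rng.normal(0.0, sd_a, size=n)
        g_f = rng.normal(0.0, sd_a, size=n)

    def measure_males(g: np.ndarray, e: np.ndarray) -> np.ndarray:
        true_nd = _floor_nd(config.nd_mean + g + e, config.nd_floor)
        if phenotype_path == "fast":
            return _measure_fast(true_nd, config, rng)
        inds = [
            SimIndividual(id=f"m{i}", sex="M", g=float(g[i]), e=float(e[i]),
                          true_nd=float(true_nd[i]),
                          tau=config.tau_mean, family_id=f"m{i}")
            for i in range(g.size)
        ]
        return _measure_full(inds, config, rng, days, bin_minutes)

    e_m = rng.normal(0.0, sd_e, size=n)
    pheno_m = measure_males(g_m, e_m)
    e_f = rng.normal(0.0, sd_e, size=n)
    pheno_f = _floor_nd(config.nd_mean + g_f + e_f, config.nd_floor)

    records: list[SelectionCycleRecord] = []
    mean_g = [float(g_m.mean())]
    cum_s = cum_r = 0.0
    for cycle in range(1, config.n_cycles + 1):
        pop_mean = float(pheno_m.mean())
        pop_var = float(pheno_m.var(ddof=1))
        order = np.argsort(pheno_m)
        sel = order[-k:] if direction == "nocturnal" else order[:k]
        if config.full_sib_mates:
            mates = sel  # his full sister shares the family index
        else:
            mates = rng.choice(n, size=k, replace=False)
        s_val = float(
            0.5 * (pheno_m[sel].mean() - pop_mean)
            + 0.5 * (pheno_f[mates].mean() - pop_mean)
        )
        mid = 0.5 * (g_m[sel] + g_f[mates])

        pair_m = rng.integers(0, k, size=n)
        pair_f = rng.integers(0, k, size=n)
        if config.full_sib_mates:
            # same pair index for a male and the female sharing his slot,
            # so index i male and index i female are full sibs
            g_m_next = mid[pair_m] + rng.normal(0.0, sd_mend, size=n)
            g_f_next = mid[pair_m] + rng.normal(0.0, sd_mend, size=n)
        else:
            g_m_next = mid[pair_m] + rng.normal(0.0, sd_mend, size=n)
            g_f_next = mid[pair_f] + rng.normal(0.0, sd_mend, size=n)
        e_m_next = rng.normal(0.0, sd_e, size=n)
        e_f_next = rng.normal(0.0, sd_e, size=n)
        pheno_m_next = measure_males(g_m_next, e_m_next)
        pheno_f_next = _floor_nd(config.nd_mean + g_f_next + e_f_next,
                                 config.nd_floor)
        progeny_mean = float(pheno_m_next.mean())
        r_val = progeny_mean - pop_mean
        cum_s += s_val
        cum_r += r_val
        records.append(
            SelectionCycleRecord(
                cycle=cycle,
                pop_mean=pop_mean,
                pop_var=pop_var,
                selected_male_mean=float(pheno_m[sel].mean()),
                sibling_female_mean=float(pheno_f[mates].mean()),
                progeny_mean=progeny_mean,
                S=s_val,
                R=r_val,
                cum_S=cum_s,
                cum_R=cum_r,
                n_phenotyped=n,
                n_selected=k,
            )
        )
        g_m, g_f = g_m_next, g_f_next
        pheno_m, pheno_f = pheno_m_next, pheno_f_next
        mean_g.append(float(g_m.mean()))
    truth = {
        "h2": config.h2,
        "direction": direction,
        "seed": config.seed,
        "mean_g_by_generation": mean_g,
    }
    return records, truth


# ---------------------------------------------------------------------------
# parent-offspring families
# ---------------------------------------------------------------------------

def simulate_parent_offspring(
    config: SimConfig,
    n_families: int = 105,
    n_progeny: int = 10,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Family tables for regression heritability.

    Unrelated parent pairs are drawn from the base population; each family
    produces ``n_progeny`` offspring (half daughters).  Returns three tables:
    ``midparent`` (mid-parent vs mid-progeny), ``mother_daughter`` and
    ``father_son`` (one offspring each), all in measured ND units.
    """
    if n_families < 3:
        raise ValueError("need at least three families")
    rng = config.rng() if rng is None else rng
    sd_a, sd_e = np.sqrt(config.va), np.sqrt(config.ve)
    sd_mend = np.sqrt(config.va / 2.0)

    g_mo = rng.normal(0.0, sd_a, size=n_families)
    g_fa = rng.normal(0.0, sd_a, size=n_families)
    p_mo = _measure_fast(
        _floor_nd(config.nd_mean + g_mo + rng.normal(0, sd_e, n_families),
                  config.nd_floor), config, rng)
    p_fa = _measure_fast(
        _floor_nd(config.nd_mean + g_fa + rng.normal(0, sd_e, n_families),
                  config.nd_floor), config, rng)
    mid = 0.5 * (g_mo + g_fa)
    prog = (mid[:, None]
            + rng.normal(0.0, sd_mend, size=(n_families, n_progeny)))
    p_prog = _measure_fast(
        _floor_nd(config.nd_mean + prog
                  + rng.normal(0, sd_e, (n_families, n_progeny)),
                  config.nd_floor), config, rng)
    half = n_progeny // 2
    daughters = p_prog[:, :max(half, 1)]
    sons = p_prog[:, max(half, 1):]
    if sons.shape[1] == 0:
        sons = daughters
    midparent = pd.DataFrame(
        {
            "family": np.arange(n_families),
            "midparent_nd": 0.5 * (p_mo + p_fa),
            "midprogeny_nd": p_prog.mean(axis=1),
        }
    )
    mother_daughter = pd.DataFrame(
        {
            "family": np.arange(n_families),
            "mother_nd": p_mo,
            "daughter_nd": daughters[:, 0],
        }
    )
    father_son = pd.DataFrame(
        {
            "family": np.arange(n_families),
            "father_nd": p_fa,
            "son_nd": sons[:, 0],
        }
    )
    return {
        "midparent": midparent,
        "mother_daughter": mother_daughter,
        "father_son": father_son,
    }


# ---------------------------------------------------------------------------
# QCT cross tables
# ---------------------------------------------------------------------------

def simulate_qct(
    config: SimConfig,
    effects: Mapping[str, float],
    n_per_cell: int = 25,
    cell_sd: float = 0.25,
    control_mean: float | None = None,
    rng: np.random.Generator | None = None,
    gene: str = "simulated",
) -> QCTTable:
    """Normal ND samples per (background, allele) cell for a QCT fixture.

    ``effects`` maps each background (N*, D*, C*) to the mean ND ratio of its
    mutant-allele cross; control-allele (balancer) crosses share
    ``control_mean`` (default: the configured population mean).
    """
    rng = config.rng() if rng is None else rng
    if set(effects) != {"N*", "D*", "C*"}:
        raise ValueError("effects must specify N*, D* and C*")
    control_mean = config.nd_mean if control_mean is None else control_mean
    cells: dict[tuple[str, str], np.ndarray] = {}
    for bg, mu in effects.items():
        cells[(bg, "mutant")] = _floor_nd(
            rng.normal(mu, cell_sd, size=n_per_cell), config.nd_floor)
        cells[(bg, "control")] = _floor_nd(
            rng.normal(control_mean, cell_sd, size=n_per_cell), config.nd_floor)
    return QCTTable(gene=gene, cells=cells)
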