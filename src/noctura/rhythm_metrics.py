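"""Per-fly circadian phenotyping.

This module turns a light-annotated :class:`~noctura.actogram_io.ActivitySeries`
into the phenotypes of interest for diurnal-preference genetics:

* the **ND ratio** — activity during the 12 h (subjective) night divided by
  activity during the 12 h (subjective) day; > 1 nocturnal, < 1 diurnal;
* **rhythmicity** by Fisher's exact g-test on the periodogram;
* the **free-running period** by the Sokolove–Bushell chi-square periodogram
  (Lomb–Scargle available as a cross-check);
* the **acrophase** (phase angle of peak activity) with circular statistics,
  mapping one hour to 15° so that ZT0 → 0° and ZT12 → 180°;
* **sleep**, scored by the standard Drosophila convention of at least five
  consecutive minutes of immobility;
* the **masking contrast** between ND ratios in LD and in constant darkness,
  with a genotype x regime two-way analysis;
* **light-pulse phase shifts** from post-pulse acrophase differences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import lombscargle as _scipy_lombscargle

from .actogram_io import (
    ActivitySeries,
    DAY_LABELS,
    NIGHT_LABELS,
)

logger = logging.getLogger(__name__)

DEGREES_PER_HOUR = 15.0  # 360 degrees / 24 h


def zt_to_angle(zt_hours: float) -> float:
    """Map Zeitgeber time in hours onto the circular day: 1 h -> 15 degrees.

    ZT0 maps to 0 degrees, ZT12 (lights-off) to 180 degrees.
    """
    return (zt_hours * DEGREES_PER_HOUR) % 360.0


def angle_to_zt(angle_deg: float) -> float:
    """Inverse of :func:`zt_to_angle`."""
    return (angle_deg / DEGREES_PER_HOUR) % 24.0


# ---------------------------------------------------------------------------
# ND ratio
# ---------------------------------------------------------------------------

def nd_ratio(
    series: ActivitySeries, pool_days: bool = False
) -> tuple[float, np.ndarray]:
    """Night/day activity ratio of a light-annotated series.

    For each complete 24 h day, the daily ratio is the summed counts in
    night bins (``D``/``subjD``) divided by the summed counts in day bins
    (``L``/``subjL``).  The headline value is the mean of the daily ratios
    (or, with ``pool_days=True``, the ratio of pooled counts).  A day with
    zero day-activity but nonzero night-activity yields an infinite daily
    ratio, which is flagged and excluded from the mean.

    Returns ``(value, per_day_ratios)``.
    """
    if series.light_flags is None:
        raise ValueError("series must be light-annotated (run annotate_light)")
    bpd = series.bins_per_day
    n_days = series.n_bins // bpd
    if n_days < 1:
        raise ValueError("need at least one complete 24 h day")
    if series.counts[: n_days * bpd].sum() == 0:
        raise ValueError("no activity")
    flags = series.light_flags[: n_days * bpd].reshape(n_days, bpd)
    counts = series.counts[: n_days * bpd].reshape(n_days, bpd)
    night = np.isin(flags, list(NIGHT_LABELS))
    day = np.isin(flags, list(DAY_LABELS))
    night_sum = np.where(night, counts, 0).sum(axis=1).astype(float)
    day_sum = np.where(day, counts, 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_day = night_sum / day_sum
    per_day = np.where((day_sum == 0) & (night_sum == 0), np.nan, per_day)
    if pool_days:
        total_day = day_sum.sum()
        value = float(night_sum.sum() / total_day) if total_day > 0 else math.inf
        return value, per_day
    finite = np.isfinite(per_day)
    n_inf = int(np.isinf(per_day).sum())
    if n_inf:
        logger.warning(
            "%s: %d day(s) with zero day-activity gave infinite ND ratio; "
            "excluded from the mean", series.fly_id, n_inf,
        )
    if finite.any():
        value = float(per_day[finite].mean())
    else:
        value = math.inf
    return value, per_day


# ---------------------------------------------------------------------------
# Fisher's exact g-test
# ---------------------------------------------------------------------------

@dataclass
class FisherGResult:
    g_stat: float
    pvalue: float
    peak_period_hours: float
    n_ordinates: int


def fisher_g_pvalue(g: float, m: int) -> float:
    """Exact null P(G >= g) for the maximum share of m periodogram ordinates.

    Under Gaussian white noise the ordinates are iid exponential and
    ``P = sum_{j=1}^{floor(1/g)} (-1)^(j-1) C(m, j) (1 - j g)^(m-1)``.
    Terms are evaluated in log space; the alternating series is summed
    directly (terms decay for the g values that arise in practice).
    """
    if not 0.0 < g <= 1.0:
        raise ValueError("g must be in (0, 1]")
    j_max = min(int(1.0 / g), m)
    total = 0.0
    for j in range(1, j_max + 1):
        base = 1.0 - j * g
        if base <= 0.0:
            continue
        ln_term = (
            math.lgamma(m + 1) - math.lgamma(j + 1) - math.lgamma(m - j + 1)
            + (m - 1) * math.log(base)
        )
        total += (-1.0) ** (j - 1) * math.exp(ln_term)
    return float(min(max(total, 0.0), 1.0))


def fisher_g_test(series: ActivitySeries) -> FisherGResult:
    """Fisher's exact g-test for a periodic component at a Fourier frequency.

    The periodogram is evaluated at the Fourier frequencies of the
    mean-centred series; g is the largest ordinate divided by the ordinate
    sum, with the exact null p-value of :func:`fisher_g_pvalue`.
    """
    x = series.counts.astype(float)
    n = x.size
    if n < 16:
        raise ValueError("series too short for the g-test (need >= 16 bins)")
    if np.ptp(x) == 0:
        raise ValueError("zero variance")
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2
    m = (n - 1) // 2
    ordinates = spec[1 : m + 1]  # exclude mean and (for even n) Nyquist
    j_peak = int(np.argmax(ordinates)) + 1
    g = float(ordinates.max() / ordinates.sum())
    p = fisher_g_pvalue(g, m)
    bin_h = series.bin_minutes / 60.0
    peak_period = n * bin_h / j_peak
    return FisherGResult(g_stat=g, pvalue=p, peak_period_hours=peak_period,
                         n_ordinates=m)


# ---------------------------------------------------------------------------
# period estimation
# ---------------------------------------------------------------------------

@dataclass
class PeriodEstimate:
    period_hours: float
    statistic: float
    threshold: float
    significant: bool
    method: str
    profile: pd.DataFrame | None = field(default=None, repr=False)


def chi2_periodogram(
    series: ActivitySeries,
    p_min: float = 18.0,
    p_max: float = 30.0,
    step: float = 0.1,
    alpha: float = 0.05,
) -> PeriodEstimate:
    """Sokolove–Bushell chi-square periodogram period estimate.

    For each candidate period the series is folded into phase columns one bin
    wide; the statistic ``Q = sum_h n_h (M_h - M)^2 / s^2`` is referred to a
    chi-square threshold with (columns - 1) degrees of freedom.  Because the
    whole period grid is scanned, ``alpha`` is controlled family-wise: the
    per-candidate level is Bonferroni-corrected by the number of candidates
    (neighbouring periods are highly correlated, so the realized false-alarm
    rate sits below the nominal level).  The returned estimate is the
    candidate with the largest excess of Q over its threshold;
    ``significant`` is False when no candidate exceeds it.
    """
    if p_min >= p_max:
        raise ValueError("p_min must be below p_max")
    y = series.counts.astype(float)
    bin_h = series.bin_minutes / 60.0
    if series.duration_hours < 2.0 * p_max:
        raise ValueError(
            f"series ({series.duration_hours:.1f} h) shorter than twice the "
            f"longest candidate period ({p_max} h)"
        )
    if np.ptp(y) == 0:
        raise ValueError("zero variance")
    t = np.arange(y.size) * bin_h
    grand = y.mean()
    s2 = y.var(ddof=1)
    periods = np.arange(p_min, p_max + step / 2, step)
    alpha_per_candidate = alpha / periods.size
    rows = []
    for p in periods:
        k = int(p // bin_h)
        if k < 2:
            continue
        idx = np.minimum((((t % p) / p) * k).astype(int), k - 1)
        col_n = np.bincount(idx, minlength=k).astype(float)
        col_sum = np.bincount(idx, weights=y, minlength=k)
        used = col_n > 0
        m_h = col_sum[used] / col_n[used]
        q = float((col_n[used] * (m_h - grand) ** 2).sum() / s2)
        thr = float(stats.chi2.ppf(1.0 - alpha_per_candidate, used.sum() - 1))
        rows.append((p, q, thr))
    prof = pd.DataFrame(rows, columns=["period_hours", "Q", "threshold"])
    excess = prof["Q"] - prof["threshold"]
    best = int(excess.idxmax())
    return PeriodEstimate(
        period_hours=float(prof.loc[best, "period_hours"]),
        statistic=float(prof.loc[best, "Q"]),
        threshold=float(prof.loc[best, "threshold"]),
        significant=bool(excess.loc[best] > 0),
        method="chi2",
        profile=prof,
    )


def lombscargle_period(
    series: ActivitySeries,
    p_min: float = 18.0,
    p_max: float = 30.0,
    step: float = 0.1,
) -> PeriodEstimate:
    """Lomb–Scargle peak period over the same search grid (cross-check only).

    The normalised power at the peak is reported as the statistic; no
    analytic significance threshold is attached (significant is set by the
    conventional normalised-power level for a single frequency).
    """
    y = series.counts.astype(float)
    if np.ptp(y) == 0:
        raise ValueError("zero variance")
    bin_h = series.bin_minutes / 60.0
    t = np.arange(y.size) * bin_h
    periods = np.arange(p_min, p_max + step / 2, step)
    omega = 2.0 * np.pi / periods
    power = _scipy_lombscargle(t, y - y.mean(), omega, normalize=True)
    best = int(np.argmax(power))
    n = y.size
    # normalised power threshold for one pre-specified frequency at alpha=0.05
    thr = 1.0 - (0.05) ** (2.0 / (n - 3))
    return PeriodEstimate(
        period_hours=float(periods[best]),
        statistic=float(power[best]),
        threshold=float(thr),
        significant=bool(power[best] > thr),
        method="lombscargle",
    )


# ---------------------------------------------------------------------------
# acrophase and circular statistics
# ---------------------------------------------------------------------------

@dataclass
class Acrophase:
    mean_deg: float
    R: float
    ci95_deg: float | None
    n: int


def _circ_mean_deg(angles_deg: np.ndarray, weights: np.ndarray | None = None
                   ) -> tuple[float, float]:
    """Weighted circular mean and mean resultant length, angles in degrees."""
    th = np.deg2rad(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(th) if weights is None else np.asarray(weights, dtype=float)
    c = float((w * np.cos(th)).sum())
    s = float((w * np.sin(th)).sum())
    tot = float(w.sum())
    if tot <= 0:
        raise ValueError("non-positive total weight")
    r = math.hypot(c, s) / tot
    mean = math.degrees(math.atan2(s, c)) % 360.0
    return mean, r


def _circ_ci95_deg(cycle_means_deg: np.ndarray) -> float | None:
    """95% CI half-width for a mean direction (Fisher's large-sample formula).

    Returns None when the dispersion is too large for the approximation to be
    valid (arcsine argument outside [0, 1]) or with fewer than two angles.
    """
    n = cycle_means_deg.size
    if n < 2:
        return None
    _, r1 = _circ_mean_deg(cycle_means_deg)
    if r1 <= 0:
        return None
    _, r2 = _circ_mean_deg((2.0 * cycle_means_deg) % 360.0)
    delta = (1.0 - r2) / (2.0 * r1 * r1)
    se = math.sqrt(delta / n)
    arg = 1.959963984540054 * se
    if arg >= 1.0:
        return None
    return math.degrees(math.asin(arg))


def acrophase(series: ActivitySeries, period_hours: float = 24.0) -> Acrophase:
    """Phase angle of peak activity on the circular day.

    The mean direction and resultant length R are the count-weighted circular
    statistics of the bin-midpoint phase angles pooled over all cycles
    (point-mass activity gives R = 1; phase-uniform activity gives R near 0).
    The 95% CI of the mean direction is computed from the dispersion of the
    per-cycle weighted mean angles (n = usable cycles); it is undefined when
    the dispersion defeats the large-sample approximation.
    """
    if series.duration_hours < period_hours:
        raise ValueError("need at least one full cycle of data")
    y = series.counts.astype(float)
    if y.sum() == 0:
        raise ValueError("no activity")
    bin_h = series.bin_minutes / 60.0
    t_mid = (np.arange(y.size) + 0.5) * bin_h
    phase_deg = ((t_mid % period_hours) / period_hours) * 360.0
    mean_deg, r_pooled = _circ_mean_deg(phase_deg, weights=y)
    cyc = (t_mid // period_hours).astype(int)
    cycle_means = []
    for c in np.unique(cyc):
        sel = cyc == c
        if y[sel].sum() == 0:
            logger.warning("%s: cycle %d has zero activity, skipped",
                           series.fly_id, c)
            continue
        m, r = _circ_mean_deg(phase_deg[sel], weights=y[sel])
        if r > 0:
            cycle_means.append(m)
    if not cycle_means:
        raise ValueError("no usable cycles")
    # CI meaningless when the pooled distribution is essentially phase-uniform
    if r_pooled < 0.1:
        ci = None
    else:
        ci = _circ_ci95_deg(np.asarray(cycle_means))
    return Acrophase(mean_deg=mean_deg, R=r_pooled, ci95_deg=ci,
                     n=len(cycle_means))


def morning_evening_peaks(
    series: ActivitySeries,
    lights_on_hour: float = 8.0,
    morning_window: tuple[float, float] = (21.0, 3.0),
    evening_window: tuple[float, float] = (9.0, 15.0),
) -> tuple[float | None, float | None]:
    """Acrophase angles (degrees) of the morning and evening activity peaks.

    The morning peak (MP) is the count-weighted circular mean angle within the
    window ZT21–ZT3 (flanking lights-on) and the evening peak (EP) within
    ZT9–ZT15 (flanking lights-off); windows are configurable.  An empty or
    silent window yields None with a warning.
    """
    bin_h = series.bin_minutes / 60.0
    t_mid = (np.arange(series.n_bins) + 0.5) * bin_h
    clock0 = series.t0.hour + series.t0.minute / 60.0 + series.t0.second / 3600.0
    zt = (clock0 - lights_on_hour + t_mid) % 24.0

    def _window_mean(window: tuple[float, float], label: str) -> float | None:
        lo, hi = window
        if lo <= hi:
            sel = (zt >= lo) & (zt < hi)
        else:  # wraps midnight of the circadian day
            sel = (zt >= lo) | (zt < hi)
        w = series.counts[sel].astype(float)
        if sel.sum() == 0 or w.sum() == 0:
            logger.warning("%s: no activity in %s window", series.fly_id, label)
            return None
        mean, _ = _circ_mean_deg(zt[sel] * DEGREES_PER_HOUR, weights=w)
        return mean

    return (_window_mean(morning_window, "morning"),
            _window_mean(evening_window, "evening"))


# ---------------------------------------------------------------------------
# sleep
# ---------------------------------------------------------------------------

def sleep_profile(series: ActivitySeries, min_bout_minutes: int = 5
                  ) -> np.ndarray:
    """Minutes asleep per clock hour, averaged across days.

    Sleep is the standard Drosophila convention: any run of at least
    ``min_bout_minutes`` consecutive zero-count minutes; every minute inside
    such a run scores as one sleep-minute.  Requires 1-minute bins (sleep
    scored on re-binned data is biased and refused).
    """
    if series.bin_minutes != 1:
        raise ValueError(
            "sleep scoring requires 1-minute bins; do not re-bin before scoring"
        )
    quiet = series.counts == 0
    # run-length encode the immobility mask
    edges = np.flatnonzero(np.diff(np.concatenate(([0], quiet.view(np.int8), [0]))))
    starts, stops = edges[::2], edges[1::2]
    asleep = np.zeros(series.n_bins, dtype=bool)
    for a, b in zip(starts, stops):
        if b - a >= min_bout_minutes:
            asleep[a:b] = True
    minute_of_day = (series.t0.hour * 60 + series.t0.minute
                     + np.arange(series.n_bins)) % 1440
    hour = minute_of_day // 60
    observed = np.bincount(hour, minlength=24).astype(float)
    slept = np.bincount(hour, weights=asleep.astype(float), minlength=24)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_hour = np.where(observed > 0, slept / (observed / 60.0), np.nan)
    return per_hour


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

@dataclass
class MaskingResult:
    nd_ld: float
    nd_dd: float
    delta: float
    group_tests: dict[str, tuple[float, float]]
    per_fly: pd.DataFrame
    posthoc: pd.DataFrame | None = None


def fly_masking_nd(
    ld: ActivitySeries, dd: ActivitySeries, skip_dd_days: int = 1
) -> tuple[float, float]:
    """(ND in LD, ND in DD) for one fly; the first DD day(s) are skipped.

    The first day in constant darkness is a transient and excluded by default,
    matching an analysis that starts from the second DD day.
    """
    if dd.light_flags is None or not np.isin(
        dd.light_flags, ["subjL", "subjD"]
    ).all():
        raise ValueError("DD series must carry subjective (subjL/subjD) flags")
    nd_ld_val, _ = nd_ratio(ld)
    dd_used = dd.slice_bins(skip_dd_days * dd.bins_per_day)
    nd_dd_val, _ = nd_ratio(dd_used)
    return nd_ld_val, nd_dd_val


def masking_contrast(
    entries: Sequence[tuple[ActivitySeries, ActivitySeries, str]],
    skip_dd_days: int = 1,
) -> MaskingResult:
    """Masking analysis of a cohort of (LD series, DD series, genotype) flies.

    Per fly, ND ratios are computed in LD and in DD (skipping the first DD
    day); the cohort is analysed as a two-way layout (genotype x light regime)
    by OLS ANOVA with F statistics for the genotype, regime and interaction
    effects, plus Tukey-adjusted post-hoc pairwise comparisons.  With a single
    genotype only the regime effect is tested.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = []
    for i, (ld, dd, genotype) in enumerate(entries):
        nd_ld_val, nd_dd_val = fly_masking_nd(ld, dd, skip_dd_days=skip_dd_days)
        if not (math.isfinite(nd_ld_val) and math.isfinite(nd_dd_val)):
            logger.warning("fly %s: infinite ND ratio, dropped from masking "
                           "ANOVA", ld.fly_id)
            continue
        rows.append({"fly": ld.fly_id or f"fly{i}", "genotype": genotype,
                     "nd_ld": nd_ld_val, "nd_dd": nd_dd_val})
    per_fly = pd.DataFrame(rows)
    if per_fly.empty:
        raise ValueError("no flies with finite ND ratios")
    long = per_fly.melt(
        id_vars=["fly", "genotype"], value_vars=["nd_ld", "nd_dd"],
        var_name="regime", value_name="nd",
    )
    long["regime"] = long["regime"].map({"nd_ld": "LD", "nd_dd": "DD"})
    tests: dict[str, tuple[float, float]] = {}
    n_geno = long["genotype"].nunique()
    if n_geno > 1:
        model = smf.ols("nd ~ C(genotype) * C(regime)", data=long).fit()
        table = sm.stats.anova_lm(model, typ=2)
        tests["genotype"] = (float(table.loc["C(genotype)", "F"]),
                             float(table.loc["C(genotype)", "PR(>F)"]))
        tests["regime"] = (float(table.loc["C(regime)", "F"]),
                           float(table.loc["C(regime)", "PR(>F)"]))
        tests["interaction"] = (
            float(table.loc["C(genotype):C(regime)", "F"]),
            float(table.loc["C(genotype):C(regime)", "PR(>F)"]),
        )
        tuk = pairwise_tukeyhsd(
            long["nd"].to_numpy(),
            (long["genotype"] + ":" + long["regime"]).to_numpy(),
        )
        res = tuk.summary()
        posthoc = pd.DataFrame(res.data[1:], columns=res.data[0])
    else:
        model = smf.ols("nd ~ C(regime)", data=long).fit()
        table = sm.stats.anova_lm(model, typ=2)
        tests["regime"] = (float(table.loc["C(regime)", "F"]),
                           float(table.loc["C(regime)", "PR(>F)"]))
        posthoc = None
    nd_ld_mean = float(per_fly["nd_ld"].mean())
    nd_dd_mean = float(per_fly["nd_dd"].mean())
    return MaskingResult(
        nd_ld=nd_ld_mean,
        nd_dd=nd_dd_mean,
        delta=nd_dd_mean - nd_ld_mean,
        group_tests=tests,
        per_fly=per_fly,
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# phase shift
# ---------------------------------------------------------------------------

def phase_shift(
    unpulsed: ActivitySeries,
    pulsed: ActivitySeries,
    fold_period_hours: float = 24.0,
    check_rhythmicity: bool = True,
) -> float | None:
    """Phase shift (hours) induced by a light pulse; delays are negative.

    Both series should cover the post-pulse free run (at least three cycles).
    The shift is the circular difference between the pulsed and unpulsed
    post-pulse acrophases at 15 degrees per hour; a post-pulse series that is
    arrhythmic by the chi-square periodogram yields None.
    """
    if check_rhythmicity:
        for s in (unpulsed, pulsed):
            est = chi2_periodogram(s)
            if not est.significant:
                logger.warning("%s: arrhythmic post-pulse series", s.fly_id)
                return None
    a_un = acrophase(unpulsed, period_hours=fold_period_hours)
    a_pu = acrophase(pulsed, period_hours=fold_period_hours)
    diff = (a_pu.mean_deg - a_un.mean_deg + 180.0) % 360.0 - 180.0
    return -diff / DEGREES_PER_HOUR


# ---------------------------------------------------------------------------
# whole-fly phenotype
# ---------------------------------------------------------------------------

@dataclass
class RhythmPhenotype:
    """Bundle of per-fly diurnal-preference metrics."""

    fly_id: str
    nd_ratio: float
    nd_per_day: np.ndarray
    rhythmic: bool
    g_stat: float
    g_pvalue: float
    frp_hours: float | None
    acrophase_deg: float | None
    sleep_by_hour: np.ndarray | None


def phenotype_fly(
    series: ActivitySeries,
    rhythm_alpha: float = 0.05,
    g_test_bin_minutes: int = 30,
    estimate_frp: bool = False,
) -> RhythmPhenotype:
    """Compute the standard phenotype bundle for one light-annotated fly.

    Rhythmicity is Fisher's exact g-test at ``rhythm_alpha`` on the series
    re-binned to ``g_test_bin_minutes``; the free-running period is estimated
    only on request (it requires a DD record).  Sleep is scored only when the
    series has 1-minute bins.
    """
    from .actogram_io import rebin

    g_series = (series if series.bin_minutes == g_test_bin_minutes
                else rebin(series, g_test_bin_minutes))
    g_res = fisher_g_test(g_series)
    value, per_day = nd_ratio(series)
    acro = acrophase(series) if series.duration_hours >= 24 else None
    sleep = sleep_profile(series) if series.bin_minutes == 1 else None
    frp = None
    if estimate_frp:
        est = chi2_periodogram(series)
        frp = est.period_hours if est.significant else None
    return RhythmPhenotype(
        fly_id=series.fly_id,
        nd_ratio=value,
        nd_per_day=per_day,
        rhythmic=g_res.pvalue < rhythm_alpha,
        g_stat=g_res.g_stat,
        g_pvalue=g_res.pvalue,
        frp_hours=frp,
        acrophase_deg=None if acro is None else acro.mean_deg,
        sleep_by_hour=sleep,
    )
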