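# noctura

Phenotyping and quantitative genetics of **diurnal preference** in
*Drosophila* locomotor-activity data.

Most animals confine activity to a characteristic part of the day. Under
laboratory LD 12:12 cycles, *D. melanogaster* is crepuscular on average, but
individual flies range from strongly diurnal to strongly nocturnal, and this
variation is partly heritable. `noctura` implements the analysis chain that
turns raw activity-monitor recordings into that evidence:

* **behavioural phenotypes** per fly — the ND ratio (night/day activity),
  rhythmicity by Fisher's exact g-test, free-running period τ by the
  Sokolove–Bushell chi-square periodogram, acrophase with circular
  statistics (1 h = 15°, so ZT0 → 0° and ZT12 → 180°), sleep (≥ 5 min
  immobility on 1-min bins), LD-vs-DD masking contrasts and light-pulse
  phase shifts;
* **genetic estimates** — realized heritability from truncation selection,
  parent–offspring regression heritability, and quantitative
  complementation-test (QCT) verdicts for candidate genes;
* a **seeded simulator** of all of the above: an infinitesimal-model
  population with heritable ND, Poisson actograms with a crepuscular
  two-bump template, light masking, multi-cycle selection experiments,
  families and QCT cross tables.

## The statistics at the core

**ND ratio.** For each complete day,
`ND = Σ counts(night bins) / Σ counts(day bins)` (subjective night/day in
DD); ND > 1 is nocturnal, < 1 diurnal.

**Rhythmicity.** Fisher's exact g-test on the periodogram at Fourier
frequencies: `g = max(I_j) / Σ I_j` over m ordinates, with the exact null
p-value `p = Σ_{j≤⌊1/g⌋} (−1)^{j−1} C(m,j)(1−jg)^{m−1}`.

**Period.** For each candidate period P (18–30 h, 0.1 h steps) the series is
folded into phase columns; `Q_P = Σ_h n_h (M̄_h − M̄)² / s²` is referred to a
χ²(K−1) threshold, family-wise corrected over the scan.

**Realized heritability.** Per selection cycle,
`S = ½(x̄_selected♂ − x̄_pop) + ½(x̄_mates♀ − x̄_pop)` and `R` is the progeny
mean minus the parental-population mean; `ĥ² = slope of cum R on cum S`
through the origin, with a parametric-bootstrap drift variance. The
breeder's equation `R = h²S` makes this consistent under the infinitesimal
model. Parent–offspring regression gives `ĥ² = b` on mid-parents and
`ĥ² = 2b` on a single parent.

**Complementation.** Across the three mutant-allele crosses (N\*, D\*, C\*
backgrounds): Kruskal–Wallis (df = 2) plus pairwise two-sample KS tests;
verdict *complemented* iff means order D\* < C\* < N\*, KS(N\* vs D\*) is
significant and KW is significant; significance without that ordering is
*failed_to_complement*; anything else is *inconclusive*.

## Worked example

```python
import numpy as np
from noctura import (SimConfig, LightRegime, simulate_activity, nd_ratio,
                     fisher_g_test, run_selection_experiment, realized_h2)
from noctura.synthetic_data import SimIndividual

cfg = SimConfig(h2=0.371, seed=42)
regime = LightRegime(lights_on_hour=8.0, photoperiod_hours=12.0)

# one mildly nocturnal fly, five LD days, 30-min bins
ind = SimIndividual(id="M1C01", sex="M", g=0.12, e=0.03,
                    true_nd=1.15, tau=24.1, family_id="F0001")
series = simulate_activity(ind, regime, days=5, config=cfg,
                           rng=np.random.default_rng(42), bin_minutes=30)
value, per_day = nd_ratio(series)
g = fisher_g_test(series)

# a whole selection experiment toward diurnality
records, truth = run_selection_experiment(cfg, direction="diurnal",
                                          rng=np.random.default_rng(42))
est = realized_h2(records)
```

This prints (via the f-strings in the repository's doctest-style example):

```
ND ratio    : 1.160  (daily: [1.087 1.193 1.303 1.082 1.134])
rhythmic    : True  (Fisher g = 0.817, p = 9.40e-86)
cum S = -1.268, cum R = -0.436
realized h2 : 34.6%  (se 0.7 pp; generator 37.1%)
```

The fly's measured ND ratio (1.16) scatters around its latent value (1.15)
with Poisson counting noise; the ten-cycle diurnal selection accumulates a
negative differential and response whose ratio estimates the heritability —
slightly below the generator value because selection erodes additive
variance over cycles (see `docs/methods.md`).

The same analyses are scriptable from a shell:

```bash
noctura simulate --config configs/default.yaml --out fixtures/
noctura phenotype --in fixtures/monitor1.txt --regime fixtures/regime.yaml \
        --out phenotypes.csv
noctura select-analyze --cycles fixtures/cycles_nocturnal.csv --out h2.json
noctura qct --in fixtures/qct.csv --out qct.json
noctura run --config configs/default.yaml --seed 7 --out report/
```

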