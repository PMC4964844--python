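# terminvest

Growth-curve kinetics, bound-phage dilution modelling and rank-based
group tests for phage-exposure experiments on *Pseudomonas fluorescens*
SBW25 — packaged as a reproducible analysis pipeline over synthetic data
with known ground truth.

## The scientific problem

When the rhizosphere bacterium *P. fluorescens* SBW25 is exposed to
UV-inactivated particles of its lytic phage SBW25Φ2, mere surface
binding — with no infection possible — triggers a *terminal-investment*
response: a transient, phage-density-dependent acceleration of division
during the first 24 h, paid for by smaller daughter cells, followed by a
compensatory slowdown and a return to baseline growth by day 4.
Quantifying that response rests on four computational pillars, each a
module here:

1. **`growth`** — the biomass doubling time of each microplate well,

   D_t = Δt · ln 2 / (ln N* − ln N₀),

   with the exponential phase (N₀ → N*, duration Δt) detected by sliding
   a fixed-width window over the log-transformed OD650 series and
   keeping the window of maximal regression slope. Since OD conflates
   cell count with cell size, the module also provides a diagnostic
   showing that shrinking cells always make this estimate of the
   division rate conservative.
2. **`dilution`** — inactivated phage never replicate, so the particles
   bound to a founder are roughly halved at each division: the mean
   per-cell load after n divisions is P₀/2ⁿ, falling below one particle
   per cell after 9–10 divisions for initial loads of 500–1000 (i.e.
   within the first two days at the measured doubling times). A
   binomial-partitioning simulator provides the stochastic counterpart.
3. **`cytometry`** — per-sample summaries of forward/side scatter
   (forward scatter as the cell-size proxy), control:treated mean-size
   ratios, and a permutation two-sample ECDF-supremum test for
   distribution changes.
4. **`stats`** — the Kruskal–Wallis rank test, implemented from its
   definition (midranks, tie correction, χ² tail via the regularized
   incomplete gamma) with exact-enumeration and Monte-Carlo permutation
   references.

A fifth module, **`synthetic_data`**, generates growth curves, cytometry
event tables and per-cell binding counts with the experiment's structure
(4 treatments: control plus phage at 10⁶, 5×10⁶ and 10⁷ particles/ml;
6 replicates; 4 days; 250 OD reads per 24 h), so every stage is testable
against a truth table without any external data. **`pipeline`** wires
everything into one seeded, byte-deterministic run with a
schema-validated JSON report.

## Worked example

```bash
python analysis/06_full_pipeline.py --seed 42 --out results/full_run
```

prints (abridged):

```
day-1 mean doubling times (h): control=1.33, ratio_1_1=0.75, ratio_1_10=0.92, ratio_1_2=0.81
day-1 Kruskal-Wallis: H=21.60, df=3, p=7.9e-05
p0=100: <1 bound phage/cell after 7 divisions (~5.8 h)
p0=500: <1 bound phage/cell after 9 divisions (~7.4 h)
p0=1000: <1 bound phage/cell after 10 divisions (~8.3 h)
```

Reading: on day 1 the populations exposed to the highest phage density
double almost twice as fast as the control (0.75 h vs 1.33 h), the
four-group rank test finds that effect overwhelming (df = 3), and every
plausible initial bound-phage load is diluted below one particle per
cell well inside the first 48 h — so the response cannot be sustained
by phage still attached to the cells. The report written to
`results/full_run/report.json` also contains the day-by-day cell-size
ratios (2.5× smaller on day 1, attenuating to 1.3× by day 4) and the
per-day distribution tests.

The individual steps are available as numbered drivers
(`analysis/01_simulate.py` … `05_phage_dilution.py`) that read and
write plain CSV, so any stage can be re-run on real data with the same
column layout (`well,day,treatment,replicate,time_h,od650` for growth;
`day,treatment,event,fsc,ssc` for cytometry).

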