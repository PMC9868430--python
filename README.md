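# sowpatterns

Quantitative ethology of peripartum sows and its consequences for piglets.

Lactating sows housed in individual farrowing pens go through a
characteristic activity arc around parturition: restlessness builds to a
peak on the day before farrowing (nest-building), collapses into
quiescence during farrowing itself (~92 % of the day spent lying), and then
settles into an early-lactation routine punctuated by nursing bouts.  How
an individual sow moves through this arc — how often she changes posture,
how much of her lying time leaves the udder accessible, what she does while
standing — is associated with whether her piglets survive the first week
and how fast they grow.

`sowpatterns` implements that full analysis as a tested, reusable pipeline
over 5-second posture/activity label streams (the output format of a
video-classification stage, which is out of scope here):

1. **Synthetic cohorts** (`sowpatterns.simulate`) — a semi-Markov chain over
   the six-posture ethogram {ST, SI, K, SL, LL, LLU} with exponential
   holding times, day-specific restlessness multipliers, log-normal
   between-sow effects and breed-specific posture preferences; plus litters
   of 12–21 piglets with proportional-hazards mortality and linear-model
   growth driven by the dam's *realised* behavioural traits.
2. **Daily traits** (`sowpatterns.streams`) — despiking of single-tick
   classifier errors, pooling of the confusable sitting/kneeling classes,
   daily postural and standing-activity budgets, and the three restlessness
   counts: PCAll (all posture changes), PCRiskCrush (standing→lying and
   sternal→lateral transitions) and PCStopNurse (exits from lateral lying
   with the udder exposed).
3. **Activity-pattern clusters** (`sowpatterns.compositions`,
   `sowpatterns.clustering`) — budgets are compositions, so they are mapped
   to isometric log-ratio (ILR) coordinates before k-means; multi-day
   periods are clustered longitudinally (joint distance over the flattened
   days × coordinates trajectory); k is chosen by the elbow rule.
4. **Association models** (`sowpatterns.association`) — piglet survival
   (Cox proportional hazards, Efron ties, Kaplan–Meier/log-rank
   descriptives, Schoenfeld proportional-hazards checks) and piglet growth
   (OLS of average daily gain D0–D7), each selected by a three-step
   protocol: per-item screening with AIC-chosen coding (continuous vs
   tertile classes I/M/S, or S vs M+I for growth), per-period backward
   elimination by likelihood-ratio test, and a final cross-period global
   model.  Every decision lands in a replayable `SelectionTrace`.

The three peripartum periods are `bf` (days −3…−1 before farrowing), `df`
(the 24 h following the first birth) and `af` (days 1…7).

## Worked example

```python
import sowpatterns as sp

cfg = sp.default_sim_config(n_sows=43, seed=7)
cohort = sp.build_cohort(cfg)          # streams -> daily traits -> litters
print(cohort.total_ticks)              # 8173440  (43 sows x 11 days x 17,280 ticks)

surv = sp.SurvivalAssociationModel(cohort.piglets, cohort.sow_covariates).fit()
print(surv.summary())
```

which prints (abridged):

```
Three-step survival association model (alpha=0.05)
behavioural terms retained: pcall_df, pcstopnurse_af
Cox proportional-hazards fit (efron ties): n=688, events=149, partial logL=-919.04, AIC=1858.09
term                                 coef      HR            95% CI        p
genetic_type=MS/MS                  0.650   1.916      [1.19, 3.09]  0.00791
...
pcall_df__cont                      0.303   1.354      [1.07, 1.71]   0.0102
pcstopnurse_af__cont               -0.018   0.982      [0.97, 0.99] 1.38e-07
```

plus a Schoenfeld proportional-hazards table (global p = 0.79 here: no
evidence against proportionality).  The generator plants its survival
effect on restlessness *after* farrowing; at 43 sows the selection keeps
two correlated proxies of it (behavioural traits are repeatable across
periods, r ≈ 0.75, so small cohorts cannot always tell neighbours apart) —
the direction is right: more posture changes ending nursing bouts on
D1–D7, lower risk.  At 300 sows the protocol retains the planted trait
itself and its hazard ratio comes back at ~0.57 per 100 changes against
the planted 0.56 (`sp.hazard_ratio_to_pct(0.57)` → ~43 % risk reduction);
that recovery is exactly what `scripts/acceptance.py` recomputes.

The same cohort drives the growth side:

```python
growth = sp.GrowthAssociationModel(cohort.piglets, cohort.sow_covariates).fit()
print(growth.summary())   # ADG shifts (g/d) for upper-tertile (S) dams
```

```
Three-step growth association model (alpha=0.05)
behavioural terms retained: pcall_bf, pcall_df, pcall_af
OLS fit of ADG (g/d): n=574, sigma=53.9, logL=-3095.42, AIC=6220.84
term                              estimate      se         p
...
pcall_bf__S                         -23.44    9.67    0.0157
pcall_df__S                         -43.89   10.22  2.07e-05
pcall_af__S                          70.82   10.30  1.67e-11
```

The upper-tertile (S) shifts land on the planted effect sizes (−22.37,
−45.33, +70.84 g/d), again through close proxies of the planted traits at
this cohort size.

A shell pipeline with on-disk artifacts (long stream CSV, trait tables,
cluster labels, JSON model reports) is available as:

```bash
sowpatterns init-config study.yaml
sowpatterns all --config study.yaml --seed 7 --out runs/demo
cat runs/demo/report.txt
```

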