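# hautil

Health-utility elicitation for end-stage kidney disease (ESKD) transplant
decisions: adaptive **standard gamble** (SG), **time trade-off** (TTO) and
**visual analog scale** (VAS) question engines with chained anchors and
life-table TTO horizons, a simulated-respondent model, a calibrated
synthetic-cohort generator, and the statistical toolbox of a utility-
elicitation feasibility study (rank tests, Cronbach alpha, power, summary
tables).

## The problem

Accepting a kidney from a hepatitis-C-viremic (HCV-viremic) donor shortens
the wait for transplantation but carries worries that persist even after a
successful transplant. Whether that trade is worth it depends on each
patient's preferences, quantified as *utilities* u ∈ [0, 100] for three
health states — chronic intermittent hemodialysis, transplant with an
HCV-unexposed kidney, and transplant with an HCV-viremic kidney — anchored
at Well (u = 100) and Dead (u = 0).

The three classic elicitation methods are implemented as adaptive binary-
choice sessions that bracket the indifference point:

* **SG** — choose between the sure intermediate state and a gamble giving
  the best anchor with probability *p*, else death. At indifference,
  u = p · u(best) + (1 − p) · u(worst). The complement 100 − u is the
  maximum acceptable risk of immediate death.
* **TTO** — trade the full horizon *T* (remaining life expectancy from a
  period life table) in the assessed state against *x* ≤ *T* years in the
  best anchor; u = (x/T) · u(best) at indifference. Offers are posed in
  whole months.
* **VAS** — a single placement on the 0–100 feeling thermometer.

The HCV-viremic state is assessed in a **chained** session whose best
anchor is the transplant state itself; the elicited raw fraction is
returned to the common scale by the chained product
`raw HCV utility × transplant utility = HCV utility`.

Sessions run a ping-pong probe ladder (0.95, 0.05, 0.85, 0.15, 0.75, 0.25)
then bisect to a bracket width of 0.005 (0.5 utility points).

## Worked example

A noise-free simulated respondent with latent utilities 82.5 / 89 / 75.5
(hemodialysis / transplant / HCV-viremic, on 0–100) goes through the
two-part SG protocol:

```python
from hautil import *

prof = RespondentProfile({HealthState.HEMODIALYSIS: 0.825,
                          HealthState.TX_UNEXPOSED: 0.89,
                          HealthState.TX_HCV_VIREMIC: 0.755})
cfg = TitrationConfig()
hemo = run_auto_session(AssessmentMethod.SG, HealthState.HEMODIALYSIS,
                        AnchorPair.well_dead(), cfg, prof)
tx = run_auto_session(AssessmentMethod.SG, HealthState.TX_UNEXPOSED,
                      AnchorPair.well_dead(), cfg, prof)
chained = run_auto_session(
    AssessmentMethod.SG, HealthState.TX_HCV_VIREMIC,
    AnchorPair.chained(HealthState.TX_UNEXPOSED, tx.normalized), cfg, prof)
print(f"hemodialysis SG utility: {hemo.normalized:.1f}")
print(f"transplant SG utility:   {tx.normalized:.1f}")
print(f"chained HCV raw fraction: {chained.raw_fraction:.4f}")
print(f"chained HCV normalized:   {chained.normalized:.1f}")
print(f"implied death risk:       {implied_death_risk(chained.normalized):.1f}%")
```

prints

```
hemodialysis SG utility: 82.7
transplant SG utility:   88.9
chained HCV raw fraction: 0.8484
chained HCV normalized:   75.4
implied death risk:       24.6%
```

Each utility lands within the 0.5-point elicitation resolution of its
latent target; the chained fraction 0.8484 ≈ 75.5/89 is the respondent's
indifference on the (transplant, Dead) anchor pair, and its product with
the elicited transplant utility recovers the HCV-viremic utility on the
common scale. The implied death risk says this respondent would accept up
to a ~25% chance of immediate death to get an HCV-unexposed rather than an
HCV-viremic kidney.

The command line exposes the same machinery:

```bash
hautil simulate --seed 1 --out cohort.csv     # synthetic 63-patient study
hautil analyze --in cohort.csv --tables out/  # knowledge + utility tables
hautil power --delta 12 --sd 16.3             # -> 30 (per-arm n)
hautil elicit --method sg --state hemodialysis  # interactive session
```

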