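# msngate

Single-cell analysis of combinatorial gene regulation by the budding-yeast
stress factors **Msn2** and **Msn4**, paired with a generative kinetic
simulator so that every stage of the analysis is exercisable without
external data.

## The scientific problem

Msn2 and Msn4 are homologous transcription factors that translocate into
the nucleus under stress and bind the same promoter elements (STREs). They
were long considered redundant, yet deletion experiments show that their
roles depend on *promoter activation kinetics* and on *input duration*:

* **Fast-kinetics promoters** (e.g. P<sub>DCS2</sub>-like) are induced by
  either factor alone — an **OR gate**.
* **Slow-kinetics promoters** (e.g. P<sub>SIP18</sub>-like) require both
  factors for a transient (30-min) input — an **AND gate** — but with a
  prolonged (60-min) input Msn4 becomes dispensable while Msn2 remains
  required.
* At the single-cell level, expression of slow promoters is **switch-like
  in Msn2** — a low threshold θ ≈ 25% of the maximal Msn2 nuclear level
  turns the gene ON, with no further benefit from more Msn2 (excess Msn2
  in fact suppresses expression by competing for shared sites) — and
  **rheostat-like in Msn4**, rising approximately linearly with Msn4
  activity.

## The model

Per cell, nuclear TF levels `msn2(t)`, `msn4(t)` follow first-order
import/export kinetics toward log-normally distributed amplitudes
(Msn4 ~3-fold lower on the normalized scale, CV 0.5 vs 0.2, lagging Msn2
by ~2.5 min). Chromatin opening of a promoter is a chain of n = 6
sequential steps

    S0 → S1 → … → S6(open),   per-step rate k_open · H(t) · g(msn4),

where `H(t)` gates the opening (slow class: `1{msn2(t) ≥ θ}` — the Msn2
switch; fast class: combined TF level above a basal occupancy) and, for
the slow class only, `g(msn4) = c + (1−c)·msn4/(K₄+msn4)` lets Msn4
accelerate opening several-fold (without Msn4 the chain still advances,
but too slowly to finish within a 30-min pulse). The default per-step rate
is 5-fold higher for the fast class. Transcription from the open state
obeys shared-site competition,

    rate = β · (w₂·msn2 + w₄·msn4) / (K + msn2 + msn4),   w₂ < w₄ (slow),

and a stable fluorescent reporter accumulates with a 10-min maturation
delay, saturating softly at its plateau. Measurement noise is additive
Gaussian on every recorded channel.

## Worked example

```bash
msngate demo --out demo_out --seed 7 --n-cells 200
```

simulates both promoter classes for WT and deletion strains at 30- and
60-min pulses, extracts per-cell features, classifies gate logic, and fits
the switch/rheostat regulator modes. It prints:

```
# Gate logic and regulator modes

Responder threshold (control 95th percentile): 1.61 expression a.u.

## fast kinetics promoter

| duration (min) | gate | WT mean | msn2d/WT | msn4d/WT |
|---|---|---|---|---|
| 30 | OR | 100 | 1.00 | 1.00 |
| 60 | OR | 100 | 1.00 | 1.00 |

## slow kinetics promoter

| duration (min) | gate | WT mean | msn2d/WT | msn4d/WT |
|---|---|---|---|---|
| 30 | AND | 57.3 | 0.00 | 0.15 |
| 60 | MSN2_REQUIRED | 99.6 | 0.00 | 0.72 |

## Slow-promoter single-cell regulator modes (WT)

- msn2: switch (threshold 10.4 normalized a.u. = 22.4% of max)
- msn4: rheostat (slope 2.87 a.u. per normalized a.u.)
```

Reading the table: `msn2d/WT` is the fraction of wild-type expression
achieved by Msn4 alone, `msn4d/WT` by Msn2 alone. The fast promoter is
fully induced by either factor (OR). The slow promoter needs both at
30 min (AND: both fractions below 25%) but tolerates losing Msn4 at
60 min (Msn2-only reaches 72% of WT), while Msn2 remains essential — the
duration-dependent gate switch. The single-cell fits recover the Msn2
switch threshold (~10 normalized a.u., ~22% of the maximal Msn2 level)
and the linear Msn4 rheostat.

The same stages are available as composable commands (`simulate`,
`features`, `analyze`, `fit`, `gates`, `report`, `schema`) and as library
functions (`generate_experiment`, `extract_features`, `bin_by_tf`,
`classify_gate`, `fit_regulator_mode`, `estimate_kinetic_ratio`, …).

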