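# lorp — library-of-reference-plans adaptive radiotherapy, in silico

`lorp` simulates the **plan-library ("plan of the day") strategy** for
adaptive short-course radiotherapy of rectal cancer, end to end, on
synthetic pelvic anatomy. It is aimed at medical-physics researchers who
want the strategy's geometric and decision logic — not a clinical TPS — in
an exact, seeded, testable form.

The daily problem: the CTV is delineated with a full bladder, but on most
treatment days the bladder is smaller, and target tissue moves anteriorly
into the vacated space. A couch shift alone cannot follow it; full daily
re-planning can, but is slow. The library strategy pre-computes plans for a
family of bladder states and picks one per fraction:

1. **Bladder library** — from the simulation bladder B, directional
   Boolean operators move the posterior wall (AP) and superior wall (SI)
   in 1 cm steps over {−1, 0, +1, +2} cm per axis: contraction by d is
   B ∩ translate(B, d inward), expansion B ∪ translate(B, d outward) —
   16 variants including the original.
2. **Target library** — CTVᵢ = envelope ∖ Bᵢ, then PTVᵢ = CTVᵢ ⊕ 6 mm
   (isotropic, Euclidean distance transform), and a reference dose per PTV
   from a surrogate conformal engine (25 Gy plateau, 8 mm linear penumbra).
3. **Daily selection** — after translation-only bony registration, select
   the *largest* library bladder whose posterior and superior walls do not
   exceed the daily bladder's; apply the selected plan with a virtual couch
   shift (`lorp_atp`). Comparators: couch shift of the original plan only
   (`catp`) and full re-planning on the daily anatomy (`ats`).
4. **Evaluation** — DVH metrics (V_D, D_mean, D_1cm³) on the daily
   ground-truth structures against a 10-row protocol with per-protocol /
   variation-acceptable / unacceptable tiers.

See `docs/methods.md` for the model, its assumptions, and its limits.

## Worked example

```python
import lorp

sim = lorp.generate_simulation_anatomy(seed=0)     # synthetic planning CT
library = lorp.build_plan_library(sim)             # 16 reference plans
scenario = lorp.sample_fraction_scenario(sim, seed=42)  # one treatment day

print(len(library), round(scenario.daily["bladder"].volume_cm3
                          / sim["bladder"].volume_cm3, 2))
# 16 0.57    <- daily bladder at 57 % of simulation volume

ctv, ptv = lorp.daily_target(scenario.daily, library.margin)
structures = {n: scenario.daily[n] for n in scenario.daily.names()}
structures["ptv"] = ptv
criteria = lorp.default_criteria()

for strategy in lorp.STRATEGIES:
    dose, sel = lorp.deliver_strategy(strategy, library, scenario, sim)
    ev, vals = lorp.evaluate_plan(dose, structures, criteria)
    print(strategy, ev.overall, round(vals["ptv_v25gy"], 1),
          sel.shift if sel else "")
# lorp_atp per_protocol 100.0 ShiftSpec(ap_cm=2.0, si_cm=1.0)
# catp acceptable 97.2
# ats per_protocol 100.0
```

On this fraction the bladder shrank to 57 % of its planning volume. The
library strategy reselects the plan built for a bladder contracted 2 cm
posteriorly and 1 cm superiorly and keeps full target coverage
(V₂₅Gy = 100 %); the conventional couch-shift plan covers only 97.2 % of
the daily PTV at the prescription dose — still acceptable here, but below
the 99 % per-protocol bound at 95 % of the prescription; full re-planning
is per-protocol by construction.

The cohort harness runs the whole study (default 10 patients × 5
fractions) from the command line:

```bash
lorp simulate-cohort --seed 1 --out scratch/cohort
lorp compare --records scratch/cohort/records.csv --metric ptv_v25gy
```

writing per-fraction records, per-strategy per-protocol/acceptable rates,
plan-selection frequencies, and paired Shapiro–Wilk/t/Wilcoxon comparisons.
`lorp build-library`, `lorp select-plan` and `lorp evaluate` expose the
individual stages; masks and doses are read and written as NIfTI, criteria
and configs as YAML.

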