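# drugcombo

Predicting cancer drug-combination efficacy from monotherapy cell-line
screens — and translating those predictions into clinical-trial hazard
ratios, log-rank powers and prospective combination rankings.

Large pharmacogenomic screens (CTRPv2-, GDSC- or NCI-ALMANAC-style
exports) measure single-drug viability across hundreds of cell lines, but
testing combinations exhaustively is infeasible.  `drugcombo` predicts
combination efficacy from monotherapy data alone under **independent drug
action (IDA)** — a combination's effect on a cell line equals the effect
of its single best constituent —

    mu_combo,IDA = (1/n) * sum_k min(EA_k, ..., EZ_k)

with **Bliss independence** (per-line product of [0,1]-clamped survival
probabilities) as a comparator null model.  Predicted mean viabilities
are treated as hazards (viability 1 ↔ hazard 1, viability 0 ↔ hazard 0),
so a test-vs-control therapy comparison yields HR = mean(test)/mean(control),
which drives a Freedman-type log-rank power estimate

    power = Phi( sqrt(k*m) * |HR - 1| / (k*HR + 1) - z_{1-alpha/2} )

for a trial with m events and allocation ratio k.  Prospective
combinations are ranked by the **IDAcomboscore**

    IDAcomboscore = Delta_via * (1 - HR_C/Mbest)

against the best constituent (or backbone) therapy, and every statistic
carries uncertainty from a semi-parametric bootstrap (normal perturbation
of measured viabilities by their standard errors, with shared compounds
coupled through common normal deviates, plus cell-line resampling).

Intended users: computational pharmacologists and translational
oncologists prioritizing combination candidates, and anyone needing a
reproducible IDA/Bliss prediction engine over tidy screen exports.

## Worked example

```python
from drugcombo import (SyntheticScreenConfig, generate_screen, fit_screen, build_panel,
                       Treatment, ida_combo, bliss_combo, idacomboscore,
                       hazard_ratio, logrank_power, TrialDesign, classify_trial,
                       BootstrapConfig, bootstrap_comboscore, complete_case_lines)

# 1. a 60-line screen for two drugs (synthetic here; use
#    read_monotherapy_screen for a real CSV export), LL4 curve fits
cfg = SyntheticScreenConfig(n_lines=60, drugs=("erlotinib", "lapatinib"), seed=7)
observations, truth = generate_screen(cfg)
fits = fit_screen(observations)

# 2. viability panel at clinically sustained concentrations (uM)
panel = build_panel(fits, [("erlotinib", 4.0), ("lapatinib", 2.5)])
combo = Treatment((("erlotinib", 4.0), ("lapatinib", 2.5)))
lines = complete_case_lines(panel, combo, min_lines=50)
ida = ida_combo(panel, combo, lines=lines)
bliss = bliss_combo(panel, combo, lines=lines)
print(f"IDA mean viability:   {ida.mean:.4f}  (n = {ida.n_lines} cell lines)")
print(f"Bliss mean viability: {bliss.mean:.4f}")

# 3. trial translation: combination arm vs erlotinib alone, 300 events
control = Treatment((("erlotinib", 4.0),))
hr = hazard_ratio(ida, ida_combo(panel, control, lines=lines))
power = logrank_power(hr.hr, TrialDesign(total_events=300))
print(f"HR (test/control):    {hr.hr:.4f}")
print(f"log-rank power:       {power.power:.4f}  -> predicted success: {classify_trial(power)}")

# 4. prospective score with bootstrap uncertainty (1,000 simulations)
score = idacomboscore(panel, combo, min_lines=50)
boot = bootstrap_comboscore(panel, combo, BootstrapConfig(n_sims=1000, seed=7), min_lines=50)
print(f"IDAcomboscore:        {score.score:.4f} +/- {boot.se:.4f}  (P(score<=0) = {boot.null_p:.3f})")
```

Output:

```
IDA mean viability:   0.3354  (n = 60 cell lines)
Bliss mean viability: 0.2136
HR (test/control):    0.7474
log-rank power:       0.7068  -> predicted success: False
IDAcomboscore:        0.0286 +/- 0.0075  (P(score<=0) = 0.000)
```

Reading: adding lapatinib is predicted to cut mean viability from 0.45
(erlotinib alone) to 0.34, an HR of 0.75 — a real but modest improvement
that a 300-event trial would detect with only ~71% power, below the
conventional 80% bar.  The positive IDAcomboscore (0.029 ± 0.008, no
simulated score ≤ 0 in 1,000 draws) still ranks the pair as better than
its best monotherapy.

## Command line

```bash
drugcombo simulate --n-lines 30 --drugs drugA,drugB,drugC --seed 1 --out data/
drugcombo fit --screen data/screen.csv --out fits.csv
drugcombo predict --fits fits.csv --treatment "drugA@1+drugB@2" --model both --min-lines 20
drugcombo trial-power --screen data/screen.csv --trials trials.csv --out results/
drugcombo comboscore --screen data/screen.csv --concentrations conc.csv --out results/
drugcombo dose-grid --fits fits.csv --drug-a drugA --drug-b drugB --max-a 5 --max-b 5
```

Options can come from a YAML file (`--config run.yaml`) with flags taking
precedence; every run writes a `manifest.json` recording inputs, seed and
parameters for exact reproduction.  Screen CSVs use columns `cell_line,
drug, concentration_uM, viability[, replicate, site]` (remappable via a
schema map; percent-scale viability needs an explicit flag).

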