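# faerspv

Disproportionality signal detection and time-to-onset analysis for
FAERS-style spontaneous adverse-event reports.

Spontaneous-report databases such as the FDA Adverse Event Reporting
System (FAERS) collect safety reports for marketed medicines. Because they
have no denominator (no exposure counts), post-marketing safety questions
are asked through *disproportionality analysis*: is an adverse event
reported together with a target drug more often than the background
reporting of the whole database would predict? `faerspv` implements this
case/non-case workflow end to end for pharmacoepidemiologists and
pharmacovigilance scientists:

* reading the FAERS quarterly ASCII dialect (DEMO/DRUG/REAC/THER/OUTC,
  `$`-delimited) and deduplicating report revisions by
  caseid/caseversion;
* extracting the cohort where the target drug is the primary suspect,
  via a brand/generic synonym dictionary, and building an available-case
  demographics table;
* mapping MedDRA Preferred Terms to System Organ Classes and SMQ PT sets
  (user-supplied TSV, or a bundled synthetic hierarchy for testing);
* four disproportionality statistics per drug–event pair with the
  conjunctive signal criterion, and dual rankings (by report count and by
  ROR CI lower bound);
* Weibull time-to-onset analysis per SOC with hazard-shape
  classification;
* a synthetic FAERS generator with an exact ground-truth manifest, so
  the whole pipeline is testable without downloading FAERS.

## The statistics

For each event term, reports are cross-tabulated against the deduplicated
background: `a` (target drug and event), `b` (target drug, other events),
`c` (other drugs, event), `d` (neither), `N = a+b+c+d`,
`E = (a+b)(a+c)/N`.

* **ROR** = `ad/bc`, 95% CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`
  (Haldane–Anscombe +0.5 on zero cells);
* **PRR** = `[a/(a+b)] / [c/(c+d)]`, with the Yates-corrected Pearson χ²
  on the 2×2 table;
* **IC** = `log2((a+0.5)/(E+0.5))`, the Bayesian information component,
  with the closed-form credible lower bound
  `IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2)` (exact gamma-posterior and
  Monte-Carlo percentiles are available as alternatives);
* **EBGM / EB05**: the empirical-Bayes geometric mean and 5th posterior
  percentile of the relative reporting rate λ under the two-component
  gamma mixture prior `λ ~ w·Γ(α₁,β₁) + (1−w)·Γ(α₂,β₂)` fitted by
  maximum marginal likelihood across all drug–event pairs (the MGPS
  shrinker).

A pair is a **signal of disproportionate reporting** when all of
`PRR ≥ 2`, `χ² ≥ 4`, `a ≥ 3`, IC lower bound `> 0` and `EBGM > 2` hold.

Time-to-onset (days from first complete therapy start to event, complete
YYYYMMDD dates only, negative onsets excluded as entry errors) is
summarized and fitted with a two-parameter Weibull; shape `β < 1` with its
whole 95% CI below 1 is classified as *early failure* (front-loaded risk),
`β > 1` as *late failure*, otherwise *constant hazard*.

## Worked example

Run the whole pipeline on a 50,000-report synthetic corpus with four
planted drug–event associations (reporting-rate ratio ρ = 5):

```python
import pathlib
from faerspv.cli import RunConfig, cmd_report

cfg = RunConfig(seed=11, output_dir=pathlib.Path("demo"))
cfg.synth = dict(
    n_reports=50_000,
    injected_pairs=[dict(drug="TARGET", pt=p, rho=5.0)
                    for p in ("Pyrexia", "Sepsis", "Neutropenia", "Rash")],
)
cmd_report(cfg)
```

`demo/run_report.md` then shows the filter chain

```
| Report versions read | 54887 |
| Deduplicated cases | 50000 |
| Target-drug cohort (role PS) | 774 |
| Cohort cases with complete TTO | 661 |
```

and `demo/signals_pt.csv` flags exactly the four planted pairs:

```
       term  a  ror  ror_l  prr  chi2  ic_lower  ebgm  is_signal
Neutropenia 40 4.20   3.02 4.03 84.01      1.37   4.4       True
    Pyrexia 34 4.35   3.05 4.20 75.54      1.37   4.4       True
       Rash 34 4.12   2.89 3.98 69.44      1.30   4.4       True
     Sepsis 31 4.10   2.83 3.97 62.81      1.26   4.4       True
```

Observed RORs sit near the planted ρ = 5 (diluted a little because each
report carries several reactions), all five criteria pass, and none of
the 75 null terms is flagged. `demo/tto_weibull_soc.csv` holds the
per-SOC Weibull fits, e.g.

```
                                 soc   n  median  alpha  beta  hazard_class
Blood and lymphatic system disorders 215    18.0  31.93  0.78 early_failure
                   Cardiac disorders  58    11.0  23.85  0.80 early_failure
```

— shapes below 1 mean the onset hazard is highest right after the start
of therapy, the expected pattern for infusion-type reactions.

The same run is available from a shell:

```bash
faerspv report --config run.yaml        # or: generate / signals / tto
```

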