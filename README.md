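# faerspv — disproportionality signal detection for spontaneous adverse-event reports

`faerspv` is a tested, reproducible implementation of the standard
pharmacovigilance desk workflow for a single target drug in FAERS-style
spontaneous reporting data, built around the motivating case of infliximab
in inflammatory bowel disease (IBD):

1. **Ingest & deduplicate** quarterly `$`-delimited ASCII tables (DEMO,
   DRUG, REAC, OUTC, THER, INDI). Per CASEID the version with the most
   recent FDA receipt date is kept, ties broken by the larger PRIMARYID.
2. **Select the cohort**: reports naming the target drug (configurable
   synonym list, e.g. INFLIXIMAB/REMICADE) as primary suspect (role PS)
   with a qualifying indication (e.g. Crohn's disease, ulcerative colitis,
   inflammatory bowel disease); everything else is the background.
3. **Detect signals** per preferred term (PT) and system organ class (SOC)
   from the 2×2 report table (a = cohort & event, b = cohort & other,
   c = background & event, d = background & other):

   - ROR = ad/bc, SE(ln ROR) = √(1/a + 1/b + 1/c + 1/d),
     95% CI = exp(ln ROR ± 1.96·SE)
   - PRR = [a(c+d)]/[c(a+b)],
     χ² = (ad − bc)²(a+b+c+d)/[(a+b)(c+d)(a+c)(b+d)]
   - BCPNN information component IC = log₂[aN/((a+c)(a+b))], with a
     shrunk posterior version E(IC) ± 2√V(IC) for the credible bound IC025

   joint signal criterion: ROR025 > 1, PRR > 2, χ² > 4, a ≥ 3 and IC025 > 0.
4. **Compare subgroups** (female vs male, monotherapy vs combination):
   stratified detection plus a between-stratum ROR within the cohort,
   χ²(1 df) p-values, Benjamini–Hochberg FDR, and volcano coordinates
   (log₂ ROR vs −log₁₀ adjusted p).
5. **Time-to-onset**: whole-day intervals between therapy start and event,
   cleaned by strict date rules; maximum-likelihood Weibull fit of scale α
   and shape β with Wald CIs on the log-parameters (β CI < 1 ⇒ "early
   failure", > 1 ⇒ "wear-out"); log-rank comparison of onset by sex.

Because real FAERS extracts are large and MedDRA is licensed, the package
ships a **synthetic multi-table generator** with exactly known ground truth
(per-PT true RORs via odds inversion, sex-specific odds multipliers,
Weibull onset times, injected duplicate case versions, missing data), so
every stage is testable end to end at desk scale.

## Worked example

The numbered drivers under `analysis/` run the whole study on a 60,000
report synthetic extract (three injected effects: a female-dominant
immune-mediated PT with overall true ROR 7.28, a male-leaning haemodynamic
PT at 27.86, a sex-neutral infection at 5.00):

```bash
cd analysis
python 01_simulate.py && python 02_ingest_dedup.py && python 04_signal_detection.py
```

prints, among other things:

```
deduplicated cases: 60000 (removed 3019 versions)
cohort: 14933  background: 45067
-- PT level: 3 signal(s) of 16 labels
                     label    a   ror  ror025   prr    chi2  ic025
Blood pressure fluctuation 1915 30.55   26.50 26.76 4989.83   1.76
       Lupus-like syndrome  371  7.02    5.83  6.87  572.99   1.28
    Pulmonary tuberculosis  214  5.03    4.04  4.97  257.79   1.06
```

All 3,019 injected duplicate versions are removed exactly; the three
elevated PTs — and none of the thirteen null PTs — pass the joint signal
criterion, with estimated RORs close to the configured truths.
`05_subgroup_comparison.py` then flags only the immune-mediated PT as
female-dominant (between-sex ROR 1.94, adjusted p ≈ 3×10⁻⁸), and
`06_time_to_onset.py` fits β = 0.745 (CI 0.733–0.758), the early-failure
pattern implied by the configured shape 0.73. Outputs land as TSV under
`results/study/`.

The same stages are available as a CLI (`faerspv simulate|ingest|summarize|
detect|subgroup|tto|all`) and as library functions.

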