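# gradedcat

Polytomous IRT toolkit for building and simulating adaptive tests of a
single latent trait: graded-response-model (GRM) calibration, a
five-filter item-bank screening pipeline, a computerized-adaptive-testing
(CAT) engine with EAP scoring, and an external-validity battery.

## What's inside

| Module | Contents |
| --- | --- |
| `gradedcat.models` | GRM / GPCM / RSM category probabilities, Fisher information, pattern likelihoods, item-bank and response-matrix containers |
| `gradedcat.calibration` | Bock–Aitkin marginal-maximum-likelihood EM, −2LL/AIC/BIC model comparison |
| `gradedcat.screening` | polychoric correlations, iterative one-factor loading filter with variance-share and eigenvalue-ratio checks, Yen's Q3 local dependence, discrimination cut, Orlando–Thissen S−χ² item fit, ordinal-logistic DIF (McFadden pseudo-R², purification), and the full pipeline with audit trail |
| `gradedcat.cat` | maximum-information item selection, EAP posterior updates on a fixed quadrature grid, fixed-length and SE-threshold stopping rules (with forced maximum length), cohort simulation |
| `gradedcat.evaluation` | marginal reliability, Mann–Whitney AUC, ROC curves, per-rule criterion-validity reports |
| `gradedcat.synth` | seeded generators for latent traits, response matrices, criterion scores, random banks, a packaged 20-item calibrated reference bank, and planted item defects (noise, low discrimination, DIF, local dependence) |

## CLI

```bash
# synthetic bank + responses + criterion scores
gradedcat generate --n-persons 500 --n-items 20 --seed 1 --out-dir data/

# EM calibration
gradedcat calibrate --responses data/responses.csv --model GRM --out bank.csv

# adaptive-test simulation under stopping rules
cat > rules.yaml <<EOF
fixed_lengths: [10, 13, 20]
se_rules:
  - {se: 0.3, max_items: 13}
EOF
gradedcat simulate-cat --bank data/bank.csv --responses data/responses.csv \
    --rules rules.yaml --criterion data/criterion.csv --out results.json

# item-bank screening pipeline
gradedcat screen --responses data/responses.csv --out-dir screen/
```

## Library sketch

```python
from gradedcat import (
    reference_bank, simulate_responses, CohortSpec,
    StoppingRule, simulate_cohort, fit_model,
)

bank = reference_bank()                      # 20 calibrated GRM items
resp, theta = simulate_responses(bank, CohortSpec(n_persons=500, seed=1))
calib = fit_model(resp, "GRM")               # Bock-Aitkin EM
rules = [StoppingRule(fixed_length=13),
         StoppingRule(se_threshold=0.3, max_items=13)]
results = simulate_cohort(resp, calib.bank, rules)
```

## Conventions

- Category codes are 0-based everywhere; CSV readers take an `origin`
  flag for 1-based Likert data.
- Logistic metric with scaling constant D = 1.
- Latent-trait prior is standard normal; the default quadrature grid is
  61 equally spaced nodes on [−6, 6] with renormalized N(0, 1) weights,
  shared by calibration and the CAT engine (so a full-bank CAT reproduces
  the batch EAP estimate exactly).
- Missing responses are omitted from likelihoods (MCAR), never imputed.
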