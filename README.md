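# wordfx

Screening mixed-worded Likert scales for wording effects with constrained
factor mixture models, and re-validating the screened scale.

## The problem

Balanced self-report scales mix positively worded items ("I am a person of
worth") with negatively worded ones ("I feel useless at times", recoded
before analysis).  A minority of respondents — through inattention,
acquiescence, or difficulty verifying item meaning — answer the two item
types inconsistently.  These few respondents depress the correlations
between positive and recoded negative items, inflate apparent
multidimensionality, and spawn spurious "method factors" in confirmatory
models, even though the majority answered coherently.

`wordfx` identifies those respondents with **constrained two-class factor
mixture models** and removes them, then quantifies how much of the wording
artifact the screen eliminated.

## The models

Both screens posit a latent class variable with two classes over a
one-factor model for *p* items, with class 1 the *inconsistent* class: its
recoded negative items load with flipped sign.  With loadings λ, intercepts
ν, uniquenesses ψ (shared across classes), factor mean α and variance Φ,
the within-class model is y = ν + λf + ε, f ~ N(α_k, Φ_k), ε ~ N(0, diag ψ).

* **Sign-flip-linked screen** ("steinmann"): positive-item λ and ν shared
  across classes with λ > 0; negative items have free ν per class and
  λ₁⁻ = −λ₂⁻; the consistent class is standardized (α₂ = 0, Φ₂ = 1) while
  α₁, Φ₁ are free.  38 free parameters for a 5+5 scale.
* **Unit-loading screen** ("arias"): all loadings fixed (+1, except −1 for
  negatives in class 1), ν shared, α₁ = α₂ = 0, Φ₁ and Φ₂ free.  23 free
  parameters.

Estimation is maximum likelihood via multistart generalized EM, treating
item codes as continuous.  Modal posterior assignment flags inconsistent
respondents; agreement between the two screens is summarized by Cohen's κ.

Downstream validation of the screened data:

* **Polychoric correlations** (two-step ML) and permutation **parallel
  analysis** with the mean criterion for dimensionality;
* **Confirmatory models** on the polychoric matrix — one factor, two
  correlated factors split by polarity, and a random-intercept item factor
  analysis (RIIFA) whose ±1 method factor captures uniform response style —
  each optionally with a free p4–p5 error covariance (θ), fitted by
  unweighted or diagonally weighted least squares, with CFI/TLI/RMSEA/SRMR,
  modification indices and SEPCs;
* **Reliability**: categorical omega computed from loadings and thresholds
  on the observed ordinal metric, Cronbach's α, item-rest correlations, and
  BCa bootstrap intervals.

A synthetic-data generator plants a known inconsistent class so the whole
chain is testable end to end.

## Worked example

```python
import numpy as np
from wordfx import (GeneratorSpec, generate_responses, arias_spec, fit_fma,
                    classify, screen_sample, polychoric_matrix,
                    block_average_correlations, correlation_eigenvalues,
                    build_cfa_spec, fit_cfa)
from wordfx.types import default_polarity

pol = default_polarity(5, 5)
lab = generate_responses(GeneratorSpec(mixing_weight=0.08, seed=12), 632)
fit = fit_fma(lab.responses, arias_spec(pol), n_starts=50, n_final=10, seed=7)
assign = classify(fit)
screened = screen_sample(lab.responses, assign)
```

Summarizing the fit and the before/after polychoric structure prints:

```
loglik=-7234.43  entropy=0.69  mixing=0.089  flagged=23
total     n=632  cross-block avg=0.30  eig1=3.99 eig2=0.93  method loading=0.157
screened  n=609  cross-block avg=0.34  eig1=4.15 eig2=0.89  method loading=0.000
```

The mixture recovers the planted 8% mixing weight (0.089), flags 23
respondents, and after screening the positive–negative cross-block average
correlation rises (0.30 → 0.34), the second eigenvalue falls, and the RIIFA
method-factor loading collapses to zero — the wording artifact was carried
by the flagged minority.

The same workflow is available from the shell:

```bash
wordfx screen --model both --data responses.csv --polarity polarity.yaml \
              --starts 200 --seed 7 --out screen.json
wordfx pa     --data responses.csv --polarity polarity.yaml --sets 1000 \
              --seed 7 --out pa.json --scree scree.csv
wordfx cfa    --matrix R.csv --n 632 --model 2f --theta p4,p5 --out fit.json
wordfx report --data responses.csv --polarity polarity.yaml --out report.json
```

## Packaged data

`wordfx.datasets.table1_matrix(sample)` loads the three published 10×10
polychoric matrices for the Rosenberg Self-Esteem Scale in the Dominican
Republic (total sample N = 632 and the two screened samples, N = 588 and
N = 582), which drive the reproduction below.

## Layout

```
src/wordfx/
  synth.py          planted-class generator          fma.py       mixture screens
  polychoric.py     thresholds + correlations        cfa.py       1F/2F/RIIFA fits
  dimensionality.py eigenvalues + parallel analysis  reliability.py omega/alpha/BCa
  pipeline.py       end-to-end report                cli.py       wordfx CLI
  datasets.py       packaged matrices
docs/methods.md     modelling and numerical choices
```
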