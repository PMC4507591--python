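# thzchem

Terahertz time-domain spectroscopy (THz-TDS) simulation, optical-constant
extraction, and PLS/iPLS chemometrics for discriminating sample classes —
built around the canonical use case of telling apart crop (wheat) varieties
from their featureless THz absorption spectra.

## The problem

Pressed-pellet transmission THz-TDS measures the electric field of a
picosecond pulse after it crosses a thin sample, giving amplitude *and*
phase. Ratioing a sample scan against an empty-path reference scan yields
the complex transmission

    H(ω) = E_sam(ω)/E_ref(ω) = ρ(ω) e^{-iφ(ω)},

and, for a single-pass slab of thickness *d*,

    n(ω) = 1 + φ(ω)·c/(ω·d)
    α(ω) = (2/d) · ln[ 4n / (ρ·(n+1)²) ]        [cm⁻¹]

Organic powders have featureless THz absorption that rises with frequency;
compositional differences between classes (e.g. wheat varieties) shift the
curves only subtly. The chemometric stage therefore regresses the integer
class code *y* ∈ {1..K} on the spectra **X** (samples × frequency
variables) with partial least squares (PLS1, NIPALS):

    X = T Pᵀ + E,   Y = U Qᵀ + F,

extracting latent factors that maximise covariance between spectral scores
and the class code. Model quality is summarised by RMSEC (training),
RMSECV (leave-one-out cross-validation), RMSEP (held-out prediction set)
and the Pearson correlation R between reference and predicted codes; a
prediction is converted to a class by rounding to the nearest integer in
1..K. Interval PLS (iPLS) splits the variable axis into equal-width blocks,
cross-validates one PLS model per block, and selects the block with the
lowest RMSECV — localising the informative band and discarding noisy,
irrelevant regions.

Because no measured spectra are publicly available for this problem, the
package ships a first-class forward simulator (`thzchem.simulate`) that
generates reference/sample time-domain traces — or feature matrices
directly — for K labelled classes with the statistical structure the
analysis assumes: published per-variety mean absorption levels, a
band-confined class-discriminative absorption bump, pellet-to-pellet
scatter, and an instrument noise floor that degrades SNR above ~1.5 THz.
Every downstream stage is therefore testable end to end without any data
download.

## Worked example

```python
from thzchem.pipeline import RunConfig, run, render_report

report = run(RunConfig())   # 8 classes x 20 samples, 3 scans each
print(render_report(report))
```

prints (abridged):

```
THz chemometrics run report
============================================================
samples: 160 (calibration 96 / prediction 64)

Full-spectrum PLS (per feature)
feature            factors    R_cal    RMSEC     R_cv   RMSECV    RMSEP    acc
absorption               5   0.9985   0.1274   0.9975   0.1618   0.2035  0.984
refractive_index         5   0.9033   0.9829   0.7978   1.4087   1.4182  0.312
best feature by RMSECV: absorption

iPLS width 8: 16 intervals; selected interval 8 (vars 57-64, 0.773-0.845 THz)
  selected RMSECV 0.1673 vs full-spectrum 0.1618; RMSEP 0.2193; accuracy 0.953
```

Reading it: on the default synthetic session the absorption-based 5-factor
PLS model predicts the class code with cross-validated error 0.16 (on a
1–8 scale) and assigns 98% of held-out samples to the right class, while
the refractive-index model is far weaker — the discriminative signal lives
in the absorption spectra. The width-8 interval search finds interval 8
(0.773–0.845 THz), exactly where the generator plants the
class-discriminative absorption band.

The same stages are scriptable from the shell:

```sh
thzchem simulate --config cfg.yaml --seed 1 --out session/
thzchem extract --manifest session/manifest.json --band 0.2:1.5 \
    --nvars 128 --feature absorption --out X.csv
thzchem fit --matrix X.csv --ncomp 5 --cv loo --out model.json
thzchem ipls --matrix X.csv --width 8 --ncomp 5 --out intervals.json
thzchem run --config cfg.yaml --out results/
```

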