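# gegdist

Distributional modelling of reaction times (RTs) with the
**generalised exponential-Gaussian (GEG)** family.

Behavioural and neuronal RTs are classically modelled by the
ex-Gaussian (EG) distribution — the sum of a Normal(μ, σ²) component
and an independent Exponential component with mean τ — which is always
right-skewed.  The GEG removes that restriction by raising the EG
distribution function to a positive power (a fractional order
statistic / Lehmann alternative):

```
F_GEG(x; τ, μ, σ, α) = [F_EG(x; τ, μ, σ)]^α ,   α > 0
f_GEG(x)            = α f_EG(x) [F_EG(x)]^(α−1)
```

α controls skewness (α = 1 is exactly the EG; small α reaches
symmetric and negatively skewed shapes), τ regulates tail weight/
kurtosis, μ and σ are location and Gaussian scale in data units.  As
τ → 0 the family collapses to the power-normal (PN), and with α = 1 to
the Normal.  The inverse risk satisfies r_GEG = α·r_EG.

The package is for researchers who want to model the *whole* RT
distribution — location, scale and shape — instead of comparing means:

* numerically stable log-space kernels (density, CDF, quantile,
  sampling, survival, inverse risk, hazard) that survive σ/τ across six
  orders of magnitude;
* maximum-likelihood fitting with standard errors from the observed
  Fisher information, Wald intervals, AIC/BIC, and comparison against
  the families commonly fitted to RTs (Exponential, Normal, t, Gamma,
  Log-Normal, EG, skew-normal SN, power-normal PN, skew-normal
  alpha-power SNAP);
* a Monte-Carlo engine for estimator bias / error / coverage studies
  over a 36-DGP grid;
* quadrature-based moments, skewness/kurtosis range scans and
  sub-family limit verification;
* a GAMLSS-style distributional-regression layer (per-parameter linear
  predictors, e.g. `rt ~ attention * task` on μ) fitted by joint
  maximum likelihood.

## Worked example

Generate a synthetic RT-like sample (strongly right-skewed GEG on the
divided-by-100 scale, the default fixture shape), fit the GEG, and
compare families:

```sh
$ geg synth --kind geg --n 3360 --seed 7 --out adhd_like.csv
$ geg fit adhd_like.csv --family GEG
GEG maximum-likelihood fit (n = 3360)
loglik = -3369.1142   AIC = 6746.228   BIC = 6770.707   converged = True
   param     estimate      std err                [95% Wald CI]
     tau       0.7905       0.0377 [      0.7166,       0.8644]
      mu       2.3921       0.0736 [      2.2479,       2.5363]
   sigma       0.2626       0.0127 [      0.2377,       0.2874]
   alpha       0.5952       0.1027 [      0.3938,       0.7966]
```

The sample was drawn with (τ, μ, σ, α) = (0.835, 2.471, 0.253, 0.486);
every estimate lands within two standard errors of its truth, and
α̂ < 1 correctly flags a shape the plain EG cannot represent exactly.
Ranking candidate families on the same sample:

```sh
$ geg compare adhd_like.csv --families NO,G,LN,EG,SN,GEG
family  k       loglik         aic         bic  converged
   GEG  4 -3369.114162 6746.228324 6770.707109       True
    EG  3 -3372.758539 6751.517077 6769.876166       True
    SN  3 -3488.301876 6982.603752 7000.962841       True
    LN  2 -3500.789695 7005.579390 7017.818783       True
     G  2 -3616.216780 7236.433559 7248.672952       True
    NO  2 -3970.800898 7945.601795 7957.841188       True
```

Lower AIC/BIC is better: the GEG wins on AIC, the Normal misses the
skewed tail by ~600 log-likelihood units, and the Log-Normal's gap
shows a log transform would not rescue normality.

The same library surface is available in Python
(`FamilyModel(data, "GEG").fit()`, statsmodels-style, returning a
results object with `params`, `bse`, `conf_int()`, `summary()`), and
the regression layer follows the same pattern:

```python
from gegdist import DistributionalModel
res = DistributionalModel(table, "rt", {"mu": "attention * task"}, family="GEG").fit()
print(res.summary())          # coefficient table with SE, z, Wald p
```

Other commands: `geg simulate` (estimator bias/rMSE/coverage studies;
`--grid` runs the full 36-DGP study), `geg shape-ranges` (attainable
skewness/kurtosis of SN/PN/SNAP), `geg regress`, and `geg synth` for
reproducible fixtures.

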