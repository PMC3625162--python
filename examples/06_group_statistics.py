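"""Group-comparison statistics: Mann-Whitney, Fisher, logistic, dichotomization.

The small-sample toolkit used for tumor group comparisons: exact Mann-Whitney
fold-difference tests, Fisher's exact test on dichotomized clinical factors,
and univariate logistic regression with separation detection.
"""

import pandas as pd

import zygoct as z

# exact Mann-Whitney on fold differences between two tumor groups
wt_folds = [0.8, 1.1, 0.9, 1.2]
mut_folds = [2.6, 3.1, 1.9, 2.2, 2.8]
mw = z.mann_whitney(wt_folds, mut_folds)
print(f"Mann-Whitney U={mw.statistic:.0f}, two-sided p={mw.pvalue:.4f} "
      f"({mw.method}, n={mw.n})")

# clinical factors dichotomized at the standard cutpoints
clinical = pd.DataFrame(
    {"age": [70, 48, 83, 62, 55, 75], "size": [8.0, 3.5, 6.0, 2.0, 9.0, 5.5],
     "mitoses": [5, 1, 2, 0, 8, 1]},
    index=[f"T{i}" for i in range(6)],
)
table = z.dichotomize_clinical(clinical)
print("\ndichotomized strata (cutpoints: age 60y, size 6cm, mitoses 2):")
print(table.strata.to_string())

# Fisher's exact test: zygosity vs high mitotic count
zygosity = pd.Series([1, 0, 1, 0, 1, 0], index=clinical.index)  # 1 = homozygous
high_mitoses = table.indicators["mitoses"]
counts = pd.crosstab(zygosity, high_mitoses).to_numpy()
fe = z.fisher_exact(counts)
print(f"\nFisher exact on zygosity x mitoses>=2: p={fe.pvalue:.3f}")

# univariate logistic regression of zygosity on the age stratum
logit = z.univariate_logistic(zygosity, table.strata["age"])
print(f"logistic coefficient for age>=60: {logit.params.iloc[1]:.3f} "
      f"(Wald p={logit.pvalues.iloc[1]:.3f}, separated levels: {logit.separated})")
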