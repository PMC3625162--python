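"""Statistical selection and group-comparison tests.

All group statistics operate on log2 relative quantities (equivalently −ΔΔCt):
the cycle scale is where qPCR noise is closest to Gaussian.  The stages are

* a control-line nonspecific filter — assays whose expression varies across
  culture conditions in the empty-vector control line respond to handling, not
  to the oncogene, and are excluded by one-way ANOVA at raw alpha;
* supervised ANOVA feature selection across sample groups (raw alpha,
  matching the original analyses; Benjamini–Hochberg is available as an
  explicit opt-in);
* a PCA-loading gene ranking for "frequently deregulated" genes;
* exact/approximate Mann–Whitney, Fisher's exact test, and univariate
  logistic regression on dichotomized clinical factors, with complete and
  quasi-separation detected and reported rather than producing meaningless
  near-1 Wald p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .ct_io import RQMatrix
from .errors import ParameterError
from .results import SelectionResult

__all__ = [
    "TestResult",
    "LogisticResult",
    "ClinicalFactorTable",
    "one_way_anova",
    "nonspecific_filter",
    "supervised_anova_select",
    "pca_gene_selection",
    "mann_whitney",
    "fisher_exact",
    "univariate_logistic",
    "dichotomize_clinical",
]


@dataclass
class TestResult:
    """A scalar test outcome: statistic, p-value, method tag, group sizes."""

    statistic: float
    pvalue: float
    method: str
    alternative: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or np.isnan(self.pvalue)):
            raise ParameterError(f"p-value out of [0, 1]: {self.pvalue}")


@dataclass
class LogisticResult:
    """Univariate logistic fit: per-level coefficients, Wald p, separation flags."""

    params: pd.Series
    pvalues: pd.Series
    separated: list[str]
    converged: bool
    n: int


@dataclass
class ClinicalFactorTable:
    """Dichotomized clinical factors with the cutpoints that produced them."""

    strata: pd.DataFrame  # string labels like "<60" / ">=60"; NaN = missing
    indicators: pd.DataFrame  # 1.0 = high stratum, 0.0 = low, NaN = missing
    cutpoints: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ANOVA-based assay selection


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA with qPCR-friendly edge conventions.

    Zero total variance (all observations identical) yields p = 1 — no
    evidence of an effect — instead of an undefined ratio.  Zero within-group
    variance with distinct group means yields p = 0.
    """
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    if all(np.ptp(g) == 0 for g in groups):
        return np.inf, 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = scipy.stats.f_oneway(*groups)
    if np.isnan(p):  # degenerate within-variance fallback
        return np.inf, 0.0
    return float(f), float(p)


def _per_assay_anova(
    log2rq: pd.DataFrame, groups: pd.Series, min_per_group: int = 2
) -> tuple[pd.Series, dict[str, str]]:
    """Per-assay one-way ANOVA p across groups; returns (p, skipped reasons)."""
    labels = [g for g in pd.unique(groups.dropna())]
    pvals: dict[str, float] = {}
    skipped: dict[str, str] = {}
    members = {g: list(groups.index[groups == g]) for g in labels}
    for assay in log2rq.index:
        row = log2rq.loc[assay]
        obs = []
        empty = []
        for g in labels:
            v = row[members[g]].dropna().to_numpy()
            if v.size == 0:
                empty.append(g)
            elif v.size >= min_per_group:
                obs.append(v)
        if empty:
            skipped[assay] = f"group(s) fully masked: {empty}"
            continue
        if len(obs) < 2:
            skipped[assay] = "fewer than 2 groups with enough detected values"
            continue
        _, p = one_way_anova(obs)
        pvals[assay] = p
    return pd.Series(pvals, dtype=float), skipped


def nonspecific_filter(
    rq: RQMatrix,
    control_conditions: pd.Series,
    alpha: float = 0.05,
) -> SelectionResult:
    """Exclude assays that respond to culture condition in the control line.

    ``control_conditions`` maps each control-line (empty-vector) sample to its
    condition.  Assays whose log2 RQ differs across conditions within the
    control line (one-way ANOVA, p < ``alpha``) are condition artefacts, not
    oncogene signalling, and are excluded.  The retained set is exactly
    {assays with p >= alpha} plus assays untestable in the controls (reported
    in ``skipped``).

    Requires at least 2 conditions with at least 2 control replicates each.
    """
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    counts = control_conditions.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ParameterError(
            "nonspecific filter needs >= 2 conditions with >= 2 control replicates "
            f"each; got {counts.to_dict()}"
        )
    sub = rq.log2()[list(control_conditions.index)]
    pvals, skipped = _per_assay_anova(sub, control_conditions)
    excluded = list(pvals.index[pvals < alpha])
    retained = [a for a in rq.rq.index if a not in set(excluded)]
    stats = pd.DataFrame({"pvalue": pvals})
    stats["excluded"] = stats.index.isin(excluded)
    return SelectionResult(
        retained=retained,
        stats=stats,
        criteria={"alpha": alpha, "filter": "control_line_anova", "direction": "exclude_p_below_alpha"},
        skipped=skipped,
    )


def supervised_anova_select(
    rq: RQMatrix,
    groups: pd.Series,
    alpha: float,
    correction: str | None = None,
) -> SelectionResult:
    """Retain assays differentially expressed across groups (one-way ANOVA).

    Per-assay ANOVA on log2 RQ across the groups in ``groups`` (sample →
    label); assays with p < ``alpha`` are retained.  Assays where any group is
    fully masked are skipped and reported.  ``correction="bh"`` switches to
    Benjamini–Hochberg adjusted p-values (off by default, matching raw-alpha
    practice; a warning notes the switch).
    """
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    samples = [s for s in groups.index if s in rq.rq.columns]
    sub = rq.log2()[samples]
    pvals, skipped = _per_assay_anova(sub, groups.loc[samples])
    stats = pd.DataFrame({"pvalue": pvals})
    if correction == "bh":
        warnings.warn(
            "Benjamini-Hochberg correction enabled; raw-alpha selection is the default",
            stacklevel=2,
        )
        stats["pvalue_adj"] = multipletests(pvals.to_numpy(), method="fdr_bh")[1]
        decide = stats["pvalue_adj"]
    elif correction is None:
        decide = stats["pvalue"]
    else:
        raise ParameterError(f"unknown correction {correction!r}")
    retained = list(stats.index[decide < alpha])
    stats["retained"] = stats.index.isin(retained)
    return SelectionResult(
        retained=retained,
        stats=stats,
        criteria={"alpha": alpha, "test": "one_way_anova_log2rq", "correction": correction},
        skipped=skipped,
    )


def pca_gene_selection(log2rq: pd.DataFrame, k: int) -> SelectionResult:
    """Rank genes by loading magnitude on the two leading principal components.

    The gene × sample log2 RQ matrix is gene-centered and decomposed; each
    gene is scored by the Euclidean norm of its variance-weighted loadings on
    components 1–2, i.e. by how much of the dominant between-sample structure
    it carries.  The top ``k`` genes are retained.  This is a reconstruction
    of a "frequently deregulated genes" pick and is documented as such.
    """
    if k < 1 or k > log2rq.shape[0]:
        raise ParameterError(f"k must be in [1, n_genes], got {k}")
    if log2rq.shape[1] < 3:
        raise ParameterError("need at least 3 samples")
    x = log2rq.to_numpy(dtype=float)
    if np.isnan(x).any():
        # mean-impute per gene: PCA needs a complete matrix
        means = np.nanmean(x, axis=1, keepdims=True)
        x = np.where(np.isnan(x), means, x)
    centered = x - x.mean(axis=1, keepdims=True)
    if np.allclose(centered, 0):
        raise ParameterError("constant matrix: no principal directions")
    # samples x genes orientation; rows are observations
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    loads = vt[:2].T  # genes x 2
    # fix signs: largest-|loading| gene positive per component
    for j in range(loads.shape[1]):
        lead = np.argmax(np.abs(loads[:, j]))
        if loads[lead, j] < 0:
            loads[:, j] = -loads[:, j]
    weights = s[:2] / np.sqrt(max(log2rq.shape[1] - 1, 1))
    score = np.sqrt(((loads * weights[None, :]) ** 2).sum(axis=1))
    stats = pd.DataFrame(
        {
            "score": score,
            "loading_pc1": loads[:, 0],
            "loading_pc2": loads[:, 1] if loads.shape[1] > 1 else 0.0,
        },
        index=log2rq.index,
    )
    order = sorted(log2rq.index, key=lambda g: (-stats.at[g, "score"], g))
    stats = stats.loc[order]
    retained = order[:k]
    stats["retained"] = stats.index.isin(retained)
    return SelectionResult(
        retained=retained,
        stats=stats,
        criteria={"method": "pca_loading_magnitude", "components": 2, "k": k},
    )


# ---------------------------------------------------------------------------
# two-sample / categorical tests


def mann_whitney(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney U test; exact by enumeration for small tie-free samples.

    The exact null distribution is used when n_a + n_b <= 12 and there are no
    ties; otherwise the normal approximation with tie correction applies.
    The reported statistic is U for the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (a.size + b.size) <= 12 and not has_ties
    res = scipy.stats.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        method="exact" if exact else "normal_tie_corrected",
        alternative=alternative,
        n=(int(a.size), int(b.size)),
    )


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2×2 count table.

    The two-sided p sums the hypergeometric probabilities of all tables (with
    margins fixed) no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError(f"need a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(np.equal(np.mod(t, 1), 0)):
        raise ParameterError("counts must be non-negative integers")
    odds, p = scipy.stats.fisher_exact(t.astype(int), alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        pvalue=float(p),
        method="fisher_exact_hypergeometric",
        alternative="two-sided",
        n=(int(t[0].sum()), int(t[1].sum())),
    )


def univariate_logistic(outcome: pd.Series, factor: pd.Series) -> LogisticResult:
    """Logistic regression of a binary outcome on a single (categorical) factor.

    The factor is reference-coded against its first category; coefficients
    are per-level log odds ratios with Wald p-values.  Levels that perfectly
    predict the outcome (a zero cell in their level × outcome table) make the
    MLE infinite; they are flagged in ``separated`` and their estimates
    reported as NaN rather than as an arbitrarily large number.
    """
    df = pd.DataFrame({"y": outcome, "x": factor}).dropna()
    y = pd.to_numeric(df["y"])
    if not set(y.unique()).issubset({0, 1}):
        raise ParameterError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise ParameterError("outcome is constant: logistic model undefined")
    x = df["x"].astype("category")
    levels = list(x.cat.categories)
    if len(levels) < 2:
        raise ParameterError("factor is constant")
    dummies = pd.get_dummies(x, drop_first=True, dtype=float)
    dummies.columns = [f"x[{lev}]" for lev in levels[1:]]

    separated = []
    for lev in levels[1:]:
        tab = pd.crosstab(x == lev, y)
        if tab.shape != (2, 2) or (tab.to_numpy() == 0).any():
            separated.append(lev)

    design = sm.add_constant(dummies)
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y.to_numpy(), design.to_numpy()).fit(disp=0, maxiter=200)
        params = pd.Series(fit.params, index=design.columns)
        pvalues = pd.Series(fit.pvalues, index=design.columns)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:  # perfect separation can abort the optimizer entirely
        params = pd.Series(np.nan, index=design.columns)
        pvalues = pd.Series(np.nan, index=design.columns)
        converged = False
    for lev in separated:
        params[f"x[{lev}]"] = np.nan
        pvalues[f"x[{lev}]"] = np.nan
    return LogisticResult(
        params=params,
        pvalues=pvalues,
        separated=separated,
        converged=converged,
        n=int(len(df)),
    )


DEFAULT_CUTPOINTS = {"age": 60.0, "size": 6.0, "mitoses": 2.0}


def dichotomize_clinical(
    raw: pd.DataFrame, cutpoints: dict[str, float] | None = None
) -> ClinicalFactorTable:
    """Split quantitative clinical factors at fixed cutpoints.

    A value >= the cutpoint lands in the high stratum (labelled ``>=c``),
    below it in ``<c``; missing stays missing.  Defaults: age 60 years,
    tumor size 6 cm, mitoses 2 per 5 mm².  Non-numeric, non-missing entries
    are a parse error.
    """
    cuts = dict(DEFAULT_CUTPOINTS if cutpoints is None else cutpoints)
    strata = {}
    indic = {}
    for factor, c in cuts.items():
        if factor not in raw.columns:
            raise ParameterError(f"clinical table has no column {factor!r}")
        col = raw[factor]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = col.notna() & numeric.isna()
        if bad.any():
            raise ParameterError(
                f"non-numeric {factor!r} values for samples {list(col.index[bad])}"
            )
        lab = pd.Series(pd.NA, index=col.index, dtype=object)
        lab[numeric >= c] = f">={c:g}"
        lab[numeric < c] = f"<{c:g}"
        strata[factor] = lab
        indic[factor] = (numeric >= c).astype(float).where(numeric.notna())
    return ClinicalFactorTable(
        strata=pd.DataFrame(strata), indicators=pd.DataFrame(indic), cutpoints=cuts
    )
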