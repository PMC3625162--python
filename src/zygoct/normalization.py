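"""Ct-scale quantification: cut-off, card-median correction, ΔΔCt, Ntarget.

The quantification stack mirrors standard relative qPCR practice on
low-density arrays:

1.  A Ct cut-off discards late amplifications (35 cycles for the cell-line
    cards, 37 for the tumor series), turning them into non-detects.
2.  Each card's Ct values are shifted so that every card shares the same
    median — the shared median acts as a perfect *virtual housekeeping gene*,
    replacing an unstable biological reference.
3.  ΔCt is the corrected Ct minus that median (or minus a reference gene's Ct
    per sample); ΔΔCt centers each assay either on a designated reference
    sample or — the default here — on the mean of all ΔCt across samples,
    which is better behaved for downstream group statistics than anchoring on
    one arbitrary sample.
4.  RQ = 2^(−ΔΔCt), assuming PCR efficiency 2; higher expression ⇒ larger RQ.

Single-plex alternatives live alongside: ``Ntarget = 2^(Ct_ref − Ct_target)``
against a reference gene, per-tumor additive correcting factors F that pin a
stable reference gene (e.g. ETV6) to its grand-mean Ct in every tumor, fold
changes relative to a baseline sample group, and a geNorm-style expression
stability ranking (M value) for choosing reference genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_io import CtMatrix, RQMatrix
from .errors import (
    DegenerateCardError,
    NormalizationError,
    ParameterError,
)

__all__ = [
    "DeltaCtMatrix",
    "CorrectionFactors",
    "StabilityRanking",
    "apply_ct_cutoff",
    "card_median_correction",
    "delta_ct",
    "delta_delta_ct",
    "ntarget_reference_gene",
    "tumor_correcting_factors",
    "fold_vs_baseline_group",
    "genorm_stability",
]


@dataclass
class DeltaCtMatrix:
    """ΔCt per assay × sample plus the centering convention that produced it."""

    dct: pd.DataFrame
    centering: str  # "card_median" or "reference_gene(<id>)"
    card_of_sample: pd.Series | None = None


@dataclass
class CorrectionFactors:
    """Additive Ct corrections: per-card shifts or per-tumor factors F.

    ``offsets[j]`` is the number of cycles *added* to every Ct of card/tumor
    ``j``.  For the card-median correction the post-condition is that every
    card's median equals ``target``; for the tumor reference correction it is
    that the reference gene's corrected Ct equals ``grand_mean`` in every
    tumor.
    """

    kind: str  # "card_median" | "tumor_reference"
    offsets: pd.Series
    target: float | None = None
    reference: str | None = None
    grand_mean: float | None = None


@dataclass
class StabilityRanking:
    """geNorm-style stability: M per gene, ascending ranking, pairwise variation.

    ``m`` holds the full-panel M value of each candidate (mean over partner
    genes of the SD across samples of the pairwise log2 expression ratio);
    low M = stable.  ``ranking`` sorts ascending by M (ties broken by assay id
    so output is deterministic).  ``exclusion_order`` lists genes removed by
    iterative worst-first exclusion down to a floor of two.
    ``pairwise_variation[n]`` is V(n/n+1), the SD across samples of the log2
    ratio of normalization factors built from the top n vs top n+1 genes.
    """

    m: pd.Series
    ranking: list[str]
    exclusion_order: list[str] = field(default_factory=list)
    pairwise_variation: pd.Series | None = None


# ---------------------------------------------------------------------------


def apply_ct_cutoff(ct: CtMatrix, cutoff: float) -> CtMatrix:
    """Discard late Ct values: cells with Ct > ``cutoff`` become non-detects.

    The input matrix is not mutated.  ``cutoff`` must lie in (0, 50].
    """
    if not 0 < cutoff <= 50:
        raise ParameterError(f"cutoff must be in (0, 50], got {cutoff}")
    out = ct.copy()
    out.values = out.values.where(out.values <= cutoff)
    return out


def _card_medians(ct: CtMatrix) -> pd.Series:
    """Median of all present Ct values per card; error on empty cards."""
    meds = {}
    empty = []
    for card in ct.cards:
        block = ct.values[ct.samples_of_card(card)].to_numpy()
        present = block[~np.isnan(block)]
        if present.size == 0:
            empty.append(card)
        else:
            meds[card] = float(np.median(present))
    if empty:
        raise DegenerateCardError(f"cards with no detected Ct value: {empty}")
    return pd.Series(meds)


def card_median_correction(
    ct: CtMatrix, target: float | str = "median_of_card_medians"
) -> tuple[CtMatrix, CorrectionFactors]:
    """Shift every card so all cards share one median Ct.

    For card *j* with median ``m_j``, corrected Ct = Ct − (m_j − target).
    After correction every card's median of present values equals ``target``
    (to 1e-9), and that shared median plays the role of a perfect virtual
    housekeeping gene.  Non-detects are untouched.

    ``target`` is either an explicit cycle value or the string
    ``"median_of_card_medians"`` (default): the median of the per-card
    medians, which is robust to cards carrying different non-detect loads.
    """
    meds = _card_medians(ct)
    if isinstance(target, str):
        if target != "median_of_card_medians":
            raise ParameterError(f"unknown target {target!r}")
        tgt = float(np.median(meds.to_numpy()))
    else:
        tgt = float(target)
    shift_per_sample = pd.Series(
        {s: meds[ct.card_of_sample[s]] - tgt for s in ct.samples}
    )
    out = ct.copy()
    out.values = out.values.sub(shift_per_sample, axis=1)
    factors = CorrectionFactors(
        kind="card_median", offsets=tgt - meds, target=tgt
    )
    return out, factors


def delta_ct(
    ct: CtMatrix, centering: str = "card_median", reference: str | None = None
) -> DeltaCtMatrix:
    """Compute ΔCt.

    ``centering="card_median"``: ΔCt = Ct − median of the sample's card, so
    each card's present ΔCt values have median 0 (the virtual-housekeeping
    convention).  ``centering="reference_gene"``: ΔCt = Ct(assay) −
    Ct(reference) per sample; samples where the reference is a non-detect are
    fully masked with a warning.
    """
    if centering == "card_median":
        meds = _card_medians(ct)
        per_sample = pd.Series({s: meds[ct.card_of_sample[s]] for s in ct.samples})
        dct = ct.values.sub(per_sample, axis=1)
        return DeltaCtMatrix(dct, "card_median", ct.card_of_sample.copy())
    if centering == "reference_gene":
        if reference is None or reference not in ct.assays:
            raise ParameterError(f"reference gene {reference!r} not in matrix")
        ref = ct.values.loc[reference]
        dead = [s for s in ct.samples if np.isnan(ref[s])]
        if dead:
            warnings.warn(
                f"reference gene {reference!r} not detected in samples {dead}; "
                "their ΔCt values are masked",
                stacklevel=2,
            )
        dct = ct.values.sub(ref, axis=1)
        return DeltaCtMatrix(
            dct, f"reference_gene({reference})", ct.card_of_sample.copy()
        )
    raise ParameterError(f"unknown centering {centering!r}")


def delta_delta_ct(
    dct: DeltaCtMatrix, reference: str = "mean_of_all_samples"
) -> RQMatrix:
    """ΔΔCt and relative quantities RQ = 2^(−ΔΔCt).

    ``reference="mean_of_all_samples"`` (default) centers each assay on the
    arithmetic mean of its present ΔCt values — more stable for group
    statistics than a single calibrator sample, and it forces the per-assay
    geometric mean of present RQ to 1.  Passing a sample id instead uses that
    sample's ΔCt as the calibrator, giving RQ = 1 for every assay in that
    sample.  Assays with no present value are dropped with a warning.
    """
    dm = dct.dct
    present_counts = dm.notna().sum(axis=1)
    dead = list(dm.index[present_counts == 0])
    if reference == "mean_of_all_samples":
        center = dm.mean(axis=1, skipna=True)
        mode = (
            "virtual_housekeeping"
            if dct.centering == "card_median"
            else dct.centering
        )
    else:
        if reference not in dm.columns:
            raise ParameterError(f"reference sample {reference!r} not in matrix")
        center = dm[reference]
        dead = sorted(set(dead) | set(dm.index[center.isna()]))
        mode = f"baseline_sample({reference})"
    if dead:
        warnings.warn(
            f"assays with no usable reference ΔCt dropped: {dead}", stacklevel=2
        )
        dm = dm.drop(index=dead)
        center = center.drop(index=dead)
    ddct = dm.sub(center, axis=0)
    rq = np.exp2(-ddct)
    return RQMatrix(rq, mode, meta={"centering": dct.centering, "reference": reference})


def ntarget_reference_gene(
    ct: CtMatrix, target_assay: str, reference_assay: str
) -> RQMatrix:
    """Single-gene relative quantity Ntarget = 2^(Ct_reference − Ct_target).

    Lower target Ct (more template) gives a larger Ntarget.  Cells where
    either assay is a non-detect are masked.
    """
    for a in (target_assay, reference_assay):
        if a not in ct.assays:
            raise ParameterError(f"assay {a!r} not in matrix")
    diff = ct.values.loc[reference_assay] - ct.values.loc[target_assay]
    rq = pd.DataFrame([np.exp2(diff)], index=[target_assay])
    return RQMatrix(rq, f"reference_gene({reference_assay})")


def tumor_correcting_factors(
    ct: CtMatrix, reference_assay: str
) -> tuple[CtMatrix, CorrectionFactors]:
    """Per-tumor additive corrections F anchored on a stable reference gene.

    F_j = grand-mean Ct of the reference − its Ct in tumor j; every Ct of
    tumor j is shifted by F_j, so the reference gene's corrected Ct equals the
    grand mean in every tumor.  The reference must be detected everywhere —
    otherwise the normalizer is unusable and the offending tumors are named.
    """
    if reference_assay not in ct.assays:
        raise ParameterError(f"reference assay {reference_assay!r} not in matrix")
    ref = ct.values.loc[reference_assay]
    dead = [s for s in ct.samples if np.isnan(ref[s])]
    if dead:
        raise NormalizationError(
            f"reference {reference_assay!r} not detected in tumors {dead}; "
            "cannot compute correcting factors"
        )
    grand = float(ref.mean())
    f = grand - ref
    out = ct.copy()
    out.values = out.values.add(f, axis=1)
    factors = CorrectionFactors(
        kind="tumor_reference",
        offsets=f,
        reference=reference_assay,
        grand_mean=grand,
    )
    return out, factors


def _geomean(values: np.ndarray) -> float:
    return float(np.exp2(np.mean(np.log2(values))))


def fold_vs_baseline_group(
    rq: RQMatrix, groups: pd.Series, baseline_group: str, center: str = "geometric"
) -> RQMatrix:
    """Fold differences relative to a baseline sample group.

    fold = rq / center(rq over baseline-group samples), per assay.  The
    geometric mean is the default center (folds are ratios); an arithmetic
    mean is offered for sensitivity checks.  Assays with no present baseline
    value are fully masked.  The baseline group's own geometric-mean fold is 1
    by construction.
    """
    if center not in ("geometric", "arithmetic"):
        raise ParameterError(f"unknown center {center!r}")
    base_samples = [s for s in rq.rq.columns if groups.get(s) == baseline_group]
    if not base_samples:
        raise ParameterError(f"no samples in baseline group {baseline_group!r}")
    folds = pd.DataFrame(np.nan, index=rq.rq.index, columns=rq.rq.columns)
    for a in rq.rq.index:
        base = rq.rq.loc[a, base_samples].dropna().to_numpy()
        if base.size == 0:
            continue  # masked row: empty baseline for this assay
        c = _geomean(base) if center == "geometric" else float(np.mean(base))
        folds.loc[a] = rq.rq.loc[a] / c
    return RQMatrix(folds, f"baseline_group({baseline_group})", meta={"center": center})


# ---------------------------------------------------------------------------
# geNorm-style reference-gene stability


def _as_log2_expression(expr: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Convert candidate-gene data to log2 expression.

    ``scale="ct"``: expression halves per extra cycle, so log2 expression is
    −Ct (constant offsets cancel in all pairwise ratios).  ``"linear"``: take
    log2.  ``"log2"``: already there.
    """
    if scale == "ct":
        return -expr
    if scale == "linear":
        if (expr.to_numpy() <= 0).any():
            raise ParameterError("linear expression must be positive")
        return np.log2(expr)
    if scale == "log2":
        return expr
    raise ParameterError(f"unknown scale {scale!r}")


def _m_values(x: pd.DataFrame) -> pd.Series:
    """M per gene: mean over partners of SD across samples of pairwise log-ratio."""
    genes = list(x.index)
    arr = x.to_numpy()
    m = {}
    for i, g in enumerate(genes):
        sds = [
            float(np.std(arr[i] - arr[k], ddof=1))
            for k in range(len(genes))
            if k != i
        ]
        m[g] = float(np.mean(sds))
    return pd.Series(m)


def genorm_stability(
    expr: pd.DataFrame, scale: str = "ct", iterate: bool = True
) -> StabilityRanking:
    """Rank candidate reference genes by expression stability (geNorm M).

    Parameters
    ----------
    expr
        Candidate genes × samples, no masked cells (impute or drop genes
        first; non-detects cannot enter ratio statistics).
    scale
        ``"ct"`` (default), ``"linear"`` or ``"log2"``; see notes in the
        module docstring.
    iterate
        Also perform worst-first iterative exclusion down to two genes and
        record the exclusion order and pairwise-variation series V(n/n+1).

    Requires at least 3 genes and 3 samples.
    """
    if expr.shape[0] < 3 or expr.shape[1] < 3:
        raise ParameterError("need >= 3 candidate genes and >= 3 samples")
    if expr.isna().to_numpy().any():
        raise ParameterError(
            "masked cells among candidate genes: impute or remove those genes first"
        )
    x = _as_log2_expression(expr.astype(float), scale)

    m_full = _m_values(x)
    # ascending by M, ties broken lexicographically by assay id
    ranking = sorted(m_full.index, key=lambda g: (m_full[g], g))
    m_sorted = m_full.loc[ranking]

    exclusion: list[str] = []
    pairwise = None
    if iterate:
        remaining = list(x.index)
        while len(remaining) > 2:
            m_cur = _m_values(x.loc[remaining])
            worst = max(remaining, key=lambda g: (m_cur[g], g))
            exclusion.append(worst)
            remaining.remove(worst)
        # pairwise variation over the ascending ranking
        v = {}
        for n in range(2, len(ranking)):
            nf_n = x.loc[ranking[:n]].mean(axis=0)
            nf_n1 = x.loc[ranking[: n + 1]].mean(axis=0)
            v[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
        pairwise = pd.Series(v) if v else None

    return StabilityRanking(
        m=m_sorted, ranking=ranking, exclusion_order=exclusion, pairwise_variation=pairwise
    )
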