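"""End-to-end analysis pipelines composed from the stage modules.

Two ready-made analyses mirror the study designs the synthetic generators
emulate:

* :func:`cell_line_zygosity_analysis` — the low-density-card workflow on the
  five-genotype panel: 35-Ct cut-off → per-card median correction → ΔΔCt
  (mean-of-all-samples reference) → control-line nonspecific filter →
  unsupervised Euclidean clustering of the stimulated KIT lines, with
  quantitative topology read-offs against genotype.
* :func:`tumor_zygosity_analysis` — the tumor-card workflow: 37-Ct cut-off →
  median correction → ΔΔCt → supervised (ANOVA-selected) and unsupervised
  clustering by zygosity.

Both return small result dataclasses so callers can inspect every
intermediate product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .clustering_pca import Dendrogram, adjusted_rand, hierarchical_cluster, supervised_cluster
from .ct_io import CtMatrix, RQMatrix, SampleAnnotation
from .normalization import apply_ct_cutoff, card_median_correction, delta_ct, delta_delta_ct
from .results import SelectionResult
from .selection_stats import nonspecific_filter

__all__ = [
    "CellLineResult",
    "TumorResult",
    "quantify",
    "cell_line_zygosity_analysis",
    "tumor_zygosity_analysis",
]

HEMIZYGOUS = ("D6", "D54")
HETEROZYGOUS = ("WT/D6", "WT/D54")


@dataclass
class CellLineResult:
    rq: RQMatrix
    nonspecific: SelectionResult
    dendrogram: Dendrogram
    wt_samples: set
    het_samples: set
    hemi_samples: set
    wt_het_monophyletic: bool
    wt_subtree_covers_het: bool
    ari_k3: float


@dataclass
class TumorResult:
    rq: RQMatrix
    supervised: Dendrogram
    unsupervised: Dendrogram
    selection: SelectionResult
    supervised_separates_zygosity: bool
    unsupervised_separates_zygosity: bool


def quantify(
    ct: CtMatrix, cutoff: float, target: float | str = "median_of_card_medians"
) -> RQMatrix:
    """Cut-off → card-median correction → ΔΔCt with mean-of-samples reference."""
    trimmed = apply_ct_cutoff(ct, cutoff)
    corrected, _ = card_median_correction(trimmed, target=target)
    dct = delta_ct(corrected)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return delta_delta_ct(dct)


def cell_line_zygosity_analysis(
    ct: CtMatrix,
    ann: SampleAnnotation,
    cutoff: float = 35.0,
    alpha_nonspecific: float = 0.05,
    condition: str = "SCF+",
    method: str = "average",
) -> CellLineResult:
    """Quantify, filter on the control line, cluster the stimulated KIT lines.

    The empty-vector (MIGR) samples across all conditions drive the
    nonspecific filter; clustering then runs on the KIT-expressing lines in
    ``condition`` over the retained assays.  The result records whether the
    WT + heterozygous samples form a clade excluding hemizygous lines, whether
    the smallest subtree over the WT samples already covers the heterozygous
    ones, and the adjusted Rand index of a 3-cut against
    {WT+heterozygous, D6, D54}.
    """
    rq = quantify(ct, cutoff)
    table = ann.table
    migr = table.index[table["genotype"] == "MIGR"]
    sel = nonspecific_filter(rq, table.loc[migr, "condition"], alpha=alpha_nonspecific)

    keep = table.index[(table["genotype"] != "MIGR") & (table["condition"] == condition)]
    log2 = rq.log2()[list(keep)]
    assays = [a for a in sel.retained if a in log2.index]
    dend = hierarchical_cluster(log2, assays=assays, method=method)

    geno = table["genotype"]
    wt = {s for s in dend.leaves if geno[s] == "WT"}
    het = {s for s in dend.leaves if geno[s] in HETEROZYGOUS}
    hemi = {s for s in dend.leaves if geno[s] in HEMIZYGOUS}
    enclosing_wt = dend.smallest_enclosing(wt)
    merged = geno.loc[dend.leaves].map(
        lambda g: "WT+het" if g == "WT" or g in HETEROZYGOUS else g
    )
    return CellLineResult(
        rq=rq,
        nonspecific=sel,
        dendrogram=dend,
        wt_samples=wt,
        het_samples=het,
        hemi_samples=hemi,
        wt_het_monophyletic=dend.is_monophyletic(wt | het),
        wt_subtree_covers_het=(het <= enclosing_wt) and enclosing_wt.isdisjoint(hemi),
        ari_k3=adjusted_rand(dend.cut(3), merged),
    )


def tumor_zygosity_analysis(
    ct: CtMatrix,
    ann: SampleAnnotation,
    cutoff: float = 37.0,
    alpha: float = 0.05,
    assay_class: str = "miRNA",
    method: str = "average",
) -> TumorResult:
    """Quantify the tumor card and cluster by zygosity, supervised and not.

    Only assays of ``assay_class`` enter the analysis (candidate reference
    genes carried on the card are excluded).  Separation is scored as
    monophyly of the homozygous tumors.
    """
    if ct.assay_meta is not None and "assay_class" in ct.assay_meta.columns:
        keep = list(ct.assay_meta.index[ct.assay_meta["assay_class"] == assay_class])
        ct = CtMatrix(ct.values.loc[keep], ct.card_of_sample, ct.assay_meta.loc[keep])
    rq = quantify(ct, cutoff)
    zyg = ann.table["zygosity"]
    sup = supervised_cluster(rq, zyg, alpha=alpha, method=method)
    uns = hierarchical_cluster(rq.log2(), method=method)
    hom_sup = {s for s in sup.leaves if zyg[s] == "homozygous"}
    hom_uns = {s for s in uns.leaves if zyg[s] == "homozygous"}
    return TumorResult(
        rq=rq,
        supervised=sup,
        unsupervised=uns,
        selection=sup.selection,
        supervised_separates_zygosity=sup.is_monophyletic(hom_sup),
        unsupervised_separates_zygosity=uns.is_monophyletic(hom_uns),
    )
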