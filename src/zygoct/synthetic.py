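"""Synthetic Ct and intensity data with planted, scored ground truth.

The generators emulate the statistical structure of a KIT-zygosity expression
study so every pipeline stage can be tested against known truth without any
download:

* a five-genotype NIH3T3-like cell-line panel — wild-type KIT (WT), two
  hemizygous exon-11 deletions (D6 = del557-558, D54 = del564-581) and the
  heterozygous combinations WT/D6 and WT/D54 — plus an empty-vector control
  line (MIGR) cultured in three conditions (SCF+, SCF-, imatinib), profiled
  on a 94-gene qPCR card;
* a tumor cohort of 6 homozygous and 13 heterozygous exon-11-mutated GISTs on
  a 384-assay miRNA card, with a stable (ETV6-like) and an unstable
  (18S-like) candidate reference gene;
* high-density arrays with 100 negative-control probes, per-array scale
  factors and planted fold-change genes.

Ct values are built mechanistically: baseline − expression effect + card
offset + Gaussian noise, with readings beyond the instrument cut-off emitted
as non-detects — so cut-off handling is exercised the way a real instrument
produces missingness (an independent-dropout option exists for robustness
checks).  The default presets encode the qualitative claims the designs are
meant to reproduce — heterozygous profiles sit close to WT (het effect =
0.15 × hemizygous effect), D6 and D54 differ on disjoint assay subsets — as
effect-size *ratios*; the absolute sizes are reconstructions, not
measurements, and are documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_selection import IntensityArray
from .ct_io import CtMatrix, SampleAnnotation
from .errors import ParameterError

__all__ = [
    "CellLinePanelDesign",
    "TumorCohortDesign",
    "HighDensityDesign",
    "simulate_cell_line_panel",
    "simulate_tumor_cohort",
    "simulate_high_density",
]

_CONDITION_CODE = {"SCF+": "SCFp", "SCF-": "SCFm", "imatinib": "IM"}


def _sample_id(genotype: str, condition: str, rep: int) -> str:
    return f"{genotype.replace('/', '.')}_{_CONDITION_CODE[condition]}_{rep}"


@dataclass
class CellLinePanelDesign:
    """Design of the synthetic five-genotype cell-line panel.

    Replicate structure follows the study layout: in SCF+ three complete
    replicates of WT, D6 and D54 and two of WT/D6 and WT/D54; two replicates
    of every line under imatinib; two MIGR control replicates in each of the
    three conditions.  Effects are log2-expression shifts in cycles: the
    hemizygous signature is split into a shared core and D6-/D54-specific
    subsets, heterozygous lines express ``het_ratio`` of their hemizygous
    partner's effect, and KIT-responsive assays separate every KIT line from
    the empty-vector control (attenuated under imatinib).  Nonspecific assays
    shift with culture condition in *all* lines (MIGR included) and carry
    extra sample-to-sample jitter — exactly what the control-line ANOVA
    filter exists to remove.
    """

    n_assays: int = 94
    include_myh9: bool = True
    scf_replicates: dict = field(
        default_factory=lambda: {"WT": 3, "D6": 3, "D54": 3, "WT/D6": 2, "WT/D54": 2}
    )
    imatinib_replicates: int = 2
    include_imatinib: bool = True
    migr_replicates: int = 2
    n_shared_signature: int = 16
    n_d6_specific: int = 12
    n_d54_specific: int = 12
    hemi_effect: float = 1.5
    het_ratio: float = 0.15
    n_kit_responsive: int = 20
    kit_effect: float = 1.0
    imatinib_attenuation: float = 0.3
    response_amplitude_sd: float = 0.0
    n_nonspecific: int = 10
    nonspecific_condition_effect: float = 1.5
    nonspecific_extra_sd: float = 0.8
    n_high_baseline: int = 4
    baseline_ct_range: tuple = (22.0, 32.0)
    high_baseline_ct: float = 34.0
    samples_per_card: int = 1
    card_offset_sd: float = 0.5
    noise_sd: float = 0.3
    cutoff: float = 35.0
    heavy_tailed: bool = False
    independent_dropout: float = 0.0


@dataclass
class TumorCohortDesign:
    """Design of the synthetic GIST cohort (homozygous vs heterozygous).

    Six homozygous and thirteen heterozygous exon-11-mutated tumors on a
    384-assay miRNA card, with a planted 13-assay zygosity signature (1.5
    cycles by default).  The default noise of 0.8 cycles lumps technical
    noise with inter-tumor biological heterogeneity — archival (FFPE) tumor
    material is far more variable than replicate cell cultures — which is
    what makes the planted signature recoverable by supervised selection yet
    invisible to unsupervised clustering over the full card.  Two candidate
    reference assays are appended: a stable ETV6-like gene (between-tumor SD
    0.2 cycles) and an unstable 18S-like gene (SD 2 cycles) to exercise
    normalizer choice.
    """

    n_assays: int = 384
    n_homozygous: int = 6
    n_heterozygous: int = 13
    n_signature: int = 13
    signature_effect: float = 1.5
    noise_sd: float = 0.8
    baseline_ct_range: tuple = (24.0, 34.0)
    n_high_baseline: int = 8
    high_baseline_ct: float = 36.5
    card_offset_sd: float = 0.5
    cutoff: float = 37.0
    stable_reference: str = "ETV6"
    stable_reference_ct: float = 25.0
    stable_reference_sd: float = 0.2
    unstable_reference: str = "RN18S"
    unstable_reference_ct: float = 14.0
    unstable_reference_sd: float = 2.0
    heavy_tailed: bool = False
    independent_dropout: float = 0.0


@dataclass
class HighDensityDesign:
    """Design of the synthetic high-density intensity arrays.

    Log-normal target intensities with a per-array scale factor (what median
    normalization must undo), 100 negative-control probes at low intensity,
    and planted between-group fold changes: strong (2.5×) genes the selection
    rule must recover and weak (1.2×) genes it must reject.
    """

    n_target_probes: int = 500
    n_negative: int = 100
    groups: tuple = (("A", 3), ("B", 3))
    n_strong: int = 20
    strong_fold: float = 2.5
    n_weak: int = 20
    weak_fold: float = 1.2
    planted_log2_baseline: float = 1.5
    baseline_log2_sd: float = 1.2
    noise_cv: float = 0.05
    array_scale_sd: float = 0.3
    negative_mean: float = 0.05
    negative_cv: float = 0.2


# ---------------------------------------------------------------------------


def _noise(rng: np.random.Generator, sd: float, size, heavy_tailed: bool) -> np.ndarray:
    if heavy_tailed:
        # t(3) scaled to unit variance, then to sd
        return rng.standard_t(3, size=size) / np.sqrt(3.0) * sd
    return rng.normal(0.0, sd, size=size)


def _emit_ct(
    rng: np.random.Generator,
    clean: pd.DataFrame,
    cutoff: float,
    independent_dropout: float,
) -> pd.DataFrame:
    """Apply mechanistic (and optional independent) non-detection."""
    vals = clean.where(clean <= cutoff)
    vals = vals.clip(lower=0.0)
    if independent_dropout > 0:
        drop = rng.random(vals.shape) < independent_dropout
        vals = vals.mask(drop)
    return vals


def _disjoint_subsets(rng: np.random.Generator, pool: list[str], sizes: list[int]):
    total = sum(sizes)
    if total > len(pool):
        raise ParameterError(
            f"effect subsets need {total} assays but only {len(pool)} available"
        )
    chosen = list(rng.choice(pool, size=total, replace=False))
    out = []
    start = 0
    for n in sizes:
        out.append(chosen[start : start + n])
        start += n
    return out


def simulate_cell_line_panel(
    design: CellLinePanelDesign | None = None, seed: int = 0
) -> tuple[CtMatrix, SampleAnnotation, dict]:
    """Simulate the five-genotype cell-line panel plus empty-vector controls.

    Returns the Ct matrix (with mechanistic non-detects), a sample annotation
    (genotype, condition, replicate) and a ground-truth dict recording which
    assays carry which planted effects.
    """
    d = design or CellLinePanelDesign()
    for label, n in d.scf_replicates.items():
        if n <= 0:
            raise ParameterError(f"group {label!r} has no samples")
    rng = np.random.default_rng(seed)

    assays = [f"G{i + 1:03d}" for i in range(d.n_assays)]
    baseline = pd.Series(
        rng.uniform(*d.baseline_ct_range, size=d.n_assays), index=assays
    )
    if d.n_high_baseline:
        high = list(rng.choice(assays, size=d.n_high_baseline, replace=False))
        baseline[high] = d.high_baseline_ct
    shared, d6_spec, d54_spec, kit_resp, nonspec = _disjoint_subsets(
        rng,
        assays,
        [
            d.n_shared_signature,
            d.n_d6_specific,
            d.n_d54_specific,
            d.n_kit_responsive,
            d.n_nonspecific,
        ],
    )

    # signed per-assay effect directions (up or down regulation)
    sign = pd.Series(rng.choice([-1.0, 1.0], size=d.n_assays), index=assays)

    def genotype_effect(genotype: str) -> pd.Series:
        eff = pd.Series(0.0, index=assays)
        if genotype == "MIGR":
            return eff
        eff[kit_resp] += d.kit_effect * sign[kit_resp]
        if genotype in ("D6", "WT/D6"):
            scale = 1.0 if genotype == "D6" else d.het_ratio
            eff[shared] += scale * d.hemi_effect * sign[shared]
            eff[d6_spec] += scale * d.hemi_effect * sign[d6_spec]
        if genotype in ("D54", "WT/D54"):
            scale = 1.0 if genotype == "D54" else d.het_ratio
            eff[shared] += scale * d.hemi_effect * sign[shared]
            eff[d54_spec] += scale * d.hemi_effect * sign[d54_spec]
        return eff

    # condition shifts on nonspecific assays, shared by every line
    cond_shift = {
        c: pd.Series(0.0, index=assays) for c in ("SCF+", "SCF-", "imatinib")
    }
    for a in nonspec:
        cond_shift["SCF-"][a] = d.nonspecific_condition_effect * rng.choice([-1.0, 1.0])
        cond_shift["imatinib"][a] = d.nonspecific_condition_effect * rng.choice(
            [-1.0, 1.0]
        )

    plan: list[tuple[str, str, int]] = []
    for g, n in d.scf_replicates.items():
        plan += [(g, "SCF+", r) for r in range(1, n + 1)]
    if d.include_imatinib:
        for g in d.scf_replicates:
            plan += [(g, "imatinib", r) for r in range(1, d.imatinib_replicates + 1)]
    for c in ("SCF+", "SCF-", "imatinib"):
        plan += [("MIGR", c, r) for r in range(1, d.migr_replicates + 1)]

    columns = {}
    ann_rows = []
    cards = {}
    card_offsets: dict[str, float] = {}
    for idx, (genotype, condition, rep) in enumerate(plan):
        sid = _sample_id(genotype, condition, rep)
        card = f"card{idx // d.samples_per_card + 1:03d}"
        if card not in card_offsets:
            card_offsets[card] = rng.normal(0.0, d.card_offset_sd)
        eff = genotype_effect(genotype)
        if condition == "imatinib":
            # kinase inhibition pulls KIT-driven expression back toward control
            eff = eff.copy()
            eff[kit_resp] *= d.imatinib_attenuation
        if d.response_amplitude_sd and genotype != "MIGR":
            # KIT-pathway response strength fluctuates between culture
            # replicates; scales the whole planted effect vector per sample
            eff = eff * max(rng.normal(1.0, d.response_amplitude_sd), 0.0)
        ct = (
            baseline
            - eff
            + cond_shift[condition]
            + card_offsets[card]
            + _noise(rng, d.noise_sd, d.n_assays, d.heavy_tailed)
        )
        extra = pd.Series(0.0, index=assays)
        extra[nonspec] = _noise(rng, d.nonspecific_extra_sd, len(nonspec), d.heavy_tailed)
        columns[sid] = ct + extra
        cards[sid] = card
        ann_rows.append(
            {"sample": sid, "genotype": genotype, "condition": condition, "replicate": rep}
        )

    values = pd.DataFrame(columns).loc[assays]
    meta = pd.DataFrame({"assay_class": ["mRNA"] * d.n_assays}, index=assays)
    if d.include_myh9:
        # the card's nominally stable gene; in practice only moderately stable
        myh9 = 24.0 + pd.Series(
            {s: card_offsets[cards[s]] for s in values.columns}
        ) + _noise(rng, 0.8, values.shape[1], d.heavy_tailed)
        values.loc["MYH9"] = myh9
        meta.loc["MYH9"] = "control"
    values = _emit_ct(rng, values, d.cutoff, d.independent_dropout)

    ct = CtMatrix(values, pd.Series(cards), meta)
    ann = SampleAnnotation(pd.DataFrame(ann_rows).set_index("sample"))
    truth = {
        "shared_signature": shared,
        "d6_specific": d6_spec,
        "d54_specific": d54_spec,
        "kit_responsive": kit_resp,
        "nonspecific": nonspec,
        "hemi_effect": d.hemi_effect,
        "het_ratio": d.het_ratio,
        "effect_sign": sign.to_dict(),
        "baseline_ct": baseline.to_dict(),
        "card_offsets": card_offsets,
        "seed": seed,
    }
    return ct, ann, truth


def simulate_tumor_cohort(
    design: TumorCohortDesign | None = None, seed: int = 0
) -> tuple[CtMatrix, SampleAnnotation, dict]:
    """Simulate the homozygous/heterozygous GIST cohort on a miRNA card.

    Emits exactly ``n_homozygous + n_heterozygous`` tumors (6 + 13 under the
    defaults), one card per tumor, with a planted zygosity signature and the
    stable/unstable reference pair.
    """
    d = design or TumorCohortDesign()
    if d.n_homozygous <= 0 or d.n_heterozygous <= 0:
        raise ParameterError("both zygosity groups need at least one tumor")
    rng = np.random.default_rng(seed)

    assays = [f"miR{i + 1:03d}" for i in range(d.n_assays)]
    baseline = pd.Series(
        rng.uniform(*d.baseline_ct_range, size=d.n_assays), index=assays
    )
    if d.n_high_baseline:
        high = list(rng.choice(assays, size=d.n_high_baseline, replace=False))
        baseline[high] = d.high_baseline_ct
    (signature,) = _disjoint_subsets(rng, assays, [d.n_signature])
    sig_sign = pd.Series(rng.choice([-1.0, 1.0], size=len(signature)), index=signature)

    tumors = [f"T{i + 1:02d}" for i in range(d.n_homozygous + d.n_heterozygous)]
    zyg = ["homozygous"] * d.n_homozygous + ["heterozygous"] * d.n_heterozygous
    # shuffle tumor order so ids carry no grouping information
    order = rng.permutation(len(tumors))
    zyg = [zyg[i] for i in order]

    columns = {}
    cards = {}
    card_offsets = {}
    for t, z in zip(tumors, zyg):
        card = f"card_{t}"
        off = rng.normal(0.0, d.card_offset_sd)
        card_offsets[card] = off
        eff = pd.Series(0.0, index=assays)
        if z == "homozygous":
            eff[signature] = d.signature_effect * sig_sign
        ct = baseline - eff + off + _noise(rng, d.noise_sd, d.n_assays, d.heavy_tailed)
        # candidate reference genes (not part of the miRNA panel)
        refs = pd.Series(
            {
                d.stable_reference: d.stable_reference_ct
                + off
                + rng.normal(0.0, d.stable_reference_sd),
                d.unstable_reference: d.unstable_reference_ct
                + off
                + rng.normal(0.0, d.unstable_reference_sd),
            }
        )
        columns[t] = pd.concat([ct, refs])
        cards[t] = card

    values = pd.DataFrame(columns)
    meta = pd.DataFrame(
        {
            "assay_class": ["miRNA"] * d.n_assays
            + ["control", "control"]
        },
        index=assays + [d.stable_reference, d.unstable_reference],
    )
    values = _emit_ct(rng, values, d.cutoff, d.independent_dropout)

    ct = CtMatrix(values, pd.Series(cards), meta)
    ann = SampleAnnotation(
        pd.DataFrame(
            {
                "mutation_class": ["KIT_ex11"] * len(tumors),
                "zygosity": zyg,
            },
            index=pd.Index(tumors, name="sample"),
        )
    )
    truth = {
        "signature": signature,
        "signature_effect": d.signature_effect,
        "signature_sign": sig_sign.to_dict(),
        "zygosity": dict(zip(tumors, zyg)),
        "stable_reference": d.stable_reference,
        "unstable_reference": d.unstable_reference,
        "card_offsets": card_offsets,
        "seed": seed,
    }
    return ct, ann, truth


def simulate_high_density(
    design: HighDensityDesign | None = None, seed: int = 0
) -> tuple[IntensityArray, pd.Series, dict]:
    """Simulate high-density intensity arrays with planted fold changes.

    Returns the raw :class:`IntensityArray` (call
    :func:`~zygoct.array_selection.median_normalize_array` and
    :func:`~zygoct.array_selection.detection_threshold` on it), a sample →
    group Series, and the ground truth of planted strong/weak genes.
    """
    d = design or HighDensityDesign()
    rng = np.random.default_rng(seed)

    targets = [f"P{i + 1:04d}" for i in range(d.n_target_probes)]
    negatives = [f"NEG{i + 1:03d}" for i in range(d.n_negative)]
    strong, weak = _disjoint_subsets(rng, targets, [d.n_strong, d.n_weak])

    base_log2 = pd.Series(
        rng.normal(0.0, d.baseline_log2_sd, size=d.n_target_probes), index=targets
    )
    base_log2[strong] = d.planted_log2_baseline
    base_log2[weak] = d.planted_log2_baseline

    arrays = []
    groups = {}
    for label, n in d.groups:
        for r in range(1, n + 1):
            aid = f"{label}{r}"
            arrays.append(aid)
            groups[label, aid] = label
    group_of = pd.Series({aid: lab for (lab, aid), lab in groups.items()})

    raw = pd.DataFrame(index=targets + negatives, columns=arrays, dtype=float)
    second_group = d.groups[1][0]
    for aid in arrays:
        scale = float(np.exp(rng.normal(0.0, d.array_scale_sd)))
        fold = pd.Series(1.0, index=targets)
        if group_of[aid] == second_group:
            fold[strong] = d.strong_fold
            fold[weak] = d.weak_fold
        tgt = (
            np.exp2(base_log2)
            * fold
            * np.exp(rng.normal(0.0, d.noise_cv, size=d.n_target_probes))
            * scale
        )
        neg = (
            d.negative_mean
            * np.exp(rng.normal(0.0, d.negative_cv, size=d.n_negative))
            * scale
        )
        raw[aid] = np.concatenate([tgt.to_numpy(), neg])

    probe_class = pd.Series(
        ["target"] * len(targets) + ["negative_control"] * len(negatives),
        index=targets + negatives,
    )
    arr = IntensityArray(raw=raw, probe_class=probe_class)
    truth = {
        "strong": strong,
        "weak": weak,
        "strong_fold": d.strong_fold,
        "weak_fold": d.weak_fold,
        "seed": seed,
    }
    return arr, group_of, truth
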