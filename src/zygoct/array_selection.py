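"""High-density array stage: normalization, detection calls, gene selection.

Single-channel oligonucleotide arrays report a raw hybridization intensity
per probe.  Cross-array comparison follows the scanner software's convention:
each array is divided by its median so the median normalized intensity is 1,
and a detection threshold is derived from the ~100 negative-control probes
spotted on each array (mean + k·SD of their normalized intensities; k = 3 by
default).  Probes below the threshold are called *absent*; a narrow band just
above it is *marginal*, everything else *present*.

Candidate genes for the follow-up qPCR card are then picked by a pairwise
fold-change rule: for every cross-group sample pair the symmetric ratio
max(a/b, b/a) is computed, and a gene is retained when the average over pairs
is at least 2, its normalized intensity exceeds 1.3 in at least one sample
(the usual amplitude floor for these arrays), and it is called
present/marginal in all samples of at least one compared group.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateArrayError, ParameterError
from .results import SelectionResult

__all__ = [
    "IntensityArray",
    "median_normalize_array",
    "detection_threshold",
    "select_differential_genes",
]

CALLS = ("present", "marginal", "absent")


@dataclass
class IntensityArray:
    """Probe intensities per array with control annotation and detection calls.

    ``raw`` is probes × arrays (non-negative).  ``probe_class`` labels each
    probe ``target`` or ``negative_control``.  ``normalized``, ``thresholds``
    (one per array) and ``calls`` are filled by
    :func:`median_normalize_array` and :func:`detection_threshold`.
    """

    raw: pd.DataFrame
    probe_class: pd.Series
    normalized: pd.DataFrame | None = None
    thresholds: pd.Series | None = None
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise ParameterError("raw intensities must be non-negative")
        missing = [p for p in self.raw.index if p not in self.probe_class.index]
        if missing:
            raise ParameterError(f"probes without a class label: {missing[:5]}...")

    @property
    def arrays(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def target_probes(self) -> list[str]:
        return [p for p in self.raw.index if self.probe_class[p] == "target"]

    @property
    def negative_probes(self) -> list[str]:
        return [p for p in self.raw.index if self.probe_class[p] == "negative_control"]


def median_normalize_array(arr: IntensityArray) -> IntensityArray:
    """Divide each array by its median intensity (over all probes).

    After normalization each array's median normalized intensity is 1, making
    arrays scanned at different overall brightness comparable.  An array whose
    median is not positive has no usable signal and is rejected.
    """
    med = arr.raw.median(axis=0)
    dead = [a for a in arr.arrays if not med[a] > 0]
    if dead:
        raise DegenerateArrayError(f"arrays with non-positive median intensity: {dead}")
    normalized = arr.raw.div(med, axis=1)
    return replace(arr, normalized=normalized)


def detection_threshold(
    arr: IntensityArray, k: float = 3.0, marginal_factor: float = 1.2
) -> IntensityArray:
    """Derive per-array detection thresholds from the negative controls.

    threshold = mean + k·SD of the negative-control normalized intensities of
    that array.  Calls: ``absent`` strictly below the threshold, ``marginal``
    in [threshold, marginal_factor·threshold), ``present`` at or above
    marginal_factor·threshold.  A probe sitting exactly at the threshold is
    therefore never absent.
    """
    if arr.normalized is None:
        raise ParameterError("normalize arrays before deriving detection thresholds")
    negs = arr.negative_probes
    if len(negs) < 2:
        raise ParameterError("need at least 2 negative-control probes")
    neg = arr.normalized.loc[negs]
    thresholds = neg.mean(axis=0) + k * neg.std(axis=0, ddof=1)
    norm = arr.normalized.to_numpy()
    thr = thresholds.to_numpy()[None, :]
    calls = np.where(
        norm < thr, "absent", np.where(norm < marginal_factor * thr, "marginal", "present")
    )
    calls = pd.DataFrame(calls, index=arr.normalized.index, columns=arr.arrays)
    return replace(arr, thresholds=thresholds, calls=calls)


def select_differential_genes(
    arr: IntensityArray,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_threshold: float = 2.0,
    amplitude: float = 1.3,
    floor: float = 0.01,
    call_rule: str = "either_group",
) -> SelectionResult:
    """Pairwise fold-change selection between two sample groups.

    A target gene is retained iff all of:

    1. the average over all cross-group sample pairs of max(a/b, b/a)
       is >= ``fc_threshold`` (symmetric in group order);
    2. its normalized intensity exceeds ``amplitude`` in at least one of the
       compared samples;
    3. it is called present or marginal in all samples of at least one group
       (``call_rule="either_group"``, the default reading of "expressed
       somewhere above background") or in all compared samples
       (``call_rule="all"``).

    Zero intensities are clamped to ``floor`` before forming ratios (and the
    gene flagged), since a literal zero would make the fold change infinite.
    """
    if not group_a or not group_b:
        raise ParameterError("both groups must be non-empty")
    if call_rule not in ("either_group", "all"):
        raise ParameterError(f"unknown call_rule {call_rule!r}")
    if arr.normalized is None or arr.calls is None:
        raise ParameterError("arrays must be normalized and called before selection")
    samples = list(group_a) + list(group_b)
    unknown = [s for s in samples if s not in arr.arrays]
    if unknown:
        raise ParameterError(f"unknown arrays: {unknown}")

    rows = []
    retained = []
    for g in arr.target_probes:
        vals = arr.normalized.loc[g]
        floored = False
        ratios = []
        for a, b in product(group_a, group_b):
            va, vb = vals[a], vals[b]
            if va < floor or vb < floor:
                floored = True
                va, vb = max(va, floor), max(vb, floor)
            ratios.append(max(va / vb, vb / va))
        avg_fc = float(np.mean(ratios))
        amp_ok = bool((vals[samples] > amplitude).any())
        calls = arr.calls.loc[g]
        expressed = calls.isin(("present", "marginal"))
        if call_rule == "either_group":
            call_ok = bool(expressed[list(group_a)].all() or expressed[list(group_b)].all())
        else:
            call_ok = bool(expressed[samples].all())
        keep = avg_fc >= fc_threshold and amp_ok and call_ok
        if keep:
            retained.append(g)
        rows.append(
            {
                "assay": g,
                "avg_fold_change": avg_fc,
                "max_intensity": float(vals[samples].max()),
                "amplitude_ok": amp_ok,
                "call_ok": call_ok,
                "floored": floored,
                "retained": keep,
            }
        )
    stats = pd.DataFrame(rows).set_index("assay")
    criteria = {
        "fc_threshold": fc_threshold,
        "amplitude_threshold": amplitude,
        "call_rule": call_rule,
        "floor": floor,
        "group_a": list(group_a),
        "group_b": list(group_b),
    }
    return SelectionResult(retained=retained, stats=stats, criteria=criteria)
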