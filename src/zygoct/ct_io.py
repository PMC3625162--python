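"""Readers, writers and shared containers for threshold-cycle (Ct) data.

Low-density-array (TLDA) instruments export per-well threshold cycles as
delimited text, with reactions that never crossed the fluorescence threshold
reported as ``Undetermined``.  Every downstream stage of this package works on
:class:`CtMatrix` — an assay × sample table of cycles with an explicit
non-detect mask and a sample → card assignment (card identity drives the
per-card "virtual housekeeping" normalization) — or on the relative-quantity
matrix :class:`RQMatrix` it produces.

Two text dialects are supported:

``long``
    One row per reaction with columns ``sample, card, assay, ct`` (optionally
    ``assay_class``).  This is the shape of a melted SDS/RQ-Manager export.
``wide``
    Assay rows × sample columns, with a mandatory sidecar mapping each sample
    to its card (card identity cannot be inferred from a wide table).

Non-detects are carried as NaN internally; they are masked out of — never
imputed into — every downstream statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AnnotationError,
    CtParseError,
    IntegrityError,
    ParameterError,
)

#: Spellings mapped to non-detect on input (case-insensitive, after stripping).
NON_DETECT_TOKENS = frozenset({"undetermined", "na", ""})

#: Token written for non-detect cells in long-format output.
NON_DETECT_OUT = "Undetermined"

CT_MIN = 0.0
CT_MAX = 50.0

# Closed label vocabularies for sample annotations.
GENOTYPES = ("MIGR", "WT", "D6", "D54", "WT/D6", "WT/D54")
CONDITIONS = ("SCF+", "SCF-", "imatinib")
MUTATION_CLASSES = ("WT", "KIT_ex9", "KIT_ex11", "PDGFRA_ex18", "PDGFRA_ex10_poly")
ZYGOSITY = ("heterozygous", "homozygous", "unknown")
ASSAY_CLASSES = ("mRNA", "miRNA", "control")


@dataclass
class CtMatrix:
    """Threshold-cycle values per assay × sample with non-detect mask.

    Parameters
    ----------
    values
        Float DataFrame, assays as rows, samples as columns.  NaN encodes a
        non-detect; every finite value is a cycle count in ``[0, 50]``.
    card_of_sample
        Series mapping every sample (column of ``values``) to exactly one
        card identifier.
    assay_meta
        Optional per-assay metadata indexed like ``values`` with columns
        ``target`` and ``assay_class`` (one of ``mRNA``, ``miRNA``,
        ``control``).
    """

    values: pd.DataFrame
    card_of_sample: pd.Series
    assay_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.card_of_sample = pd.Series(self.card_of_sample)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def assays(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cards(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.card_of_sample:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def detect_mask(self) -> pd.DataFrame:
        """Boolean DataFrame; False marks a non-detect cell."""
        return self.values.notna()

    def samples_of_card(self, card: str) -> list[str]:
        return [s for s in self.samples if self.card_of_sample[s] == card]

    def n_detected(self) -> int:
        return int(self.detect_mask.values.sum())

    def copy(self) -> "CtMatrix":
        meta = None if self.assay_meta is None else self.assay_meta.copy()
        return CtMatrix(self.values.copy(), self.card_of_sample.copy(), meta)

    def validate(self) -> None:
        """Enforce the data-model invariants; raise on violation."""
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise IntegrityError(f"duplicate assay ids: {list(dups)}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise IntegrityError(f"duplicate sample ids: {list(dups)}")
        missing = [s for s in self.samples if s not in self.card_of_sample.index]
        if missing:
            raise AnnotationError(f"samples without a card assignment: {missing}")
        vals = self.values.to_numpy()
        present = ~np.isnan(vals)
        if np.any(~np.isfinite(vals[present])):
            raise CtParseError("non-finite Ct value in matrix")
        bad = present & ((vals < CT_MIN) | (vals > CT_MAX))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CtParseError(
                f"Ct out of range [{CT_MIN}, {CT_MAX}] at "
                f"({self.assays[i]}, {self.samples[j]}): {vals[i, j]}"
            )
        if self.assay_meta is not None:
            unknown = set(self.assay_meta.get("assay_class", pd.Series(dtype=object)).dropna()) - set(
                ASSAY_CLASSES
            )
            if unknown:
                raise AnnotationError(f"unknown assay classes: {sorted(unknown)}")


@dataclass
class SampleAnnotation:
    """Per-sample labels: genotype/condition (cell lines) or mutation/zygosity (tumors).

    The ``table`` is indexed by sample id.  Recognised columns are checked
    against closed vocabularies; any other column (clinical factors such as
    age, tumor size, mitoses) is carried through untouched.
    """

    table: pd.DataFrame

    _VOCAB = {
        "genotype": GENOTYPES,
        "condition": CONDITIONS,
        "mutation_class": MUTATION_CLASSES,
        "zygosity": ZYGOSITY,
    }

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.table.index.has_duplicates:
            raise IntegrityError("duplicate sample ids in annotation")
        for col, vocab in self._VOCAB.items():
            if col in self.table.columns:
                bad = set(self.table[col].dropna()) - set(vocab)
                if bad:
                    raise AnnotationError(f"unknown {col} labels: {sorted(bad)}")
        if "replicate" in self.table.columns:
            reps = pd.to_numeric(self.table["replicate"], errors="coerce")
            if (reps.dropna() < 1).any():
                raise AnnotationError("replicate index must be >= 1")

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def labels(self, column: str) -> pd.Series:
        if column not in self.table.columns:
            raise AnnotationError(f"annotation has no column {column!r}")
        return self.table[column]

    def matches(self, ct: CtMatrix) -> bool:
        """True iff annotation samples equal the matrix columns exactly."""
        return set(self.samples) == set(ct.samples)


@dataclass
class RQMatrix:
    """Relative quantities (positive reals) per assay × sample.

    ``reference_mode`` records the normalization convention: the per-card
    median ("virtual housekeeping gene"), a named reference gene, or a
    baseline sample group.  NaN marks a missing (non-detected) cell.
    """

    rq: pd.DataFrame
    reference_mode: str = "virtual_housekeeping"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rq = self.rq.astype(float)
        vals = self.rq.to_numpy()
        present = ~np.isnan(vals)
        if np.any(vals[present] <= 0):
            raise ParameterError("relative quantities must be strictly positive")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.rq.isna()

    def log2(self) -> pd.DataFrame:
        """log2 relative quantities (= −ΔΔCt); the scale used for statistics."""
        return np.log2(self.rq)


# ---------------------------------------------------------------------------
# parsing helpers


def _parse_ct(token: str, decimal: str, where: str) -> float:
    text = token.strip()
    if text.lower() in NON_DETECT_TOKENS:
        return math.nan
    if decimal == ",":
        if "." in text:
            raise CtParseError(f"unexpected '.' in decimal-comma value {token!r} at {where}")
        text = text.replace(",", ".")
    try:
        return float(text)
    except ValueError:
        raise CtParseError(f"cannot parse Ct value {token!r} at {where}") from None


def _read_card_map(card_map, sep: str) -> pd.Series:
    if isinstance(card_map, pd.Series):
        return card_map.astype(str)
    if isinstance(card_map, Mapping):
        return pd.Series(card_map, dtype=str)
    table = pd.read_csv(card_map, sep=sep, dtype=str)
    cols = [c.lower() for c in table.columns]
    table.columns = cols
    if not {"sample", "card"}.issubset(cols):
        raise IntegrityError("card map needs columns 'sample' and 'card'")
    if table["sample"].duplicated().any():
        raise IntegrityError("duplicate samples in card map")
    return table.set_index("sample")["card"]


def read_ct_table(
    path,
    dialect: str = "long",
    sep: str = "\t",
    decimal: str = ".",
    card_map=None,
) -> CtMatrix:
    """Read a Ct table from delimited text.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"long"`` (columns ``sample, card, assay, ct`` and optionally
        ``assay_class``) or ``"wide"`` (assay rows × sample columns, needing a
        ``card_map`` sidecar).
    sep
        Field delimiter; tab by default, use ``","`` for CSV.
    decimal
        ``"."`` (default) or ``","``.  The decimal-comma dialect is never
        auto-detected: silent locale guessing corrupts Ct values.
    card_map
        Required for the wide dialect: a path to a two-column
        ``sample<sep>card`` file, a mapping, or a Series.

    Raises
    ------
    CtParseError
        Malformed numeric cell (the message names the offending row).
    IntegrityError
        Duplicate (assay, sample) pair or inconsistent card assignment.
    AnnotationError
        Wide-dialect sample absent from the card map.
    """
    if dialect not in ("long", "wide"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    if decimal not in (".", ","):
        raise ParameterError(f"decimal must be '.' or ',', got {decimal!r}")

    if dialect == "long":
        table = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        table.columns = [c.lower() for c in table.columns]
        required = {"sample", "card", "assay", "ct"}
        if not required.issubset(table.columns):
            raise IntegrityError(
                f"long dialect needs columns {sorted(required)}, got {list(table.columns)}"
            )
        seen: set[tuple[str, str]] = set()
        card_of: dict[str, str] = {}
        ct_by_cell: dict[tuple[str, str], float] = {}
        assay_class: dict[str, str] = {}
        assay_order: dict[str, None] = {}
        sample_order: dict[str, None] = {}
        for i, row in enumerate(table.itertuples(index=False), start=2):  # 1-based + header
            rec = dict(zip(table.columns, row))
            key = (rec["assay"], rec["sample"])
            if key in seen:
                raise IntegrityError(f"duplicate (assay, sample) pair {key} at row {i}")
            seen.add(key)
            prev = card_of.setdefault(rec["sample"], rec["card"])
            if prev != rec["card"]:
                raise IntegrityError(
                    f"sample {rec['sample']!r} assigned to cards {prev!r} and {rec['card']!r}"
                )
            ct_by_cell[key] = _parse_ct(rec["ct"], decimal, f"row {i}")
            if "assay_class" in rec and rec["assay_class"]:
                assay_class[rec["assay"]] = rec["assay_class"]
            assay_order.setdefault(rec["assay"], None)
            sample_order.setdefault(rec["sample"], None)
        assays = list(assay_order)
        samples = list(sample_order)
        values = pd.DataFrame(np.nan, index=assays, columns=samples, dtype=float)
        for (a, s), v in ct_by_cell.items():
            values.at[a, s] = v
        meta = None
        if assay_class:
            meta = pd.DataFrame(
                {"assay_class": [assay_class.get(a) for a in assays]}, index=assays
            )
        return CtMatrix(values, pd.Series(card_of), meta)

    # wide
    if card_map is None:
        raise ParameterError("wide dialect requires a card_map sidecar (sample -> card)")
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique()
        raise IntegrityError(f"duplicate assay rows: {list(dups)}")
    cards = _read_card_map(card_map, sep)
    missing = [s for s in raw.columns if s not in cards.index]
    if missing:
        raise AnnotationError(f"samples missing from card map: {missing}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for a in raw.index:
        for s in raw.columns:
            values.at[a, s] = _parse_ct(raw.at[a, s], decimal, f"assay {a!r}, sample {s!r}")
    return CtMatrix(values, cards.loc[list(raw.columns)])


def write_ct_table(ct: CtMatrix, path, dialect: str = "long", sep: str = "\t") -> None:
    """Write a CtMatrix as delimited text.

    Long output carries one row per cell with non-detects spelled
    ``Undetermined``; wide output leaves non-detect cells empty (the card map
    must then be written separately with :func:`write_card_map`).  Values are
    rendered with 13 significant digits, so a read-back reproduces them to
    better than 1e-12 relative error.
    """
    path = Path(path)
    if dialect == "long":
        rows = []
        has_class = ct.assay_meta is not None and "assay_class" in ct.assay_meta.columns
        for a in ct.assays:
            for s in ct.samples:
                v = ct.values.at[a, s]
                rec = {
                    "sample": s,
                    "card": ct.card_of_sample[s],
                    "assay": a,
                    "ct": NON_DETECT_OUT if math.isnan(v) else format(v, ".13g"),
                }
                if has_class:
                    rec["assay_class"] = ct.assay_meta.at[a, "assay_class"]
                rows.append(rec)
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    elif dialect == "wide":
        out = ct.values.map(lambda v: "" if math.isnan(v) else format(v, ".13g"))
        out.index.name = "assay"
        out.to_csv(path, sep=sep)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")


def write_card_map(ct: CtMatrix, path, sep: str = "\t") -> None:
    """Write the sample → card sidecar used by the wide dialect."""
    table = pd.DataFrame(
        {"sample": ct.samples, "card": [ct.card_of_sample[s] for s in ct.samples]}
    )
    table.to_csv(path, sep=sep, index=False)


def write_rq_table(rq: RQMatrix, path, sep: str = "\t") -> None:
    """Write relative quantities as a wide table; missing cells are empty."""
    out = rq.rq.map(lambda v: "" if math.isnan(v) else format(v, ".13g"))
    out.index.name = "assay"
    out.to_csv(path, sep=sep)


def read_rq_table(path, reference_mode: str = "virtual_housekeeping", sep: str = "\t") -> RQMatrix:
    """Read back a wide relative-quantity table written by :func:`write_rq_table`."""
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    values = raw.map(lambda t: math.nan if t.strip() == "" else float(t)).astype(float)
    return RQMatrix(values, reference_mode)


def read_annotation(path, sep: str = "\t") -> SampleAnnotation:
    """Read a sample annotation table (one row per sample, ``sample`` id column)."""
    table = pd.read_csv(path, sep=sep, dtype=str)
    table.columns = [c.lower() for c in table.columns]
    if "sample" not in table.columns:
        raise IntegrityError("annotation table needs a 'sample' column")
    table = table.set_index("sample")
    if "replicate" in table.columns:
        table["replicate"] = pd.to_numeric(table["replicate"])
    return SampleAnnotation(table)


def write_annotation(ann: SampleAnnotation, path, sep: str = "\t") -> None:
    out = ann.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep=sep)


def intersect_assays(ct: CtMatrix, available: Sequence[str]) -> CtMatrix:
    """Restrict a CtMatrix to the assays actually available on a card.

    Mirrors the step where a candidate gene list from a discovery platform is
    narrowed to the subset that exists as validated qPCR assays.
    """
    keep = [a for a in ct.assays if a in set(available)]
    meta = None if ct.assay_meta is None else ct.assay_meta.loc[keep]
    return CtMatrix(ct.values.loc[keep], ct.card_of_sample.copy(), meta)
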