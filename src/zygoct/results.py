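"""Shared result container for assay/gene selection stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class SelectionResult:
    """Outcome of a filtering/selection step.

    ``retained`` lists the surviving assay ids; ``stats`` carries one row per
    tested assay with the statistics that drove the decision; ``criteria``
    records the thresholds and rules applied, so the provenance of every
    admitted assay is explicit; ``skipped`` maps untestable assays to the
    reason they were skipped.
    """

    retained: list[str]
    stats: pd.DataFrame
    criteria: dict
    skipped: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.retained)

    def __contains__(self, assay: str) -> bool:
        return assay in set(self.retained)
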