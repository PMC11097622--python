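"""Developmental and cross-species expression scoring.

Two readouts replace visual inspection of developmental trajectories and
cross-species cortical dot plots:

* an *early-uplift score*: the log2 ratio of mean expression over prenatal +
  infancy samples to mean expression later in life, with a small pseudo-count
  to stabilize logs of zero RPKM;
* presence/absence flags at a fraction-expressing threshold (5% by default),
  including a deliberately simple human-restricted rule — expressed in human
  and in no non-human primate with data. The latter is a surrogate
  classification, not a differential-expression statistic.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

SPECIES = ("human", "chimpanzee", "macaque", "marmoset")

PRENATAL, INFANCY, LATER = "prenatal", "infancy", "later"

_STAGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*(pcw|mos|yrs)\s*$")

#: Fraction-expressing threshold of the dot-plot convention (inclusive).
DEFAULT_MIN_FRACTION = 0.05


def stage_class(stage_label: str) -> str:
    """Map a developmental-stage label to prenatal / infancy / later.

    Labels follow the developmental-atlas unit convention: post-conception
    weeks ("21 pcw") are prenatal, months ("10 mos") infancy, years
    ("40 yrs") later life.
    """
    m = _STAGE_RE.match(stage_label)
    if not m:
        raise ValueError(f"unparseable stage label: {stage_label!r}")
    unit = m.group(2)
    return {"pcw": PRENATAL, "mos": INFANCY, "yrs": LATER}[unit]


@dataclass(frozen=True)
class StageSample:
    stage_label: str
    stage_class: str
    value: float  # RPKM, >= 0

    def __post_init__(self) -> None:
        if self.stage_class not in (PRENATAL, INFANCY, LATER):
            raise ValueError(f"bad stage class: {self.stage_class!r}")
        if self.value < 0:
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class StageProfile:
    """Expression of one gene across ordered developmental-stage samples."""

    gene: str
    samples: tuple[StageSample, ...]

    @classmethod
    def from_pairs(cls, gene: str, pairs: Sequence[tuple[str, float]]) -> "StageProfile":
        return cls(
            gene,
            tuple(StageSample(lbl, stage_class(lbl), val) for lbl, val in pairs),
        )

    def values(self, *classes: str) -> list[float]:
        return [s.value for s in self.samples if s.stage_class in classes]


def early_uplift_score(profile: StageProfile, epsilon: float = 0.01) -> float:
    """log2((mean prenatal+infancy + eps) / (mean later + eps)).

    Positive scores mean expression is uplifted in early brain development; a
    score of ~3-4 corresponds to the three-to-four log2-magnitudes uplift
    seen for the strongest early-development candidates. Requires at least
    one early (prenatal or infancy) and one later sample.
    """
    early = profile.values(PRENATAL, INFANCY)
    later = profile.values(LATER)
    if not early or not later:
        raise ValueError(
            f"{profile.gene}: need >= 1 prenatal/infancy and >= 1 later sample"
        )
    return math.log2(
        (sum(early) / len(early) + epsilon) / (sum(later) / len(later) + epsilon)
    )


@dataclass(frozen=True)
class PanelEntry:
    gene: str
    species: str
    cell_type: str
    fraction_expressing: float
    mean_level: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species: {self.species!r}")
        if not (0.0 <= self.fraction_expressing <= 1.0):
            raise ValueError("fraction_expressing must be within [0,1]")
        if self.mean_level < 0:
            raise ValueError("mean_level must be non-negative")


class CellTypePanel:
    """Gene x species x cortical-cell-type fraction-expressing table."""

    def __init__(self, entries: Sequence[PanelEntry]):
        self.entries = list(entries)
        self._by_key = {(e.gene, e.species, e.cell_type): e for e in self.entries}

    def get(self, gene: str, species: str, cell_type: str) -> Optional[PanelEntry]:
        return self._by_key.get((gene, species, cell_type))

    def __len__(self) -> int:
        return len(self.entries)


def expressed_in(
    panel: CellTypePanel,
    gene: str,
    species: str,
    cell_type: str,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> bool:
    """True iff the gene is expressed in >= ``min_fraction`` of cells
    (inclusive threshold). Absent entries count as not expressed (warned)."""
    entry = panel.get(gene, species, cell_type)
    if entry is None:
        logger.warning("no panel entry for (%s, %s, %s)", gene, species, cell_type)
        return False
    return entry.fraction_expressing >= min_fraction


def human_specific_expression(
    panel: CellTypePanel,
    gene: str,
    cell_type: str,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> bool:
    """Human-restricted expression call for one gene/cell-type pair.

    True iff the gene passes the expression threshold in human and in no
    non-human species holding an entry for that cell type. This is a simple
    presence/absence surrogate, not a cross-species differential test.
    """
    if not expressed_in(panel, gene, "human", cell_type, min_fraction):
        return False
    for species in SPECIES:
        if species == "human":
            continue
        if panel.get(gene, species, cell_type) is None:
            continue
        if expressed_in(panel, gene, species, cell_type, min_fraction):
            return False
    return True


def read_stage_profiles(path) -> dict[str, StageProfile]:
    """Long-format TSV (gene, stage_label, value) -> per-gene profiles."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, StageProfile] = {}
    for gene, sub in df.groupby("gene", sort=False):
        out[gene] = StageProfile.from_pairs(
            gene, list(zip(sub["stage_label"], sub["value"].astype(float)))
        )
    return out


def read_panel(path) -> CellTypePanel:
    """Long-format TSV (gene, species, cell_type, fraction, mean_level)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    entries = [
        PanelEntry(
            gene=row.gene,
            species=row.species,
            cell_type=row.cell_type,
            fraction_expressing=float(row.fraction),
            mean_level=float(getattr(row, "mean_level", 0.0)),
        )
        for row in df.itertuples(index=False)
    ]
    return CellTypePanel(entries)
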