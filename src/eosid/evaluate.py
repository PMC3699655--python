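"""Scoring against simulator ground truth and published set arithmetic.

Two independent jobs live here: (i) recovery metrics (sensitivity, false
discovery rate, per-class confusion counts) of a selection run against the
synthetic-study truth table, and (ii) verification of the packaged
transcriptions of the published gene tables together with the percentage
arithmetic the study reports (e.g. 99 of 299 = 33.1%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .datamodel import GeneList, MARKER_GENES
from .io import (
    airway_eos_core_gene_list,
    sputum_eos_gene_list,
    sputum_eos_raw_entry_count,
)
from .simulate import GENE_CLASSES, SimTruth

logger = logging.getLogger("eosid")


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

@dataclass
class RecoveryMetrics:
    """How well a selection recovered the simulated airway-EOS program."""

    sensitivity: float
    fdr: float
    #: rows = gene class, columns = selected / not_selected
    confusion: pd.DataFrame
    n_selected: int
    n_positive: int

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
            "n_selected": self.n_selected,
            "n_positive": self.n_positive,
            "confusion": {cls: {"selected": int(r["selected"]),
                                "not_selected": int(r["not_selected"])}
                          for cls, r in self.confusion.iterrows()},
        }


def evaluate_recovery(selection, truth: SimTruth) -> RecoveryMetrics:
    """Score a selection's final intersection against simulator truth.

    The positive class is ``eos_specific`` ∪ ``eos_activated``.  An empty
    selection has FDR 0 by convention (with a warning) so a failed run does
    not divide by zero.
    """
    inter = getattr(selection, "intersection", None)
    selected = set(inter.to_set()) if hasattr(inter, "to_set") else set(selection)
    universe = set(truth.genes.index)
    stray = selected - universe
    if stray:
        raise ValueError(f"selected gene(s) outside truth universe: "
                         f"{sorted(stray)[:5]}")
    positives = set(truth.positive_genes())
    tp = len(selected & positives)
    sensitivity = tp / len(positives) if positives else 0.0
    if selected:
        fdr = (len(selected) - tp) / len(selected)
    else:
        warnings.warn("empty selection: FDR reported as 0.0", stacklevel=2)
        fdr = 0.0
    rows = []
    for cls in GENE_CLASSES:
        members = set(truth.genes_of_class(cls))
        rows.append((cls, len(members & selected), len(members - selected)))
    confusion = pd.DataFrame(rows, columns=["gene_class", "selected",
                                            "not_selected"]).set_index("gene_class")
    assert int(confusion.to_numpy().sum()) == len(universe)
    return RecoveryMetrics(float(sensitivity), float(fdr), confusion,
                           len(selected), len(positives))


# ---------------------------------------------------------------------------
# published set arithmetic
# ---------------------------------------------------------------------------

def percent_of(part: int, whole: int, decimals: int = 1) -> float:
    """100*part/whole, rounded half-away-from-zero to ``decimals`` places.

    Matches how the study's percentages are printed (33.1% for 99/299,
    46% for 168/365, 28% for 16/57).
    """
    if whole <= 0:
        raise ValueError("whole must be > 0")
    if part < 0:
        raise ValueError("part must be >= 0")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(part) / Decimal(whole)).quantize(
        quantum, rounding=ROUND_HALF_UP)
    return float(value)


@dataclass
class DifferentialSummary:
    """Group means of cell percentages and the reduction between groups."""

    label_a: str
    label_b: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    #: 100 * (mean_a - mean_b) / mean_a
    reduction_of_means_pct: float
    #: mean of per-subject reductions 100 * (a_i - b_i) / a_i (paired only)
    mean_of_subject_reductions_pct: float | None


def _sem(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(values.size))


def summarize_differentials(group_a, group_b, label_a: str = "a",
                            label_b: str = "b") -> DifferentialSummary:
    """Mean, SEM and percent reduction between two groups of percentages.

    The reduction is reported under both conventions: reduction of the
    group means, and — when the groups are paired (equal length) — the mean
    of the per-subject reductions.  The two differ whenever subjects vary.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if a.mean() == 0:
        raise ValueError("group A mean is zero; reduction undefined")
    reduction_means = 100.0 * (a.mean() - b.mean()) / a.mean()
    per_subject = None
    if a.size == b.size and (a != 0).all():
        per_subject = float(np.mean(100.0 * (a - b) / a))
    return DifferentialSummary(label_a, label_b, float(a.mean()), _sem(a),
                               float(b.mean()), _sem(b), int(a.size),
                               int(b.size), float(reduction_means), per_subject)


# ---------------------------------------------------------------------------
# packaged-table verification
# ---------------------------------------------------------------------------

#: Recorded expectations for the packaged transcriptions.
EXPECTED_SPUTUM_RAW_ENTRIES = 365
EXPECTED_CORE_ENTRIES = 57
EXPECTED_INTERSECTION = 57


@dataclass
class TableVerification:
    sputum_raw_entries: int
    sputum_unique_entries: int
    core_entries: int
    intersection_size: int
    markers_in_core: bool
    ok: bool

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def verify_tables(sputum_list: GeneList | None = None,
                  core_list: GeneList | None = None,
                  sputum_raw_count: int | None = None) -> TableVerification:
    """Check the packaged gene-table transcriptions against recorded counts.

    Verifies: 365 raw sputum entries, 57 core entries, the core list fully
    contained in the sputum list, and all four marker genes in the core list.
    """
    sputum_list = sputum_list or sputum_eos_gene_list()
    core_list = core_list or airway_eos_core_gene_list()
    if sputum_raw_count is None:
        sputum_raw_count = sputum_eos_raw_entry_count()
    inter = core_list.to_set() & sputum_list.to_set()
    markers = all(m in core_list for m in MARKER_GENES)
    ok = (sputum_raw_count == EXPECTED_SPUTUM_RAW_ENTRIES
          and len(core_list) == EXPECTED_CORE_ENTRIES
          and len(inter) == EXPECTED_INTERSECTION
          and markers)
    report = TableVerification(sputum_raw_count, len(sputum_list),
                               len(core_list), len(inter), markers, ok)
    if not ok:
        logger.error("table verification failed: %s", report.as_dict())
    return report
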