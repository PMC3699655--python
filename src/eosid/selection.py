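"""The three fold-change selection branches and their intersection.

Airway-eosinophil genes are attributed by combining three perturbation
responses, each evaluated per subject on linear-scale fold changes and
required to hold in *every* subject analyzed:

1. **BAL branch** — genes up-regulated more than ``bal_up_fc`` (default 2)
   in BAL cells 48 h after segmental allergen challenge (V2 vs V1).
2. **Mepolizumab branch** — among BAL-up genes, genes decreased more than
   ``mepo_down_fc`` (default 1.5) when the challenge is repeated after
   eosinophil depletion.  Two criteria are computed per subject: the direct
   ratio expr(V2)/expr(V4), and the ratio of fold changes
   FC(V2/V1) / FC(V4/V3); by default both must exceed the threshold (the
   1.5 threshold reflects that mepolizumab roughly halves the BAL EOS
   fraction, so a pure EOS transcript is expected to drop about 2-fold).
3. **Sputum branch** — genes up-regulated more than ``sputum_up_fc``
   (default 1.5) after whole-lung allergen challenge (V2 vs V1) in every
   *gated* sputum subject.  A subject is gated in when all four canonical
   EOS marker transcripts (IL5RA, RNASE2, RNASE3, SIGLEC8) rise more than
   ``sputum_marker_fc`` (default 2), i.e. the subject actually mounted
   sputum eosinophilia.

The final gene set is the three-way intersection; the seven disjoint Venn
regions are tracked for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, GeneList, MARKER_GENES, SampleTable, \
    normalize_symbol

logger = logging.getLogger("eosid")


@dataclass(frozen=True)
class SelectionThresholds:
    """Fold-change thresholds for the three branches.

    ``strict`` selects the comparison mode: ``True`` uses ``>`` ("more than
    n-fold", the default), ``False`` uses ``>=``.  ``mepo_rule`` combines the
    two mepolizumab criteria (``"and"`` by default; ``"or"`` provided for
    sensitivity analysis).
    """

    bal_up_fc: float = 2.0
    mepo_down_fc: float = 1.5
    sputum_marker_fc: float = 2.0
    sputum_up_fc: float = 1.5
    strict: bool = True
    mepo_rule: str = "and"

    def __post_init__(self) -> None:
        for name in ("bal_up_fc", "mepo_down_fc", "sputum_marker_fc", "sputum_up_fc"):
            if getattr(self, name) <= 1:
                raise ValueError(f"{name} must be > 1")
        if self.mepo_rule not in ("and", "or"):
            raise ValueError("mepo_rule must be 'and' or 'or'")

    def exceeds(self, values, threshold: float):
        """Elementwise threshold comparison in the configured mode."""
        return values > threshold if self.strict else values >= threshold

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# fold changes
# ---------------------------------------------------------------------------

def _visit_values(matrix: ExpressionMatrix, metadata: SampleTable,
                  compartment: str, visit: str, subjects: list[str]) -> pd.DataFrame:
    cols = {}
    for s in subjects:
        try:
            cols[s] = matrix.values[metadata.sample_for(s, compartment, visit)]
        except KeyError:
            raise ValueError(
                f"missing visit {visit} ({compartment}) for subject {s!r}")
    return pd.DataFrame(cols)


def compute_fold_change(matrix: ExpressionMatrix, metadata: SampleTable,
                        contrast: tuple[str, str], compartment: str = "BAL",
                        subjects: list[str] | None = None) -> pd.DataFrame:
    """Per-subject linear fold changes for one visit contrast.

    Parameters
    ----------
    contrast
        ``(numerator_visit, denominator_visit)``, e.g. ``("V2", "V1")``.
    compartment
        Which compartment's samples to pair, ``"BAL"`` or ``"sputum"``.
    subjects
        Restrict to these subjects (default: all subjects with samples in
        the compartment).

    Returns a genes x subjects DataFrame of fold changes.  Log2 input is
    exponentiated first (FC = 2**(log2num - log2den)); near-zero linear
    denominators are floored at 1e-6 x the median positive value of the
    matrix, and every floored cell is logged.
    """
    num_visit, den_visit = contrast
    for v in contrast:
        if v not in ("V1", "V2", "V3", "V4"):
            raise ValueError(f"unknown contrast visit {v!r}")
    if subjects is None:
        subjects = metadata.subjects(compartment)
    linear = matrix.to_linear()
    num = _visit_values(linear, metadata, compartment, num_visit, subjects)
    den = _visit_values(linear, metadata, compartment, den_visit, subjects)
    positive = linear.values.to_numpy()
    positive = positive[positive > 0]
    eps = 1e-6 * (np.median(positive) if positive.size else 1.0)
    n_floored = int((den.to_numpy() < eps).sum())
    if n_floored:
        logger.warning("floored %d near-zero denominator(s) at eps=%.3g",
                       n_floored, eps)
    fc = num / den.clip(lower=eps)
    fc.index = linear.values.index
    fc.columns = list(subjects)
    return fc


def fold_change_records(fc: pd.DataFrame, contrast_label: str) -> pd.DataFrame:
    """Long-format view: one row per (gene, subject) with its fold change."""
    long = fc.stack().rename("fold_change").reset_index()
    long.columns = ["gene", "subject_id", "fold_change"]
    long.insert(2, "contrast", contrast_label)
    return long


# ---------------------------------------------------------------------------
# branches
# ---------------------------------------------------------------------------

def select_bal_upregulated(fc: pd.DataFrame,
                           thresholds: SelectionThresholds | None = None) -> GeneList:
    """Genes with FC above ``bal_up_fc`` in every subject (BAL V2 vs V1)."""
    thresholds = thresholds or SelectionThresholds()
    if fc.shape[1] == 0:
        raise ValueError("no subjects in fold-change records")
    passed = thresholds.exceeds(fc, thresholds.bal_up_fc).all(axis=1)
    return GeneList("bal_up", fc.index[passed],
                    provenance=f"BAL V2/V1 > {thresholds.bal_up_fc} in all "
                               f"{fc.shape[1]} subject(s)")


def mepolizumab_criteria(matrix: ExpressionMatrix, metadata: SampleTable,
                         subjects: list[str] | None = None
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two per-subject decrease criteria for the mepolizumab contrast.

    Returns ``(direct, fc_ratio)``, both genes x subjects:
    ``direct`` = expr(V2)/expr(V4) and ``fc_ratio`` = FC(V2/V1) / FC(V4/V3).
    """
    if subjects is None:
        subjects = metadata.subjects("BAL")
    direct = compute_fold_change(matrix, metadata, ("V2", "V4"), "BAL", subjects)
    fc21 = compute_fold_change(matrix, metadata, ("V2", "V1"), "BAL", subjects)
    fc43 = compute_fold_change(matrix, metadata, ("V4", "V3"), "BAL", subjects)
    return direct, fc21 / fc43


def select_mepolizumab_decreased(matrix: ExpressionMatrix, metadata: SampleTable,
                                 candidate_genes: GeneList,
                                 thresholds: SelectionThresholds | None = None,
                                 subjects: list[str] | None = None) -> GeneList:
    """Candidate genes decreased by eosinophil depletion in every subject.

    Both decrease criteria (direct V2/V4 ratio and ratio of fold changes)
    must exceed ``mepo_down_fc`` under the default ``"and"`` rule.
    """
    thresholds = thresholds or SelectionThresholds()
    absent = sorted(set(candidate_genes.to_set()) - set(matrix.gene_ids))
    if absent:
        raise KeyError(f"candidate gene(s) absent from matrix: {', '.join(absent)}")
    direct, fc_ratio = mepolizumab_criteria(matrix, metadata, subjects)
    crit1 = thresholds.exceeds(direct, thresholds.mepo_down_fc)
    crit2 = thresholds.exceeds(fc_ratio, thresholds.mepo_down_fc)
    both = (crit1 & crit2) if thresholds.mepo_rule == "and" else (crit1 | crit2)
    passed = set(direct.index[both.all(axis=1)])
    return GeneList("mepo_down", [g for g in candidate_genes if g in passed],
                    provenance=f"both decrease criteria > {thresholds.mepo_down_fc} "
                               f"in all subjects ({thresholds.mepo_rule} rule)")


def gate_sputum_subjects(fc: pd.DataFrame,
                         marker_genes=MARKER_GENES,
                         thresholds: SelectionThresholds | None = None) -> list[str]:
    """Sputum subjects in whom all four EOS marker genes rose > threshold.

    ``fc`` is the genes x subjects sputum V2/V1 fold-change frame.
    """
    thresholds = thresholds or SelectionThresholds()
    markers = [normalize_symbol(m) for m in marker_genes]
    missing = sorted(set(markers) - set(fc.index))
    if missing:
        raise KeyError(f"marker gene(s) missing from matrix: {', '.join(missing)}")
    ok = thresholds.exceeds(fc.loc[markers], thresholds.sputum_marker_fc).all(axis=0)
    gated = [s for s in fc.columns if bool(ok[s])]
    logger.info("marker gating: %d of %d sputum subject(s) passed",
                len(gated), fc.shape[1])
    return gated


def select_sputum_associated(fc: pd.DataFrame, gated_subjects: list[str],
                             thresholds: SelectionThresholds | None = None) -> GeneList:
    """Genes with FC above ``sputum_up_fc`` in every gated sputum subject."""
    thresholds = thresholds or SelectionThresholds()
    if not gated_subjects:
        raise ValueError("no subjects passed marker gating")
    sub = fc[list(gated_subjects)]
    passed = thresholds.exceeds(sub, thresholds.sputum_up_fc).all(axis=1)
    return GeneList("sputum_assoc", fc.index[passed],
                    provenance=f"sputum V2/V1 > {thresholds.sputum_up_fc} in "
                               f"{len(gated_subjects)} gated subject(s)")


# ---------------------------------------------------------------------------
# intersection / Venn accounting
# ---------------------------------------------------------------------------

VENN_REGIONS = ("bal_only", "sputum_only", "mepo_only", "bal_sputum",
                "bal_mepo", "sputum_mepo", "all_three")


@dataclass
class GeneSelectionResult:
    """The three branch gene sets, the 7 disjoint Venn regions, and the
    final three-way intersection."""

    bal_up: GeneList
    mepo_down: GeneList
    sputum_assoc: GeneList
    regions: dict[str, frozenset[str]]
    intersection: GeneList
    gated_subjects: tuple[str, ...] = ()
    thresholds: SelectionThresholds | None = None

    def region_counts(self) -> dict[str, int]:
        return {k: len(self.regions[k]) for k in VENN_REGIONS}

    def check_invariants(self) -> None:
        b, m, s = (self.bal_up.to_set(), self.mepo_down.to_set(),
                   self.sputum_assoc.to_set())
        sets = [self.regions[k] for k in VENN_REGIONS]
        union = frozenset().union(*sets)
        assert union == b | m | s, "regions do not cover the branch union"
        assert sum(len(r) for r in sets) == len(union), "regions overlap"
        assert self.intersection.to_set() == b & m & s
        assert self.regions["all_three"] == self.intersection.to_set()


def intersect_branches(bal_up: GeneList, mepo_down: GeneList,
                       sputum_assoc: GeneList,
                       gated_subjects: list[str] | None = None,
                       thresholds: SelectionThresholds | None = None
                       ) -> GeneSelectionResult:
    """Three-way intersection with full Venn-region accounting.

    The Venn is computed over the union of the three branch outputs: a gene
    absent from one platform's matrix simply never enters that branch.
    """
    b, m, s = bal_up.to_set(), mepo_down.to_set(), sputum_assoc.to_set()
    regions = {
        "bal_only": frozenset(b - m - s),
        "sputum_only": frozenset(s - b - m),
        "mepo_only": frozenset(m - b - s),
        "bal_sputum": frozenset((b & s) - m),
        "bal_mepo": frozenset((b & m) - s),
        "sputum_mepo": frozenset((s & m) - b),
        "all_three": frozenset(b & m & s),
    }
    inter = GeneList("intersection", sorted(b & m & s),
                     provenance="bal_up ∩ mepo_down ∩ sputum_assoc")
    result = GeneSelectionResult(bal_up, mepo_down, sputum_assoc, regions, inter,
                                 tuple(gated_subjects or ()), thresholds)
    result.check_invariants()
    return result


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_selection(bal_matrix: ExpressionMatrix, sputum_matrix: ExpressionMatrix,
                  metadata: SampleTable,
                  thresholds: SelectionThresholds | None = None
                  ) -> GeneSelectionResult:
    """Run all three branches on a study and intersect them."""
    thresholds = thresholds or SelectionThresholds()
    bal_fc = compute_fold_change(bal_matrix, metadata, ("V2", "V1"), "BAL")
    bal_up = select_bal_upregulated(bal_fc, thresholds)
    mepo_down = select_mepolizumab_decreased(bal_matrix, metadata, bal_up, thresholds)
    sputum_fc = compute_fold_change(sputum_matrix, metadata, ("V2", "V1"), "sputum")
    gated = gate_sputum_subjects(sputum_fc, MARKER_GENES, thresholds)
    sputum_assoc = select_sputum_associated(sputum_fc, gated, thresholds)
    return intersect_branches(bal_up, mepo_down, sputum_assoc, gated, thresholds)


def selection_report(bal_matrix: ExpressionMatrix, sputum_matrix: ExpressionMatrix,
                     metadata: SampleTable, result: GeneSelectionResult
                     ) -> pd.DataFrame:
    """Per-gene report: per-subject fold changes and pass/fail flags."""
    thresholds = result.thresholds or SelectionThresholds()
    bal_fc = compute_fold_change(bal_matrix, metadata, ("V2", "V1"), "BAL")
    direct, fc_ratio = mepolizumab_criteria(bal_matrix, metadata)
    sputum_fc = compute_fold_change(sputum_matrix, metadata, ("V2", "V1"), "sputum")
    frames = {f"bal_fc_{s}": bal_fc[s] for s in bal_fc.columns}
    frames.update({f"mepo_direct_{s}": direct[s] for s in direct.columns})
    frames.update({f"mepo_fcratio_{s}": fc_ratio[s] for s in fc_ratio.columns})
    frames.update({f"sputum_fc_{s}": sputum_fc[s]
                   for s in result.gated_subjects})
    report = pd.DataFrame(frames)
    report.insert(0, "gene", report.index)
    for branch in ("bal_up", "mepo_down", "sputum_assoc", "intersection"):
        members = getattr(result, branch).to_set()
        report[f"in_{branch}"] = report["gene"].isin(members)
    return report.reset_index(drop=True)
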