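"""Core domain types for airway-eosinophil expression analysis.

The study design these types support: bulk gene expression is measured in two
airway compartments (bronchoalveolar lavage, BAL, and induced sputum) of the
same subjects before and after an in vivo allergen challenge, with a second
BAL challenge pair performed after eosinophil depletion by mepolizumab
(anti-IL-5).  Visits are labelled V1–V4 for BAL (pre/post challenge, then
pre/post challenge after mepolizumab) and V1–V2 for sputum.  Genes expressed
by airway eosinophils are attributed by combining fold-change responses
across these perturbations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("eosid")

VISITS = ("V1", "V2", "V3", "V4")
COMPARTMENTS = ("BAL", "sputum", "purified_EOS")

#: Canonical eosinophil marker transcripts used to gate sputum subjects.
MARKER_GENES = ("IL5RA", "RNASE2", "RNASE3", "SIGLEC8")

#: Cell classes scored on cytospin differentials.
CELL_CLASSES = ("eosinophil", "macrophage", "lymphocyte", "neutrophil", "epithelial")


def normalize_symbol(symbol: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace and uppercase.

    Normalization is deliberately minimal (no alias mapping): the published
    gene lists are symbol-level, and alias resolution would silently change
    set cardinalities.  The function is idempotent.
    """
    return str(symbol).strip().upper()


class ExpressionMatrix:
    """A genes x samples intensity matrix on a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.  The scale must
        be declared by the caller; it is never auto-detected.
    collapse
        Policy for duplicate gene rows after symbol normalization:
        ``"max"`` (default, keeps the most responsive probe per sample) or
        ``"mean"``.
    """

    def __init__(self, values: pd.DataFrame, scale: str = "linear",
                 collapse: str = "max") -> None:
        if scale not in ("linear", "log2"):
            raise ValueError(f"scale must be 'linear' or 'log2', got {scale!r}")
        if collapse not in ("max", "mean"):
            raise ValueError(f"collapse must be 'max' or 'mean', got {collapse!r}")
        values = values.copy()
        if values.shape[0] == 0:
            raise ValueError("no genes: expression matrix has no data rows")
        if values.shape[1] == 0:
            raise ValueError("expression matrix has no sample columns")
        sample_ids = [str(c) for c in values.columns]
        if len(set(sample_ids)) != len(sample_ids):
            dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample_id(s): {', '.join(dupes)}")
        values.columns = sample_ids
        values.index = [normalize_symbol(g) for g in values.index]
        values = values.astype(float)
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if scale == "linear" and (values.to_numpy() < 0).any():
            bad = values.index[(values < 0).any(axis=1)][:5].tolist()
            raise ValueError(f"negative linear-scale values (e.g. genes {bad})")
        if values.index.has_duplicates:
            n_dup = int(values.index.duplicated().sum())
            grouped = values.groupby(level=0, sort=False)
            values = grouped.max() if collapse == "max" else grouped.mean()
            logger.info("collapsed %d duplicate gene row(s) with policy %r",
                        n_dup, collapse)
        self._values = values
        self.scale = scale

    # -- accessors ---------------------------------------------------------

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def gene_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape

    def to_linear(self) -> "ExpressionMatrix":
        """Return the matrix on the linear scale (2**x for log2 input)."""
        if self.scale == "linear":
            return self
        return ExpressionMatrix(2.0 ** self._values, scale="linear")

    def attach_metadata(self, metadata: "SampleTable") -> None:
        """Validate that every sample has exactly one annotation record."""
        missing = sorted(set(self.sample_ids) - set(metadata.sample_ids))
        if missing:
            raise ValueError(f"samples without metadata: {', '.join(missing)}")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"ExpressionMatrix({self.shape[0]} genes x {self.shape[1]} "
                f"samples, scale={self.scale})")


@dataclass(frozen=True)
class SampleInfo:
    """Annotation of one bulk sample."""

    sample_id: str
    subject_id: str
    compartment: str
    visit: str
    mepolizumab: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.visit not in VISITS:
            raise ValueError(f"unknown visit {self.visit!r}")
        if self.compartment == "sputum" and self.visit not in ("V1", "V2"):
            raise ValueError("sputum samples only have visits V1/V2")
        if self.visit in ("V1", "V2") and self.mepolizumab:
            raise ValueError("mepolizumab must be False for V1/V2 samples")


class SampleTable:
    """A collection of :class:`SampleInfo` records with study-design checks."""

    def __init__(self, records: Iterable[SampleInfo]) -> None:
        records = list(records)
        ids = [r.sample_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")
        keys = [(r.subject_id, r.compartment, r.visit) for r in records]
        if len(set(keys)) != len(keys):
            raise ValueError("(subject_id, compartment, visit) not unique")
        self._records = {r.sample_id: r for r in records}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SampleTable":
        required = ["sample_id", "subject_id", "compartment", "visit", "mepolizumab"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"metadata missing column(s): {', '.join(missing)}")
        recs = []
        for row in df.itertuples(index=False):
            mep = row.mepolizumab
            if isinstance(mep, str):
                mep = mep.strip().lower() in ("true", "1", "yes")
            recs.append(SampleInfo(str(row.sample_id), str(row.subject_id),
                                   str(row.compartment), str(row.visit), bool(mep)))
        return cls(recs)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.sample_id, r.subject_id, r.compartment, r.visit, r.mepolizumab)
             for r in self._records.values()],
            columns=["sample_id", "subject_id", "compartment", "visit", "mepolizumab"],
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, sample_id: str) -> SampleInfo:
        return self._records[sample_id]

    def subjects(self, compartment: str) -> list[str]:
        """Subject ids present in a compartment, in first-seen order."""
        seen: dict[str, None] = {}
        for r in self._records.values():
            if r.compartment == compartment:
                seen.setdefault(r.subject_id)
        return list(seen)

    def sample_for(self, subject_id: str, compartment: str, visit: str) -> str:
        """The unique sample id for (subject, compartment, visit)."""
        for r in self._records.values():
            if (r.subject_id, r.compartment, r.visit) == (subject_id, compartment, visit):
                return r.sample_id
        raise KeyError(
            f"no sample for subject {subject_id!r}, {compartment}, {visit}")


@dataclass(frozen=True)
class CellDifferential:
    """Cytospin differential counts for one sample."""

    sample_id: str
    counts: Mapping[str, int]
    total_counted: int

    def __post_init__(self) -> None:
        if self.total_counted < 0:
            raise ValueError("total_counted must be non-negative")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative cell count")
        if sum(self.counts.values()) != self.total_counted:
            raise ValueError("class counts do not sum to total_counted")

    def percentages(self) -> dict[str, float]:
        if self.total_counted == 0:
            return {k: 0.0 for k in self.counts}
        return {k: 100.0 * v / self.total_counted for k, v in self.counts.items()}


class GeneList:
    """A named, ordered, duplicate-free list of normalized gene symbols."""

    def __init__(self, name: str, symbols: Iterable[str], provenance: str = "") -> None:
        self.name = name
        self.provenance = provenance
        seen: dict[str, None] = {}
        dropped = 0
        for s in symbols:
            s = normalize_symbol(s)
            if not s:
                continue
            if s in seen:
                dropped += 1
            else:
                seen[s] = None
        if dropped:
            logger.info("gene list %r: dropped %d duplicate symbol(s)", name, dropped)
        self.symbols: tuple[str, ...] = tuple(seen)
        self.n_duplicates_dropped = dropped

    def to_set(self) -> frozenset[str]:
        return frozenset(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.to_set()

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneList) and self.symbols == other.symbols

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneList({self.name!r}, {len(self)} genes)"
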