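"""Relative qPCR quantification: standard curves, 2^-ΔΔCt, paired testing.

The comparative cycle-threshold (ΔΔCt) method expresses a gene's abundance
in a sample as a fold change relative to a calibrator sample, after
normalizing both to a reference transcript (here GUSB by convention)::

    ΔCt   = Ct(gene, sample)  - Ct(reference, sample)
    ΔΔCt  = ΔCt(sample)       - ΔCt(calibrator)
    fold change = 2 ** (-ΔΔCt)

Base 2 assumes perfect amplification efficiency; measured efficiencies from
dilution-series standard curves (slope of Ct against log10 quantity,
``E = 10**(-1/slope) - 1``) are reported but, by default, not used to
correct the fold change — an efficiency-corrected mode is available.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import SampleTable, normalize_symbol

logger = logging.getLogger("eosid")

#: Slope of an ideal (100%-efficient) standard curve, cycles per log10 unit.
IDEAL_SLOPE = -math.log(10.0) / math.log(2.0)  # -3.3219...

#: Default acceptance band for primer efficiencies, percent.
DEFAULT_EFFICIENCY_BAND = (91.0, 96.0)


@dataclass(frozen=True)
class StandardCurve:
    """A fitted dilution-series line and the efficiency it implies."""

    gene: str
    slope: float                 # cycles per log10 quantity unit
    intercept: float
    efficiency_percent: float    # (10**(-1/slope) - 1) * 100
    r_squared: float
    n_points: int
    in_band: bool

    def predict_ct(self, log10_quantity) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log10_quantity)


def fit_standard_curve(points, gene: str = "",
                       efficiency_band: tuple[float, float] = DEFAULT_EFFICIENCY_BAND
                       ) -> StandardCurve:
    """Fit Ct against log10 relative quantity by ordinary least squares.

    ``points`` is a DataFrame with columns ``log10_quantity`` and ``ct`` or a
    sequence of ``(log10_quantity, ct)`` pairs; at least 3 dilution points
    are required and the series should span >= 2 log10 units (a narrower
    span only warns).  A non-negative slope means the dilution series is
    invalid.  ``in_band`` flags whether the efficiency lies inside the
    acceptance band (default 91–96%).
    """
    if isinstance(points, pd.DataFrame):
        x = points["log10_quantity"].to_numpy(float)
        y = points["ct"].to_numpy(float)
    else:
        arr = np.asarray(list(points), dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise ValueError("standard curve needs at least 3 dilution points")
    if x.max() - x.min() < 2.0:
        warnings.warn("dilution series spans less than 2 log10 units",
                      stacklevel=2)
    fit = stats.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("invalid dilution series: non-negative slope")
    efficiency = (10.0 ** (-1.0 / fit.slope) - 1.0) * 100.0
    in_band = efficiency_band[0] <= efficiency <= efficiency_band[1]
    if not in_band:
        logger.warning("efficiency %.1f%% for %s outside band [%g, %g]",
                       efficiency, gene or "curve", *efficiency_band)
    return StandardCurve(gene, float(fit.slope), float(fit.intercept),
                         float(efficiency), float(fit.rvalue ** 2), len(x), in_band)


# ---------------------------------------------------------------------------
# ΔΔCt
# ---------------------------------------------------------------------------

def _mean_ct(wells: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of replicate Cts per (sample, gene), wide format."""
    wells = wells.copy()
    wells["gene"] = wells["gene"].map(normalize_symbol)
    return wells.pivot_table(index="sample_id", columns="gene", values="ct",
                             aggfunc="mean")


def delta_delta_ct(wells: pd.DataFrame, reference_gene: str,
                   calibrator_sample: str,
                   efficiencies: Mapping[str, float] | None = None,
                   samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Relative quantification of a well table against one calibrator sample.

    ``wells`` has columns ``sample_id, gene, replicate, ct``.  Returns one
    row per (sample, gene) with ``mean_ct``, ``delta_ct``, ``delta_delta_ct``
    and ``fold_change``.  The reference gene's fold change is exactly 1 in
    every sample, and every gene's fold change is exactly 1 in the
    calibrator sample.

    When ``efficiencies`` (per-gene fractional efficiencies, e.g. 0.93) is
    given, fold changes use the measured base ``1 + eff`` per gene instead
    of 2 (efficiency-corrected mode; off by default).
    """
    reference_gene = normalize_symbol(reference_gene)
    mean_ct = _mean_ct(wells)
    if samples is not None:
        missing = sorted(set(samples) - set(mean_ct.index))
        if missing:
            raise ValueError(f"samples not on plate: {', '.join(missing)}")
        mean_ct = mean_ct.loc[list(samples)]
    if calibrator_sample not in mean_ct.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not on plate")
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"reference gene {reference_gene!r} not on plate")
    if mean_ct[reference_gene].isna().any():
        bad = mean_ct.index[mean_ct[reference_gene].isna()].tolist()
        raise ValueError(f"reference gene missing in sample(s): {bad}")

    delta_ct = mean_ct.sub(mean_ct[reference_gene], axis=0)
    ddct = delta_ct.sub(delta_ct.loc[calibrator_sample], axis=1)
    if efficiencies is None:
        fold = 2.0 ** (-ddct)
    else:
        bases = pd.Series({g: 1.0 + efficiencies[g] for g in ddct.columns})
        fold = bases.pow(-ddct)  # type: ignore[arg-type]
    out = pd.DataFrame({
        "mean_ct": mean_ct.stack(),
        "delta_ct": delta_ct.stack(),
        "delta_delta_ct": ddct.stack(),
        "fold_change": fold.stack(),
    }).reset_index()
    out.columns = ["sample_id", "gene", "mean_ct", "delta_ct",
                   "delta_delta_ct", "fold_change"]
    return out


def delta_delta_ct_by_subject(wells: pd.DataFrame, metadata: SampleTable,
                              reference_gene: str,
                              calibrator_visit: str = "V1",
                              calibrator_compartment: str = "BAL",
                              efficiencies: Mapping[str, float] | None = None
                              ) -> pd.DataFrame:
    """ΔΔCt with each subject calibrated to their own pre-challenge sample.

    This is the grouping used for the validation figure: fold changes of BAL
    V2, BAL V4 and purified-EOS samples relative to the same subject's BAL
    V1.  Adds ``subject_id``, ``compartment`` and ``visit`` columns.
    """
    plate_samples = set(wells["sample_id"])
    frames = []
    for subject in {metadata[s].subject_id for s in plate_samples}:
        cal = metadata.sample_for(subject, calibrator_compartment, calibrator_visit)
        subj_samples = [s for s in plate_samples
                        if metadata[s].subject_id == subject]
        sub = wells[wells["sample_id"].isin(subj_samples)]
        res = delta_delta_ct(sub, reference_gene, cal, efficiencies=efficiencies)
        res.insert(0, "subject_id", subject)
        frames.append(res)
    out = pd.concat(frames, ignore_index=True)
    out["compartment"] = [metadata[s].compartment for s in out["sample_id"]]
    out["visit"] = [metadata[s].visit for s in out["sample_id"]]
    return out.sort_values(["gene", "subject_id", "sample_id"],
                           ignore_index=True)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    t: float
    p: float
    tier: str  # "", "#", "##" or "###" following the figure-legend markers
    n: int


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "###"
    if p < 0.01:
        return "##"
    if p < 0.05:
        return "#"
    return ""


def paired_log_test(fold_changes_a, fold_changes_b) -> PairedTestResult:
    """Two-sided Student's paired t-test on log-transformed fold changes.

    Fold changes are transformed with the natural log (any base gives the
    same t and p).  All-zero paired differences return t=0, p=1 with a
    warning rather than NaN.
    """
    a = np.asarray(fold_changes_a, dtype=float)
    b = np.asarray(fold_changes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("paired t-test needs n >= 2")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold changes must be positive")
    diffs = np.log(a) - np.log(b)
    if np.allclose(diffs.std(ddof=1), 0.0):
        # degenerate fixtures: all-zero differences are a true null (t=0,
        # p=1); constant non-zero differences saturate the statistic
        if np.allclose(diffs, 0.0):
            warnings.warn("zero-variance paired differences; returning t=0, p=1",
                          stacklevel=2)
            return PairedTestResult(0.0, 1.0, "", len(a))
        warnings.warn("constant non-zero paired differences; t saturates",
                      stacklevel=2)
        t = math.copysign(math.inf, float(diffs.mean()))
        return PairedTestResult(t, 0.0, significance_tier(0.0), len(a))
    t, p = stats.ttest_rel(np.log(a), np.log(b))
    return PairedTestResult(float(t), float(p), significance_tier(float(p)),
                            len(a))


@dataclass(frozen=True)
class FoldChangeSummary:
    median: float
    q25: float
    q75: float
    mean: float
    n: int


def summarize_fold_changes(values) -> FoldChangeSummary:
    """Median, quartiles (linear interpolation) and mean of a group."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty group")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return FoldChangeSummary(float(med), float(q25), float(q75),
                             float(arr.mean()), int(arr.size))
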