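"""Synthetic allergen-challenge studies from a two-compartment mixture model.

Each bulk sample is modelled as a mixture of an eosinophil (EOS) compartment
and a non-EOS compartment.  For gene ``g`` in sample ``s`` with EOS fraction
``f_s``, the noiseless bulk intensity is::

    x_gs = f_s * E_g * a_g(s) + (1 - f_s) * B_g * b_g(s)

where ``E_g``/``B_g`` are the per-compartment baseline expression levels and
``a_g``/``b_g`` are condition multipliers applied only in post-challenge
samples (BAL V2/V4, sputum V2).  The measured value multiplies in
``exp(eps)`` with ``eps ~ Normal(0, sigma^2)`` (multiplicative log-normal
noise, the standard microarray error model — fold changes stay scale-free).

Gene classes
------------
``eos_specific``
    Constitutively EOS-enriched: ``E_g = ratio * B_g`` (ratio default 50),
    ``a = b = 1``.  The four canonical marker genes (IL5RA, RNASE2, RNASE3,
    SIGLEC8) belong to this class.
``eos_activated``
    EOS-enriched and further induced in EOS by the challenge:
    ``E_g = ratio * B_g`` and ``a_g`` = activation multiplier (default 3)
    post-challenge.
``noneos_challenge_induced``
    Expressed evenly across cell types (``E_g = B_g``) and induced by the
    challenge *independently of eosinophils* (``a_g = b_g`` = induction
    multiplier, default 3, post-challenge).  These genes rise with challenge
    in both compartments' cells, so they pass the BAL and sputum branches
    yet show no mepolizumab response — the confounder class the
    depletion contrast exists to remove.
``null``
    Flat housekeeping-like genes (``E_g = B_g``, no multipliers).  The
    reference transcript GUSB is the first null gene, giving the qPCR
    normalizer a constant true abundance by construction.

Per-subject EOS fractions are drawn from truncated normals whose means are
the study's reported cell differentials (BAL ~0.5% pre-challenge, 73.9%
post-challenge, 34% post-challenge after mepolizumab; sputum 2.0% → 8.2%).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CELL_CLASSES,
    CellDifferential,
    ExpressionMatrix,
    MARKER_GENES,
    SampleInfo,
    SampleTable,
)

logger = logging.getLogger("eosid")

GENE_CLASSES = ("eos_specific", "eos_activated", "noneos_challenge_induced", "null")

#: Visits in which the challenge-response multipliers apply.
POST_CHALLENGE_VISITS = ("V2", "V4")

#: Reported BAL EOS percentages are mean ± SEM over n=8 subjects; per-subject
#: sd = SEM * sqrt(8).  Sputum dispersions are not reported; the SEMs used
#: (0.3% / 1.8%, n=6) are chosen so that marker gating typically admits
#: 3-4 of 6 subjects, as observed in the study.
DEFAULT_FRACTIONS: dict[tuple[str, str], tuple[float, float]] = {
    ("BAL", "V1"): (0.005, 0.002 * math.sqrt(8)),
    ("BAL", "V2"): (0.739, 0.042 * math.sqrt(8)),
    ("BAL", "V3"): (0.005, 0.002 * math.sqrt(8)),
    ("BAL", "V4"): (0.340, 0.090 * math.sqrt(8)),
    ("sputum", "V1"): (0.020, 0.003 * math.sqrt(6)),
    ("sputum", "V2"): (0.082, 0.018 * math.sqrt(6)),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a synthetic study; defaults follow the study design."""

    n_genes: int = 1000
    #: class counts default to 10% of n_genes each (eos_specific at least 4,
    #: to hold the marker genes); the remainder is the null class
    n_eos_specific: int | None = None
    n_eos_activated: int | None = None
    n_noneos_induced: int | None = None
    n_subjects_bal: int = 8
    n_subjects_sputum: int = 6
    #: (mean, sd) of the per-subject EOS fraction per (compartment, visit).
    fractions: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS))
    #: EOS/non-EOS expression ratio for EOS-enriched genes.
    eos_expression_ratio: float = 50.0
    #: EOS activation multiplier for eos_activated genes, post-challenge.
    activation_multiplier: float = 3.0
    #: Challenge-induction multiplier for noneos_challenge_induced genes.
    induction_multiplier: float = 3.0
    #: sd of the multiplicative log-normal noise, natural-log units.
    sigma: float = 0.25
    #: EOS fraction of purified-EOS samples.
    purity: float = 0.995
    #: Baselines B_g are drawn log-uniform over 2**[lo, hi].
    baseline_log2_range: tuple[float, float] = (4.0, 12.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        tenth = max(1, round(0.1 * self.n_genes))
        if self.n_eos_specific is None:
            object.__setattr__(self, "n_eos_specific",
                               max(len(MARKER_GENES), tenth))
        if self.n_eos_activated is None:
            object.__setattr__(self, "n_eos_activated", tenth)
        if self.n_noneos_induced is None:
            object.__setattr__(self, "n_noneos_induced", tenth)
        if self.n_null < 0:
            raise ValueError("gene class counts exceed n_genes")
        if self.n_eos_specific < len(MARKER_GENES):
            raise ValueError("need at least 4 eos_specific genes for the markers")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        for key, (mean, sd) in self.fractions.items():
            if not 0 < mean < 1:
                raise ValueError(f"fraction mean for {key} must be in (0,1)")
            if sd < 0:
                raise ValueError(f"fraction sd for {key} must be >= 0")

    @property
    def n_null(self) -> int:
        return (self.n_genes - self.n_eos_specific - self.n_eos_activated
                - self.n_noneos_induced)

    def noiseless(self) -> "SimConfig":
        """The deterministic limit: sigma=0 and all fraction sds at 0."""
        flat = {k: (m, 0.0) for k, (m, _) in self.fractions.items()}
        return replace(self, sigma=0.0, fractions=flat)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic study.

    ``genes`` has one row per gene with columns ``gene_class``, ``E``
    (EOS-compartment baseline), ``B`` (non-EOS baseline), ``activation``
    (``a_g``) and ``induction`` (``b_g``); ``fractions`` maps each emitted
    sample to its drawn EOS fraction.
    """

    genes: pd.DataFrame
    fractions: pd.Series
    config: SimConfig

    def genes_of_class(self, *classes: str) -> list[str]:
        mask = self.genes["gene_class"].isin(classes)
        return list(self.genes.index[mask])

    def positive_genes(self) -> frozenset[str]:
        """The true airway-EOS program: eos_specific ∪ eos_activated."""
        return frozenset(self.genes_of_class("eos_specific", "eos_activated"))

    def expected_expression(self, gene: str, f: float, post_challenge: bool) -> float:
        """Evaluate the noiseless mixture formula for one gene and fraction."""
        row = self.genes.loc[gene]
        a = row["activation"] if post_challenge else 1.0
        b = row["induction"] if post_challenge else 1.0
        return f * row["E"] * a + (1.0 - f) * row["B"] * b


@dataclass
class QpcrPlate:
    """Replicate Ct measurements plus per-primer amplification efficiencies."""

    wells: pd.DataFrame  # columns: sample_id, gene, replicate, ct
    reference_gene: str
    efficiencies: dict[str, float]


@dataclass
class SimStudy:
    """Everything one synthetic study emits."""

    bal: ExpressionMatrix
    sputum: ExpressionMatrix
    metadata: SampleTable
    differentials: list[CellDifferential]
    qpcr: QpcrPlate
    truth: SimTruth


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size), 0.0, 1.0)


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    names: list[str] = []
    classes: list[str] = []
    counters = {"eos_specific": config.n_eos_specific,
                "eos_activated": config.n_eos_activated,
                "noneos_challenge_induced": config.n_noneos_induced,
                "null": config.n_null}
    idx = 0
    for cls in GENE_CLASSES:
        for j in range(counters[cls]):
            if cls == "eos_specific" and j < len(MARKER_GENES):
                names.append(MARKER_GENES[j])
            elif cls == "null" and j == 0:
                names.append("GUSB")
            else:
                idx += 1
                names.append(f"G{idx:04d}")
            classes.append(cls)
    lo, hi = config.baseline_log2_range
    B = 2.0 ** rng.uniform(lo, hi, config.n_genes)
    cls_arr = np.array(classes)
    enriched = np.isin(cls_arr, ("eos_specific", "eos_activated"))
    E = np.where(enriched, config.eos_expression_ratio * B, B)
    activation = np.where(cls_arr == "eos_activated", config.activation_multiplier, 1.0)
    # challenge-induced genes rise in every cell class, EOS included
    activation = np.where(cls_arr == "noneos_challenge_induced",
                          config.induction_multiplier, activation)
    induction = np.where(cls_arr == "noneos_challenge_induced",
                         config.induction_multiplier, 1.0)
    return pd.DataFrame({"gene_class": classes, "E": E, "B": B,
                         "activation": activation, "induction": induction},
                        index=pd.Index(names, name="gene"))


def _mixture_matrix(truth: pd.DataFrame, fractions: pd.Series,
                    post_challenge: pd.Series) -> pd.DataFrame:
    f = fractions.to_numpy()[None, :]
    post = post_challenge.to_numpy()[None, :].astype(float)
    E = truth["E"].to_numpy()[:, None]
    B = truth["B"].to_numpy()[:, None]
    a = 1.0 + (truth["activation"].to_numpy()[:, None] - 1.0) * post
    b = 1.0 + (truth["induction"].to_numpy()[:, None] - 1.0) * post
    values = f * E * a + (1.0 - f) * B * b
    return pd.DataFrame(values, index=truth.index, columns=fractions.index)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig | None = None,
                   rng: np.random.Generator | int | None = None) -> SimStudy:
    """Generate a complete synthetic study with known ground truth.

    Emits a BAL matrix (V1–V4 per BAL subject), a sputum matrix (V1–V2 per
    sputum subject), full sample metadata (including purified-EOS V2
    samples, which appear in the qPCR plate rather than the array
    matrices), cytospin differentials, a qPCR plate for the validation
    targets, and the :class:`SimTruth` table.  Identical config + seed give
    identical outputs.
    """
    config = config or SimConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    genes = _draw_truth(config, rng)

    records: list[SampleInfo] = []
    fracs: dict[str, float] = {}
    post: dict[str, bool] = {}

    bal_subjects = [f"B{i + 1}" for i in range(config.n_subjects_bal)]
    sputum_subjects = [f"S{i + 1}" for i in range(config.n_subjects_sputum)]
    for visit in ("V1", "V2", "V3", "V4"):
        mean, sd = config.fractions[("BAL", visit)]
        draws = _truncated_normal(rng, mean, sd, len(bal_subjects))
        for subj, f in zip(bal_subjects, draws):
            sid = f"{subj}_BAL_{visit}"
            records.append(SampleInfo(sid, subj, "BAL", visit,
                                      mepolizumab=visit in ("V3", "V4")))
            fracs[sid] = float(f)
            post[sid] = visit in POST_CHALLENGE_VISITS
    for visit in ("V1", "V2"):
        mean, sd = config.fractions[("sputum", visit)]
        draws = _truncated_normal(rng, mean, sd, len(sputum_subjects))
        for subj, f in zip(sputum_subjects, draws):
            sid = f"{subj}_SPU_{visit}"
            records.append(SampleInfo(sid, subj, "sputum", visit))
            fracs[sid] = float(f)
            post[sid] = visit == "V2"
    for subj in bal_subjects:  # purified BAL EOS, collected at V2
        sid = f"{subj}_EOS_V2"
        records.append(SampleInfo(sid, subj, "purified_EOS", "V2"))
        fracs[sid] = config.purity
        post[sid] = True

    metadata = SampleTable(records)
    frac_series = pd.Series(fracs, name="eos_fraction")
    post_series = pd.Series(post)
    truth = SimTruth(genes, frac_series, config)

    def noisy_matrix(sample_ids: list[str]) -> ExpressionMatrix:
        expected = _mixture_matrix(genes, frac_series[sample_ids],
                                   post_series[sample_ids])
        noise = rng.normal(0.0, config.sigma, expected.shape)
        return ExpressionMatrix(expected * np.exp(noise), scale="linear")

    bal_ids = [f"{s}_BAL_{v}" for v in ("V1", "V2", "V3", "V4")
               for s in bal_subjects]
    spu_ids = [f"{s}_SPU_{v}" for v in ("V1", "V2") for s in sputum_subjects]
    bal = noisy_matrix(bal_ids)
    sputum = noisy_matrix(spu_ids)

    differentials = [
        simulate_cell_differentials(_airway_composition(frac_series[sid],
                                                        metadata[sid].compartment),
                                    total_counted=400, rng=rng, sample_id=sid)
        for sid in bal_ids + spu_ids
    ]

    # Fig-4-style validation panel: a marker, a constitutive EOS gene, an
    # EOS-activated gene, and an EOS-independent induced gene as negative control.
    by_class = genes.groupby("gene_class", sort=False).groups
    validation_targets = ["IL5RA"]
    for cls in ("eos_specific", "eos_activated", "noneos_challenge_induced"):
        extra = [g for g in by_class.get(cls, []) if g not in MARKER_GENES]
        if extra:
            validation_targets.append(extra[0])
    qpcr = simulate_qpcr(truth, targets=validation_targets, reference_gene="GUSB",
                         rng=rng)
    return SimStudy(bal, sputum, metadata, differentials, qpcr, truth)


def _airway_composition(eos_fraction: float, compartment: str) -> dict[str, float]:
    """Split the non-EOS remainder over the other scored cell classes."""
    rest = 1.0 - eos_fraction
    if compartment == "sputum":
        weights = {"macrophage": 0.35, "lymphocyte": 0.05,
                   "neutrophil": 0.45, "epithelial": 0.15}
    else:  # BAL is macrophage-dominated
        weights = {"macrophage": 0.80, "lymphocyte": 0.12,
                   "neutrophil": 0.05, "epithelial": 0.03}
    comp = {"eosinophil": eos_fraction}
    comp.update({k: rest * w for k, w in weights.items()})
    return comp


def simulate_cell_differentials(fractions: Mapping[str, float],
                                total_counted: int = 400,
                                rng: np.random.Generator | int | None = None,
                                sample_id: str = "sample") -> CellDifferential:
    """Draw a cytospin differential: multinomial counts over cell classes."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    classes = list(fractions)
    p = np.array([fractions[c] for c in classes], dtype=float)
    if (p < 0).any():
        raise ValueError("negative cell-class probability")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError(f"class probabilities sum to {p.sum():.6f}, not 1")
    counts = rng.multinomial(total_counted, p / p.sum()) if total_counted else \
        np.zeros(len(p), dtype=int)
    return CellDifferential(sample_id, dict(zip(classes, counts.tolist())),
                            total_counted)


def simulate_qpcr(truth: SimTruth, targets: Sequence[str],
                  reference_gene: str = "GUSB",
                  efficiencies: Mapping[str, float] | None = None,
                  replicates: int = 3, ct_noise_sd: float = 0.15,
                  rng: np.random.Generator | int | None = None,
                  ct_anchor: float = 28.0,
                  calibrator_visit: str = "V1") -> QpcrPlate:
    """Simulate replicate Ct values for target genes across BAL samples.

    For gene ``g`` in sample ``s`` with relative quantity ``q`` (noiseless
    mixture expression normalized to the subject's calibrator-visit BAL
    sample) and per-primer efficiency ``eff``::

        Ct = ct_anchor - ln(q) / ln(1 + eff) + Normal(0, ct_noise_sd**2)

    so a perfectly efficient primer (eff = 1) loses exactly one cycle per
    doubling of template.  Plates cover BAL V1, V2, V4 and the purified-EOS
    V2 samples of every BAL subject.  Default efficiencies are drawn
    uniformly from the validated range [0.91, 0.96] per primer pair.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    genes = list(dict.fromkeys([*targets, reference_gene]))
    unknown = [g for g in genes if g not in truth.genes.index]
    if unknown:
        raise KeyError(f"unknown target gene(s): {', '.join(unknown)}")
    if efficiencies is None:
        efficiencies = {g: float(rng.uniform(0.91, 0.96)) for g in genes}
    else:
        efficiencies = dict(efficiencies)
        missing = [g for g in genes if g not in efficiencies]
        if missing:
            raise ValueError(f"no efficiency for: {', '.join(missing)}")
        for g, e in efficiencies.items():
            if not 0 < e <= 1.2:
                raise ValueError(f"efficiency for {g} outside (0, 1.2]: {e}")

    config = truth.config
    subjects = sorted({sid.split("_")[0] for sid in truth.fractions.index
                       if "_BAL_" in sid})
    plate_samples = []
    for subj in subjects:
        for visit in ("V1", "V2", "V4"):
            plate_samples.append((f"{subj}_BAL_{visit}", visit in
                                  POST_CHALLENGE_VISITS))
        eos_sid = f"{subj}_EOS_V2"
        if eos_sid in truth.fractions.index:
            plate_samples.append((eos_sid, True))

    rows = []
    for subj in subjects:
        cal_sid = f"{subj}_BAL_{calibrator_visit}"
        for sid, is_post in plate_samples:
            if not sid.startswith(f"{subj}_"):
                continue
            f = truth.fractions[sid]
            f_cal = truth.fractions[cal_sid]
            for g in genes:
                q = (truth.expected_expression(g, f, is_post)
                     / truth.expected_expression(g, f_cal, False))
                ct0 = ct_anchor - math.log(q) / math.log1p(efficiencies[g])
                for rep in range(1, replicates + 1):
                    ct = ct0 + float(rng.normal(0.0, ct_noise_sd)) \
                        if ct_noise_sd > 0 else ct0
                    rows.append((sid, g, rep, ct))
    wells = pd.DataFrame(rows, columns=["sample_id", "gene", "replicate", "ct"])
    return QpcrPlate(wells, reference_gene, efficiencies)


def simulate_standard_curve(efficiency: float, n_points: int = 5,
                            top_log10_quantity: float = 0.0, step: float = -1.0,
                            ct_at_top: float = 20.0, noise_sd: float = 0.0,
                            rng: np.random.Generator | int | None = None
                            ) -> pd.DataFrame:
    """Dilution-series points (log10 quantity, Ct) at a known efficiency."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    logq = top_log10_quantity + step * np.arange(n_points)
    slope = -math.log(10.0) / math.log1p(efficiency)  # cycles per log10 unit
    ct = ct_at_top + slope * (logq - top_log10_quantity)
    if noise_sd > 0:
        ct = ct + rng.normal(0.0, noise_sd, n_points)
    return pd.DataFrame({"log10_quantity": logq, "ct": ct})


# ---------------------------------------------------------------------------
# truth serialization
# ---------------------------------------------------------------------------

def write_sim_truth(truth: SimTruth, genes_path, fractions_path) -> None:
    df = truth.genes.reset_index()
    df.to_csv(genes_path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")
    fr = truth.fractions.rename_axis("sample_id").reset_index()
    fr.to_csv(fractions_path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def read_sim_truth(genes_path, fractions_path=None,
                   config: SimConfig | None = None) -> SimTruth:
    # keep_default_na: the class label "null" must not parse as NaN
    genes = pd.read_csv(genes_path, sep="\t", index_col="gene",
                        keep_default_na=False)
    for col in ("E", "B", "activation", "induction"):
        genes[col] = genes[col].astype(float)
    if fractions_path is not None:
        fr = pd.read_csv(fractions_path, sep="\t", index_col="sample_id")
        fractions = fr["eos_fraction"]
    else:
        fractions = pd.Series(dtype=float)
    return SimTruth(genes, fractions, config or SimConfig())
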