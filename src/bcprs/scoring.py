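"""Variant harmonization, cohort QC and polygenic risk score computation.

The score of sample *j* is the weighted allele count

    PRS_j = sum_i a_ij * beta_i

over the variants of a PRS model, where ``a_ij`` is the dosage of the
model's effect allele and ``beta_i`` its log-odds effect size.  No
clumping, pruning or p-value thresholding is applied: published weight
sets are taken as-is.  Scores are then z-standardized over the entire
cohort (cases and controls pooled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import GenotypeMatrix, WeightTable

PALINDROMIC_PAIRS = {frozenset("AT"), frozenset("CG")}


@dataclass
class QCReport:
    n_variants_in: int
    n_samples_in: int
    n_variants_removed_missing: int
    n_variants_removed_maf: int
    n_samples_removed_missing: int

    @property
    def n_variants_out(self) -> int:
        return (self.n_variants_in - self.n_variants_removed_missing
                - self.n_variants_removed_maf)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_removed_missing

    def to_dict(self) -> dict:
        return {**self.__dict__, "n_variants_out": self.n_variants_out,
                "n_samples_out": self.n_samples_out}


def qc_filter(genotypes: GenotypeMatrix,
              snp_missing_max: float = 0.02,
              maf_min: float = 0.02,
              sample_missing_max: float = 0.02) -> tuple[GenotypeMatrix, QCReport]:
    """Three-stage genotype QC: variant missingness, then MAF, then sample
    missingness.

    Thresholds are fractions in [0, 1]; a variant is removed when its
    missing fraction *exceeds* ``snp_missing_max`` or its MAF falls *below*
    ``maf_min``, and likewise for samples.  The stages are applied in the
    order listed, so MAF is computed on the variants surviving the
    missingness filter and sample missingness on the surviving variants.
    """
    for name, thr in (("snp_missing_max", snp_missing_max), ("maf_min", maf_min),
                      ("sample_missing_max", sample_missing_max)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {thr}")

    n_var, n_samp = len(genotypes.variant_ids), len(genotypes.sample_ids)

    keep_v = genotypes.missing_fraction_per_variant() <= snp_missing_max
    n_miss = int((~keep_v).sum())
    gm = genotypes.subset(variant_mask=keep_v)

    with np.errstate(invalid="ignore"):
        keep_v2 = gm.minor_allele_frequency() >= maf_min
    n_maf = int((~keep_v2).sum())
    gm = gm.subset(variant_mask=keep_v2)
    if len(gm.variant_ids) == 0:
        raise ValueError("QC removed every variant or sample")

    keep_s = gm.missing_fraction_per_sample() <= sample_missing_max
    n_sm = int((~keep_s).sum())
    gm = gm.subset(sample_mask=keep_s)

    if gm.dosage.size == 0:
        raise ValueError("QC removed every variant or sample")
    report = QCReport(n_var, n_samp, n_miss, n_maf, n_sm)
    return gm, report


@dataclass
class HarmonizationReport:
    """Accounting of how a PRS model's variants mapped onto the genotypes."""

    n_in_model: int
    n_matched: int
    n_flipped: int
    n_dropped: int
    dropped_ids: list = field(default_factory=list)
    dropped_reasons: dict = field(default_factory=dict)  # id -> absent|palindromic|allele_mismatch

    def __post_init__(self) -> None:
        assert self.n_matched + self.n_dropped == self.n_in_model
        assert self.n_flipped <= self.n_matched

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["dropped_ids"] = list(self.dropped_ids)
        return d


@dataclass
class AlignedDosages:
    """Dosages of the matched model variants, oriented to the effect allele."""

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray          # n_samples x n_matched, NaN = missing
    betas: np.ndarray           # aligned with variant_ids


def harmonize(weights: WeightTable,
              genotypes: GenotypeMatrix) -> tuple[AlignedDosages, HarmonizationReport]:
    """Align genotype dosages to a weight model's effect-allele orientation.

    Per model variant: same allele pair in the same orientation -> matched;
    swapped orientation -> dosage becomes ``2 - dosage`` and counts as
    flipped; strand-ambiguous palindromic pairs (A/T, C/G) and allele-set
    mismatches -> dropped; variants absent from the genotypes -> dropped.
    Genotypes without declared alleles are assumed already model-oriented.
    """
    col_of = {v: i for i, v in enumerate(genotypes.variant_ids)}
    declared = genotypes.declared_alleles

    cols, vids, betas = [], [], []
    flip = []
    dropped: dict[str, str] = {}
    for _, row in weights.df.iterrows():
        vid, ea, oa = row["variant_id"], row["effect_allele"], row["other_allele"]
        if vid not in col_of:
            dropped[vid] = "absent"
            continue
        if frozenset((ea, oa)) in PALINDROMIC_PAIRS:
            dropped[vid] = "palindromic"
            continue
        do_flip = False
        if declared is not None and vid in declared.index:
            a1, a2 = declared.loc[vid, "a1"], declared.loc[vid, "a2"]
            if (a1, a2) == (ea, oa):
                do_flip = False
            elif (a1, a2) == (oa, ea):
                do_flip = True
            else:
                dropped[vid] = "allele_mismatch"
                continue
        vids.append(vid)
        betas.append(row["beta"])
        flip.append(do_flip)
        cols.append(col_of[vid])

    dosage = genotypes.dosage[:, cols].copy() if cols else \
        np.empty((len(genotypes.sample_ids), 0))
    flip = np.asarray(flip, dtype=bool)
    if flip.any():
        dosage[:, flip] = 2.0 - dosage[:, flip]

    report = HarmonizationReport(
        n_in_model=len(weights), n_matched=len(vids), n_flipped=int(flip.sum()),
        n_dropped=len(dropped), dropped_ids=list(dropped), dropped_reasons=dropped)
    aligned = AlignedDosages(list(genotypes.sample_ids), vids, dosage,
                             np.asarray(betas, dtype=float))
    return aligned, report


@dataclass
class ScoreSet:
    """Raw and (after :func:`standardize`) z-standardized PRS per sample."""

    sample_ids: list[str]
    prs_raw: np.ndarray
    prs_z: np.ndarray | None = None
    cohort_mean: float | None = None
    cohort_sd: float | None = None


def compute_prs(aligned: AlignedDosages) -> ScoreSet:
    """Weighted dosage sum over matched variants.

    Missing dosages are imputed with the variant's cohort-mean dosage
    before summation, so a sample's score is never NaN.
    """
    if aligned.dosage.shape[1] == 0:
        raise ValueError("no matched variants: cannot compute PRS")
    dosage = aligned.dosage
    col_mean = np.nanmean(np.where(np.isnan(dosage).all(axis=0, keepdims=True),
                                   0.0, dosage), axis=0)
    filled = np.where(np.isnan(dosage), col_mean, dosage)
    raw = filled @ aligned.betas
    return ScoreSet(list(aligned.sample_ids), raw)


def standardize(scores: ScoreSet) -> ScoreSet:
    """Z-score the raw PRS over the whole scored cohort.

    Uses the population (divide-by-N) standard deviation; the resulting
    z-scores have mean 0 and SD 1 by construction.
    """
    raw = np.asarray(scores.prs_raw, dtype=float)
    mean = float(raw.mean())
    sd = float(raw.std(ddof=0))
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("constant PRS: standard deviation is zero")
    return ScoreSet(scores.sample_ids, raw, (raw - mean) / sd, mean, sd)


class PRSScorer(BaseEstimator, TransformerMixin):
    """Genotypes-to-standardized-PRS transformer.

    ``fit`` runs QC on the genotype matrix, harmonizes it against the
    weight model and learns the cohort imputation means and the
    standardization constants; ``transform`` returns the z-scored PRS of
    the fitted cohort (or of new genotypes scored against the fitted
    cohort's constants).

    Parameters
    ----------
    weights : WeightTable
        Published PRS model (variant ids, effect alleles, betas).
    snp_missing_max, maf_min, sample_missing_max : float
        QC thresholds, defaults 0.02 each.
    apply_qc : bool
        Disable to score a pre-filtered matrix unchanged.
    """

    def __init__(self, weights: WeightTable | None = None,
                 snp_missing_max: float = 0.02, maf_min: float = 0.02,
                 sample_missing_max: float = 0.02, apply_qc: bool = True):
        self.weights = weights
        self.snp_missing_max = snp_missing_max
        self.maf_min = maf_min
        self.sample_missing_max = sample_missing_max
        self.apply_qc = apply_qc

    def fit(self, X: GenotypeMatrix, y=None) -> "PRSScorer":
        if self.weights is None:
            raise ValueError("PRSScorer requires a weight table")
        gm = X
        if self.apply_qc:
            gm, self.qc_report_ = qc_filter(gm, self.snp_missing_max,
                                            self.maf_min, self.sample_missing_max)
        else:
            self.qc_report_ = None
        aligned, self.harmonization_report_ = harmonize(self.weights, gm)
        if aligned.dosage.shape[1] == 0:
            raise ValueError("no matched variants after harmonization")
        scores = standardize(compute_prs(aligned))
        self.matched_variant_ids_ = aligned.variant_ids
        self.betas_ = aligned.betas
        with np.errstate(invalid="ignore"):
            cm = np.nanmean(aligned.dosage, axis=0)
        self.imputation_means_ = np.where(np.isfinite(cm), cm, 0.0)
        self.cohort_mean_ = scores.cohort_mean
        self.cohort_sd_ = scores.cohort_sd
        self.sample_ids_ = scores.sample_ids
        self.scores_ = scores
        return self

    def transform(self, X: GenotypeMatrix) -> np.ndarray:
        """Standardized PRS (column vector) using the fitted constants."""
        if not hasattr(self, "betas_"):
            raise ValueError("PRSScorer is not fitted")
        aligned, _ = harmonize(self.weights, X)
        col_of = {v: i for i, v in enumerate(aligned.variant_ids)}
        try:
            cols = [col_of[v] for v in self.matched_variant_ids_]
        except KeyError:
            missing = set(self.matched_variant_ids_) - set(aligned.variant_ids)
            raise ValueError(f"genotypes lack {len(missing)} fitted variants")
        dosage = aligned.dosage[:, cols]
        filled = np.where(np.isnan(dosage), self.imputation_means_, dosage)
        raw = filled @ self.betas_
        return ((raw - self.cohort_mean_) / self.cohort_sd_)[:, None]
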