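"""Readers, writers and validation for the pipeline's tabular inputs.

Four table families flow through the pipeline:

* **weight tables** — per-variant effect alleles and effect sizes of a
  published PRS model;
* **genotype dosage matrices** — sample x variant counts (0/1/2) of a
  declared allele, with ``NA`` for missing calls;
* **phenotype / cohort tables** — case status, entry and exit ages and the
  event indicator needed for left-truncated survival analysis;
* **rate tables** — age-binned incidence or mortality hazards published per
  100,000 person-years and carried internally per person-year.

All files are tab-separated with a header line.  Parse errors name the
offending line (1-based, counting the header as line 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

WEIGHT_COLUMNS = ["variant_id", "chromosome", "position",
                  "effect_allele", "other_allele", "beta"]

PHENOTYPE_COLUMNS = ["sample_id", "status", "entry_age", "exit_age", "event"]


class TableFormatError(ValueError):
    """A structural or value-level problem in an input table."""


# ---------------------------------------------------------------------------
# Weight tables


@dataclass
class WeightTable:
    """Per-variant effect sizes of a PRS model.

    ``beta`` is on the per-effect-allele log-odds scale; the score of a
    sample is the dosage-weighted sum of betas over the model's variants.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.df.columns]
        if missing:
            raise TableFormatError(f"weight table missing column(s): {missing}")
        df = self.df
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise TableFormatError(f"duplicate variant_id {dup!r} in weight table")
        for col in ("effect_allele", "other_allele"):
            bad = ~df[col].isin(list(VALID_ALLELES))
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise TableFormatError(
                    f"non-ACGT allele {df.loc[bad, col].iloc[0]!r} in column "
                    f"{col} at line {line}")
        same = df["effect_allele"] == df["other_allele"]
        if same.any():
            line = int(np.flatnonzero(same.to_numpy())[0]) + 2
            raise TableFormatError(f"effect_allele equals other_allele at line {line}")
        beta = pd.to_numeric(df["beta"], errors="coerce").to_numpy(dtype=float)
        if not np.all(np.isfinite(beta)):
            line = int(np.flatnonzero(~np.isfinite(beta))[0]) + 2
            raise TableFormatError(f"non-numeric or non-finite beta at line {line}")
        self.df = df.assign(beta=beta, position=df["position"].astype(int),
                            chromosome=df["chromosome"].astype(str))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> list[str]:
        return self.df["variant_id"].tolist()

    @property
    def betas(self) -> np.ndarray:
        return self.df["beta"].to_numpy()


def read_weights(path: str | Path) -> WeightTable:
    """Read a five-column PRS weight file (TSV with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chromosome": str,
                                            "effect_allele": str, "other_allele": str})
    return WeightTable(df)


def write_weights(weights: WeightTable, path: str | Path) -> None:
    weights.df.to_csv(path, sep="\t", index=False, columns=WEIGHT_COLUMNS)


# ---------------------------------------------------------------------------
# Rate tables


@dataclass
class RateTable:
    """Age-specific hazard rates on contiguous half-open integer-year bins.

    ``rate`` is per person-year; files publish per-100,000 rates and the
    reader divides by 1e5.  Within a bin the hazard is a constant step,
    matching how registries publish incidence and mortality.
    """

    kind: str  # "incidence" | "mortality"
    age_lo: np.ndarray
    age_hi: np.ndarray
    rate: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("incidence", "mortality"):
            raise TableFormatError(f"unknown rate-table kind {self.kind!r}")
        self.age_lo = np.asarray(self.age_lo, dtype=int)
        self.age_hi = np.asarray(self.age_hi, dtype=int)
        self.rate = np.asarray(self.rate, dtype=float)
        if not (len(self.age_lo) == len(self.age_hi) == len(self.rate)):
            raise TableFormatError("rate table columns have unequal lengths")
        if len(self.rate) == 0:
            raise TableFormatError("empty rate table")
        if np.any(self.age_hi <= self.age_lo):
            raise TableFormatError("rate table has a bin with age_hi <= age_lo")
        gaps = self.age_lo[1:] != self.age_hi[:-1]
        if np.any(gaps):
            i = int(np.flatnonzero(gaps)[0])
            raise TableFormatError(
                f"rate table bins not contiguous: [{self.age_lo[i]},{self.age_hi[i]}) "
                f"followed by [{self.age_lo[i + 1]},{self.age_hi[i + 1]})")
        if np.any(self.rate < 0):
            raise TableFormatError("negative rate in rate table")

    def __len__(self) -> int:
        return len(self.rate)

    @property
    def span(self) -> tuple[int, int]:
        return int(self.age_lo[0]), int(self.age_hi[-1])

    def yearly(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to a 1-year grid: (integer ages, per-year rates).

        Age ``a`` carries the rate of the bin containing ``[a, a+1)``.
        """
        ages = np.arange(self.age_lo[0], self.age_hi[-1])
        return ages, self.rate_at(ages)

    def rate_at(self, ages: np.ndarray) -> np.ndarray:
        """Step-function lookup; ages outside the span raise."""
        ages = np.asarray(ages)
        lo, hi = self.span
        if np.any(ages < lo) or np.any(ages >= hi):
            raise ValueError(f"age outside rate-table span [{lo},{hi})")
        idx = np.searchsorted(self.age_hi, ages, side="right")
        return self.rate[idx]


def read_rate_table(path: str | Path, kind: str) -> RateTable:
    """Read an age-binned rate file with columns age_lo, age_hi, rate_per_100k."""
    df = pd.read_csv(path, sep="\t")
    for col in ("age_lo", "age_hi", "rate_per_100k"):
        if col not in df.columns:
            raise TableFormatError(f"rate table missing column {col!r}")
    return RateTable(kind=kind,
                     age_lo=df["age_lo"].to_numpy(),
                     age_hi=df["age_hi"].to_numpy(),
                     rate=df["rate_per_100k"].to_numpy(dtype=float) / 1e5)


def write_rate_table(table: RateTable, path: str | Path) -> None:
    pd.DataFrame({"age_lo": table.age_lo, "age_hi": table.age_hi,
                  "rate_per_100k": table.rate * 1e5}
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Cohort (phenotype) tables


@dataclass
class CohortTable:
    """Per-sample case status and follow-up window on the age time scale.

    ``entry_age`` is the age at enrolment (left-truncation age); ``exit_age``
    is the age at diagnosis for cases and the age at last follow-up for
    controls.  ``prs_raw``/``prs_z`` are filled by the scoring stage.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"phenotype table missing column(s): {missing}")
        bad_status = ~df["status"].isin(["case", "control"])
        if bad_status.any():
            line = int(np.flatnonzero(bad_status.to_numpy())[0]) + 2
            raise TableFormatError(f"status must be case/control at line {line}")
        entry = df["entry_age"].to_numpy(dtype=float)
        exit_ = df["exit_age"].to_numpy(dtype=float)
        if np.any(entry < 0):
            raise TableFormatError("negative entry_age")
        nonpos = exit_ <= entry
        if np.any(nonpos):
            line = int(np.flatnonzero(nonpos)[0]) + 2
            raise TableFormatError(f"exit_age <= entry_age at line {line}")
        event = df["event"].astype(bool)
        if (event & (df["status"] != "case")).any():
            raise TableFormatError("event=true requires status=case")
        if df["sample_id"].duplicated().any():
            raise TableFormatError("duplicate sample_id in phenotype table")
        for col in ("prs_raw", "prs_z"):
            if col not in df.columns:
                df = df.assign(**{col: np.nan})
        self.df = df.assign(event=event, entry_age=entry, exit_age=exit_)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def n_cases(self) -> int:
        return int((self.df["status"] == "case").sum())

    @property
    def n_controls(self) -> int:
        return int((self.df["status"] == "control").sum())


def read_phenotypes(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "status": str})
    return CohortTable(df)


def write_phenotypes(cohort: CohortTable, path: str | Path) -> None:
    out = cohort.df.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Genotype dosage matrices


@dataclass
class GenotypeMatrix:
    """Sample x variant effective-allele dosages.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for missing.
    ``declared_alleles`` optionally records, per variant, the (counted,
    other) allele pair the dosages refer to; when absent, harmonization
    assumes dosages already count each model's effect allele.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray
    declared_alleles: pd.DataFrame | None = None  # index variant_id, cols a1, a2

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise TableFormatError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_ids)} variants")
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise TableFormatError("dosage values must be 0, 1, 2 or NA")
        if self.declared_alleles is not None:
            extra = set(self.declared_alleles.index) - set(self.variant_ids)
            self.declared_alleles = self.declared_alleles.drop(index=sorted(extra))
            self.declared_alleles.index.name = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    def missing_fraction_per_variant(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def missing_fraction_per_sample(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-variant MAF from non-missing dosages (folded to [0, 0.5])."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def subset(self, sample_mask=None, variant_mask=None) -> "GenotypeMatrix":
        smask = np.ones(len(self.sample_ids), bool) if sample_mask is None else sample_mask
        vmask = np.ones(len(self.variant_ids), bool) if variant_mask is None else variant_mask
        vids = [v for v, k in zip(self.variant_ids, vmask) if k]
        da = None
        if self.declared_alleles is not None:
            da = self.declared_alleles.loc[self.declared_alleles.index.intersection(vids)]
        return GenotypeMatrix(
            sample_ids=[s for s, k in zip(self.sample_ids, smask) if k],
            variant_ids=vids,
            dosage=self.dosage[np.ix_(smask, vmask)],
            declared_alleles=da)


def read_dosage_matrix(path: str | Path,
                       alleles_path: str | Path | None = None) -> GenotypeMatrix:
    """Read a dosage TSV: first column sample_id, one column per variant.

    Cells must be 0, 1, 2 or ``NA``.  An optional sidecar TSV (columns
    variant_id, allele1, allele2) declares which allele each column counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    sample_ids = df[first].tolist()
    variant_ids = [c for c in df.columns if c != first]
    raw = df[variant_ids].to_numpy()
    dosage = np.full(raw.shape, np.nan)
    ok = {"0": 0.0, "1": 1.0, "2": 2.0}
    flat = raw.ravel()
    for sym in pd.unique(flat):
        if isinstance(sym, float) and np.isnan(sym):
            continue
        if sym == "NA" or sym is None:
            continue
        if sym not in ok:
            idx = int(np.flatnonzero(flat == sym)[0])
            line = idx // len(variant_ids) + 2
            raise TableFormatError(f"unknown dosage symbol {sym!r} at line {line}")
    mask = pd.notna(raw) & (raw != "NA")
    dosage[mask] = np.vectorize(ok.get, otypes=[float])(raw[mask])
    declared = None
    if alleles_path is not None:
        al = pd.read_csv(alleles_path, sep="\t", dtype=str)
        declared = al.set_index("variant_id").rename(
            columns={"allele1": "a1", "allele2": "a2"})[["a1", "a2"]]
    return GenotypeMatrix(sample_ids, variant_ids, dosage, declared)


def write_dosage_matrix(gm: GenotypeMatrix, path: str | Path,
                        alleles_path: str | Path | None = None) -> None:
    cells = np.where(np.isnan(gm.dosage), "NA",
                     gm.dosage.astype(object))
    df = pd.DataFrame(cells, columns=gm.variant_ids)
    df = df.map(lambda v: v if v == "NA" else str(int(v)))
    df.insert(0, "sample_id", gm.sample_ids)
    df.to_csv(path, sep="\t", index=False)
    if alleles_path is not None and gm.declared_alleles is not None:
        out = gm.declared_alleles.rename(columns={"a1": "allele1", "a2": "allele2"})
        out = out.rename_axis("variant_id")
        out.to_csv(alleles_path, sep="\t")


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Ingest genotypes from a VCF: GT fields become ALT-allele dosages.

    The counted allele is ALT, the other is REF, recorded in
    ``declared_alleles``.  Multi-allelic records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variant_ids, cols, a1, a2 = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        vid = rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}"
        variant_ids.append(vid)
        gts = np.asarray(rec.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        d = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        cols.append(d)
        a1.append(rec.ALT[0])
        a2.append(rec.REF)
    declared = pd.DataFrame({"a1": a1, "a2": a2}, index=variant_ids)
    return GenotypeMatrix(sample_ids, variant_ids,
                          np.column_stack(cols) if cols else
                          np.empty((len(sample_ids), 0)), declared)
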