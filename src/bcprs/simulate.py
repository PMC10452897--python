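"""Synthetic cohorts with known ground truth for every pipeline input.

The generators emulate the structure of a female breast-cancer
case/control genotyping study: biallelic dosages in Hardy–Weinberg
proportions over a minor-allele-frequency spectrum, external PRS weight
sets, registry-shaped incidence and mortality curves, and ages of onset
drawn from the proportional-hazards model h(t, z) = lambda0(t) e^{b z}
with left truncation (subjects whose outcome precedes their enrolment
age never enter the cohort) and right censoring at the last follow-up.
Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CohortTable, GenotypeMatrix, RateTable, WeightTable

_NON_PALINDROMIC = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SimulationConfig:
    """Study conditions for an end-to-end synthetic cohort.

    Defaults describe a population-scale screening-age cohort: enrolment
    around age 40, administrative censoring around the late seventies,
    and a per-SD hazard ratio of about 1.5 for the standardized PRS.
    """

    n_samples: int = 8000
    n_variants: int = 313
    maf_range: tuple[float, float] = (0.01, 0.49)
    true_b: float = float(np.log(1.494))
    entry_age_dist: tuple[float, float, float] = (40.0, 10.0, 20.0)  # mean, sd, min
    censor_age_dist: tuple[float, float] = (78.0, 8.0)               # mean, sd
    max_age: int = 90
    seed: int = 0
    effect_sd: float = 0.1
    incidence_shape: dict = field(default_factory=dict)
    case_control_target: tuple[int, int] | None = None


def simulate_genotypes(n_samples: int, n_variants: int,
                       maf_range: tuple[float, float] = (0.01, 0.49),
                       seed: int = 0,
                       missing_rate: float = 0.0,
                       n_low_maf: int = 0, low_maf: float = 0.005,
                       n_high_missing_samples: int = 0,
                       high_missing_rate: float = 0.1,
                       allow_palindromic: bool = False
                       ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Hardy–Weinberg dosage matrix with per-variant MAF ~ U(maf_range).

    Dosages count the variant's first declared allele, whose frequency is
    the drawn MAF; each dosage is two independent allele draws, i.e.
    Binomial(2, maf).  Optional planted features support QC tests: the
    first ``n_low_maf`` variants get frequency ``low_maf`` and the first
    ``n_high_missing_samples`` samples get extra missing calls at rate
    ``high_missing_rate``.  Returns the matrix and the true frequencies.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_variants)
    maf[:n_low_maf] = low_maf
    dosage = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(float)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan
    if n_high_missing_samples > 0:
        extra = rng.random((n_high_missing_samples, n_variants)) < high_missing_rate
        dosage[:n_high_missing_samples][extra] = np.nan
    pool = _NON_PALINDROMIC + (_PALINDROMIC if allow_palindromic else [])
    pairs = [pool[i] for i in rng.integers(0, len(pool), n_variants)]
    vids = [f"rs{i + 1}" for i in range(n_variants)]
    declared = pd.DataFrame({"a1": [p[0] for p in pairs],
                             "a2": [p[1] for p in pairs]}, index=vids)
    gm = GenotypeMatrix([f"S{i + 1}" for i in range(n_samples)], vids,
                        dosage, declared)
    return gm, maf


def simulate_weights(n_variants: int, effect_sd: float = 0.1, seed: int = 0,
                     variant_ids: Sequence[str] | None = None,
                     alleles: pd.DataFrame | None = None,
                     allow_palindromic: bool = False) -> WeightTable:
    """Stand-in PRS weight set with betas ~ N(0, effect_sd).

    When ``alleles`` (a declared_alleles frame) is given, the effect
    allele is each variant's first declared allele so the weights align
    with a matching genotype matrix without flips.
    """
    rng = np.random.default_rng(seed)
    vids = list(variant_ids) if variant_ids is not None else \
        [f"rs{i + 1}" for i in range(n_variants)]
    if alleles is not None:
        ea = alleles.loc[vids, "a1"].tolist()
        oa = alleles.loc[vids, "a2"].tolist()
    else:
        pool = _NON_PALINDROMIC + (_PALINDROMIC if allow_palindromic else [])
        pairs = [pool[i] for i in rng.integers(0, len(pool), n_variants)]
        ea = [p[0] for p in pairs]
        oa = [p[1] for p in pairs]
    betas = rng.normal(0.0, effect_sd, n_variants) if effect_sd > 0 \
        else np.zeros(n_variants)
    df = pd.DataFrame({
        "variant_id": vids,
        "chromosome": [str(1 + i % 22) for i in range(n_variants)],
        "position": np.arange(1, n_variants + 1) * 1000,
        "effect_allele": ea, "other_allele": oa, "beta": betas})
    return WeightTable(df)


def synthetic_rates(plateau: float = 3.3e-3, midpoint: float = 50.0,
                    scale: float = 8.0, onset_age: int = 25,
                    mort_alpha: float = 2e-5, mort_gamma: float = 0.095,
                    age_max: int = 85, bin_width: int = 5
                    ) -> tuple[RateTable, RateTable]:
    """Registry-shaped incidence and mortality stand-ins.

    Incidence is zero before ``onset_age`` and rises along a logistic
    curve toward ``plateau`` (per person-year) with the given midpoint
    and scale, the shape of Nordic female breast-cancer registry rates.
    Mortality is Gompertz, m(t) = alpha * e^{gamma t}.  Both are returned
    as rate tables on ``bin_width``-year bins covering [0, age_max), each
    bin carrying the mean of its yearly rates.
    """
    years = np.arange(0, age_max)

    def yearly_incidence(t):
        r = plateau / (1.0 + np.exp(-(t - midpoint) / scale))
        return np.where(t < onset_age, 0.0, r)

    inc_y = yearly_incidence(years.astype(float))
    mort_y = mort_alpha * np.exp(mort_gamma * years)

    lo = np.arange(0, age_max, bin_width)
    hi = np.minimum(lo + bin_width, age_max)
    inc = np.array([inc_y[l:h].mean() for l, h in zip(lo, hi)])
    mort = np.array([mort_y[l:h].mean() for l, h in zip(lo, hi)])
    return (RateTable("incidence", lo, hi, inc),
            RateTable("mortality", lo, hi, mort))


def _sample_piecewise_times(rate_table: RateTable, multiplier: np.ndarray,
                            rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF event ages from hazard rate(t) * multiplier_i.

    Draws E ~ Exp(1) per subject and solves cumhaz(t) = E / multiplier on
    the yearly step grid with linear interpolation inside the year.
    Subjects whose hazard never accumulates enough mass get +inf.
    """
    ages, rates = rate_table.yearly()
    edges = np.append(ages.astype(float), ages[-1] + 1.0)
    cum = np.concatenate([[0.0], np.cumsum(rates)])  # cumhaz at year edges
    target = rng.exponential(size=len(multiplier)) / multiplier
    idx = np.searchsorted(cum, target, side="right") - 1
    out = np.full(len(target), np.inf)
    inside = idx < len(rates)
    i = idx[inside]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (target[inside] - cum[i]) / rates[i]
    ok = np.isfinite(frac)
    vals = np.where(ok, edges[i] + frac, np.inf)
    out[inside] = vals
    return out


def simulate_onset_cohort(prs_z: np.ndarray, true_b: float,
                          lambda0: RateTable, mortality: RateTable | None,
                          config: SimulationConfig,
                          sample_ids: Sequence[str] | None = None,
                          rng: np.random.Generator | None = None
                          ) -> tuple[CohortTable, np.ndarray]:
    """Cohort with onset ages drawn from h(t, z) = lambda0(t) e^{b z}.

    Onset, death, enrolment and administrative-censoring ages are drawn
    independently; the event fires when onset precedes all of death,
    censoring and ``max_age``.  Subjects whose outcome (event or
    censoring) precedes their enrolment age are discarded, realizing left
    truncation the way a prevalent cohort arises.  Returns the cohort and
    the boolean mask of retained subjects (for aligning ``prs_z``).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z = np.asarray(prs_z, dtype=float)
    n = len(z)
    onset = _sample_piecewise_times(lambda0, np.exp(true_b * z), rng)
    if mortality is not None:
        death = _sample_piecewise_times(mortality, np.ones(n), rng)
    else:
        death = np.full(n, np.inf)
    mean_e, sd_e, min_e = config.entry_age_dist
    entry = np.maximum(rng.normal(mean_e, sd_e, n), min_e)
    mean_c, sd_c = config.censor_age_dist
    censor = rng.normal(mean_c, sd_c, n)
    end = np.minimum.reduce([death, censor, np.full(n, float(config.max_age))])
    event = onset <= end
    exit_age = np.where(event, onset, end)
    keep = exit_age > entry
    if not keep.any():
        raise ValueError("left truncation discarded the entire cohort")

    ids = list(sample_ids) if sample_ids is not None else \
        [f"S{i + 1}" for i in range(n)]
    df = pd.DataFrame({
        "sample_id": [ids[i] for i in np.flatnonzero(keep)],
        "status": np.where(event[keep], "case", "control"),
        "entry_age": entry[keep],
        "exit_age": exit_age[keep],
        "event": event[keep],
        "prs_raw": np.nan,
        "prs_z": z[keep]})

    if config.case_control_target is not None:
        n_cases, n_controls = config.case_control_target
        case_idx = np.flatnonzero(df["event"].to_numpy())
        ctrl_idx = np.flatnonzero(~df["event"].to_numpy())
        if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
            raise ValueError(
                f"cohort too small for target {config.case_control_target}: "
                f"{len(case_idx)} cases / {len(ctrl_idx)} controls available")
        sel = np.sort(np.concatenate([
            rng.choice(case_idx, n_cases, replace=False),
            rng.choice(ctrl_idx, n_controls, replace=False)]))
        df = df.iloc[sel].reset_index(drop=True)
        keep2 = np.zeros(n, dtype=bool)
        keep_pos = np.flatnonzero(keep)[sel]
        keep2[keep_pos] = True
        keep = keep2

    return CohortTable(df), keep


def simulate_cohort_end_to_end(config: SimulationConfig
                               ) -> dict:
    """Full input bundle: genotypes, weights, rates, cohort and truth.

    The cohort's PRS is the genotype-by-weight score, z-standardized, so
    the scoring, discrimination, survival and risk stages can all be run
    against known ground truth (``true_b`` per SD of the realized score).
    """
    from .scoring import compute_prs, harmonize, standardize

    rng = np.random.default_rng(config.seed)
    gm, maf = simulate_genotypes(config.n_samples, config.n_variants,
                                 config.maf_range,
                                 seed=int(rng.integers(2 ** 31)))
    weights = simulate_weights(config.n_variants, config.effect_sd,
                               seed=int(rng.integers(2 ** 31)),
                               variant_ids=gm.variant_ids,
                               alleles=gm.declared_alleles)
    incidence, mortality = synthetic_rates(**config.incidence_shape)
    aligned, _ = harmonize(weights, gm)
    scores = standardize(compute_prs(aligned))
    cohort, keep = simulate_onset_cohort(
        scores.prs_z, config.true_b, incidence, mortality, config,
        sample_ids=gm.sample_ids, rng=rng)
    df = cohort.df.copy()
    df["prs_raw"] = np.asarray(scores.prs_raw)[keep]
    cohort = CohortTable(df)
    return {"genotypes": gm, "weights": weights, "incidence": incidence,
            "mortality": mortality, "cohort": cohort, "true_maf": maf,
            "true_b": config.true_b, "keep_mask": keep}
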