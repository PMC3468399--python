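"""Permutation-based empirical null, p-values and FDR for pair DI scores.

The null model randomly rearranges class labels while keeping the original
class sizes, then reruns the full pair scan (and protein aggregation).
Because discrimination scores computed under shuffled labels carry no
biological meaning yet preserve the dependency structure among peptides,
the pooled |score| collection serves as an empirical null.  Labels are
permuted at the patient level by default: both technical replicates of a
patient move together, since replicates are not exchangeable across
patients.

For an observed score T, the empirical p-value is the fraction of null
scores >= T.  The empirical false discovery rate at threshold T is
S_null / S_true with S_true = #observed >= T and S_null the null
exceedance count rescaled to the observed-set size (null counts divided by
the number of permutations, implementing the equal-totals assumption).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import IntensityTable, PeptideProteinMap, SampleAnnotation
from .scoring import aggregate_protein_pairs, scan_peptide_pairs

log = logging.getLogger(__name__)

LEVELS = ("peptide", "protein")
PERMUTE_UNITS = ("patient", "sample")


@dataclass
class NullDistribution:
    """Absolute DI scores collected over label permutations.

    `per_perm_scores` keeps one array of |d| (peptide level) or |D|
    (protein level) per permutation, so both the pooled null and the
    per-permutation maxima (for family-wise calibrated p-values of a top
    score) are available.
    """

    level: str
    n_perm: int
    seed: int
    per_perm_scores: list = field(default_factory=list)

    @property
    def scores(self) -> np.ndarray:
        """All null |scores| pooled across permutations."""
        return np.concatenate(self.per_perm_scores)

    @property
    def n_scores(self) -> int:
        return int(sum(len(s) for s in self.per_perm_scores))

    @property
    def per_perm_max(self) -> np.ndarray:
        """Largest null |score| in each permutation."""
        return np.array([s.max() for s in self.per_perm_scores])


def permute_labels(
    annot: SampleAnnotation,
    seed: int | np.random.Generator,
    unit: str = "patient",
) -> SampleAnnotation:
    """Randomly reassign class labels, preserving class sizes.

    With ``unit='patient'`` (default) the multiset of patient labels is
    shuffled across patients, so every sample of a patient keeps a common
    label and the patient counts per class are exactly preserved.  With
    ``unit='sample'`` labels are shuffled across individual sample columns
    instead.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if unit == "patient":
        patients = annot.patient_ids
        labels = annot.class_of_patient().loc[patients].to_numpy()
        shuffled = labels[rng.permutation(len(labels))]
        return annot.with_patient_labels(dict(zip(patients, shuffled)))
    if unit == "sample":
        f = annot.frame.copy()
        labels = f["class_label"].to_numpy()
        f["class_label"] = labels[rng.permutation(len(labels))]
        # shuffled samples form singleton pseudo-patients so that patient
        # invariants (one label per patient) still hold
        f["patient_id"] = f["sample_id"]
        return SampleAnnotation(f)
    raise ValueError(f"unit must be one of {PERMUTE_UNITS}")


def build_null(
    table: IntensityTable,
    annot: SampleAnnotation,
    level: str = "protein",
    pmap: PeptideProteinMap | None = None,
    n_perm: int = 100,
    seed: int = 0,
    sd_mode: str = "sample",
    ratio_scale: str = "log",
    permute_unit: str = "patient",
) -> NullDistribution:
    """Rerun the full scan under `n_perm` label permutations.

    Each permutation re-derives the usable-pair universe from scratch
    (exclusion rules can differ between permutations), scans all peptide
    pairs and, at protein level, aggregates to protein pairs.  Collects
    the absolute scores.  Bit-reproducible given the seed.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if level == "protein" and pmap is None:
        raise ValueError("protein-level null requires a peptide-protein map")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    null = NullDistribution(level=level, n_perm=n_perm, seed=seed)
    for r in range(n_perm):
        perm = permute_labels(annot, rng, unit=permute_unit)
        scores = scan_peptide_pairs(
            table, perm, sd_mode=sd_mode, ratio_scale=ratio_scale
        )
        if level == "protein":
            scores = aggregate_protein_pairs(scores, pmap)
            null.per_perm_scores.append(scores["D"].abs().to_numpy())
        else:
            null.per_perm_scores.append(scores["d"].abs().to_numpy())
    log.info(
        "built %s-level null: %d permutations, %d scores",
        level,
        n_perm,
        null.n_scores,
    )
    return null


def empirical_pvalue(observed: float, null: NullDistribution) -> float:
    """Fraction of pooled null scores >= |observed| (no pseudocount)."""
    pooled = null.scores
    return float(np.count_nonzero(pooled >= abs(observed)) / pooled.size)


def top_score_pvalue(observed_top: float, null: NullDistribution) -> float:
    """Family-wise p-value of a top score against per-permutation maxima.

    The pooled-null p-value of a maximum over many pairs is biased small by
    construction (the observed value is itself an extreme).  Comparing
    against the distribution of the per-permutation best score gives a
    calibrated p-value: uniform on {0, 1/n_perm, ..., 1} when the labels
    carry no information.
    """
    maxima = null.per_perm_max
    return float(np.count_nonzero(maxima >= abs(observed_top)) / null.n_perm)


def empirical_fdr(
    observed_scores: np.ndarray, null: NullDistribution
) -> pd.DataFrame:
    """Empirical FDR for each observed |score| used as its own threshold T.

    Returns a frame aligned with `observed_scores` holding S_true (observed
    exceedances of T), S_null_scaled (null exceedances divided by n_perm)
    and fdr = S_null_scaled / S_true, capped at 1 for reporting.
    """
    observed = np.abs(np.asarray(observed_scores, dtype=float))
    if observed.size == 0:
        raise ValueError("observed_scores must be nonempty")
    pooled = np.sort(null.scores)
    sorted_obs = np.sort(observed)
    # counts >= T via right-side search on ascending sorts
    s_true = observed.size - np.searchsorted(sorted_obs, observed, side="left")
    s_null = (pooled.size - np.searchsorted(pooled, observed, side="left")) / null.n_perm
    fdr = np.minimum(s_null / s_true, 1.0)
    return pd.DataFrame(
        {"S_true": s_true, "S_null_scaled": s_null, "fdr": fdr},
        index=pd.RangeIndex(observed.size),
    )


def attach_significance(
    ranked: pd.DataFrame, null: NullDistribution, score_column: str = "abs_D"
) -> pd.DataFrame:
    """Add p_value and fdr columns to a ranked pair table."""
    pooled = np.sort(null.scores)
    obs = ranked[score_column].to_numpy()
    exceed = pooled.size - np.searchsorted(pooled, obs, side="left")
    out = ranked.copy()
    out["p_value"] = exceed / pooled.size
    out["fdr"] = empirical_fdr(obs, null)["fdr"].to_numpy()
    return out
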