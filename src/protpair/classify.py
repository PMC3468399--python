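"""Single-threshold ratio classifier on the top pair, with patient-grouped
leave-one-out cross-validation.

The classifier has one tunable parameter: a threshold on the peptide
abundance ratio of the selected pair.  Cross-validation leaves out all
measurements of one patient per fold (both technical replicates), refits
the entire pipeline — pair ranking included — on the remaining patients,
and predicts each held-out replicate individually.  The reported rate is
1 - e/N with e misclassifications over N tested samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateSpreadError, ProtPairError
from .io import average_replicates, filter_min_peptides
from .model import IntensityTable, PeptideProteinMap, SampleAnnotation
from .scoring import (
    aggregate_protein_pairs,
    compute_ratios,
    rank_protein_pairs,
    scan_peptide_pairs,
)

log = logging.getLogger(__name__)

ABSTAIN = "abstain"
CV_RULES = ("top-peptide", "vote")


@dataclass
class ThresholdRule:
    """One ratio threshold: predict P on `direction` side of t; ties go to C."""

    peptide_i: str
    peptide_j: str
    threshold: float
    high_is_P: bool

    def decide(self, ratio: float) -> str:
        if ratio > self.threshold:
            return "P" if self.high_is_P else "C"
        return "C" if self.high_is_P else "P"


@dataclass
class PairClassifier:
    """Fitted top-pair classifier.

    `rules` holds one threshold rule per representative peptide pair: a
    single rule under the default top-peptide strategy, one per
    constituent peptide pair under the vote strategy (majority decides,
    ties predict C).
    """

    protein_1: str
    protein_2: str
    rules: list = field(default_factory=list)

    @property
    def rep_peptide_i(self) -> str:
        return self.rules[0].peptide_i

    @property
    def rep_peptide_j(self) -> str:
        return self.rules[0].peptide_j

    @property
    def threshold(self) -> float:
        return self.rules[0].threshold


@dataclass
class CVReport:
    """Leave-one-patient-out cross-validation outcome."""

    per_sample: pd.DataFrame  # sample_id, patient_id, true, predicted
    folds: list
    e: int
    N: int
    prediction_rate: float
    n_skipped_folds: int = 0


def prediction_rate(e: int, N: int) -> float:
    """Estimated prediction rate 1 - e/N."""
    if not 0 <= e <= N:
        raise ValueError(f"need 0 <= e <= N, got e={e}, N={N}")
    return 1.0 - e / N


def _fit_threshold(ratios_C: np.ndarray, ratios_P: np.ndarray) -> tuple[float, bool]:
    """Choose the ratio threshold maximising training accuracy.

    Candidates are midpoints of adjacent sorted distinct training ratios.
    The side of the threshold predicting P is fixed first by which side
    holds the P-class median.  Accuracy ties between candidate thresholds
    break toward the midpoint with the largest margin (distance to the
    nearest training ratio).
    """
    all_ratios = np.sort(np.unique(np.concatenate([ratios_C, ratios_P])))
    if all_ratios.size < 2:
        raise DegenerateSpreadError("all training ratios identical: degenerate")
    high_is_P = bool(np.median(ratios_P) > np.median(ratios_C))
    candidates = (all_ratios[:-1] + all_ratios[1:]) / 2.0
    best = None
    for t in candidates:
        n_correct = (
            np.count_nonzero(ratios_P > t) + np.count_nonzero(ratios_C <= t)
            if high_is_P
            else np.count_nonzero(ratios_P <= t) + np.count_nonzero(ratios_C > t)
        )
        acc = n_correct / (ratios_C.size + ratios_P.size)
        margin = float(np.min(np.abs(all_ratios - t)))
        key = (acc, margin)
        if best is None or key > best[0]:
            best = (key, float(t))
    return best[1], high_is_P


def fit_pair_classifier(
    table: IntensityTable,
    annot: SampleAnnotation,
    pmap: PeptideProteinMap,
    min_peptides: int = 2,
    sd_mode: str = "sample",
    ratio_scale: str = "log",
    cv_rule: str = "top-peptide",
) -> PairClassifier:
    """Run the full ranking on training data and fit the threshold rule(s).

    Filters proteins to >= `min_peptides` peptides, scans all peptide
    pairs, aggregates and ranks protein pairs, takes the top pair, then —
    under the default top-peptide rule — picks its constituent peptide pair
    with maximal |d| as representative and fits one ratio threshold on the
    training samples.  Under the vote rule every constituent peptide pair
    gets its own threshold.
    """
    if cv_rule not in CV_RULES:
        raise ValueError(f"cv_rule must be one of {CV_RULES}")
    ftable, fmap = filter_min_peptides(table, pmap, min_peptides=min_peptides)
    scores = scan_peptide_pairs(ftable, annot, sd_mode=sd_mode, ratio_scale=ratio_scale)
    ranked = rank_protein_pairs(aggregate_protein_pairs(scores, fmap))
    top = ranked.iloc[0]
    p1, p2 = top["protein_1"], top["protein_2"]

    mapping = fmap.peptide_to_protein
    prot_i = scores["peptide_i"].map(mapping)
    prot_j = scores["peptide_j"].map(mapping)
    member = ((prot_i == p1) & (prot_j == p2)) | ((prot_i == p2) & (prot_j == p1))
    members = scores.loc[member].assign(abs_d=scores.loc[member, "d"].abs())
    members = members.sort_values(
        ["abs_d", "peptide_i", "peptide_j"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    if cv_rule == "top-peptide":
        members = members.iloc[:1]

    rules = []
    for _, row in members.iterrows():
        rs = compute_ratios(table, annot, row["peptide_i"], row["peptide_j"])
        t, high_is_P = _fit_threshold(rs.ratios_C, rs.ratios_P)
        rules.append(ThresholdRule(row["peptide_i"], row["peptide_j"], t, high_is_P))
    return PairClassifier(protein_1=p1, protein_2=p2, rules=rules)


def predict(clf: PairClassifier, table: IntensityTable, sample_id: str) -> str:
    """Classify one sample; 'abstain' when a required intensity is unusable.

    Under the vote strategy the majority over per-peptide-pair rules
    decides; vote ties predict C.  A rule whose peptide intensities are
    missing or nonpositive in the sample abstains from the vote; if every
    rule abstains the prediction is 'abstain'.
    """
    votes = []
    col = table.data[sample_id]
    for rule in clf.rules:
        a, b = col.get(rule.peptide_i, np.nan), col.get(rule.peptide_j, np.nan)
        if not (a > 0 and b > 0):
            continue
        votes.append(rule.decide(a / b))
    if not votes:
        return ABSTAIN
    n_p = votes.count("P")
    n_c = votes.count("C")
    return "P" if n_p > n_c else "C"


def loocv(
    table: IntensityTable,
    annot: SampleAnnotation,
    pmap: PeptideProteinMap,
    min_peptides: int = 2,
    sd_mode: str = "sample",
    ratio_scale: str = "log",
    cv_rule: str = "top-peptide",
    replicate_handling: str = "independent",
) -> CVReport:
    """Patient-grouped leave-one-out cross-validation.

    One fold per patient: all of that patient's samples are held out, the
    classifier (pair selection and threshold) is refit from scratch on the
    remaining patients' samples, and each held-out replicate is predicted
    and counted individually.  Abstentions count as errors, keeping N fixed
    at the full sample count.  Folds whose training data would contain a
    single class are skipped with a warning and excluded from N.
    """
    if replicate_handling not in ("independent", "average"):
        raise ValueError("replicate_handling must be 'independent' or 'average'")
    patients = annot.patient_ids
    if len(patients) < 3:
        raise ProtPairError("leave-one-out CV needs at least 3 patients")
    records = []
    folds = []
    n_skipped = 0
    truth = annot.class_of_sample()
    for patient in patients:
        test_samples = annot.samples_of_patient(patient)
        try:
            train_annot = annot.drop_patient(patient)
        except ProtPairError:
            log.warning("fold %s skipped: training would be single-class", patient)
            n_skipped += 1
            continue
        train_table = table
        if replicate_handling == "average":
            train_table, train_annot = average_replicates(table, train_annot)
        clf = fit_pair_classifier(
            train_table,
            train_annot,
            pmap,
            min_peptides=min_peptides,
            sd_mode=sd_mode,
            ratio_scale=ratio_scale,
            cv_rule=cv_rule,
        )
        folds.append(
            {
                "patient": patient,
                "protein_1": clf.protein_1,
                "protein_2": clf.protein_2,
                "rep_peptide_i": clf.rep_peptide_i,
                "rep_peptide_j": clf.rep_peptide_j,
                "threshold": clf.threshold,
            }
        )
        for sample in test_samples:
            records.append(
                {
                    "sample_id": sample,
                    "patient_id": patient,
                    "true": truth[sample],
                    "predicted": predict(clf, table, sample),
                }
            )
    per_sample = pd.DataFrame(records)
    n_total = len(per_sample)
    errors = int((per_sample["predicted"] != per_sample["true"]).sum())
    rate = prediction_rate(errors, n_total)
    log.info("LOOCV: e=%d, N=%d, prediction rate %.1f%%", errors, n_total, 100 * rate)
    return CVReport(
        per_sample=per_sample,
        folds=folds,
        e=errors,
        N=n_total,
        prediction_rate=rate,
        n_skipped_folds=n_skipped,
    )
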