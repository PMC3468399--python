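"""Pairwise-ratio discriminability scoring and protein-pair aggregation.

The central statistic is the Discriminability Index (DI) of an ordered
peptide pair (i, j).  Within each sample k the relative abundance is the
intensity ratio

    R_ijk = I_ik / I_jk,

computed only where both peak areas are strictly positive; any common
per-sample scale factor cancels, which is why no normalisation of the raw
areas is needed.  With ratio vectors R^C (controls) and R^P (progressors),

    d_ij = (median(R^C) - median(R^P)) / (sd(R^C) * sd(R^P)).

The median makes the location estimate robust to outlier peak areas; the
product of the class standard deviations penalises spread, so a large |d|
requires both separation and tight within-class ratio distributions.  Each
unordered pair is evaluated once in canonical orientation (numerator =
peptide earlier in table row order) and ranked by |d|.

By default the index is evaluated on log-ratios (``ratio_scale="log"``).
Applied to raw ratios the index carries units of 1/ratio — for a pair whose
ratios sit around a scale c, the numerator grows like c while the
denominator grows like c^2 — so raw scores are incomparable between pairs
whose peptides differ in abundance, and a ranking over a wide-dynamic-range
table is dominated by arbitrary abundance offsets and by the orientation
chosen for each pair.  Taking logs removes the scale (and makes the two
orientations exact negatives) while leaving the statistic otherwise
unchanged.  ``ratio_scale="raw"`` evaluates the literal raw-ratio form.

Protein pairs are scored by the median signed d over all cross-protein
peptide pairs: mixed directions of change cancel, so a high |D| demands
consistent same-direction discrimination across every constituent peptide
pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateSpreadError,
    InsufficientSamplesError,
    NoScorablePairsError,
    ValidationError,
)
from .model import IntensityTable, PeptideProteinMap, SampleAnnotation

log = logging.getLogger(__name__)

SD_MODES = {"sample": 1, "population": 0}
RATIO_SCALES = ("log", "raw")

#: columns of the peptide-pair score frame returned by the scans
PEPTIDE_SCORE_COLUMNS = ["peptide_i", "peptide_j", "d", "n_C", "n_P"]


def pair_count(n: int) -> int:
    """Number of unordered pairs among n items: n choose 2."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return n * (n - 1) // 2


@dataclass
class RatioSet:
    """Per-class intensity-ratio vectors for one ordered peptide pair."""

    peptide_i: str
    peptide_j: str
    ratios_C: np.ndarray
    ratios_P: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.ratios_C, self.ratios_P):
            arr = np.asarray(arr, dtype=float)
            if arr.size and not (np.isfinite(arr).all() and (arr > 0).all()):
                raise ValidationError("ratios must be strictly positive and finite")
        self.ratios_C = np.asarray(self.ratios_C, dtype=float)
        self.ratios_P = np.asarray(self.ratios_P, dtype=float)


def compute_ratios(
    table: IntensityTable,
    annot: SampleAnnotation,
    peptide_i: str,
    peptide_j: str,
) -> RatioSet:
    """Per-sample intensity ratios I_i/I_j, split by class.

    A sample contributes a ratio only when both peptides have a strictly
    positive measurement in it; samples with a missing or nonpositive value
    on either side are omitted.  Fewer than two usable samples in either
    class raises :class:`InsufficientSamplesError` (a signal, not a crash).
    """
    if peptide_i == peptide_j:
        raise ValueError("peptide_i and peptide_j must differ")
    row_i = table.data.loc[peptide_i]
    row_j = table.data.loc[peptide_j]
    out = {}
    for label in ("C", "P"):
        ratios = []
        for sample in annot.samples_of_class(label):
            a, b = row_i[sample], row_j[sample]
            if a > 0 and b > 0:  # False for NaN as well
                ratios.append(a / b)
        out[label] = np.asarray(ratios, dtype=float)
    if len(out["C"]) < 2 or len(out["P"]) < 2:
        raise InsufficientSamplesError(
            f"pair ({peptide_i}, {peptide_j}): usable samples "
            f"C={len(out['C'])}, P={len(out['P'])} (need >=2 each)"
        )
    return RatioSet(peptide_i, peptide_j, out["C"], out["P"])


def discriminability_index(
    ratios: RatioSet, sd_mode: str = "sample", ratio_scale: str = "log"
) -> float:
    """Signed DI of one peptide pair.

    (median of control ratios - median of progressor ratios) divided by
    the product of the two class standard deviations.  The median of an
    even-length vector is the mean of the two central order statistics.
    With ``ratio_scale="log"`` (default) the statistic is evaluated on the
    natural log of the ratios, making it scale-free; ``"raw"`` evaluates
    it on the ratios as given.  A zero standard deviation in either class
    makes the index undefined and raises :class:`DegenerateSpreadError`.
    """
    if ratio_scale not in RATIO_SCALES:
        raise ValueError(f"ratio_scale must be one of {RATIO_SCALES}")
    ddof = SD_MODES[sd_mode]
    rc, rp = ratios.ratios_C, ratios.ratios_P
    if ratio_scale == "log":
        rc, rp = np.log(rc), np.log(rp)
    if len(rc) < 2 or len(rp) < 2:
        raise InsufficientSamplesError("need >=2 ratios per class")
    sd_c = float(np.std(rc, ddof=ddof))
    sd_p = float(np.std(rp, ddof=ddof))
    if sd_c == 0.0 or sd_p == 0.0:
        raise DegenerateSpreadError(
            f"pair ({ratios.peptide_i}, {ratios.peptide_j}): degenerate-spread"
        )
    return float((np.median(rc) - np.median(rp)) / (sd_c * sd_p))


def _pairwise_class_stats(values: np.ndarray, ddof: int, log_mode: bool):
    """Median, SD and usable-sample count of pairwise ratios over samples.

    `values` is a (peptides x samples) array with NaN for unusable entries;
    in log mode the statistics are taken over log(V_i/V_j).  Ratios inherit
    NaN from either operand, so per-pair sample masks fall out of the
    broadcasting.  Returns three (p x p) arrays.
    """
    n_pep = values.shape[0]
    med = np.empty((n_pep, n_pep))
    sd = np.empty((n_pep, n_pep))
    count = np.empty((n_pep, n_pep), dtype=np.int64)
    chunk = max(1, int(2**24 // max(1, n_pep * values.shape[1])))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for start in range(0, n_pep, chunk):
            stop = min(start + chunk, n_pep)
            ratios = values[start:stop, None, :] / values[None, :, :]
            if log_mode:
                ratios = np.log(ratios)
            cnt = np.sum(~np.isnan(ratios), axis=2)
            # NaN-aware median via sort (NaNs sort last); even-length
            # median = mean of the two central order statistics
            srt = np.sort(ratios, axis=2)
            lo = np.take_along_axis(
                srt, (np.maximum(cnt - 1, 0) // 2)[..., None], axis=2
            )[..., 0]
            hi = np.take_along_axis(
                srt, np.where(cnt > 0, cnt // 2, 0)[..., None], axis=2
            )[..., 0]
            med[start:stop] = (lo + hi) / 2.0
            sd[start:stop] = np.nanstd(ratios, axis=2, ddof=ddof)
            count[start:stop] = cnt
    return med, sd, count


def scan_peptide_pairs(
    table: IntensityTable,
    annot: SampleAnnotation,
    sd_mode: str = "sample",
    ratio_scale: str = "log",
) -> pd.DataFrame:
    """Exhaustive DI scan over all unordered peptide pairs.

    Evaluates every pair once in canonical orientation (numerator = row
    earlier in the table) and returns a frame with columns
    ``peptide_i, peptide_j, d, n_C, n_P`` in enumeration order.  Pairs with
    fewer than two usable samples in either class or with a zero ratio
    standard deviation are excluded; exclusion counts are logged.  The scan
    is deterministic and, pair for pair, identical to scoring each pair
    individually with :func:`compute_ratios` + :func:`discriminability_index`.
    """
    if ratio_scale not in RATIO_SCALES:
        raise ValueError(f"ratio_scale must be one of {RATIO_SCALES}")
    peptides = table.peptide_ids
    if len(peptides) < 2:
        raise NoScorablePairsError("need at least two peptides to form a pair")
    ddof = SD_MODES[sd_mode]
    sub = table.subset_samples(annot.sample_ids)
    values = sub.positive_values()
    class_of = annot.class_of_sample()
    col_classes = np.array([class_of[s] for s in sub.sample_ids])

    stats = {
        lab: _pairwise_class_stats(
            values[:, col_classes == lab], ddof, log_mode=ratio_scale == "log"
        )
        for lab in ("C", "P")
    }
    med_c, sd_c, n_c = stats["C"]
    med_p, sd_p, n_p = stats["P"]

    iu, ju = np.triu_indices(len(peptides), k=1)
    enough = (n_c[iu, ju] >= 2) & (n_p[iu, ju] >= 2)
    with np.errstate(invalid="ignore"):
        spread_ok = (sd_c[iu, ju] > 0) & (sd_p[iu, ju] > 0)
    usable = enough & spread_ok
    n_insufficient = int((~enough).sum())
    n_degenerate = int((enough & ~spread_ok).sum())
    if not usable.any():
        raise NoScorablePairsError("no scorable pairs in table")

    ii, jj = iu[usable], ju[usable]
    d = (med_c[ii, jj] - med_p[ii, jj]) / (sd_c[ii, jj] * sd_p[ii, jj])
    pep = np.asarray(peptides, dtype=object)
    scores = pd.DataFrame(
        {
            "peptide_i": pep[ii],
            "peptide_j": pep[jj],
            "d": d,
            "n_C": n_c[ii, jj],
            "n_P": n_p[ii, jj],
        }
    )
    log.info(
        "scanned %d pairs: %d scored, %d excluded (insufficient-samples), "
        "%d excluded (degenerate-spread)",
        pair_count(len(peptides)),
        len(scores),
        n_insufficient,
        n_degenerate,
    )
    return scores


def scan_feature_pairs(
    table: IntensityTable,
    annot: SampleAnnotation,
    sd_mode: str = "sample",
    ratio_scale: str = "log",
) -> pd.DataFrame:
    """DI scan over MS1 feature pairs; no peptide->protein map required.

    Identical contract to :func:`scan_peptide_pairs` with feature ids in
    place of peptide ids, for pair discovery directly on aligned MS1
    isotopic features before any identification step.
    """
    return scan_peptide_pairs(table, annot, sd_mode=sd_mode, ratio_scale=ratio_scale)


def rank_peptide_pairs(scores: pd.DataFrame) -> pd.DataFrame:
    """Sort a peptide-pair score frame by |d| descending (deterministic)."""
    out = scores.assign(abs_d=scores["d"].abs())
    out = out.sort_values(
        ["abs_d", "peptide_i", "peptide_j"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return out.reset_index(drop=True)


def aggregate_protein_pairs(
    scores: pd.DataFrame,
    pmap: PeptideProteinMap,
) -> pd.DataFrame:
    """Median-aggregate peptide-pair DI scores into protein-pair scores.

    For every unordered protein pair (P1, P2) with at least one usable
    cross-protein peptide pair, D is the median of the signed d over all
    contributing peptide pairs, with orientation harmonised so that
    peptide_i's protein is protein_1 (protein_1 = lexicographically smaller
    id; contributions listed the other way round enter with flipped sign).
    Intra-protein peptide pairs never contribute.  Columns:
    ``protein_1, protein_2, D, abs_D, n_peptide_pairs, direction_consistency``.
    """
    mapping = pmap.peptide_to_protein
    unmapped = sorted(
        set(scores["peptide_i"]).union(scores["peptide_j"]) - set(mapping.index)
    )
    if unmapped:
        raise ValidationError(f"unmapped peptide id(s) in scores: {unmapped}")

    prot_i = scores["peptide_i"].map(mapping)
    prot_j = scores["peptide_j"].map(mapping)
    cross = prot_i != prot_j
    if not cross.any():
        raise NoScorablePairsError("no cross-protein peptide pairs to aggregate")

    sub = scores.loc[cross]
    pi, pj = prot_i[cross], prot_j[cross]
    flip = pi > pj
    protein_1 = pi.where(~flip, pj)
    protein_2 = pj.where(~flip, pi)
    d_harmonised = sub["d"].where(~flip, -sub["d"])

    frame = pd.DataFrame(
        {"protein_1": protein_1, "protein_2": protein_2, "d": d_harmonised}
    )
    grouped = frame.groupby(["protein_1", "protein_2"], sort=True)
    out = grouped["d"].agg(D="median", n_peptide_pairs="size").reset_index()
    # consistency: fraction of contributing d sharing the sign of D
    # (for D == 0 the "shared sign" is 0, i.e. the fraction of exact zeros)
    d_med = grouped["d"].transform("median").to_numpy()
    shares = np.sign(frame["d"].to_numpy()) == np.sign(d_med)
    out["direction_consistency"] = (
        pd.Series(shares, index=frame.index)
        .groupby([frame["protein_1"], frame["protein_2"]], sort=True)
        .mean()
        .to_numpy()
    )
    out["abs_D"] = out["D"].abs()
    out = out[
        ["protein_1", "protein_2", "D", "abs_D", "n_peptide_pairs",
         "direction_consistency"]
    ]
    log.info(
        "aggregated %d cross-protein peptide pairs into %d protein pairs",
        int(cross.sum()),
        len(out),
    )
    return out


def rank_protein_pairs(pairs: pd.DataFrame) -> pd.DataFrame:
    """Rank protein pairs by |D| descending.

    Ties break by n_peptide_pairs descending, then lexicographic protein
    ids, so the ordering is fully deterministic.  Adds a ``direction``
    column naming the protein whose relative abundance is higher in
    progressors (reported tables orient each pair so the up-in-P member
    comes first; the signed D keeps the canonical orientation).
    """
    if len(pairs) == 0:
        raise NoScorablePairsError("cannot rank an empty protein-pair list")
    out = pairs.sort_values(
        ["abs_D", "n_peptide_pairs", "protein_1", "protein_2"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    # D < 0 means protein_1/protein_2 is lower in controls than progressors
    # would require; D > 0 means the ratio is higher in controls.
    out["up_in_P"] = np.where(out["D"] < 0, out["protein_1"], out["protein_2"])
    return out
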