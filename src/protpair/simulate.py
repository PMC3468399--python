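"""Synthetic two-class proteomics cohorts with planted co-dysregulated pairs.

The generator emulates the statistical structure the pairwise-ratio method
assumes in label-free plasma proteomics: positive peak areas spanning
several orders of magnitude, patient-level biological variation, technical
replicate noise, occasional missing measurements, and a small set of
protein pairs whose relative abundance shifts consistently between the two
classes.

Model, all on the natural-log scale.  Each protein draws a base abundance
from N(loc, scale).  For each patient the protein's abundance is
base + class effect (planted proteins only, applied in progressors) +
biological noise.  Each peptide of the protein adds a fixed response
factor (ionisation/digestion efficiency offset) and, per technical
replicate, independent replicate noise.  Intensities are exponentiated and
then masked missing completely at random.  A planted pair perturbs one
protein up and its partner down by the stated log effect, producing the
anti-correlated ratio signature the scan is designed to find.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as ppio
from .model import IntensityTable, PeptideProteinMap, SampleAnnotation


def _default_planted() -> list:
    return [("PROT001", "PROT002", 1.0)]


@dataclass
class SimConfig:
    """Cohort design and noise model.

    Defaults mirror a small clinical discovery cohort: 8 control and 13
    progressor patients, 2 technical replicates each, 50 proteins with
    2-4 peptides, and one planted anti-correlated protein pair at
    +/- 1.0 natural-log effect.  Technical noise (sd 0.15, ~15% CV) and
    biological noise (sd 0.4, ~40% CV) are on the log scale; the base
    abundance scale 2.3 spans roughly four orders of magnitude of peak
    area across proteins.
    """

    n_control: int = 8
    n_progressor: int = 13
    n_replicates: int = 2
    n_proteins: int = 50
    peptides_per_protein: tuple = (2, 4)  # inclusive range
    log_intensity_loc: float = 13.8  # ~1e6 peak-area units
    log_intensity_scale: float = 2.3
    response_factor_sd: float = 1.0
    planted_pairs: list = field(default_factory=_default_planted)
    biological_noise_sd: float = 0.4
    replicate_noise_sd: float = 0.15
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_progressor", "n_replicates", "n_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.peptides_per_protein
        if not (1 <= lo <= hi):
            raise ValueError("peptides_per_protein must be an increasing range >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for up, down, effect in self.planted_pairs:
            if not np.isfinite(effect):
                raise ValueError(f"non-finite effect for planted pair ({up}, {down})")


@dataclass
class GroundTruth:
    """What was planted: signed protein effects and peptide response factors."""

    planted_pairs: list  # (protein_up, protein_down, log_effect)
    protein_effects: dict  # protein_id -> signed log effect in progressors
    response_factors: dict  # peptide_id -> log response factor


def generate_cohort(
    cfg: SimConfig,
) -> tuple[IntensityTable, SampleAnnotation, PeptideProteinMap, GroundTruth]:
    """Draw one cohort; bit-reproducible for a given config (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)

    proteins = [f"PROT{k + 1:03d}" for k in range(cfg.n_proteins)]
    known = {p for up, down, _ in cfg.planted_pairs for p in (up, down)}
    unknown = sorted(known - set(proteins))
    if unknown:
        raise ValueError(f"planted protein(s) not in cohort: {unknown}")

    effects = dict.fromkeys(proteins, 0.0)
    for up, down, effect in cfg.planted_pairs:
        effects[up] += float(effect)
        effects[down] -= float(effect)

    lo, hi = cfg.peptides_per_protein
    n_peps = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    peptides, parents = [], []
    for prot, k in zip(proteins, n_peps):
        for t in range(int(k)):
            peptides.append(f"{prot}_pep{t + 1}")
            parents.append(prot)
    pmap = PeptideProteinMap(pd.Series(parents, index=peptides, name="protein_id"))

    patients = [f"C{k + 1:02d}" for k in range(cfg.n_control)]
    patients += [f"P{k + 1:02d}" for k in range(cfg.n_progressor)]
    classes = ["C"] * cfg.n_control + ["P"] * cfg.n_progressor
    sample_ids, sample_patient, sample_class, sample_rep = [], [], [], []
    for patient, label in zip(patients, classes):
        for r in range(cfg.n_replicates):
            sample_ids.append(f"{patient}_r{r + 1}")
            sample_patient.append(patient)
            sample_class.append(label)
            sample_rep.append(r + 1)
    annot = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": sample_patient,
                "class_label": sample_class,
                "replicate_index": sample_rep,
            }
        )
    )

    n_prot, n_pat, n_pep_total = cfg.n_proteins, len(patients), len(peptides)
    base = rng.normal(cfg.log_intensity_loc, cfg.log_intensity_scale, size=n_prot)
    response = rng.normal(0.0, cfg.response_factor_sd, size=n_pep_total)
    effect_vec = np.array([effects[p] for p in proteins])
    is_progressor = np.array([c == "P" for c in classes], dtype=float)

    # patient-level protein abundance (protein x patient), log scale
    bio = rng.normal(0.0, cfg.biological_noise_sd, size=(n_prot, n_pat))
    prot_abund = base[:, None] + effect_vec[:, None] * is_progressor[None, :] + bio

    parent_idx = np.array([proteins.index(p) for p in parents])
    pep_patient = prot_abund[parent_idx, :] + response[:, None]
    # expand patients to replicate sample columns, add technical noise
    patient_of_sample = np.array([patients.index(p) for p in sample_patient])
    log_intensity = pep_patient[:, patient_of_sample] + rng.normal(
        0.0, cfg.replicate_noise_sd, size=(n_pep_total, len(sample_ids))
    )
    intensity = np.exp(log_intensity)
    if cfg.missing_rate > 0:
        mask = rng.random(intensity.shape) < cfg.missing_rate
        intensity[mask] = np.nan

    table = IntensityTable(
        pd.DataFrame(intensity, index=peptides, columns=sample_ids)
    )
    truth = GroundTruth(
        planted_pairs=[tuple(p) for p in cfg.planted_pairs],
        protein_effects=effects,
        response_factors=dict(zip(peptides, response.tolist())),
    )
    return table, annot, pmap, truth


def write_fixture(
    cohort: tuple,
    directory,
    delimiter: str | None = None,
) -> dict:
    """Write the three TSVs plus a ground-truth JSON; returns the paths.

    The tables round-trip exactly through the package loaders.
    """
    table, annot, pmap, truth = cohort
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": directory / "intensities.tsv",
        "annotation": directory / "annotation.tsv",
        "peptide_map": directory / "peptide_map.tsv",
        "ground_truth": directory / "ground_truth.json",
    }
    ppio.write_intensity_table(table, paths["intensities"], delimiter=delimiter)
    ppio.write_annotation(annot, paths["annotation"], delimiter=delimiter)
    ppio.write_peptide_protein_map(pmap, paths["peptide_map"], delimiter=delimiter)
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(asdict(truth), fh, indent=2)
    return paths
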