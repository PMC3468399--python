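"""Core data containers: intensity matrix, sample annotation, peptide-protein map.

Intensities are raw peak areas integrated from selected ion chromatograms;
no normalisation or transformation is applied anywhere in the package, so
the containers store the numbers exactly as read.  Missing measurements are
held as NaN; zeros are accepted on input but treated as missing wherever a
ratio would be formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

CLASS_LABELS = ("C", "P")


@dataclass
class IntensityTable:
    """Peptide-by-sample matrix of raw peak areas.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by peptide (or MS1 feature) id, columns by sample id.
        Values are nonnegative floats; NaN marks a missing measurement.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate peptide id(s): {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        values = self.data.to_numpy(dtype=float)
        bad = np.isfinite(values) & (values < 0)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"negative intensity at peptide {idx[r]!r}, sample {cols[c]!r}"
            )
        if np.isinf(values).any():
            raise ValidationError("non-finite intensity encountered")
        self.data = self.data.astype(float)

    @property
    def peptide_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_peptides(self, peptides) -> "IntensityTable":
        return IntensityTable(self.data.loc[list(peptides)])

    def subset_samples(self, samples) -> "IntensityTable":
        return IntensityTable(self.data[list(samples)])

    def positive_values(self) -> np.ndarray:
        """Matrix with nonpositive and missing entries replaced by NaN.

        Ratios are defined only for strictly positive peak areas, so this
        is the canonical analysis view of the table.
        """
        values = self.data.to_numpy(dtype=float).copy()
        values[~(values > 0)] = np.nan
        return values


@dataclass
class SampleAnnotation:
    """Sample -> patient -> class mapping for a two-class cohort.

    Class labels are 'C' (control) and 'P' (progressor).  Technical
    replicates of one patient are distinct samples sharing the patient's
    class label.
    """

    frame: pd.DataFrame  # columns: sample_id, patient_id, class_label, replicate_index

    REQUIRED = ("sample_id", "patient_id", "class_label", "replicate_index")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"annotation missing column(s): {missing}")
        f = self.frame.reset_index(drop=True).copy()
        f["sample_id"] = f["sample_id"].astype(str)
        f["patient_id"] = f["patient_id"].astype(str)
        f["class_label"] = f["class_label"].astype(str)
        f["replicate_index"] = f["replicate_index"].astype(int)
        if f["sample_id"].duplicated().any():
            dups = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample id(s) in annotation: {dups}")
        bad_labels = sorted(set(f["class_label"]) - set(CLASS_LABELS))
        if bad_labels:
            raise ValidationError(
                f"class label(s) {bad_labels} outside {set(CLASS_LABELS)}"
            )
        per_patient = f.groupby("patient_id")["class_label"].nunique()
        inconsistent = per_patient[per_patient > 1].index.tolist()
        if inconsistent:
            raise ValidationError(
                f"patient(s) with inconsistent class labels: {inconsistent}"
            )
        if (f["replicate_index"] < 1).any():
            raise ValidationError("replicate_index must be a positive integer")
        n_patients = self.patient_classes(f)
        for lab in CLASS_LABELS:
            if n_patients.get(lab, 0) < 2:
                raise ValidationError(
                    "both classes required with >=2 patients each; "
                    f"got patient counts {dict(n_patients)}"
                )
        self.frame = f

    @staticmethod
    def patient_classes(frame: pd.DataFrame) -> pd.Series:
        """Number of patients per class label."""
        return frame.drop_duplicates("patient_id")["class_label"].value_counts()

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    @property
    def patient_ids(self) -> list[str]:
        return self.frame["patient_id"].drop_duplicates().tolist()

    def class_of_sample(self) -> pd.Series:
        return self.frame.set_index("sample_id")["class_label"]

    def class_of_patient(self) -> pd.Series:
        return self.frame.drop_duplicates("patient_id").set_index("patient_id")[
            "class_label"
        ]

    def samples_of_patient(self, patient_id: str) -> list[str]:
        f = self.frame
        return f.loc[f["patient_id"] == str(patient_id), "sample_id"].tolist()

    def samples_of_class(self, label: str) -> list[str]:
        f = self.frame
        return f.loc[f["class_label"] == label, "sample_id"].tolist()

    def class_counts(self) -> dict:
        """Patient and sample counts per class, for audit logging."""
        by_patient = self.patient_classes(self.frame).to_dict()
        by_sample = self.frame["class_label"].value_counts().to_dict()
        return {"patients": by_patient, "samples": by_sample}

    def drop_patient(self, patient_id: str) -> "SampleAnnotation":
        f = self.frame[self.frame["patient_id"] != str(patient_id)]
        return SampleAnnotation(f.reset_index(drop=True))

    def with_patient_labels(self, labels: dict) -> "SampleAnnotation":
        """Return a copy with class labels replaced patient-wise."""
        f = self.frame.copy()
        f["class_label"] = f["patient_id"].map(labels)
        if f["class_label"].isna().any():
            raise ValidationError("patient label map does not cover all patients")
        return SampleAnnotation(f)


@dataclass
class PeptideProteinMap:
    """Many-to-one assignment of peptides to proteins.

    Upstream ambiguity resolution (peptides matching several database
    entries) is assumed done; each peptide carries exactly one protein id.
    """

    peptide_to_protein: pd.Series  # index: peptide_id, value: protein_id
    protein_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.peptide_to_protein
        if s.index.has_duplicates:
            conflicts = (
                s.groupby(level=0).nunique().loc[lambda x: x > 1].index.tolist()
            )
            if conflicts:
                raise ValidationError(
                    f"peptide(s) mapped to multiple proteins: {conflicts}"
                )
            s = s[~s.index.duplicated()]
        self.peptide_to_protein = s.astype(str)
        self.peptide_to_protein.index = self.peptide_to_protein.index.astype(str)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.peptide_to_protein.index)

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self.peptide_to_protein.unique())

    def protein_of(self, peptide_id: str) -> str:
        return self.peptide_to_protein[str(peptide_id)]

    def peptides_of(self, protein_id: str) -> list[str]:
        s = self.peptide_to_protein
        return list(s.index[s == str(protein_id)])

    def subset(self, peptides) -> "PeptideProteinMap":
        keep = [p for p in self.peptide_to_protein.index if p in set(map(str, peptides))]
        return PeptideProteinMap(self.peptide_to_protein.loc[keep], self.protein_names)
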