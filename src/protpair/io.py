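"""Readers and writers for the three plain-text input tables.

All files are delimited text (TSV by default, CSV by extension or flag),
UTF-8, with the intensity table fixed as peptides-in-rows.  The missing
value token defaults to "NA"; raw peak areas are never normalised on the
way in.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .model import IntensityTable, PeptideProteinMap, SampleAnnotation

log = logging.getLogger(__name__)

DEFAULT_MISSING = "NA"


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_intensity_table(
    path,
    delimiter: str | None = None,
    missing_token: str = DEFAULT_MISSING,
) -> IntensityTable:
    """Read a peptide-by-sample peak-area matrix.

    First column holds peptide ids, header row holds sample ids.  Cells
    equal to `missing_token` become NaN; negative values are rejected.
    Row and column order are preserved as in the file.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=0,
        na_values=[missing_token],
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"non-numeric intensity cell in {path}: {exc}") from exc
    table = IntensityTable(df)
    log.info("loaded intensity table %s: %d peptides x %d samples", path, *table.shape)
    return table


def write_intensity_table(
    table: IntensityTable,
    path,
    delimiter: str | None = None,
    missing_token: str = DEFAULT_MISSING,
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    out = table.data.copy()
    out.index.name = "peptide_id"
    out.to_csv(path, sep=sep, na_rep=missing_token)


def load_annotation(path, delimiter: str | None = None) -> SampleAnnotation:
    """Read the sample annotation table.

    Requires columns sample_id, patient_id, class_label, replicate_index;
    class labels must be 'C' or 'P' and consistent within a patient.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    annot = SampleAnnotation(frame)
    log.info("loaded annotation %s: class counts %s", path, annot.class_counts())
    return annot


def write_annotation(annot: SampleAnnotation, path, delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    annot.frame.to_csv(path, sep=sep, index=False)


def load_peptide_protein_map(path, delimiter: str | None = None) -> PeptideProteinMap:
    """Read the peptide -> protein assignment table.

    Requires columns peptide_id and protein_id; an optional protein_name
    column supplies descriptive names.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    frame = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("peptide_id", "protein_id"):
        if col not in frame.columns:
            raise ValidationError(f"mapping file missing column {col!r}")
    mapping = frame.set_index("peptide_id")["protein_id"]
    names = {}
    if "protein_name" in frame.columns:
        names = (
            frame.dropna(subset=["protein_name"])
            .drop_duplicates("protein_id")
            .set_index("protein_id")["protein_name"]
            .to_dict()
        )
    return PeptideProteinMap(mapping, names)


def write_peptide_protein_map(
    pmap: PeptideProteinMap, path, delimiter: str | None = None
) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    frame = pmap.peptide_to_protein.rename("protein_id").rename_axis("peptide_id")
    frame = frame.reset_index()
    if pmap.protein_names:
        frame["protein_name"] = frame["protein_id"].map(pmap.protein_names)
    frame.to_csv(path, sep=sep, index=False)


def filter_min_peptides(
    table: IntensityTable,
    pmap: PeptideProteinMap,
    min_peptides: int = 2,
) -> tuple[IntensityTable, PeptideProteinMap]:
    """Drop proteins supported by fewer than `min_peptides` peptides.

    Protein-level confidence filter: only proteins identified by at least
    `min_peptides` peptides present in the table are kept.  Peptides of
    dropped proteins, and peptides with no protein assignment at all, are
    removed from the returned table (unmapped peptides remain usable in
    feature-level scans of the original table).  Sample columns are
    unchanged.  The operation is idempotent.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    assigned = pmap.peptide_to_protein
    in_table = [p for p in table.peptide_ids if p in assigned.index]
    counts = assigned.loc[in_table].value_counts()
    kept_proteins = set(counts[counts >= min_peptides].index)
    kept_peptides = [p for p in in_table if assigned[p] in kept_proteins]
    out_table = table.subset_peptides(kept_peptides)
    out_map = PeptideProteinMap(assigned.loc[kept_peptides], pmap.protein_names)
    log.info(
        "min-peptide filter (>=%d): %d -> %d proteins, %d -> %d peptides",
        min_peptides,
        len(counts),
        len(kept_proteins),
        len(table.peptide_ids),
        len(kept_peptides),
    )
    return out_table, out_map


def average_replicates(
    table: IntensityTable, annot: SampleAnnotation
) -> tuple[IntensityTable, SampleAnnotation]:
    """Collapse technical replicates to one patient-level column each.

    Replicate peak areas are arithmetically averaged, ignoring missing
    entries.  Off by default throughout the package: replicates are
    normally treated as independent samples.
    """
    cols = {}
    for patient in annot.patient_ids:
        samples = annot.samples_of_patient(patient)
        cols[patient] = table.data[samples].mean(axis=1, skipna=True)
    avg = pd.DataFrame(cols)
    classes = annot.class_of_patient()
    frame = pd.DataFrame(
        {
            "sample_id": list(avg.columns),
            "patient_id": list(avg.columns),
            "class_label": [classes[p] for p in avg.columns],
            "replicate_index": 1,
        }
    )
    return IntensityTable(avg), SampleAnnotation(frame)
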