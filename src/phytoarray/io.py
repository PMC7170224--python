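"""Readers and writers for the pipeline's tab-delimited files.

Dialect: UTF-8, single header row, tab separators, ``#`` comment lines.
The GEO series-matrix reader handles the plain-text deposition format
(``!``-prefixed metadata lines followed by a ``!series_matrix_table_begin``
block) without any network access; the user supplies the file.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ArrayDesign, FormatError, IntegrityError, SampleSheet

log = logging.getLogger(__name__)

_READ_KW = dict(sep="\t", comment="#", dtype=str)

DESIGN_COLUMNS = ["probe_id", "target_id", "gene", "process", "strain_id",
                  "phylogroup", "ecotype", "control_role"]


def _read_table(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **_READ_KW)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise FormatError(str(exc)) from exc


def read_design(path: str | Path) -> ArrayDesign:
    """Read a probe-annotation table into an :class:`ArrayDesign`.

    One row per probe. Control probes have a non-empty ``control_role`` and
    empty target fields; annotated probes carry the full
    target/strain/phylogroup annotation.
    """
    df = _read_table(path)
    missing = {"probe_id", "target_id"} - set(df.columns)
    if missing:
        raise FormatError(f"design file missing columns: {sorted(missing)}")
    for col in DESIGN_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df.fillna("")
    is_control = df["control_role"] != ""
    controls = (df.loc[is_control, ["probe_id", "control_role"]]
                .rename(columns={"control_role": "role"}))
    annotated = df.loc[~is_control]
    if (annotated["target_id"] == "").any():
        raise IntegrityError("non-control probe without target_id")
    orphan = annotated[(annotated["strain_id"] == "")
                       | (annotated["phylogroup"] == "")]
    if len(orphan):
        raise IntegrityError(
            f"{len(orphan)} probes map to targets with no strain/phylogroup "
            f"annotation, e.g. {orphan['probe_id'].head(3).tolist()}")
    probes = annotated[["probe_id", "target_id"]]
    targets = (annotated[["target_id", "gene", "process", "strain_id",
                          "phylogroup", "ecotype"]]
               .drop_duplicates())
    if targets["target_id"].duplicated().any():
        raise IntegrityError("target_id annotated inconsistently across probes")
    design = ArrayDesign(probes=probes, targets=targets, controls=controls)
    log.info("read design: %d probes, %d targets, %d strains, %d controls",
             len(design.probes), len(design.targets),
             design.targets["strain_id"].nunique(), len(design.controls))
    return design


def write_design(design: ArrayDesign, path: str | Path) -> None:
    ann = design.probes.merge(design.targets, on="target_id", how="left")
    ann["control_role"] = ""
    ctrl = design.controls.rename(columns={"role": "control_role"})
    for col in DESIGN_COLUMNS:
        if col not in ctrl.columns:
            ctrl[col] = ""
    out = pd.concat([ann[DESIGN_COLUMNS], ctrl[DESIGN_COLUMNS]],
                    ignore_index=True)
    out.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> SampleSheet:
    df = _read_table(path)
    if "replicate" in df.columns:
        df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def write_samples(sheet: SampleSheet, path: str | Path) -> None:
    sheet.samples.to_csv(path, sep="\t", index=False)


def read_intensities(path: str | Path, design: ArrayDesign | None = None
                     ) -> pd.DataFrame:
    """Read a probe × sample matrix of raw linear intensities.

    Values must be strictly positive and numeric. Probes absent from the
    design are dropped with a logged count (annotation drift is common on
    environmental arrays); known probes are returned in design order where
    possible.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    mat = df.apply(pd.to_numeric, errors="coerce")
    if mat.isna().any().any():
        bad = mat.isna().sum().sum()
        raise ValueError(f"{bad} non-numeric intensity cells")
    if (mat.values <= 0).any():
        n = int((mat.values <= 0).sum())
        raise ValueError(f"{n} non-positive intensity cells (raw intensities "
                         "must be strictly positive)")
    mat.index = mat.index.astype(str)
    mat.index.name = "probe_id"
    if design is not None:
        known = set(design.probe_ids) | set(design.controls["probe_id"])
        extra = [p for p in mat.index if p not in known]
        if extra:
            log.warning("dropping %d probes absent from design", len(extra))
            mat = mat.drop(index=extra)
    return mat


def write_intensities(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", float_format="%.12g")


def write_matrix(mat: pd.DataFrame, path: str | Path) -> None:
    """Write a numeric matrix with stable float formatting (determinism)."""
    mat.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# GEO series matrix
# ---------------------------------------------------------------------------

#: Regex table mapping sample title/characteristics text to metadata.
#: Patterns are tried in order; first hit wins. Unmatched samples are an
#: error, never a guess.
TREATMENT_PATTERNS: list[tuple[str, str]] = [
    (r"N\s*\+\s*Fe|NFe|NplusFe", "NplusFe"),
    (r"NO3|nitrate", "NO3"),
    (r"NH4|ammonium", "NH4"),
    (r"urea", "urea"),
    (r"FDW|deep\s*water", "FDW"),
    (r"Fe|iron", "Fe"),
    (r"control|ctrl", "control"),
]
TIMEPOINT_PATTERN = re.compile(r"\bT(0|24)\b", re.IGNORECASE)
REPLICATE_PATTERN = re.compile(r"rep(?:licate)?[ _]?(\d+)", re.IGNORECASE)


def parse_sample_description(text: str) -> tuple[str, str, int]:
    """Extract (timepoint, treatment, replicate) from a GEO sample title."""
    m = TIMEPOINT_PATTERN.search(text)
    if not m:
        raise FormatError(f"cannot parse timepoint from sample text: {text!r}")
    timepoint = f"T{m.group(1)}"
    treatment = None
    for pat, name in TREATMENT_PATTERNS:
        if re.search(pat, text, re.IGNORECASE):
            treatment = name
            break
    if treatment is None:
        raise FormatError(f"cannot parse treatment from sample text: {text!r}")
    r = REPLICATE_PATTERN.search(text)
    replicate = int(r.group(1)) if r else 1
    return timepoint, treatment, replicate


def read_geo_series_matrix(path: str | Path
                           ) -> tuple[pd.DataFrame, SampleSheet, str]:
    """Parse a GEO series-matrix text file.

    Returns the expression/intensity matrix (probe or gene rows × samples),
    the sample sheet parsed from sample titles, and the recorded matrix
    level (``"processed"`` — series matrices carry the submitter-normalized
    values; the exact normalization state is recorded, not re-inferred).
    """
    titles: list[str] = []
    accessions: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_begin = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                saw_begin = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_title"):
                titles = [t.strip().strip('"') for t in line.split("\t")[1:]]
            elif line.startswith("!Sample_geo_accession"):
                accessions = [t.strip().strip('"') for t in line.split("\t")[1:]]
    if not saw_begin:
        raise FormatError("missing !series_matrix_table_begin")
    if not table_lines:
        raise FormatError("empty series matrix table")
    header = [h.strip('"') for h in table_lines[0].split("\t")]
    rows = [ln.split("\t") for ln in table_lines[1:] if ln]
    mat = pd.DataFrame(rows, columns=header).set_index(header[0])
    mat = mat.apply(pd.to_numeric, errors="coerce")
    if not titles:
        raise FormatError("missing !Sample_title line")
    if len(titles) != mat.shape[1]:
        raise FormatError("sample title count does not match matrix columns")
    ids = accessions if len(accessions) == mat.shape[1] else list(mat.columns)
    records = []
    for sid, title in zip(ids, titles):
        tp, tr, rep = parse_sample_description(title)
        records.append((sid, tp, tr, rep))
    sheet = SampleSheet(pd.DataFrame(
        records, columns=["sample_id", "timepoint", "treatment", "replicate"]),
        strict=False)
    mat.columns = ids
    log.info("GEO series matrix: %d rows x %d samples", *mat.shape)
    return mat, sheet, "processed"
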