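"""Standard-format I/O: mzTab (documented subset), MSstats and Triqler exports.

The mzTab writer emits a subset of mzTab 1.0: an MTD block (version/mode/type
first), then PRT, PEP and PSM sections, each with its own header line
(PRH/PEH/PSH) and exactly as many fields per row as the header.  Missing
values are serialized as the literal ``null``; floats use the fixed ``%.6g``
format so identical inputs produce byte-identical files.  Columns outside the
mzTab 1.0 core use the ``opt_`` prefix.  ``read_mztab`` is the exact inverse
of ``write_mztab`` on its own output.

The MSstats export is the canonical ten-column table (ProteinName ...
Intensity); the isobaric dialect replaces IsotopeLabelType with Channel.
The Triqler export carries run, condition, charge, searchScore (1 - PEP),
intensity, peptide and the whitespace-joined protein accessions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .id_scoring import PsmRecord
from .protein_inference import ProteinGroup

__all__ = [
    "MzTabDocument",
    "MzTabError",
    "ExportError",
    "write_mztab",
    "read_mztab",
    "protein_table",
    "psm_table",
    "export_msstats",
    "export_triqler",
    "MSSTATS_COLUMNS",
    "TRIQLER_COLUMNS",
]

FLOAT_FMT = "%.6g"
NULL = "null"


class MzTabError(ValueError):
    """Malformed mzTab content or unserializable input."""


class ExportError(ValueError):
    """Export cannot be produced (e.g. a run without condition annotation)."""


def _fmt(value) -> str:
    if value is None:
        return NULL
    if isinstance(value, float):
        if np.isnan(value):
            return NULL
        return FLOAT_FMT % value
    if isinstance(value, (np.floating,)):
        return _fmt(float(value))
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


@dataclass
class MzTabDocument:
    """Parsed mzTab: ordered metadata plus one table per section."""

    metadata: dict[str, str] = field(default_factory=dict)
    proteins: pd.DataFrame = field(default_factory=pd.DataFrame)
    peptides: pd.DataFrame = field(default_factory=pd.DataFrame)
    psms: pd.DataFrame = field(default_factory=pd.DataFrame)


_DEFAULT_MTD = (
    ("mzTab-version", "1.0.0"),
    ("mzTab-mode", "Summary"),
    ("mzTab-type", "Quantification"),
    ("description", "quantcore export"),
)


def _sort_section(df: pd.DataFrame, keys: tuple[str, ...]) -> pd.DataFrame:
    present = [k for k in keys if k in df.columns]
    if present:
        df = df.sort_values(present, kind="stable")
    return df.reset_index(drop=True)


def write_mztab(
    proteins: pd.DataFrame | None = None,
    peptides: pd.DataFrame | None = None,
    psms: pd.DataFrame | None = None,
    metadata: dict[str, str] | None = None,
) -> str:
    """Serialize protein/peptide/PSM tables to mzTab text.

    Sections are emitted in MTD, PRT, PEP, PSM order with deterministic row
    order (proteins by accession; peptides by sequence, then accession; PSMs
    by spectra_ref, then sequence).  Empty/None tables are omitted, so empty
    input yields an MTD-only document.  Duplicate protein accessions raise
    :class:`MzTabError`.
    """
    lines: list[str] = []
    mtd: dict[str, str] = dict(_DEFAULT_MTD)
    if metadata:
        mtd.update(metadata)
    ordered = [k for k, _ in _DEFAULT_MTD] + [
        k for k in mtd if k not in dict(_DEFAULT_MTD)
    ]
    for key in ordered:
        lines.append(f"MTD\t{key}\t{_fmt(mtd[key])}")
    sections = (
        ("PRH", "PRT", proteins, ("accession",)),
        ("PEH", "PEP", peptides, ("sequence", "accession")),
        ("PSH", "PSM", psms, ("spectra_ref", "sequence")),
    )
    for header_tag, row_tag, df, sort_keys in sections:
        if df is None or len(df) == 0:
            continue
        df = _sort_section(df, sort_keys)
        if row_tag == "PRT" and df["accession"].duplicated().any():
            dupes = sorted(df.loc[df["accession"].duplicated(), "accession"])
            raise MzTabError(f"duplicate protein accession row(s): {dupes}")
        lines.append("")
        lines.append(header_tag + "\t" + "\t".join(str(c) for c in df.columns))
        for row in df.itertuples(index=False):
            lines.append(row_tag + "\t" + "\t".join(_fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def read_mztab(text: str) -> MzTabDocument:
    """Parse mzTab text written by :func:`write_mztab` (or a compatible dialect).

    ``null`` cells become None.  Unknown section prefixes and ragged rows
    raise :class:`MzTabError` with the offending 1-based line number.
    """
    metadata: dict[str, str] = {}
    headers: dict[str, list[str]] = {}
    rows: dict[str, list[list]] = {"PRT": [], "PEP": [], "PSM": []}
    header_of = {"PRT": "PRH", "PEP": "PEH", "PSM": "PSH"}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("COM"):
            continue
        cells = line.split("\t")
        tag = cells[0]
        if tag == "MTD":
            if len(cells) != 3:
                raise MzTabError(f"line {lineno}: malformed MTD line")
            metadata[cells[1]] = cells[2]
        elif tag in ("PRH", "PEH", "PSH"):
            headers[tag] = cells[1:]
        elif tag in rows:
            htag = header_of[tag]
            if htag not in headers:
                raise MzTabError(f"line {lineno}: {tag} row before its {htag} header")
            if len(cells) - 1 != len(headers[htag]):
                raise MzTabError(
                    f"line {lineno}: ragged {tag} row "
                    f"({len(cells) - 1} fields, expected {len(headers[htag])})"
                )
            rows[tag].append([None if c == NULL else c for c in cells[1:]])
        else:
            raise MzTabError(f"line {lineno}: unknown section prefix {tag!r}")

    def _df(tag: str) -> pd.DataFrame:
        htag = header_of[tag]
        if htag not in headers:
            return pd.DataFrame()
        return pd.DataFrame(rows[tag], columns=headers[htag], dtype=object)

    return MzTabDocument(
        metadata=metadata, proteins=_df("PRT"), peptides=_df("PEP"), psms=_df("PSM")
    )


# ---------------------------------------------------------------------------
# Table builders from domain objects
# ---------------------------------------------------------------------------


def protein_table(groups: list[ProteinGroup]) -> pd.DataFrame:
    """PRT-section table from protein groups."""
    return pd.DataFrame(
        [
            {
                "accession": g.accessions[0],
                "ambiguity_members": "|".join(g.accessions),
                "best_search_engine_score[1]": g.score,
                "opt_global_q_value": g.q_value,
                "opt_global_is_decoy": g.is_decoy,
                "opt_global_unique_peptides": g.unique_peptide_count,
            }
            for g in groups
        ],
        columns=[
            "accession",
            "ambiguity_members",
            "best_search_engine_score[1]",
            "opt_global_q_value",
            "opt_global_is_decoy",
            "opt_global_unique_peptides",
        ],
    )


def psm_table(records: list[PsmRecord]) -> pd.DataFrame:
    """PSM-section table from consensus PSM records."""
    return pd.DataFrame(
        [
            {
                "sequence": r.peptide,
                "PSM_ID": i,
                "accession": "|".join(r.accessions),
                "charge": r.charge,
                "spectra_ref": f"{r.run}:{r.spectrum_ref}",
                "opt_global_PEP": r.pep,
                "opt_global_q_value": r.q_value,
                "opt_global_is_decoy": r.is_decoy,
                "opt_global_intensity": r.intensity,
            }
            for i, r in enumerate(records)
        ],
        columns=[
            "sequence",
            "PSM_ID",
            "accession",
            "charge",
            "spectra_ref",
            "opt_global_PEP",
            "opt_global_q_value",
            "opt_global_is_decoy",
            "opt_global_intensity",
        ],
    )


# ---------------------------------------------------------------------------
# MSstats / Triqler exports
# ---------------------------------------------------------------------------

MSSTATS_COLUMNS = (
    "ProteinName",
    "PeptideSequence",
    "PrecursorCharge",
    "FragmentIon",
    "ProductCharge",
    "IsotopeLabelType",
    "Condition",
    "BioReplicate",
    "Run",
    "Intensity",
)

TRIQLER_COLUMNS = (
    "run",
    "condition",
    "charge",
    "searchScore",
    "intensity",
    "peptide",
    "proteins",
)


def _run_annotation(design_annotation: pd.DataFrame) -> dict[str, tuple[str, object]]:
    ann: dict[str, tuple[str, object]] = {}
    for row in design_annotation.itertuples(index=False):
        ann[str(row.Run)] = (str(row.Condition), row.BioReplicate)
    return ann


def export_msstats(
    peptide_quant: pd.DataFrame,
    design_annotation: pd.DataFrame,
    plex: bool = False,
) -> pd.DataFrame:
    """Ten-column MSstats input table.

    ``peptide_quant`` needs columns accession/peptide/charge/run/intensity
    (plus ``channel`` for the isobaric dialect); ``design_annotation`` is the
    Run/Condition/BioReplicate table from the experimental design.  Label-free
    rows carry IsotopeLabelType "L" and "NA" placeholders for FragmentIon and
    ProductCharge; the isobaric dialect replaces IsotopeLabelType with
    Channel.  A run without condition annotation raises :class:`ExportError`.
    """
    ann = _run_annotation(design_annotation)
    rows = []
    for rec in peptide_quant.itertuples(index=False):
        run = str(rec.run)
        if run not in ann:
            raise ExportError(f"run {run!r} lacks condition annotation")
        condition, bio = ann[run]
        row = {
            "ProteinName": rec.accession,
            "PeptideSequence": rec.peptide,
            "PrecursorCharge": rec.charge,
            "FragmentIon": "NA",
            "ProductCharge": "NA",
            "IsotopeLabelType": "L",
            "Condition": condition,
            "BioReplicate": bio,
            "Run": run,
            "Intensity": rec.intensity,
        }
        if plex:
            row["IsotopeLabelType"] = None
            row["Channel"] = getattr(rec, "channel", None)
        rows.append(row)
    columns = list(MSSTATS_COLUMNS)
    if plex:
        columns[columns.index("IsotopeLabelType")] = "Channel"
    return pd.DataFrame(
        [{c: r.get(c) for c in columns} for r in rows], columns=columns
    )


def export_triqler(
    psms: list[PsmRecord],
    design_annotation: pd.DataFrame,
    include_decoys: bool = False,
) -> pd.DataFrame:
    """Triqler input table; searchScore = 1 - PEP, decoys dropped by default."""
    ann = _run_annotation(design_annotation)
    rows = []
    for r in psms:
        if r.is_decoy and not include_decoys:
            continue
        if r.run not in ann:
            raise ExportError(f"run {r.run!r} lacks condition annotation")
        condition, _bio = ann[r.run]
        rows.append(
            {
                "run": r.run,
                "condition": condition,
                "charge": r.charge,
                "searchScore": 1.0 - (r.pep if r.pep is not None else 1.0),
                "intensity": r.intensity,
                "peptide": r.peptide,
                "proteins": " ".join(r.accessions),
            }
        )
    return pd.DataFrame(rows, columns=list(TRIQLER_COLUMNS))


def write_tsv(df: pd.DataFrame) -> str:
    """Tab-delimited serialization with %.6g floats and empty-string missing."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format=FLOAT_FMT)
    return buf.getvalue()
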