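"""SDRF parsing and experimental-design inference.

The SDRF (sample and data relationship format) is a tab-delimited table in
which every row ties one sample ("source name") to one instrument file
(a ``comment[data file]`` cell), together with free-text annotation columns:
``characteristics[...]`` describe the sample, ``comment[...]`` the acquisition,
and ``factor value[...]`` the variables under study.  This module parses the
dialect, routes every run to an acquisition branch (label-free DDA, isobaric
DDA, or DIA), recognises the isobaric labelling scheme from the channel names,
and builds the :class:`ExperimentalDesign` that quantification and the
statistical exports consume.

Only a minimal set of columns is required ("source name" plus a data-file
comment); everything else is optional with documented defaults, because public
SDRF files vary widely in completeness.  Ontology terms are carried through as
opaque strings and never resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "SdrfValidationError",
    "RoutingConflictError",
    "UnsupportedLabelSchemeError",
    "DesignError",
    "SdrfTable",
    "ExperimentalDesign",
    "parse_sdrf",
    "parse_annotation",
    "serialize_sdrf",
    "infer_acquisition",
    "infer_label_scheme",
    "build_design",
    "LABEL_SCHEMES",
    "CONDITION_SEPARATOR",
]


class SdrfValidationError(ValueError):
    """Malformed SDRF content (missing required column, ragged row...)."""


class RoutingConflictError(ValueError):
    """A run carries mutually exclusive acquisition annotations."""


class UnsupportedLabelSchemeError(ValueError):
    """Observed channel names fit no supported labelling scheme."""


class DesignError(ValueError):
    """Inconsistent experimental design (duplicate channel, bad fractions...)."""


# ---------------------------------------------------------------------------
# SDRF table
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def _norm_header(name: str) -> str:
    return _WS.sub(" ", name.strip().lower())


@dataclass
class SdrfTable:
    """A parsed SDRF file: ordered headers plus rows keyed by header."""

    columns: list[str]
    rows: list[dict[str, str]]

    def column(self, name: str) -> list[str]:
        """Values of one column (exact normalized-header match)."""
        key = _norm_header(name)
        if key not in self.columns:
            raise KeyError(key)
        return [row[key] for row in self.rows]

    def find_columns(self, substring: str) -> list[str]:
        """All headers containing ``substring`` (normalized), in file order."""
        sub = _norm_header(substring)
        return [c for c in self.columns if sub in c]

    def serialize(self) -> str:
        lines = ["\t".join(self.columns)]
        for row in self.rows:
            lines.append("\t".join(row[c] for c in self.columns))
        return "\n".join(lines) + "\n"


DATA_FILE_COLUMN_HINT = "data file"


def parse_sdrf(text: str) -> SdrfTable:
    """Parse tab-delimited SDRF content into a validated :class:`SdrfTable`.

    Headers are lower-cased and whitespace-normalized; cell whitespace is
    trimmed.  Raises :class:`SdrfValidationError` for a missing required
    column ("source name" or a ``data file`` comment), duplicated headers, or
    ragged rows (reported with their 1-based data-row index).
    """
    if not text or not text.strip():
        raise SdrfValidationError("empty SDRF: expected a header line")
    lines = text.splitlines()
    columns = [_norm_header(c) for c in lines[0].split("\t")]
    if len(set(columns)) != len(columns):
        dupes = sorted({c for c in columns if columns.count(c) > 1})
        raise SdrfValidationError(f"duplicate SDRF column header(s): {dupes}")
    if "source name" not in columns:
        raise SdrfValidationError('missing required SDRF column "source name"')
    if not any(DATA_FILE_COLUMN_HINT in c for c in columns):
        raise SdrfValidationError(
            'missing required SDRF data-file column (a "comment[data file]" header)'
        )
    rows: list[dict[str, str]] = []
    for i, line in enumerate(lines[1:], start=1):
        if line == "":
            continue
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) != len(columns):
            raise SdrfValidationError(
                f"ragged SDRF row {i}: {len(cells)} cells, expected {len(columns)}"
            )
        rows.append(dict(zip(columns, cells)))
    return SdrfTable(columns=columns, rows=rows)


def serialize_sdrf(table: SdrfTable) -> str:
    return table.serialize()


def parse_annotation(cell: str) -> dict[str, str]:
    """Parse a key=value annotation cell such as ``NT=Oxidation;MT=variable;TA=M``.

    Segments without ``=`` are returned under the key ``NT`` if it is free,
    otherwise ignored; this mirrors the loose dialect of public SDRFs.
    """
    out: dict[str, str] = {}
    for seg in cell.split(";"):
        seg = seg.strip()
        if not seg:
            continue
        if "=" in seg:
            k, v = seg.split("=", 1)
            out[k.strip()] = v.strip()
        elif "NT" not in out:
            out["NT"] = seg
    return out


# ---------------------------------------------------------------------------
# Labelling schemes and acquisition routing
# ---------------------------------------------------------------------------

_TMT10 = (
    "TMT126",
    "TMT127N",
    "TMT127C",
    "TMT128N",
    "TMT128C",
    "TMT129N",
    "TMT129C",
    "TMT130N",
    "TMT130C",
    "TMT131",
)

#: Canonical channel sets for the supported labelling schemes, ordered by
#: plex size so the subset lookup prefers the smallest consistent scheme.
LABEL_SCHEMES: dict[str, tuple[str, ...]] = {
    "label-free": ("LABEL FREE SAMPLE",),
    "iTRAQ4": ("ITRAQ114", "ITRAQ115", "ITRAQ116", "ITRAQ117"),
    "TMT6": ("TMT126", "TMT127", "TMT128", "TMT129", "TMT130", "TMT131"),
    "iTRAQ8": (
        "ITRAQ113",
        "ITRAQ114",
        "ITRAQ115",
        "ITRAQ116",
        "ITRAQ117",
        "ITRAQ118",
        "ITRAQ119",
        "ITRAQ121",
    ),
    "TMT10": _TMT10,
    "TMT11": _TMT10 + ("TMT131C",),
    "TMT16": (
        "TMT126",
        "TMT127N",
        "TMT127C",
        "TMT128N",
        "TMT128C",
        "TMT129N",
        "TMT129C",
        "TMT130N",
        "TMT130C",
        "TMT131N",
        "TMT131C",
        "TMT132N",
        "TMT132C",
        "TMT133N",
        "TMT133C",
        "TMT134N",
    ),
}

SCHEME_SIZES = {
    "label-free": 1,
    "iTRAQ4": 4,
    "iTRAQ8": 8,
    "TMT6": 6,
    "TMT10": 10,
    "TMT11": 11,
    "TMT16": 16,
}

_SCHEME_ORDER = ("label-free", "iTRAQ4", "TMT6", "iTRAQ8", "TMT10", "TMT11", "TMT16")


def _norm_channel(label: str) -> str:
    up = _WS.sub(" ", label.strip().upper())
    if "LABEL FREE" in up or up in ("", "NONE", "NOT APPLICABLE"):
        return "LABEL FREE SAMPLE"
    return up.replace(" ", "").replace("-", "").replace("PLEX", "")


def infer_label_scheme(channels: set[str] | list[str] | tuple[str, ...]) -> str:
    """Smallest supported scheme whose canonical channel set covers ``channels``.

    Channel strings are normalized (case, whitespace, "plex" suffixes), so
    ``"TMT 127N"`` and ``"tmt127n"`` both resolve.  Raises
    :class:`UnsupportedLabelSchemeError` when no scheme covers the set.
    """
    if not channels:
        raise UnsupportedLabelSchemeError("empty channel set")
    observed = {_norm_channel(c) for c in channels}
    for scheme in _SCHEME_ORDER:
        if observed <= set(LABEL_SCHEMES[scheme]):
            return scheme
    offending = sorted(observed)
    raise UnsupportedLabelSchemeError(
        f"channels fit no supported labelling scheme: {offending}"
    )


_ISOBARIC = re.compile(r"^(TMT|ITRAQ)\d")

DDA_LFQ = "DDA-LFQ"
DDA_PLEX = "DDA-plex"
DIA_LFQ = "DIA-LFQ"


def _data_file_column(table: SdrfTable) -> str:
    return table.find_columns(DATA_FILE_COLUMN_HINT)[0]


def infer_acquisition(table: SdrfTable) -> dict[str, str]:
    """Assign every run (data file) one of DDA-LFQ / DDA-plex / DIA-LFQ.

    TMT/iTRAQ labels force DDA-plex; a "data-independent" acquisition-method
    annotation forces DIA-LFQ (routing only; DIA processing is external).
    A run carrying both raises :class:`RoutingConflictError`.
    """
    file_col = _data_file_column(table)
    label_cols = table.find_columns("label")
    method_cols = [
        c
        for c in table.find_columns("acquisition")
        if "method" in c or "mode" in c or c.endswith("acquisition]")
    ] or table.find_columns("acquisition method")
    routing: dict[str, str] = {}
    conflicts: list[str] = []
    for row in table.rows:
        run = row[file_col]
        isobaric = any(
            _ISOBARIC.match(_norm_channel(row[c])) for c in label_cols if row[c]
        )
        dia = any(
            "data-independent" in row[c].lower() or "data independent" in row[c].lower()
            for c in method_cols
            if row[c]
        )
        if isobaric and dia:
            conflicts.append(run)
            continue
        mode = DDA_PLEX if isobaric else (DIA_LFQ if dia else DDA_LFQ)
        prev = routing.get(run)
        if prev is not None and prev != mode:
            conflicts.append(run)
        routing[run] = mode
    if conflicts:
        raise RoutingConflictError(
            f"conflicting acquisition annotations for run(s): {sorted(set(conflicts))}"
        )
    return routing


# ---------------------------------------------------------------------------
# Experimental design
# ---------------------------------------------------------------------------

#: Separator used to join multiple factor values into one condition label.
CONDITION_SEPARATOR = "."


@dataclass
class ExperimentalDesign:
    """Runs, samples, labelling and acquisition derived from one SDRF."""

    runs: list[tuple[str, str, int, int]]  # (run id, data file, fraction, tech rep)
    samples: list[tuple[str, str, int]]  # (sample id, condition, bio replicate)
    label_scheme: str
    channel_map: dict[tuple[str, str], str] = field(default_factory=dict)
    acquisition: dict[str, str] = field(default_factory=dict)

    def run_to_sample(self) -> dict[str, str]:
        """Run -> sample map for label-free designs (one channel per run)."""
        out: dict[str, str] = {}
        for (run, _channel), sample in self.channel_map.items():
            out[run] = sample
        return out

    def condition_of(self, sample: str) -> str:
        for sid, cond, _ in self.samples:
            if sid == sample:
                return cond
        raise KeyError(sample)

    def annotation_table(self):
        """Run/Condition/BioReplicate rows for statistical export (label-free)."""
        import pandas as pd

        bio = {sid: rep for sid, _c, rep in self.samples}
        cond = {sid: c for sid, c, _r in self.samples}
        r2s = self.run_to_sample()
        rows = [
            {
                "Run": run,
                "Condition": cond[r2s[run]],
                "BioReplicate": bio[r2s[run]],
            }
            for run, _f, _fr, _t in self.runs
            if run in r2s
        ]
        return pd.DataFrame(rows, columns=["Run", "Condition", "BioReplicate"])

    def to_tsv(self) -> str:
        """Two-section tab-delimited design (run table, then sample table)."""
        lines = ["[runs]", "run\tdata_file\tfraction\ttechnical_replicate"]
        for run, df, fr, tr in self.runs:
            lines.append(f"{run}\t{df}\t{fr}\t{tr}")
        lines.append("")
        lines.append("[samples]")
        lines.append("sample\tcondition\tbiological_replicate")
        for sid, cond, rep in self.samples:
            lines.append(f"{sid}\t{cond}\t{rep}")
        return "\n".join(lines) + "\n"


def _int_cell(value: str, default: int, what: str, row_idx: int) -> int:
    if not value:
        return default
    try:
        out = int(float(value))
    except ValueError as exc:
        raise DesignError(f"row {row_idx}: non-numeric {what} {value!r}") from exc
    if out < 1:
        raise DesignError(f"row {row_idx}: {what} must be >= 1, got {out}")
    return out


def build_design(table: SdrfTable) -> ExperimentalDesign:
    """Build an :class:`ExperimentalDesign` from a parsed SDRF table.

    Conditions come from the ``factor value[...]`` columns joined with
    :data:`CONDITION_SEPARATOR` in column order (falling back to the source
    name when no factor column exists).  Missing fraction / technical-replicate
    columns default to 1.  Biological replicates come from a
    ``characteristics[biological replicate]`` column when present, otherwise
    each distinct sample gets its own index in order of appearance.
    """
    file_col = _data_file_column(table)
    factor_cols = [c for c in table.columns if c.startswith("factor value")]
    label_cols = table.find_columns("label")
    frac_cols = table.find_columns("fraction")
    tech_cols = table.find_columns("technical replicate")
    bio_cols = table.find_columns("biological replicate")

    runs: dict[str, tuple[str, str, int, int]] = {}
    sample_cond: dict[str, str] = {}
    sample_bio: dict[str, int] = {}
    channel_map: dict[tuple[str, str], str] = {}
    frac_by_group: dict[tuple[str, int], set[int]] = {}

    for i, row in enumerate(table.rows, start=1):
        sample = row["source name"]
        data_file = row[file_col]
        run = data_file
        fraction = _int_cell(
            row[frac_cols[0]] if frac_cols else "", 1, "fraction", i
        )
        tech = _int_cell(
            row[tech_cols[0]] if tech_cols else "", 1, "technical replicate", i
        )
        if factor_cols:
            condition = CONDITION_SEPARATOR.join(row[c] for c in factor_cols)
        else:
            condition = sample
        prev = sample_cond.get(sample)
        if prev is not None and prev != condition:
            raise DesignError(
                f"sample {sample!r} has conflicting factor values across rows "
                f"({prev!r} vs {condition!r})"
            )
        sample_cond[sample] = condition
        if bio_cols and row[bio_cols[0]]:
            sample_bio[sample] = _int_cell(row[bio_cols[0]], 1, "biological replicate", i)
        elif sample not in sample_bio:
            sample_bio[sample] = len(sample_bio) + 1

        label = row[label_cols[0]] if label_cols and row[label_cols[0]] else "label free sample"
        channel = _norm_channel(label)
        key = (run, channel)
        if key in channel_map and channel_map[key] != sample:
            raise DesignError(
                f"duplicate (run, channel) assignment: {key} -> "
                f"{channel_map[key]!r} and {sample!r}"
            )
        channel_map[key] = sample
        runs[run] = (run, data_file, fraction, tech)
        frac_by_group.setdefault((sample, tech), set()).add(fraction)

    for (sample, tech), fracs in frac_by_group.items():
        expected = set(range(1, len(fracs) + 1))
        if fracs != expected:
            raise DesignError(
                f"fractions for sample {sample!r} (replicate {tech}) are not a "
                f"contiguous 1..F set: {sorted(fracs)}"
            )

    channels = {ch for (_run, ch) in channel_map}
    scheme = infer_label_scheme(channels)
    design = ExperimentalDesign(
        runs=list(runs.values()),
        samples=[(s, sample_cond[s], sample_bio[s]) for s in sample_cond],
        label_scheme=scheme,
        channel_map=channel_map,
        acquisition=infer_acquisition(table),
    )
    return design
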