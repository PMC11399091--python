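"""Protein-level quantification: spectral counts, summed intensities, IBAQ,
and isobaric reporter-ion correction/normalization.

Label-free quantities are built from unique peptides only (a peptide shared
between protein groups contributes to none).  IBAQ divides a protein's summed
unique-peptide intensity by the number of theoretically observable tryptic
peptides of its representative (first) accession; the digestion convention is
trypsin with zero missed cleavages, cleaving after K or R but not before P,
counting peptides of length 6-30.  Isobaric reporter intensities are corrected
for isotope impurities by solving the channel-impurity linear system and
clipping negative components to zero, then median-normalized within a run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protein_inference import ProteinGroup

__all__ = [
    "tryptic_peptides",
    "digest_count",
    "read_fasta",
    "spectral_counts",
    "protein_intensity",
    "compute_ibaq",
    "IsotopeCorrectionMatrix",
    "load_isotope_matrix",
    "correct_reporter_intensities",
    "normalize_reporters",
]

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXUBZ")


def tryptic_peptides(sequence: str) -> list[str]:
    """Fully tryptic peptides of ``sequence`` (zero missed cleavages).

    Cleaves after K or R except when the next residue is P.  Ambiguous
    residues X/U/B/Z are accepted and treated as non-cleaving.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - _VALID_RESIDUES
    if bad:
        raise ValueError(f"invalid residues in sequence: {sorted(bad)}")
    peptides: list[str] = []
    start = 0
    for i, aa in enumerate(seq):
        if aa in "KR" and not (i + 1 < len(seq) and seq[i + 1] == "P"):
            peptides.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.append(seq[start:])
    return peptides


def digest_count(sequence: str, min_len: int = 6, max_len: int = 30) -> int:
    """Number of theoretically observable tryptic peptides (length 6-30)."""
    if not sequence or not sequence.strip():
        warnings.warn("empty protein sequence: digest count 0", stacklevel=2)
        return 0
    return sum(1 for p in tryptic_peptides(sequence) if min_len <= len(p) <= max_len)


def read_fasta(source) -> dict[str, str]:
    """Read FASTA into an accession -> sequence map.

    ``source`` is a path or file-like object.  The accession is the first
    whitespace-delimited token of the header; ``sp|ACC|NAME``-style headers
    yield the middle token.  Decoy entries are ordinary records whose
    accession carries the decoy prefix.
    """
    from pyteomics import fasta as _fasta

    out: dict[str, str] = {}
    for header, seq in _fasta.read(source):
        token = header.split()[0]
        parts = token.split("|")
        acc = parts[1] if len(parts) >= 3 and parts[1] else token
        out[acc] = seq
    return out


# ---------------------------------------------------------------------------
# Label-free quantities
# ---------------------------------------------------------------------------


def _unique_peptide_map(groups: list[ProteinGroup]) -> dict[str, int]:
    """peptide -> index of the single group it belongs to (shared excluded)."""
    owner: dict[str, int | None] = {}
    for gi, g in enumerate(groups):
        for p in g.peptides:
            owner[p] = gi if p not in owner else None
    return {p: gi for p, gi in owner.items() if gi is not None}


def spectral_counts(
    psms,
    groups: list[ProteinGroup],
    run_to_sample: dict[str, str] | None = None,
) -> dict[tuple[tuple[str, ...], str], int]:
    """PSM counts per (group accessions, sample) over unique peptides.

    A PSM whose peptide is shared between groups contributes to no group.
    ``run_to_sample`` maps run ids to sample ids (identity when omitted),
    which pools fractions of one sample.
    """
    unique = _unique_peptide_map(groups)
    counts: dict[tuple[tuple[str, ...], str], int] = {}
    for rec in psms:
        gi = unique.get(rec.peptide)
        if gi is None:
            continue
        sample = run_to_sample.get(rec.run, rec.run) if run_to_sample else rec.run
        key = (groups[gi].accessions, sample)
        counts[key] = counts.get(key, 0) + 1
    return counts


def protein_intensity(
    peptides: pd.DataFrame,
    groups: list[ProteinGroup],
    run_to_sample: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Summed unique-peptide intensity per (group, sample).

    ``peptides`` needs columns peptide/run/intensity (charge and channel are
    carried through the sum when present).  Fractions of one sample are summed
    together; a group-sample with no observed unique-peptide intensity is
    missing (NaN), not zero.  Returns columns group, accession (representative
    = first of the group), sample, intensity.
    """
    if len(peptides) and (peptides["intensity"].dropna() < 0).any():
        raise ValueError("negative peptide intensity")
    unique = _unique_peptide_map(groups)
    rows: dict[tuple[int, str], float] = {}
    seen: set[tuple[int, str]] = set()
    for rec in peptides.itertuples(index=False):
        gi = unique.get(rec.peptide)
        if gi is None:
            continue
        sample = (
            run_to_sample.get(rec.run, rec.run) if run_to_sample else rec.run
        )
        key = (gi, sample)
        seen.add(key)
        if rec.intensity is not None and not (
            isinstance(rec.intensity, float) and np.isnan(rec.intensity)
        ):
            rows[key] = rows.get(key, 0.0) + float(rec.intensity)
    records = [
        {
            "group": "|".join(groups[gi].accessions),
            "accession": groups[gi].accessions[0],
            "sample": sample,
            "intensity": rows.get((gi, sample), np.nan),
        }
        for gi, sample in sorted(seen, key=lambda k: (k[0], k[1]))
    ]
    return pd.DataFrame(
        records, columns=["group", "accession", "sample", "intensity"]
    )


def compute_ibaq(
    quant: pd.DataFrame,
    fasta: dict[str, str],
    min_len: int = 6,
    max_len: int = 30,
    ribaq: bool = False,
) -> pd.DataFrame:
    """IBAQ per (group, sample): summed intensity / theoretical peptide count.

    The representative accession (``accession`` column, first of the group)
    must be present in ``fasta``; groups whose representative digests into
    zero observable peptides get a missing IBAQ.  With ``ribaq=True`` a
    relative IBAQ column (ibaq / per-sample ibaq sum) is added.
    """
    missing = sorted(set(quant["accession"]) - set(fasta))
    if missing:
        raise LookupError(f"accession(s) absent from FASTA: {missing}")
    out = quant.copy()
    counts = {
        acc: digest_count(fasta[acc], min_len, max_len)
        for acc in out["accession"].unique()
    }
    n_theor = out["accession"].map(counts).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ibaq"] = np.where(n_theor > 0, out["intensity"] / n_theor, np.nan)
    out["log10_ibaq"] = np.log10(out["ibaq"].where(out["ibaq"] > 0))
    if ribaq:
        totals = out.groupby("sample")["ibaq"].transform("sum")
        out["ribaq"] = out["ibaq"] / totals
    return out


# ---------------------------------------------------------------------------
# Isobaric reporter correction and normalization
# ---------------------------------------------------------------------------


@dataclass
class IsotopeCorrectionMatrix:
    """Channel x channel isotope-impurity matrix.

    Entry (i, j) is the fraction of channel j's reporter signal observed in
    channel i.  Columns must be dominated by their diagonal, entries must be
    non-negative, and column sums must not exceed 1 (+1e-6).
    """

    channels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.values, dtype=float)
        k = len(self.channels)
        if m.shape != (k, k):
            raise ValueError(f"matrix shape {m.shape} does not match {k} channels")
        if (m < 0).any():
            raise ValueError("negative impurity fractions")
        if not np.allclose(m.max(axis=0), np.diag(m)):
            raise ValueError("each column's maximum must sit on the diagonal")
        if (m.sum(axis=0) > 1.0 + 1e-6).any():
            raise ValueError("column sums exceed 1")
        self.values = m


def load_isotope_matrix(text: str) -> IsotopeCorrectionMatrix:
    """Parse a tab-delimited square impurity table with channel headers."""
    import io

    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    return IsotopeCorrectionMatrix(
        channels=tuple(str(c) for c in df.columns), values=df.to_numpy(dtype=float)
    )


_MAX_CONDITION = 1e8


def correct_reporter_intensities(
    observed, matrix: IsotopeCorrectionMatrix | np.ndarray
) -> np.ndarray:
    """Solve the impurity system M x = observed; clip negatives to zero."""
    m = matrix.values if isinstance(matrix, IsotopeCorrectionMatrix) else np.asarray(
        matrix, dtype=float
    )
    obs = np.asarray(observed, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"correction matrix must be square, got {m.shape}")
    if obs.shape[-1] != m.shape[0]:
        raise ValueError(
            f"observed vector length {obs.shape[-1]} does not match plex size {m.shape[0]}"
        )
    if np.linalg.cond(m) >= _MAX_CONDITION:
        raise np.linalg.LinAlgError("correction matrix is ill-conditioned")
    x = np.linalg.solve(m, obs.T).T
    return np.clip(x, 0.0, None)


def normalize_reporters(
    matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Equalize channel medians within one run.

    Every channel (column) is scaled so its median equals the smallest
    channel median of the run (channels are scaled down, never up).  Returns
    the scaled matrix and the per-channel factors; an all-missing channel
    gets factor 1 with a warning.
    """
    medians = matrix.median(axis=0, skipna=True)
    valid = medians.dropna()
    factors = pd.Series(1.0, index=matrix.columns)
    if len(valid) and (valid > 0).any():
        ref = valid[valid > 0].min()
        for ch in matrix.columns:
            med = medians[ch]
            if pd.isna(med):
                warnings.warn(f"channel {ch!r} is all-missing; factor 1", stacklevel=2)
            elif med > 0:
                factors[ch] = ref / med
    else:
        warnings.warn("no usable channel medians; factors all 1", stacklevel=2)
    return matrix * factors, factors
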