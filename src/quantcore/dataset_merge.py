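"""Cross-dataset protein-list merging with stand-in decoys.

Protein inference pipelines report protein-level q-values but often no
explicit decoy proteins, so their lists cannot be pooled under a common FDR.
The device implemented here injects *stand-in decoys* into each dataset's
protein list so that, at every rank of the q-sorted list, the ratio of decoy
to target entries equals the target's nominal q-value: for the k-th target
(ascending q) the cumulative decoy requirement is

    d_k = round_half_up(q_k * k),

and d_k - d_{k-1} decoys with nominal q = q_k are emitted.  The lists are
then pooled; a target seen in several datasets keeps only its lowest-q
observation (with provenance), while every stand-in decoy is retained, since
each one encodes its source dataset's uncertainty.  Each target's q-value is
re-estimated as the ratio of decoys to targets with nominal q as good or
better, monotonized by the usual worst-to-best cumulative minimum, and the
combined build is filtered at a strict adjusted FDR (q-hat < 0.01 by
default).

The injection is neutral: it neither improves nor worsens the calibration of
the per-dataset q-values, it only transports them into countable form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MergeEntry",
    "DatasetProteinList",
    "BuildRecord",
    "MergedBuild",
    "inject_standin_decoys",
    "merge_protein_lists",
    "reestimate_qvalues",
    "filter_adjusted_fdr",
    "combine_expression_profiles",
]


@dataclass(frozen=True)
class MergeEntry:
    """One entry of a (merged) protein list."""

    accession: str
    q: float
    dataset: str
    is_standin_decoy: bool = False


@dataclass
class DatasetProteinList:
    """One dataset's q-sorted protein list with its stand-in decoys."""

    dataset_id: str
    entries: list[MergeEntry]

    def targets(self) -> list[MergeEntry]:
        return [e for e in self.entries if not e.is_standin_decoy]

    def decoys(self) -> list[MergeEntry]:
        return [e for e in self.entries if e.is_standin_decoy]


def _round_half_up(x: float) -> int:
    # 1e-12 guards against 1.4999999999999998-style float droop at exact halves
    return int(math.floor(x + 0.5 + 1e-12))


def inject_standin_decoys(entries, dataset_id: str) -> DatasetProteinList:
    """Inject stand-in decoys so decoy/target ratios encode the q-values.

    ``entries`` is an iterable of (accession, q) target pairs (no decoys).
    Targets are sorted ascending by q; after the k-th target the cumulative
    decoy count is brought up to round_half_up(q_k * k), each new decoy
    carrying nominal q = q_k and accession ``DECOY_STANDIN_<dataset>_<i>``.
    """
    targets = [(str(a), float(q)) for a, q in entries]
    seen: set[str] = set()
    for acc, q in targets:
        if not (0.0 <= q <= 1.0):
            raise ValueError(f"q-value out of [0, 1] for {acc!r}: {q}")
        if acc in seen:
            raise ValueError(f"duplicate target accession {acc!r}")
        seen.add(acc)
    targets.sort(key=lambda t: (t[1], t[0]))
    out: list[MergeEntry] = []
    d_prev = 0
    decoy_idx = 0
    for k, (acc, q) in enumerate(targets, start=1):
        out.append(MergeEntry(acc, q, dataset_id, False))
        d_k = _round_half_up(q * k)
        for _ in range(d_k - d_prev):
            decoy_idx += 1
            out.append(
                MergeEntry(
                    f"DECOY_STANDIN_{dataset_id}_{decoy_idx}", q, dataset_id, True
                )
            )
        d_prev = d_k
    return DatasetProteinList(dataset_id, out)


def merge_protein_lists(lists) -> list[MergeEntry]:
    """Pool per-dataset lists (decoys already injected) into one sorted list.

    A target appearing in several datasets keeps only its lowest-q observation
    (ties broken by dataset id for determinism); stand-in decoys are all
    retained.  The result is sorted ascending by nominal q, targets before
    decoys at equal q, then by accession.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("need at least one dataset protein list")
    best: dict[str, MergeEntry] = {}
    decoys: list[MergeEntry] = []
    for lst in lists:
        for e in lst.entries:
            if e.is_standin_decoy:
                decoys.append(e)
            else:
                cur = best.get(e.accession)
                if cur is None or (e.q, e.dataset) < (cur.q, cur.dataset):
                    best[e.accession] = e
    merged = list(best.values()) + decoys
    merged.sort(key=lambda e: (e.q, e.is_standin_decoy, e.accession))
    return merged


@dataclass(frozen=True)
class BuildRecord:
    """A target protein of the merged build with its re-estimated q-value."""

    accession: str
    dataset: str
    nominal_q: float
    adjusted_q: float


@dataclass
class MergedBuild:
    """Merged cross-dataset build: targets with adjusted q, decoys retained."""

    targets: list[BuildRecord]
    decoys: list[MergeEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "accession": t.accession,
                    "dataset": t.dataset,
                    "nominal_q": t.nominal_q,
                    "adjusted_q": t.adjusted_q,
                }
                for t in self.targets
            ],
            columns=["accession", "dataset", "nominal_q", "adjusted_q"],
        )


def reestimate_qvalues(merged: list[MergeEntry], monotonize: bool = True) -> MergedBuild:
    """Re-estimate each target's q as the decoy/target ratio at its threshold.

    For a target with nominal q, raw = (#decoys with nominal q <= q) /
    (#targets with nominal q <= q), capped at 1 ("as well or better" includes
    ties on both sides).  With ``monotonize=True`` (the standard q-value
    definition) the raw ratios are replaced by their cumulative minimum
    scanning from the largest nominal q downward.  Decoys receive no
    adjusted q but are kept with their provenance.
    """
    if not merged:
        raise ValueError("empty merged list")
    entries = sorted(merged, key=lambda e: (e.q, e.is_standin_decoy, e.accession))
    qs = np.array([e.q for e in entries])
    dec = np.array([e.is_standin_decoy for e in entries], dtype=bool)
    n = len(entries)
    if dec.all():
        raise ValueError("no target entries in merged list")
    cum_d = np.cumsum(dec)
    cum_t = np.cumsum(~dec)
    is_end = np.append(qs[1:] != qs[:-1], True)
    end_idx = np.flatnonzero(is_end)
    block_end = end_idx[np.searchsorted(end_idx, np.arange(n))]
    D = cum_d[block_end].astype(float)
    T = cum_t[block_end].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(T > 0, D / np.maximum(T, 1.0), 1.0)
    raw = np.minimum(raw, 1.0)
    if monotonize:
        qhat = np.minimum.accumulate(raw[::-1])[::-1]
    else:
        qhat = raw
    targets = [
        BuildRecord(e.accession, e.dataset, e.q, float(qh))
        for e, qh in zip(entries, qhat)
        if not e.is_standin_decoy
    ]
    return MergedBuild(targets=targets, decoys=[e for e in entries if e.is_standin_decoy])


def filter_adjusted_fdr(
    build: MergedBuild, alpha: float = 0.01, strict: bool = True
) -> tuple[list[BuildRecord], dict]:
    """Filter the build at the adjusted FDR threshold.

    With ``strict=True`` (default) a target is retained when its adjusted q is
    strictly below ``alpha`` ("less than 0.01"); ``strict=False`` retains at
    q <= alpha.  Returns the retained targets and a report with counts and a
    per-dataset provenance summary.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if strict:
        retained = [t for t in build.targets if t.adjusted_q < alpha]
    else:
        retained = [t for t in build.targets if t.adjusted_q <= alpha]
    per_dataset: dict[str, int] = {}
    for t in retained:
        per_dataset[t.dataset] = per_dataset.get(t.dataset, 0) + 1
    report = {
        "alpha": alpha,
        "strict": strict,
        "n_targets": len(build.targets),
        "n_retained": len(retained),
        "n_removed": len(build.targets) - len(retained),
        "n_standin_decoys": len(build.decoys),
        "retained_per_dataset": dict(sorted(per_dataset.items())),
    }
    return retained, report


def combine_expression_profiles(
    retained: list[BuildRecord], quant: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Per-protein expression summary across datasets and sample classes.

    ``quant`` needs columns accession / dataset / sample_class / ibaq.  For
    every (accession, sample class) of a build-surviving protein the summary
    reports the number of datasets observed and the median and MAD (median
    absolute deviation, unscaled) of log10 IBAQ.  Quant rows for accessions
    outside the build are skipped; their count is returned alongside.
    """
    keep = {t.accession for t in retained}
    skipped = int((~quant["accession"].isin(keep)).sum())
    sub = quant[quant["accession"].isin(keep)].copy()
    if sub.empty:
        cols = ["accession", "sample_class", "n_datasets", "median_log10_ibaq", "mad_log10_ibaq"]
        return pd.DataFrame(columns=cols), skipped
    sub["log10_ibaq"] = np.log10(sub["ibaq"].where(sub["ibaq"] > 0))

    def _mad(x: pd.Series) -> float:
        x = x.dropna()
        if x.empty:
            return float("nan")
        return float((x - x.median()).abs().median())

    out = (
        sub.groupby(["accession", "sample_class"])
        .agg(
            n_datasets=("dataset", "nunique"),
            median_log10_ibaq=("log10_ibaq", "median"),
            mad_log10_ibaq=("log10_ibaq", _mad),
        )
        .reset_index()
        .sort_values(["accession", "sample_class"])
        .reset_index(drop=True)
    )
    return out, skipped
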