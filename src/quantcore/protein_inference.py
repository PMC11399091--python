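"""Protein inference and picked protein-level FDR.

Peptide evidence is aggregated into protein groups: accessions whose peptide
sets are identical are indistinguishable and merged into one group; the group
score is the best (minimum) peptide PEP among its peptides.  A peptide shared
between groups scores every group containing it but counts as "unique" for
none, which is the counting rule behind the >= 2-unique-peptides
quantifiability filter.

Protein FDR uses the picked target-decoy strategy: each target competes with
its decoy counterpart (matched by stripping the decoy accession prefix) and
only the better-scoring member of the pair survives; unpaired groups survive
unconditionally.  Standard target-decoy q-values are then computed on the
survivors only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .id_scoring import PsmRecord, target_decoy_qvalues

__all__ = [
    "DEFAULT_DECOY_PREFIX",
    "ProteinGroup",
    "EvidenceError",
    "aggregate_inference",
    "picked_protein_fdr",
    "quantifiability_filter",
]

DEFAULT_DECOY_PREFIX = "DECOY_"


class EvidenceError(ValueError):
    """Invalid peptide evidence (e.g. a PSM with no protein accessions)."""


@dataclass
class ProteinGroup:
    """An inferred protein group (indistinguishable accessions).

    ``score`` is PEP-like: lower is better.  ``unique_peptide_count`` counts
    the group's peptides that map to no other group.
    """

    accessions: tuple[str, ...]
    score: float
    q_value: float | None = None
    is_decoy: bool = False
    unique_peptide_count: int = 0
    peptides: frozenset[str] = frozenset()


def aggregate_inference(
    psms: list[PsmRecord], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinGroup]:
    """Aggregate peptide-FDR-passing PSMs into scored protein groups.

    Accessions with identical peptide sets are merged (indistinguishable).
    Group score = minimum peptide PEP over the group's peptides; a group is
    decoy iff every member accession carries ``decoy_prefix``.  Shared
    peptides belong to all containing groups but are unique to none.
    """
    peptide_pep: dict[str, float] = {}
    acc_peptides: dict[str, set[str]] = {}
    for rec in psms:
        if not rec.accessions:
            raise EvidenceError(
                f"PSM ({rec.run!r}, {rec.spectrum_ref!r}) has an empty accession list"
            )
        if rec.pep is None:
            raise EvidenceError(f"PSM {rec.spectrum_ref!r} lacks a PEP")
        prev = peptide_pep.get(rec.peptide)
        if prev is None or rec.pep < prev:
            peptide_pep[rec.peptide] = rec.pep
        for acc in rec.accessions:
            acc_peptides.setdefault(acc, set()).add(rec.peptide)

    by_pepset: dict[frozenset[str], list[str]] = {}
    for acc, peps in acc_peptides.items():
        by_pepset.setdefault(frozenset(peps), []).append(acc)

    groups: list[ProteinGroup] = []
    for pepset, accs in by_pepset.items():
        accs = tuple(sorted(accs))
        groups.append(
            ProteinGroup(
                accessions=accs,
                score=min(peptide_pep[p] for p in pepset),
                is_decoy=all(a.startswith(decoy_prefix) for a in accs),
                peptides=pepset,
            )
        )
    groups.sort(key=lambda g: g.accessions)

    membership: dict[str, int] = {}
    for g in groups:
        for p in g.peptides:
            membership[p] = membership.get(p, 0) + 1
    for g in groups:
        g.unique_peptide_count = sum(1 for p in g.peptides if membership[p] == 1)
    return groups


def _strip(acc: str, prefix: str) -> str:
    return acc[len(prefix) :] if acc.startswith(prefix) else acc


def picked_protein_fdr(
    groups: list[ProteinGroup], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinGroup]:
    """Picked protein FDR: pairwise target/decoy competition, then q-values.

    Groups are paired by their prefix-stripped accession sets; within a pair
    only the better-scoring member survives (target wins ties).  Unpaired
    groups survive unconditionally.  Target-decoy q-values are computed on the
    survivors (group scores are PEP-like, so the ranking score is -score) and
    assigned to the surviving groups; eliminated groups are not returned and
    keep no q-value.
    """
    buckets: dict[frozenset[str], dict[bool, ProteinGroup]] = {}
    unpaired: list[ProteinGroup] = []
    for g in groups:
        key = frozenset(_strip(a, decoy_prefix) for a in g.accessions)
        side = buckets.setdefault(key, {})
        if g.is_decoy in side:
            # two same-side groups with one stripped key cannot compete; keep both
            unpaired.append(g)
        else:
            side[g.is_decoy] = g

    survivors: list[ProteinGroup] = []
    for side in buckets.values():
        if len(side) == 2:
            target, decoy = side[False], side[True]
            survivors.append(target if target.score <= decoy.score else decoy)
        else:
            survivors.extend(side.values())
    survivors.extend(unpaired)
    if not survivors:
        return []
    survivors.sort(key=lambda g: (g.score, g.is_decoy, g.accessions))
    if all(g.is_decoy for g in survivors):
        return [replace(g, q_value=None) for g in survivors]
    q = target_decoy_qvalues([(-g.score, g.is_decoy) for g in survivors])
    return [replace(g, q_value=float(v)) for g, v in zip(survivors, q)]


def quantifiability_filter(
    groups: list[ProteinGroup], min_unique_peptides: int = 2
) -> list[ProteinGroup]:
    """Target groups with at least ``min_unique_peptides`` unique peptides.

    The default of 2 is the usual requirement for quantifying a protein;
    ineligible groups stay in the identification output but are excluded from
    quantification tables.
    """
    return [
        g
        for g in groups
        if not g.is_decoy and g.unique_peptide_count >= min_unique_peptides
    ]
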