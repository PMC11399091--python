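"""PSM scoring: posterior error probabilities, multi-engine consensus, and
target-decoy q-values at PSM and peptide level.

The scoring model is a two-component Gaussian mixture on the search-engine
score axis (the PeptideProphet lineage): one component for incorrect matches,
initialised from the decoy score distribution, and one for correct matches,
initialised from the upper half of the target scores.  The posterior error
probability of a PSM with score s is

    PEP(s) = pi0 f0(s) / (pi0 f0(s) + (1 - pi0) f1(s)),

clamped to [1e-10, 1], where f0/f1 are the incorrect/correct densities and
pi0 the incorrect mixing weight.  Consensus across engines averages per-engine
PEPs per candidate peptide, with an engine that searched the spectrum but did
not report the candidate contributing PEP = 1 (maximally uncertain).

q-values follow the plain target-decoy ratio: at every score threshold the
FDR estimate is (#decoys at or above) / (#targets at or above), capped at 1,
and q-values are the cumulative minimum scanning from worst to best score.
The ratio is D/T, not (D+1)/T; ties share the counts of the full tie block.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "PEP_FLOOR",
    "PsmRecord",
    "MixtureFit",
    "MixtureInitError",
    "DuplicateRecordError",
    "fit_pep_mixture",
    "consensus_psm",
    "target_decoy_qvalues",
    "collapse_peptides",
    "peptide_level_qvalues",
    "filter_at_fdr",
]

#: Lower clamp for posterior error probabilities.
PEP_FLOOR = 1e-10


class MixtureInitError(ValueError):
    """Mixture fit could not be initialised (no decoys, too few scores)."""


class DuplicateRecordError(ValueError):
    """Same (run, spectrum, peptide) reported twice by one engine."""


@dataclass
class PsmRecord:
    """One peptide-spectrum match.

    ``engine_scores`` maps engine name to raw score (oriented higher = better);
    ``pep`` is the combined posterior error probability once assigned;
    ``accessions`` is the non-empty tuple of protein accessions the peptide
    maps to; ``intensity`` is the precursor intensity or None.
    """

    run: str
    spectrum_ref: str
    peptide: str
    charge: int
    engine_scores: dict[str, float] = field(default_factory=dict)
    pep: float | None = None
    q_value: float | None = None
    is_decoy: bool = False
    accessions: tuple[str, ...] = ()
    intensity: float | None = None


# ---------------------------------------------------------------------------
# Two-component mixture / PEP
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Fitted two-Gaussian mixture: component 0 = incorrect, 1 = correct."""

    mu0: float
    sigma0: float
    mu1: float
    sigma1: float
    pi0: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0
    log_transform: bool = False

    def pep(self, scores) -> np.ndarray:
        """Posterior error probability for raw score(s), clamped to [1e-10, 1]."""
        x = np.asarray(scores, dtype=float)
        if self.log_transform:
            x = np.log(x)
        f0 = norm.pdf(x, self.mu0, self.sigma0)
        f1 = norm.pdf(x, self.mu1, self.sigma1)
        num = self.pi0 * f0
        den = num + (1.0 - self.pi0) * f1
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0)
        return np.clip(p, PEP_FLOOR, 1.0)


_MIN_SIGMA = 1e-3


def fit_pep_mixture(
    scores,
    decoy_flags,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    log_transform: bool = False,
) -> MixtureFit:
    """Fit the two-component Gaussian mixture by EM on the target scores.

    Decoy scores are held out of the likelihood and only initialise the
    incorrect component (mean/variance); the correct component is initialised
    from the upper half of the target scores, with mixing weight 0.5.  The
    log-likelihood is monotone non-decreasing across iterations; if EM does
    not converge within ``max_iter`` iterations the best fit is returned with
    ``converged=False`` and a warning.

    Requires at least 50 scores and at least one decoy.
    """
    scores = np.asarray(scores, dtype=float)
    decoy = np.asarray(decoy_flags, dtype=bool)
    if scores.shape != decoy.shape:
        raise ValueError("scores and decoy_flags must have equal length")
    if scores.size < 50:
        raise MixtureInitError(f"need >= 50 scores, got {scores.size}")
    if log_transform:
        if np.any(scores <= 0):
            raise ValueError("log transform requires strictly positive scores")
        scores = np.log(scores)
    dec = scores[decoy]
    x = scores[~decoy]
    if dec.size == 0:
        raise MixtureInitError("no decoys available to initialise the null component")
    rng = np.random.default_rng(seed)
    mu0 = float(dec.mean())
    s0 = max(float(dec.std()), _MIN_SIGMA)
    upper = np.sort(x)[x.size // 2 :]
    mu1 = float(upper.mean())
    s1 = max(float(upper.std()), _MIN_SIGMA)
    if abs(mu1 - mu0) < 1e-9:  # degenerate init: nudge apart deterministically
        mu1 = mu0 + s0 * (1.0 + rng.random() * 1e-6)
    pi0 = 0.5

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p0 = pi0 * norm.pdf(x, mu0, s0)
        p1 = (1.0 - pi0) * norm.pdf(x, mu1, s1)
        tot = np.maximum(p0 + p1, 1e-300)
        ll = float(np.log(tot).sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        r0 = p0 / tot
        w0 = float(r0.sum())
        w1 = float(x.size - w0)
        if w0 < 1e-12 or w1 < 1e-12:
            break
        pi0 = min(max(w0 / x.size, 1e-6), 1.0 - 1e-6)
        mu0 = float((r0 * x).sum() / w0)
        s0 = max(float(np.sqrt((r0 * (x - mu0) ** 2).sum() / w0)), _MIN_SIGMA)
        r1 = 1.0 - r0
        mu1 = float((r1 * x).sum() / w1)
        s1 = max(float(np.sqrt((r1 * (x - mu1) ** 2).sum() / w1)), _MIN_SIGMA)
    if not converged:
        warnings.warn(
            f"EM did not converge in {max_iter} iterations; returning best fit",
            RuntimeWarning,
            stacklevel=2,
        )
    fit = MixtureFit(
        mu0=mu0,
        sigma0=s0,
        mu1=mu1,
        sigma1=s1,
        pi0=pi0,
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        log_transform=log_transform,
    )
    if fit.mu0 > fit.mu1:  # keep component 0 = incorrect (lower-scoring)
        fit = replace(
            fit,
            mu0=fit.mu1,
            sigma0=fit.sigma1,
            mu1=fit.mu0,
            sigma1=fit.sigma0,
            pi0=1.0 - fit.pi0,
        )
    return fit


# ---------------------------------------------------------------------------
# Multi-engine consensus
# ---------------------------------------------------------------------------


def consensus_psm(per_engine: dict[str, list[PsmRecord]]) -> list[PsmRecord]:
    """Combine per-engine PSMs into one consensus record per spectrum.

    PSMs are matched across engines by (run, spectrum reference).  For every
    candidate peptide of a spectrum the combined PEP is the arithmetic mean of
    its per-engine PEPs over the engines that searched the spectrum, with an
    engine that searched it but did not report the candidate contributing
    PEP = 1.  The candidate with the lowest combined PEP is retained (ties
    broken lexicographically by peptide); its accession lists are unioned.

    Raises :class:`DuplicateRecordError` when one engine reports the same
    (run, spectrum, peptide) twice.
    """
    spectra: dict[tuple[str, str], dict[str, dict[str, PsmRecord]]] = {}
    for engine, records in per_engine.items():
        for rec in records:
            if rec.pep is None:
                raise ValueError(
                    f"engine {engine!r} record {rec.spectrum_ref!r} lacks a PEP"
                )
            cands = spectra.setdefault((rec.run, rec.spectrum_ref), {}).setdefault(
                engine, {}
            )
            if rec.peptide in cands:
                raise DuplicateRecordError(
                    f"engine {engine!r} reports ({rec.run!r}, {rec.spectrum_ref!r}, "
                    f"{rec.peptide!r}) more than once"
                )
            cands[rec.peptide] = rec

    out: list[PsmRecord] = []
    for (run, ref) in sorted(spectra):
        by_engine = spectra[(run, ref)]
        engines = sorted(by_engine)
        candidates = sorted({p for cands in by_engine.values() for p in cands})
        best: PsmRecord | None = None
        for peptide in candidates:
            peps = [
                by_engine[e][peptide].pep if peptide in by_engine[e] else 1.0
                for e in engines
            ]
            # exact when all engines agree, so k duplicated engines reproduce
            # the single-engine result bit-for-bit
            combined = peps[0] if min(peps) == max(peps) else float(np.mean(peps))
            reporting = [by_engine[e][peptide] for e in engines if peptide in by_engine[e]]
            accessions = tuple(
                sorted({a for r in reporting for a in r.accessions})
            )
            engine_scores: dict[str, float] = {}
            for r in reporting:
                engine_scores.update(r.engine_scores)
            intensity = next(
                (r.intensity for r in reporting if r.intensity is not None), None
            )
            cand = PsmRecord(
                run=run,
                spectrum_ref=ref,
                peptide=peptide,
                charge=reporting[0].charge,
                engine_scores=engine_scores,
                pep=max(combined, PEP_FLOOR),
                is_decoy=reporting[0].is_decoy,
                accessions=accessions,
                intensity=intensity,
            )
            if best is None or (cand.pep, cand.peptide) < (best.pep, best.peptide):
                best = cand
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# Target-decoy q-values
# ---------------------------------------------------------------------------


def target_decoy_qvalues(records) -> np.ndarray:
    """q-values from (score, is_decoy) pairs; higher score = better.

    FDR(s) = #decoys(score >= s) / #targets(score >= s), capped at 1
    (and 1 where no target scores at or above s); q-values are the running
    minimum from the worst score upward.  Tied scores share the counts taken
    after the full tie block.  Returns q-values in the input order; decoy
    records receive the q of their position.
    """
    scores = np.asarray([r[0] for r in records], dtype=float)
    decoy = np.asarray([bool(r[1]) for r in records], dtype=bool)
    n = scores.size
    if n == 0:
        return np.empty(0)
    bad = np.flatnonzero(np.isnan(scores))
    if bad.size:
        raise ValueError(f"NaN scores at indices {bad.tolist()}")
    if decoy.all():
        raise ValueError("no target records: cannot estimate FDR")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    d = decoy[order]
    cum_d = np.cumsum(d)
    cum_t = np.cumsum(~d)
    is_end = np.append(s[1:] != s[:-1], True)
    end_idx = np.flatnonzero(is_end)
    block_end = end_idx[np.searchsorted(end_idx, np.arange(n))]
    D = cum_d[block_end].astype(float)
    T = cum_t[block_end].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(T > 0, D / np.maximum(T, 1.0), 1.0)
    fdr = np.minimum(fdr, 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = q_sorted
    return q


def collapse_peptides(psms: list[PsmRecord]) -> list[PsmRecord]:
    """One best PSM per modified peptide sequence.

    Best = lowest PEP; ties broken by higher charge, then lexicographically
    smaller spectrum reference.  Output sorted by peptide for stability.
    """
    best: dict[str, PsmRecord] = {}
    for rec in psms:
        if rec.pep is None:
            raise ValueError(f"PSM {rec.spectrum_ref!r} lacks a PEP")
        cur = best.get(rec.peptide)
        key = (rec.pep, -rec.charge, rec.spectrum_ref)
        if cur is None or key < (cur.pep, -cur.charge, cur.spectrum_ref):
            best[rec.peptide] = rec
    return [best[p] for p in sorted(best)]


def peptide_level_qvalues(psms: list[PsmRecord]) -> dict[str, float]:
    """Peptide-level q-values: collapse to best PSM per peptide, then the
    target-decoy procedure on the collapsed list (score = -PEP)."""
    collapsed = collapse_peptides(psms)
    if not collapsed:
        return {}
    q = target_decoy_qvalues([(-r.pep, r.is_decoy) for r in collapsed])
    return {r.peptide: float(v) for r, v in zip(collapsed, q)}


def filter_at_fdr(records, alpha: float):
    """Retain target records with q-value <= alpha; decoys are dropped.

    Works on anything exposing ``q_value`` and ``is_decoy`` attributes
    (PSM records, protein groups).  ``alpha`` must lie in (0, 1].
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    out = []
    for rec in records:
        if rec.is_decoy:
            continue
        if rec.q_value is None:
            raise ValueError("record lacks a q-value; run the FDR step first")
        if rec.q_value <= alpha:
            out.append(rec)
    return out
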