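"""Synthetic multi-engine, multi-dataset proteomics data with ground truth.

The generator emulates the statistical structure the identification and
quantification stages assume, with everything downstream of spectra already
abstracted into tabular scores and intensities:

* proteins are random tryptic-block sequences (no proline, no internal K/R),
  so the theoretical digest count is known exactly by construction;
* a configurable fraction of proteins is *present*; present proteins spawn
  detected peptides and correct PSMs whose engine scores come from the
  "correct" score component, shifted by the separation ``delta``;
* incorrect target PSMs and decoy PSMs draw from the null component in equal
  numbers, so decoy counting estimates the false-match rate among targets;
* the ``n_engines`` engine scores of one PSM share a latent standard normal
  with loading sqrt(rho), which induces pairwise correlation rho;
* peptide intensities are log-normal around the protein's true abundance with
  per-condition fold changes and missing-at-random dropout.

Everything is driven by one integer seed; identical configurations produce
byte-identical outputs.  Besides the full generator there are two lightweight
samplers used for calibration studies (PSM score sets and per-dataset protein
q-value lists), plus the QC metrics bundle and an end-to-end harness that runs
score -> consensus -> FDR -> inference -> quantification against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .id_scoring import (
    PsmRecord,
    consensus_psm,
    filter_at_fdr,
    fit_pep_mixture,
    peptide_level_qvalues,
    target_decoy_qvalues,
)
from .protein_inference import (
    aggregate_inference,
    picked_protein_fdr,
    quantifiability_filter,
)
from .quantify import compute_ibaq, protein_intensity

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "simulate_psm_scores",
    "simulate_protein_qlists",
    "qc_metrics",
    "end_to_end",
]

_ENGINES = ("engineA", "engineB", "engineC")
# residue alphabet for synthetic sequences: no K/R (inserted as cleavage
# sites) and no P (would suppress cleavage and blur the theoretical digest)
_AA = np.array(list("ACDEFGHILMNQSTVWY"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``delta`` is the standardized mean difference between correct and
    incorrect PSM scores; ``rho`` the between-engine score correlation;
    ``incorrect_rate`` the number of incorrect target PSMs generated per
    correct PSM (decoy PSMs are generated in equal number, so the decoy
    population mirrors the incorrect-target population).  Abundances are
    log10-normal with mean ``log10_abundance_mu`` and spread
    ``log10_abundance_sigma``; peptide intensities scatter around the protein
    abundance with log10 measurement noise ``intensity_sigma``.
    """

    seed: int = 0
    n_proteins: int = 300
    fraction_present: float = 0.7
    n_engines: int = 2
    rho: float = 0.5
    delta: float = 3.5
    peptides_per_protein_mean: float = 5.0
    peptides_per_protein_dispersion: float = 50.0
    theoretical_peptides_range: tuple[int, int] = (6, 20)
    n_runs: int = 1
    n_fractions: int = 1
    label_scheme: str = "label-free"
    conditions: tuple[str, ...] = ("A",)
    fold_changes: dict[str, float] = field(default_factory=dict)
    regulated_fraction: float = 0.0
    log10_abundance_mu: float = 2.5
    log10_abundance_sigma: float = 1.0
    intensity_sigma: float = 0.2
    missingness: float = 0.1
    incorrect_rate: float = 0.4
    psms_per_peptide: int = 1

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if not (0.0 < self.fraction_present <= 1.0):
            raise ValueError("fraction_present must be in (0, 1]")
        if round(self.fraction_present * self.n_proteins) < 1:
            raise ValueError("infeasible config: zero present proteins")
        if self.n_engines not in (1, 2, 3):
            raise ValueError("n_engines must be 1, 2 or 3")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if not (0.0 <= self.missingness < 1.0):
            raise ValueError("missingness must be in [0, 1)")
        if self.incorrect_rate < 0:
            raise ValueError("incorrect_rate must be non-negative")


@dataclass
class GroundTruth:
    """What the generator knows: presence, abundance, per-PSM correctness."""

    present: dict[str, bool]
    abundance: dict[tuple[str, str], float]  # (accession, condition) -> true value
    psm_correct: dict[tuple[str, str], bool]  # (run, spectrum_ref) -> label


@dataclass
class SimulatedDataset:
    per_engine: dict[str, list[PsmRecord]]
    fasta: dict[str, str]
    sdrf: str
    truth: GroundTruth
    config: SimulationConfig


def _random_sequences(rng: np.random.Generator, n: int, lo: int, hi: int):
    """Sequences made of tryptic blocks; digest count == block count."""
    seqs: list[str] = []
    n_blocks = rng.integers(lo, hi + 1, size=n)
    for nb in n_blocks:
        lengths = rng.integers(6, 31, size=nb)
        parts = []
        for L in lengths:
            body = rng.choice(_AA, size=L - 1)
            tail = "K" if rng.random() < 0.5 else "R"
            parts.append("".join(body) + tail)
        seqs.append("".join(parts))
    return seqs


def _engine_scores(rng: np.random.Generator, n: int, k: int, rho: float, shift: float):
    """n x k engine score matrix with pairwise correlation rho, mean shift."""
    z = rng.standard_normal((n, 1))
    eps = rng.standard_normal((n, k))
    return shift + np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps


def _random_peptide(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        L = int(rng.integers(7, 21))
        pep = "".join(rng.choice(_AA, size=L))
        if pep not in taken:
            taken.add(pep)
            return pep


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate per-engine PSM tables, FASTA, SDRF and ground truth."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.theoretical_peptides_range
    n = config.n_proteins
    accs = [f"PROT{i:05d}" for i in range(n)]
    seqs = _random_sequences(rng, n, lo, hi)
    fasta = dict(zip(accs, seqs))
    for acc, seq in list(fasta.items()):
        fasta["DECOY_" + acc] = seq[::-1]

    n_present = int(round(config.fraction_present * n))
    present_idx = rng.choice(n, size=n_present, replace=False)
    present = {acc: False for acc in accs}
    for i in present_idx:
        present[accs[i]] = True

    regulated = set()
    if config.regulated_fraction > 0 and config.fold_changes:
        n_reg = int(round(config.regulated_fraction * n_present))
        regulated = {accs[i] for i in rng.choice(present_idx, size=n_reg, replace=False)}

    base_abund = 10.0 ** rng.normal(
        config.log10_abundance_mu, config.log10_abundance_sigma, size=n
    )
    abundance: dict[tuple[str, str], float] = {}
    for i, acc in enumerate(accs):
        if not present[acc]:
            continue
        for cond in config.conditions:
            fc = config.fold_changes.get(cond, 1.0) if acc in regulated else 1.0
            abundance[(acc, cond)] = base_abund[i] * fc

    # peptide detection: beta-binomial thinning of the theoretical digest
    from .quantify import tryptic_peptides

    detected: dict[str, list[str]] = {}
    for i, acc in enumerate(accs):
        if not present[acc]:
            continue
        theor = [p for p in tryptic_peptides(seqs[i]) if 6 <= len(p) <= 30]
        p_mean = min(max(config.peptides_per_protein_mean / len(theor), 0.02), 1.0)
        conc = config.peptides_per_protein_dispersion
        p_det = rng.beta(p_mean * conc, (1.0 - p_mean) * conc + 1e-9) if p_mean < 1 else 1.0
        mask = rng.random(len(theor)) < p_det
        peps = [p for p, m in zip(theor, mask) if m]
        if not peps:
            peps = [theor[int(rng.integers(len(theor)))]]
        detected[acc] = peps

    engines = _ENGINES[: config.n_engines]
    run_conditions = [
        config.conditions[r % len(config.conditions)] for r in range(config.n_runs)
    ]
    per_engine: dict[str, list[PsmRecord]] = {e: [] for e in engines}
    psm_correct: dict[tuple[str, str], bool] = {}
    taken_peptides: set[str] = {p for peps in detected.values() for p in peps}
    scan = 0

    def _emit(run, peptide, accessions, is_decoy, correct, scores, intensity):
        nonlocal scan
        scan += 1
        ref = f"scan{scan:07d}"
        if not is_decoy:
            psm_correct[(run, ref)] = correct
        charge = int(2 + (scan % 2))
        for e, s in zip(engines, scores):
            per_engine[e].append(
                PsmRecord(
                    run=run,
                    spectrum_ref=ref,
                    peptide=peptide,
                    charge=charge,
                    engine_scores={e: float(s)},
                    is_decoy=is_decoy,
                    accessions=accessions,
                    intensity=intensity,
                )
            )

    for r in range(config.n_runs):
        cond = run_conditions[r]
        run = f"run{r + 1}"
        correct_jobs = [
            (acc, pep)
            for acc in accs
            if present[acc]
            for pep in detected[acc]
            for _ in range(config.psms_per_peptide)
        ]
        n_correct = len(correct_jobs)
        sc = _engine_scores(rng, n_correct, len(engines), config.rho, config.delta)
        noise = 10.0 ** rng.normal(0.0, config.intensity_sigma, size=n_correct)
        miss = rng.random(n_correct) < config.missingness
        for j, (acc, pep) in enumerate(correct_jobs):
            intensity = None if miss[j] else float(abundance[(acc, cond)] * noise[j])
            _emit(run, pep, (acc,), False, True, sc[j], intensity)

        n_null = int(round(config.incorrect_rate * n_correct))
        sc_inc = _engine_scores(rng, n_null, len(engines), config.rho, 0.0)
        sc_dec = _engine_scores(rng, n_null, len(engines), config.rho, 0.0)
        inc_intens = 10.0 ** rng.normal(1.5, 0.5, size=n_null)
        host_idx = rng.integers(0, n, size=2 * n_null)
        for j in range(n_null):
            pep = _random_peptide(rng, taken_peptides)
            _emit(
                run, pep, (accs[host_idx[j]],), False, False, sc_inc[j],
                float(inc_intens[j]),
            )
        for j in range(n_null):
            pep = _random_peptide(rng, taken_peptides)
            _emit(
                run, pep, ("DECOY_" + accs[host_idx[n_null + j]],), True, False,
                sc_dec[j], None,
            )

    sdrf = _sdrf_text(config, run_conditions)
    truth = GroundTruth(present=present, abundance=abundance, psm_correct=psm_correct)
    return SimulatedDataset(
        per_engine=per_engine, fasta=fasta, sdrf=sdrf, truth=truth, config=config
    )


def _sdrf_text(config: SimulationConfig, run_conditions: list[str]) -> str:
    header = [
        "source name",
        "characteristics[organism]",
        "assay name",
        "comment[label]",
        "comment[fraction identifier]",
        "comment[technical replicate]",
        "comment[data file]",
        "factor value[condition]",
    ]
    lines = ["\t".join(header)]
    for r, cond in enumerate(run_conditions, start=1):
        for f in range(1, config.n_fractions + 1):
            run = f"run{r}" if config.n_fractions == 1 else f"run{r}_f{f}"
            lines.append(
                "\t".join(
                    [
                        f"sample{r}",
                        "homo sapiens",
                        f"assay{r}",
                        "label free sample",
                        str(f),
                        "1",
                        f"{run}.mzML",
                        cond,
                    ]
                )
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Lightweight samplers for calibration studies
# ---------------------------------------------------------------------------


def simulate_psm_scores(
    rng: np.random.Generator,
    n_correct: int = 3500,
    n_incorrect: int = 750,
    delta: float = 3.0,
):
    """Scores + decoy flags + correctness labels for one synthetic run.

    Correct target scores ~ N(delta, 1); incorrect target scores and an equal
    number of decoy scores ~ N(0, 1).  Returns (scores, is_decoy, is_correct)
    arrays; ``is_correct`` is defined for targets only (decoys False).
    """
    s_corr = rng.normal(delta, 1.0, size=n_correct)
    s_inc = rng.normal(0.0, 1.0, size=n_incorrect)
    s_dec = rng.normal(0.0, 1.0, size=n_incorrect)
    scores = np.concatenate([s_corr, s_inc, s_dec])
    decoy = np.concatenate(
        [np.zeros(n_correct + n_incorrect, bool), np.ones(n_incorrect, bool)]
    )
    correct = np.concatenate(
        [np.ones(n_correct, bool), np.zeros(2 * n_incorrect, bool)]
    )
    return scores, decoy, correct


def simulate_protein_qlists(
    rng: np.random.Generator,
    n_datasets: int = 3,
    n_proteins_range: tuple[int, int] = (500, 2000),
    true_fraction: float = 0.5,
    delta: float = 3.0,
    universe_size: int = 4000,
):
    """Per-dataset protein (accession, q) lists with known true/false labels.

    Each dataset samples its proteins from a shared universe of true proteins
    (true hits replicate across datasets) while false-positive hits get
    dataset-unique accessions (spurious identifications rarely recur).  True
    protein scores ~ N(delta, 1), false scores ~ N(0, 1); each dataset's
    nominal q-value is the oracle tail FDR of that generating mixture,

        q(s) = n_false P0(S >= s) / (n_false P0(S >= s) + n_true P1(S >= s)),

    which models a well-calibrated upstream inference procedure — the premise
    under which the stand-in-decoy merge is neutral.

    Returns (lists, labels): ``lists`` maps dataset id -> list of
    (accession, q); ``labels`` maps accession -> True (true protein) / False.
    """
    from scipy.stats import norm as _norm

    universe = [f"TRUE{i:05d}" for i in range(universe_size)]
    lists: dict[str, list[tuple[str, float]]] = {}
    labels: dict[str, bool] = {}
    for d in range(n_datasets):
        ds = f"DS{d + 1}"
        n = int(rng.integers(n_proteins_range[0], n_proteins_range[1] + 1))
        n_true = int(round(true_fraction * n))
        n_false = n - n_true
        true_accs = list(
            np.array(universe)[rng.choice(universe_size, size=n_true, replace=False)]
        )
        false_accs = [f"FALSE_{ds}_{i:05d}" for i in range(n_false)]
        scores = np.concatenate(
            [rng.normal(delta, 1.0, size=n_true), rng.normal(0.0, 1.0, size=n_false)]
        )
        sf0 = _norm.sf(scores, 0.0, 1.0)
        sf1 = _norm.sf(scores, delta, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.minimum(
                n_false * sf0 / np.maximum(n_false * sf0 + n_true * sf1, 1e-300), 1.0
            )
        lists[ds] = [
            (acc, float(qv)) for acc, qv in zip(true_accs + false_accs, q)
        ]
        for acc in true_accs:
            labels[acc] = True
        for acc in false_accs:
            labels[acc] = False
    return lists, labels


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------


def qc_metrics(psms, groups=None, spectrum_totals: dict[str, int] | None = None) -> dict:
    """QC bundle: peptides/protein histogram, PEP deciles, id rates, scores.

    ``spectrum_totals`` (run -> total spectra) enables the identification-rate
    metric; without totals the metric is omitted.  Returns a JSON-serializable
    dict; empty inputs give empty metrics.
    """
    metrics: dict = {}
    peps = [r.pep for r in psms if r.pep is not None]
    if peps:
        deciles = np.percentile(peps, np.arange(0, 101, 10))
        metrics["pep_deciles"] = [float(x) for x in deciles]
    if groups is not None:
        hist: dict[int, int] = {}
        for g in groups:
            k = len(g.peptides)
            hist[k] = hist.get(k, 0) + 1
        metrics["peptides_per_protein"] = {str(k): hist[k] for k in sorted(hist)}
    engine_scores: dict[str, list[float]] = {}
    per_run_ids: dict[str, set[str]] = {}
    for r in psms:
        per_run_ids.setdefault(r.run, set()).add(r.spectrum_ref)
        for e, s in r.engine_scores.items():
            engine_scores.setdefault(e, []).append(s)
    if engine_scores:
        metrics["engine_score_summary"] = {
            e: {
                "mean": float(np.mean(v)),
                "sd": float(np.std(v)),
                "n": len(v),
            }
            for e, v in sorted(engine_scores.items())
        }
    if spectrum_totals:
        metrics["identification_rate"] = {
            run: len(per_run_ids.get(run, ())) / total
            for run, total in sorted(spectrum_totals.items())
            if total > 0
        }
    return metrics


# ---------------------------------------------------------------------------
# End-to-end harness
# ---------------------------------------------------------------------------


def end_to_end(config: SimulationConfig, alpha: float = 0.01) -> dict:
    """Run score -> consensus -> FDR -> inference -> quantification on one
    synthetic dataset and compare every stage against the ground truth.

    Returns a report with PSM/protein counts, realized false-discovery
    proportions at ``alpha``, sensitivity, and the Spearman correlation of
    IBAQ with true abundance.
    """
    from scipy.stats import spearmanr

    sim = simulate_dataset(config)
    engines = sorted(sim.per_engine)
    for e in engines:
        recs = sim.per_engine[e]
        scores = [r.engine_scores[e] for r in recs]
        flags = [r.is_decoy for r in recs]
        fit = fit_pep_mixture(scores, flags, seed=config.seed)
        peps = fit.pep(scores)
        for r, p in zip(recs, peps):
            r.pep = float(p)

    consensus = consensus_psm(sim.per_engine)
    q = target_decoy_qvalues([(-r.pep, r.is_decoy) for r in consensus])
    for r, v in zip(consensus, q):
        r.q_value = float(v)
    psm_pass = filter_at_fdr(consensus, alpha)
    n_false_psm = sum(
        1 for r in psm_pass if not sim.truth.psm_correct[(r.run, r.spectrum_ref)]
    )
    n_true_total = sum(1 for v in sim.truth.psm_correct.values() if v)

    pep_q = peptide_level_qvalues(consensus)
    # decoy PSMs pass through the peptide filter so the picked protein
    # competition keeps its decoy population
    pept_pass = [
        r for r in consensus if r.is_decoy or pep_q[r.peptide] <= alpha
    ]
    groups = aggregate_inference(pept_pass)
    survivors = picked_protein_fdr(groups)
    prot_pass = filter_at_fdr(survivors, alpha)
    n_false_prot = sum(
        1
        for g in prot_pass
        if not any(sim.truth.present.get(a, False) for a in g.accessions)
    )

    quantifiable = quantifiability_filter(prot_pass)
    pep_rows = pd.DataFrame(
        [
            {
                "peptide": r.peptide,
                "charge": r.charge,
                "run": r.run,
                "channel": "LF",
                "intensity": r.intensity,
            }
            for r in psm_pass
        ],
        columns=["peptide", "charge", "run", "channel", "intensity"],
    )
    ibaq_spearman = float("nan")
    if quantifiable and len(pep_rows):
        quant = protein_intensity(pep_rows, quantifiable)
        quant = compute_ibaq(quant, sim.fasta)
        cond = config.conditions[0]
        truth_vals, est_vals = [], []
        for row in quant.itertuples(index=False):
            key = (row.accession, cond)
            if key in sim.truth.abundance and np.isfinite(row.ibaq):
                truth_vals.append(sim.truth.abundance[key])
                est_vals.append(row.ibaq)
        if len(truth_vals) >= 3:
            ibaq_spearman = float(spearmanr(truth_vals, est_vals).statistic)

    return {
        "config": asdict(config),
        "alpha": alpha,
        "n_consensus_psms": len(consensus),
        "n_psms_passing": len(psm_pass),
        "psm_fdp": n_false_psm / len(psm_pass) if psm_pass else 0.0,
        "psm_sensitivity": (len(psm_pass) - n_false_psm) / max(n_true_total, 1),
        "n_protein_groups": len(groups),
        "n_proteins_passing": len(prot_pass),
        "protein_fdp": n_false_prot / len(prot_pass) if prot_pass else 0.0,
        "n_quantifiable": len(quantifiable),
        "ibaq_spearman": ibaq_spearman,
        "qc": qc_metrics(consensus, groups),
    }
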