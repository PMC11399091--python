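"""Shared fixtures and independent brute-force oracles.

The oracles recompute FDR quantities by direct counting (O(n^2) comparisons,
no sorting tricks) so the fast implementations can be checked against them
exactly.  They are deliberately written in the most literal style possible.
"""

from __future__ import annotations

import numpy as np
import pytest


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------


def oracle_qvalues(scores, decoys):
    """Direct-counting q-values: for every record count decoys/targets at or
    above its score, cap at 1, then take the minimum FDR over all records
    scoring no better (brute-force monotonization)."""
    scores = np.asarray(scores, dtype=float)
    decoys = np.asarray(decoys, dtype=bool)
    n = len(scores)
    fdr = np.empty(n)
    for i in range(n):
        at_or_above = scores >= scores[i]
        d = int(np.sum(at_or_above & decoys))
        t = int(np.sum(at_or_above & ~decoys))
        fdr[i] = min(d / t, 1.0) if t > 0 else 1.0
    q = np.empty(n)
    for i in range(n):
        q[i] = fdr[scores <= scores[i]].min()
    return q


def oracle_picked(pairs, unpaired):
    """Brute-force picked FDR on explicit (target_score, decoy_score) pairs.

    Scores are PEP-like (lower = better).  ``unpaired`` is a list of
    (score, is_decoy) singletons that survive unconditionally.  Returns the
    survivor list [(score, is_decoy)] and the oracle q per target survivor,
    aligned with targets sorted best-to-worst.
    """
    survivors = []
    for t_score, d_score in pairs:
        if t_score <= d_score:
            survivors.append((t_score, False))
        else:
            survivors.append((d_score, True))
    survivors.extend(unpaired)
    ranking = [(-s, d) for s, d in survivors]
    q = oracle_qvalues([r[0] for r in ranking], [r[1] for r in ranking])
    targets = sorted(
        [(s, qi) for (s, d), qi in zip(survivors, q) if not d], key=lambda x: x[0]
    )
    return survivors, [qi for _s, qi in targets]


def oracle_reestimate(entries, monotonize=True):
    """Brute-force re-estimated q-hat for merged (q, is_decoy) entries.

    For every target: count decoys and targets with nominal q as good or
    better (<=), ratio capped at 1; monotonization takes the minimum raw
    ratio over all targets with nominal q at or above the target's.
    Returns q-hat per target in ascending nominal-q order.
    """
    qs = np.asarray([e[0] for e in entries], dtype=float)
    dec = np.asarray([e[1] for e in entries], dtype=bool)
    t_q = np.sort(qs[~dec])
    raw = np.empty(len(t_q))
    for i, q in enumerate(t_q):
        d = int(np.sum(dec & (qs <= q)))
        t = int(np.sum(~dec & (qs <= q)))
        raw[i] = min(d / t, 1.0)
    if not monotonize:
        return raw
    out = np.empty_like(raw)
    for i, q in enumerate(t_q):
        out[i] = raw[t_q >= q].min()
    return out


def regex_digest_count(sequence, min_len=6, max_len=30):
    """Regex-based tryptic digestion oracle (cleave after K/R, not before P)."""
    import re

    peptides = re.split(r"(?<=[KR])(?!P)", sequence.strip().upper())
    peptides = [p for p in peptides if p]
    return sum(1 for p in peptides if min_len <= len(p) <= max_len)


def binomial_interval(n, p):
    """Central 95% interval for a Binomial(n, p) count."""
    from scipy.stats import binom

    return binom.ppf(0.025, n, p), binom.ppf(0.975, n, p)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

SDRF_HEADER = (
    "source name\tcharacteristics[organism]\tassay name\tcomment[label]\t"
    "comment[fraction identifier]\tcomment[technical replicate]\t"
    "comment[data file]\tfactor value[phenotype]"
)


@pytest.fixture
def sdrf_text():
    """Two label-free samples, one raw file each."""
    return (
        SDRF_HEADER + "\n"
        "sample1\thomo sapiens\tassay1\tlabel free sample\t1\t1\ta1.raw\tcontrol\n"
        "sample2\thomo sapiens\tassay2\tlabel free sample\t1\t1\ta2.raw\tdisease\n"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
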