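"""Nucleotide divergence estimation and molecular-clock dating.

Two estimators are provided: the Kimura two-parameter (K2P) distance on
arbitrary (non-coding) alignments, used for LTR pairs, and the Nei–Gojobori
(1986) synonymous distance Ks for in-frame coding sequence, used for tandem
gene duplications.  Either divergence K converts to an age through the
neutral clock, age = K / (2 r), with r the per-year substitution rate of the
appropriate compartment: LTRs evolve at twice the gene rate, so the default
clock uses gene_rate = 6.5e-9 and ltr_rate = 1.3e-8 substitutions/site/year.

Columns containing gaps or N are removed before counting (pairwise
deletion).  Unaligned pairs are first globally aligned with an affine-gap
Needleman–Wunsch (match +1, mismatch -1, gap open 5, extend 1).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Data import CodonTable

from zeinhap.genomic_model import ClockParams

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


class SaturationError(ValueError):
    """Distance is inestimable: observed divergence at or beyond model saturation."""


class FrameError(ValueError):
    """Coding input whose length is not a whole number of codons."""


class DegenerateInputError(ValueError):
    """No comparable sites remain after pairwise deletion."""


@dataclass(frozen=True)
class SiteCounts:
    """Aligned-site summary: n comparable sites, transition and transversion proportions."""

    n: int
    P: float
    Q: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise DegenerateInputError("no comparable sites")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise ValueError(f"invalid proportions P={self.P}, Q={self.Q}")


@dataclass(frozen=True)
class DistanceEstimate:
    """A divergence estimate in substitutions/site with its sampling variance."""

    K: float
    variance: float
    n: int


@dataclass(frozen=True)
class DatedEvent:
    """An insertion or duplication with its clock-converted age in mya."""

    event_id: str
    kind: str  # "re_insertion" | "gene_duplication"
    K_or_Ks: float
    age: float  # mya
    age_se: float  # mya
    rate_used: float  # substitutions/site/year


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="global")
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def is_transition(x: str, y: str) -> bool:
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


def pairwise_site_counts(a: str, b: str, prealigned: bool = False) -> SiteCounts:
    """Transition/transversion proportions between two sequences.

    With ``prealigned`` the inputs must be equal-length gapped strings;
    otherwise they are globally aligned first.  Columns containing '-' or
    'N' in either sequence are dropped (pairwise deletion).
    """
    a, b = a.upper(), b.upper()
    if prealigned:
        if len(a) != len(b):
            raise ValueError("prealigned sequences must have equal length")
        cols = zip(a, b)
    else:
        aln = _global_aligner().align(a.replace("-", ""), b.replace("-", ""))[0]
        cols = zip(aln[0], aln[1])
    n = ts = tv = 0
    for x, y in cols:
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise DegenerateInputError("zero comparable sites after pairwise deletion")
    return SiteCounts(n=n, P=ts / n, Q=tv / n)


def k2p(counts: SiteCounts) -> DistanceEstimate:
    """Kimura two-parameter distance with its delta-method variance.

    K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)); the variance uses
    c1 = 1/(1-2P-Q), c2 = 1/(1-2Q), c3 = (c1+c2)/2:
    var = (c1^2 P + c3^2 Q - (c1 P + c3 Q)^2) / n.
    """
    P, Q, n = counts.P, counts.Q, counts.n
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g} (P={P:.4g}, Q={Q:.4g})"
        )
    K = -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 normalises -0.0
    c1 = 1 / w1
    c2 = 1 / w2
    c3 = 0.5 * (c1 + c2)
    variance = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / n
    return DistanceEstimate(K=K, variance=variance, n=n)


def date_ltr_pair(
    ltr5: str, ltr3: str, clock: ClockParams | None = None, prealigned: bool = False,
    event_id: str = "ltr_pair",
) -> DatedEvent:
    """Date a retroelement insertion from the divergence of its two LTRs.

    The LTRs are identical at insertion and each accumulates substitutions
    at ``ltr_rate`` thereafter, so age = K / (2 ltr_rate).
    """
    clock = clock or ClockParams()
    if not ltr5 or not ltr3:
        raise ValueError("both LTRs must be non-empty")
    est = k2p(pairwise_site_counts(ltr5, ltr3, prealigned=prealigned))
    denom = 2 * clock.ltr_rate * 1e6
    return DatedEvent(
        event_id=event_id,
        kind="re_insertion",
        K_or_Ks=est.K,
        age=est.K / denom,
        age_se=math.sqrt(max(est.variance, 0.0)) / denom,
        rate_used=clock.ltr_rate,
    )


# ---------------------------------------------------------------------------
# Nei–Gojobori (1986) synonymous distance

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD.stop_codons)


def _aa(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return _STANDARD.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon: per position, the fraction of the
    three possible changes that are synonymous (changes to stops count as
    non-synonymous)."""
    total = 0.0
    ref = _aa(codon)
    for pos in range(3):
        syn = 0
        for base in _VALID - {codon[pos]}:
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _aa(alt) == ref:
                syn += 1
        total += syn / 3
    return total


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/non-synonymous difference counts over all minimal
    mutational pathways between two codons; pathways through stop codons are
    excluded when any stop-free pathway exists."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[tuple[int, int]] = []
    stop_free: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                hit_stop = True
            if not hit_stop and _aa(cur) == _aa(nxt):
                sd += 1
            elif not hit_stop:
                nd += 1
            else:
                nd += 1  # steps at/after a stop counted non-synonymous
            cur = nxt
        paths.append((sd, nd))
        if not hit_stop:
            stop_free.append((sd, nd))
    use = stop_free or paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def ks_ng86(cds_a: str, cds_b: str) -> DistanceEstimate:
    """Nei–Gojobori synonymous distance between two aligned in-frame CDS.

    Counts synonymous sites S (averaged over the two sequences) and
    synonymous differences Sd over all codon pairs free of stops, gaps and
    ambiguity; ps = Sd/S is Jukes–Cantor corrected,
    Ks = -3/4 ln(1 - 4 ps / 3).
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("coding sequences must be aligned to equal length")
    if len(a) % 3:
        raise FrameError(f"length {len(a)} is not a multiple of 3")
    S_a = S_b = Sd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if set(ca) - _VALID or set(cb) - _VALID:
            continue
        if ca in _STOPS or cb in _STOPS:
            continue  # stop codons excluded from site counts
        used += 1
        S_a += _syn_sites(ca)
        S_b += _syn_sites(cb)
        Sd += _path_counts(ca, cb)[0]
    if used == 0:
        raise DegenerateInputError("no comparable stop-free codons")
    S = 0.5 * (S_a + S_b)
    if S <= 0:
        raise DegenerateInputError("zero synonymous sites")
    ps = Sd / S
    if ps >= 0.75:
        raise SaturationError(f"NG86 saturated: ps={ps:.4g} >= 0.75")
    Ks = -0.75 * math.log(1 - 4 * ps / 3)
    # delta-method variance of the Jukes-Cantor corrected ps
    var_ps = ps * (1 - ps) / S
    variance = var_ps / (1 - 4 * ps / 3) ** 2
    return DistanceEstimate(K=Ks, variance=variance, n=round(S))


def date_duplication(
    ks: DistanceEstimate, clock: ClockParams | None = None, event_id: str = "duplication"
) -> DatedEvent:
    """Date a gene duplication from its synonymous divergence, age = Ks/(2 gene_rate)."""
    clock = clock or ClockParams()
    if not math.isfinite(ks.K):
        raise ValueError("Ks must be finite")
    denom = 2 * clock.gene_rate * 1e6
    return DatedEvent(
        event_id=event_id,
        kind="gene_duplication",
        K_or_Ks=ks.K,
        age=ks.K / denom,
        age_se=math.sqrt(max(ks.variance, 0.0)) / denom,
        rate_used=clock.gene_rate,
    )
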