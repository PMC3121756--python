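"""Gene-copy status, promoter motifs, composition/conservation summaries,
insertion chronology and helitron terminal structure.

Copy status follows a fixed precedence — a physical retroelement disruption
dominates point defects, which dominate truncation calls:
re_disrupted > start_loss > truncated > premature_stop > intact.
The truncation threshold (80% of the intact model length) is configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from zeinhap.genomic_model import (
    AnnotatedHaplotype,
    Feature,
    FeatureKind,
    reverse_complement,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}

IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class CopyStatus:
    status: str  # intact | premature_stop | truncated | start_loss | re_disrupted
    detail: str = ""


@dataclass
class MotifHit:
    motif_name: str
    pattern: str
    offset_upstream: int  # 1-based bp from the A of ATG to the motif's 5'-most window base
    strand: str


@dataclass
class CompositionSummary:
    total_len: int
    re_pct: float
    dna_te_pct: float
    genic_pct: float
    intergenic_pct: float
    conserved_pct: float


@dataclass
class ChronologyReport:
    ordered: list[tuple[str, float]]  # (event_id, age mya), oldest first
    violations: list[tuple[str, str]] = field(default_factory=list)


def classify_copy_status(
    gene_seq: str,
    model_len: int,
    overlapping_insertions: list[Feature] | None = None,
    truncation_fraction: float = 0.8,
) -> CopyStatus:
    """Classify a gene copy against an intact family model.

    Precedence: re_disrupted (any overlapping retroelement feature) >
    start_loss (first codon is not ATG) > truncated (shorter than
    ``truncation_fraction`` x model length, or no in-frame stop) >
    premature_stop (in-frame stop before the model's stop codon) > intact.
    """
    if not gene_seq:
        raise ValueError("empty gene sequence")
    if model_len <= 0:
        raise ValueError("model_len must be positive")
    seq = gene_seq.upper()
    if overlapping_insertions:
        res = [
            f for f in overlapping_insertions
            if f.kind in (FeatureKind.retroelement, FeatureKind.ltr)
        ]
        if res:
            return CopyStatus(
                "re_disrupted",
                f"insertion {res[0].feature_id} overlaps the coding span",
            )
    if seq[:3] != "ATG":
        return CopyStatus("start_loss", f"first codon is {seq[:3]}, not ATG")
    stops = [
        i // 3
        for i in range(0, len(seq) - len(seq) % 3, 3)
        if seq[i : i + 3] in STOP_CODONS
    ]
    if len(seq) < truncation_fraction * model_len:
        return CopyStatus(
            "truncated", f"length {len(seq)} < {truncation_fraction:g} x {model_len}"
        )
    if not stops:
        return CopyStatus("truncated", "no in-frame stop codon in the sequence")
    model_stop_codon = model_len // 3 - 1
    if stops[0] < model_stop_codon:
        return CopyStatus("premature_stop", f"stop at codon {stops[0]}")
    return CopyStatus("intact", "")


def iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(
        c if len(cls := IUPAC_CLASSES[c]) == 1 else f"[{cls}]"
        for c in pattern.upper()
    ))


def scan_promoter_motifs(
    promoter: str,
    motifs: list[tuple[str, str]],
    strands: str = "both",
) -> list[MotifHit]:
    """Scan a promoter window (3' end adjacent to the A of ATG) for IUPAC motifs.

    ``offset_upstream`` of a hit is the distance from the ATG to the
    window-leftmost (5'-most, farthest) base of the match, so a P-box whose
    8 bases span 300..293 bp upstream reports offset 300.  Both strands are
    scanned; overlapping matches are all reported.
    """
    window = promoter.upper()
    L = len(window)
    hits: list[MotifHit] = []
    for name, pattern in motifs:
        if len(pattern) > L:
            import warnings

            warnings.warn(
                f"motif {name!r} ({len(pattern)} bp) longer than window ({L} bp)",
                stacklevel=2,
            )
            continue
        rx = re.compile(f"(?=({iupac_regex(pattern).pattern}))")
        if strands in ("both", "+"):
            for m in rx.finditer(window):
                hits.append(MotifHit(name, pattern, L - m.start(), "+"))
        if strands in ("both", "-"):
            rc = reverse_complement(window)
            for m in rx.finditer(rc):
                # match [j, j+k) on the reverse strand maps to window
                # [L-j-k, L-j); leftmost window base offset = j + k
                hits.append(MotifHit(name, pattern, m.start() + len(pattern), "-"))
    hits.sort(key=lambda h: (-h.offset_upstream, h.motif_name, h.strand))
    return hits


_RE_KINDS = {FeatureKind.retroelement}
_DNA_TE_KINDS = {FeatureKind.dna_transposon, FeatureKind.helitron}


def composition_summary(
    hap: AnnotatedHaplotype, conserved_blocks: list[tuple[int, int]] | None = None
) -> CompositionSummary:
    """Partition every contig base into RE / DNA-TE / genic / intergenic.

    Overlaps resolve by precedence RE > DNA-TE > genic; nested elements are
    counted once.  conserved_pct is computed independently from the supplied
    block list (percent of the contig covered).
    """
    n = len(hap.contig)
    paint = np.zeros(n, dtype=np.int8)  # 0 intergenic, 1 genic, 2 dna_te, 3 re
    for f in hap.features:
        if f.kind == FeatureKind.zein_gene:
            paint[f.start : f.end] = np.maximum(paint[f.start : f.end], 1)
    for f in hap.features:
        if f.kind in _DNA_TE_KINDS:
            paint[f.start : f.end] = np.maximum(paint[f.start : f.end], 2)
    for f in hap.features:
        if f.kind in _RE_KINDS:
            paint[f.start : f.end] = 3
    counts = np.bincount(paint, minlength=4)
    conserved = 0
    if conserved_blocks:
        cov = np.zeros(n, dtype=bool)
        for s, e in conserved_blocks:
            if not 0 <= s < e <= n:
                raise ValueError(f"conserved block [{s},{e}) outside contig")
            cov[s:e] = True
        conserved = int(cov.sum())
    pct = lambda c: 100.0 * c / n  # noqa: E731
    return CompositionSummary(
        total_len=n,
        re_pct=pct(counts[3]),
        dna_te_pct=pct(counts[2]),
        genic_pct=pct(counts[1]),
        intergenic_pct=pct(counts[0]),
        conserved_pct=pct(conserved),
    )


# ---------------------------------------------------------------------------
# Conserved coverage by exact-seed chaining


def conserved_blocks(
    a: str,
    b: str,
    min_identity: float = 0.95,
    min_block: int = 500,
    k: int = 50,
    max_seed_gap: int = 200,
    max_kmer_hits: int = 10,
) -> list[tuple[int, int]]:
    """Syntenic blocks of ``a`` matching ``b``: exact k-mer seeds grouped by
    alignment diagonal, chained when closer than ``max_seed_gap``, and the
    chained span verified base-by-base for identity >= ``min_identity``.
    Returns merged intervals on ``a``."""
    a, b = a.upper(), b.upper()
    if len(a) < k or len(b) < k:
        return []
    index: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        index.setdefault(b[j : j + k], []).append(j)
    # seeds grouped by diagonal (i - j)
    by_diag: dict[int, list[int]] = {}
    step = max(k // 2, 1)
    for i in range(0, len(a) - k + 1, step):
        hits = index.get(a[i : i + k])
        if not hits or len(hits) > max_kmer_hits:
            continue
        for j in hits:
            by_diag.setdefault(i - j, []).append(i)
    blocks: list[tuple[int, int]] = []
    for diag, starts in by_diag.items():
        starts.sort()
        chain_start = prev = starts[0]
        for i in starts[1:] + [None]:  # type: ignore[list-item]
            if i is not None and i - prev <= max_seed_gap + k:
                prev = i
                continue
            s, e = chain_start, prev + k
            # verify identity over the chained span on this diagonal
            js = s - diag
            je = e - diag
            if js >= 0 and je <= len(b):
                seg_a, seg_b = a[s:e], b[js:je]
                ident = sum(x == y for x, y in zip(seg_a, seg_b)) / len(seg_a)
                if ident >= min_identity and (e - s) >= min_block:
                    blocks.append((s, e))
            if i is not None:
                chain_start = prev = i
    if not blocks:
        return []
    blocks.sort()
    merged = [blocks[0]]
    for s, e in blocks[1:]:
        if s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(e, merged[-1][1]))
        else:
            merged.append((s, e))
    return merged


def conserved_coverage(
    hap_a: AnnotatedHaplotype | str,
    hap_b: AnnotatedHaplotype | str,
    min_identity: float = 0.95,
    min_block: int = 500,
    **kwargs,
) -> float:
    """Percent of haplotype A covered by conserved blocks shared with B."""
    a = hap_a if isinstance(hap_a, str) else hap_a.contig.seq
    b = hap_b if isinstance(hap_b, str) else hap_b.contig.seq
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    blocks = conserved_blocks(a, b, min_identity=min_identity, min_block=min_block,
                              **kwargs)
    covered = sum(e - s for s, e in blocks)
    return 100.0 * covered / len(a)


def insertion_chronology(
    events: list, containment: list[tuple[str, str]] | None = None
) -> ChronologyReport:
    """Order dated events oldest to youngest and flag nesting violations.

    ``containment`` lists (nested_id, host_id) pairs; a nested element older
    than its host is appended to ``violations``.
    """
    by_id = {e.event_id: e for e in events}
    ordered = sorted(events, key=lambda e: -e.age)
    violations: list[tuple[str, str]] = []
    for nested_id, host_id in containment or []:
        if nested_id not in by_id or host_id not in by_id:
            raise ValueError(
                f"containment pair ({nested_id}, {host_id}) references unknown events"
            )
        if by_id[nested_id].age > by_id[host_id].age + 1e-12:
            violations.append((nested_id, host_id))
    return ChronologyReport(
        ordered=[(e.event_id, e.age) for e in ordered], violations=violations
    )


def detect_helitron(
    window: str,
    stem_len: int = 8,
    max_loop: int = 12,
    tail_len: int = 100,
) -> tuple[bool, str]:
    """Check a window for helitron terminal structure.

    Candidate iff the window starts with TC, ends with CTAG, and a hairpin
    (self-complementary stem >= ``stem_len`` with loop <= ``max_loop``)
    occurs within ``tail_len`` bp of the 3' end.
    """
    seq = window.upper()
    if len(seq) < 100:
        raise ValueError("window must be at least 100 bp")
    if not seq.startswith("TC"):
        return False, "no 5'-TC terminus"
    if not seq.endswith("CTAG"):
        return False, "no CTAG-3' terminus"
    tail = seq[-tail_len:]
    for a in range(len(tail) - 2 * stem_len):
        stem = tail[a : a + stem_len]
        want = reverse_complement(stem)
        for loop in range(0, max_loop + 1):
            b = a + stem_len + loop
            if b + stem_len > len(tail):
                break
            if tail[b : b + stem_len] == want:
                pos = len(seq) - tail_len + a
                return True, (
                    f"hairpin stem {stem_len} bp at {pos}, loop {loop} bp"
                )
    return False, "termini present but no hairpin near the 3' end"
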