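"""Per-cytosine bisulfite methylation calling on promoter amplicons.

The analysis is top-strand only: amplicons come from one primer pair per
locus, so symmetric CG methylation on the bottom strand is out of reach and
not inferred.  Contexts are assigned from the reference alone (CG, CHG, CHH
with H = A/C/T); a read contributes C (methylated) or T (converted) at each
reference cytosine, any other base at that position is treated as sequencing
error and excluded from the site's coverage.  No conversion-efficiency
correction is applied; the overall converted fraction is reported as a crude
QC note instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from zeinhap.genomic_model import BisulfiteRead


class DegenerateProfileError(ValueError):
    """No usable reads survived alignment filtering."""


@dataclass
class CytosineSite:
    """One top-strand reference cytosine with its context and call counts.

    ``offset_upstream`` is 1-based distance from the A of ATG: the last base
    of a 500-bp promoter window is 1 bp upstream.
    """

    offset_upstream: int
    context: str  # CG | CHG | CHH
    n_methylated: int = 0
    n_total: int = 0
    flagged: bool = False  # trailing C with insufficient 3' sequence

    @property
    def pct(self) -> float | None:
        if self.n_total == 0:
            return None
        return 100.0 * self.n_methylated / self.n_total


@dataclass
class MethylationProfile:
    """Per-cytosine methylation of one locus promoter in one tissue."""

    locus: str
    tissue: str
    sites: list[CytosineSite] = field(default_factory=list)
    conversion_note: str = ""
    n_reads_used: int = 0
    n_reads_dropped: int = 0


def cytosine_contexts(reference: str) -> list[CytosineSite]:
    """Classify every top-strand C of the reference promoter.

    CG if the next base is G; CHG if the next is H (A/C/T) and the base
    after that is G; CHH otherwise.  Cs within the last two bases that
    cannot be fully classified default to CHH and are flagged.
    """
    ref = reference.upper()
    n = len(ref)
    sites: list[CytosineSite] = []
    for i, base in enumerate(ref):
        if base != "C":
            continue
        nxt = ref[i + 1] if i + 1 < n else None
        nxt2 = ref[i + 2] if i + 2 < n else None
        flagged = False
        if nxt == "G":
            context = "CG"
        elif nxt is None:
            context, flagged = "CHH", True
        elif nxt2 == "G":
            context = "CHG"
        elif nxt2 is None:
            context, flagged = "CHH", True
        else:
            context = "CHH"
        sites.append(
            CytosineSite(offset_upstream=n - i, context=context, flagged=flagged)
        )
    return sites


def _bisulfite_aligner() -> Align.PairwiseAligner:
    """Global aligner whose scoring treats reference C vs read T as a match."""
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGT":
        for y in "ACGT":
            mat[x, y] = 1.0 if x == y else -1.0
    mat["C", "T"] = 1.0  # conversion-aware: target C may read as T
    for x in "ACGTN":
        mat["N", x] = 0.0
        mat[x, "N"] = 0.0
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def _aligned_read(reference: str, read: str) -> tuple[str, float]:
    """Project a read onto reference coordinates.

    Returns a string of reference length (read base per reference position,
    '-' where the read has a gap) and the conversion-aware identity over
    reference positions.
    """
    if len(read) == len(reference):
        proj = read
    else:
        aln = _bisulfite_aligner().align(reference, read)[0]
        ref_row, read_row = aln[0], aln[1]
        chars = []
        for r, q in zip(ref_row, read_row):
            if r == "-":
                continue  # insertion in read relative to reference
            chars.append(q if q != "-" else "-")
        proj = "".join(chars)
    matches = sum(
        1 for r, q in zip(reference, proj) if q == r or (r == "C" and q == "T")
    )
    return proj, matches / len(reference)


def call_site_methylation(
    reads: list[BisulfiteRead],
    reference: str,
    min_identity: float = 0.9,
    locus: str | None = None,
    tissue: str | None = None,
) -> MethylationProfile:
    """Call per-cytosine percent methylation from bisulfite clone reads.

    Reads are aligned to the reference with conversion-aware matching
    (reference C matches read C or T); reads below ``min_identity`` are
    dropped and counted.  At each reference C, a read showing C is counted
    methylated, T unmethylated, anything else excluded from coverage.
    """
    reference = reference.upper()
    sites = cytosine_contexts(reference)
    c_positions = [len(reference) - s.offset_upstream for s in sites]
    used = dropped = 0
    retained = converted = 0
    for read in reads:
        proj, identity = _aligned_read(reference, read.seq)
        if identity < min_identity:
            dropped += 1
            continue
        used += 1
        for site, pos in zip(sites, c_positions):
            q = proj[pos]
            if q == "C":
                site.n_methylated += 1
                site.n_total += 1
                retained += 1
            elif q == "T":
                site.n_total += 1
                converted += 1
    if used == 0:
        raise DegenerateProfileError(
            f"no usable reads (all {dropped} below identity {min_identity})"
        )
    total = retained + converted
    note = (
        f"{converted}/{total} cytosine observations converted "
        f"({100 * converted / total:.1f}%); no conversion correction applied"
        if total
        else "no cytosine observations"
    )
    return MethylationProfile(
        locus=locus or (reads[0].locus if reads else "unknown"),
        tissue=tissue or (reads[0].tissue if reads else "unknown"),
        sites=sites,
        conversion_note=note,
        n_reads_used=used,
        n_reads_dropped=dropped,
    )


def context_averages(profile: MethylationProfile) -> dict[str, float | None]:
    """Arithmetic mean of per-site percent methylation within each context.

    Contexts absent from the reference (or with no covered sites) map to
    None — e.g. a promoter whose cytosines are exclusively CHH yields CG and
    CHG as not-applicable.
    """
    out: dict[str, float | None] = {}
    for context in ("CG", "CHG", "CHH"):
        pcts = [
            s.pct for s in profile.sites if s.context == context and s.pct is not None
        ]
        out[context] = float(np.mean(pcts)) if pcts else None
    return out


def compare_tissue_profiles(
    profiles: list[MethylationProfile], min_coverage: int = 10
) -> tuple[list[dict], list[dict]]:
    """Pairwise per-site and per-context differences between tissue profiles.

    The first profile is the reference; every other profile is compared to
    it (alt - ref).  Sites with coverage below ``min_coverage`` in either
    profile are masked: excluded from per-site deltas and from the context
    means.  All profiles must be over the same reference (same site offsets
    and contexts).
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to compare")
    ref = profiles[0]
    key = [(s.offset_upstream, s.context) for s in ref.sites]
    for p in profiles[1:]:
        if [(s.offset_upstream, s.context) for s in p.sites] != key:
            raise ValueError(
                f"profile {p.tissue!r} is over a different reference than {ref.tissue!r}"
            )
    site_rows: list[dict] = []
    context_rows: list[dict] = []
    for alt in profiles[1:]:
        deltas_by_context: dict[str, list[float]] = {"CG": [], "CHG": [], "CHH": []}
        for s_ref, s_alt in zip(ref.sites, alt.sites):
            masked = s_ref.n_total < min_coverage or s_alt.n_total < min_coverage
            delta = (
                None
                if masked or s_ref.pct is None or s_alt.pct is None
                else s_alt.pct - s_ref.pct
            )
            site_rows.append(
                {
                    "ref_tissue": ref.tissue,
                    "alt_tissue": alt.tissue,
                    "offset_upstream": s_ref.offset_upstream,
                    "context": s_ref.context,
                    "delta_pct": delta,
                    "masked": masked,
                }
            )
            if delta is not None:
                deltas_by_context[s_ref.context].append(delta)
        for context, deltas in deltas_by_context.items():
            context_rows.append(
                {
                    "ref_tissue": ref.tissue,
                    "alt_tissue": alt.tissue,
                    "context": context,
                    "mean_delta_pct": float(np.mean(deltas)) if deltas else None,
                    "n_sites": len(deltas),
                }
            )
    return site_rows, context_rows
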