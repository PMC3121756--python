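"""Shared domain types and FASTA/GFF3 I/O.

Internal coordinates are 0-based half-open throughout the package; GFF3's
1-based inclusive convention is converted at the file boundary.  Minus-strand
feature sequences are returned reverse-complemented, so downstream code
always sees the coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.iterators import DataIterator


class FormatError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally invalid annotation (spans, parents, labels)."""


VALID_LOCI = {"z1A1", "z1A2", "z1B", "z1C1", "z1C2", "z1D", "custom"}

_IUPAC = set("ACGTNRYSWKMBDHV")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class FeatureKind(str, Enum):
    zein_gene = "zein_gene"
    retroelement = "retroelement"
    dna_transposon = "dna_transposon"
    helitron = "helitron"
    ltr = "ltr"
    tsd = "tsd"
    promoter = "promoter"
    other = "other"


@dataclass
class GenomicSequence:
    """A named DNA sequence (contig, gene copy, LTR, promoter...)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - _IUPAC
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """An annotated interval on a contig, 0-based half-open."""

    feature_id: str
    kind: FeatureKind
    start: int
    end: int
    strand: str = "+"
    parent: str | None = None
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kind = FeatureKind(self.kind)
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"feature {self.feature_id!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Feature") -> bool:
        return self.start <= other.start and other.end <= self.end

    def abuts(self, other: "Feature") -> bool:
        return other.end == self.start or other.start == self.end


@dataclass
class AnnotatedHaplotype:
    """One inbred's contig at one locus, with its typed features.

    Features are kept sorted by start.  ``ltr`` children must lie inside
    their retroelement parent; ``tsd`` children must abut it (target-site
    duplications flank the element by construction).
    """

    inbred: str
    locus: str
    contig: GenomicSequence
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.locus not in VALID_LOCI:
            raise ValidationError(
                f"locus {self.locus!r} not in {sorted(VALID_LOCI)}; use 'custom'"
            )
        self.features.sort(key=lambda f: (f.start, f.end))
        self.validate()

    def validate(self) -> None:
        index = {f.feature_id: f for f in self.features}
        if len(index) != len(self.features):
            seen: set[str] = set()
            for f in self.features:
                if f.feature_id in seen:
                    raise ValidationError(f"duplicate feature id {f.feature_id!r}")
                seen.add(f.feature_id)
        n = len(self.contig)
        for f in self.features:
            if f.end > n:
                raise ValidationError(
                    f"feature {f.feature_id!r} span [{f.start},{f.end}) exceeds "
                    f"contig length {n}"
                )
            if f.parent is not None:
                if f.parent not in index:
                    raise ValidationError(
                        f"feature {f.feature_id!r} references unknown parent {f.parent!r}"
                    )
                parent = index[f.parent]
                if f.kind in (FeatureKind.ltr, FeatureKind.tsd) and parent.kind not in (
                    FeatureKind.retroelement,
                ):
                    raise ValidationError(
                        f"{f.kind.value} feature {f.feature_id!r} must have a "
                        f"retroelement parent, got {parent.kind.value}"
                    )
                if f.kind == FeatureKind.tsd:
                    if not (parent.contains(f) or parent.abuts(f)):
                        raise ValidationError(
                            f"tsd {f.feature_id!r} neither inside nor abutting "
                            f"parent {f.parent!r}"
                        )
                elif not parent.contains(f):
                    raise ValidationError(
                        f"child {f.feature_id!r} span [{f.start},{f.end}) outside "
                        f"parent {f.parent!r} span [{parent.start},{parent.end})"
                    )

    def feature(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"no feature {feature_id!r} in haplotype {self.inbred}/{self.locus}")

    def features_of_kind(self, kind: FeatureKind) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def children_of(self, feature_id: str) -> list[Feature]:
        return [f for f in self.features if f.parent == feature_id]


@dataclass
class CloneRecord:
    """A consensus cDNA clone sequence from one sample."""

    clone_id: str
    seq: str
    sample: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"clone {self.clone_id!r}: empty sequence")
        if not self.sample:
            raise ValidationError(f"clone {self.clone_id!r}: sample label required")
        self.seq = self.seq.upper()


@dataclass
class BisulfiteRead:
    """A bisulfite-converted clone read from one locus amplicon and tissue."""

    read_id: str
    seq: str
    locus: str
    tissue: str

    VALID_TISSUES = ("leaf", "endosperm", "cultured_endosperm")

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValidationError(f"read {self.read_id!r}: empty sequence")
        if self.tissue not in self.VALID_TISSUES:
            raise ValidationError(
                f"read {self.read_id!r}: tissue {self.tissue!r} not in {self.VALID_TISSUES}"
            )
        self.seq = self.seq.upper()


@dataclass
class ClockParams:
    """Molecular-clock rates in substitutions/site/year.

    The LTR clock runs twice as fast as the gene clock; a ratio other than
    2 is accepted with a warning.  ``kappa`` is the transition/transversion
    rate ratio of the substitution model.
    """

    gene_rate: float = 6.5e-9
    ltr_rate: float = 1.3e-8
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.gene_rate <= 0 or self.ltr_rate <= 0 or self.kappa <= 0:
            raise ValidationError("clock rates and kappa must be positive")
        if abs(self.ltr_rate - 2 * self.gene_rate) > 1e-12 * self.ltr_rate:
            warnings.warn(
                f"ltr_rate ({self.ltr_rate:g}) is not 2 x gene_rate "
                f"({self.gene_rate:g}); ages from the two clocks will not be "
                "on a common timescale",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# File I/O


def parse_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a multi-record FASTA into GenomicSequence records, order preserved."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found (empty or malformed file)")
    out: list[GenomicSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append(GenomicSequence(id=rec.id, seq=str(rec.seq).upper(), description=desc))
    return out


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            header = f">{s.id}" + (f" {s.description}" if s.description else "")
            fh.write(header + "\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


_KIND_TO_GFF = {k: k.value for k in FeatureKind}
_GFF_TO_KIND = {v: k for k, v in _KIND_TO_GFF.items()}


def parse_gff3(path: str | Path, contigs: list[GenomicSequence]) -> list[AnnotatedHaplotype]:
    """Read GFF3 annotations onto the given contigs.

    One AnnotatedHaplotype is returned per contig that carries features.
    ``region``-type rows may carry ``inbred`` and ``locus`` attributes naming
    the haplotype; otherwise both default to placeholders.  Coordinates are
    converted from GFF3 1-based inclusive to 0-based half-open.
    """
    path = Path(path)
    by_id = {c.id: c for c in contigs}
    feats: dict[str, list[Feature]] = {c.id: [] for c in contigs}
    meta: dict[str, dict[str, str]] = {}
    for row in DataIterator(str(path)):
        if row.seqid not in by_id:
            raise FormatError(f"{path}: unknown seqid {row.seqid!r}")
        attrs = {k: v[0] for k, v in row.attributes.items() if v}
        if row.featuretype == "region":
            meta[row.seqid] = attrs
            continue
        kind = _GFF_TO_KIND.get(row.featuretype, FeatureKind.other)
        fid = attrs.pop("ID", None) or f"{row.seqid}:{row.featuretype}:{row.start}"
        parent = attrs.pop("Parent", None)
        feats[row.seqid].append(
            Feature(
                feature_id=fid,
                kind=kind,
                start=row.start - 1,
                end=row.end,
                strand=row.strand if row.strand in "+-" else "+",
                parent=parent,
                attributes=attrs,
            )
        )
    out = []
    for cid, flist in feats.items():
        if not flist and cid not in meta:
            continue
        m = meta.get(cid, {})
        out.append(
            AnnotatedHaplotype(
                inbred=m.get("inbred", "unknown"),
                locus=m.get("locus", "custom"),
                contig=by_id[cid],
                features=flist,
            )
        )
    return out


def write_gff3(haps: Iterable[AnnotatedHaplotype], path: str | Path) -> None:
    """Write haplotypes as GFF3 (region row per contig, features with Parent links)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for hap in haps:
            cid = hap.contig.id
            fh.write(f"##sequence-region {cid} 1 {len(hap.contig)}\n")
            fh.write(
                f"{cid}\tzeinhap\tregion\t1\t{len(hap.contig)}\t.\t+\t.\t"
                f"ID=region-{cid};inbred={hap.inbred};locus={hap.locus}\n"
            )
            for f in hap.features:
                attrs = [f"ID={f.feature_id}"]
                if f.parent:
                    attrs.append(f"Parent={f.parent}")
                attrs += [f"{k}={v}" for k, v in sorted(f.attributes.items())]
                fh.write(
                    f"{cid}\tzeinhap\t{_KIND_TO_GFF[f.kind]}\t{f.start + 1}\t{f.end}"
                    f"\t.\t{f.strand}\t.\t{';'.join(attrs)}\n"
                )


def extract_feature_sequence(hap: AnnotatedHaplotype, feature_id: str) -> GenomicSequence:
    """Substring of the contig at a feature, reverse-complemented for minus strand."""
    f = hap.feature(feature_id)
    sub = hap.contig.seq[f.start : f.end]
    if f.strand == "-":
        sub = reverse_complement(sub)
    return GenomicSequence(
        id=feature_id, seq=sub, description=f"{f.kind.value} {hap.contig.id}:{f.start}-{f.end}({f.strand})"
    )
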