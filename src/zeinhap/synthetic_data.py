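"""Synthetic haplotypes, clone libraries and bisulfite reads with known truth.

The generator emulates the structures of a tandemly amplified storage-protein
locus in a pair of inbred haplotypes: aged gene copies sharing a common
ancestor, retroelement insertions (shared, haplotype-specific and nested)
whose two LTRs have diverged according to a neutral clock, target-site
duplications flanking every element, multinomially sampled cDNA clone
libraries with sequencing error, and bisulfite-converted promoter reads with
per-cytosine methylation probabilities and imperfect conversion.  Every
stochastic choice is recorded in a SyntheticTruth ledger so downstream
estimators can be tested for parameter recovery.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` child streams (ancestral sequences, per-copy
evolution, per-element evolution, placement, library sampling), so outputs
are byte-identical across runs and platforms for a given configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from zeinhap.genomic_model import (
    AnnotatedHaplotype,
    BisulfiteRead,
    ClockParams,
    CloneRecord,
    Feature,
    FeatureKind,
    GenomicSequence,
)

BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
# transition partner, then the two transversion partners, per base
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

DEFAULT_O2_MOTIF = "TCCACGTAGA"  # stand-in consensus for the Opaque2 target
DEFAULT_PBOX = "GTGTAAAG"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# K2P forward simulation


def k2p_sojourn(expected_divergence: float, kappa: float) -> tuple[float, float]:
    """Expected observed transition (P) and transversion (Q) proportions after
    evolving a sequence to ``expected_divergence`` substitutions/site under a
    K2P process with transition/transversion rate ratio ``kappa``.

    With transition rate a and per-transversion rate b (d = (a+2b)t):
    P(t) = 1/4 + 1/4 e^{-4bt} - 1/2 e^{-2(a+b)t},  Q(t) = 1/2 - 1/2 e^{-4bt}.
    The K2P estimator is the exact method-of-moments inverse of these, so
    distances estimated between input and output converge to d.
    """
    d = expected_divergence
    bt = d / (kappa + 2)
    at = kappa * bt
    P = 0.25 + 0.25 * math.exp(-4 * bt) - 0.5 * math.exp(-2 * (at + bt))
    Q = 0.5 - 0.5 * math.exp(-4 * bt)
    return P, Q


def evolve_sequence(
    seq: str,
    expected_divergence: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> str:
    """Evolve a sequence under the K2P substitution process.

    Each site is independently replaced by its transition partner with
    probability P and by each transversion partner with probability Q/2,
    where (P, Q) are the exact K2P sojourn probabilities for the requested
    divergence — so the K2P *estimate* between input and output converges to
    ``expected_divergence`` as length grows.  Non-ACGT characters are copied
    unchanged.  Deterministic given the seed.
    """
    if expected_divergence < 0:
        raise ConfigError(f"expected_divergence must be >= 0, got {expected_divergence}")
    if not seq:
        raise ConfigError("cannot evolve an empty sequence")
    if expected_divergence == 0:
        return seq
    rng = _rng(seed)
    P, Q = k2p_sojourn(expected_divergence, kappa)
    u = rng.random(len(seq))
    out = list(seq)
    for i, (base, x) in enumerate(zip(seq, u)):
        if base not in _BASE_INDEX:
            continue
        if x < P:
            out[i] = _TRANSITION[base]
        elif x < P + Q:
            # split the transversion mass evenly between the two partners
            out[i] = _TRANSVERSIONS[base][0 if (x - P) < Q / 2 else 1]
    return "".join(out)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class REInsertion:
    """One configured retroelement insertion.

    ``nested_in`` is the index of the host insertion in the configured list
    (the host must be older).  ``haplotype_specific`` elements are present
    only in ``carrier`` ("A" or "B").
    """

    age: float  # mya
    ltr_len: int = 1000
    body_len: int = 4000
    nested_in: int | None = None
    haplotype_specific: bool = False
    carrier: str = "B"
    family: str = "RE"

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ConfigError(f"insertion age must be >= 0, got {self.age}")
        if self.ltr_len < 1 or self.body_len < 1:
            raise ConfigError("ltr_len and body_len must be positive")
        if self.carrier not in ("A", "B"):
            raise ConfigError(f"carrier must be 'A' or 'B', got {self.carrier!r}")


def _default_insertions() -> list[REInsertion]:
    # The stated world: a 6.2-mya shared element, a 2.04-mya shared host
    # carrying a 1.19-mya nested element, a 0.12-mya haplotype-specific
    # element, and a brand-new (identical-LTR) nested haplotype-specific one.
    return [
        REInsertion(age=6.2, family="Gypsy35"),
        REInsertion(age=2.04, family="Prem2"),
        REInsertion(age=1.19, nested_in=1, family="Zeon2"),
        REInsertion(age=0.12, haplotype_specific=True, carrier="A", family="Zeon2"),
        REInsertion(age=0.0, nested_in=0, haplotype_specific=True, carrier="B",
                    family="Gypsy73"),
    ]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic locus pair.

    Defaults mirror the conditions reported for the maize alpha-zein loci:
    five gene copies with duplication ages from 11.9 to 0.5 mya, one copy
    (the youngest) carrying >90% of transcripts, clone libraries of three
    96-well plates with 0.5% per-base error, bisulfite sets of one 96-well
    plate with 0.5% conversion failure, and a 5-bp target-site duplication.
    """

    seed: int = 0
    n_zein_copies: int = 5
    copy_ages: Sequence[float] = (11.9, 2.2, 1.4, 0.6, 0.5)
    re_insertions: list[REInsertion] = field(default_factory=_default_insertions)
    tsd_len: int = 5
    expression_fractions: Sequence[float] = (0.02, 0.03, 0.05, 0.90, 0.0)
    clone_error_rate: float = 0.005
    n_clones: int = 288
    methylation_probs: Sequence[float] | None = None  # default pattern if None
    conversion_failure_rate: float = 0.005
    n_bs_reads: int = 96
    clock: ClockParams = field(default_factory=ClockParams)
    # layout knobs
    gene_codons: int = 249  # CDS length 750 bp including stop
    promoter_len: int = 500
    intergenic_len: int = 3000
    flank_len: int = 2000
    absent_in_b: Sequence[int] = ()
    inbred_a: str = "B73"
    inbred_b: str = "BSSS53"
    locus: str = "custom"

    def validate(self) -> None:
        if self.n_zein_copies < 1:
            raise ConfigError("need at least one gene copy")
        if len(self.copy_ages) != self.n_zein_copies:
            raise ConfigError(
                f"copy_ages has {len(self.copy_ages)} entries for "
                f"{self.n_zein_copies} copies"
            )
        if any(a < 0 for a in self.copy_ages):
            raise ConfigError("copy ages must be >= 0")
        if len(self.expression_fractions) != self.n_zein_copies:
            raise ConfigError("expression_fractions must have one entry per copy")
        if any(not 0 <= f <= 1 for f in self.expression_fractions):
            raise ConfigError("expression fractions must lie in [0, 1]")
        if abs(sum(self.expression_fractions) - 1) > 1e-9:
            raise ConfigError(
                f"expression_fractions sum to {sum(self.expression_fractions)!r}, not 1"
            )
        for rate in (self.clone_error_rate, self.conversion_failure_rate):
            if not 0 <= rate <= 1:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        if self.tsd_len < 1:
            raise ConfigError("tsd_len must be >= 1")
        for i, ins in enumerate(self.re_insertions):
            if ins.nested_in is not None:
                if not 0 <= ins.nested_in < len(self.re_insertions) or ins.nested_in == i:
                    raise ConfigError(f"insertion {i}: bad nested_in {ins.nested_in}")
                host = self.re_insertions[ins.nested_in]
                if host.nested_in is not None:
                    raise ConfigError(
                        f"insertion {i}: host {ins.nested_in} is itself nested "
                        "(only one nesting level is simulated)"
                    )
                if host.age < ins.age:
                    raise ConfigError(
                        f"insertion {i} (age {ins.age}) nested in younger host "
                        f"{ins.nested_in} (age {host.age})"
                    )
                if host.haplotype_specific and (
                    not ins.haplotype_specific or ins.carrier != host.carrier
                ):
                    raise ConfigError(
                        f"insertion {i} nested in haplotype-specific host must be "
                        "specific to the same haplotype"
                    )
        if any(not 0 <= i < self.n_zein_copies for i in self.absent_in_b):
            raise ConfigError("absent_in_b indices out of range")
        if self.methylation_probs is not None and any(
            not 0 <= p <= 1 for p in self.methylation_probs
        ):
            raise ConfigError("methylation probabilities must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ledger of every true quantity behind one simulated locus pair."""

    true_ages: dict[str, float] = field(default_factory=dict)  # element/copy id -> mya
    copy_provenance: dict[str, str | None] = field(default_factory=dict)
    true_expression: dict[str, float] = field(default_factory=dict)
    true_methylation: list[float] = field(default_factory=list)
    insertion_order: list[str] = field(default_factory=list)  # oldest -> youngest
    nesting: dict[str, str] = field(default_factory=dict)  # nested id -> host id
    carriers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    clone_sources: dict[str, str] = field(default_factory=dict)
    promoter_reference: str = ""

    def validate(self) -> None:
        for nested, host in self.nesting.items():
            if self.true_ages[nested] > self.true_ages[host] + 1e-12:
                raise ConfigError(
                    f"truth inconsistent: nested {nested} older than host {host}"
                )


# ---------------------------------------------------------------------------
# Locus-pair simulation


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + TAA; length 3*(n_codons+1)."""
    stops = {"TAA", "TAG", "TGA"}
    codons = ["ATG"]
    while len(codons) < n_codons:
        c = "".join(BASES[rng.integers(0, 4, size=3)])
        if c not in stops:
            codons.append(c)
    return "".join(codons) + "TAA"


def _ancestral_promoter(rng: np.random.Generator, length: int) -> str:
    """Random promoter carrying the prolamin box (leftmost base 300 bp
    upstream of ATG) and the O2 motif on the lower strand (171 bp upstream)."""
    from zeinhap.genomic_model import reverse_complement

    seq = list(random_sequence(length, rng))
    pb_start = length - 300
    if pb_start >= 0:
        seq[pb_start : pb_start + len(DEFAULT_PBOX)] = DEFAULT_PBOX
    o2_rc = reverse_complement(DEFAULT_O2_MOTIF)
    o2_start = length - 171
    if o2_start >= 0:
        seq[o2_start : o2_start + len(o2_rc)] = o2_rc
    return "".join(seq)


@dataclass
class _Element:
    """Internal: one materialised insertion."""

    elem_id: str
    spec: REInsertion
    seq_ltr5: str
    body: str
    seq_ltr3: str
    position: int  # backbone coordinate (top-level) or raw-body offset (nested)
    children: list[int] = field(default_factory=list)  # indices into element list

    @property
    def raw_len(self) -> int:
        return len(self.seq_ltr5) + len(self.body) + len(self.seq_ltr3)


def _expand_element(
    elements: list[_Element], idx: int, present: set[int], tsd_len: int, backbone: str | None = None
) -> tuple[str, list[Feature]]:
    """Recursively expand an element with its nested insertions present in
    this haplotype, returning its final sequence and features in element-local
    coordinates (retroelement span, ltr children, nested features, TSDs of
    nested elements)."""
    e = elements[idx]
    raw = e.seq_ltr5 + e.body + e.seq_ltr3
    kids = sorted(
        (k for k in e.children if k in present), key=lambda k: elements[k].position
    )
    parts: list[str] = []
    feats: list[Feature] = []
    ltr_len = len(e.seq_ltr5)
    feats.append(
        Feature(f"{e.elem_id}_ltr5", FeatureKind.ltr, 0, ltr_len, "+", e.elem_id)
    )
    cursor = 0
    out = 0
    for k in kids:
        child = elements[k]
        o = child.position
        parts.append(raw[cursor:o])
        out += o - cursor
        tsd = raw[o : o + tsd_len]
        child_seq, child_feats = _expand_element(elements, k, present, tsd_len)
        feats.append(
            Feature(f"{child.elem_id}_tsd_l", FeatureKind.tsd, out, out + tsd_len, "+",
                    child.elem_id)
        )
        shift = out + tsd_len
        for cf in child_feats:
            parent = cf.parent
            if cf.feature_id == child.elem_id and cf.kind == FeatureKind.retroelement:
                parent = e.elem_id  # record the nesting relation
            feats.append(
                Feature(cf.feature_id, cf.kind, cf.start + shift, cf.end + shift,
                        cf.strand, parent, dict(cf.attributes))
            )
        parts.append(tsd + child_seq)
        out += tsd_len + len(child_seq)
        feats.append(
            Feature(f"{child.elem_id}_tsd_r", FeatureKind.tsd, out, out + tsd_len, "+",
                    child.elem_id)
        )
        cursor = o
    parts.append(raw[cursor:])
    out += len(raw) - cursor
    feats.append(
        Feature(f"{e.elem_id}_ltr3", FeatureKind.ltr, out - ltr_len, out, "+", e.elem_id)
    )
    feats.insert(
        0,
        Feature(e.elem_id, FeatureKind.retroelement, 0, out, "+", None,
                {"family": e.spec.family, "age_mya": f"{e.spec.age:g}"}),
    )
    return "".join(parts), feats


def simulate_locus_pair(
    config: SimulationConfig,
) -> tuple[AnnotatedHaplotype, AnnotatedHaplotype, SyntheticTruth]:
    """Simulate two haplotypes of one locus plus their truth ledger.

    Both haplotypes share the ancestral gene copies and all non-specific
    retroelements (byte-identical); haplotype-specific elements appear only
    in their carrier.  Each element's two LTRs are independently evolved
    from a common ancestral LTR by age x ltr_rate, so their expected pairwise
    divergence is 2 x age x ltr_rate.  Every element is flanked by an
    identical TSD of ``tsd_len`` bases duplicated from its insertion site.
    """
    config.validate()
    cfg = config
    clock = cfg.clock
    (anc_rng, copy_rng, elem_rng, place_rng, meth_rng) = _streams(cfg.seed, 5)

    truth = SyntheticTruth()

    # --- ancestral gene + promoter, aged copies -----------------------------
    anc_cds = _random_cds(anc_rng, cfg.gene_codons)
    anc_prom = _ancestral_promoter(anc_rng, cfg.promoter_len)
    gene_len = len(anc_cds)
    copies: list[tuple[str, str]] = []  # (promoter, cds) per copy
    copy_streams = copy_rng.spawn(cfg.n_zein_copies)
    for i, age in enumerate(cfg.copy_ages):
        d = age * 1e6 * clock.gene_rate
        rs = copy_streams[i]
        prom = evolve_sequence(anc_prom, d, clock.kappa, rs) if d > 0 else anc_prom
        cds = evolve_sequence(anc_cds, d, clock.kappa, rs) if d > 0 else anc_cds
        copies.append((prom, cds))
        cid = f"zein{i + 1}"
        truth.true_ages[cid] = float(age)
        truth.copy_provenance[cid] = f"zein{i}" if i else None
        truth.true_expression[cid] = float(cfg.expression_fractions[i])
        truth.carriers[cid] = ("A",) if i in cfg.absent_in_b else ("A", "B")

    # --- backbone in ancestral coordinates ----------------------------------
    parts = [random_sequence(cfg.flank_len, anc_rng)]
    pos = cfg.flank_len
    backbone_feats: list[Feature] = []
    intergenic: list[tuple[int, int]] = [(0, cfg.flank_len)]
    for i, (prom, cds) in enumerate(copies):
        backbone_feats.append(
            Feature(f"prom{i + 1}", FeatureKind.promoter, pos, pos + len(prom), "+",
                    None, {"copy": f"zein{i + 1}"})
        )
        parts.append(prom)
        pos += len(prom)
        backbone_feats.append(
            Feature(f"zein{i + 1}", FeatureKind.zein_gene, pos, pos + len(cds), "+",
                    None, {"age_mya": f"{cfg.copy_ages[i]:g}"})
        )
        parts.append(cds)
        pos += len(cds)
        spacer = random_sequence(cfg.intergenic_len, anc_rng)
        intergenic.append((pos, pos + len(spacer)))
        parts.append(spacer)
        pos += len(spacer)
    backbone = "".join(parts)

    # --- materialise elements ------------------------------------------------
    elements: list[_Element] = []
    elem_streams = elem_rng.spawn(max(len(cfg.re_insertions), 1) * 3)
    for i, spec in enumerate(cfg.re_insertions):
        anc_ltr = random_sequence(spec.ltr_len, elem_streams[3 * i])
        d = spec.age * 1e6 * clock.ltr_rate
        ltr5 = evolve_sequence(anc_ltr, d, clock.kappa, elem_streams[3 * i + 1]) if d else anc_ltr
        ltr3 = evolve_sequence(anc_ltr, d, clock.kappa, elem_streams[3 * i + 2]) if d else anc_ltr
        body = random_sequence(spec.body_len, elem_streams[3 * i])
        elements.append(_Element(f"re{i + 1}", spec, ltr5, body, ltr3, position=-1))

    # placement: top-level elements get distinct intergenic backbone positions,
    # nested ones an offset inside the host body (never inside an LTR)
    top = [i for i, s in enumerate(cfg.re_insertions) if s.nested_in is None]
    slots: list[int] = []
    for start, end in intergenic:
        lo, hi = start + 1, end - cfg.tsd_len - 1
        if hi > lo:
            slots.append((lo, hi))
    if len(slots) < 1 and top:
        raise ConfigError("no intergenic space for insertions")
    for j, i in enumerate(top):
        lo, hi = slots[j % len(slots)]
        elements[i].position = int(place_rng.integers(lo, hi))
    # keep distinct positions (re-draw collisions deterministically)
    taken: set[int] = set()
    for i in top:
        while elements[i].position in taken:
            lo, hi = slots[0]
            elements[i].position = int(place_rng.integers(lo, hi))
        taken.add(elements[i].position)
    for i, spec in enumerate(cfg.re_insertions):
        if spec.nested_in is not None:
            host = elements[spec.nested_in]
            lo = len(host.seq_ltr5) + 1
            hi = len(host.seq_ltr5) + len(host.body) - cfg.tsd_len - 1
            elements[i].position = int(place_rng.integers(lo, hi))
            host.children.append(i)

    for i, spec in enumerate(cfg.re_insertions):
        eid = f"re{i + 1}"
        truth.true_ages[eid] = float(spec.age)
        truth.carriers[eid] = (spec.carrier,) if spec.haplotype_specific else ("A", "B")
        if spec.nested_in is not None:
            truth.nesting[eid] = f"re{spec.nested_in + 1}"
    truth.insertion_order = [
        f"re{i + 1}"
        for i in sorted(range(len(cfg.re_insertions)),
                        key=lambda i: (-cfg.re_insertions[i].age, i))
    ]

    # --- linearise one haplotype ---------------------------------------------
    def _copy_index(f: Feature) -> int:
        tag = f.attributes.get("copy", f.feature_id)
        return int(tag.replace("zein", "")) - 1

    def build(hap_label: str, inbred: str) -> AnnotatedHaplotype:
        present = {
            i for i, s in enumerate(cfg.re_insertions)
            if (not s.haplotype_specific) or s.carrier == hap_label
        }
        absent_copies = set(cfg.absent_in_b) if hap_label == "B" else set()
        # one sweep over the backbone handling insertions and absent-copy
        # excisions in coordinate order
        events: list[tuple[int, str, object]] = [
            (elements[i].position, "ins", i) for i in top if i in present
        ]
        events += [
            (fi.start, "skip", (fi.start, fi.end))
            for fi in backbone_feats
            if _copy_index(fi) in absent_copies
        ]
        events.sort(key=lambda t: t[0])
        parts: list[str] = []
        feats: list[Feature] = []
        ins_blocks: list[tuple[int, int]] = []  # (backbone pos, inserted length)
        skips: list[tuple[int, int]] = []
        cursor = 0
        out = 0
        for p, what, payload in events:
            parts.append(backbone[cursor:p])
            out += p - cursor
            cursor = p
            if what == "ins":
                i = payload  # type: ignore[assignment]
                e = elements[i]
                tsd = backbone[p : p + cfg.tsd_len]
                elem_seq, elem_feats = _expand_element(elements, i, present, cfg.tsd_len)
                feats.append(
                    Feature(f"{e.elem_id}_tsd_l", FeatureKind.tsd, out,
                            out + cfg.tsd_len, "+", e.elem_id)
                )
                shift = out + cfg.tsd_len
                for cf in elem_feats:
                    feats.append(
                        Feature(cf.feature_id, cf.kind, cf.start + shift,
                                cf.end + shift, cf.strand, cf.parent,
                                dict(cf.attributes))
                    )
                parts.append(tsd + elem_seq)
                block = cfg.tsd_len + len(elem_seq)
                out += block
                feats.append(
                    Feature(f"{e.elem_id}_tsd_r", FeatureKind.tsd, out,
                            out + cfg.tsd_len, "+", e.elem_id)
                )
                ins_blocks.append((p, block))
                # cursor stays at p: the original TSD bases follow the block
            else:
                s, e_ = payload  # type: ignore[misc]
                skips.append((s, e_))
                cursor = e_
        parts.append(backbone[cursor:])
        seq = "".join(parts)

        for fi in backbone_feats:
            if _copy_index(fi) in absent_copies:
                continue
            delta = sum(L for p, L in ins_blocks if p <= fi.start)
            delta -= sum(e_ - s for s, e_ in skips if e_ <= fi.start)
            feats.append(
                Feature(fi.feature_id, fi.kind, fi.start + delta, fi.end + delta,
                        fi.strand, fi.parent, dict(fi.attributes))
            )
        contig = GenomicSequence(
            id=f"{inbred}_{cfg.locus}_hap{hap_label}", seq=seq,
            description=f"synthetic haplotype {hap_label}",
        )
        return AnnotatedHaplotype(inbred=inbred, locus=cfg.locus, contig=contig,
                                  features=feats)

    hap_a = build("A", cfg.inbred_a)
    hap_b = build("B", cfg.inbred_b)

    # --- methylation truth over the reference promoter -----------------------
    ref_prom = copies[0][0]
    truth.promoter_reference = ref_prom
    c_positions = [i for i, b in enumerate(ref_prom) if b == "C"]
    if cfg.methylation_probs is not None:
        if len(cfg.methylation_probs) != len(c_positions):
            raise ConfigError(
                f"methylation_probs has {len(cfg.methylation_probs)} entries but the "
                f"reference promoter has {len(c_positions)} top-strand cytosines"
            )
        truth.true_methylation = [float(p) for p in cfg.methylation_probs]
    else:
        # default pattern: five highly methylated CG-context peaks, low background
        from zeinhap.bisulfite_methylation import cytosine_contexts

        sites = cytosine_contexts(ref_prom)
        probs = []
        n_peaks = 0
        for s in sites:
            if s.context == "CG" and n_peaks < 5:
                probs.append(0.9)
                n_peaks += 1
            else:
                probs.append(0.05)
        truth.true_methylation = probs

    truth.validate()
    return hap_a, hap_b, truth


# ---------------------------------------------------------------------------
# Clone library


@dataclass
class CloneLibrary:
    """A simulated clone set plus its truth side channel (clone id -> source)."""

    clones: list[CloneRecord]
    sources: dict[str, str]


def simulate_clone_library(
    refdb: list[GenomicSequence],
    fractions: Sequence[float],
    n_clones: int,
    error_rate: float,
    seed: int | np.random.Generator,
    sample: str = "endosperm",
) -> CloneLibrary:
    """Draw cDNA clones multinomially from reference copies with per-base error."""
    if not refdb:
        raise ConfigError("reference database is empty")
    if len(fractions) != len(refdb):
        raise ConfigError("one fraction per reference copy required")
    if abs(sum(fractions) - 1) > 1e-9:
        raise ConfigError(f"fractions sum to {sum(fractions)!r}, not 1")
    if not 0 <= error_rate <= 1:
        raise ConfigError("error_rate must lie in [0, 1]")
    rng = _rng(seed)
    picks = rng.choice(len(refdb), size=n_clones, p=np.asarray(fractions, dtype=float))
    clones: list[CloneRecord] = []
    sources: dict[str, str] = {}
    for j, k in enumerate(picks):
        src = refdb[int(k)]
        seq = list(src.seq)
        if error_rate > 0:
            hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
            for i in hits:
                base = seq[i]
                if base in _BASE_INDEX:
                    alts = [b for b in "ACGT" if b != base]
                    seq[i] = alts[int(rng.integers(0, 3))]
        cid = f"{sample}_clone{j + 1}"
        clones.append(CloneRecord(clone_id=cid, seq="".join(seq), sample=sample))
        sources[cid] = src.id
    return CloneLibrary(clones=clones, sources=sources)


# ---------------------------------------------------------------------------
# Bisulfite reads


def simulate_bisulfite_reads(
    promoter: str,
    methylation_probs: Sequence[float],
    conversion_failure_rate: float,
    n_reads: int,
    seed: int | np.random.Generator,
    locus: str = "z1A",
    tissue: str = "endosperm",
) -> list[BisulfiteRead]:
    """Simulate top-strand bisulfite clone reads of a promoter amplicon.

    Each top-strand cytosine is retained as C with probability
    p_meth + (1 - p_meth) x conversion_failure_rate and otherwise written as
    T; all other bases are copied unchanged.
    """
    promoter = promoter.upper()
    c_positions = [i for i, b in enumerate(promoter) if b == "C"]
    if len(methylation_probs) != len(c_positions):
        raise ConfigError(
            f"{len(methylation_probs)} methylation probabilities for "
            f"{len(c_positions)} top-strand cytosines"
        )
    if not 0 <= conversion_failure_rate <= 1:
        raise ConfigError("conversion_failure_rate must lie in [0, 1]")
    rng = _rng(seed)
    retain_p = np.array(
        [p + (1 - p) * conversion_failure_rate for p in methylation_probs]
    )
    reads: list[BisulfiteRead] = []
    for j in range(n_reads):
        keep = rng.random(len(c_positions)) < retain_p
        seq = list(promoter)
        for pos, k in zip(c_positions, keep):
            seq[pos] = "C" if k else "T"
        reads.append(
            BisulfiteRead(
                read_id=f"{locus}_{tissue}_read{j + 1}",
                seq="".join(seq),
                locus=locus,
                tissue=tissue,
            )
        )
    return reads
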