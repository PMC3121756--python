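"""Run configuration, orchestration and report generation.

One validated RunConfig drives the whole analysis: in synthetic mode a locus
pair with known truth is generated and every stage runs on it (dating,
trees, annotation, expression, methylation); in user_data mode generation is
skipped and FASTA/GFF3 (plus optional clone and bisulfite FASTA) inputs are
analysed.  A single master seed deterministically spawns per-stage seeds, so
synthetic bundles are a pure function of (config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

import zeinhap
from zeinhap.genomic_model import (
    AnnotatedHaplotype,
    ClockParams,
    CloneRecord,
    BisulfiteRead,
    FeatureKind,
    GenomicSequence,
    extract_feature_sequence,
    parse_fasta,
    parse_gff3,
    write_fasta,
    write_gff3,
)
from zeinhap import divergence_dating as dd
from zeinhap import synthetic_data as sd
from zeinhap import phylo_trees as pt
from zeinhap import locus_annotation as la
from zeinhap import expression_attribution as ea
from zeinhap import bisulfite_methylation as bm

log = logging.getLogger("zeinhap.pipeline")


class ConfigError(ValueError):
    """Invalid run configuration; message lists every violation."""


@dataclass
class RunConfig:
    mode: str = "synthetic"
    seed: int | None = None
    outdir: str = "zeinhap_out"
    sim: sd.SimulationConfig | None = None
    clock: ClockParams = field(default_factory=ClockParams)
    # user_data inputs
    fasta: str | None = None
    gff3: str | None = None
    clones_fasta: str | None = None
    bisulfite_fasta: str | None = None
    bisulfite_reference: str | None = None
    # thresholds
    score_min: float | None = None
    margin_min: float = 2.0
    min_identity: float = 0.95
    min_block: int = 500
    min_coverage: int = 10
    alpha: float = 0.05
    fold_min: float = 2.0
    confidence: float = 0.95
    n_bootstrap: int = 200


def validate_config(raw: dict) -> RunConfig:
    """Build a RunConfig from a plain mapping, reporting all violations at once."""
    problems: list[str] = []
    known = {f for f in RunConfig.__dataclass_fields__}
    extra = set(raw) - known - {"clock", "sim"}
    if extra:
        problems.append(f"unknown keys: {sorted(extra)}")
    mode = raw.get("mode", "synthetic")
    if mode not in ("synthetic", "user_data"):
        problems.append(f"mode must be 'synthetic' or 'user_data', got {mode!r}")
    seed = raw.get("seed")
    if mode == "synthetic" and seed is None:
        problems.append("missing required field: seed (mandatory in synthetic mode)")
    clock_raw = raw.get("clock") or {}
    try:
        clock = clock_raw if isinstance(clock_raw, ClockParams) else ClockParams(**clock_raw)
    except (TypeError, ValueError) as err:
        problems.append(f"clock: {err}")
        clock = ClockParams()
    for key, lo, hi in (("alpha", 0, 1), ("confidence", 0, 1), ("min_identity", 0, 1)):
        val = raw.get(key)
        if val is not None and not lo < float(val) < hi:
            problems.append(f"{key} must lie in ({lo}, {hi}), got {val}")
    if mode == "user_data":
        for key in ("fasta", "gff3"):
            path = raw.get(key)
            if path is None:
                problems.append(f"missing required field: {key} (user_data mode)")
            elif not Path(path).exists():
                problems.append(f"{key} path does not exist: {path}")
        for key in ("clones_fasta", "bisulfite_fasta", "bisulfite_reference"):
            path = raw.get(key)
            if path is not None and not Path(path).exists():
                problems.append(f"{key} path does not exist: {path}")
    sim_raw = raw.get("sim") or {}
    sim: sd.SimulationConfig | None = None
    if mode == "synthetic":
        try:
            if isinstance(sim_raw, sd.SimulationConfig):
                sim = sim_raw
            else:
                sim_kwargs = dict(sim_raw)
                if "re_insertions" in sim_kwargs:
                    sim_kwargs["re_insertions"] = [
                        ins if isinstance(ins, sd.REInsertion) else sd.REInsertion(**ins)
                        for ins in sim_kwargs["re_insertions"]
                    ]
                sim = sd.SimulationConfig(
                    seed=int(seed or 0), clock=clock, **sim_kwargs
                )
            sim.validate()
        except (TypeError, ValueError) as err:
            problems.append(f"sim: {err}")
    if problems:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))
    kwargs = {
        k: raw[k]
        for k in known
        if k in raw and k not in ("clock", "sim", "mode", "seed")
    }
    return RunConfig(mode=mode, seed=seed, clock=clock, sim=sim, **kwargs)


@dataclass
class ReportBundle:
    outdir: Path
    files: dict[str, Path]
    dating: pd.DataFrame
    chronology: la.ChronologyReport | None
    trees: dict[str, pt.Tree]
    composition: pd.DataFrame
    copy_status: pd.DataFrame
    motifs: pd.DataFrame
    expression: pd.DataFrame | None
    expression_comparison: pd.DataFrame | None
    methylation_sites: pd.DataFrame | None
    methylation_context: pd.DataFrame | None
    manifest: dict


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(master).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


def _date_retroelements(
    haps: list[AnnotatedHaplotype], clock: ClockParams
) -> tuple[pd.DataFrame, list[dd.DatedEvent], list[tuple[str, str]]]:
    rows = []
    events: dict[str, dd.DatedEvent] = {}
    containment: list[tuple[str, str]] = []
    seen_pairs = set()
    for hap in haps:
        for re_feat in hap.features_of_kind(FeatureKind.retroelement):
            ltrs = sorted(
                (f for f in hap.children_of(re_feat.feature_id)
                 if f.kind == FeatureKind.ltr),
                key=lambda f: f.start,
            )
            if len(ltrs) != 2:
                log.warning("element %s: expected 2 LTRs, found %d — skipped",
                            re_feat.feature_id, len(ltrs))
                continue
            if re_feat.feature_id in events:
                continue  # shared element already dated from the other haplotype
            ltr5 = extract_feature_sequence(hap, ltrs[0].feature_id).seq
            ltr3 = extract_feature_sequence(hap, ltrs[1].feature_id).seq
            prealigned = len(ltr5) == len(ltr3)
            try:
                ev = dd.date_ltr_pair(ltr5, ltr3, clock, prealigned=prealigned,
                                      event_id=re_feat.feature_id)
            except dd.SaturationError as err:
                log.warning("element %s: %s", re_feat.feature_id, err)
                continue
            events[ev.event_id] = ev
            counts = dd.pairwise_site_counts(ltr5, ltr3, prealigned=prealigned)
            rows.append({
                "event_id": ev.event_id, "kind": ev.kind, "n": counts.n,
                "P": counts.P, "Q": counts.Q, "K": ev.K_or_Ks,
                "age_mya": ev.age, "age_se_mya": ev.age_se,
                "rate_used": ev.rate_used, "haplotype": hap.inbred,
            })
            if re_feat.parent:
                pair = (re_feat.feature_id, re_feat.parent)
                if pair not in seen_pairs:
                    containment.append(pair)
                    seen_pairs.add(pair)
    return pd.DataFrame(rows), list(events.values()), containment


def _date_duplications(
    copy_seqs: dict[str, str], provenance: dict[str, str | None], clock: ClockParams
) -> pd.DataFrame:
    rows = []
    for cid, parent in provenance.items():
        if parent is None or cid not in copy_seqs or parent not in copy_seqs:
            continue
        try:
            ks = dd.ks_ng86(copy_seqs[cid], copy_seqs[parent])
            ev = dd.date_duplication(ks, clock, event_id=f"{parent}->{cid}")
        except (dd.SaturationError, dd.FrameError, dd.DegenerateInputError) as err:
            log.warning("duplication %s->%s: %s", parent, cid, err)
            continue
        rows.append({
            "event_id": ev.event_id, "kind": ev.kind, "n": ks.n, "P": float("nan"),
            "Q": float("nan"), "K": ev.K_or_Ks, "age_mya": ev.age,
            "age_se_mya": ev.age_se, "rate_used": ev.rate_used, "haplotype": "shared",
        })
    return pd.DataFrame(rows)


def _copy_sequences(hap: AnnotatedHaplotype) -> dict[str, str]:
    return {
        f.feature_id: extract_feature_sequence(hap, f.feature_id).seq
        for f in hap.features_of_kind(FeatureKind.zein_gene)
    }


def _annotate(haps: list[AnnotatedHaplotype], model_len: int,
              motifs: list[tuple[str, str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    status_rows, motif_rows = [], []
    for hap in haps:
        for gene in hap.features_of_kind(FeatureKind.zein_gene):
            overlapping = [
                f for f in hap.features
                if f.kind in (FeatureKind.retroelement, FeatureKind.ltr)
                and f.start < gene.end and gene.start < f.end
            ]
            seq = extract_feature_sequence(hap, gene.feature_id).seq
            st = la.classify_copy_status(seq, model_len, overlapping)
            status_rows.append({
                "haplotype": hap.inbred, "copy_id": gene.feature_id,
                "status": st.status, "detail": st.detail,
            })
        for prom in hap.features_of_kind(FeatureKind.promoter):
            window = extract_feature_sequence(hap, prom.feature_id).seq
            for hit in la.scan_promoter_motifs(window, motifs):
                motif_rows.append({
                    "haplotype": hap.inbred, "promoter_id": prom.feature_id,
                    "motif": hit.motif_name, "offset_upstream": hit.offset_upstream,
                    "strand": hit.strand,
                })
    return pd.DataFrame(status_rows), pd.DataFrame(motif_rows)


def _composition(haps: list[AnnotatedHaplotype], cfg: RunConfig) -> pd.DataFrame:
    rows = []
    for hap, other in zip(haps, reversed(haps)):
        blocks = la.conserved_blocks(
            hap.contig.seq, other.contig.seq,
            min_identity=cfg.min_identity, min_block=cfg.min_block,
        ) if len(haps) == 2 else []
        summary = la.composition_summary(hap, blocks)
        rows.append({"haplotype": hap.inbred, "locus": hap.locus, **asdict(summary)})
    return pd.DataFrame(rows)


def _cultured_fractions(fracs: list[float]) -> list[float]:
    """Tissue-culture 'resetting' stand-in: reactivate the first silent copy
    with 20% of the pool taken from the dominant copy."""
    out = list(fracs)
    zeros = [i for i, f in enumerate(out) if f == 0]
    if not zeros:
        return out
    top = max(range(len(out)), key=out.__getitem__)
    shift = min(0.2, out[top] / 2)
    out[top] -= shift
    out[zeros[0]] += shift
    return out


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute every stage and write the report bundle under config.outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    manifest: dict = {
        "zeinhap_version": zeinhap.__version__,
        "numpy_version": np.__version__,
        "mode": config.mode,
        "seed": config.seed,
        "clock": asdict(config.clock),
    }

    truth: sd.SyntheticTruth | None = None
    clones: list[CloneRecord] = []
    bs_reference: str | None = None
    bs_reads: list[BisulfiteRead] = []

    if config.mode == "synthetic":
        assert config.sim is not None
        seeds = _stage_seeds(config.sim.seed)
        hap_a, hap_b, truth = sd.simulate_locus_pair(config.sim)
        haps = [hap_a, hap_b]
        write_fasta([h.contig for h in haps], outdir / "haplotypes.fasta")
        write_gff3(haps, outdir / "annotations.gff3")
        files["haplotypes"] = outdir / "haplotypes.fasta"
        files["annotations"] = outdir / "annotations.gff3"
        manifest["sim"] = {
            "n_zein_copies": config.sim.n_zein_copies,
            "copy_ages": list(config.sim.copy_ages),
            "re_ages": [i.age for i in config.sim.re_insertions],
            "n_clones": config.sim.n_clones,
            "n_bs_reads": config.sim.n_bs_reads,
        }
    else:
        contigs = parse_fasta(config.fasta)
        haps = parse_gff3(config.gff3, contigs)
        if not haps:
            raise ConfigError("no annotated contigs found in user inputs")
        if config.clones_fasta:
            clones = [
                CloneRecord(s.id, s.seq, s.description or "sample")
                for s in parse_fasta(config.clones_fasta)
            ]
        if config.bisulfite_fasta and config.bisulfite_reference:
            bs_reference = parse_fasta(config.bisulfite_reference)[0].seq
            bs_reads = [
                BisulfiteRead(s.id, s.seq, "z1A",
                              s.description.split()[0] if s.description else "leaf")
                for s in parse_fasta(config.bisulfite_fasta)
            ]
        seeds = _stage_seeds(config.seed or 0)

    # --- dating ------------------------------------------------------------
    re_table, re_events, containment = _date_retroelements(haps, config.clock)
    copy_seqs = _copy_sequences(haps[0])
    if truth is not None:
        provenance = truth.copy_provenance
    else:
        ids = sorted(copy_seqs)
        provenance = {cid: (ids[i - 1] if i else None) for i, cid in enumerate(ids)}
    dup_table = _date_duplications(copy_seqs, provenance, config.clock)
    dating = pd.concat([re_table, dup_table], ignore_index=True)
    dating.to_csv(outdir / "dating.tsv", sep="\t", index=False)
    files["dating"] = outdir / "dating.tsv"

    chronology = None
    if re_events:
        chronology = la.insertion_chronology(re_events, containment)
        pd.DataFrame(
            [{"event_id": eid, "age_mya": age} for eid, age in chronology.ordered]
        ).to_csv(outdir / "chronology.tsv", sep="\t", index=False)
        files["chronology"] = outdir / "chronology.tsv"
        manifest["chronology_violations"] = chronology.violations

    # --- trees -------------------------------------------------------------
    trees: dict[str, pt.Tree] = {}
    leaf_seqs = [
        (f"{hap.inbred}_{gene.feature_id}",
         extract_feature_sequence(hap, gene.feature_id).seq)
        for hap in haps
        for gene in hap.features_of_kind(FeatureKind.zein_gene)
    ]
    lengths = {len(s) for _, s in leaf_seqs}
    if len(leaf_seqs) >= 3 and len(lengths) == 1:
        for method in ("nj", "upgma"):
            tree = pt.bootstrap(
                leaf_seqs, method=method, n_reps=config.n_bootstrap, seed=seeds[1]
            )
            trees[method] = tree
            pt.write_newick(tree, str(outdir / f"tree_{method}.nwk"))
            files[f"tree_{method}"] = outdir / f"tree_{method}.nwk"
    else:
        log.warning("tree stage skipped: need >=3 equal-length gene sequences")

    # --- annotation summaries ----------------------------------------------
    model_len = max((len(s) for s in copy_seqs.values()), default=0)
    motifs = [("P-box", sd.DEFAULT_PBOX), ("O2", sd.DEFAULT_O2_MOTIF)]
    copy_status, motif_table = _annotate(haps, model_len, motifs)
    copy_status.to_csv(outdir / "copy_status.tsv", sep="\t", index=False)
    motif_table.to_csv(outdir / "motifs.tsv", sep="\t", index=False)
    composition = _composition(haps, config)
    composition.to_csv(outdir / "composition.tsv", sep="\t", index=False)
    files["copy_status"] = outdir / "copy_status.tsv"
    files["motifs"] = outdir / "motifs.tsv"
    files["composition"] = outdir / "composition.tsv"

    # --- expression ---------------------------------------------------------
    expression = expression_cmp = None
    refdb: ea.CopyReferenceDB | None = None
    if config.mode == "synthetic":
        assert config.sim is not None and truth is not None
        refdb = ea.CopyReferenceDB.from_sequences(
            [GenomicSequence(cid, seq) for cid, seq in sorted(copy_seqs.items())],
            locus=haps[0].locus, inbred=haps[0].inbred,
        )
        fracs = [truth.true_expression[cid] for cid in refdb.copy_ids]
        lib_ref = sd.simulate_clone_library(
            [GenomicSequence(cid, copy_seqs[cid]) for cid in refdb.copy_ids],
            fracs, config.sim.n_clones, config.sim.clone_error_rate, seeds[2],
            sample="endosperm",
        )
        lib_alt = sd.simulate_clone_library(
            [GenomicSequence(cid, copy_seqs[cid]) for cid in refdb.copy_ids],
            _cultured_fractions(fracs), config.sim.n_clones,
            config.sim.clone_error_rate, seeds[3], sample="cultured_endosperm",
        )
        truth.clone_sources.update(lib_ref.sources)
        truth.clone_sources.update(lib_alt.sources)
        clones = lib_ref.clones + lib_alt.clones
    profiles = {}
    if clones:
        db = refdb
        if db is None:
            db = ea.CopyReferenceDB.from_sequences(
                [GenomicSequence(cid, seq) for cid, seq in sorted(copy_seqs.items())]
            )
        by_sample: dict[str, list[CloneRecord]] = {}
        for c in clones:
            by_sample.setdefault(c.sample, []).append(c)
        rows = []
        for sample, recs in by_sample.items():
            assignments = ea.assign_clones(
                recs, db, score_min=config.score_min, margin_min=config.margin_min
            )
            prof = ea.expression_profile(assignments, sample, db.copy_ids)
            profiles[sample] = prof
            for cid in db.copy_ids:
                rows.append({
                    "sample": sample, "copy_id": cid, "count": prof.counts[cid],
                    "percent": prof.percents[cid],
                    "n_assigned": prof.n_assigned,
                    "n_ambiguous": prof.n_ambiguous,
                    "n_unassigned": prof.n_unassigned,
                })
            log.info("sample %s: %d assigned, %d ambiguous, %d unassigned",
                     sample, prof.n_assigned, prof.n_ambiguous, prof.n_unassigned)
        expression = pd.DataFrame(rows)
        expression.to_csv(outdir / "expression_profiles.tsv", sep="\t", index=False)
        files["expression"] = outdir / "expression_profiles.tsv"
        if "endosperm" in profiles and "cultured_endosperm" in profiles:
            cmps = ea.compare_profiles(
                profiles["endosperm"], profiles["cultured_endosperm"],
                alpha=config.alpha, fold_min=config.fold_min,
                confidence=config.confidence,
            )
            expression_cmp = pd.DataFrame([asdict(c) for c in cmps])
            expression_cmp.to_csv(
                outdir / "expression_comparison.tsv", sep="\t", index=False
            )
            files["expression_comparison"] = outdir / "expression_comparison.tsv"

    # --- methylation ---------------------------------------------------------
    meth_sites = meth_context = None
    meth_profiles: list[bm.MethylationProfile] = []
    if config.mode == "synthetic":
        assert config.sim is not None and truth is not None
        ref = truth.promoter_reference
        probs = truth.true_methylation
        cultured = [min(1.0, p + 0.25) for p in probs]
        for tissue, p_vec, seed in (
            ("endosperm", probs, seeds[4]),
            ("leaf", probs, seeds[5]),
            ("cultured_endosperm", cultured, seeds[6]),
        ):
            reads = sd.simulate_bisulfite_reads(
                ref, p_vec, config.sim.conversion_failure_rate,
                config.sim.n_bs_reads, seed, locus=haps[0].locus, tissue=tissue,
            )
            meth_profiles.append(bm.call_site_methylation(reads, ref))
        bs_reference = ref
    elif bs_reads and bs_reference:
        by_tissue: dict[str, list[BisulfiteRead]] = {}
        for r in bs_reads:
            by_tissue.setdefault(r.tissue, []).append(r)
        for tissue, rs in by_tissue.items():
            meth_profiles.append(
                bm.call_site_methylation(rs, bs_reference, tissue=tissue)
            )
    if meth_profiles:
        rows = []
        for prof in meth_profiles:
            for s in prof.sites:
                rows.append({
                    "tissue": prof.tissue, "offset_upstream": s.offset_upstream,
                    "context": s.context, "n_methylated": s.n_methylated,
                    "n_total": s.n_total, "pct": s.pct,
                })
        meth_sites = pd.DataFrame(rows)
        meth_sites.to_csv(outdir / "methylation_sites.tsv", sep="\t", index=False)
        files["methylation_sites"] = outdir / "methylation_sites.tsv"
        ctx_rows = []
        for prof in meth_profiles:
            for context, mean in bm.context_averages(prof).items():
                ctx_rows.append({
                    "tissue": prof.tissue, "context": context, "mean_pct": mean,
                })
        meth_context = pd.DataFrame(ctx_rows)
        meth_context.to_csv(outdir / "methylation_context.tsv", sep="\t", index=False)
        files["methylation_context"] = outdir / "methylation_context.tsv"
        if len(meth_profiles) >= 2:
            site_rows, context_rows = bm.compare_tissue_profiles(
                meth_profiles, min_coverage=config.min_coverage
            )
            pd.DataFrame(site_rows).to_csv(
                outdir / "methylation_deltas.tsv", sep="\t", index=False
            )
            files["methylation_deltas"] = outdir / "methylation_deltas.tsv"
            manifest["methylation_context_deltas"] = context_rows

    manifest["files"] = {k: p.name for k, p in sorted(files.items())}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = outdir / "manifest.json"

    return ReportBundle(
        outdir=outdir, files=files, dating=dating, chronology=chronology,
        trees=trees, composition=composition, copy_status=copy_status,
        motifs=motif_table, expression=expression,
        expression_comparison=expression_cmp, methylation_sites=meth_sites,
        methylation_context=meth_context, manifest=manifest,
    )
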