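"""End-to-end pipeline driver over the library modules.

Stages run in dependency order (simulate -> annotate -> {orf, snps, novel}
-> de); each stage reads and writes plain-text files under ``out_dir`` so
runs are inspectable and byte-reproducible for a fixed seed. Outputs are
written to temporary paths and renamed on success.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from . import dge, homology, novelreg, orfproj, snps
from .io_formats import (
    GeneModel,
    read_ace,
    read_blast_tabular,
    read_counts,
    read_fasta,
    read_gff3_models,
    read_gmt,
    read_orthology,
    write_ace,
    write_blast_tabular,
    write_counts,
    write_fasta,
    write_gff3,
    write_orthology,
    write_tsv,
)
from .syndata import (
    SimConfig,
    generate_assemblies,
    generate_counts,
    generate_hit_table,
    generate_isotigs,
    generate_reference_panel,
)

log = logging.getLogger("isopipe")

DEFAULT_CONTRASTS = (("C.1", "C.3"), ("C.2", "C.4"), ("C.1", "C.2"), ("C.3", "C.4"))


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All thresholds and paths; the single seed governs every stage."""

    out_dir: str = "isopipe_out"
    seed: int = 1
    sim: SimConfig = field(default_factory=SimConfig)
    min_depth: int = 6
    min_fraction: float = 0.30
    high_depth: int = 31
    flank_n_fraction: float = 0.20
    unique_ratio: float = 2.0
    orf_complete: float = 0.75
    novel_min_len: int = 50
    identity_reject: float = 70.0
    gap_open_multiplier: float = 3.0
    alpha: float = 0.05
    storey_lambda: float = 0.5
    contrasts: tuple = DEFAULT_CONTRASTS

    def __post_init__(self):
        if self.sim.seed != self.seed:
            self.sim = replace(self.sim, seed=self.seed)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.unique_ratio < 1:
            raise ValueError("unique_ratio must be >= 1")

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim_data = data.pop("sim", {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        sim = SimConfig(**sim_data) if sim_data else SimConfig()
        return cls(sim=sim, **data)

    def path(self, name: str) -> Path:
        return Path(self.out_dir) / name


def _require(cfg: PipelineConfig, name: str, producer: str) -> Path:
    p = cfg.path(name)
    if not p.exists():
        raise PipelineError(
            f"missing {p.name}: run the '{producer}' stage first"
        )
    return p


def _atomic(writer, path, *args):
    tmp = str(path) + ".tmp"
    writer(*args, tmp)
    os.replace(tmp, path)


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig) -> dict:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = cfg.sim

    panel = generate_reference_panel(sim)
    records, truth = generate_isotigs(panel, sim)
    assemblies = generate_assemblies(records, truth, sim)
    hsps, chain_truth = generate_hit_table(records, panel, sim)
    gene_ids = [f"{core}_{panel.species[0]}" for core in panel.gene_cores]
    counts, planted_de = generate_counts(gene_ids, sim)
    truth.planted_de_genes = planted_de

    for sp in panel.species:
        sp_models = [m for m in panel.models if m.species == sp]
        _atomic(lambda ms, p: write_fasta({m.transcript_id: m.transcript_seq for m in ms}, p),
                out / f"transcripts_{sp}.fasta", sp_models)
        _atomic(lambda g, p: write_fasta(g, p), out / f"genome_{sp}.fasta",
                panel.genomes[sp])
        _atomic(write_gff3, out / f"models_{sp}.gff3", sp_models)
    _atomic(write_orthology, out / "orthology.tsv", panel.orthology)
    _atomic(lambda rs, p: write_fasta([(r.isotig_id, r.seq) for r in rs], p),
            out / "isotigs.fasta", records)
    _atomic(write_ace, out / "assemblies.ace", assemblies)
    _atomic(write_blast_tabular, out / "hits.tsv", hsps)
    _atomic(write_counts, out / "counts.tsv", counts)

    # provenance segments let downstream stages avoid re-deriving them
    write_tsv(
        [
            {"isotig_id": r.isotig_id, "gene_core": r.gene_core,
             "q_start": q0, "q_end": q1, "t_start": t0, "t_end": t1}
            for r in records for q0, q1, t0, t1 in r.segments
        ],
        out / "segments.tsv",
    )
    write_tsv(
        [
            {"isotig_id": s.isotig_id, "position": s.position,
             "ref_allele": s.ref_allele, "alt_allele": s.alt_allele,
             "target_alt_fraction": round(s.target_alt_fraction, 4),
             "true_depth": s.true_depth,
             "true_alt_fraction": round(s.true_alt_fraction, 4)}
            for s in truth.planted_snps
        ],
        out / "truth_snps.tsv",
        columns=["isotig_id", "position", "ref_allele", "alt_allele",
                 "target_alt_fraction", "true_depth", "true_alt_fraction"],
    )
    write_tsv(
        [
            {"isotig_id": r.isotig_id, "start": r.start, "end": r.end,
             "class": r.cls, "orf_preserving": r.orf_preserving, "source": r.source}
            for r in truth.planted_novel_regions
        ],
        out / "truth_novel.tsv",
        columns=["isotig_id", "start", "end", "class", "orf_preserving", "source"],
    )
    write_tsv(
        [
            {"gene_id": d.gene_id, "contrast": f"{d.contrast[0]}|{d.contrast[1]}",
             "log2_fold": d.log2_fold}
            for d in truth.planted_de_genes
        ],
        out / "truth_de.tsv",
        columns=["gene_id", "contrast", "log2_fold"],
    )
    write_tsv(
        [
            {"gene_core": core, "category": cat}
            for core, cat in sorted(truth.planted_categories.items())
        ],
        out / "truth_categories.tsv",
    )
    write_tsv(
        [
            {"isotig_id": iso, "gene_core": core,
             "transcripts": ";".join(f"{sp}:{tid}" for sp, tid in sorted(tids.items()))}
            for iso, (core, tids) in sorted(truth.variant_map.items())
        ],
        out / "variant_map.tsv",
    )

    # toy gene sets for the enrichment stage
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 99])
    de_genes = [d.gene_id for d in planted_de]
    with open(out / "gene_sets.gmt.tmp", "w") as fh:
        if de_genes:
            fh.write("planted_de\tsynthetic DE set\t" + "\t".join(de_genes) + "\n")
        for i in range(2):
            pick = sorted(
                rng.choice(gene_ids, size=min(10, len(gene_ids)), replace=False)
            )
            fh.write(f"random_term_{i + 1}\tsynthetic null set\t" + "\t".join(pick) + "\n")
    os.replace(out / "gene_sets.gmt.tmp", out / "gene_sets.gmt")

    log.info("simulate: %d genes, %d isotigs, %d planted SNPs, %d planted regions",
             sim.n_genes, len(records), len(truth.planted_snps),
             len(truth.planted_novel_regions))
    return {
        "n_genes": sim.n_genes,
        "n_isotigs": len(records),
        "n_planted_snps": len(truth.planted_snps),
        "n_planted_novel": len(truth.planted_novel_regions),
    }


# ---------------------------------------------------------------------------
# shared loading helpers
# ---------------------------------------------------------------------------

def _load_models(cfg: PipelineConfig) -> dict[str, GeneModel]:
    orthology = read_orthology(_require(cfg, "orthology.tsv", "simulate"))
    models = {}
    for sp in cfg.sim.species[: cfg.sim.n_species]:
        gff = _require(cfg, f"models_{sp}.gff3", "simulate")
        fasta = _require(cfg, f"transcripts_{sp}.fasta", "simulate")
        for m in read_gff3_models(gff, fasta, sp, orthology):
            models[m.transcript_id] = m
    return models


def _species_of(models: dict[str, GeneModel]) -> list[str]:
    seen = []
    for m in models.values():
        if m.species not in seen:
            seen.append(m.species)
    return seen


def _load_annotation(cfg: PipelineConfig):
    import pandas as pd

    path = _require(cfg, "annotation.tsv", "annotate")
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotate
# ---------------------------------------------------------------------------

def run_annotate(cfg: PipelineConfig) -> dict:
    models = _load_models(cfg)
    orthology = read_orthology(_require(cfg, "orthology.tsv", "simulate"))
    hsps = read_blast_tabular(_require(cfg, "hits.tsv", "simulate"))
    species = _species_of(models)

    grouped: dict[tuple[str, str], list] = {}
    for h in hsps:
        grouped.setdefault((h.query_id, h.target_id), []).append(h)

    per_query_species: dict[str, dict[str, list[homology.ChainedHit]]] = {}
    for (qid, tid), group in sorted(grouped.items()):
        chain = homology.chain_query_target(group)
        homology.resolve_gene(chain, models)
        sp = models[tid].species
        per_query_species.setdefault(qid, {}).setdefault(sp, []).append(chain)

    ann_rows, calls_by_species = [], {sp: [] for sp in species}
    unique_genes: dict[str, dict[str, str | None]] = {}
    for qid in sorted(per_query_species):
        for sp in species:
            chains = per_query_species[qid].get(sp, [])
            call = homology.classify_unique(chains, cfg.unique_ratio)
            if call.status != "no-hit":
                call.query_id = qid
                calls_by_species[sp].append(call)
            best = call.best
            ann_rows.append(
                {
                    "isotig_id": qid,
                    "species": sp,
                    "gene_id": best.gene_id if best else "",
                    "transcript_id": best.target_id if best else "",
                    "status": call.status,
                    "coverage": best.coverage if best else 0,
                    "total_bits": round(best.total_bits, 1) if best else 0.0,
                    "coding_bp": best.coding_bp if best else 0,
                    "utr_bp": best.utr_bp if best else 0,
                    "size_ratio": "" if call.runner_up is None else round(call.size_ratio, 3),
                    "bits_ratio": "" if call.runner_up is None else round(call.bits_ratio, 3),
                }
            )
            unique_genes.setdefault(qid, {})[sp] = (
                best.gene_id if call.status == "unique" and best else None
            )
    write_tsv(ann_rows, cfg.path("annotation.tsv"))

    cluster_rows = []
    n_clusters_sp0 = 0
    for sp in species:
        clusters = homology.cluster_by_gene(calls_by_species[sp], sp, models)
        if sp == species[0]:
            n_clusters_sp0 = len(clusters)
        for cl in clusters:
            cluster_rows.append(
                {
                    "species": sp,
                    "gene_id": cl.gene_id,
                    "n_members": len(cl.member_isotigs),
                    "representative": cl.representative,
                    "non_overlapping": ";".join(cl.non_overlapping),
                }
            )
    write_tsv(cluster_rows, cfg.path("clusters.tsv"))

    cat_rows = []
    sp0 = species[0]
    for qid in sorted(unique_genes):
        genes = unique_genes[qid]
        if all(g is None for g in genes.values()):
            continue
        call0 = next(
            (c for c in calls_by_species[sp0] if c.query_id == qid and c.status == "unique"),
            None,
        )
        coding = call0.best.coding_bp if call0 and call0.best else None
        utr = call0.best.utr_bp if call0 and call0.best else None
        cat = homology.assign_category(qid, genes, orthology, coding, utr)
        cat_rows.append(
            {
                "isotig_id": qid,
                **{f"gene_{sp}": genes.get(sp) or "" for sp in species},
                "category": cat.category,
                "coding_portion": "" if cat.coding_portion is None else round(cat.coding_portion, 4),
                "aligned_total": cat.aligned_total,
            }
        )
    write_tsv(cat_rows, cfg.path("categories.tsv"))

    n_unique = sum(
        1 for c in calls_by_species[sp0] if c.status == "unique"
    )
    log.info("annotate: %d isotigs, %d unique (%s), %d clusters",
             len(unique_genes), n_unique, sp0, n_clusters_sp0)
    return {
        "n_isotigs_with_hits": len(per_query_species),
        "n_unique_sp0": n_unique,
        "n_clusters_sp0": n_clusters_sp0,
        "category_counts": {
            k: sum(1 for r in cat_rows if r["category"] == k) for k in (3, 2, 1)
        },
    }


def _unique_map(cfg: PipelineConfig, species: str):
    """isotig -> (gene_id, transcript_id, coverage) for unique calls."""
    ann = _load_annotation(cfg)
    sub = ann[(ann.species == species) & (ann.status == "unique")]
    return {
        r.isotig_id: (r.gene_id, r.transcript_id, int(r.coverage))
        for r in sub.itertuples()
    }


# ---------------------------------------------------------------------------
# orf
# ---------------------------------------------------------------------------

def run_orf(cfg: PipelineConfig) -> dict:
    models = _load_models(cfg)
    isotigs = read_fasta(_require(cfg, "isotigs.fasta", "simulate"))
    sp0 = _species_of(models)[0]
    unique = _unique_map(cfg, sp0)

    rows, proteins = [], []
    n_complete = n_ptc = 0
    for iso in sorted(unique):
        gene_id, tid, _cov = unique[iso]
        model = models[tid]
        if model.cds_on_transcript is None:
            continue
        proj = orfproj.project_orf(
            iso, isotigs[iso], tid, model.transcript_seq,
            model.cds_on_transcript, cfg.orf_complete,
        )
        if proj is None:
            rows.append({"isotig_id": iso, "transcript_id": tid, "status": "no-projection"})
            continue
        n_complete += proj.complete75
        n_ptc += proj.ptc
        rows.append(
            {
                "isotig_id": iso,
                "transcript_id": tid,
                "status": "projected",
                "aligned_cds_fraction": round(proj.aligned_cds_fraction, 4),
                "orf_start": proj.orf_interval[0],
                "orf_end": proj.orf_interval[1],
                "frame": proj.frame,
                "ptc": proj.ptc,
                "ptc_position": "" if proj.ptc_position is None else proj.ptc_position,
                "complete75": proj.complete75,
                "uninterrupted": proj.uninterrupted,
                "frameshift_warning": proj.frameshift_warning,
            }
        )
        proteins.append((iso, proj.protein))
    write_tsv(rows, cfg.path("orf.tsv"))
    _atomic(lambda ps, p: write_fasta(ps, p), cfg.path("proteins.fasta"), proteins)
    log.info("orf: %d projections, %d complete75, %d PTC", len(proteins), n_complete, n_ptc)
    return {"n_projected": len(proteins), "n_complete75": n_complete, "n_ptc": n_ptc}


# ---------------------------------------------------------------------------
# snps
# ---------------------------------------------------------------------------

def run_snps(cfg: PipelineConfig) -> dict:
    assemblies = read_ace(_require(cfg, "assemblies.ace", "simulate"))
    ann = _load_annotation(cfg)
    sp0 = sorted(ann.species.unique())  # stable
    sp0 = list(cfg.sim.species)[0]
    sub = ann[(ann.species == sp0) & (ann.status == "unique")]
    isotig_gene = {r.isotig_id: r.gene_id for r in sub.itertuples()}
    coverage = {r.isotig_id: int(r.coverage) for r in sub.itertuples()}

    calls = []
    for asm in assemblies:
        calls.extend(
            snps.call_snps(asm, cfg.min_depth, cfg.min_fraction, cfg.flank_n_fraction)
        )
    final = snps.dedupe_per_gene(
        calls, {a.isotig_id: isotig_gene.get(a.isotig_id) for a in assemblies}, coverage
    )
    report = snps.summarize(final, cfg.high_depth)

    write_tsv(
        [
            {
                "isotig_id": c.isotig_id,
                "gene_id": c.gene_id or "",
                "position": c.position,
                "major_allele": c.major_allele,
                "minor_allele": c.minor_allele,
                "depth": c.depth,
                "minor_fraction": round(c.minor_fraction, 4),
                "substitution_class": c.substitution_class,
                "is_transition": c.is_transition,
                "high_depth": c.high_depth,
            }
            for c in sorted(final, key=lambda c: (c.isotig_id, c.position))
        ],
        cfg.path("snps.tsv"),
        columns=["isotig_id", "gene_id", "position", "major_allele", "minor_allele",
                 "depth", "minor_fraction", "substitution_class", "is_transition",
                 "high_depth"],
    )
    summary_rows = []
    for label, s in (("all", report.all), ("depth_ge_high", report.high_depth)):
        summary_rows.append(
            {
                "subset": label,
                "n_calls": s.n_calls,
                "n_genes": s.n_genes,
                **{f"n_{k}": v for k, v in s.class_counts.items()},
                "transition_pct": "NA" if s.transition_pct is None else s.transition_pct,
            }
        )
    write_tsv(summary_rows, cfg.path("snp_summary.tsv"))
    log.info("snps: %d calls (%s transitions %%), %d high-depth",
             report.all.n_calls, report.all.transition_pct, report.high_depth.n_calls)
    return {
        "n_calls": report.all.n_calls,
        "transition_pct": report.all.transition_pct,
        "n_high_depth": report.high_depth.n_calls,
        "class_counts": report.all.class_counts,
    }


# ---------------------------------------------------------------------------
# novel
# ---------------------------------------------------------------------------

def run_novel(cfg: PipelineConfig) -> dict:
    models = _load_models(cfg)
    orthology = read_orthology(_require(cfg, "orthology.tsv", "simulate"))
    isotigs = read_fasta(_require(cfg, "isotigs.fasta", "simulate"))
    hsps = read_blast_tabular(_require(cfg, "hits.tsv", "simulate"))
    species = _species_of(models)
    sp0 = species[0]
    unique = _unique_map(cfg, sp0)
    genomes = {
        sp: read_fasta(_require(cfg, f"genome_{sp}.fasta", "simulate"))
        for sp in species
    }

    by_gene_species: dict[tuple[str, str], GeneModel] = {}
    group_to_models: dict[str, dict[str, GeneModel]] = {}
    for m in models.values():
        if m.ortholog_group:
            group_to_models.setdefault(m.ortholog_group, {})[m.species] = m

    grouped: dict[tuple[str, str], list] = {}
    for h in hsps:
        grouped.setdefault((h.query_id, h.target_id), []).append(h)

    rows = []
    report_lines = []
    counts = {"novel": 0, "rejected-intronic": 0, "rejected-short": 0, "unresolved": 0}
    for iso in sorted(unique):
        gene_id, tid, _cov = unique[iso]
        model = models[tid]
        group = orthology.group_of(sp0, gene_id)
        sp_models = group_to_models.get(group, {sp0: model})
        pair = grouped.get((iso, tid))
        if not pair:
            continue
        chain = homology.chain_query_target(pair)
        proj = None
        if model.cds_on_transcript is not None:
            proj = orfproj.project_orf(
                iso, isotigs[iso], tid, model.transcript_seq, model.cds_on_transcript
            )
        regions = novelreg.detect_novel_regions(
            iso, isotigs[iso], chain, sp_models, genomes, proj,
            cfg.novel_min_len, cfg.gap_open_multiplier, cfg.identity_reject,
        )
        for r in regions:
            counts[r.status] = counts.get(r.status, 0) + 1
            rows.append(
                {
                    "isotig_id": iso,
                    "start": r.interval[0],
                    "end": r.interval[1],
                    "length": r.length,
                    "class": r.cls or "",
                    "status": r.status,
                    "intron_identity": round(r.intron_identity, 2),
                    "orf_status": r.orf_status,
                    "left_flank_target": f"{r.left_flank.t_start}-{r.left_flank.t_end}",
                    "right_flank_target": f"{r.right_flank.t_start}-{r.right_flank.t_end}",
                }
            )
            if r.status in ("novel", "rejected-intronic"):
                s, e = r.interval
                seq = isotigs[iso]
                report_lines.append(
                    f"> {iso}:{s}-{e} {r.status} class={r.cls} "
                    f"intron_identity={r.intron_identity:.1f}%\n"
                    f"  left flank  : ...{seq[max(0, s - 30):s]}\n"
                    f"  novel region: {seq[s:min(e, s + 60)]}"
                    f"{'...' if e - s > 60 else ''}\n"
                    f"  right flank : {seq[e:e + 30]}...\n"
                )
    write_tsv(rows, cfg.path("novel_regions.tsv"),
              columns=["isotig_id", "start", "end", "length", "class", "status",
                       "intron_identity", "orf_status", "left_flank_target",
                       "right_flank_target"])
    tmp = cfg.path("novel_report.txt.tmp")
    with open(tmp, "w") as fh:
        fh.write("\n".join(report_lines))
    os.replace(tmp, cfg.path("novel_report.txt"))
    log.info("novel: %s", counts)
    return counts


# ---------------------------------------------------------------------------
# de
# ---------------------------------------------------------------------------

def run_de(cfg: PipelineConfig) -> dict:
    table = read_counts(_require(cfg, "counts.tsv", "simulate"))
    rows = []
    sig_per_contrast = {}
    selected_by_contrast = {}
    for contrast in cfg.contrasts:
        results = dge.de_table(table, tuple(contrast), cfg.storey_lambda)
        chi_cache = {}
        for r in results:
            key = r.gene_id
            if key not in chi_cache:
                chi_cache[key] = dge.chi2_test(
                    table.counts.loc[key].to_numpy(), table.totals, key
                )
            chi = chi_cache[key]
            rows.append(
                {
                    "gene_id": r.gene_id,
                    "contrast": f"{r.contrast[0]}|{r.contrast[1]}",
                    "k1": r.k1,
                    "k2": r.k2,
                    "M": round(r.M, 4),
                    "A": round(r.A, 4),
                    "p_mars": f"{r.p_value:.6g}",
                    "q_bh": f"{r.q_bh:.6g}",
                    "q_storey": f"{r.q_storey:.6g}",
                    "p_chi2_4lib": f"{chi.p_value:.6g}",
                    "testable": r.testable,
                }
            )
        label = f"{contrast[0]}|{contrast[1]}"
        sig = [r.gene_id for r in results if r.testable and r.p_value < cfg.alpha]
        sig_per_contrast[label] = len(sig)
        selected_by_contrast[label] = (sig, [r.gene_id for r in results if r.testable])
    write_tsv(rows, cfg.path("de.tsv"))

    gmt_path = cfg.path("gene_sets.gmt")
    enr_rows = []
    if gmt_path.exists():
        gmt = read_gmt(gmt_path)
        for label, (sig, background) in selected_by_contrast.items():
            if not sig:
                continue
            for e in dge.enrich(sig, background, gmt):
                enr_rows.append(
                    {
                        "contrast": label,
                        "term": e.term,
                        "count": e.overlap,
                        "p_value": f"{e.p_value:.4g}",
                        "fdr": f"{e.fdr:.4g}",
                    }
                )
        write_tsv(enr_rows, cfg.path("enrichment.tsv"),
                  columns=["contrast", "term", "count", "p_value", "fdr"])
    log.info("de: significant per contrast %s", sig_per_contrast)
    return {"significant_per_contrast": sig_per_contrast}


# ---------------------------------------------------------------------------
# all
# ---------------------------------------------------------------------------

def run_all(cfg: PipelineConfig) -> dict:
    sim = run_simulate(cfg)
    ann = run_annotate(cfg)
    orf = run_orf(cfg)
    snp = run_snps(cfg)
    novel = run_novel(cfg)
    de = run_de(cfg)

    summary = {
        "n_genes": sim["n_genes"],
        "n_isotigs": sim["n_isotigs"],
        "n_isotigs_with_hits": ann["n_isotigs_with_hits"],
        "n_unique_sp0": ann["n_unique_sp0"],
        "n_clusters_sp0": ann["n_clusters_sp0"],
        "category3": ann["category_counts"][3],
        "category2": ann["category_counts"][2],
        "category1": ann["category_counts"][1],
        "n_orf_projected": orf["n_projected"],
        "n_orf_complete75": orf["n_complete75"],
        "n_snp_calls": snp["n_calls"],
        "snp_transition_pct": snp["transition_pct"],
        "n_snp_high_depth": snp["n_high_depth"],
        **{f"snp_{k}": v for k, v in snp["class_counts"].items()},
        "novel_regions": novel.get("novel", 0),
        "novel_rejected_intronic": novel.get("rejected-intronic", 0),
        **{
            f"de_significant_{k.replace('|', '_vs_')}": v
            for k, v in de["significant_per_contrast"].items()
        },
    }
    write_tsv(
        [{"metric": k, "value": v} for k, v in summary.items()],
        cfg.path("summary.tsv"),
    )
    return summary
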