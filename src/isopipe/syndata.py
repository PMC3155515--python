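"""Synthetic reference panels, isotigs, read stacks, hit tables and counts.

The generator emulates the inputs of a 454-style transcriptome annotation
study: three diverged pseudo-species (mouse/rat/human stand-ins) with
exon/CDS/UTR gene models and ortholog groups; isotigs copied from the first
species' transcripts carrying planted biallelic sites, novel insertions and
splice variants; error-free read stacks tagged by four libraries
(brain/muscle x normoxia/hypoxia); BLAST-tabular hit tables with decoy
paralog hits; and multinomial per-gene library counts. Every planted feature
is recorded in a :class:`TruthSet` so downstream stages can be scored
without external data.

All coordinates are 0-based half-open. Regeneration with the same seed is
byte-identical across all outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    LIBRARIES,
    AssemblyRead,
    CountTable,
    GeneModel,
    HSP,
    IsotigAssembly,
    OrthologyTable,
)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Ranges are sized to mimic the scales of the emulated study (isotigs of
    hundreds to a few thousand bp, read depths straddling the 6 and 31
    thresholds); parameters the study does not state are free choices
    documented in the methods note.
    """

    seed: int = 1
    n_genes: int = 30
    n_species: int = 3
    species: tuple[str, ...] = ("mouse", "rat", "human")
    exon_len_range: tuple[int, int] = (120, 400)
    n_exons_range: tuple[int, int] = (2, 6)
    intron_len_range: tuple[int, int] = (100, 400)
    utr5_len: int = 60
    utr3_len: int = 120
    snp_rate: float = 2.0  # planted biallelic sites per kb
    minor_allele_frac_range: tuple[float, float] = (0.30, 0.50)
    depth_range: tuple[int, int] = (6, 40)
    read_len: int = 100
    n_rate: float = 0.0  # ambiguous-base injection rate per read base
    novel_insert_len_range: tuple[int, int] = (60, 300)
    frac_novel_isotigs: float = 0.2
    frac_intron_retention: float = 0.0
    frac_splice_variants: float = 0.2
    inframe_insert_prob: float = 0.5
    library_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    substitution_divergence: float = 0.05
    frac_species_dropout: float = 0.05
    frac_group_reassign: float = 0.05
    frac_category1: float = 0.05
    decoy_ratio: float = 0.4
    frac_decoy: float = 0.3
    mean_count: float = 50.0
    n_de_genes: int = 0
    de_log2fc: float = 2.0
    de_contrast: tuple[int, int] = (0, 1)  # library indices into C.1..C.4

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if not 2 <= self.n_species <= len(self.species):
            raise ConfigurationError("n_species must be >=2 and named in `species`")
        for name in (
            "frac_novel_isotigs",
            "frac_intron_retention",
            "frac_splice_variants",
            "frac_species_dropout",
            "frac_group_reassign",
            "frac_category1",
            "n_rate",
            "inframe_insert_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.minor_allele_frac_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ConfigurationError("minor_allele_frac_range must be within [0, 1]")
        if self.novel_insert_len_range[0] < 50:
            raise ConfigurationError("novel inserts must be at least 50 bp")
        if sum(self.library_weights) <= 0 or min(self.library_weights) < 0:
            raise ConfigurationError("library_weights must be nonnegative, sum > 0")
        if self.depth_range[0] < 1:
            raise ConfigurationError("depth_range minimum must be >= 1")
        if not 0.0 <= self.substitution_divergence < 0.75:
            raise ConfigurationError("substitution_divergence out of range")


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class PlantedSnp:
    isotig_id: str
    position: int  # 0-based on the isotig consensus
    ref_allele: str
    alt_allele: str
    target_alt_fraction: float
    true_depth: int | None = None  # realized at assembly time
    true_alt_fraction: float | None = None


@dataclass
class PlantedNovelRegion:
    isotig_id: str
    start: int
    end: int  # half-open
    cls: str  # insertion-in-exon | novel-exon
    orf_preserving: bool
    source: str = "random"  # random | intron (intron-retention control)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PlantedDeGene:
    gene_id: str
    contrast: tuple[str, str]  # library labels, e.g. ("C.1", "C.2")
    log2_fold: float


@dataclass
class TruthSet:
    planted_snps: list[PlantedSnp] = field(default_factory=list)
    planted_novel_regions: list[PlantedNovelRegion] = field(default_factory=list)
    planted_de_genes: list[PlantedDeGene] = field(default_factory=list)
    variant_map: dict[str, tuple[str, dict[str, str]]] = field(default_factory=dict)
    planted_categories: dict[str, int] = field(default_factory=dict)

    def validate(self, isotig_lengths: dict[str, int]):
        for s in self.planted_snps:
            if not 0 <= s.position < isotig_lengths[s.isotig_id]:
                raise ConfigurationError(f"planted SNP outside isotig {s.isotig_id}")
        for r in self.planted_novel_regions:
            if not 0 <= r.start < r.end <= isotig_lengths[r.isotig_id]:
                raise ConfigurationError(f"planted region outside isotig {r.isotig_id}")
            if r.length < 50:
                raise ConfigurationError("planted novel region shorter than 50 bp")
        return self


@dataclass
class ReferencePanel:
    species: list[str]
    models: list[GeneModel]
    orthology: OrthologyTable
    genomes: dict[str, dict[str, str]]  # species -> chrom -> sequence
    gene_cores: list[str]
    introns: dict[tuple[str, str], list[str]]  # (gene core, species) -> intron seqs

    def model(self, gene_core: str, species: str) -> GeneModel | None:
        tid = f"t_{gene_core}_{species}"
        for m in self.models:
            if m.transcript_id == tid:
                return m
        return None

    def models_by_transcript(self) -> dict[str, GeneModel]:
        return {m.transcript_id: m for m in self.models}


@dataclass
class IsotigRecord:
    """An isotig plus the provenance needed to emit truthful hit tables."""

    isotig_id: str
    seq: str
    gene_core: str
    source_transcript: str
    # conserved blocks: (q_start, q_end, t_start, t_end) on the source transcript
    segments: list[tuple[int, int, int, int]]


def _rng(cfg: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, *tags])


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _mutate(rng, seq: str, rate: float, protect_stops: tuple[int, int] | None = None) -> str:
    """Substitute ~rate of the sites; optionally avoid creating premature
    stop codons inside the frame-0 CDS interval ``protect_stops``."""
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    positions = rng.choice(n, size=k, replace=False)
    out = list(seq)
    for p in sorted(positions):
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    if protect_stops is not None:
        cs, ce = protect_stops
        # keep the start and stop codons intact across species
        out[cs:cs + 3] = list(seq[cs:cs + 3])
        out[ce - 3:ce] = list(seq[ce - 3:ce])
        for cod in range(cs, ce - 3, 3):
            if "".join(out[cod:cod + 3]) in _STOPS:
                out[cod:cod + 3] = list(seq[cod:cod + 3])
    return "".join(out)


# ---------------------------------------------------------------------------
# Reference panel
# ---------------------------------------------------------------------------

def generate_reference_panel(cfg: SimConfig) -> ReferencePanel:
    """Build gene models, ortholog groups and genomes for the pseudo-species.

    Each gene has one transcript per species; species copies diverge from a
    common ancestral sequence by ``substitution_divergence`` (half the rate
    per branch). Gene/intron coordinates are shared across species so
    transcript coordinates are directly comparable. A configurable fraction
    of genes is withheld from one non-first species or reassigned to a
    different ortholog group, planting orthology categories 1 and 2.
    """
    rng = _rng(cfg, 1)
    species = list(cfg.species[: cfg.n_species])
    half = cfg.substitution_divergence / 2.0

    models: list[GeneModel] = []
    orthology = OrthologyTable()
    genome_parts: dict[str, list[str]] = {sp: [] for sp in species}
    cursors = {sp: 0 for sp in species}
    gene_cores, introns = [], {}
    categories: dict[str, int] = {}

    n_cat1 = int(round(cfg.frac_category1 * cfg.n_genes))
    n_drop = int(round(cfg.frac_species_dropout * cfg.n_genes))
    n_reassign = int(round(cfg.frac_group_reassign * cfg.n_genes))

    for gi in range(cfg.n_genes):
        core = f"g{gi:04d}"
        gene_cores.append(core)
        n_exons = int(rng.integers(cfg.n_exons_range[0], cfg.n_exons_range[1] + 1))
        exon_lens = [
            int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
            for _ in range(n_exons)
        ]
        total = sum(exon_lens)
        cds_len = total - cfg.utr5_len - cfg.utr3_len
        if cds_len < 9:
            exon_lens[-1] += 9 - cds_len
            total = sum(exon_lens)
            cds_len = 9
        cds_len -= cds_len % 3
        cds = (cfg.utr5_len, cfg.utr5_len + cds_len)

        n_codons = cds_len // 3
        body = "".join(
            _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
        )
        anc_transcript = (
            _random_seq(rng, cfg.utr5_len)
            + "ATG" + body + "TAA"
            + _random_seq(rng, total - cfg.utr5_len - cds_len)
        )
        intron_lens = [
            int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
            for _ in range(n_exons - 1)
        ]
        anc_introns = [_random_seq(rng, L) for L in intron_lens]

        # planted category plumbing
        if gi < n_cat1:
            planted_cat, drop_sp, reassigned = 1, None, species[1:3]
        elif gi < n_cat1 + n_drop:
            planted_cat, drop_sp, reassigned = 2, species[1 + gi % (len(species) - 1)], []
        elif gi < n_cat1 + n_drop + n_reassign:
            planted_cat, drop_sp, reassigned = 2, None, [species[1 + gi % (len(species) - 1)]]
        else:
            planted_cat, drop_sp, reassigned = 3, None, []
        categories[core] = planted_cat

        for si, sp in enumerate(species):
            if sp == drop_sp:
                continue
            tseq = _mutate(rng, anc_transcript, half, protect_stops=cds)
            sp_introns = [_mutate(rng, s, half) for s in anc_introns]
            introns[(core, sp)] = sp_introns

            chrom = f"chr_{sp}"
            start = cursors[sp] + 200  # intergenic spacer
            genome_parts[sp].append(_random_seq(rng, 200))
            exons, pos, toff = [], start, 0
            for ei, elen in enumerate(exon_lens):
                exons.append((pos, pos + elen))
                genome_parts[sp].append(tseq[toff:toff + elen])
                pos += elen
                toff += elen
                if ei < n_exons - 1:
                    genome_parts[sp].append(sp_introns[ei])
                    pos += len(sp_introns[ei])
            cursors[sp] = pos

            gene_id = f"{core}_{sp}"
            if sp in reassigned:
                group = f"OG_{core}_{sp}"
            else:
                group = f"OG_{core}"
            orthology.add(sp, gene_id, group)
            models.append(
                GeneModel(f"t_{core}_{sp}", gene_id, sp, chrom, exons, cds, tseq, group)
            )
    genomes = {sp: {f"chr_{sp}": "".join(genome_parts[sp])} for sp in species}
    panel = ReferencePanel(species, models, orthology, genomes, gene_cores, introns)
    panel.planted_categories = categories  # type: ignore[attr-defined]
    return panel


# ---------------------------------------------------------------------------
# Isotigs
# ---------------------------------------------------------------------------

def _exon_boundaries(model: GeneModel) -> list[int]:
    bounds, acc = [], 0
    for s, e in model.exons:
        acc += e - s
        bounds.append(acc)
    return bounds  # cumulative transcript offsets at exon ends


def _orf_preserving(seq: str, cds_start: int, ref_stop_pos: int) -> bool:
    """True if translation from cds_start reaches ref_stop_pos without a stop
    and the reading frame is preserved there."""
    if (ref_stop_pos - cds_start) % 3 != 0:
        return False
    for p in range(cds_start, ref_stop_pos, 3):
        if seq[p:p + 3] in _STOPS:
            return False
    return True


def _make_inframe_insert(rng, length: int, offset_in_frame: int) -> str:
    """Random insert of ~length (rounded to a codon multiple) built so that
    inserting it at a position with the given frame offset introduces no stop."""
    length = max(51, length - length % 3)
    # Build codon-aligned in the local frame by padding with the flanks'
    # bases conceptually; simplest robust construction: all-sense codons in
    # frame 0 and shift by composing from a codon list that is stop-free in
    # any rotation. Codons drawn from {A,C} x {A,C} x {A,C} can never form a
    # stop in any frame (stops all contain T/G at position 1/2 patterns).
    alphabet = ["AAC", "ACA", "CAA", "CCA", "CAC", "ACC", "AAA", "CCC"]
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length // 3))


def generate_isotigs(panel: ReferencePanel, cfg: SimConfig):
    """Derive isotigs from the first species' transcripts.

    Returns ``(records, truth)``: isotig records carrying conserved-segment
    provenance, and the :class:`TruthSet` of planted SNPs, novel regions,
    splice variants and categories.
    """
    rng = _rng(cfg, 2)
    sp0 = panel.species[0]
    truth = TruthSet(planted_categories=dict(
        getattr(panel, "planted_categories", {})
    ))
    records: list[IsotigRecord] = []

    # first assemble the (gene, exon subset) plan
    plans = []  # (gene core, exon indices)
    for core in panel.gene_cores:
        model = panel.model(core, sp0)
        if model is None:
            continue
        n_exons = len(model.exons)
        plans.append((core, list(range(n_exons))))
        if rng.random() < cfg.frac_splice_variants and n_exons >= 3:
            skip = int(rng.integers(1, n_exons - 1))
            plans.append((core, [i for i in range(n_exons) if i != skip]))

    n_iso = len(plans)
    novel_flags = rng.random(n_iso) < cfg.frac_novel_isotigs
    retention_flags = rng.random(n_iso) < cfg.frac_intron_retention

    for idx, (core, exon_idx) in enumerate(plans):
        model = panel.model(core, sp0)
        iso_id = f"isotig{idx:05d}"
        bounds = [0] + _exon_boundaries(model)
        # pieces: ('ref', t0, t1) per kept exon
        pieces: list[tuple] = [("ref", bounds[i], bounds[i + 1]) for i in exon_idx]

        cds_s, cds_e = model.cds_on_transcript
        planted_regions = []

        def insert_at(pieces, piece_i, within_offset, ins_seq, cls, source):
            """Split/insert; within_offset is relative to the piece start."""
            kind, t0, t1 = pieces[piece_i]
            assert kind == "ref"
            new = []
            if within_offset > 0:
                new.append(("ref", t0, t0 + within_offset))
            new.append(("ins", ins_seq, cls, source))
            if t0 + within_offset < t1:
                new.append(("ref", t0 + within_offset, t1))
            return pieces[:piece_i] + new + pieces[piece_i + 1:]

        if novel_flags[idx]:
            length = int(
                rng.integers(cfg.novel_insert_len_range[0], cfg.novel_insert_len_range[1] + 1)
            )
            cls = "insertion-in-exon" if rng.random() < 0.5 else "novel-exon"
            if cls == "novel-exon" and len(pieces) < 2:
                cls = "insertion-in-exon"
            if cls == "novel-exon":
                # between two kept exon pieces
                gap_i = int(rng.integers(1, len(pieces)))
                t_pos = pieces[gap_i][1]  # target coord at the junction
                ins_seq = _random_seq(rng, length)
                if cds_s <= t_pos < cds_e and rng.random() < cfg.inframe_insert_prob:
                    ins_seq = _make_inframe_insert(rng, length, (t_pos - cds_s) % 3)
                pieces = pieces[:gap_i] + [("ins", ins_seq, cls, "random")] + pieces[gap_i:]
            else:
                piece_i = int(rng.integers(0, len(pieces)))
                _, t0, t1 = pieces[piece_i]
                if t1 - t0 > 60:
                    off = int(rng.integers(25, t1 - t0 - 25))
                else:
                    off = (t1 - t0) // 2
                t_pos = t0 + off
                ins_seq = _random_seq(rng, length)
                if cds_s <= t_pos < cds_e and rng.random() < cfg.inframe_insert_prob:
                    ins_seq = _make_inframe_insert(rng, length, (t_pos - cds_s) % 3)
                pieces = insert_at(pieces, piece_i, off, ins_seq, cls, "random")
        elif retention_flags[idx] and len(pieces) >= 2:
            # copy a slice of the real intervening intron (intron-retention control)
            gap_i = int(rng.integers(1, len(pieces)))
            # exon index left of the junction in the kept subset
            left_exon = exon_idx[gap_i - 1]
            intron_seq = panel.introns[(core, sp0)][min(left_exon, len(panel.introns[(core, sp0)]) - 1)]
            max_len = min(len(intron_seq), cfg.novel_insert_len_range[1])
            length = int(rng.integers(min(60, max_len), max_len + 1)) if max_len > 60 else max_len
            start_off = int(rng.integers(0, len(intron_seq) - length + 1))
            ins_seq = intron_seq[start_off:start_off + length]
            pieces = pieces[:gap_i] + [("ins", ins_seq, "novel-exon", "intron")] + pieces[gap_i:]

        # realize the sequence and the provenance segments
        seq_parts, segments = [], []
        q = 0
        for piece in pieces:
            if piece[0] == "ref":
                _, t0, t1 = piece
                frag = model.transcript_seq[t0:t1]
                # merge with previous ref segment when contiguous in q and t
                if segments and segments[-1][1] == q and segments[-1][3] == t0:
                    q0, _, ts, _ = segments[-1]
                    segments[-1] = (q0, q + (t1 - t0), ts, t1)
                else:
                    segments.append((q, q + (t1 - t0), t0, t1))
                seq_parts.append(frag)
                q += t1 - t0
            else:
                _, ins_seq, cls, source = piece
                planted_regions.append(
                    PlantedNovelRegion(iso_id, q, q + len(ins_seq), cls, False, source)
                )
                seq_parts.append(ins_seq)
                q += len(ins_seq)
        seq = "".join(seq_parts)

        # ORF-preservation bookkeeping: translate from the isotig position of
        # the reference CDS start in the projected frame
        for reg in planted_regions:
            iso_cds_start = None
            for q0, q1, t0, t1 in segments:
                if t0 <= cds_s < t1:
                    iso_cds_start = q0 + (cds_s - t0)
                    break
            if iso_cds_start is None or reg.start < iso_cds_start:
                continue
            ref_stop_iso = None
            for q0, q1, t0, t1 in segments:
                if t0 <= cds_e - 3 < t1:
                    ref_stop_iso = q0 + (cds_e - 3 - t0)
                    break
            if ref_stop_iso is None or reg.end > ref_stop_iso:
                continue
            reg.orf_preserving = _orf_preserving(seq, iso_cds_start, ref_stop_iso)

        truth.planted_novel_regions.extend(planted_regions)
        truth.variant_map[iso_id] = (
            core,
            {
                sp: f"t_{core}_{sp}"
                for sp in panel.species
                if panel.model(core, sp) is not None
            },
        )
        records.append(IsotigRecord(iso_id, seq, core, model.transcript_id, segments))

        # planted biallelic sites (realized in the read stacks)
        lo = min(cfg.read_len, max(1, len(seq) // 4))
        hi = max(lo + 1, len(seq) - cfg.read_len)
        interior = hi - lo
        n_snps = rng.binomial(len(seq), cfg.snp_rate / 1000.0)
        n_snps = min(n_snps, interior // 4)
        if n_snps > 0:
            positions = sorted(
                int(p) + lo for p in rng.choice(interior, size=n_snps, replace=False)
            )
            for p in positions:
                ref = seq[p]
                if ref not in "ACGT":
                    continue
                alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                frac = float(
                    rng.uniform(*cfg.minor_allele_frac_range)
                )
                truth.planted_snps.append(PlantedSnp(iso_id, p, ref, alt, frac))

    truth.validate({r.isotig_id: len(r.seq) for r in records})
    return records, truth


# ---------------------------------------------------------------------------
# Read stacks
# ---------------------------------------------------------------------------

def generate_assembly(
    record: IsotigRecord,
    cfg: SimConfig,
    snps: list[PlantedSnp] | None = None,
    rng: np.random.Generator | None = None,
) -> IsotigAssembly:
    """Tile the isotig with error-free reads realizing the planted alleles.

    At each planted site the alternative allele is written into
    ``round(fraction * covering_reads)`` of the covering reads; the realized
    depth and fraction are recorded back into the planted-SNP records.
    """
    if rng is None:
        rng = _rng(cfg, 3, abs(hash(record.isotig_id)) % (2**31))
    snps = snps or []
    seq = record.seq
    L = len(seq)
    rl = min(cfg.read_len, L)
    depth = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
    if depth <= 0:
        raise ConfigurationError("requested depth must be positive")
    step = max(1, rl // depth)
    offsets = list(range(0, L - rl + 1, step))
    if offsets[-1] != L - rl:
        offsets.append(L - rl)

    weights = np.asarray(cfg.library_weights, dtype=float)
    weights = weights / weights.sum()
    read_seqs = [list(seq[o:o + rl]) for o in offsets]

    if cfg.n_rate > 0:
        for rs in read_seqs:
            k = rng.binomial(rl, cfg.n_rate)
            if k:
                for p in rng.choice(rl, size=k, replace=False):
                    rs[p] = "N"

    for snp in snps:
        cover = [i for i, o in enumerate(offsets) if o <= snp.position < o + rl]
        k = int(math.floor(snp.target_alt_fraction * len(cover) + 0.5))
        chosen = sorted(rng.choice(len(cover), size=k, replace=False)) if k else []
        for ci in chosen:
            i = cover[ci]
            read_seqs[i][snp.position - offsets[i]] = snp.alt_allele
        snp.true_depth = len(cover)
        snp.true_alt_fraction = k / len(cover) if cover else 0.0

    reads = []
    strands = rng.random(len(offsets)) < 0.5
    libs = rng.choice(4, size=len(offsets), p=weights)
    for i, o in enumerate(offsets):
        rs = "".join(read_seqs[i])
        strand = "-" if strands[i] else "+"
        if strand == "-":
            rs = revcomp(rs)
        reads.append(
            AssemblyRead(f"{record.isotig_id}.r{i:04d}", o, strand, LIBRARIES[libs[i]], rs)
        )
    return IsotigAssembly(record.isotig_id, seq, reads).validate()


def generate_assemblies(records, truth: TruthSet, cfg: SimConfig) -> list[IsotigAssembly]:
    by_iso: dict[str, list[PlantedSnp]] = {}
    for s in truth.planted_snps:
        by_iso.setdefault(s.isotig_id, []).append(s)
    out = []
    for i, rec in enumerate(records):
        rng = _rng(cfg, 3, i)
        out.append(generate_assembly(rec, cfg, by_iso.get(rec.isotig_id, []), rng))
    return out


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    if not a:
        return 100.0
    m = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * m / len(a)


def generate_hit_table(records, panel: ReferencePanel, cfg: SimConfig):
    """Emit BLAST-tabular style HSPs for every isotig x species.

    One HSP per conserved exon block (segments split at exon boundaries);
    planted novel regions produce no HSP. Decoy paralog hits against a
    different gene are emitted for a fraction of isotigs with coverage
    ``floor(r * true)`` and bit score ``r * true`` so the downstream 2x
    unique rule can be exercised exactly at, above and below threshold.

    Returns ``(hsps, chain_truth)`` where chain_truth maps
    ``(isotig_id, species)`` to the expected chained coverage, HSP count and
    whether a decoy was planted.
    """
    rng = _rng(cfg, 4)
    hsps: list[HSP] = []
    chain_truth: dict[tuple[str, str], dict] = {}
    decoy_flags = rng.random(len(records)) < cfg.frac_decoy

    for ri, rec in enumerate(records):
        for sp in panel.species:
            model = panel.model(rec.gene_core, sp)
            if model is None:
                continue
            bounds = [0] + _exon_boundaries(model)
            sp_hsps = []
            for q0, q1, t0, t1 in rec.segments:
                cuts = [t0] + [b for b in bounds if t0 < b < t1] + [t1]
                for a, b in zip(cuts[:-1], cuts[1:]):
                    qa, qb = q0 + (a - t0), q0 + (b - t0)
                    ident = _identity(rec.seq[qa:qb], model.transcript_seq[a:b])
                    bits = round(2.0 * (qb - qa) * ident / 100.0, 1)
                    sp_hsps.append(
                        HSP(rec.isotig_id, model.transcript_id, qa, qb, a, b,
                            "+", round(ident, 2), bits, 1e-30)
                    )
            coverage = sum(h.q_len for h in sp_hsps)
            total_bits = sum(h.bit_score for h in sp_hsps)
            hsps.extend(sp_hsps)
            entry = {"coverage": coverage, "n_hsps": len(sp_hsps), "decoy": False}

            if decoy_flags[ri] and coverage > 0:
                dec_cov = max(1, int(math.floor(cfg.decoy_ratio * coverage)))
                target = None
                for other in panel.gene_cores:
                    if other == rec.gene_core:
                        continue
                    m2 = panel.model(other, sp)
                    if m2 is not None and m2.transcript_len >= dec_cov:
                        target = m2
                        break
                if target is not None and dec_cov <= len(rec.seq):
                    hsps.append(
                        HSP(rec.isotig_id, target.transcript_id, 0, dec_cov,
                            0, dec_cov, "+", 75.0,
                            cfg.decoy_ratio * total_bits, 1e-10)
                    )
                    entry["decoy"] = True
            chain_truth[(rec.isotig_id, sp)] = entry
    return hsps, chain_truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def generate_counts(
    gene_ids,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
):
    """Draw per-gene library counts; returns ``(CountTable, planted DE genes)``.

    Null genes are multinomial over ``library_weights``; the first
    ``n_de_genes`` genes have the weight of the first library of
    ``de_contrast`` multiplied by ``2**de_log2fc``.
    """
    import pandas as pd

    if rng is None:
        rng = _rng(cfg, 5)
    gene_ids = list(gene_ids)
    w = np.asarray(cfg.library_weights, dtype=float)
    base_p = w / w.sum()
    a, b = cfg.de_contrast
    w_de = w.copy()
    w_de[a] *= 2.0 ** cfg.de_log2fc
    de_p = w_de / w_de.sum()

    planted = []
    rows = np.zeros((len(gene_ids), 4), dtype=int)
    for i, gid in enumerate(gene_ids):
        is_de = i < cfg.n_de_genes
        p = de_p if is_de else base_p
        total = rng.poisson(cfg.mean_count)
        rows[i] = rng.multinomial(total, p)
        if is_de:
            planted.append(
                PlantedDeGene(gid, (LIBRARIES[a], LIBRARIES[b]), cfg.de_log2fc)
            )
    counts = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"),
                          columns=["n1", "n2", "n3", "n4"])
    totals = tuple(int(t) for t in rows.sum(axis=0))
    return CountTable(counts, totals), planted
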