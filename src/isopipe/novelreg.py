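"""Detection of non-conserved (novel) transcribed regions.

An isotig segment is a novel-region candidate when it falls in a query gap
between two chained HSPs (conserved flanks on both sides) and is longer than
50 bp. Candidates are then re-aligned, together with their flanks, against
the intervening genomic (intronic) sequence of every reference species with
a raised gap-opening penalty; a candidate that itself aligns to the intron
at high identity over most of its length is rejected as intron retention or
a missed weak similarity. Surviving regions are classified as
insertion-in-exon (flanks contiguous on the target) or novel-exon (flanks
separated by an annotated intron), and checked for reading-frame impact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology import ChainedHit
from .io_formats import GeneModel, HSP
from .orfproj import OrfProjection, align_pair

MIN_NOVEL_LEN = 50  # strictly more than 50 bp
IDENTITY_REJECT = 70.0  # percent
COVERAGE_REJECT = 0.80  # fraction of candidate length that must align to reject
GAP_OPEN_MULTIPLIER = 3.0
FLANK_ADJACENT_BP = 10
FLANK_CONTEXT = 50  # bp of each flank carried into the anchor alignment
FLANK_ANCHOR_IDENTITY = 0.90


@dataclass
class NovelRegion:
    isotig_id: str
    interval: tuple[int, int]  # isotig bp, half-open
    left_flank: HSP
    right_flank: HSP
    status: str = "candidate"  # candidate | novel | rejected-short | rejected-intronic | unresolved
    cls: str | None = None  # insertion-in-exon | novel-exon
    intron_identity: float = 0.0  # best percent identity vs intervening target sequence
    orf_status: str = "untested"  # ORF | PTC+ | untested

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


def find_candidates(
    chain: ChainedHit, isotig_len: int, min_len: int = MIN_NOVEL_LEN
) -> list[NovelRegion]:
    """Query gaps between consecutive chained HSPs, flanked on both sides.

    Gaps of ``min_len`` bp or shorter are reported as rejected-short;
    uncovered isotig termini are never candidates (no flank on one side).
    """
    regions = []
    members = chain.members
    for left, right in zip(members[:-1], members[1:]):
        gap = right.q_start - left.q_end
        if gap <= 0:
            continue
        status = "candidate" if gap > min_len else "rejected-short"
        regions.append(
            NovelRegion(
                chain.query_id, (left.q_end, right.q_start), left, right, status
            )
        )
    return regions


def _local_identity(candidate: str, target: str, gap_open_multiplier: float):
    """Best local alignment of the candidate against a target span.

    Returns (percent identity over aligned columns, fraction of the
    candidate aligned).
    """
    if not target or not candidate:
        return 0.0, 0.0
    aln = align_pair(candidate, target, gap_open_multiplier, mode="local")
    if not aln.blocks:
        return 0.0, 0.0
    return 100.0 * aln.identity(), aln.query_aligned_len() / len(candidate)


def _flank_target_genomic(flank: HSP, model: GeneModel) -> tuple[int, int]:
    """Genomic span of a flank's target interval (transcript-space HSP)."""
    pieces = model.transcript_to_genomic(flank.t_start, flank.t_end)
    return pieces[0][0], pieces[-1][1]


def intron_filter(
    region: NovelRegion,
    isotig_seq: str,
    models: dict[str, GeneModel],  # species -> model of the target gene
    genomes: dict[str, dict[str, str]],  # species -> chrom -> sequence
    gap_open_multiplier: float = GAP_OPEN_MULTIPLIER,
    identity_reject: float = IDENTITY_REJECT,
    coverage_reject: float = COVERAGE_REJECT,
) -> NovelRegion:
    """Align the candidate and its flanks to every species' intervening span.

    The flanks (up to ``FLANK_CONTEXT`` bp each) must anchor to the target
    span at high identity; otherwise the candidate is left unresolved. The
    candidate is rejected as intronic if its own best local identity reaches
    ``identity_reject`` percent over at least ``coverage_reject`` of its
    length in ANY species.
    """
    s, e = region.interval
    cand = isotig_seq[s:e]
    # context never extends beyond the flanking HSP itself, so its genomic
    # image is guaranteed to lie inside the extracted target span
    left_ctx_len = min(FLANK_CONTEXT, region.left_flank.q_len)
    right_ctx_len = min(FLANK_CONTEXT, region.right_flank.q_len)
    left_ctx = isotig_seq[max(0, s - left_ctx_len):s]
    right_ctx = isotig_seq[e:e + right_ctx_len]

    best_identity = 0.0
    anchored_somewhere = False
    for species, model in models.items():
        genome = genomes.get(species, {}).get(model.chrom)
        if genome is None:
            continue
        l_start, l_end = _flank_target_genomic(region.left_flank, model)
        r_start, r_end = _flank_target_genomic(region.right_flank, model)
        span_lo = max(0, l_end - left_ctx_len)
        span_hi = min(len(genome), r_start + right_ctx_len)
        if span_lo >= span_hi:
            continue
        span = genome[span_lo:span_hi]

        # sanity anchors: both flank contexts must find their known positions
        ok = True
        for ctx in (left_ctx, right_ctx):
            if len(ctx) >= 20:
                ident, cov = _local_identity(ctx, span, gap_open_multiplier)
                if ident / 100.0 < FLANK_ANCHOR_IDENTITY or cov < 0.8:
                    ok = False
        if not ok:
            continue
        anchored_somewhere = True

        intron = genome[l_end:r_start]
        target = intron if len(intron) >= 20 else span
        ident, cov = _local_identity(cand, target, gap_open_multiplier)
        if cov >= coverage_reject:
            best_identity = max(best_identity, ident)
        if ident >= identity_reject and cov >= coverage_reject:
            region.status = "rejected-intronic"
            region.intron_identity = ident
            return region

    region.intron_identity = best_identity
    region.status = "novel" if anchored_somewhere else "unresolved"
    return region


def classify_region(
    region: NovelRegion,
    model: GeneModel,
    adjacency_bp: int = FLANK_ADJACENT_BP,
) -> str:
    """insertion-in-exon when the flanks are contiguous on the target genome;
    novel-exon when they map across an annotated intron."""
    _, l_end = _flank_target_genomic(region.left_flank, model)
    r_start, _ = _flank_target_genomic(region.right_flank, model)
    gap = r_start - l_end
    region.cls = "insertion-in-exon" if gap <= adjacency_bp else "novel-exon"
    return region.cls


_STOPS = {"TAA", "TAG", "TGA"}


def orf_status(
    region: NovelRegion, isotig_seq: str, projection: OrfProjection | None
) -> str:
    """ORF iff the region lies inside the projected CDS, keeps the frame and
    introduces no stop codon; PTC+ if a stop is introduced; untested without
    a projection or outside the coding region."""
    if projection is None:
        region.orf_status = "untested"
        return region.orf_status
    s, e = region.interval
    ps, pe = projection.orf_interval
    if s < ps or e > pe:
        region.orf_status = "untested"
        return region.orf_status
    if (e - s) % 3 != 0:
        region.orf_status = "PTC+"
        return region.orf_status
    # walk codons of the projected frame overlapping the region
    first_codon = ps + ((s - ps) // 3) * 3
    for p in range(first_codon, e, 3):
        if isotig_seq[p:p + 3] in _STOPS:
            region.orf_status = "PTC+"
            return region.orf_status
    region.orf_status = "ORF"
    return region.orf_status


def detect_novel_regions(
    isotig_id: str,
    isotig_seq: str,
    chain: ChainedHit,
    models: dict[str, GeneModel],
    genomes: dict[str, dict[str, str]],
    projection: OrfProjection | None = None,
    min_len: int = MIN_NOVEL_LEN,
    gap_open_multiplier: float = GAP_OPEN_MULTIPLIER,
    identity_reject: float = IDENTITY_REJECT,
) -> list[NovelRegion]:
    """Candidate discovery, intron filtering and classification for one isotig."""
    if len(chain.members) < 2:
        return []
    primary = next(
        (m for m in models.values() if m.transcript_id == chain.target_id),
        next(iter(models.values())),
    )
    regions = find_candidates(chain, len(isotig_seq), min_len)
    for region in regions:
        if region.status != "candidate":
            continue
        intron_filter(
            region, isotig_seq, models, genomes, gap_open_multiplier, identity_reject
        )
        classify_region(region, primary)
        if region.status == "novel":
            orf_status(region, isotig_seq, projection)
    return regions
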