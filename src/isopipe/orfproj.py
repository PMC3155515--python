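"""Reference-projected ORF prediction.

Aligns an isotig to its best-mapped reference transcript (semi-global,
affine penalties, free end gaps on the isotig side), projects the reference
CDS through the alignment, translates the isotig in the projected frame and
locates premature termination codons (PTC): stops strictly upstream of the
isotig position aligned to the reference stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}

# Alignment scoring is configuration, not a truth claim.
MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -12.0
GAP_EXTEND = -2.0


def make_aligner(gap_open_multiplier: float = 1.0, mode: str = "global") -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN * gap_open_multiplier
    a.extend_gap_score = GAP_EXTEND
    if mode == "global":
        # free end gaps on the query (isotig) row: reference overhangs cost 0
        a.end_deletion_score = 0.0
    return a


@dataclass
class PairwiseAlignment:
    """A pairwise alignment as paired coordinate blocks.

    ``blocks`` pairs target (reference) intervals with query (isotig)
    intervals of equal length, ascending in both sequences.
    """

    target: str
    query: str
    score: float
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]

    def identity(self) -> float:
        """Matches over aligned columns (gap columns excluded)."""
        matched = aligned = 0
        for (ts, te), (qs, qe) in self.blocks:
            aligned += te - ts
            matched += sum(
                1 for a, b in zip(self.target[ts:te], self.query[qs:qe]) if a == b
            )
        return matched / aligned if aligned else 0.0

    def query_aligned_len(self) -> int:
        return sum(qe - qs for (_, _), (qs, qe) in self.blocks)


def align_pair(
    isotig_seq: str, transcript_seq: str, gap_open_multiplier: float = 1.0,
    mode: str = "global",
) -> PairwiseAlignment:
    """Align an isotig (query) against a reference sequence (target)."""
    if not isotig_seq or not transcript_seq:
        raise ValueError("cannot align empty sequences")
    aligner = make_aligner(gap_open_multiplier, mode)
    aln = aligner.align(transcript_seq, isotig_seq)[0]
    t_blocks, q_blocks = aln.aligned
    blocks = [
        ((int(ts), int(te)), (int(qs), int(qe)))
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
    ]
    return PairwiseAlignment(transcript_seq, isotig_seq, float(aln.score), blocks)


@dataclass
class CdsProjection:
    isotig_interval: tuple[int, int]
    frame: int
    aligned_cds_fraction: float
    translation_start: int  # isotig coordinate of the projected codon-1 start
    ref_stop_isotig_pos: int | None  # isotig base aligned to the reference stop codon
    frameshift: bool


def _map_target_to_query(blocks, t_pos: int) -> int | None:
    for (ts, te), (qs, qe) in blocks:
        if ts <= t_pos < te:
            return qs + (t_pos - ts)
    return None


def project_cds(
    alignment: PairwiseAlignment, cds: tuple[int, int]
) -> CdsProjection | None:
    """Map the reference CDS interval through the alignment.

    Returns ``None`` when no CDS column is aligned. The frame anchors codon 1
    of the reference: translation starts at the isotig base aligned to the
    first aligned CDS column, shifted back to its codon boundary.
    """
    cs, ce = cds
    if ce - cs < 3:
        raise ValueError("reference CDS shorter than one codon")
    aligned_cols = 0
    first = last = None
    for (ts, te), (qs, qe) in alignment.blocks:
        lo, hi = max(ts, cs), min(te, ce)
        if lo < hi:
            aligned_cols += hi - lo
            q_lo = qs + (lo - ts)
            q_hi = qs + (hi - ts)
            if first is None:
                first = (lo, q_lo)
            last = (hi, q_hi)
    if aligned_cols == 0 or first is None:
        return None

    t0, q0 = first
    offset = (t0 - cs) % 3
    start = q0 - offset
    if start < 0:
        # advance to the next reference codon boundary inside the alignment
        start = q0 + ((3 - offset) % 3)
    end = last[1]
    end = start + ((end - start) // 3) * 3
    if end <= start:
        return None

    # frameshift heuristic: within the CDS, target and query advance by
    # different amounts between consecutive blocks not divisible by 3
    frameshift = False
    prev = None
    for (ts, te), (qs, qe) in alignment.blocks:
        if te <= cs or ts >= ce:
            continue
        if prev is not None:
            t_gap = ts - prev[0]
            q_gap = qs - prev[1]
            if (t_gap - q_gap) % 3 != 0:
                frameshift = True
        prev = (te, qe)

    ref_stop = _map_target_to_query(alignment.blocks, ce - 3)
    return CdsProjection(
        isotig_interval=(start, end),
        frame=start % 3,
        aligned_cds_fraction=aligned_cols / (ce - cs),
        translation_start=start,
        ref_stop_isotig_pos=ref_stop,
        frameshift=frameshift,
    )


@dataclass
class OrfProjection:
    isotig_id: str
    transcript_id: str
    aligned_cds_fraction: float
    orf_interval: tuple[int, int]
    frame: int
    protein: str
    ptc: bool
    ptc_position: int | None  # isotig coordinate of the premature stop codon
    complete75: bool
    uninterrupted: bool
    frameshift_warning: bool = False


def predict_protein(
    isotig_id: str,
    isotig_seq: str,
    transcript_id: str,
    projection: CdsProjection,
    complete_threshold: float = 0.75,
) -> OrfProjection:
    """Translate the isotig in the projected frame and flag PTCs.

    Translation runs from the projected start to the first stop codon or the
    end of the projected interval; a stop strictly before the isotig position
    aligned to the reference stop codon is a PTC.
    """
    s, e = projection.isotig_interval
    if e - s < 3:
        raise ValueError("projected interval shorter than one codon")
    # translation runs past the projected interval to the first stop or the
    # end of the isotig (predicted ORF segments may exceed the alignment)
    stop_at = None
    aa = []
    p = s
    while p + 3 <= len(isotig_seq):
        codon = isotig_seq[p:p + 3]
        if codon in _STOPS:
            stop_at = p
            break
        aa.append(str(Seq(codon).translate()))
        p += 3
    orf_end = stop_at + 3 if stop_at is not None else p
    ref_stop = projection.ref_stop_isotig_pos
    ptc = stop_at is not None and (ref_stop is None or stop_at < ref_stop)
    uninterrupted = stop_at is None or (ref_stop is not None and stop_at >= ref_stop)
    return OrfProjection(
        isotig_id=isotig_id,
        transcript_id=transcript_id,
        aligned_cds_fraction=projection.aligned_cds_fraction,
        orf_interval=(s, orf_end),
        frame=projection.frame,
        protein="".join(aa),
        ptc=ptc,
        ptc_position=stop_at if ptc else None,
        complete75=projection.aligned_cds_fraction > complete_threshold,
        uninterrupted=uninterrupted,
        frameshift_warning=projection.frameshift,
    )


def project_orf(
    isotig_id: str,
    isotig_seq: str,
    transcript_id: str,
    transcript_seq: str,
    cds: tuple[int, int],
    complete_threshold: float = 0.75,
) -> OrfProjection | None:
    """Convenience wrapper: align, project, translate. None if CDS unaligned."""
    aln = align_pair(isotig_seq, transcript_seq)
    proj = project_cds(aln, cds)
    if proj is None:
        return None
    return predict_protein(isotig_id, isotig_seq, transcript_id, proj, complete_threshold)
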