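"""ORF calling on circular genomes.

An ORF is a maximal ATG-to-stop reading frame: within a run of in-frame start
codons sharing one stop, only the most upstream ATG is reported.  Calls are
wrap-aware on circular genomes, made on both strands, and filtered by a
minimum protein length (default 50 aa, i.e. >= 153 nt including the stop).
Overlap resolution is a deterministic longest-first greedy rule, and naming
assigns zero-padded ordinals clockwise from an anchor ORF (conventionally the
polyhedrin gene in nucleopolyhedrovirus genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_core import (
    STOP_CODONS,
    CircularGenome,
    GenomicInterval,
    reverse_complement,
    translate,
)


@dataclass
class OrfRecord:
    interval: GenomicInterval
    frame: int
    protein: str
    name: str = ""
    start_codon: str = "ATG"

    @property
    def span(self) -> int:
        return self.interval.span

    @property
    def strand(self) -> str:
        return self.interval.strand


def _scan_strand(seq: str, L: int, min_nt: int):
    """Yield (start, span) of maximal ATG..stop ORFs in plus-strand coords of ``seq``.

    ``seq`` is the doubled sequence for circular genomes so frames can run
    through the origin.  Spans are capped at L: an open frame longer than the
    genome wraps onto itself and is not a complete ORF, so the most upstream
    ATG within span L of the stop wins.
    """
    n = len(seq)
    for frame in range(3):
        atgs: list[int] = []  # in-frame ATG positions since the last stop
        pos = frame
        while pos + 3 <= n:
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                end = pos + 3
                for a in atgs:
                    span = end - a
                    if span <= L:
                        if span >= min_nt and a < L:
                            yield a, span
                        break  # most upstream valid ATG for this stop
                atgs = []
            elif codon == "ATG":
                atgs.append(pos)
            pos += 3


def find_orfs(genome: CircularGenome, min_aa: int = 50) -> list[OrfRecord]:
    """All maximal ATG-to-stop ORFs with protein >= min_aa, both strands.

    Sorted by start position (then span, then strand).  Wrap-aware: on a
    circular genome the reading frames continue through the origin.
    """
    L = genome.length
    min_nt = 3 * (min_aa + 1)  # protein + stop codon
    seq = genome.sequence
    doubled = seq + seq if genome.is_circular else seq

    # one ORF per (stop codon, strand): keep the longest (most upstream ATG).
    # The stop key is taken in the coordinate frame of the scan so that
    # minus-strand ORFs sharing a stop collapse correctly.
    best: dict[tuple[int, str], tuple[int, int]] = {}

    def _consider(stop_key: int, start: int, span: int, strand: str):
        key = (stop_key, strand)
        prev = best.get(key)
        if prev is None or span > prev[1]:
            best[key] = (start, span)

    for start, span in _scan_strand(doubled, L, min_nt):
        _consider((start + span - 3) % L, start % L, span, "+")
    rc = reverse_complement(seq)
    rc_doubled = rc + rc if genome.is_circular else rc
    for start, span in _scan_strand(rc_doubled, L, min_nt):
        # map rc-coordinate [start, start+span) back onto the plus strand
        g_start = (L - (start % L) - span) % L
        _consider((start + span - 3) % L, g_start, span, "-")

    orfs = []
    for (_stop, strand), (start, span) in best.items():
        iv = GenomicInterval(start=start, span=span, strand=strand)
        cds = _extract_cds(genome, iv)
        protein = translate(cds)
        frame = start % 3 if strand == "+" else ((L - (start + span) % L) % 3)
        orfs.append(OrfRecord(interval=iv, frame=frame, protein=protein))
    orfs.sort(key=lambda o: (o.interval.start, o.interval.span, o.interval.strand))
    return orfs


def _extract_cds(genome: CircularGenome, iv: GenomicInterval) -> str:
    from .genome_core import extract

    return extract(genome, iv)


def _overlap_len(a: GenomicInterval, b: GenomicInterval, L: int) -> int:
    """Overlap in bp between two (possibly wrapping) intervals on a circle."""

    def segments(iv):
        if iv.start + iv.span <= L:
            return [(iv.start, iv.start + iv.span)]
        return [(iv.start, L), (0, iv.start + iv.span - L)]

    total = 0
    for s1, e1 in segments(a):
        for s2, e2 in segments(b):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def resolve_overlaps(
    orfs: list[OrfRecord], max_overlap_frac: float = 0.25, genome_length: int | None = None
) -> list[OrfRecord]:
    """Longest-first greedy selection discarding heavily overlapping ORFs.

    An ORF is discarded when its overlap with any already-kept ORF exceeds
    ``max_overlap_frac`` of the shorter of the two.  Ties in length break by
    lower start, then plus strand.
    """
    if genome_length is None:
        genome_length = max((o.interval.start + o.interval.span for o in orfs), default=1)
    ranked = sorted(
        orfs, key=lambda o: (-o.interval.span, o.interval.start, 0 if o.strand == "+" else 1)
    )
    kept: list[OrfRecord] = []
    for cand in ranked:
        ok = True
        for k in kept:
            ov = _overlap_len(cand.interval, k.interval, genome_length)
            shorter = min(cand.interval.span, k.interval.span)
            if ov > max_overlap_frac * shorter:
                ok = False
                break
        if ok:
            kept.append(cand)
    kept.sort(key=lambda o: (o.interval.start, o.interval.span))
    return kept


def name_orfs(orfs: list[OrfRecord], prefix: str, anchor: OrfRecord | None = None) -> list[OrfRecord]:
    """Assign ``prefix`` + zero-padded ordinal clockwise from the anchor ORF.

    With no anchor, numbering starts at the ORF with the leftmost start.
    """
    if not orfs:
        return []
    ordered = sorted(orfs, key=lambda o: (o.interval.start, o.interval.span))
    if anchor is not None:
        try:
            i0 = next(i for i, o in enumerate(ordered) if o is anchor)
        except StopIteration:
            raise ValueError("anchor ORF is not in the list") from None
        ordered = ordered[i0:] + ordered[:i0]
    width = max(3, len(str(len(ordered))))
    for i, orf in enumerate(ordered, start=1):
        orf.name = f"{prefix}{i:0{width}d}"
    return ordered
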