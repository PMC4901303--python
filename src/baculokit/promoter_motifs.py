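"""Promoter-motif screening in fixed upstream windows of ORFs.

Baculovirus early promoters carry TATA-box and CAGT initiator elements and
GATA factor sites; the late promoter core is TAAG, recognized by the viral
RNA polymerase.  Motifs are matched as exact literals (IUPAC degeneracy codes
supported in user-supplied motifs) on the coding strand only, within a fixed
window (default 200 bp) immediately 5' of the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_core import CircularGenome, GenomicInterval, extract
from .orf_annotation import OrfRecord

DEFAULT_MOTIFS = ("TAAG", "TATA", "CAGT", "GATA")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class MotifHit:
    orf_name: str
    motif: str
    offset: int  # 1-based bp upstream of the ATG; 1 = base immediately 5'

    def __post_init__(self):
        if self.offset < 1:
            raise ValueError("offset must be >= 1")


def upstream_window(genome: CircularGenome, orf: OrfRecord, window: int = 200) -> str:
    """The ``window`` bases immediately 5' of the start codon on the coding strand.

    Wrap-aware on circular genomes; truncated at the sequence end only on
    linear genomes.  Returned 5'->3', so the last base abuts the ATG.
    """
    iv = orf.interval
    L = genome.length
    if iv.strand == "+":
        if genome.is_circular:
            start = (iv.start - window) % L
            return extract(genome, GenomicInterval(start, min(window, L), "+"))
        start = max(0, iv.start - window)
        if iv.start == 0:
            return ""
        return extract(genome, GenomicInterval(start, iv.start - start, "+"))
    # minus strand: upstream is 3' of the interval in plus coordinates
    after = (iv.start + iv.span) % L
    if genome.is_circular:
        return extract(genome, GenomicInterval(after, min(window, L), "-"))
    span = min(window, L - after)
    if span <= 0:
        return ""
    return extract(genome, GenomicInterval(after, span, "-"))


def _matches(motif: str, window: str, i: int) -> bool:
    for k, m in enumerate(motif):
        allowed = IUPAC.get(m)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {m!r} in motif {motif!r}")
        if window[i + k] not in allowed:
            return False
    return True


def scan_motifs(
    window: str,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
    orf_name: str = "",
) -> list[MotifHit]:
    """All exact (IUPAC-aware) occurrences of each motif in the window.

    Overlapping occurrences are all reported.  Offsets count upstream of the
    start codon: a motif whose 3'-most base abuts the ATG has offset 1.
    """
    W = len(window)
    hits = []
    for motif in motifs:
        m = motif.upper()
        k = len(m)
        for i in range(W - k + 1):
            if _matches(m, window, i):
                hits.append(MotifHit(orf_name=orf_name, motif=motif, offset=W - (i + k) + 1))
    hits.sort(key=lambda h: (h.motif, h.offset))
    return hits


def screen_orfs(
    genome: CircularGenome,
    orfs: list[OrfRecord],
    window: int = 200,
    motifs: tuple[str, ...] = DEFAULT_MOTIFS,
) -> list[MotifHit]:
    """Screen every ORF's upstream window; hits carry the ORF name."""
    out = []
    for orf in orfs:
        w = upstream_window(genome, orf, window)
        out.extend(scan_motifs(w, motifs, orf_name=orf.name or f"orf@{orf.interval.start}"))
    return out


def has_late_promoter(hits: list[MotifHit], orf_name: str) -> bool:
    """Late-promoter-bearing classification: any TAAG hit in the ORF's window."""
    return any(h.orf_name == orf_name and h.motif == "TAAG" for h in hits)
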