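"""Homologous-region (hr) discovery on circular baculovirus genomes.

hrs are interspersed clusters of imperfect palindromic repeats (unit length
~38 bp in nucleopolyhedroviruses) involved in DNA replication and
transcriptional enhancement.  The detector scores every window by
self-complementarity (palindromicity), merges overlapping qualifying windows
to the local maximum, single-linkage clusters the resulting units on circular
gap distance, and reports a per-cluster majority consensus.  An in silico PCR
routine verifies locus positions with primer pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_core import (
    PAIRS,
    CircularGenome,
    GenomicInterval,
    circular_distance,
    extract,
    reverse_complement,
)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class PalindromeUnit:
    interval: GenomicInterval
    palindromicity: float
    sequence: str


@dataclass
class HrRegion:
    interval: GenomicInterval
    units: list[PalindromeUnit]
    consensus: str
    label: str = ""
    conservation: list[float] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class PcrProduct:
    interval: GenomicInterval
    size: int
    fwd_site: GenomicInterval
    rev_site: GenomicInterval


def palindrome_score(window: str) -> float:
    """Fraction of positions that base-pair with their mirror position.

    Position i is matched when window[i] is the Watson-Crick complement of
    window[L-1-i]; N pairs with nothing.  Symmetric under reverse complement.
    """
    if not window:
        raise ValueError("empty window")
    L = len(window)
    n = sum(1 for i in range(L) if (window[i], window[L - 1 - i]) in PAIRS)
    return n / L


def _window_scores(seq: str, unit_len: int, circular: bool) -> np.ndarray:
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    arr = np.fromiter((lookup[c] for c in seq), dtype=np.int8, count=len(seq))
    comp = np.where(arr < 4, 3 - arr, 9)  # N never matches
    n = len(arr)
    if circular:
        ext = np.concatenate([arr, arr[: unit_len - 1]])
        cext = np.concatenate([comp, comp[: unit_len - 1]])
        n_win = n
    else:
        ext, cext = arr, comp
        n_win = n - unit_len + 1
    if n_win <= 0:
        return np.zeros(0)
    counts = np.zeros(n_win, dtype=np.int32)
    for j in range(unit_len):
        counts += ext[j : j + n_win] == cext[unit_len - 1 - j : unit_len - 1 - j + n_win]
    return counts / unit_len


def scan_palindromes(
    genome: CircularGenome, unit_len: int = 38, min_score: float = 0.6
) -> list[PalindromeUnit]:
    """Sliding-window palindromic-unit scan, wrap-aware on circular genomes.

    Overlapping qualifying windows are merged to the local score maximum
    (ties broken leftmost); units are returned sorted by start.
    """
    if unit_len < 4:
        raise ValueError("unit_len must be >= 4")
    L = genome.length
    if unit_len > L:
        return []
    scores = _window_scores(genome.sequence, unit_len, genome.is_circular)
    qual = np.nonzero(scores >= min_score)[0]
    if len(qual) == 0:
        return []
    # overlapping qualifying windows resolve to local score maxima: greedy
    # non-maximum suppression, highest score first, ties to the leftmost
    # start.  (Tandem palindromic repeats make the straddling mid-window
    # itself palindromic, so a simple chain-merge would fuse adjacent units.)
    order = sorted((int(w) for w in qual), key=lambda w: (-scores[w], w))
    taken: list[int] = []
    for w in order:
        clash = False
        for t in taken:
            d = abs(w - t)
            if genome.is_circular:
                d = min(d, L - d)
            if d < unit_len:
                clash = True
                break
        if not clash:
            taken.append(w)
    units = []
    for w in sorted(taken):
        iv = GenomicInterval(start=w % L, span=unit_len, strand="+")
        units.append(
            PalindromeUnit(
                interval=iv,
                palindromicity=float(scores[w]),
                sequence=extract(genome, iv),
            )
        )
    return units


def cluster_into_hrs(
    units: list[PalindromeUnit],
    genome_length: int,
    max_gap: int = 500,
    min_units: int = 2,
    circular: bool = True,
) -> list[HrRegion]:
    """Single-linkage clustering of units on circular gap distance.

    Clusters with fewer than ``min_units`` members are discarded; survivors
    are labelled hr1..hrN clockwise from the origin.  The region interval is
    the minimal hull covering all member units.
    """
    if not units:
        return []
    units = sorted(units, key=lambda u: u.interval.start)
    clusters: list[list[PalindromeUnit]] = [[units[0]]]
    for u in units[1:]:
        prev = clusters[-1][-1]
        gap = u.interval.start - (prev.interval.start + prev.interval.span)
        if gap <= max_gap:
            clusters[-1].append(u)
        else:
            clusters.append([u])
    if circular and len(clusters) > 1:
        last = clusters[-1][-1]
        first = clusters[0][0]
        wrap_gap = (first.interval.start + genome_length) - (
            last.interval.start + last.interval.span
        )
        if wrap_gap <= max_gap:
            clusters[0] = clusters.pop() + clusters[0]
    regions = []
    for members in clusters:
        if len(members) < min_units:
            continue
        start = members[0].interval.start
        end = members[-1].interval.start + members[-1].interval.span
        span = end - start if end > start else end + genome_length - start
        region = HrRegion(
            interval=GenomicInterval(start=start % genome_length, span=span, strand="+"),
            units=members,
            consensus="",
        )
        region.consensus, region.conservation = hr_consensus(region)
        regions.append(region)
    regions.sort(key=lambda r: r.interval.start)
    for i, r in enumerate(regions, start=1):
        r.label = f"hr{i}"
    return regions


def hr_consensus(region: HrRegion) -> tuple[str, list[float]]:
    """Column-wise majority consensus over the (equal-length) member units.

    Ties break to the alphabetically first base.  Also returns per-column
    conservation fractions; strictly identical columns score 1.0.
    """
    if not region.units:
        raise ValueError("region has no units")
    seqs = [u.sequence for u in region.units]
    length = len(seqs[0])
    cons, conserv = [], []
    for j in range(length):
        counts: dict[str, int] = {}
        for s in seqs:
            counts[s[j]] = counts.get(s[j], 0) + 1
        best = max(sorted(counts), key=lambda b: counts[b])
        cons.append(best)
        conserv.append(counts[best] / len(seqs))
    return "".join(cons), conserv


# ---------------------------------------------------------------------------
# in silico PCR


def _primer_sites(seq: str, primer: str, circular: bool, max_mismatch: int, three_prime_at_end: bool):
    """Start positions where the primer anneals on the given strand of ``seq``.

    ``three_prime_at_end``: the primer's 3' terminal base sits at the last
    (rightmost) footprint position; it must match exactly.
    """
    L = len(seq)
    k = len(primer)
    ext = seq + seq[: k - 1] if circular else seq
    n_win = L if circular else L - k + 1
    hits = []
    for i in range(max(0, n_win)):
        window = ext[i : i + k]
        mism = sum(1 for a, b in zip(primer, window) if a != b)
        if mism > max_mismatch:
            continue
        ti = k - 1 if three_prime_at_end else 0
        if primer[ti] != window[ti]:
            continue
        hits.append(i)
    return hits


def insilico_pcr(
    genome: CircularGenome,
    fwd: str,
    rev: str,
    max_mismatch: int = 0,
    max_product: int = 5000,
) -> list[PcrProduct]:
    """All inward-facing primer-site pairs yielding a product <= max_product.

    The forward primer anneals to the minus strand (its sequence appears on
    the plus strand); the reverse primer anneals to the plus strand (its
    reverse complement appears on the plus strand, 3' end leftmost).  The
    product includes both primer footprints; products may wrap the origin.
    A perfect-match 3' terminal base is always required.
    """
    fwd, rev = fwd.replace(" ", "").upper(), rev.replace(" ", "").upper()
    if len(fwd) < 10 or len(rev) < 10:
        raise ValueError("primers must be >= 10 nt")
    L = genome.length
    seq = genome.sequence
    fwd_hits = _primer_sites(seq, fwd, genome.is_circular, max_mismatch, three_prime_at_end=True)
    rev_rc = reverse_complement(rev)
    # rev primer's 3' base maps to the leftmost base of its plus-strand footprint
    rev_hits = _primer_sites(seq, rev_rc, genome.is_circular, max_mismatch, three_prime_at_end=False)
    products = []
    for f in fwd_hits:
        for r in rev_hits:
            size = ((r + len(rev)) - f) % L
            if size == 0:
                size = L
            if size < len(fwd) + len(rev):
                continue  # footprints overlap or face outward
            if size > max_product:
                continue
            products.append(
                PcrProduct(
                    interval=GenomicInterval(start=f, span=size, strand="+"),
                    size=size,
                    fwd_site=GenomicInterval(start=f, span=len(fwd), strand="+"),
                    rev_site=GenomicInterval(start=r, span=len(rev), strand="-"),
                )
            )
    products.sort(key=lambda p: (p.interval.start, p.size))
    return products


def check_duplicate_primers(primer_table: dict[str, tuple[str, str]]) -> list[tuple[str, str, str]]:
    """Flag primer sequences shared between loci (possible typos in a table).

    Returns (locus_a, locus_b, primer) triples; e.g. identical forward
    primers printed for two different hrs.
    """
    flags = []
    names = sorted(primer_table)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            for pa in primer_table[a]:
                for pb in primer_table[b]:
                    if pa.replace(" ", "").upper() == pb.replace(" ", "").upper():
                        flags.append((a, b, pa))
    return flags
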