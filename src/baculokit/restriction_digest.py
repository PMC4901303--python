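"""In silico restriction digestion of circular genomes.

Used as an assembly-validation step: the predicted fragment-size profile of a
digest with common six-cutters is compared against an expected (previously
published) profile.  Recognition sequences and cut offsets ship as a small
editable table; they are constants of record, not computed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_core import CircularGenome, reverse_complement

# enzyme -> (recognition site, cut offset from site start on the top strand)
ENZYMES: dict[str, tuple[str, int]] = {
    "BamHI": ("GGATCC", 1),
    "EcoRI": ("GAATTC", 1),
    "PstI": ("CTGCAG", 5),
    "HindIII": ("AAGCTT", 1),
    "XhoI": ("CTCGAG", 1),
}


@dataclass
class DigestResult:
    enzyme: str
    site: str
    cut_positions: list[int]
    fragments: list[int]  # bp sizes, descending

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


def _find_sites(seq: str, site: str, circular: bool) -> list[int]:
    """Start positions of every site occurrence, on both strands, wrap-aware."""
    L = len(seq)
    k = len(site)
    ext = seq + seq[: k - 1] if circular else seq
    hits = set()
    for probe in {site, reverse_complement(site)}:
        start = 0
        while True:
            i = ext.find(probe, start)
            if i == -1 or i >= L:
                break
            hits.add((i, probe))
            start = i + 1
    return sorted(h[0] for h in hits)


def digest(genome: CircularGenome, enzyme: str, site: str | None = None, cut_offset: int | None = None) -> DigestResult:
    """Cut at every recognition-site occurrence; fragments are circular arcs.

    For a circular genome with n >= 1 sites the digest yields exactly n
    fragments whose sizes sum to the genome length; zero sites leave one
    uncut fragment.
    """
    if site is None or cut_offset is None:
        if enzyme not in ENZYMES:
            raise KeyError(f"unknown enzyme {enzyme!r}; supply site and cut_offset")
        site, cut_offset = ENZYMES[enzyme]
    if not site:
        raise ValueError("empty recognition site")
    if not 0 <= cut_offset <= len(site):
        raise ValueError("cut_offset outside site")
    L = genome.length
    sites = _find_sites(genome.sequence, site, genome.is_circular)
    cuts = sorted({(s + cut_offset) % L for s in sites})
    if not cuts:
        return DigestResult(enzyme=enzyme, site=site, cut_positions=[], fragments=[L])
    if genome.is_circular:
        frags = [
            (cuts[(i + 1) % len(cuts)] - cuts[i]) % L or L for i in range(len(cuts))
        ]
    else:
        frags = [cuts[0]] if cuts[0] > 0 else []
        frags += [cuts[i + 1] - cuts[i] for i in range(len(cuts) - 1)]
        if L - cuts[-1] > 0:
            frags.append(L - cuts[-1])
    return DigestResult(
        enzyme=enzyme, site=site, cut_positions=cuts, fragments=sorted(frags, reverse=True)
    )


@dataclass
class ProfileComparison:
    matched: list[tuple[int, int, float]]  # (observed, expected, relative error)
    unmatched_observed: list[int]
    unmatched_expected: list[int]
    passed: bool


def compare_profiles(
    observed: DigestResult, expected: list[int], tol_frac: float = 0.05
) -> ProfileComparison:
    """Sorted-greedy one-to-one matching of fragment sizes at a relative tolerance.

    Both lists are walked largest-first; the current heads are paired when
    their relative error (vs the expected size) is within ``tol_frac``,
    otherwise the larger head is declared unmatched and dropped.
    """
    if not expected:
        raise ValueError("expected profile is empty")
    obs = sorted(observed.fragments, reverse=True)
    exp = sorted(expected, reverse=True)
    matched, un_o, un_e = [], [], []
    i = j = 0
    while i < len(obs) and j < len(exp):
        rel = abs(obs[i] - exp[j]) / exp[j]
        if rel <= tol_frac:
            matched.append((obs[i], exp[j], rel))
            i += 1
            j += 1
        elif obs[i] > exp[j]:
            un_o.append(obs[i])
            i += 1
        else:
            un_e.append(exp[j])
            j += 1
    un_o += obs[i:]
    un_e += exp[j:]
    passed = not un_o and not un_e and all(r <= tol_frac for *_pair, r in matched)
    return ProfileComparison(matched, un_o, un_e, passed)
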