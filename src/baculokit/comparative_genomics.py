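"""Ortholog assignment, unique-ORF classification, synteny/inversion mapping,
and the hr-proximity permutation test.

Protein pairs are compared by optimal Smith-Waterman local alignment with
affine gaps (BLOSUM62 by default); significance uses the Karlin-Altschul
formula E = K*m*n*exp(-lambda*S) with fixed published gapped constants, since
database-scale BLAST statistics cannot be recomputed offline.  Orthology is
reciprocal best hit; an ORF with no hit at E <= threshold in any subject
genome is classified unique.  Shared orthologs reduced to a signed
permutation of genomic ranks yield synteny blocks, with inverted blocks
(descending rank, flipped strand) flagged; a permutation test asks whether
unique ORFs sit closer to hrs than uniform placement predicts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

# Karlin-Altschul gapped constants for BLOSUM62 with gap open 11 / extend 1
DEFAULT_K = 0.041
DEFAULT_LAMBDA = 0.267

_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass
class AlignmentResult:
    raw_score: float
    score: float  # bit score
    identity: float
    aligned_length: int
    evalue: float | None = None


def _make_aligner(matrix: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def align_proteins(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> AlignmentResult:
    """Optimal local alignment with affine gaps; identity over aligned columns."""
    if not a or not b:
        raise ValueError("empty sequence")
    for s in (a, b):
        bad = next((c for c in s if c not in _AA), None)
        if bad is not None:
            raise ValueError(f"non-amino-acid character {bad!r}")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    score = aligner.score(a, b)
    if score <= 0:
        return AlignmentResult(raw_score=0.0, score=0.0, identity=0.0, aligned_length=0)
    aln = next(iter(aligner.align(a, b)))
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / aligned_cols if aligned_cols else 0.0
    bits = (lam * score - math.log(K)) / math.log(2)
    return AlignmentResult(
        raw_score=float(score), score=bits, identity=identity, aligned_length=int(aligned_cols)
    )


def estimate_evalue(
    raw_score: float, m: int, n: int, K: float = DEFAULT_K, lam: float = DEFAULT_LAMBDA
) -> float:
    """Karlin-Altschul expected number of chance alignments at this score."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space dimensions must be positive")
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    return K * m * n * math.exp(-lam * raw_score)


@dataclass
class OrthologTable:
    """Pairwise best-hit assignments of a focal proteome against subjects.

    ``df`` columns: query, subject_genome, subject (None = no significant
    hit), raw_score, identity, evalue, reciprocal.
    """

    df: pd.DataFrame
    focal_genome: str = "focal"

    def unique_orfs(self) -> list[str]:
        """Queries with no significant hit in any subject genome."""
        no_hit = self.df.groupby("query")["subject"].apply(lambda s: s.isna().all())
        return sorted(no_hit[no_hit].index)

    def reciprocal_pairs(self, subject_genome: str) -> set[tuple[str, str]]:
        sub = self.df[(self.df.subject_genome == subject_genome) & self.df.reciprocal]
        return {(q, s) for q, s in zip(sub["query"], sub["subject"]) if isinstance(s, str)}

    def ortholog_of(self, query: str, subject_genome: str) -> str | None:
        sub = self.df[(self.df["query"] == query) & (self.df.subject_genome == subject_genome)]
        if sub.empty:
            return None
        s = sub.iloc[0]["subject"]
        return s if isinstance(s, str) else None


def _best_hits(scores: dict[tuple[str, str], AlignmentResult], queries, subjects):
    """query -> best subject by raw score, ties by identity then name."""
    best = {}
    for q in queries:
        ranked = sorted(
            ((s, scores[(q, s)]) for s in subjects),
            key=lambda item: (-item[1].raw_score, -item[1].identity, item[0]),
        )
        if ranked:
            best[q] = ranked[0]
    return best


def assign_orthologs(
    query_proteome: dict[str, str],
    subject_proteomes: dict[str, dict[str, str]],
    e_threshold: float = 1e-3,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    K: float = DEFAULT_K,
    lam: float = DEFAULT_LAMBDA,
) -> OrthologTable:
    """Best hit per subject genome with reciprocal-best-hit flags.

    Hits with E above the threshold are recorded as no-hit (subject None);
    the unique-ORF classification falls out as queries with no hit anywhere.
    """
    if not query_proteome or not subject_proteomes:
        raise ValueError("empty proteome")
    rows = []
    for genome_name, subject in subject_proteomes.items():
        n_total = sum(len(s) for s in subject.values())
        scores: dict[tuple[str, str], AlignmentResult] = {}
        for qname, qseq in query_proteome.items():
            for sname, sseq in subject.items():
                scores[(qname, sname)] = align_proteins(
                    qseq, sseq, matrix, gap_open, gap_extend, K, lam
                )
        fwd = _best_hits(scores, query_proteome, subject)
        rev_scores = {(s, q): r for (q, s), r in scores.items()}
        rev = _best_hits(rev_scores, subject, query_proteome)
        m_total = sum(len(s) for s in query_proteome.values())
        for qname, qseq in query_proteome.items():
            sname, res = fwd[qname]
            ev = estimate_evalue(res.raw_score, len(qseq), n_total, K, lam)
            if ev > e_threshold:
                rows.append(
                    dict(query=qname, subject_genome=genome_name, subject=None,
                         raw_score=None, identity=None, evalue=None, reciprocal=False)
                )
                continue
            rev_name, rev_res = rev[sname]
            rev_ev = estimate_evalue(rev_res.raw_score, len(subject[sname]), m_total, K, lam)
            reciprocal = rev_name == qname and rev_ev <= e_threshold
            rows.append(
                dict(query=qname, subject_genome=genome_name, subject=sname,
                     raw_score=res.raw_score, identity=res.identity, evalue=ev,
                     reciprocal=reciprocal)
            )
    return OrthologTable(df=pd.DataFrame(rows))


def identity_heatmap_table(table: OrthologTable) -> pd.DataFrame:
    """Focal-ORF x genome matrix of best-hit identity fractions (NaN = unique).

    The data behind a circular identity heat map: one row per focal ORF, one
    column per compared genome.
    """
    return table.df.pivot(index="query", columns="subject_genome", values="identity")


@dataclass
class SyntenyBlock:
    pairs: list[tuple[int, int]]  # (focal rank, subject rank)
    orientation: str  # collinear | inverted

    @property
    def length(self) -> int:
        return len(self.pairs)


@dataclass
class SyntenyMap:
    blocks: list[SyntenyBlock]
    singletons: list[tuple[int, int]]
    focal_order: list[str]
    subject_order: list[str]

    @property
    def inverted_blocks(self) -> list[SyntenyBlock]:
        return [b for b in self.blocks if b.orientation == "inverted"]


def synteny_map(focal_orfs, subject_orfs, table: OrthologTable, subject_genome: str) -> SyntenyMap:
    """Reduce shared orthologs to a signed permutation and report monotone runs.

    Focal and subject ORFs are ranked by genomic start; each ortholog pair
    becomes (focal rank, subject rank) with sign +1 when the two copies lie
    on agreeing strands.  Maximal runs with strictly increasing subject rank
    and + sign are collinear blocks; strictly decreasing rank with - sign are
    inverted blocks.  Runs of length 1 are reported as singletons, so the
    decomposition covers every shared ortholog exactly once.
    """
    focal_sorted = sorted(focal_orfs, key=lambda o: o.interval.start)
    subject_sorted = sorted(subject_orfs, key=lambda o: o.interval.start)
    subject_rank = {o.name: i for i, o in enumerate(subject_sorted)}
    subject_strand = {o.name: o.interval.strand for o in subject_sorted}
    perm = []  # (focal rank, subject rank, sign)
    for qi, orf in enumerate(focal_sorted):
        s = table.ortholog_of(orf.name, subject_genome)
        if s is None or s not in subject_rank:
            continue
        sign = 1 if orf.interval.strand == subject_strand[s] else -1
        perm.append((qi, subject_rank[s], sign))
    blocks: list[SyntenyBlock] = []
    singles: list[tuple[int, int]] = []
    i = 0
    while i < len(perm):
        j = i + 1
        direction = None
        while j < len(perm):
            step = perm[j][1] - perm[j - 1][1]
            want = "collinear" if (step > 0 and perm[j][2] == 1 and perm[j - 1][2] == 1) else (
                "inverted" if (step < 0 and perm[j][2] == -1 and perm[j - 1][2] == -1) else None
            )
            if want is None or (direction is not None and want != direction):
                break
            direction = want
            j += 1
        run = [(q, s) for q, s, _ in perm[i:j]]
        if len(run) >= 2:
            blocks.append(SyntenyBlock(pairs=run, orientation=direction))
        else:
            singles.append(run[0])
        i = j
    return SyntenyMap(
        blocks=blocks,
        singletons=singles,
        focal_order=[o.name for o in focal_sorted],
        subject_order=[o.name for o in subject_sorted],
    )


def _distance_to_hrs(positions: np.ndarray, hrs, L: int) -> np.ndarray:
    """Circular distance from each position to the nearest hr boundary (0 inside)."""
    d = np.full(positions.shape, np.inf)
    for iv in hrs:
        rel = (positions - iv.start) % L
        inside = rel < iv.span
        outside_d = np.minimum(rel - iv.span, L - rel)
        d = np.minimum(d, np.where(inside, 0.0, outside_d))
    return d


def hr_proximity_test(
    unique_orf_midpoints: list[int],
    hr_intervals,
    genome_length: int,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test: are unique-ORF midpoints closer to hrs than chance?

    Statistic: mean circular distance from each midpoint to the nearest hr
    boundary (0 for midpoints inside an hr).  Null: midpoints repositioned
    uniformly at random.  One-sided p = (1 + #{null <= observed}) / (n_perm + 1).
    """
    if not unique_orf_midpoints or not list(hr_intervals):
        raise ValueError("need at least one midpoint and one hr")
    rng = np.random.default_rng(seed)
    mids = np.asarray(unique_orf_midpoints)
    observed = float(_distance_to_hrs(mids, hr_intervals, genome_length).mean())
    null_pos = rng.integers(0, genome_length, size=(n_perm, len(mids)))
    null_stats = _distance_to_hrs(null_pos, hr_intervals, genome_length).mean(axis=1)
    p = (1 + int(np.sum(null_stats <= observed))) / (n_perm + 1)
    return observed, p
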