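"""Truth-tracked synthetic circular genomes for end-to-end pipeline testing.

The generator plants non-overlapping ORFs (ATG..stop on both strands, with
promoter motifs in fixed upstream windows), homologous regions built as tandem
arrays of an imperfect 38-bp palindromic repeat, and restriction sites, on an
i.i.d. background at a configurable GC content.  The background is then
scrubbed: chance ORFs above the calling threshold, chance restriction-site
occurrences and chance high-scoring palindromic windows are destroyed by
single-base edits that never touch a planted feature, so the planted truth is
the *complete* truth and exact-count assertions are possible downstream.

A second entry point derives rearranged genomes (inversions, translocations,
gene gain/loss) plus per-base sequence divergence, recording the old<->new
coordinate mapping, which gives the synteny and orthology stages a replayable
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .genome_core import (
    CircularGenome,
    FeatureRecord,
    GenomicInterval,
    STOP_CODONS,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .orf_annotation import find_orfs
from .restriction_digest import ENZYMES

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(
    c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT") if c not in STOP_CODONS
)


class CapacityError(ValueError):
    """Requested features do not fit in the genome without overlap."""


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate a group I alphabaculovirus genome: ~120 kb circular,
    134 ORFs of >= 50 aa, seven homologous regions each a tandem array of an
    imperfect 38-bp palindromic repeat, ~42% GC, and the four canonical
    baculovirus promoter motifs planted upstream of a designated ORF subset.
    """

    genome_length: int = 120_000
    n_orfs: int = 134
    orf_length_range: tuple[int, int] = (153, 1200)  # nt incl. stop, multiple of 3
    n_hrs: int = 7
    units_per_hr_range: tuple[int, int] = (3, 8)
    unit_length: int = 38
    unit_divergence: float = 0.1
    promoter_motifs_planted: tuple[str, ...] = ("TAAG", "TATA", "CAGT", "GATA")
    n_promoter_orfs: int = 12
    restriction_sites_planted: dict = field(
        default_factory=lambda: {"BamHI": 3, "EcoRI": 3, "PstI": 3}
    )
    gc_content: float = 0.42
    seed: int = 0
    min_orf_aa: int = 50
    promoter_window: int = 200
    palindrome_scrub_score: float = 0.6

    def __post_init__(self):
        for name in ("n_orfs", "n_hrs", "genome_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.unit_divergence <= 1.0:
            raise ValueError("unit_divergence must be in [0,1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0,1)")


@dataclass
class RearrangementOp:
    """One derivation step; coordinates refer to the genome state it is applied to."""

    kind: str  # inversion | translocation | loss | gain
    start: int | None = None
    span: int | None = None
    dest: int | None = None  # translocation insertion point (post-excision coords)
    label: str | None = None  # loss target
    length: int | None = None  # gain ORF length (nt incl. stop)


@dataclass
class TruthTable:
    features: list[FeatureRecord]
    derivation_ops: list[RearrangementOp] = field(default_factory=list)
    config: SimConfig | None = None

    def of_kind(self, kind: str) -> list[FeatureRecord]:
        return [f for f in self.features if f.kind == kind]

    @property
    def orfs(self) -> list[FeatureRecord]:
        return self.of_kind("ORF")

    @property
    def hrs(self) -> list[FeatureRecord]:
        return self.of_kind("hr")

    def proteome(self) -> dict[str, str]:
        return {f.label: f.attributes["protein"] for f in self.orfs}


# ---------------------------------------------------------------------------
# low-level sequence helpers


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _arr_to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


def _str_to_arr(s: str) -> np.ndarray:
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.fromiter((lookup[c] for c in s), dtype=np.int8, count=len(s))


def mutate_sequence(seq: str, rate: float, seed: int) -> str:
    """Substitute each base independently with probability ``rate``.

    Substitutions are uniform over the three alternative bases; the result is
    a pure function of (seq, rate, seed).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    return _mutate_with_rng(seq, rate, rng)


def _mutate_with_rng(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = _str_to_arr(seq)
    mask = rng.random(len(arr)) < rate
    shifts = rng.integers(1, 4, size=len(arr))
    arr[mask] = (arr[mask] + shifts[mask]) % 4
    return _arr_to_str(arr)


def _random_orf_seq(rng: np.random.Generator, length_nt: int) -> str:
    """ATG + random non-stop codons + stop; length_nt includes the stop codon."""
    if length_nt % 3 != 0 or length_nt < 9:
        raise ValueError("ORF length must be a multiple of 3 and >= 9")
    n_mid = length_nt // 3 - 2
    mids = rng.choice(len(_NONSTOP_CODONS), size=n_mid)
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in mids) + stop


def _random_palindrome(rng: np.random.Generator, length: int, forbidden: tuple[str, ...] = ()) -> str:
    """A perfect palindromic unit free of ATG/CAT triplets (keeps hrs ORF-free)
    and of any forbidden motif (e.g. planted restriction sites)."""
    half = length // 2
    for _ in range(10_000):
        left = _arr_to_str(rng.choice(4, size=half))
        unit = left + ("" if length % 2 == 0 else "A") + reverse_complement(left)
        unit = unit[:length]
        if "ATG" in unit or "CAT" in unit:
            continue
        if any(m in unit for m in forbidden):
            continue
        return unit
    raise RuntimeError("could not draw an ORF-free palindromic unit")


# ---------------------------------------------------------------------------
# genome assembly


def _build_blocks(cfg: SimConfig, rng: np.random.Generator):
    """Return (blocks, master_unit): each block is (seq, rel_features)."""
    blocks = []

    # ORF blocks.  A guard stop codon sits immediately 5' of every planted ATG
    # so the planted start is the maximal (most upstream) start for its stop.
    lo, hi = cfg.orf_length_range
    lo3, hi3 = (max(9, lo + (-lo) % 3), hi - hi % 3)
    n_prom = min(cfg.n_promoter_orfs, cfg.n_orfs) if cfg.promoter_motifs_planted else 0
    for i in range(cfg.n_orfs):
        length = int(rng.integers(lo3 // 3, hi3 // 3 + 1)) * 3
        orf_seq = _random_orf_seq(rng, length)
        strand = "+" if rng.random() < 0.5 else "-"
        rel_feats = []
        prom = ""
        if i < n_prom:
            prom_arr = _random_background(rng, cfg.promoter_window, cfg.gc_content)
            prom = _arr_to_str(prom_arr)
            motifs = list(cfg.promoter_motifs_planted)
            # distinct, non-overlapping slots inside the window
            max_mlen = max(len(m) for m in motifs)
            slots = rng.permutation(cfg.promoter_window // (max_mlen + 2))[: len(motifs)]
            for m, slot in zip(motifs, slots):
                off = int(slot) * (max_mlen + 2)
                prom = prom[:off] + m + prom[off + len(m) :]
                rel_feats.append(("motif", off, len(m), {"motif": m}))
        coding_block = prom + "TAA" + orf_seq
        orf_rel_start = len(prom) + 3
        rel_feats.append(
            ("ORF", orf_rel_start, length, {"protein_seq": orf_seq, "strand": "+"})
        )
        rel_feats.append(("guard", len(prom), 3, {}))
        if strand == "-":
            blen = len(coding_block)
            coding_block = reverse_complement(coding_block)
            rel_feats = [
                (kind, blen - (off + span), span, dict(at, strand="-"))
                for kind, off, span, at in rel_feats
            ]
        blocks.append(("orf", coding_block, rel_feats, {"orf_index": i}))

    # hr blocks: tandem arrays of an imperfect copy of one master palindrome
    forbidden = tuple(ENZYMES[e][0] for e in cfg.restriction_sites_planted)
    master = _random_palindrome(rng, cfg.unit_length, forbidden) if cfg.n_hrs else ""
    for _ in range(cfg.n_hrs):
        n_units = int(rng.integers(cfg.units_per_hr_range[0], cfg.units_per_hr_range[1] + 1))
        seq_parts = []
        rel_feats = []
        pos = 0
        for u in range(n_units):
            spacer = int(rng.integers(3, 21))
            seq_parts.append(_arr_to_str(_random_background(rng, spacer, cfg.gc_content)))
            pos += spacer
            unit = _mutate_with_rng(master, cfg.unit_divergence, rng)
            seq_parts.append(unit)
            rel_feats.append(("repeat_unit", pos, cfg.unit_length, {"unit_seq": unit}))
            pos += cfg.unit_length
        block_seq = "".join(seq_parts)
        first = rel_feats[0][1]
        hull = (rel_feats[-1][1] + cfg.unit_length) - first
        rel_feats.append(("hr", first, hull, {"n_units": n_units}))
        blocks.append(("hr", block_seq, rel_feats, {}))

    # restriction-site blocks
    for enzyme, count in sorted(cfg.restriction_sites_planted.items()):
        site = ENZYMES[enzyme][0]
        for _ in range(count):
            blocks.append(
                ("site", site, [("restriction_site", 0, len(site), {"enzyme": enzyme})], {})
            )
    return blocks, master


def generate_genome(cfg: SimConfig) -> tuple[CircularGenome, TruthTable]:
    """Build a circular genome with planted, truth-tracked features.

    Deterministic given ``cfg`` (including its seed).  Raises
    :class:`CapacityError` when the requested features cannot be packed
    without overlap.
    """
    rng = np.random.default_rng(cfg.seed)
    blocks, master = _build_blocks(cfg, rng)
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    total_block = sum(len(b[1]) for b in blocks)
    n_gaps = len(blocks) + 1
    # hr loci must stay distinct under downstream clustering (max_gap 500 bp),
    # so any junction adjacent to an hr block gets a larger floor
    hr_margin = 600
    min_gaps = []
    for k in range(n_gaps):
        left_hr = k > 0 and blocks[k - 1][0] == "hr"
        right_hr = k < len(blocks) and blocks[k][0] == "hr"
        min_gaps.append(hr_margin if (left_hr or right_hr) else 2)
    slack = cfg.genome_length - total_block - sum(min_gaps)
    if slack < 0:
        raise CapacityError(
            f"planted features need {total_block + sum(min_gaps)} bp "
            f"but genome_length is {cfg.genome_length}"
        )
    extra = rng.multinomial(slack, np.full(n_gaps, 1.0 / n_gaps)) if n_gaps else []
    gaps = [m + int(e) for m, e in zip(min_gaps, extra)]

    parts = []
    features: list[FeatureRecord] = []
    guards: list[tuple[int, int]] = []
    pos = 0
    orf_counter = 0
    hr_counter = 0
    site_counter = 0
    motif_counter = 0
    pending_motifs = []  # (orf_index_in_block_meta, feature) resolved after naming
    for (btype, bseq, rel_feats, meta), gap in zip(blocks, gaps[:-1]):
        parts.append(_arr_to_str(_random_background(rng, gap, cfg.gc_content)))
        pos += gap
        for kind, off, span, attrs in rel_feats:
            strand = attrs.pop("strand", "+")
            if kind == "guard":
                guards.append((pos + off, span))
                continue
            if kind == "ORF":
                orf_counter += 1
                label = f"orf{orf_counter:03d}"
                orf_seq = attrs.pop("protein_seq")
                from .genome_core import translate

                attrs["protein"] = translate(orf_seq)
            elif kind == "hr":
                hr_counter += 1
                label = f"hr{hr_counter}"
            elif kind == "repeat_unit":
                label = f"unit{len([f for f in features if f.kind == 'repeat_unit']) + 1:03d}"
            elif kind == "restriction_site":
                site_counter += 1
                label = f"site{site_counter:03d}"
            elif kind == "motif":
                motif_counter += 1
                label = f"pmotif{motif_counter:03d}"
            else:
                label = f"{kind}{len(features)}"
            features.append(
                FeatureRecord(
                    interval=GenomicInterval(start=pos + off, span=span, strand=strand),
                    kind=kind,
                    label=label,
                    attributes=attrs,
                )
            )
        parts.append(bseq)
        pos += len(bseq)
    parts.append(_arr_to_str(_random_background(rng, gaps[-1], cfg.gc_content)))
    seq = "".join(parts)
    assert len(seq) == cfg.genome_length

    # attach motif features to their ORF by position (motif upstream window)
    genome = CircularGenome(id=f"synthetic_seed{cfg.seed}", sequence=seq)
    seq = _scrub(genome.sequence, cfg, features, guards, rng)
    genome = CircularGenome(id=genome.id, sequence=seq)
    truth = TruthTable(features=features, derivation_ops=[], config=cfg)
    truth.master_unit = master  # type: ignore[attr-defined]
    return genome, truth


# ---------------------------------------------------------------------------
# scrubbing


def _palindrome_scores(arr: np.ndarray, unit_len: int, circular: bool = True) -> np.ndarray:
    """Self-complementarity score of every window start (vectorized)."""
    comp = 3 - arr  # A<->T, C<->G under the 0..3 encoding
    n = len(arr)
    ext = np.concatenate([arr, arr[: unit_len - 1]]) if circular else arr
    cext = np.concatenate([comp, comp[: unit_len - 1]]) if circular else comp
    n_win = n if circular else n - unit_len + 1
    if n_win <= 0:
        return np.zeros(0)
    counts = np.zeros(n_win, dtype=np.int32)
    for j in range(unit_len):
        counts += ext[j : j + n_win] == cext[unit_len - 1 - j : unit_len - 1 - j + n_win]
    return counts / unit_len


class _EditGuard:
    """Decides whether a single-base substitution keeps all planted truth intact."""

    def __init__(self, L: int, cfg: SimConfig, features, guards):
        self.L = L
        self.cfg = cfg
        self.protected = np.zeros(L, dtype=bool)
        self.orf_at = np.full(L, -1, dtype=np.int64)
        self.orfs = [f for f in features if f.kind == "ORF"]
        # repeat units are soft-protected: editable only as a last resort,
        # with the edit written back into the unit's truth sequence
        self.repeat_at = np.full(L, -1, dtype=np.int64)
        self.repeat_units = [f for f in features if f.kind == "repeat_unit"]
        for i, f in enumerate(self.repeat_units):
            for p in f.interval.positions(L):
                self.repeat_at[p] = i
        for kind_protect in ("motif", "restriction_site"):
            for f in features:
                if f.kind == kind_protect:
                    for p in f.interval.positions(L):
                        self.protected[p] = True
        for s, span in guards:
            for k in range(span):
                self.protected[(s + k) % L] = True
        for i, f in enumerate(self.orfs):
            iv = f.interval
            for k in range(iv.span):
                p = (iv.start + k) % L
                self.orf_at[p] = i
                if k < 3 or k >= iv.span - 3:  # start + stop codons fixed
                    self.protected[p] = True

    def ok(self, seq: list, p: int, new_base: str, allow_repeat: bool = False) -> bool:
        if self.protected[p]:
            return False
        if self.repeat_at[p] >= 0 and not allow_repeat:
            return False
        i = self.orf_at[p]
        if i < 0:
            return True
        iv = self.orfs[i].interval
        off = (p - iv.start) % self.L
        if iv.strand == "-":
            off = iv.span - 1 - off
        ci = off // 3
        codon_positions = []
        for k in range(3):
            plus_off = ci * 3 + k if iv.strand == "+" else iv.span - 1 - (ci * 3 + k)
            codon_positions.append((iv.start + plus_off) % self.L)
        codon = ""
        for gp in codon_positions:
            b = new_base if gp == p else seq[gp]
            codon += b if iv.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[b]
        return codon not in STOP_CODONS


def _scrub(sequence: str, cfg: SimConfig, features, guards, rng: np.random.Generator) -> str:
    """Destroy chance ORFs, chance restriction sites and chance palindromic
    windows by single-base edits that never touch planted truth."""
    L = len(sequence)
    seq = list(sequence)
    guard = _EditGuard(L, cfg, features, guards)
    truth_orf_keys = {
        (f.interval.start, f.interval.span, f.interval.strand)
        for f in features
        if f.kind == "ORF"
    }
    site_truth = {}
    for f in features:
        if f.kind == "restriction_site":
            site_truth.setdefault(f.attributes["enzyme"], set()).add(f.interval.start)
    hr_mask = np.zeros(L, dtype=bool)
    for f in features:
        if f.kind == "hr":
            for p in f.interval.positions(L):
                hr_mask[p] = True

    def try_edit(p: int, forbidden: set[str], allow_repeat: bool = False) -> bool:
        cur = seq[p]
        for b in rng.permutation(list("ACGT")):
            if b == cur or b in forbidden:
                continue
            if guard.ok(seq, p, b, allow_repeat=allow_repeat):
                _apply_edit(seq, p, b, guard, L)
                return True
        return False

    enzymes_used = sorted(cfg.restriction_sites_planted)
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}

    for _round in range(60):
        dirty = False
        s = "".join(seq)
        genome = CircularGenome(id="scrub", sequence=s)

        # 1. chance ORFs at or above the calling threshold
        for orf in find_orfs(genome, min_aa=cfg.min_orf_aa):
            key = (orf.interval.start, orf.interval.span, orf.interval.strand)
            if key in truth_orf_keys:
                continue
            dirty = True
            if not _break_orf(seq, orf, guard, rng, L):
                raise RuntimeError(
                    f"cannot scrub chance ORF at {orf.interval.start} without touching truth"
                )

        # 2. chance restriction-site occurrences
        s = "".join(seq)
        ext = s + s[:8]
        for enzyme in enzymes_used:
            site = ENZYMES[enzyme][0]
            truth_pos = site_truth.get(enzyme, set())
            start = 0
            while True:
                hit = ext.find(site, start)
                if hit == -1 or hit >= L:
                    break
                start = hit + 1
                if hit % L in truth_pos:
                    continue
                dirty = True
                fixed = False
                for allow_repeat in (False, True):
                    for k in rng.permutation(len(site)):
                        if try_edit((hit + int(k)) % L, forbidden=set(), allow_repeat=allow_repeat):
                            fixed = True
                            break
                    if fixed:
                        break
                if not fixed:
                    raise RuntimeError(f"cannot scrub chance {enzyme} site at {hit}")

        # 3. chance palindromic windows away from planted hrs
        arr = _str_to_arr("".join(seq))
        if cfg.unit_length <= L:
            scores = _palindrome_scores(arr, cfg.unit_length)
            for w in np.nonzero(scores >= cfg.palindrome_scrub_score)[0]:
                window_pos = [(int(w) + k) % L for k in range(cfg.unit_length)]
                if any(hr_mask[p] for p in window_pos):
                    continue
                dirty = True
                fixed = False
                for k in rng.permutation(cfg.unit_length):
                    p = window_pos[int(k)]
                    partner = window_pos[cfg.unit_length - 1 - int(k)]
                    # break this pairing: any base that no longer complements
                    cur_partner = seq[partner]
                    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}[cur_partner]
                    if seq[p] != comp:
                        continue  # not a matched position; editing won't help much
                    if try_edit(p, forbidden={comp}):
                        fixed = True
                        break
                if not fixed:
                    # fall back: any edit inside the window
                    for k in rng.permutation(cfg.unit_length):
                        if try_edit(window_pos[int(k)], forbidden=set()):
                            fixed = True
                            break
                if not fixed:
                    raise RuntimeError(f"cannot scrub chance palindrome at {w}")

        if not dirty:
            break
    else:
        raise RuntimeError("background scrubbing did not converge")
    return "".join(seq)


def _apply_edit(seq: list, p: int, b: str, guard: _EditGuard, L: int) -> None:
    seq[p] = b
    ri = guard.repeat_at[p]
    if ri >= 0:  # keep the unit's truth sequence in sync
        unit = guard.repeat_units[ri]
        off = (p - unit.interval.start) % L
        us = unit.attributes["unit_seq"]
        unit.attributes["unit_seq"] = us[:off] + b + us[off + 1 :]


def _break_orf(seq: list, orf, guard: _EditGuard, rng: np.random.Generator, L: int) -> bool:
    iv = orf.interval
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # positions of the start codon on the genome
    start_positions = []
    for k in range(3):
        plus_off = k if iv.strand == "+" else iv.span - 1 - k
        start_positions.append((iv.start + plus_off) % L)
    for allow_repeat in (False, True):
        for k in rng.permutation(3):
            p = start_positions[int(k)]
            cur = seq[p]
            for b in rng.permutation(list("ACGT")):
                if b == cur:
                    continue
                if not guard.ok(seq, p, b, allow_repeat=allow_repeat):
                    continue
                # must actually destroy the ATG
                codon = ""
                for gp in start_positions:
                    c = b if gp == p else seq[gp]
                    codon += c if iv.strand == "+" else comp[c]
                if codon == "ATG":
                    continue
                _apply_edit(seq, p, b, guard, L)
                return True
        # otherwise create an early in-frame stop
        n_codons = iv.span // 3
        for ci in range(1, n_codons - 1):
            positions = []
            for k in range(3):
                plus_off = ci * 3 + k if iv.strand == "+" else iv.span - 1 - (ci * 3 + k)
                positions.append((iv.start + plus_off) % L)
            current = "".join(
                seq[p] if iv.strand == "+" else comp[seq[p]] for p in positions
            )
            for stop in ("TAA", "TAG", "TGA"):
                diffs = [k for k in range(3) if current[k] != stop[k]]
                if len(diffs) != 1:
                    continue
                k = diffs[0]
                p = positions[k]
                b = stop[k] if iv.strand == "+" else comp[stop[k]]
                if guard.ok(seq, p, b, allow_repeat=allow_repeat):
                    _apply_edit(seq, p, b, guard, L)
                    return True
    return False


# ---------------------------------------------------------------------------
# derived (rearranged + diverged) genomes


def derive_rearranged_genome(
    genome: CircularGenome,
    truth: TruthTable,
    ops: list[RearrangementOp],
    divergence_rate: float = 0.0,
    seed: int = 0,
) -> tuple[CircularGenome, TruthTable]:
    """Apply rearrangements left-to-right, then per-base divergence.

    Inversions reverse-complement a segment in place; translocations excise
    and reinsert; loss deletes a truth ORF; gain inserts a novel ORF.  No op
    segment may bisect a planted feature (raises ValueError).  Substitutions
    during the divergence step avoid planted promoter-motif footprints and
    never break a planted ORF (start/stop codons kept, no internal stop
    created), so truth features remain recoverable by annotation.
    """
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    feats = [
        FeatureRecord(
            interval=f.interval,
            kind=f.kind,
            label=f.label,
            attributes=dict(
                f.attributes,
                source_start=f.interval.start,
                source_span=f.interval.span,
                source_strand=f.interval.strand,
            ),
        )
        for f in truth.features
    ]
    applied = []
    for op in ops:
        seq, feats = _apply_op(seq, feats, op, rng, truth.config)
        applied.append(op)

    if divergence_rate > 0:
        cfg = truth.config or SimConfig(genome_length=len(seq), n_orfs=0, n_hrs=0)
        # the in-frame stop immediately 5' of each planted ATG keeps the
        # planted start maximal; it must survive divergence
        guards = []
        L = len(seq)
        for f in feats:
            if f.kind != "ORF":
                continue
            iv = f.interval
            if iv.strand == "+":
                guards.append(((iv.start - 3) % L, 3))
            else:
                guards.append(((iv.start + iv.span) % L, 3))
        seq = _diverge(seq, feats, divergence_rate, rng, cfg, guards)

    derived = CircularGenome(id=genome.id + "_derived", sequence=seq)
    # refresh ORF proteins: divergence changes the encoded sequence
    from .genome_core import extract, translate

    for f in feats:
        if f.kind == "ORF":
            f.attributes["source_protein"] = f.attributes.get("protein")
            f.attributes["protein"] = translate(extract(derived, f.interval))
    out = TruthTable(features=feats, derivation_ops=applied, config=truth.config)
    return derived, out


def _segments_disjoint(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[1] <= b[0] or b[1] <= a[0]


def _check_no_bisection(feats, start: int, end: int, L: int):
    for f in feats:
        iv = f.interval
        f_start, f_end = iv.start, iv.start + iv.span
        if f_end > L:
            raise ValueError("rearrangement ops require non-wrapping truth features")
        inside = f_start >= start and f_end <= end
        outside = f_end <= start or f_start >= end
        if not (inside or outside):
            raise ValueError(
                f"op segment [{start},{end}) bisects planted feature {f.label!r}"
            )


def _apply_op(seq: str, feats, op: RearrangementOp, rng, cfg):
    L = len(seq)
    if op.kind == "inversion":
        s, e = op.start, op.start + op.span
        if not (0 <= s < e <= L):
            raise ValueError("inversion segment out of range")
        _check_no_bisection(feats, s, e, L)
        seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
        for f in feats:
            iv = f.interval
            if s <= iv.start and iv.start + iv.span <= e:
                new_start = s + (e - (iv.start + iv.span))
                new_strand = "-" if iv.strand == "+" else "+"
                f.interval = GenomicInterval(new_start, iv.span, new_strand)
                f.attributes["inverted"] = True
        return seq, feats
    if op.kind == "translocation":
        s, e = op.start, op.start + op.span
        if not (0 <= s < e <= L):
            raise ValueError("translocation segment out of range")
        _check_no_bisection(feats, s, e, L)
        segment = seq[s:e]
        remainder = seq[:s] + seq[e:]
        d = op.dest
        if d is None or not (0 <= d <= len(remainder)):
            raise ValueError("translocation dest out of range")
        _check_no_bisection(
            [f for f in feats if f.interval.start + f.interval.span <= s or f.interval.start >= e],
            d if d < s else d + (e - s),
            d if d < s else d + (e - s),
            L,
        )
        seq = remainder[:d] + segment + remainder[d:]

        def remap(pos: int) -> int:
            if s <= pos < e:  # inside moved segment
                return d + (pos - s)
            p = pos if pos < s else pos - (e - s)  # post-excision coordinate
            return p if p < d else p + (e - s)

        for f in feats:
            iv = f.interval
            f.interval = GenomicInterval(remap(iv.start), iv.span, iv.strand)
        return seq, feats
    if op.kind == "loss":
        target = next((f for f in feats if f.label == op.label and f.kind == "ORF"), None)
        if target is None:
            raise ValueError(f"loss target {op.label!r} not found")
        s, e = target.interval.start, target.interval.start + target.interval.span
        _check_no_bisection(feats, s, e, L)
        seq = seq[:s] + seq[e:]
        new_feats = []
        for f in feats:
            if f is target:
                continue
            iv = f.interval
            if iv.start >= e:
                f.interval = GenomicInterval(iv.start - (e - s), iv.span, iv.strand)
            elif iv.start >= s:
                raise ValueError("loss segment overlaps another feature")
            new_feats.append(f)
        return seq, new_feats
    if op.kind == "gain":
        length = op.length or 300
        orf_seq = _random_orf_seq(rng, length)
        insert = "TAA" + orf_seq
        d = op.start if op.start is not None else 0
        if not (0 <= d <= L):
            raise ValueError("gain position out of range")
        _check_no_bisection(feats, d, d, L)
        for f in feats:
            iv = f.interval
            if iv.start + iv.span > d and not (iv.start >= d):
                raise ValueError("gain position falls inside a planted feature")
        seq = seq[:d] + insert + seq[d:]
        shift = len(insert)
        for f in feats:
            iv = f.interval
            if iv.start >= d:
                f.interval = GenomicInterval(iv.start + shift, iv.span, iv.strand)
        from .genome_core import translate

        n_gained = sum(1 for f in feats if f.attributes.get("novel"))
        feats.append(
            FeatureRecord(
                interval=GenomicInterval(d + 3, length, "+"),
                kind="ORF",
                label=f"gained{n_gained + 1:03d}",
                attributes={"protein": translate(orf_seq), "novel": True},
            )
        )
        return seq, feats
    raise ValueError(f"unknown op kind {op.kind!r}")


def _diverge(seq: str, feats, rate: float, rng, cfg: SimConfig, guards) -> str:
    """Per-base substitution that preserves motif/primer footprints and keeps
    planted ORFs translatable (frames tracked after rearrangement)."""
    L = len(seq)
    # repeat units stay editable (hr divergence is part of the model); motifs
    # and primer sites are hard-protected; ORFs get codon-aware edits.
    pseudo = [
        FeatureRecord(interval=f.interval, kind="motif" if f.kind == "primer_site" else f.kind,
                      label=f.label, attributes=f.attributes)
        for f in feats
        if f.kind in ("ORF", "motif", "primer_site")
    ]
    guard = _EditGuard(L, cfg, pseudo, guards)
    out = list(seq)
    positions = np.nonzero(rng.random(L) < rate)[0]
    for p in positions:
        p = int(p)
        cur = out[p]
        for b in rng.permutation(list("ACGT")):
            if b == cur:
                continue
            if guard.ok(out, p, b):
                out[p] = b
                break
    return "".join(out)


# ---------------------------------------------------------------------------
# file export


def write_outputs(outdir, genome: CircularGenome, truth: TruthTable) -> None:
    """Emit FASTA + GFF3 truth + a YAML sidecar of the config and derivation ops."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_fasta(os.path.join(outdir, f"{genome.id}.fasta"), [genome])
    write_gff3(os.path.join(outdir, f"{genome.id}.gff3"), genome, truth.features)
    def _plain(obj):
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_plain(v) for v in obj]
        return obj

    sidecar = {
        "config": _plain(asdict(truth.config)) if truth.config else None,
        "derivation_ops": [_plain(asdict(op)) for op in truth.derivation_ops],
    }
    with open(os.path.join(outdir, f"{genome.id}.yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)
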