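"""Sequence primitives, circular-coordinate arithmetic, and standard-format I/O.

Coordinates are 0-based with an explicit span (never an end), so features that
wrap through the origin of a circular genome are unambiguous: a feature with
``start + span > length`` simply continues past the origin.  Conversion to the
1-based inclusive conventions of GFF3/GenBank happens only at I/O boundaries.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Watson-Crick pairing used by the palindrome scanner; N pairs with nothing.
PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_CODON_TABLE = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()

STOP_CODONS = frozenset(c for c, a in _CODON_TABLE.items() if a == "*")


class AlphabetError(ValueError):
    """A sequence contains a character outside {A,C,G,T,N}."""


class TopologyError(ValueError):
    """An origin-wrapping operation was requested on a linear genome."""


class TranslationError(ValueError):
    """A coding sequence cannot be translated (internal stop or bad length)."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


def _check_alphabet(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in DNA_ALPHABET:
            raise AlphabetError(f"invalid character {ch!r} at position {i}")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, start+span) on a genome; may wrap the origin.

    ``strand`` is "+" or "-"; the span is measured along the genome regardless
    of strand.
    """

    start: int
    span: int
    strand: str = "+"

    def __post_init__(self):
        if self.span < 1:
            raise ValueError("span must be >= 1")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")

    def end(self, genome_length: int) -> int:
        """Exclusive end position modulo genome length."""
        return (self.start + self.span) % genome_length

    def wraps(self, genome_length: int) -> bool:
        return self.start + self.span > genome_length

    def positions(self, genome_length: int) -> Iterable[int]:
        for k in range(self.span):
            yield (self.start + k) % genome_length


@dataclass(frozen=True)
class CircularGenome:
    """A DNA sequence with explicit topology (circular by default)."""

    id: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty genome")
        if self.topology not in ("circular", "linear"):
            raise ValueError("topology must be 'circular' or 'linear'")
        seq = self.sequence.upper()
        _check_alphabet(seq)
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass
class FeatureRecord:
    """A located, labelled annotation on one genome."""

    interval: GenomicInterval
    kind: str  # ORF, hr, repeat_unit, primer_site, restriction_site, motif
    label: str
    attributes: dict = field(default_factory=dict)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def extract(genome: CircularGenome, iv: GenomicInterval) -> str:
    """Bases covered by ``iv``, wrap-aware; minus strand returns the revcomp."""
    L = genome.length
    if not 0 <= iv.start < L:
        raise ValueError(f"start {iv.start} outside genome of length {L}")
    if iv.span > L:
        raise ValueError(f"span {iv.span} exceeds genome length {L}")
    if iv.start + iv.span > L:
        if not genome.is_circular:
            raise TopologyError("interval wraps the origin of a linear genome")
        seq = genome.sequence[iv.start:] + genome.sequence[: (iv.start + iv.span) - L]
    else:
        seq = genome.sequence[iv.start : iv.start + iv.span]
    if iv.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate(cds: str) -> str:
    """Standard-code translation; trailing stop dropped, internal stop rejected."""
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    _check_alphabet(cds)
    protein = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        aa = _CODON_TABLE.get(codon)
        if aa is None:  # codon containing N
            aa = "X"
        if aa == "*":
            if i < n_codons - 1:
                raise TranslationError(f"internal stop codon at codon {i}")
            break
        protein.append(aa)
    return "".join(protein)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[CircularGenome]:
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        genomes.append(CircularGenome(id=rec.id, sequence=str(rec.seq).upper()))
    if not genomes:
        raise ParseError(f"no FASTA records in {path}")
    return genomes


def write_fasta(path, genomes: Iterable[CircularGenome], width: int = 60) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


def read_protein_fasta(path) -> dict[str, str]:
    """name -> amino-acid sequence (order-preserving dict)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


def write_protein_fasta(path, proteins: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in proteins.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank (read-only)


def read_genbank_features(path) -> tuple[CircularGenome, list[FeatureRecord]]:
    """Parse a GenBank flat file into a genome plus its CDS features as ORFs.

    Origin-spanning CDS (join locations crossing the end of a circular record)
    become a single wrap-aware FeatureRecord.
    """
    rec = SeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "linear")
    genome = CircularGenome(
        id=rec.id, sequence=str(rec.seq).upper(), topology="circular" if topology == "circular" else "linear"
    )
    L = genome.length
    feats = []
    idx = 0
    for f in rec.features:
        if f.type != "CDS":
            continue
        idx += 1
        strand = "-" if f.location.strand == -1 else "+"
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        start = int(parts[0].start)
        end = int(parts[-1].end)
        if len(parts) == 2 and int(parts[-1].end) == L and int(parts[0].start) == 0:
            # origin-spanning join: (a..L, 1..b)
            start = int(parts[1].start) if int(parts[1].end) == L else int(parts[0].start)
            # the part ending at L is the upstream half on the plus strand
            upstream = next(p for p in parts if int(p.end) == L)
            downstream = next(p for p in parts if int(p.start) == 0)
            start = int(upstream.start)
            span = (L - start) + int(downstream.end)
        else:
            span = end - start
        quals = {k: v[0] if isinstance(v, list) and v else v for k, v in f.qualifiers.items()}
        label = quals.get("locus_tag") or quals.get("gene") or f"CDS{idx:03d}"
        feats.append(
            FeatureRecord(
                interval=GenomicInterval(start=start % L, span=span, strand=strand),
                kind="ORF",
                label=str(label),
                attributes=quals,
            )
        )
    return genome, feats


# ---------------------------------------------------------------------------
# GFF3


_GFF_KIND_TO_SO = {
    "ORF": "CDS",
    "hr": "repeat_region",
    "repeat_unit": "repeat_unit",
    "primer_site": "primer_binding_site",
    "restriction_site": "restriction_enzyme_recognition_site",
    "motif": "sequence_motif",
}
_SO_TO_KIND = {v: k for k, v in _GFF_KIND_TO_SO.items()}


def _esc(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _unesc(value: str) -> str:
    return value.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")


def write_gff3(path, genome: CircularGenome, features: Iterable[FeatureRecord], source: str = "baculokit") -> None:
    """Emit 1-based inclusive GFF3; wrap features split into two parts sharing an ID."""
    L = genome.length
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {L}\n")
        circ = "true" if genome.is_circular else "false"
        fh.write(f"# topology=circular\n" if genome.is_circular else "# topology=linear\n")
        del circ
        for feat in features:
            iv = feat.interval
            so_type = _GFF_KIND_TO_SO.get(feat.kind, feat.kind)
            attrs = [f"ID={_esc(feat.label)}", f"baculokit_kind={_esc(feat.kind)}"]
            for k, v in feat.attributes.items():
                attrs.append(f"{_esc(k)}={_esc(v)}")
            attr_s = ";".join(attrs)
            if iv.wraps(L):
                # part 1: start..L ; part 2: 1..remainder — same ID joins them
                fh.write(
                    f"{genome.id}\t{source}\t{so_type}\t{iv.start + 1}\t{L}\t.\t{iv.strand}\t.\t{attr_s}\n"
                )
                rest = iv.start + iv.span - L
                fh.write(f"{genome.id}\t{source}\t{so_type}\t1\t{rest}\t.\t{iv.strand}\t.\t{attr_s}\n")
            else:
                fh.write(
                    f"{genome.id}\t{source}\t{so_type}\t{iv.start + 1}\t{iv.start + iv.span}\t.\t{iv.strand}\t.\t{attr_s}\n"
                )


def read_gff3(path, genome_length: int | None = None) -> list[FeatureRecord]:
    """Read features written by :func:`write_gff3`, rejoining wrap parts by ID."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 GFF3 columns, got {len(cols)}", line=lineno)
            try:
                start1, end1 = int(cols[3]), int(cols[4])
            except ValueError:
                raise ParseError("non-integer coordinate", line=lineno) from None
            attrs: dict[str, str] = {}
            for item in cols[8].split(";"):
                if not item:
                    continue
                if "=" not in item:
                    raise ParseError(f"malformed attribute {item!r}", line=lineno)
                k, v = item.split("=", 1)
                attrs[_unesc(k)] = _unesc(v)
            rows.append((cols[2], start1, end1, cols[6], attrs))
    # rejoin split wrap features by shared ID
    features: list[FeatureRecord] = []
    by_id: dict[str, list] = {}
    order: list[str] = []
    for so_type, start1, end1, strand, attrs in rows:
        fid = attrs.get("ID", f"_anon{len(order)}")
        if fid not in by_id:
            by_id[fid] = []
            order.append(fid)
        by_id[fid].append((so_type, start1, end1, strand, attrs))
    for fid in order:
        parts = by_id[fid]
        so_type, start1, end1, strand, attrs = parts[0]
        kind = attrs.pop("baculokit_kind", None) or _SO_TO_KIND.get(so_type, so_type)
        attrs.pop("ID", None)
        if len(parts) == 1:
            iv = GenomicInterval(start=start1 - 1, span=end1 - start1 + 1, strand=strand)
        elif len(parts) == 2:
            (_, s1, e1, _, _), (_, s2, e2, _, a2) = parts
            a2.pop("baculokit_kind", None)
            a2.pop("ID", None)
            if genome_length is None:
                genome_length = e1  # first part must run to the genome end
            span = (e1 - s1 + 1) + (e2 - s2 + 1)
            iv = GenomicInterval(start=s1 - 1, span=span, strand=strand)
        else:
            raise ParseError(f"feature {fid!r} has {len(parts)} parts; at most 2 supported")
        features.append(FeatureRecord(interval=iv, kind=kind, label=fid, attributes=attrs))
    return features


# ---------------------------------------------------------------------------
# Newick


def write_newick(path, tree) -> None:
    """Write any object exposing ``to_newick()`` (a phylogeny TreeNode)."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest arc distance between two positions on a circle of given length."""
    d = abs(a - b) % length
    return min(d, length - d)
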