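"""Readers and writers for the plain-text formats the toolkit speaks.

FASTA and FASTQ go through Bio.SeqIO; SAM parsing goes through pysam
(which also reconstructs per-base mismatches from the MD tag); SAM
*writing* is a small deterministic text emitter so that reruns are
byte-identical and diff-able.  BED SNP loci and the BED12 transcript
map are parsed by hand (whitespace-separated columns).

Coordinate conventions: everything internal is 0-based half-open;
SAM (1-based inclusive) and BED (0-based half-open) are converted at
the I/O boundary.  Simulation truth is carried redundantly in the
read name and in a TSV sidecar so that tools which mangle read names
can still be benchmarked.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
MAX_PHRED = 41

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed input files; the message names the offending record/line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ReadRecord:
    """A single sequencing read: name, bases and per-base Phred scores."""

    name: str
    sequence: str
    qualities: list[int]

    def __post_init__(self):
        if not self.name or any(c.isspace() for c in self.name):
            raise FormatError(f"invalid read name {self.name!r}")
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.name}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}")
        if not set(self.sequence) <= DNA_ALPHABET:
            bad = sorted(set(self.sequence) - DNA_ALPHABET)
            raise FormatError(f"read {self.name}: characters {bad} not in A/C/G/T/N")
        if any(q < 0 or q > MAX_PHRED for q in self.qualities):
            raise FormatError(f"read {self.name}: Phred scores must lie in [0, {MAX_PHRED}]")


@dataclass
class SamRecord:
    """One SAM alignment line (minimal dialect: CIGAR M/I/D, NM/MD tags)."""

    read_name: str
    flag: int
    ref_name: str
    pos: int                      # 1-based leftmost; 0 for unmapped
    mapq: int
    cigar: str
    sequence: str
    qualities: list[int]
    tags: dict[str, object] = field(default_factory=dict)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    def cigar_ops(self) -> list[tuple[str, int]]:
        ops, n = [], ""
        for c in self.cigar:
            if c.isdigit():
                n += c
            else:
                ops.append((c, int(n)))
                n = ""
        return ops

    def reference_span(self) -> tuple[int, int]:
        """0-based half-open genomic interval covered by reference-consuming ops."""
        start = self.pos - 1
        ref_len = sum(n for op, n in self.cigar_ops() if op in "MDN")
        return start, start + ref_len

    def aligned_pairs(self) -> list[tuple[int, int, str, str]]:
        """(read_offset, ref_pos_0based, read_base, ref_base) for every M column.

        The reference base is reconstructed from the MD tag; read offsets are
        given in SEQ orientation (as stored).  Requires the MD tag.
        """
        if "MD" not in self.tags:
            raise FormatError(
                f"record {self.read_name} lacks an MD tag; per-base mismatch "
                "reconstruction needs MD (realign or add MD tags)")
        md = str(self.tags["MD"])
        # walk CIGAR and MD together
        ref_bases_md = _md_reference_bases(md)
        pairs: list[tuple[int, int, str, str]] = []
        qpos, rpos, mdi = 0, self.pos - 1, 0
        for op, n in self.cigar_ops():
            if op == "M":
                for _ in range(n):
                    rb = ref_bases_md[mdi]
                    rb = self.sequence[qpos] if rb is None else rb
                    pairs.append((qpos, rpos, self.sequence[qpos], rb))
                    qpos += 1
                    rpos += 1
                    mdi += 1
            elif op == "I":
                qpos += n
            elif op in ("D", "N"):
                rpos += n
                if op == "D":
                    mdi += n
            elif op == "S":
                qpos += n
            else:
                raise FormatError(f"unsupported CIGAR op {op!r} in {self.read_name}")
        return pairs


def _md_reference_bases(md: str) -> list[object]:
    """Expand an MD tag into one entry per reference-consuming column of the
    alignment: None where read == reference, the reference base at mismatches
    and deleted positions."""
    out: list[object] = []
    i = 0
    while i < len(md):
        if md[i].isdigit():
            j = i
            while j < len(md) and md[j].isdigit():
                j += 1
            out.extend([None] * int(md[i:j]))
            i = j
        elif md[i] == "^":
            i += 1
            while i < len(md) and md[i].isalpha():
                out.append(md[i])
                i += 1
        else:
            out.append(md[i])
            i += 1
    return out


@dataclass(frozen=True)
class TruthRecord:
    """True origin of one simulated read, for benchmarking."""

    read_name: str
    ref_name: str
    strand: str                   # '+' or '-'
    start: int                    # 1-based
    cluster_id: int
    is_binding_site: bool
    n_tc_conversions: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be +/-, got {self.strand!r}")
        if self.start < 1:
            raise ValueError("start must be >= 1")


@dataclass(frozen=True)
class SnpLoci:
    """Known SNP positions as a set of (ref_name, 1-based position) pairs."""

    loci: frozenset[tuple[str, int]]

    def __contains__(self, item: tuple[str, int]) -> bool:
        return item in self.loci

    def __len__(self) -> int:
        return len(self.loci)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, uppercased sequence) pairs.

    Rejects empty sequences and characters outside {A,C,G,T,N}.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r}: empty sequence")
        if not set(seq) <= DNA_ALPHABET:
            bad = sorted(set(seq) - DNA_ALPHABET)
            raise FormatError(f"FASTA record {rec.id!r}: characters {bad} not in A/C/G/T/N")
        out.append((rec.id, seq))
    if not out and os.path.getsize(path) > 0:
        raise FormatError(f"{path}: no FASTA records parsed (malformed header?)")
    return out


def write_fasta(records: list[tuple[str, str]], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)
# ---------------------------------------------------------------------------

def read_fastq(path: str | os.PathLike) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), list(quals)))
    return out


def write_fastq(records: list[ReadRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# truth sidecar + read-name codec
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "read_name\tref\tstrand\tstart\tcluster_id\tis_binding\tn_tc"
_NAME_SEP = "|"


def encode_truth_name(t: TruthRecord) -> str:
    """Pack all truth fields into a read name (no whitespace, no '/')."""
    fields = (t.read_name, t.ref_name, t.strand, str(t.start),
              str(t.cluster_id), "1" if t.is_binding_site else "0",
              str(t.n_tc_conversions))
    for f in fields:
        if any(c.isspace() for c in f) or "/" in f or _NAME_SEP in f:
            raise FormatError(f"truth field {f!r} contains a reserved character")
    return _NAME_SEP.join(fields)


def decode_truth_name(name: str) -> TruthRecord:
    parts = name.split(_NAME_SEP)
    if len(parts) != 7:
        raise FormatError(f"read name {name!r} does not encode a truth record")
    rn, ref, strand, start, cid, binding, ntc = parts
    try:
        return TruthRecord(rn, ref, strand, int(start), int(cid),
                           binding == "1", int(ntc))
    except ValueError as e:
        raise FormatError(f"read name {name!r}: {e}") from e


def write_truth_table(records: list[TruthRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for t in records:
            fh.write(f"{t.read_name}\t{t.ref_name}\t{t.strand}\t{t.start}\t"
                     f"{t.cluster_id}\t{int(t.is_binding_site)}\t{t.n_tc_conversions}\n")


def read_truth_table(path: str | os.PathLike) -> dict[str, TruthRecord]:
    out: dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TRUTH_HEADER:
            raise FormatError(f"{path}: unexpected truth-table header {header!r}")
        for ln, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise FormatError(f"{path}:{ln}: expected 7 columns")
            t = TruthRecord(parts[0], parts[1], parts[2], int(parts[3]),
                            int(parts[4]), parts[5] == "1", int(parts[6]))
            out[t.read_name] = t
    return out


# ---------------------------------------------------------------------------
# SAM dialect
# ---------------------------------------------------------------------------

def write_sam(records: list[SamRecord], header_refs: list[tuple[str, int]],
              path: str | os.PathLike) -> None:
    """Write SAM text with an @SQ line per reference.  Deterministic output."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in header_refs:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in records:
            _check_cigar(r)
            qual = "".join(chr(q + 33) for q in r.qualities) if r.qualities else "*"
            cols = [r.read_name, str(r.flag),
                    r.ref_name if not r.is_unmapped else "*",
                    str(r.pos if not r.is_unmapped else 0),
                    str(r.mapq), r.cigar if not r.is_unmapped else "*",
                    "*", "0", "0", r.sequence or "*", qual]
            for k, v in sorted(r.tags.items()):
                tp = "i" if isinstance(v, int) else "f" if isinstance(v, float) else "Z"
                cols.append(f"{k}:{tp}:{v}")
            fh.write("\t".join(cols) + "\n")


def _check_cigar(r: SamRecord) -> None:
    if r.is_unmapped:
        return
    read_len = sum(n for op, n in r.cigar_ops() if op in "MIS")
    if read_len != len(r.sequence):
        raise FormatError(
            f"record {r.read_name}: CIGAR {r.cigar} consumes {read_len} read "
            f"bases but SEQ has {len(r.sequence)}")


def parse_sam(path: str | os.PathLike) -> tuple[list[SamRecord], list[tuple[str, int]]]:
    """Parse SAM text via pysam.  Returns (records, [(ref_name, length), ...])."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        refs = [(name, length) for name, length in zip(af.references, af.lengths)]
        records = []
        for aln in af:
            tags = dict(aln.get_tags())
            qual = list(aln.query_qualities) if aln.query_qualities is not None else []
            rec = SamRecord(
                read_name=aln.query_name,
                flag=aln.flag,
                ref_name=aln.reference_name if not aln.is_unmapped else "*",
                pos=(aln.reference_start + 1) if not aln.is_unmapped else 0,
                mapq=aln.mapping_quality,
                cigar=aln.cigarstring or "*",
                sequence=aln.query_sequence or "",
                qualities=qual,
                tags=tags,
            )
            if not rec.is_unmapped:
                _check_cigar(rec)
            records.append(rec)
    return records, refs


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_snp_bed(path: str | os.PathLike) -> SnpLoci:
    """Read a BED3 file of SNP loci.

    BED is 0-based half-open; every covered position is converted to the
    internal 1-based (ref, position) representation.
    """
    loci = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: BED3 needs 3 columns")
            ref, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end <= start:
                raise FormatError(f"{path}:{ln}: bad interval [{start},{end})")
            for p in range(start, end):
                loci.add((ref, p + 1))
    return SnpLoci(frozenset(loci))


@dataclass(frozen=True)
class TranscriptMap:
    """Exon structure of one transcript on the genome (BED12 semantics)."""

    name: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]   # 0-based half-open genome intervals, ascending

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


def read_bed12(path: str | os.PathLike) -> dict[str, TranscriptMap]:
    out: dict[str, TranscriptMap] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 12:
                raise FormatError(f"{path}:{ln}: BED12 needs 12 columns")
            chrom, chrom_start, name, strand = parts[0], int(parts[1]), parts[3], parts[5]
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != len(starts) or len(sizes) != int(parts[9]):
                raise FormatError(f"{path}:{ln}: block columns inconsistent")
            blocks = tuple((chrom_start + st, chrom_start + st + sz)
                           for st, sz in zip(starts, sizes))
            out[name] = TranscriptMap(name, chrom, strand, blocks)
    return out
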