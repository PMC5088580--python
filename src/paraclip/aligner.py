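"""Error-profile-aware FM-index read alignment.

The search walks the reference's prefix trie (equivalently: FM-index
backward search, last read base first).  Every trie extension multiplies a
running probability::

    p_i = p_{i+1} * D                     if a reference base is deleted
    p_i = p_{i+1} * I                     if read[i] is inserted
    p_i = p_{i+1} * M(ref[j], read[i])    otherwise

with p_|read| = 1.  A read placement is accepted when the full-read
probability reaches the closed-form threshold::

    T = avg(match)^(|read|-X) * avg(mismatch)^X

where X is the (real-valued) expected number of mismatches and the two
averages summarise the profile (four diagonal entries plus the no-indel
probability; twelve off-diagonal entries plus I and D).  Because T budgets
*average* mismatches, frequent error types — the T->C conversion in
PAR-CLIP data — are much cheaper than rare ones, and a read may carry more
than X of them and still be accepted.

Partial paths are pruned as soon as even the best possible extension of the
remaining read prefix cannot reach T (the per-base optimistic factor is
max(diag(M), 1-(I+D)), an upper bound on every recursion factor, so no
accepted placement is ever missed).  A classic counted-mismatch backward
search (`align_baseline`) is provided as the BWA-style comparator.

Comparison counting: one comparison per evaluation of a read base against
an existing trie branch (a non-empty backward extension), including
branches that subsequently fail; indel extensions and sentinel branches are
never counted.  All probabilities are computed in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .error_model import ErrorProfile
from .fmindex import FmIndex, encode_bases
from .formats_io import ReadRecord, SamRecord, TranscriptMap, revcomp

BASES = "ACGT"
_LOG_EPS = 1e-9          # slack when comparing log-probabilities against log T
MIN_READ_LENGTH = 5


class ReadTooShortError(ValueError):
    pass


# ---------------------------------------------------------------------------
# threshold arithmetic
# ---------------------------------------------------------------------------

def avg_rates(profile: ErrorProfile) -> tuple[float, float]:
    """(avg_match, avg_mismatch): the profile summarised as one average
    probability of a matching event (four diagonal entries plus the
    probability 1-(I+D) of no indel) and one of a mismatching event
    (twelve off-diagonal entries plus I and D)."""
    M, I, D = profile.M, profile.I, profile.D
    avg_match = (float(np.trace(M)) + (1.0 - (I + D))) / 5.0
    avg_mismatch = (float(M.sum() - np.trace(M)) + I + D) / 14.0
    return avg_match, avg_mismatch


def estimate_X(profile: ErrorProfile, read_length: int) -> float:
    """Expected number of mismatches for a read of this length under the
    profile, assuming uniform reference base composition; floored at 1."""
    if read_length < 1:
        raise ValueError("read_length must be >= 1")
    M = profile.M
    mbar = float(M.sum() - np.trace(M)) / 4.0 + profile.I + profile.D
    return max(1.0, read_length * mbar)


def threshold(profile: ErrorProfile, read_length: int, X: float) -> float:
    """Closed-form acceptance threshold T = avg_match^(L-X) * avg_mismatch^X."""
    if not 0 <= X <= read_length:
        raise ValueError("X must lie in [0, read_length]")
    avg_match, avg_mismatch = avg_rates(profile)
    if X > 0 and avg_mismatch <= 0:
        return 0.0               # degenerate profile: accept everything
    log_t = (read_length - X) * math.log(avg_match)
    if X > 0:
        log_t += X * math.log(avg_mismatch)
    return math.exp(log_t)


# ---------------------------------------------------------------------------
# search parameters & hits
# ---------------------------------------------------------------------------

@dataclass
class SearchParams:
    """Knobs of the probabilistic search for one read length."""

    profile: ErrorProfile
    X: float | str = 2.0          # expected-mismatch budget, or "auto"
    T: float | None = None        # explicit threshold override
    max_hits: int = 100
    count_comparisons: bool = False
    allow_indels: bool = True
    both_strands: bool = True

    def threshold_for(self, read_length: int) -> float:
        if self.T is not None:
            return self.T
        x = estimate_X(self.profile, read_length) if self.X == "auto" else float(self.X)
        x = min(x, float(read_length))
        return threshold(self.profile, read_length, x)


@dataclass
class AlignmentHit:
    """One accepted read placement."""

    ref_name: str
    strand: str                   # '+' or '-'
    start: int                    # 1-based leftmost reference position
    ops: list[tuple[str, int, int | None, int | None]]
    # ops: ("M"|"I"|"D", read_offset, ref_base_code, read_base_code),
    # left-to-right in SEQ orientation (SEQ = reverse complement on '-')
    log_p: float = 0.0
    n_mismatches: int = 0

    @property
    def p(self) -> float:
        return math.exp(self.log_p)

    @property
    def edits(self) -> list[tuple[int, str, str | None, str | None]]:
        """(read_offset, kind in {sub, ins, del}, ref_base, read_base)."""
        out = []
        for op, roff, rb, qb in self.ops:
            if op == "M" and rb != qb:
                out.append((roff, "sub", BASES[rb], BASES[qb] if qb is not None and qb >= 0 else "N"))
            elif op == "I":
                out.append((roff, "ins", None, BASES[qb] if qb is not None and qb >= 0 else "N"))
            elif op == "D":
                out.append((roff, "del", BASES[rb], None))
        return out

    def cigar(self) -> str:
        runs: list[tuple[str, int]] = []
        for op, *_ in self.ops:
            if runs and runs[-1][0] == op:
                runs[-1] = (op, runs[-1][1] + 1)
            else:
                runs.append((op, 1))
        return "".join(f"{n}{op}" for op, n in runs)

    def md_and_nm(self, sequence: str) -> tuple[str, int]:
        md, run, nm = [], 0, 0
        i = 0
        ops = self.ops
        while i < len(ops):
            op, roff, rb, qb = ops[i]
            if op == "M":
                if rb == qb:
                    run += 1
                else:
                    md.append(str(run))
                    md.append(BASES[rb])
                    run = 0
                    nm += 1
                i += 1
            elif op == "I":
                nm += 1
                i += 1
            else:                 # deletion run
                md.append(str(run))
                run = 0
                md.append("^")
                while i < len(ops) and ops[i][0] == "D":
                    md.append(BASES[ops[i][2]])
                    nm += 1
                    i += 1
        md.append(str(run))
        return "".join(md), nm


def path_log_probability(ops, log_M: np.ndarray, log_I: float, log_D: float,
                         log_n: float) -> float:
    """Canonical (left-to-right) recomputation of log p from an op list."""
    total = 0.0
    for op, _, rb, qb in ops:
        if op == "I":
            total += log_I
        elif op == "D":
            total += log_D
        elif qb is None or qb < 0:
            total += log_n        # read N: smallest entry of M
        else:
            total += log_M[rb, qb]
    return total


# ---------------------------------------------------------------------------
# probabilistic search
# ---------------------------------------------------------------------------

def _search_one_strand(index: FmIndex, read_codes: np.ndarray, profile: ErrorProfile,
                       log_t: float, allow_indels: bool) -> tuple[dict, int]:
    """DFS backward search of one oriented read.  Returns
    ({text_pos: (log_p, ops_right_to_left)}, n_comparisons)."""
    with np.errstate(divide="ignore"):
        log_M = np.log(profile.M)
    log_n = float(log_M.min())
    log_I = math.log(profile.I) if profile.I > 0 else -math.inf
    log_D = math.log(profile.D) if profile.D > 0 else -math.inf
    bound = max(float(profile.M.diagonal().max()), 1.0 - (profile.I + profile.D))
    log_bound = math.log(bound) if bound < 1.0 else 0.0
    L = len(read_codes)
    occ, C = index.occ, index.C
    limit = log_t - _LOG_EPS

    hits: dict[int, tuple[float, tuple]] = {}
    comparisons = 0
    lo0, hi0 = index.full_interval()
    # state: (next read index i, lo, hi, log_p, consecutive indel ops, path link)
    stack = [(L - 1, lo0, hi0, 0.0, 0, None)]
    while stack:
        i, lo, hi, log_p, indel_run, link = stack.pop()
        qb = int(read_codes[i])
        # substitution / match branches
        for b in range(4):
            code = b + 1
            c = C[code]
            nlo, nhi = c + occ[lo, code], c + occ[hi, code]
            if nlo >= nhi:
                continue
            comparisons += 1
            factor = log_n if qb < 0 else float(log_M[b, qb])
            np_log = log_p + factor
            if np_log + i * log_bound < limit:
                continue
            nlink = (link, ("M", i, b, qb))
            if i == 0:
                if np_log >= limit:
                    _record_hits(hits, index, int(nlo), int(nhi), np_log, nlink)
            else:
                stack.append((i - 1, int(nlo), int(nhi), np_log, 0, nlink))
        if allow_indels and indel_run < 2 and 2 <= i <= L - 3:
            # deletion: consume a reference base, keep the read position
            if log_D > -math.inf:
                for b in range(4):
                    code = b + 1
                    c = C[code]
                    nlo, nhi = c + occ[lo, code], c + occ[hi, code]
                    if nlo >= nhi:
                        continue
                    np_log = log_p + log_D
                    if np_log + (i + 1) * log_bound < limit:
                        continue
                    stack.append((i, int(nlo), int(nhi), np_log,
                                  indel_run + 1, (link, ("D", i, b, None))))
            # insertion: consume the read base, keep the interval
            if log_I > -math.inf:
                np_log = log_p + log_I
                if np_log + i * log_bound >= limit:
                    nlink = (link, ("I", i, None, qb))
                    if i == 0:
                        if np_log >= limit:
                            _record_hits(hits, index, lo, hi, np_log, nlink)
                    else:
                        stack.append((i - 1, lo, hi, np_log, indel_run + 1, nlink))
    return hits, comparisons


def _record_hits(hits: dict, index: FmIndex, lo: int, hi: int,
                 log_p: float, link) -> None:
    for tp in index.locate(lo, hi):
        tp = int(tp)
        prev = hits.get(tp)
        if prev is None or log_p > prev[0] + _LOG_EPS:
            hits[tp] = (log_p, link)


def _unwind(link) -> list:
    ops = []
    while link is not None:
        link, op = link
        ops.append(op)
    return ops                    # right-to-left path reversed => left-to-right


def align_read(index: FmIndex, read: ReadRecord | str,
               params: SearchParams) -> tuple[list[AlignmentHit], int]:
    """Probabilistic alignment of one read.

    Returns every distinct placement whose best-path probability reaches the
    threshold, with its maximal p, plus the number of base comparisons
    performed (0 unless ``params.count_comparisons``).
    """
    seq = read.sequence if isinstance(read, ReadRecord) else str(read).upper()
    if len(seq) < MIN_READ_LENGTH:
        raise ReadTooShortError(f"read of length {len(seq)} is too short (< {MIN_READ_LENGTH})")
    log_t_val = params.threshold_for(len(seq))
    log_t = math.log(log_t_val) if log_t_val > 0 else -math.inf

    with np.errstate(divide="ignore"):
        log_M = np.log(params.profile.M)
    log_n = float(log_M.min())
    log_I = math.log(params.profile.I) if params.profile.I > 0 else -math.inf
    log_D = math.log(params.profile.D) if params.profile.D > 0 else -math.inf

    out: list[AlignmentHit] = []
    comparisons = 0
    strands = [("+", seq, params.profile)]
    if params.both_strands:
        strands.append(("-", revcomp(seq), params.profile.complemented()))
    for strand, oriented, prof in strands:
        codes = encode_bases(oriented)
        raw, n_cmp = _search_one_strand(index, codes, prof, log_t, params.allow_indels)
        comparisons += n_cmp
        with np.errstate(divide="ignore"):
            s_log_M = np.log(prof.M)
        s_log_n = float(s_log_M.min())
        for tp, (log_p, link) in raw.items():
            ref_name, pos0 = index.text_to_ref(tp)
            ops = _unwind(link)
            canon = path_log_probability(ops, s_log_M, log_I, log_D, s_log_n)
            out.append(AlignmentHit(ref_name, strand, pos0 + 1, ops, canon,
                                    n_mismatches=sum(1 for op, _, rb, qb in ops
                                                     if op != "M" or rb != qb)))
    ref_order = {name: i for i, name in enumerate(index.ref_names)}
    out.sort(key=lambda h: (-h.log_p, ref_order[h.ref_name], h.start, h.strand != "+"))
    if not params.count_comparisons:
        comparisons = 0
    return out[: params.max_hits], comparisons


# ---------------------------------------------------------------------------
# counted-mismatch baseline
# ---------------------------------------------------------------------------

def align_baseline(index: FmIndex, read: ReadRecord | str, max_mismatches: int,
                   both_strands: bool = False,
                   count_comparisons: bool = True) -> tuple[list[AlignmentHit], int]:
    """Classic backward search allowing at most ``max_mismatches``
    substitutions and no indels (the BWA-style comparator)."""
    seq = read.sequence if isinstance(read, ReadRecord) else str(read).upper()
    if len(seq) < MIN_READ_LENGTH:
        raise ReadTooShortError(f"read of length {len(seq)} is too short (< {MIN_READ_LENGTH})")
    out: list[AlignmentHit] = []
    comparisons = 0
    strands = [("+", seq)]
    if both_strands:
        strands.append(("-", revcomp(seq)))
    occ, C = index.occ, index.C
    for strand, oriented in strands:
        codes = encode_bases(oriented)
        L = len(codes)
        stack = [(L - 1, *index.full_interval(), 0, None)]
        while stack:
            i, lo, hi, n_mm, link = stack.pop()
            qb = int(codes[i])
            for b in range(4):
                code = b + 1
                c = C[code]
                nlo, nhi = c + occ[lo, code], c + occ[hi, code]
                if nlo >= nhi:
                    continue
                comparisons += 1
                mm = n_mm + (0 if b == qb else 1)
                if mm > max_mismatches:
                    continue
                nlink = (link, ("M", i, b, qb))
                if i == 0:
                    for tp in index.locate(int(nlo), int(nhi)):
                        ref_name, pos0 = index.text_to_ref(int(tp))
                        out.append(AlignmentHit(ref_name, strand, pos0 + 1,
                                                _unwind(nlink), 0.0, mm))
                else:
                    stack.append((i - 1, int(nlo), int(nhi), mm, nlink))
    best: dict[tuple, AlignmentHit] = {}
    for h in out:
        key = (h.ref_name, h.start, h.strand)
        if key not in best or h.n_mismatches < best[key].n_mismatches:
            best[key] = h
    ref_order = {name: i for i, name in enumerate(index.ref_names)}
    hits = sorted(best.values(),
                  key=lambda h: (h.n_mismatches, ref_order[h.ref_name], h.start,
                                 h.strand != "+"))
    return hits, (comparisons if count_comparisons else 0)


# ---------------------------------------------------------------------------
# dataset alignment -> SAM
# ---------------------------------------------------------------------------

def _mapq(hits: list[AlignmentHit]) -> int:
    if len(hits) == 1:
        return 60
    total = sum(h.p for h in hits)
    if total <= 0:
        return 0
    frac = hits[0].p / total
    if frac >= 1.0:
        return 60
    return min(60, int(round(-10.0 * math.log10(1.0 - frac))))


def hit_to_sam(read: ReadRecord, hit: AlignmentHit, mapq: int) -> SamRecord:
    seq = read.sequence
    quals = read.qualities
    if hit.strand == "-":
        seq = revcomp(seq)
        quals = quals[::-1]
    md, nm = hit.md_and_nm(seq)
    flag = 0x10 if hit.strand == "-" else 0
    return SamRecord(read.name, flag, hit.ref_name, hit.start, mapq, hit.cigar(),
                     seq, list(quals), tags={"NM": nm, "MD": md})


def unmapped_sam(read: ReadRecord) -> SamRecord:
    return SamRecord(read.name, 0x4, "*", 0, 0, "*", read.sequence,
                     list(read.qualities), tags={})


def align_dataset(index: FmIndex, reads: list[ReadRecord], params: SearchParams,
                  baseline_mm: int | None = None) -> list[SamRecord]:
    """Align a read set; one primary record per read (ties broken by highest
    p, then reference order, leftmost position, forward strand), unmapped
    reads emitted with flag 0x4.  ``baseline_mm`` switches to the
    counted-mismatch baseline instead of the probabilistic search."""
    records: list[SamRecord] = []
    for read in reads:
        if len(read.sequence) < MIN_READ_LENGTH:
            records.append(unmapped_sam(read))
            continue
        if baseline_mm is None:
            hits, _ = align_read(index, read, params)
        else:
            hits, _ = align_baseline(index, read, baseline_mm, both_strands=True,
                                     count_comparisons=False)
        if not hits:
            records.append(unmapped_sam(read))
        else:
            mapq = _mapq(hits) if baseline_mm is None else (60 if len(hits) == 1 else 0)
            records.append(hit_to_sam(read, hits[0], mapq))
    return records


# ---------------------------------------------------------------------------
# multi-reference combination (transcriptome -> genome liftover)
# ---------------------------------------------------------------------------

def _lift_record(rec: SamRecord, tmap: TranscriptMap,
                 genome_seq: str | None) -> SamRecord:
    """Lift a transcript-space alignment to genome coordinates through the
    transcript's exon blocks; junction-spanning reads get N-gapped CIGARs."""
    gpos_of = []
    for s, e in tmap.blocks:
        gpos_of.extend(range(s, e))
    if tmap.strand == "-":
        gpos_of = gpos_of[::-1]
    # expand the alignment into per-column ops in transcript orientation
    cols: list[tuple[str, int | None]] = []
    tpos = rec.pos - 1
    for op, n in rec.cigar_ops():
        for _ in range(n):
            if op == "M":
                cols.append(("M", tpos)); tpos += 1
            elif op == "D":
                cols.append(("D", tpos)); tpos += 1
            elif op == "I":
                cols.append(("I", None))
            else:
                raise ValueError(f"cannot lift CIGAR op {op!r}")
    if tpos > tmap.length:
        raise ValueError(f"alignment of {rec.read_name} overruns transcript {tmap.name}")
    seq, quals, flag = rec.sequence, list(rec.qualities), rec.flag
    if tmap.strand == "-":
        cols = cols[::-1]
        seq = revcomp(seq)
        quals = quals[::-1]
        flag ^= 0x10
    # emit genome CIGAR, inserting N over introns
    runs: list[tuple[str, int]] = []

    def push(op: str, n: int = 1):
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + n)
        else:
            runs.append((op, n))

    prev_g = None
    first_g = None
    for op, t in cols:
        if op == "I":
            push("I")
            continue
        g = gpos_of[t]
        if first_g is None:
            first_g = g
        if prev_g is not None and g - prev_g > 1:
            push("N", g - prev_g - 1)
        push(op)
        prev_g = g
    cigar = "".join(f"{n}{op}" for op, n in runs)
    new = SamRecord(rec.read_name, flag, tmap.chrom, first_g + 1, rec.mapq,
                    cigar, seq, quals, tags=dict(rec.tags))
    new.tags.pop("MD", None)      # transcript-space MD is no longer valid
    if genome_seq is not None:
        md, nm = _md_from_genome(new, genome_seq)
        new.tags["MD"], new.tags["NM"] = md, nm
    return new


def _md_from_genome(rec: SamRecord, genome_seq: str) -> tuple[str, int]:
    md, run, nm = [], 0, 0
    qpos, gpos = 0, rec.pos - 1
    for op, n in rec.cigar_ops():
        if op == "M":
            for _ in range(n):
                rb, qb = genome_seq[gpos].upper(), rec.sequence[qpos]
                if rb == qb:
                    run += 1
                else:
                    md.append(str(run)); md.append(rb); run = 0; nm += 1
                qpos += 1; gpos += 1
        elif op == "I":
            qpos += n; nm += n
        elif op == "D":
            md.append(str(run)); run = 0; md.append("^")
            for _ in range(n):
                md.append(genome_seq[gpos].upper()); gpos += 1; nm += 1
        elif op == "N":
            gpos += n
    md.append(str(run))
    return "".join(md), nm


def combine_references(genome_records: list[SamRecord],
                       transcriptome_records: list[SamRecord],
                       transcript_map: dict[str, TranscriptMap],
                       genome_refs: dict[str, str] | None = None) -> list[SamRecord]:
    """Merge a genome alignment with a transcriptome alignment.

    Genome-mapped reads pass through unchanged; reads unmapped on the genome
    but mapped to a transcript are lifted to genome coordinates; reads
    unmapped in both stay unmapped.
    """
    by_name: dict[str, SamRecord] = {}
    for rec in transcriptome_records:
        if not rec.is_unmapped:
            by_name.setdefault(rec.read_name, rec)
    merged: list[SamRecord] = []
    for rec in genome_records:
        if not rec.is_unmapped:
            merged.append(rec)
            continue
        trec = by_name.get(rec.read_name)
        if trec is None:
            merged.append(rec)
            continue
        if trec.ref_name not in transcript_map:
            raise ValueError(f"transcript {trec.ref_name!r} missing from the transcript map")
        tmap = transcript_map[trec.ref_name]
        gseq = genome_refs.get(tmap.chrom) if genome_refs else None
        merged.append(_lift_record(trec, tmap, gseq))
    return merged
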