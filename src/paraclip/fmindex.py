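"""FM-index over a multi-reference DNA text.

The index concatenates all references (N runs split each reference into
separate indexed segments), appends a sentinel after each segment, builds
the suffix array by numpy prefix-doubling (Manber-Myers, O(n log^2 n)),
and derives the BWT, cumulative character counts and a full occurrence
table.  Backward search extends a suffix-array interval by one preceding
reference base per step; an interval is exactly a node of the reference's
prefix trie, which is what makes per-branch comparison counting on the
index equivalent to counting on the trie itself.

Only the forward strand is indexed; reverse-strand queries are handled by
the aligner searching the reverse-complemented read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

# encoding: sentinel < A < C < G < T
SENTINEL = 0
_ENC = {"A": 1, "C": 2, "G": 3, "T": 4}
_DEC = "$ACGT"


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling with numpy lexsort."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord, k_ord = rank[order], key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        if n > 1:
            changed[1:] = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


@dataclass(frozen=True)
class Segment:
    """One indexed stretch of ungapped A/C/G/T within a reference."""

    ref_name: str
    ref_offset: int               # 0-based offset of the segment within the reference
    text_start: int               # position of the segment in the concatenated text
    length: int


class FmIndex:
    """FM-index with full occurrence table; suited to references up to ~1 Mb."""

    def __init__(self, references: list[tuple[str, str]]):
        if not references:
            raise ValueError("cannot index an empty reference list")
        self.ref_names = [name for name, _ in references]
        self.ref_lengths = {name: len(seq) for name, seq in references}
        self.segments: list[Segment] = []
        pieces: list[np.ndarray] = []
        pos = 0
        for name, seq in references:
            seq = seq.upper()
            if not seq:
                raise ValueError(f"reference {name!r} is empty")
            for m in re.finditer(r"[ACGT]+", seq):
                seg = m.group(0)
                self.segments.append(Segment(name, m.start(), pos, len(seg)))
                codes = np.frombuffer(seg.encode(), dtype=np.uint8)
                enc = np.zeros(len(seg) + 1, dtype=np.int64)
                for b, v in _ENC.items():
                    enc[:-1][codes == ord(b)] = v
                pieces.append(enc)               # trailing sentinel per segment
                pos += len(seg) + 1
            if not re.search(r"[ACGT]", seq):
                raise ValueError(f"reference {name!r} contains no A/C/G/T bases")
        self.text = np.concatenate(pieces)
        n = len(self.text)
        self.sa = _suffix_array(self.text)
        bwt = self.text[(self.sa - 1) % n]
        # C[c] = number of text characters strictly smaller than c
        counts = np.bincount(self.text, minlength=5)
        self.C = np.concatenate([[0], np.cumsum(counts)])[:5]
        # occ[i, c] = occurrences of c in bwt[:i]
        one_hot = np.zeros((n + 1, 5), dtype=np.int64)
        one_hot[1:][np.arange(n), bwt] = 1
        self.occ = np.cumsum(one_hot, axis=0)
        self._seg_starts = np.array([s.text_start for s in self.segments])

    @property
    def size(self) -> int:
        return len(self.text)

    def full_interval(self) -> tuple[int, int]:
        """Interval of the empty pattern: every suffix."""
        return 0, len(self.text)

    def extend(self, lo: int, hi: int, base_code: int) -> tuple[int, int]:
        """Backward-extend interval [lo, hi) by prepending base_code (1..4)."""
        c = self.C[base_code]
        return c + self.occ[lo, base_code], c + self.occ[hi, base_code]

    def locate(self, lo: int, hi: int) -> np.ndarray:
        """Text positions of the suffixes in [lo, hi)."""
        return self.sa[lo:hi]

    def text_to_ref(self, text_pos: int) -> tuple[str, int]:
        """Map a text position to (ref_name, 0-based position on the reference)."""
        i = int(np.searchsorted(self._seg_starts, text_pos, side="right")) - 1
        seg = self.segments[i]
        off = text_pos - seg.text_start
        if off >= seg.length:
            raise IndexError(f"text position {text_pos} falls on a sentinel")
        return seg.ref_name, seg.ref_offset + off

    def segment_at(self, text_pos: int) -> Segment:
        i = int(np.searchsorted(self._seg_starts, text_pos, side="right")) - 1
        return self.segments[i]

    def exact_occurrences(self, pattern: str) -> list[tuple[str, int]]:
        """All (ref_name, 0-based position) occurrences of an exact pattern."""
        lo, hi = self.full_interval()
        for ch in reversed(pattern.upper()):
            code = _ENC.get(ch)
            if code is None:
                return []
            lo, hi = self.extend(lo, hi, code)
            if lo >= hi:
                return []
        return sorted(self.text_to_ref(int(p)) for p in self.locate(lo, hi))


    def save(self, path) -> None:
        """Persist the index as a .npz archive (a runtime cache, not a format)."""
        import json
        meta = {
            "ref_names": self.ref_names,
            "ref_lengths": self.ref_lengths,
            "segments": [[s.ref_name, s.ref_offset, s.text_start, s.length]
                         for s in self.segments],
        }
        np.savez_compressed(path, text=self.text, sa=self.sa, occ=self.occ,
                            C=self.C, meta=np.frombuffer(json.dumps(meta).encode(),
                                                         dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "FmIndex":
        import json
        obj = cls.__new__(cls)
        with np.load(path) as npz:
            obj.text = npz["text"]
            obj.sa = npz["sa"]
            obj.occ = npz["occ"]
            obj.C = npz["C"]
            meta = json.loads(bytes(npz["meta"]).decode())
        obj.ref_names = meta["ref_names"]
        obj.ref_lengths = {k: int(v) for k, v in meta["ref_lengths"].items()}
        obj.segments = [Segment(n, int(o), int(t), int(l))
                        for n, o, t, l in meta["segments"]]
        obj._seg_starts = np.array([s.text_start for s in obj.segments])
        return obj


def encode_bases(seq: str) -> np.ndarray:
    """Encode A/C/G/T into 0..3 (matrix row/column order); N maps to -1."""
    out = np.full(len(seq), -1, dtype=np.int64)
    codes = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        out[codes == ord(b)] = i
    return out
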