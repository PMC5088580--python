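"""Score an alignment against simulation truth.

A mapped read is *correct* when it sits on the true reference and strand
with its reported start within ``tolerance`` bases (default 5) of the true
start — slack that absorbs the simulated start-site wobble and small indel
shifts.  From the per-read classifications:

* recall    = correct / simulated
* precision = correct / mapped
* accuracy  = correct / (simulated + false placements)

The accuracy denominator charges every wrong placement on top of the full
read set, so accuracy is bounded above by both recall and precision.
"""

from __future__ import annotations

from dataclasses import dataclass

from .formats_io import SamRecord, TruthRecord

CORRECT, WRONG, UNMAPPED = "correct", "wrong", "unmapped"


@dataclass(frozen=True)
class BenchmarkResult:
    n_total: int
    n_mapped: int
    n_correct: int
    recall: float
    precision: float
    accuracy: float
    tolerance: int
    precision_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total, "n_mapped": self.n_mapped,
            "n_correct": self.n_correct, "recall": self.recall,
            "precision": self.precision, "accuracy": self.accuracy,
            "tolerance": self.tolerance,
        }


def classify(hit: SamRecord, truth: TruthRecord, tolerance: int = 5) -> str:
    """Classify one alignment record against its truth record."""
    if hit.is_unmapped:
        return UNMAPPED
    strand = "-" if hit.is_reverse else "+"
    if (hit.ref_name == truth.ref_name and strand == truth.strand
            and abs(hit.pos - truth.start) <= tolerance):
        return CORRECT
    return WRONG


def classify_records(records: list[SamRecord], truths: dict[str, TruthRecord],
                     tolerance: int = 5) -> list[str]:
    out = []
    for rec in records:
        truth = truths.get(rec.read_name)
        if truth is None:
            raise KeyError(f"read {rec.read_name!r} absent from the truth table")
        out.append(classify(rec, truth, tolerance))
    return out


def summarize(classifications: list[str], tolerance: int = 5) -> BenchmarkResult:
    """Aggregate per-read classifications into rates."""
    if not classifications:
        raise ValueError("no classifications to summarize")
    n_total = len(classifications)
    n_correct = sum(1 for c in classifications if c == CORRECT)
    n_mapped = sum(1 for c in classifications if c != UNMAPPED)
    recall = n_correct / n_total
    precision_defined = n_mapped > 0
    precision = n_correct / n_mapped if precision_defined else 0.0
    accuracy = n_correct / (n_total + (n_mapped - n_correct))
    return BenchmarkResult(n_total, n_mapped, n_correct, recall, precision,
                           accuracy, tolerance, precision_defined)


def benchmark(records: list[SamRecord], truths: dict[str, TruthRecord],
              tolerance: int = 5) -> BenchmarkResult:
    """Classify and summarize in one step (primary records only)."""
    primary = [r for r in records if not (r.flag & 0x100)]
    return summarize(classify_records(primary, truths, tolerance), tolerance)


def write_report(result: BenchmarkResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k, v in result.as_dict().items():
            fh.write(f"{k}\t{v:.6g}\n" if isinstance(v, float) else f"{k}\t{v}\n")
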