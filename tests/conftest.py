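"""Shared fixtures: synthetic transcript databases, default profiles, and an
independent SAM-record builder (its MD/NM construction is deliberately
separate from the aligner's emitter)."""

from __future__ import annotations

import pytest

from paraclip.error_model import PositionModels
from paraclip.formats_io import SamRecord
from paraclip.simulator import (SimulatorConfig, default_background_profile,
                                default_conversion_model, default_position_models,
                                parclip_error_profile, simulate_dataset,
                                synthetic_transcripts)


@pytest.fixture(scope="session")
def transcripts_small():
    return synthetic_transcripts(10, (700, 1100), seed=3)


@pytest.fixture(scope="session")
def parclip_profile():
    return parclip_error_profile()


@pytest.fixture(scope="session")
def sim_small(transcripts_small):
    """A modest simulated dataset shared by read-only tests."""
    cfg = SimulatorConfig(lam=0.65, n_reads=1500, seed=11)
    return simulate_dataset(cfg, transcripts_small)


def build_md(ref_sub: str, read_seq: str, cigar_ops: list[tuple[str, int]]) -> tuple[str, int]:
    """Independent MD/NM builder for hand-made alignments (M/I/D ops)."""
    md, run, nm = [], 0, 0
    q = r = 0
    for op, n in cigar_ops:
        if op == "M":
            for _ in range(n):
                if ref_sub[r] == read_seq[q]:
                    run += 1
                else:
                    md.append(str(run))
                    md.append(ref_sub[r])
                    run = 0
                    nm += 1
                q += 1
                r += 1
        elif op == "I":
            q += n
            nm += n
        elif op == "D":
            md.append(str(run))
            run = 0
            md.append("^" + ref_sub[r:r + n])
            r += n
            nm += n
    md.append(str(run))
    return "".join(md), nm


def make_sam(name: str, ref_name: str, pos1: int, ref_sub: str, read_seq: str,
             cigar: str | None = None, reverse: bool = False,
             qual: int = 35) -> SamRecord:
    """Hand-build a mapped SAM record with a correct MD tag."""
    if cigar is None:
        cigar = f"{len(read_seq)}M"
    ops, num = [], ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            ops.append((c, int(num)))
            num = ""
    md, nm = build_md(ref_sub, read_seq, ops)
    flag = 0x10 if reverse else 0
    return SamRecord(name, flag, ref_name, pos1, 60, cigar, read_seq,
                     [qual] * len(read_seq), tags={"MD": md, "NM": nm})


@pytest.fixture()
def no_indel_position_models() -> PositionModels:
    import numpy as np
    base = default_position_models()
    return PositionModels(np.zeros_like(base.mu), base.delta)


@pytest.fixture(scope="session")
def default_profiles():
    return (default_background_profile(), default_conversion_model(),
            default_position_models())
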