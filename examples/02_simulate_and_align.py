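"""Simulate a PAR-CLIP dataset and compare the probabilistic aligner with
the counted-mismatch baseline on recall/precision against the truth."""

from paraclip import benchmark as bm
from paraclip.aligner import SearchParams, align_dataset
from paraclip.fmindex import FmIndex
from paraclip.simulator import (SimulatorConfig, parclip_error_profile,
                                simulate_dataset, synthetic_transcripts)

transcripts = synthetic_transcripts(30, (700, 1100), seed=7)
cfg = SimulatorConfig(lam=0.65, n_reads=2000, seed=42)
res = simulate_dataset(cfg, transcripts)
n_binding = sum(t.is_binding_site for t in res.truths)
print(f"simulated {len(res.reads)} reads in {len(res.clusters)} clusters; "
      f"{n_binding} reads ({n_binding / len(res.reads):.1%}) lie in binding clusters")

idx = FmIndex(transcripts)
truths = {t.read_name: t for t in res.truths}
params = SearchParams(profile=parclip_error_profile(), X=2.0)

para = bm.benchmark(align_dataset(idx, res.reads, params), truths)
base = bm.benchmark(align_dataset(idx, res.reads, params, baseline_mm=2), truths)

print(f"probabilistic search: recall={para.recall:.4f} "
      f"precision={para.precision:.4f} accuracy={para.accuracy:.4f}")
print(f"2-mismatch baseline:  recall={base.recall:.4f} "
      f"precision={base.precision:.4f} accuracy={base.accuracy:.4f}")
print("-> reads carrying several T->C conversions exceed the two-mismatch "
      "budget but stay above the probability threshold, so the "
      "profile-aware search recovers more true placements.")
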