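"""PAR-CLIP read simulation on a transcript database.

The generative model mirrors how a PAR-CLIP library is produced.  For each
selected transcript, one to three clusters (read stacks) are placed
uniformly at random; the number of reads per cluster is drawn from a
normal distribution with mean 16 and standard deviation 10 (redrawn until
at least one read, i.e. truncated at 1); read start sites wobble around
the cluster start (normal, sd 1).  A fraction lambda of clusters are true
binding sites; the rest mimic contaminating unbound RNA.  Binding clusters
receive T->C conversion sites: the site count follows the per-cluster
site-count distribution, the major site's position follows beta, and each
covering read converts site s independently with probability alpha[rank(s)].
Afterwards every read receives background sequencing errors from epsilon,
position-specific indels from mu, and Phred scores from delta — in that
order, so errors can also hit converted bases.

All randomness flows through one numpy Generator (PCG64) seeded from the
config, making output byte-reproducible.  Every read carries its truth
(origin, cluster, binding flag, conversion count) both encoded in its name
and in a TSV sidecar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .error_model import (BackgroundProfile, ConversionModel, ErrorProfile,
                          PositionModels, N_BETA_BINS, MAX_PHRED,
                          _floor_and_renormalize)
from .formats_io import ReadRecord, TruthRecord, encode_truth_name

BASES = "ACGT"


# ---------------------------------------------------------------------------
# default study-condition profiles
# ---------------------------------------------------------------------------

def parclip_error_profile() -> ErrorProfile:
    """Aligner-side PAR-CLIP profile: T->C conversions at 6.3%, all other
    substitutions at sequencing-error level (0.2%), indels at 0.2%."""
    M = np.full((4, 4), 0.002)
    np.fill_diagonal(M, 0.0)
    M[3, 1] = 0.063               # T -> C
    np.fill_diagonal(M, 1.0 - M.sum(axis=1))
    return ErrorProfile(M, 0.002, 0.002)


def default_background_profile() -> BackgroundProfile:
    """Illumina-like background: each substitution at 0.1% per aligned base
    (~0.3 errors per 100 bases in total), T->C at the same level."""
    eps = np.full((4, 4), 0.001)
    np.fill_diagonal(eps, 0.0)
    np.fill_diagonal(eps, 1.0 - eps.sum(axis=1))
    return BackgroundProfile(eps)


def default_conversion_model() -> ConversionModel:
    """Cross-link conversion structure: ~70% conversion frequency at the
    major site with decaying minor sites, 1-3 sites per cluster, and a
    centre-peaked positional preference for the major site."""
    alpha = np.array([0.70, 0.40, 0.20])
    centres = (np.arange(N_BETA_BINS) + 0.5) / N_BETA_BINS
    beta = np.maximum(1.0 - 2.0 * np.abs(centres - 0.5), 0.05)
    beta /= beta.sum()
    n_sites = np.array([1 / 3, 1 / 3, 1 / 3])
    return ConversionModel(alpha, beta, n_sites)


def default_position_models(max_len: int = 36) -> PositionModels:
    """Indels at 5e-4 per position; Phred scores high early (Q38-40) with a
    mild decay towards the read tail."""
    mu = np.full(max_len, 5e-4)
    delta = np.zeros((max_len, MAX_PHRED + 1))
    for i in range(max_len):
        centre = 39.0 - 6.0 * (i / max(max_len - 1, 1))
        scores = np.arange(25, MAX_PHRED + 1)
        w = np.exp(-0.5 * ((scores - centre) / 2.0) ** 2)
        delta[i, scores] = w / w.sum()
    return PositionModels(mu, delta)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulatorConfig:
    """Study conditions of a simulation run."""

    lam: float = 0.65                       # fraction of clusters that are binding sites
    n_transcripts: int = 100                # transcripts to sample (ignored if n_reads set)
    n_reads: int | None = None              # stop after this many reads, if set
    cluster_count_range: tuple[int, int] = (1, 3)
    cluster_size_mean: float = 16.0
    cluster_size_sd: float = 10.0
    shift_sd: float = 1.0
    read_length: tuple[int, int] | int = (20, 30)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0,1]")
        if self.cluster_size_mean <= 0:
            raise ValueError("cluster_size_mean must be positive")

    @property
    def max_read_length(self) -> int:
        return self.read_length if isinstance(self.read_length, int) else self.read_length[1]

    def draw_read_length(self, rng: np.random.Generator) -> int:
        if isinstance(self.read_length, int):
            return self.read_length
        lo, hi = self.read_length
        return int(rng.integers(lo, hi + 1))


@dataclass
class ClusterPlacement:
    start: int                    # 0-based transcript position
    n_reads: int
    is_binding: bool


@dataclass
class SimulatedRead:
    """One read with its full provenance (kept in memory for invariants)."""

    name: str
    transcript: str
    start: int                    # 0-based true start (pre-noise)
    ref_seq: str                  # reference substring the read derives from
    sequence: str                 # final sequence after conversions/noise/indels
    qualities: list[int]
    cluster_id: int
    is_binding: bool
    conversions: list[int]        # read offsets of injected T->C conversions
    edits: list[tuple] = field(default_factory=list)   # ops in application order


@dataclass
class SimulatedCluster:
    transcript: str
    start: int
    end: int
    is_binding: bool
    cluster_id: int
    tc_sites: list[tuple[int, float]]       # (transcript position, conversion prob)
    reads: list[SimulatedRead] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the generative steps
# ---------------------------------------------------------------------------

def draw_cluster_size(rng: np.random.Generator, mean: float, sd: float) -> int:
    """Normal(mean, sd) rounded; redrawn until >= 1 (truncation at one read)."""
    while True:
        n = int(round(rng.normal(mean, sd)))
        if n >= 1:
            return n


def place_clusters(transcript_len: int, rng: np.random.Generator,
                   config: SimulatorConfig) -> list[ClusterPlacement]:
    """Cluster placements for one transcript: count ~ Uniform{1..3}, size ~
    truncated Normal(16, 10), start uniform over the valid range, binding ~
    Bernoulli(lambda)."""
    max_start = transcript_len - config.max_read_length
    if max_start < 1:
        raise ValueError("transcript shorter than the maximum read length")
    lo, hi = config.cluster_count_range
    n_clusters = int(rng.integers(lo, hi + 1))
    out = []
    for _ in range(n_clusters):
        n_reads = draw_cluster_size(rng, config.cluster_size_mean, config.cluster_size_sd)
        start = int(rng.integers(0, max_start + 1))
        binding = bool(rng.random() < config.lam)
        out.append(ClusterPlacement(start, n_reads, binding))
    return out


def make_reads(placement: ClusterPlacement, transcript_name: str, transcript_seq: str,
               rng: np.random.Generator, config: SimulatorConfig,
               cluster_id: int) -> list[SimulatedRead]:
    """Raw reads for one cluster: start = cluster start + round(Normal(0, sd)),
    clamped to the transcript; true coordinates recorded before any mutation."""
    tlen = len(transcript_seq)
    reads = []
    for _ in range(placement.n_reads):
        shift = int(round(rng.normal(0.0, config.shift_sd))) if config.shift_sd > 0 else 0
        length = config.draw_read_length(rng)
        start = min(max(placement.start + shift, 0), tlen - length)
        ref_seq = transcript_seq[start:start + length]
        reads.append(SimulatedRead(
            name="", transcript=transcript_name, start=start, ref_seq=ref_seq,
            sequence=ref_seq, qualities=[], cluster_id=cluster_id,
            is_binding=placement.is_binding, conversions=[]))
    return reads


def inject_conversions(reads: list[SimulatedRead], cluster: SimulatedCluster,
                       transcript_seq: str, conv: ConversionModel,
                       rng: np.random.Generator) -> list[tuple[int, float]]:
    """Select T->C sites for a binding cluster and convert covering reads.

    The site count follows n_sites_dist; the major site's relative position
    follows beta (snapped to the nearest reference T); minor sites are drawn
    uniformly from the remaining T positions.  Each covering read converts
    site s independently with probability alpha[rank(s)].  Returns the
    chosen (position, probability) sites; empty if the span holds no T.
    """
    if not cluster.is_binding:
        return []
    span = (min(r.start for r in reads),
            max(r.start + len(r.ref_seq) for r in reads))
    sites = _choose_tc_sites(transcript_seq, span, conv, rng)
    if sites:
        cluster.tc_sites = sites
        _convert_reads(reads, sites, rng)
    return sites


def _choose_tc_sites(transcript_seq: str, span: tuple[int, int],
                     conv: ConversionModel, rng: np.random.Generator
                     ) -> list[tuple[int, float]]:
    lo, hi = span
    t_pos = [p for p in range(lo, hi) if transcript_seq[p] == "T"]
    if not t_pos:
        return []
    n_sites = int(rng.choice(len(conv.n_sites_dist), p=conv.n_sites_dist)) + 1
    n_sites = min(n_sites, len(t_pos))
    b = int(rng.choice(len(conv.beta), p=conv.beta))
    rel = (b + rng.random()) / len(conv.beta)
    target = lo + rel * (hi - lo)
    major = min(t_pos, key=lambda p: (abs(p - target), p))
    rest = [p for p in t_pos if p != major]
    minors = (list(rng.choice(rest, size=n_sites - 1, replace=False))
              if n_sites > 1 and rest else [])
    out = []
    for rank, pos in enumerate([major] + sorted(int(p) for p in minors)):
        a = float(conv.alpha[min(rank, len(conv.alpha) - 1)])
        out.append((int(pos), a))
    return out


def _convert_reads(reads: list[SimulatedRead], sites: list[tuple[int, float]],
                   rng: np.random.Generator) -> None:
    for read in reads:
        for pos, prob in sites:
            off = pos - read.start
            if 0 <= off < len(read.ref_seq) and read.ref_seq[off] == "T":
                if rng.random() < prob:
                    read.sequence = read.sequence[:off] + "C" + read.sequence[off + 1:]
                    read.conversions.append(off)
                    read.edits.append(("sub", off, "T", "C"))


def apply_sequencing_noise(read: SimulatedRead, background: BackgroundProfile,
                           posm: PositionModels, rng: np.random.Generator) -> None:
    """Background substitutions (epsilon row of the *current* base), then
    position-specific indels (mu), then Phred scores (delta)."""
    eps = background.epsilon
    seq = list(read.sequence)
    for i, base in enumerate(seq):
        row = eps[BASES.index(base)]
        new = BASES[int(rng.choice(4, p=row))]
        if new != base:
            read.edits.append(("sub", i, base, new))
            seq[i] = new
    # indels: walk positions once; insertion adds a random base before i,
    # deletion removes base i
    mu = posm.mu
    out = []
    i = 0
    while i < len(seq):
        rate = float(mu[min(i, len(mu) - 1)])
        if rate > 0 and rng.random() < rate:
            if rng.random() < 0.5:
                ins = BASES[int(rng.integers(4))]
                read.edits.append(("ins", len(out), ins))
                out.append(ins)
                out.append(seq[i])
            else:
                read.edits.append(("del", len(out), seq[i]))
        else:
            out.append(seq[i])
        i += 1
    read.sequence = "".join(out)
    delta = posm.delta
    read.qualities = [int(rng.choice(MAX_PHRED + 1, p=delta[min(i, len(delta) - 1)]))
                      for i in range(len(read.sequence))]


def revert_edits(read: SimulatedRead) -> str:
    """Undo the recorded edits (inverse ops in reverse order); the result
    must equal the reference substring the read was cut from."""
    seq = read.sequence
    for edit in reversed(read.edits):
        kind = edit[0]
        if kind == "sub":
            _, off, old, new = edit
            assert seq[off] == new, "edit log inconsistent"
            seq = seq[:off] + old + seq[off + 1:]
        elif kind == "ins":
            _, off, base = edit
            assert seq[off] == base
            seq = seq[:off] + seq[off + 1:]
        else:                     # del
            _, off, base = edit
            seq = seq[:off] + base + seq[off:]
    return seq


# ---------------------------------------------------------------------------
# whole-dataset simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    reads: list[ReadRecord]
    truths: list[TruthRecord]     # keyed by the encoded FASTQ read name
    clusters: list[SimulatedCluster]
    sim_reads: list[SimulatedRead]


def simulate_dataset(config: SimulatorConfig, transcripts: list[tuple[str, str]],
                     background: BackgroundProfile | None = None,
                     conv: ConversionModel | None = None,
                     posm: PositionModels | None = None) -> SimulationResult:
    """Run the full generative model.  Deterministic given config.seed."""
    if not transcripts:
        raise ValueError("transcript database is empty")
    background = background or default_background_profile()
    conv = conv or default_conversion_model()
    posm = posm or default_position_models()
    rng = np.random.default_rng(config.seed)

    usable = [(n, s) for n, s in transcripts if len(s) >= config.max_read_length + 8]
    n_skipped = len(transcripts) - len(usable)
    if not usable:
        raise ValueError("every transcript is shorter than the maximum cluster length")

    clusters: list[SimulatedCluster] = []
    sim_reads: list[SimulatedRead] = []
    cluster_id = 0
    read_serial = 0
    target_reads = config.n_reads

    def done() -> bool:
        if target_reads is not None:
            return len(sim_reads) >= target_reads
        return False

    n_iter = config.n_transcripts if target_reads is None else 10 ** 9
    it = 0
    while it < n_iter and not done():
        it += 1
        idx = int(rng.integers(0, len(usable)))
        tname, tseq = usable[idx]
        for placement in place_clusters(len(tseq), rng, config):
            if done():
                break
            cl = SimulatedCluster(tname, placement.start, placement.start,
                                  placement.is_binding, cluster_id, [])
            reads = make_reads(placement, tname, tseq, rng, config, cluster_id)
            span = (min(r.start for r in reads),
                    max(r.start + len(r.ref_seq) for r in reads))
            if placement.is_binding:
                sites = inject_conversions(reads, cl, tseq, conv, rng)
                attempts = 0
                while not sites and attempts < 10:
                    # binding cluster with no reference T: re-place it
                    new_start = int(rng.integers(0, len(tseq) - config.max_read_length + 1))
                    placement = dataclasses.replace(placement, start=new_start)
                    reads = make_reads(placement, tname, tseq, rng, config, cluster_id)
                    span = (min(r.start for r in reads),
                            max(r.start + len(r.ref_seq) for r in reads))
                    sites = inject_conversions(reads, cl, tseq, conv, rng)
                    attempts += 1
                if not sites:     # give up: flag as contamination
                    cl.is_binding = False
                    for r in reads:
                        r.is_binding = False
            cl.start, cl.end = span[0], span[1]
            for r in reads:
                apply_sequencing_noise(r, background, posm, rng)
            cl.reads = reads
            clusters.append(cl)
            sim_reads.extend(reads)
            cluster_id += 1
        # assign names lazily below

    if target_reads is not None:
        sim_reads = sim_reads[:target_reads]

    fastq_reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    for r in sim_reads:
        short = f"r{read_serial:06d}"
        read_serial += 1
        t = TruthRecord(short, r.transcript, "+", r.start + 1, r.cluster_id,
                        r.is_binding, len(r.conversions))
        name = encode_truth_name(t)
        r.name = name
        fastq_reads.append(ReadRecord(name, r.sequence, r.qualities))
        truths.append(dataclasses.replace(t, read_name=name))
    if n_skipped and not fastq_reads:
        raise ValueError("all transcripts were skipped")
    return SimulationResult(fastq_reads, truths, clusters, sim_reads)


# ---------------------------------------------------------------------------
# fixtures & parameter recovery
# ---------------------------------------------------------------------------

def synthetic_transcripts(n: int, length_range: tuple[int, int] = (500, 3000),
                          seed: int = 7) -> list[tuple[str, str]]:
    """Synthetic transcript database: i.i.d. uniform bases, for offline tests."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(BASES[b] for b in rng.integers(0, 4, size=length))
        out.append((f"t{i:04d}", seq))
    return out


def fit_truncated_normal(values, truncation: float = 0.5) -> tuple[float, float]:
    """Maximum-likelihood (loc, scale) of a normal truncated below at
    ``truncation``, fitted to the observed values.

    Cluster sizes are rounded normals redrawn below 1, i.e. the underlying
    draw is conditioned on exceeding 0.5 — hence the default truncation.
    """
    x = np.asarray(values, dtype=float)

    def nll(params):
        loc, scale = params
        if scale <= 0:
            return np.inf
        a = (truncation - loc) / scale
        return -float(np.sum(stats.truncnorm.logpdf(x, a, np.inf, loc=loc, scale=scale)))

    res = optimize.minimize(nll, x0=[float(np.mean(x)), float(np.std(x))],
                            method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    return float(res.x[0]), float(res.x[1])
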