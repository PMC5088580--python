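"""Single-linkage read stacking and high-confidence binding-site filters.

Aligned reads on the same reference and strand are linked whenever their
genomic intervals share at least ``min_overlap`` (default 5) bases; the
clusters are the connected components of that overlap graph.  Because reads
are swept in start order, a read belongs to the current component exactly
when it overlaps the component's rightmost member by the threshold, which
makes the sweep equivalent to explicit single linkage.

A cluster is a high-confidence binding-site candidate when it has at least
10 reads, at least 25% of its reads carry a T->C conversion, spans at most
75 bases, and at least one of its conversion sites is not a known SNP
locus.  Conversions are scored in sense orientation: on a minus-strand
cluster a genomic A read as G is the T->C event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import FormatError, SamRecord, SnpLoci

_SENSE_TC = {"+": ("T", "C"), "-": ("A", "G")}


@dataclass
class Cluster:
    """A stack of overlapping aligned reads with per-position conversion tallies."""

    ref_name: str
    strand: str
    start: int                    # 1-based inclusive span of member reads
    end: int
    read_names: list[str] = field(default_factory=list)
    tc_read_count: int = 0
    site_table: dict[int, list[int]] = field(default_factory=dict)
    # site_table[1-based position] = [coverage at a sense-T position, T->C count]

    @property
    def read_count(self) -> int:
        return len(self.read_names)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def tc_fraction(self, mode: str = "reads") -> float:
        if mode == "reads":
            return self.tc_read_count / self.read_count if self.read_count else 0.0
        cov = sum(c for c, _ in self.site_table.values())
        tc = sum(t for _, t in self.site_table.values())
        return tc / cov if cov else 0.0

    def conversion_sites(self) -> list[int]:
        return sorted(p for p, (_, tc) in self.site_table.items() if tc > 0)

    def major_site(self) -> int | None:
        sites = [(tc / cov, p) for p, (cov, tc) in self.site_table.items()
                 if tc > 0 and cov > 0]
        if not sites:
            return None
        return max(sites, key=lambda s: (s[0], -s[1]))[1]


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    failed_rules: frozenset[str]


def _record_tallies(cluster: Cluster, rec: SamRecord) -> None:
    ref_t, read_c = _SENSE_TC[cluster.strand]
    has_tc = False
    for _, rpos, read_b, ref_b in rec.aligned_pairs():
        if ref_b.upper() != ref_t:
            continue
        entry = cluster.site_table.setdefault(rpos + 1, [0, 0])
        entry[0] += 1
        if read_b.upper() == read_c:
            entry[1] += 1
            has_tc = True
    if has_tc:
        cluster.tc_read_count += 1


def stack_reads(sam_records: list[SamRecord], min_overlap: int = 5) -> list[Cluster]:
    """Single-linkage stacking of mapped reads (>= min_overlap shared bases,
    same reference and strand).  Result is independent of input order."""
    mapped = [r for r in sam_records if not r.is_unmapped]
    for r in mapped:
        if "MD" not in r.tags:
            raise FormatError(
                f"record {r.read_name} lacks an MD tag; realign or annotate "
                "MD tags so conversion tallies can be computed")
    groups: dict[tuple[str, str], list[SamRecord]] = {}
    for r in mapped:
        groups.setdefault((r.ref_name, "-" if r.is_reverse else "+"), []).append(r)
    clusters: list[Cluster] = []
    for (ref, strand), recs in sorted(groups.items()):
        recs.sort(key=lambda r: (r.pos, r.read_name))
        current: Cluster | None = None
        for rec in recs:
            s0, e0 = rec.reference_span()          # 0-based half-open
            start, end = s0 + 1, e0                # 1-based inclusive
            if current is not None and min(current.end, end) - start + 1 >= min_overlap:
                current.end = max(current.end, end)
            else:
                current = Cluster(ref, strand, start, end)
                clusters.append(current)
            current.start = min(current.start, start)
            current.read_names.append(rec.read_name)
            _record_tallies(current, rec)
    clusters.sort(key=lambda c: (c.ref_name, c.start, c.strand))
    return clusters


def filter_high_confidence(clusters: list[Cluster], snp_loci: SnpLoci | None = None,
                           min_reads: int = 10, min_tc_fraction: float = 0.25,
                           max_length: int = 75, tc_fraction_mode: str = "reads"
                           ) -> tuple[list[Cluster], list[tuple[Cluster, FilterVerdict]]]:
    """Apply the binding-site filters; returns (kept, discarded-with-verdict)."""
    kept, discarded = [], []
    for cl in clusters:
        failed = set()
        if cl.read_count < min_reads:
            failed.add("min_reads")
        if cl.tc_fraction(tc_fraction_mode) < min_tc_fraction:
            failed.add("min_tc_fraction")
        if cl.length > max_length:
            failed.add("max_length")
        sites = cl.conversion_sites()
        non_snp = [p for p in sites
                   if snp_loci is None or (cl.ref_name, p) not in snp_loci]
        if not non_snp:
            failed.add("snp_only_sites")
        if failed:
            discarded.append((cl, FilterVerdict(False, frozenset(failed))))
        else:
            kept.append(cl)
    return kept, discarded


_REPORT_HEADER = ("#ref\tstart\tend\tcluster_id\tread_count\tstrand\t"
                  "tc_fraction\tmajor_site")


def write_cluster_report(clusters: list[Cluster], path) -> None:
    """BED-like table: 0-based half-open coordinates, one row per cluster,
    sorted by (ref, start)."""
    with open(path, "w") as fh:
        fh.write(_REPORT_HEADER + "\n")
        for i, cl in enumerate(sorted(clusters, key=lambda c: (c.ref_name, c.start))):
            major = cl.major_site()
            fh.write(f"{cl.ref_name}\t{cl.start - 1}\t{cl.end}\tcluster_{i}\t"
                     f"{cl.read_count}\t{cl.strand}\t{cl.tc_fraction():.6g}\t"
                     f"{major - 1 if major is not None else -1}\n")


def read_cluster_report(path) -> list[dict]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _REPORT_HEADER:
            raise FormatError(f"{path}: unexpected cluster-report header")
        for line in fh:
            ref, s, e, cid, n, strand, tc, major = line.rstrip("\n").split("\t")
            out.append(dict(ref=ref, start=int(s) + 1, end=int(e), id=cid,
                            read_count=int(n), strand=strand, tc_fraction=float(tc),
                            major_site=int(major) + 1 if int(major) >= 0 else None))
    return out
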