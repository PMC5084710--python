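"""Replicate-consensus peak selection, gene attribution and positional
Monte Carlo enrichment for ChIP-seq of a meristem transcription factor.

The pipeline consumes MACS2-style narrowPeak calls (0-based half-open
coordinates, -log10 q in column 9) from three treatment and three control
replicates:

1. :func:`consensus_regions` keeps the genomic intervals covered by a peak
   with q <= 1e-3 in *every* treatment replicate, at least 50 nt long, and
   not overlapping any control peak.
2. :func:`assign_to_genes` attributes each consensus region (by its centre)
   to gene models within 3 kb upstream / 1.5 kb downstream of the coding
   sequence, strand-aware, with no intervening coding sequence.
3. :func:`positional_enrichment` tests whether observed centres concentrate
   in promoter + downstream windows versus transcribed regions, against
   peaks placed uniformly at random within the attributed genes' extended
   spans (Monte Carlo, default 10,000 simulations).
4. :func:`export_motif_sequences` writes the observed +/-75 nt sequence
   windows and a 10x larger random control set for motif discovery.

GFF3 input (1-based closed) is converted to 0-based half-open on read;
everything downstream is 0-based half-open.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import gffutils
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PeakCall",
    "ConsensusRegion",
    "GeneModel",
    "EnrichmentResult",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_models",
    "write_gff3",
    "consensus_regions",
    "assign_to_genes",
    "positional_enrichment",
    "export_motif_sequences",
    "overlap_fisher",
]

logger = logging.getLogger(__name__)

NARROWPEAK_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "signalValue",
    "pValue",
    "qValue",
    "peak",
]

ZONE_PROMOTER, ZONE_TRANSCRIBED, ZONE_DOWNSTREAM = 0, 1, 2
_ZONE_NAMES = {ZONE_PROMOTER: "promoter", ZONE_TRANSCRIBED: "transcribed", ZONE_DOWNSTREAM: "downstream"}


@dataclasses.dataclass(frozen=True)
class PeakCall:
    """One called peak (0-based half-open)."""

    chrom: str
    start: int
    end: int
    neg_log10_q: float
    fold_enrichment: float = 0.0
    summit_offset: int = 0
    replicate_id: str = ""
    name: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"peak end {self.end} <= start {self.start}")
        if self.neg_log10_q < 0:
            raise ValueError("neg_log10_q must be >= 0")


@dataclasses.dataclass(frozen=True)
class ConsensusRegion:
    """Interval covered by all treatment replicates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    source_peaks: tuple[tuple[str, ...], ...] = ()

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Gene with coding-sequence and transcript spans (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    transcript_start: int
    transcript_end: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (self.transcript_start <= self.cds_start < self.cds_end <= self.transcript_end):
            raise ValueError(
                f"gene {self.gene_id}: CDS [{self.cds_start},{self.cds_end}) not within "
                f"transcript [{self.transcript_start},{self.transcript_end})"
            )

    def extended_span(self, upstream: int = 3000, downstream: int = 1500) -> tuple[int, int]:
        """CDS span widened by the strand-adjusted upstream/downstream windows."""
        if self.strand == "+":
            return self.cds_start - upstream, self.cds_end + downstream
        return self.cds_start - downstream, self.cds_end + upstream


@dataclasses.dataclass
class EnrichmentResult:
    """Observed vs simulated positional distribution of peak centres."""

    observed_counts: dict[str, int]
    statistic: int
    null_statistics: np.ndarray
    n_sims: int
    p_value: float
    histogram: pd.DataFrame


# ---------------------------------------------------------------------------
# narrowPeak / GFF3 IO


def read_narrowpeak(path: str | Path, replicate_id: str = "") -> list[PeakCall]:
    """Read an ENCODE 10-column narrowPeak file into PeakCall records."""
    df = pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS, comment="#")
    peaks = []
    for row in df.itertuples(index=False):
        peaks.append(
            PeakCall(
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                neg_log10_q=float(row.qValue),
                fold_enrichment=float(row.signalValue),
                summit_offset=int(row.peak),
                replicate_id=replicate_id,
                name=str(row.name),
            )
        )
    return peaks


def write_narrowpeak(peaks: Sequence[PeakCall], path: str | Path) -> None:
    """Write PeakCall records as a 10-column narrowPeak file."""
    rows = []
    for i, p in enumerate(peaks):
        rows.append(
            (
                p.chrom,
                p.start,
                p.end,
                p.name or f"peak_{i}",
                min(1000, int(10 * p.neg_log10_q)),
                ".",
                p.fold_enrichment,
                -1,
                p.neg_log10_q,
                p.summit_offset,
            )
        )
    pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS).to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based closed → 0-based half-open).

    The transcript span is the gene feature's span; the CDS span is the
    union of the gene's CDS features. Genes without CDS features are
    skipped with a warning.
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds = list(db.children(g, featuretype="CDS"))
        if not cds:
            logger.warning("gene %s has no CDS features; skipped", g.id)
            continue
        cds_start = min(c.start for c in cds) - 1  # GFF3 1-based closed → 0-based half-open
        cds_end = max(c.end for c in cds)
        try:
            genes.append(
                GeneModel(
                    gene_id=g.id,
                    chrom=g.seqid,
                    strand=g.strand,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    transcript_start=g.start - 1,
                    transcript_end=g.end,
                )
            )
        except ValueError as e:
            logger.warning("malformed gene span skipped: %s", e)
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene + mRNA + single CDS)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tapexkit\tgene\t{g.transcript_start + 1}\t{g.transcript_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tapexkit\tmRNA\t{g.transcript_start + 1}\t{g.transcript_end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tapexkit\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.1\n"
            )


# ---------------------------------------------------------------------------
# consensus selection


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Merge overlapping/abutting half-open intervals (coverage semantics)."""
    if len(iv) == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged)


def _intersect_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersection of two merged, sorted half-open interval lists."""
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out).reshape(-1, 2)


def consensus_regions(
    treatment: Sequence[Sequence[PeakCall]],
    controls: Sequence[Sequence[PeakCall]],
    q_max: float = 1e-3,
    min_overlap: int = 50,
    n_required: int | None = None,
) -> list[ConsensusRegion]:
    """Replicate-consensus intervals from treatment vs control peak calls.

    Keeps intervals covered (coverage semantics) by q-passing peaks in all
    treatment replicates, of length >= ``min_overlap`` nt, and with no
    positional overlap (>= 1 nt) with any control peak — controls are used
    as called, with no q filter. With ``n_required`` set, an n-of-n rule is
    applied to that many replicates instead of the standard three (a
    warning is logged when the replicate count is not 3).
    """
    n_reps = len(treatment)
    if n_required is None:
        n_required = n_reps
    if n_reps != 3:
        logger.warning("replicate count %d != 3; applying %d-of-%d rule", n_reps, n_required, n_reps)
    if n_required != n_reps:
        raise NotImplementedError("only the n-of-n consensus rule is implemented")
    nlq_min = -np.log10(q_max) - 1e-9

    chroms = sorted({p.chrom for reps in treatment for p in reps})
    regions: list[ConsensusRegion] = []
    for chrom in chroms:
        per_rep = []
        for reps in treatment:
            iv = np.array(
                [(p.start, p.end) for p in reps if p.chrom == chrom and p.neg_log10_q >= nlq_min],
                dtype=np.int64,
            ).reshape(-1, 2)
            per_rep.append(_merge_intervals(iv))
        inter = per_rep[0]
        for other in per_rep[1:]:
            inter = _intersect_two(inter, other)
            if len(inter) == 0:
                break
        if len(inter) == 0:
            continue
        inter = inter[(inter[:, 1] - inter[:, 0]) >= min_overlap]
        if len(inter) == 0:
            continue
        ctrl = np.array(
            [(p.start, p.end) for reps in controls for p in reps if p.chrom == chrom],
            dtype=np.int64,
        ).reshape(-1, 2)
        ctrl = _merge_intervals(ctrl)
        for s, e in inter:
            if len(ctrl) and np.any((ctrl[:, 0] < e) & (ctrl[:, 1] > s)):
                continue
            sources = tuple(
                tuple(
                    (p.name or f"{p.replicate_id}:{p.start}-{p.end}")
                    for p in reps
                    if p.chrom == chrom and p.start < e and p.end > s and p.neg_log10_q >= nlq_min
                )
                for reps in treatment
            )
            regions.append(ConsensusRegion(chrom=chrom, start=int(s), end=int(e), source_peaks=sources))
    return regions


# ---------------------------------------------------------------------------
# gene attribution


def assign_to_genes(
    regions: Sequence[ConsensusRegion],
    genes: Sequence[GeneModel],
    upstream: int = 3000,
    downstream: int = 1500,
) -> pd.DataFrame:
    """Attribute consensus regions to gene models by their centre.

    A region is attributed to gene g iff its centre lies within g's
    strand-adjusted window [CDS - upstream, CDS + downstream] and no other
    gene's CDS lies entirely between the centre and g's CDS (intervening
    coding sequence, strand-agnostic). A region may be attributed to
    several flanking genes. Returns a tidy table with one row per
    (region, gene) attribution.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    for ridx, r in enumerate(regions):
        center = r.center
        for g in by_chrom.get(r.chrom, ()):
            lo, hi = g.extended_span(upstream, downstream)
            if not (lo <= center < hi):
                continue
            if center < g.cds_start:
                b_lo, b_hi = center, g.cds_start
            elif center >= g.cds_end:
                b_lo, b_hi = g.cds_end, center
            else:
                b_lo = b_hi = center  # centre inside the CDS: nothing can intervene
            blocked = any(
                h.gene_id != g.gene_id and h.cds_start > b_lo and h.cds_end <= b_hi
                for h in by_chrom[r.chrom]
            )
            if blocked:
                continue
            if g.cds_start <= center < g.cds_end:
                relation = "cds"
                distance = 0
            elif center < g.cds_start:
                distance = g.cds_start - center
                relation = "upstream" if g.strand == "+" else "downstream"
            else:
                distance = center - g.cds_end
                relation = "downstream" if g.strand == "+" else "upstream"
            rows.append(
                {
                    "region_index": ridx,
                    "chrom": r.chrom,
                    "region_start": r.start,
                    "region_end": r.end,
                    "center": center,
                    "gene_id": g.gene_id,
                    "strand": g.strand,
                    "relation": relation,
                    "distance_to_cds": distance,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_index",
            "chrom",
            "region_start",
            "region_end",
            "center",
            "gene_id",
            "strand",
            "relation",
            "distance_to_cds",
        ],
    )


# ---------------------------------------------------------------------------
# positional Monte Carlo enrichment


def _zone_segments(
    genes: Sequence[GeneModel], upstream: int, downstream: int
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Partition each chromosome's attributed-gene footprint into zones.

    Returns per chromosome (boundaries (m+1,), zone codes (m,)); zone -1
    marks positions outside every extended span. Where genes overlap,
    transcribed takes precedence over promoter over downstream.
    """
    per_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for g in genes:
        lo, hi = g.extended_span(upstream, downstream)
        if g.strand == "+":
            prom = (lo, g.transcript_start, ZONE_PROMOTER)
            down = (g.transcript_end, hi, ZONE_DOWNSTREAM)
        else:
            prom = (g.transcript_end, hi, ZONE_PROMOTER)
            down = (lo, g.transcript_start, ZONE_DOWNSTREAM)
        tx = (g.transcript_start, g.transcript_end, ZONE_TRANSCRIBED)
        for s, e, z in (prom, tx, down):
            if s < e:
                per_chrom.setdefault(g.chrom, []).append((s, e, z))

    out = {}
    precedence = {ZONE_TRANSCRIBED: 0, ZONE_PROMOTER: 1, ZONE_DOWNSTREAM: 2}
    for chrom, items in per_chrom.items():
        bounds = np.unique(
            np.concatenate([[s for s, _, _ in items], [e for _, e, _ in items]])
        )
        codes = np.full(len(bounds) - 1, -1, dtype=np.int8)
        best = np.full(len(bounds) - 1, 99, dtype=np.int8)
        for s, e, z in items:
            i0, i1 = np.searchsorted(bounds, [s, e])
            pr = precedence[z]
            seg = slice(i0, i1)
            take = best[seg] > pr
            codes[seg] = np.where(take, z, codes[seg])
            best[seg] = np.minimum(best[seg], pr)
        out[chrom] = (bounds, codes)
    return out


def _classify_centers(
    chroms: Sequence[str], positions: np.ndarray, segments
) -> np.ndarray:
    """Zone code per centre (-1 = outside all extended spans)."""
    zones = np.full(len(positions), -1, dtype=np.int8)
    for chrom in set(chroms):
        idx = [i for i, c in enumerate(chroms) if c == chrom]
        if chrom not in segments:
            continue
        bounds, codes = segments[chrom]
        pos = positions[idx]
        k = np.searchsorted(bounds, pos, side="right") - 1
        valid = (k >= 0) & (k < len(codes))
        z = np.full(len(idx), -1, dtype=np.int8)
        z[valid] = codes[k[valid]]
        zones[idx] = z
    return zones


def positional_enrichment(
    regions: Sequence[ConsensusRegion],
    genes: Sequence[GeneModel],
    n_sims: int = 10_000,
    seed: int | np.random.Generator | None = None,
    upstream: int = 3000,
    downstream: int = 1500,
    bin_width: int = 150,
    max_dist: int = 3000,
    compute_histogram: bool = True,
) -> EnrichmentResult:
    """Monte Carlo test for promoter/downstream concentration of centres.

    Observed centres are classified as promoter, transcribed or downstream
    relative to the attributed genes. The null places the same number of
    centres uniformly at random within the union of the genes' extended
    spans and classifies them identically. The statistic is the
    promoter + downstream count; ``p = (1 + #{sims >= observed}) /
    (n_sims + 1)``, bounded below by 1/(n_sims+1). A per-bin histogram of
    centre positions relative to transcript start (5'→3') is also emitted.
    """
    if len(regions) == 0:
        raise ValueError("no regions to test")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    segments = _zone_segments(genes, upstream, downstream)
    obs_chroms = [r.chrom for r in regions]
    obs_pos = np.array([r.center for r in regions], dtype=np.int64)
    obs_zone = _classify_centers(obs_chroms, obs_pos, segments)
    counts = {name: int((obs_zone == code).sum()) for code, name in _ZONE_NAMES.items()}
    counts["outside"] = int((obs_zone == -1).sum())
    statistic = counts["promoter"] + counts["downstream"]

    # flatten the zone segments of the union of extended spans for sampling
    seg_zone, seg_len = [], []
    for chrom, (bounds, codes) in sorted(segments.items()):
        keep = codes >= 0
        seg_zone.append(codes[keep])
        seg_len.append(np.diff(bounds)[keep])
    seg_zone = np.concatenate(seg_zone)
    seg_len = np.concatenate(seg_len).astype(float)
    pz = seg_len / seg_len.sum()
    n = len(regions)
    # a simulated centre's zone is fully determined by which segment it
    # lands in, so sample segment indices length-weighted
    sim_segments = rng.choice(len(seg_zone), size=(n_sims, n), p=pz)
    sim_zone = seg_zone[sim_segments]
    null_stats = ((sim_zone == ZONE_PROMOTER) | (sim_zone == ZONE_DOWNSTREAM)).sum(axis=1)
    p = (1 + int((null_stats >= statistic).sum())) / (n_sims + 1)

    if compute_histogram:
        hist = _position_histogram(regions, genes, upstream, downstream, bin_width, max_dist)
    else:
        hist = pd.DataFrame(columns=["bin_start", "bin_end", "observed"])
    return EnrichmentResult(
        observed_counts=counts,
        statistic=statistic,
        null_statistics=null_stats,
        n_sims=n_sims,
        p_value=p,
        histogram=hist,
    )


def _position_histogram(regions, genes, upstream, downstream, bin_width, max_dist):
    """Histogram of centre offsets from transcript start, 5'→3' signed."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    offsets = []
    for r in regions:
        best = None
        for g in by_chrom.get(r.chrom, ()):
            lo, hi = g.extended_span(upstream, downstream)
            if not (lo <= r.center < hi):
                continue
            if g.strand == "+":
                off = r.center - g.transcript_start
            else:
                off = g.transcript_end - 1 - r.center
            if best is None or abs(off) < abs(best):
                best = off
        if best is not None:
            offsets.append(best)
    edges = np.arange(-max_dist, max_dist + bin_width, bin_width)
    counts, _ = np.histogram(offsets, bins=edges)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "observed": counts}
    )


# ---------------------------------------------------------------------------
# motif-input sequences and overlap test


def export_motif_sequences(
    regions: Sequence[ConsensusRegion],
    genome_fasta: str | Path,
    observed_path: str | Path,
    control_path: str | Path,
    half_width: int = 75,
    control_factor: int = 10,
    seed: int | np.random.Generator | None = None,
) -> tuple[int, int]:
    """Write observed and random-control sequence sets for motif discovery.

    The observed set is centre +/- ``half_width`` (2*half_width + 1 nt) for
    each consensus region; the control set is ``control_factor`` times as
    many windows of the same width at uniform random genome positions
    (length-weighted across chromosomes, seeded). Windows exceeding
    chromosome bounds are clipped with a warning. Returns the record
    counts written.
    """
    import pyfaidx

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fa = pyfaidx.Fasta(str(genome_fasta))
    chrom_lens = {name: len(fa[name]) for name in fa.keys()}

    def window(chrom: str, center: int) -> str:
        L = chrom_lens[chrom]
        lo, hi = center - half_width, center + half_width + 1
        if lo < 0 or hi > L:
            logger.warning("window %s:%d-%d clipped to chromosome bounds", chrom, lo, hi)
            lo, hi = max(0, lo), min(L, hi)
        return str(fa[chrom][lo:hi])

    with open(observed_path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f">observed_{i} {r.chrom}:{r.start}-{r.end}\n{window(r.chrom, r.center)}\n")

    names = sorted(chrom_lens)
    lens = np.array([chrom_lens[c] for c in names], dtype=float)
    n_ctrl = control_factor * len(regions)
    chrom_idx = rng.choice(len(names), size=n_ctrl, p=lens / lens.sum())
    with open(control_path, "w") as fh:
        for i, ci in enumerate(chrom_idx):
            chrom = names[ci]
            center = int(rng.integers(0, chrom_lens[chrom]))
            fh.write(f">control_{i} {chrom}:{center}\n{window(chrom, center)}\n")
    return len(regions), n_ctrl


def overlap_fisher(
    set_a: Sequence[str], set_b: Sequence[str], universe: Sequence[str]
) -> tuple[float, float]:
    """Two-sided Fisher exact test for the overlap of two gene sets.

    Both sets must be subsets of the universe. Returns (odds ratio, p),
    with p the sum of hypergeometric probabilities of tables at most as
    probable as the observed one.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    a, b = set(set_a) & uni, set(set_b) & uni
    if set(set_a) - uni or set(set_b) - uni:
        raise ValueError("sets must be subsets of the universe")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(uni) - n11 - n10 - n01
    odds, p = sps.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    return float(odds), float(p)
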