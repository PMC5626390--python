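"""Interval computations on ChIP-seq peak sets.

Peak-to-gene assignment uses the dual rule: a peak is assigned to a gene when
it overlaps the gene body (full transcript span) by at least 1 bp, or when
its nearest base lies strictly within ``window`` bp (default 50 kb) of the
TSS, on either side. Overlap between two peaks means >=1 bp intersection in
half-open coordinates; no reciprocal-fraction requirement is imposed.

An interval tree indexes gene windows so assignment is O((n+m) log) instead
of all-pairs; the brute-force scan lives in the test suite as the oracle.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .models import GeneModel, GeneModelSet, Peak, PeakSet, ValidationError

DEFAULT_WINDOW = 50_000


def peak_tss_distance(peak: Peak, gene: GeneModel) -> int:
    """Signed distance from a peak to a gene's TSS.

    0 if the peak covers the TSS; otherwise the offset of the peak's nearest
    covered base, positive downstream of the TSS relative to the gene's
    strand.
    """
    tss = gene.tss
    if peak.start <= tss < peak.end:
        d = 0
    elif peak.start > tss:
        d = peak.start - tss
    else:
        d = (peak.end - 1) - tss
    return d if gene.strand == "+" else -d


@dataclass(frozen=True)
class AssignedPair:
    peak_id: str
    gene_id: str
    relation: str  # "in_body" | "near_tss"
    distance: int  # signed bp to TSS (strand-relative)


@dataclass
class PeakGeneAssignment:
    """Many-to-many peak/gene assignment with per-pair evidence."""

    peaks: PeakSet
    genes: GeneModelSet
    window: int
    pairs: List[AssignedPair]
    n_unassignable_chrom_peaks: int = 0
    peak_to_genes: Dict[str, Set[str]] = field(init=False)
    gene_to_peaks: Dict[str, Set[str]] = field(init=False)

    def __post_init__(self) -> None:
        p2g: Dict[str, Set[str]] = defaultdict(set)
        g2p: Dict[str, Set[str]] = defaultdict(set)
        for pair in self.pairs:
            p2g[pair.peak_id].add(pair.gene_id)
            g2p[pair.gene_id].add(pair.peak_id)
        self.peak_to_genes = dict(p2g)
        self.gene_to_peaks = dict(g2p)

    @property
    def bound_gene_ids(self) -> Set[str]:
        return set(self.gene_to_peaks)

    @property
    def assigned_peak_ids(self) -> Set[str]:
        return set(self.peak_to_genes)

    def pair_set(self) -> Set[Tuple[str, str]]:
        return {(p.peak_id, p.gene_id) for p in self.pairs}


def assign_peaks_to_genes(
    peaks: PeakSet, genes: GeneModelSet, window: int = DEFAULT_WINDOW
) -> PeakGeneAssignment:
    """Assign peaks to genes: gene-body overlap or nearest base < ``window``
    bp from the TSS (both strands' flanks).

    A peak may map to several genes and a gene to several peaks; when a peak
    both overlaps the body and sits near the TSS, the single pair is labelled
    "in_body". Peaks on chromosomes absent from the gene models are counted
    but assigned to nothing.
    """
    if window < 0:
        raise ValidationError("window must be non-negative")
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        lo = min(g.start, max(g.tss - window + 1, 0))
        hi = max(g.end, g.tss + window)
        trees.setdefault(g.chrom, IntervalTree()).addi(lo, hi, g)
    pairs: List[AssignedPair] = []
    unassignable = 0
    for p in peaks:
        tree = trees.get(p.chrom)
        if tree is None:
            unassignable += 1
            continue
        for iv in tree.overlap(p.start, p.end):
            g: GeneModel = iv.data
            in_body = p.start < g.end and g.start < p.end
            d = peak_tss_distance(p, g)
            near = abs(d) < window
            if not (in_body or near):
                continue
            pairs.append(
                AssignedPair(
                    peak_id=p.peak_id,
                    gene_id=g.gene_id,
                    relation="in_body" if in_body else "near_tss",
                    distance=d,
                )
            )
    pairs.sort(key=lambda x: (x.peak_id, x.gene_id))
    return PeakGeneAssignment(
        peaks=peaks,
        genes=genes,
        window=window,
        pairs=pairs,
        n_unassignable_chrom_peaks=unassignable,
    )


def _overlap_flags(a: PeakSet, b: PeakSet) -> Dict[str, bool]:
    """For each peak of ``a``: does it intersect >=1 peak of ``b`` by >=1 bp?"""
    trees: Dict[str, IntervalTree] = {}
    for p in b:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    flags = {}
    for p in a:
        tree = trees.get(p.chrom)
        flags[p.peak_id] = bool(tree is not None and tree.overlaps(p.start, p.end))
    return flags


@dataclass
class OverlapReport:
    """Shared/unique peak counts between two condition peak sets.

    ``shared_a`` counts A-side peaks overlapping any B peak (and vice versa),
    so the two shared counts differ when overlaps are many-to-one.
    """

    name_a: str
    name_b: str
    shared_a: int
    unique_a: int
    shared_b: int
    unique_b: int
    flags_a: Dict[str, bool]
    flags_b: Dict[str, bool]

    @property
    def frac_shared_a(self) -> float:
        return self.shared_a / (self.shared_a + self.unique_a)

    @property
    def frac_shared_b(self) -> float:
        return self.shared_b / (self.shared_b + self.unique_b)

    def to_dict(self) -> dict:
        return {
            "set_a": self.name_a,
            "set_b": self.name_b,
            "shared_a": self.shared_a,
            "unique_a": self.unique_a,
            "shared_b": self.shared_b,
            "unique_b": self.unique_b,
            "frac_shared_a": self.frac_shared_a,
            "frac_shared_b": self.frac_shared_b,
        }


def classify_condition_overlap(peaks_a: PeakSet, peaks_b: PeakSet) -> OverlapReport:
    """Fraction of each condition's peaks detected in the other condition."""
    if len(peaks_a) == 0 or len(peaks_b) == 0:
        raise ValidationError("both peak sets must be non-empty")
    flags_a = _overlap_flags(peaks_a, peaks_b)
    flags_b = _overlap_flags(peaks_b, peaks_a)
    shared_a = sum(flags_a.values())
    shared_b = sum(flags_b.values())
    return OverlapReport(
        name_a=peaks_a.name,
        name_b=peaks_b.name,
        shared_a=shared_a,
        unique_a=len(peaks_a) - shared_a,
        shared_b=shared_b,
        unique_b=len(peaks_b) - shared_b,
        flags_a=flags_a,
        flags_b=flags_b,
    )


@dataclass
class ExclusivityReport:
    """Partition of the bound-gene universe by which condition binds each gene."""

    a_only: Set[str]
    b_only: Set[str]
    both: Set[str]

    @property
    def n_total(self) -> int:
        return len(self.a_only) + len(self.b_only) + len(self.both)

    def fractions(self) -> Dict[str, float]:
        n = self.n_total
        if n == 0:
            return {"a_only": 0.0, "b_only": 0.0, "both": 0.0}
        return {
            "a_only": len(self.a_only) / n,
            "b_only": len(self.b_only) / n,
            "both": len(self.both) / n,
        }


def gene_association_exclusivity(
    assign_a: PeakGeneAssignment, assign_b: PeakGeneAssignment
) -> ExclusivityReport:
    """Genes associated exclusively with A-condition peaks, exclusively with
    B-condition peaks, or with both, over the union of bound genes."""
    if assign_a.genes is not assign_b.genes and assign_a.genes != assign_b.genes:
        raise ValidationError("assignments must share gene models")
    a, b = assign_a.bound_gene_ids, assign_b.bound_gene_ids
    return ExclusivityReport(a_only=a - b, b_only=b - a, both=a & b)


@dataclass
class TssProfile:
    """Binned distance-to-nearest-TSS profile of assigned peaks."""

    bin_edges: np.ndarray
    fractions: np.ndarray  # per bin, of all assigned peaks
    mean_amplitudes: np.ndarray  # NaN for empty bins
    n_assigned: int


def tss_distance_profile(
    assignment: PeakGeneAssignment, bin_edges: Sequence[float]
) -> TssProfile:
    """Fraction of peaks and mean amplitude per |distance-to-nearest-TSS| bin.

    Each assigned peak contributes once, at the absolute distance to the
    nearest TSS among its assigned genes. Bins are half-open
    ``[edge_i, edge_{i+1})``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValidationError("bin edges must be strictly increasing, >=2 values")
    if not assignment.pairs:
        raise ValidationError("empty assignment")
    best: Dict[str, int] = {}
    for pair in assignment.pairs:
        d = abs(pair.distance)
        if pair.peak_id not in best or d < best[pair.peak_id]:
            best[pair.peak_id] = d
    peak_ids = sorted(best)
    dists = np.array([best[p] for p in peak_ids], dtype=float)
    amps = np.array([assignment.peaks[p].amplitude for p in peak_ids])
    which = np.digitize(dists, edges) - 1  # -1 or nbins => outside
    nbins = len(edges) - 1
    fractions = np.zeros(nbins)
    means = np.full(nbins, np.nan)
    for i in range(nbins):
        mask = which == i
        fractions[i] = mask.sum() / len(dists)
        if mask.any():
            means[i] = amps[mask].mean()
    return TssProfile(
        bin_edges=edges,
        fractions=fractions,
        mean_amplitudes=means,
        n_assigned=len(dists),
    )


@dataclass
class AmplitudeFlags:
    """Per-peak high-amplitude flags against a quantile threshold."""

    q: float
    threshold: float
    flags: Dict[str, bool]

    def high_peak_ids(self) -> Set[str]:
        return {p for p, f in self.flags.items() if f}


def amplitude_quantile_flag(peaks: PeakSet, q: float = 0.75) -> AmplitudeFlags:
    """Flag peaks whose amplitude is within the top ``1-q`` of the whole set.

    The threshold is the linear-interpolation ``q``-quantile of all
    amplitudes; the flag is amplitude >= threshold, so q=0.75 marks the top
    quartile and equal-amplitude sets are flagged entirely.
    """
    if len(peaks) == 0:
        raise ValidationError("empty peak set")
    if not 0 <= q <= 1:
        raise ValidationError("quantile must be in [0, 1]")
    amps = np.asarray(peaks.amplitudes(), dtype=float)
    threshold = float(np.quantile(amps, q))
    flags = {p.peak_id: bool(p.amplitude >= threshold) for p in peaks}
    return AmplitudeFlags(q=q, threshold=threshold, flags=flags)


@dataclass
class CooccupancyReport:
    """Fraction of A peaks overlapped by B peaks, with midpoint offsets."""

    fraction: float
    flags: Dict[str, bool]
    midpoint_distances: Dict[str, float]  # signed B-midpoint minus A-midpoint


def cooccupancy(peaks_a: PeakSet, peaks_b: PeakSet) -> CooccupancyReport:
    """Two-TF co-occupancy: share of A peaks with >=1 overlapping B peak.

    Also reports, per A peak, the signed offset from its midpoint to the
    nearest B-peak midpoint on the same chromosome (NaN when the chromosome
    carries no B peaks), for co-localization histograms.
    """
    report = classify_condition_overlap(peaks_a, peaks_b)
    mids_by_chrom: Dict[str, np.ndarray] = {}
    grouped: Dict[str, List[float]] = defaultdict(list)
    for p in peaks_b:
        grouped[p.chrom].append(p.midpoint)
    for chrom, mids in grouped.items():
        mids_by_chrom[chrom] = np.sort(np.asarray(mids))
    distances: Dict[str, float] = {}
    for p in peaks_a:
        mids = mids_by_chrom.get(p.chrom)
        if mids is None:
            distances[p.peak_id] = float("nan")
            continue
        m = p.midpoint
        i = int(np.searchsorted(mids, m))
        candidates = [mids[j] for j in (i - 1, i) if 0 <= j < len(mids)]
        nearest = min(candidates, key=lambda x: abs(x - m))
        distances[p.peak_id] = float(nearest - m)
    return CooccupancyReport(
        fraction=report.frac_shared_a,
        flags=report.flags_a,
        midpoint_distances=distances,
    )
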