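"""Synthetic genomes, peak sets and expression tables with planted truth.

The generator emulates the statistical structure of a two-condition TF
ChIP-seq x RNA-seq study: a set of bound genes receives peaks near its TSSs
in the treated condition, a configurable fraction of which is shared with
the untreated condition; responsive genes carry planted fold changes (with a
down-regulated majority) on negative-binomial counts; and the planted
signature is the bound-and-responsive intersection. Everything is
deterministic under the seed.

Two presets are provided: :func:`SimConfig.study_like` mirrors the published
study's summary structure (about 20% of bound genes responsive, about 50% of
responsive genes bound, a quarter/half shared-peak asymmetry between
conditions, 60% of responses down-regulated); :func:`SimConfig.strong_effect`
is a recovery benchmark with large planted effects (|log2FC| >= 2) and
sparse background binding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .expression import ExpressionTable, nb_exact_test
from .models import (
    GeneModel,
    GeneModelSet,
    Peak,
    PeakSet,
    ValidationError,
)

MIN_GENE_SPACING = 10_000


@dataclass(frozen=True)
class SimConfig:
    """All knobs of one simulation; ``seed`` is mandatory."""

    seed: int
    n_genes: int = 2000
    chrom_sizes: Tuple[Tuple[str, int], ...] = (
        ("chr1", 200_000_000),
        ("chr2", 200_000_000),
    )
    gene_length_range: Tuple[int, int] = (2_000, 20_000)
    # sparse relative to the 50 kb assignment window so one peak binds one gene
    gene_spacing_range: Tuple[int, int] = (100_000, 200_000)
    n_bound_genes: int = 500
    n_responsive_genes: int = 200
    overlap_rho: Optional[float] = 0.2  # P(responsive | bound); None = neutral
    lfc_log_mean: float = np.log(2.0)  # lognormal params of |log2FC|
    lfc_log_sigma: float = 0.35
    lfc_min: float = 1.2  # floor on |log2FC| of responsive genes
    frac_down: float = 0.6  # down-regulated majority
    # baseline expression levels in RPKM-like units (counts scale with gene
    # length); responsive cytokine targets sit above the bulk so planted
    # effects survive the median-offset damping applied by the preprocessing,
    # but not so high that they dominate library size (which would compress
    # fold changes through the per-sample depth normalization)
    mu_background_log_mean: float = np.log(30.0)
    mu_background_log_sigma: float = 1.2
    mu_responsive_log_mean: float = np.log(150.0)
    mu_responsive_log_sigma: float = 0.5
    dispersion: float = 0.05
    n_replicates: int = 3
    peaks_per_bound_gene: float = 1.6  # mean; each bound gene gets >=1
    tss_distance_sigma: float = 15_000.0
    peak_width: int = 500
    amp_treated_log_mean: float = np.log(50.0)
    amp_treated_log_sigma: float = 0.6
    amp_background_log_mean: float = np.log(12.0)
    amp_background_log_sigma: float = 0.5
    amp_untreated_ratio: float = 1.5  # treated amplitudes exceed shared copies
    n_background_peaks: int = 50
    shared_fraction_treated: float = 0.25  # of treated peaks also seen untreated
    shared_fraction_untreated: float = 0.5  # of untreated peaks shared back
    window: int = 50_000
    condition_untreated: str = "untreated"
    condition_treated: str = "treated"

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_bound_genes, self.n_responsive_genes,
            self.n_background_peaks, self.n_replicates,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("counts must be non-negative")
        probs = (
            self.frac_down, self.shared_fraction_treated,
            self.shared_fraction_untreated,
        )
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("probabilities must be in [0, 1]")
        if self.overlap_rho is not None and not 0 <= self.overlap_rho <= 1:
            raise ValidationError("overlap_rho must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if max(self.n_bound_genes, self.n_responsive_genes) > self.n_genes:
            raise ValidationError("bound/responsive counts exceed n_genes")

    @classmethod
    def study_like(cls, seed: int) -> "SimConfig":
        """Default structure mirroring the study's summary statistics."""
        return cls(seed=seed)

    @classmethod
    def strong_effect(cls, seed: int) -> "SimConfig":
        """Recovery benchmark: 1,000 genes, 120 bound, 100 responsive,
        planted |log2FC| >= 2, three replicates, sparse background."""
        return cls(
            seed=seed,
            n_genes=1000,
            n_bound_genes=120,
            n_responsive_genes=100,
            overlap_rho=0.5,
            lfc_min=2.0,
            lfc_log_mean=np.log(2.5),
            lfc_log_sigma=0.25,
            n_background_peaks=50,
        )


def gene_ids(n: int) -> List[str]:
    width = max(4, len(str(max(n - 1, 0))))
    return [f"g{i:0{width}d}" for i in range(n)]


@dataclass
class SimTruth:
    """Planted ground truth: the oracle for recovery tests."""

    bound: List[str]
    responsive: Dict[str, Dict]  # gene -> {"log2fc": float, "direction": str}
    full_signature: List[str]
    compact_signature: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not set(self.compact_signature) <= set(self.full_signature):
            raise ValidationError("compact truth must be a subset of full truth")

    @property
    def bound_set(self) -> set:
        return set(self.bound)

    @property
    def responsive_set(self) -> set:
        return set(self.responsive)

    def to_dict(self) -> dict:
        return {
            "bound": sorted(self.bound),
            "responsive": {
                g: dict(v) for g, v in sorted(self.responsive.items())
            },
            "full_signature": sorted(self.full_signature),
            "compact_signature": sorted(self.compact_signature),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            bound=list(d["bound"]),
            responsive={g: dict(v) for g, v in d["responsive"].items()},
            full_signature=list(d["full_signature"]),
            compact_signature=list(d["compact_signature"]),
        )


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None
                    ) -> GeneModelSet:
    """Place non-overlapping genes with >=10 kb spacing, random strands.

    Genes fill chromosomes in order; an infeasible packing raises.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo_len, hi_len = config.gene_length_range
    lo_sp, hi_sp = config.gene_spacing_range
    if lo_sp < MIN_GENE_SPACING:
        raise ValidationError(f"gene spacing must be >= {MIN_GENE_SPACING} bp")
    chroms = list(config.chrom_sizes)
    genes = []
    ids = gene_ids(config.n_genes)
    ci = 0
    cursor = int(rng.integers(lo_sp, hi_sp + 1))
    for gid in ids:
        length = int(rng.integers(lo_len, hi_len + 1))
        placed = False
        while ci < len(chroms):
            chrom, size = chroms[ci]
            if cursor + length <= size:
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                              start=cursor, end=cursor + length)
                )
                cursor += length + int(rng.integers(lo_sp, hi_sp + 1))
                placed = True
                break
            ci += 1
            cursor = int(rng.integers(lo_sp, hi_sp + 1))
        if not placed:
            raise ValidationError(
                "infeasible packing: genes do not fit the chromosomes"
            )
    return GeneModelSet(genes)


def make_truth(config: SimConfig, rng: Optional[np.random.Generator] = None
               ) -> SimTruth:
    """Sample bound and responsive gene sets and planted fold changes.

    The responsive set is enriched among bound genes according to
    ``overlap_rho`` = P(responsive | bound); ``None`` means independence.
    The full-signature truth is bound AND responsive with |log2FC| above
    the default more-than-twofold bar; the compact truth is filled in by
    :func:`simulate_peaks` once peak amplitudes exist.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    ids = gene_ids(config.n_genes)
    bound = sorted(
        rng.choice(config.n_genes, size=config.n_bound_genes, replace=False)
    )
    bound_ids = [ids[i] for i in bound]
    rho = (
        config.overlap_rho
        if config.overlap_rho is not None
        else config.n_responsive_genes / config.n_genes
    )
    n_overlap = int(round(rho * config.n_bound_genes))
    n_outside = config.n_responsive_genes - n_overlap
    n_unbound = config.n_genes - config.n_bound_genes
    if n_overlap > min(config.n_bound_genes, config.n_responsive_genes):
        raise ValidationError("overlap_rho requests more overlap than feasible")
    if n_outside < 0 or n_outside > n_unbound:
        raise ValidationError("infeasible bound/responsive overlap request")
    unbound_ids = [g for g in ids if g not in set(bound_ids)]
    inside = rng.choice(len(bound_ids), size=n_overlap, replace=False)
    outside = rng.choice(len(unbound_ids), size=n_outside, replace=False)
    responsive_ids = sorted(
        [bound_ids[i] for i in inside] + [unbound_ids[i] for i in outside]
    )
    magnitudes = np.maximum(
        rng.lognormal(config.lfc_log_mean, config.lfc_log_sigma,
                      size=len(responsive_ids)),
        config.lfc_min,
    )
    downs = rng.random(len(responsive_ids)) < config.frac_down
    responsive = {}
    for gid, mag, down in zip(responsive_ids, magnitudes, downs):
        responsive[gid] = {
            "log2fc": float(-mag if down else mag),
            "direction": "down" if down else "up",
        }
    full = sorted(
        g for g in responsive
        if g in set(bound_ids) and abs(responsive[g]["log2fc"]) > 1.0
    )
    return SimTruth(bound=bound_ids, responsive=responsive, full_signature=full)


def simulate_peaks(
    genes: GeneModelSet,
    truth: SimTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PeakSet, PeakSet, pd.DataFrame]:
    """Two-condition peak sets plus per-peak provenance.

    Every bound gene receives at least one treated-condition peak within the
    assignment window; a configured fraction of treated peaks is copied
    (jittered by less than half a peak width, amplitude shrunk) into the
    untreated set, which is then padded with untreated-specific peaks near
    random genes so its own shared fraction matches the config. Background
    peaks land uniformly on the genome, many outside gene windows.

    Also fills ``truth.compact_signature``: responsive-and-bound genes whose
    planted peaks reach the top quartile of treated amplitudes with
    |log2FC| above the more-than-threefold bar.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    if not truth.bound_set <= set(genes.gene_ids):
        raise ValidationError("truth.bound contains unknown gene ids")
    width = config.peak_width
    for chrom, size in config.chrom_sizes:
        if size <= 2 * (config.window + width):
            raise ValidationError("window inconsistent with chromosome bounds")
    chrom_sizes = dict(config.chrom_sizes)
    margin = config.window - width - 1
    if margin <= 0:
        raise ValidationError("peak width incompatible with window")

    treated_peaks: List[Peak] = []
    provenance: List[dict] = []
    best_amp: Dict[str, float] = {}
    n = 0

    def add_treated(chrom: str, start: int, amplitude: float, origin: str,
                    gene_id: str) -> Peak:
        nonlocal n
        n += 1
        peak = Peak(chrom=chrom, start=start, end=start + width,
                    peak_id=f"{config.condition_treated}_peak_{n}",
                    amplitude=float(amplitude))
        treated_peaks.append(peak)
        provenance.append(
            {"peak_id": peak.peak_id, "condition": config.condition_treated,
             "origin": origin, "gene_id": gene_id}
        )
        return peak

    for gid in sorted(truth.bound_set):
        g = genes[gid]
        k = 1 + rng.poisson(max(config.peaks_per_bound_gene - 1.0, 0.0))
        for _ in range(k):
            d = rng.normal(0.0, config.tss_distance_sigma)
            d = int(np.clip(d, -margin, margin))
            start = g.tss + d - width // 2
            start = int(np.clip(start, 0, chrom_sizes[g.chrom] - width))
            amp = rng.lognormal(config.amp_treated_log_mean,
                                config.amp_treated_log_sigma)
            peak = add_treated(g.chrom, start, amp, "bound", gid)
            best_amp[gid] = max(best_amp.get(gid, 0.0), peak.amplitude)

    chrom_names = [c for c, _ in config.chrom_sizes]
    sizes = np.array([chrom_sizes[c] for c in chrom_names], dtype=float)
    chrom_p = sizes / sizes.sum()
    for _ in range(config.n_background_peaks):
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_p)]
        start = int(rng.integers(0, chrom_sizes[chrom] - width))
        amp = rng.lognormal(config.amp_background_log_mean,
                            config.amp_background_log_sigma)
        add_treated(chrom, start, amp, "background", "")

    # shared copies into the untreated condition
    n_shared = int(round(config.shared_fraction_treated * len(treated_peaks)))
    shared_idx = rng.choice(len(treated_peaks), size=n_shared, replace=False)
    untreated_peaks: List[Peak] = []
    m = 0
    for i in sorted(shared_idx):
        src = treated_peaks[i]
        m += 1
        shift = int(rng.integers(-(width // 2 - 1), width // 2))
        start = int(np.clip(src.start + shift, 0,
                            chrom_sizes[src.chrom] - width))
        amp = src.amplitude / config.amp_untreated_ratio * rng.lognormal(0, 0.2)
        peak = Peak(chrom=src.chrom, start=start, end=start + width,
                    peak_id=f"{config.condition_untreated}_peak_{m}",
                    amplitude=float(amp))
        untreated_peaks.append(peak)
        provenance.append(
            {"peak_id": peak.peak_id, "condition": config.condition_untreated,
             "origin": "shared_copy", "gene_id": provenance[i]["gene_id"]}
        )
    # untreated-specific peaks near random genes
    if config.shared_fraction_untreated > 0:
        n_total_untreated = int(round(n_shared / config.shared_fraction_untreated))
    else:
        n_total_untreated = n_shared
    all_ids = genes.gene_ids
    for _ in range(max(n_total_untreated - n_shared, 0)):
        m += 1
        gid = all_ids[rng.choice(len(all_ids))]
        g = genes[gid]
        d = int(np.clip(rng.normal(0.0, config.tss_distance_sigma),
                        -margin, margin))
        start = int(np.clip(g.tss + d - width // 2, 0,
                            chrom_sizes[g.chrom] - width))
        amp = rng.lognormal(config.amp_treated_log_mean - np.log(
            config.amp_untreated_ratio), config.amp_treated_log_sigma)
        peak = Peak(chrom=g.chrom, start=start, end=start + width,
                    peak_id=f"{config.condition_untreated}_peak_{m}",
                    amplitude=float(amp))
        untreated_peaks.append(peak)
        provenance.append(
            {"peak_id": peak.peak_id, "condition": config.condition_untreated,
             "origin": "untreated_specific", "gene_id": gid}
        )

    amps = np.array([p.amplitude for p in treated_peaks])
    if len(amps):
        threshold = float(np.quantile(amps, 0.75))
        compact = sorted(
            g for g in truth.full_signature
            if best_amp.get(g, 0.0) >= threshold
            and abs(truth.responsive[g]["log2fc"]) > np.log2(3.0)
        )
        truth.compact_signature = compact

    prov = pd.DataFrame(
        provenance, columns=["peak_id", "condition", "origin", "gene_id"]
    )
    return (
        PeakSet(config.condition_untreated, untreated_peaks),
        PeakSet(config.condition_treated, treated_peaks),
        prov,
    )


def simulate_expression(
    genes: GeneModelSet,
    truth: SimTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> ExpressionTable:
    """Negative-binomial counts and derived RPKM for both conditions.

    Baseline expression levels (RPKM-like units) are lognormal; responsive
    genes draw from a higher-abundance lognormal so planted effects are not
    swamped by the median offset the preprocessing adds. Expected counts are
    level x gene length in kb, so longer genes accumulate more reads; treated
    means are scaled by the planted fold change. RPKM = count / (gene length
    in kb x sample depth in millions).
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    if config.n_replicates < 2:
        raise ValidationError("need >=2 replicates per condition")
    ids = genes.gene_ids
    n_genes = len(ids)
    responsive = truth.responsive
    level = rng.lognormal(config.mu_background_log_mean,
                          config.mu_background_log_sigma, size=n_genes)
    for i, gid in enumerate(ids):
        if gid in responsive:
            level[i] = rng.lognormal(config.mu_responsive_log_mean,
                                     config.mu_responsive_log_sigma)
    lengths_kb_arr = np.array(
        [(genes[g].end - genes[g].start) / 1000.0 for g in ids]
    )
    mu = level * lengths_kb_arr
    lfc = np.array(
        [responsive.get(g, {}).get("log2fc", 0.0) for g in ids], dtype=float
    )
    mu_treated = mu * np.power(2.0, lfc)
    r = 1.0 / config.dispersion
    samples, conditions, columns = [], {}, {}
    for cond, mu_cond in (
        (config.condition_untreated, mu),
        (config.condition_treated, mu_treated),
    ):
        for rep in range(1, config.n_replicates + 1):
            name = f"{cond}:{rep}"
            counts = rng.negative_binomial(r, r / (r + mu_cond))
            columns[name] = counts
            conditions[name] = cond
            samples.append(name)
    counts = pd.DataFrame(columns, index=pd.Index(ids, name="gene_id"))
    lengths_kb = np.array([(genes[g].end - genes[g].start) / 1000.0 for g in ids])
    depth_m = counts.sum(axis=0).to_numpy() / 1e6
    rpkm = counts / lengths_kb[:, None] / depth_m[None, :]
    return ExpressionTable(
        rpkm=rpkm, sample_conditions=conditions, counts=counts
    )


@dataclass
class SimulatedStudy:
    config: SimConfig
    genes: GeneModelSet
    truth: SimTruth
    peaks_untreated: PeakSet
    peaks_treated: PeakSet
    provenance: pd.DataFrame
    expression: ExpressionTable

    @property
    def contrast(self) -> Tuple[str, str]:
        return (self.config.condition_treated, self.config.condition_untreated)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Run genome -> truth -> peaks -> expression with one master seed."""
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    genes = simulate_genome(config, np.random.default_rng(seeds[0]))
    truth = make_truth(config, np.random.default_rng(seeds[1]))
    untreated, treated, prov = simulate_peaks(
        genes, truth, config, np.random.default_rng(seeds[2])
    )
    expr = simulate_expression(
        genes, truth, config, np.random.default_rng(seeds[3])
    )
    return SimulatedStudy(
        config=config,
        genes=genes,
        truth=truth,
        peaks_untreated=untreated,
        peaks_treated=treated,
        provenance=prov,
        expression=expr,
    )


def null_type_i_error(
    n_reps: int = 2000,
    mu: float = 50.0,
    dispersion: float = 0.1,
    n_per_group: int = 3,
    alpha: float = 0.05,
    seed: int = 11,
) -> float:
    """Empirical type-I error of the built-in NB exact test under its null.

    Simulates a table of ``n_reps`` null genes and tests each with the
    table-level common dispersion, the same path :func:`tfsig.call_degs`
    uses with ``p_source='builtin'``.
    """
    from .expression import common_dispersion

    rng = np.random.default_rng(seed)
    r = 1.0 / dispersion
    p = r / (r + mu)
    a = rng.negative_binomial(r, p, size=(n_reps, n_per_group))
    b = rng.negative_binomial(r, p, size=(n_reps, n_per_group))
    phi = common_dispersion(a, b)
    rejections = sum(
        nb_exact_test(a[i], b[i], dispersion=phi) < alpha
        for i in range(n_reps)
    )
    return rejections / n_reps
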