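import numpy as np
import pandas as pd
import pytest

from tfsig import ExpressionTable, GeneModel, GeneModelSet, Peak, PeakSet


def make_table(rows, samples, conditions, counts=None, pvalues=None,
               transcript_ids=None):
    """Build an ExpressionTable from a dict gene_id -> list of RPKM values."""
    if transcript_ids is None:
        index = pd.Index(list(rows), name="gene_id")
    else:
        index = pd.MultiIndex.from_arrays(
            [list(rows), transcript_ids], names=["gene_id", "transcript_id"]
        )
    rpkm = pd.DataFrame(
        np.array([rows[g] for g in rows], dtype=float),
        index=index, columns=samples,
    )
    counts_df = None
    if counts is not None:
        counts_df = pd.DataFrame(
            np.array([counts[g] for g in counts]), index=index, columns=samples
        )
    pv = {}
    if pvalues is not None:
        pv = {name: pd.Series(vals, index=index) for name, vals in pvalues.items()}
    return ExpressionTable(
        rpkm=rpkm, sample_conditions=dict(zip(samples, conditions)),
        counts=counts_df, pvalues=pv,
    )


@pytest.fixture
def two_condition_samples():
    samples = ["ctrl:1", "ctrl:2", "stim:1", "stim:2"]
    conditions = ["ctrl", "ctrl", "stim", "stim"]
    return samples, conditions


@pytest.fixture
def worked_table(two_condition_samples):
    """Three genes whose preprocessing can be followed by hand:
    pooled median (offset) 4; gA up 13/6, gB flat, gC down 6/14."""
    samples, conditions = two_condition_samples
    return make_table(
        {"gA": [1, 3, 8, 10], "gB": [4, 4, 4, 4], "gC": [10, 10, 2, 2]},
        samples, conditions,
        pvalues={"stim_vs_ctrl": {"gA": 0.01, "gB": 0.9, "gC": 0.02}},
    )


def random_instance(rng, n_peaks=200, n_genes=50, chrom_count=3,
                    span=2_000_000):
    """A random peak/gene instance for oracle comparisons."""
    genes = []
    for i in range(n_genes):
        chrom = f"chr{rng.integers(1, chrom_count + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1_000, 50_000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(
            gene_id=f"g{i}", chrom=chrom, strand=strand,
            start=start, end=start + length,
        ))
    peaks = []
    for i in range(n_peaks):
        chrom = f"chr{rng.integers(1, chrom_count + 2)}"  # some geneless chroms
        start = int(rng.integers(0, span))
        width = int(rng.integers(50, 2_000))
        peaks.append(Peak(
            chrom=chrom, start=start, end=start + width,
            peak_id=f"p{i}", amplitude=float(rng.integers(0, 100)),
        ))
    # GeneModelSet forbids duplicate ids; ids are unique by construction
    return PeakSet("random", peaks), GeneModelSet(genes)


def brute_force_assignment(peaks, genes, window):
    """All-pairs oracle for peak-to-gene assignment (independent of the
    interval-tree implementation)."""
    pairs = set()
    for p in peaks:
        for g in genes:
            if p.chrom != g.chrom:
                continue
            in_body = p.start < g.end and g.start < p.end
            if p.start <= g.tss < p.end:
                d = 0
            elif p.start > g.tss:
                d = p.start - g.tss
            else:
                d = g.tss - (p.end - 1)
            if in_body or d < window:
                pairs.add((p.peak_id, g.gene_id))
    return pairs
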