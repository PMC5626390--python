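"""Readers and writers for the external formats the pipeline touches.

Supported dialects: BED12 and a GTF-like TSV for gene models, BED6 and
ENCODE narrowPeak for ChIP-seq peaks, GMT for gene sets, TSV for expression
tables and signatures, JSON for reports. Everything is converted to 0-based
half-open coordinates on read; output ordering is deterministic so repeated
runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import pandas as pd

from .expression import ExpressionTable
from .models import (
    GeneModel,
    GeneModelSet,
    GeneSetCollection,
    Peak,
    PeakSet,
    Signature,
    SignatureEvidence,
    ValidationError,
)

PathLike = Union[str, Path]

PVALUE_PREFIX = "pvalue:"
SIGNATURE_COLUMNS = [
    "gene_id",
    "tier",
    "fold_change",
    "p_value",
    "best_peak_id",
    "best_amplitude",
    "direction",
    "relation",
]


def _records(path: PathLike):
    """Yield (line_number, fields) for non-empty, non-comment lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_gene_models(path: PathLike, format: str = "bed12") -> GeneModelSet:
    """Read gene models from BED12 (0-based half-open) or a GTF-like TSV
    (1-based inclusive coordinates; start is decremented on read).

    The TSV dialect needs a header with columns gene_id, chrom, strand,
    start, end. Malformed coordinates or strands are reported with their
    line number.
    """
    genes = []
    if format == "bed12":
        for lineno, fields in _records(path):
            if len(fields) < 6:
                raise ValidationError(f"{path}:{lineno}: BED12 needs >=6 columns")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(_make_gene(name, chrom, strand, start, end, path, lineno))
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        required = {"gene_id", "chrom", "strand", "start", "end"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for i, row in frame.iterrows():
            genes.append(
                _make_gene(
                    row["gene_id"],
                    row["chrom"],
                    row["strand"],
                    int(row["start"]) - 1,  # GTF-like 1-based start
                    row["end"],
                    path,
                    i + 2,
                )
            )
    else:
        raise ValidationError(f"unknown gene-model format {format!r}")
    return GeneModelSet(genes)


def _make_gene(name, chrom, strand, start, end, path, lineno) -> GeneModel:
    try:
        start_i, end_i = int(start), int(end)
    except ValueError as exc:
        raise ValidationError(f"{path}:{lineno}: bad coordinates") from exc
    try:
        return GeneModel(
            gene_id=str(name), chrom=str(chrom), strand=str(strand),
            start=start_i, end=end_i,
        )
    except ValidationError as exc:
        raise ValidationError(f"{path}:{lineno}: {exc}") from exc


def write_gene_models(genes: GeneModelSet, path: PathLike) -> None:
    """Write gene models as BED12 (single-block genes)."""
    with open(path, "w") as fh:
        for g in genes:
            size = g.end - g.start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                        g.start, g.end, "0,0,0", 1, f"{size},", "0,",
                    )
                )
                + "\n"
            )


def read_peaks(path: PathLike, format: str = "bed6") -> PeakSet:
    """Read a peak set from BED6 (amplitude = score column) or ENCODE
    10-column narrowPeak (amplitude = signalValue).

    Peaks with a missing/placeholder name get ids "peak_<n>" in file order.
    """
    if format not in ("bed6", "narrowPeak"):
        raise ValidationError(f"unknown peak format {format!r}")
    peaks = []
    n = 0
    for lineno, fields in _records(path):
        n += 1
        min_cols = 10 if format == "narrowPeak" else 5
        if len(fields) < min_cols:
            raise ValidationError(
                f"{path}:{lineno}: {format} needs >={min_cols} columns"
            )
        chrom, start, end = fields[0], fields[1], fields[2]
        name = fields[3] if len(fields) > 3 else ""
        if name in ("", "."):
            name = f"peak_{n}"
        amplitude_field = fields[6] if format == "narrowPeak" else fields[4]
        try:
            amplitude = float(amplitude_field)
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: bad numeric field") from exc
        try:
            peaks.append(
                Peak(chrom=chrom, start=start_i, end=end_i, peak_id=name,
                     amplitude=amplitude)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(Path(path).stem, peaks)


def write_peaks(peaks: PeakSet, path: PathLike, format: str = "bed6") -> None:
    """Write a peak set as BED6 or narrowPeak (amplitude in the matching column)."""
    with open(path, "w") as fh:
        for p in peaks:
            if format == "bed6":
                row = (p.chrom, p.start, p.end, p.peak_id, _fmt(p.amplitude), ".")
            elif format == "narrowPeak":
                row = (
                    p.chrom, p.start, p.end, p.peak_id, 0, ".",
                    _fmt(p.amplitude), -1, -1, (p.end - p.start) // 2,
                )
            else:
                raise ValidationError(f"unknown peak format {format!r}")
            fh.write("\t".join(str(x) for x in row) + "\n")


def _fmt(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else repr(float(x))


def read_expression(
    path: PathLike,
    sample_conditions: Optional[Mapping[str, str]] = None,
) -> ExpressionTable:
    """Read a genes x samples RPKM TSV.

    Expected columns: ``gene_id``, optional ``transcript_id``, numeric sample
    columns, optional raw-count columns named ``count:<sample>``, optional
    precomputed p-value columns named ``pvalue:<treated>_vs_<reference>``.

    Sample -> condition mapping comes from ``sample_conditions`` (a sidecar
    config) or, failing that, from the header convention
    ``<condition>:<replicate>``.
    """
    frame = pd.read_csv(path, sep="\t")
    if "gene_id" not in frame.columns:
        raise ValidationError(f"{path}: missing gene_id column")
    id_cols = ["gene_id"] + (["transcript_id"] if "transcript_id" in frame else [])
    pvalue_cols = [c for c in frame.columns if c.startswith(PVALUE_PREFIX)]
    count_cols = [c for c in frame.columns if c.startswith("count:")]
    sample_cols = [
        c for c in frame.columns if c not in id_cols + pvalue_cols + count_cols
    ]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns")
    if sample_conditions is None:
        sample_conditions = {}
        for c in sample_cols:
            if ":" not in c:
                raise ValidationError(
                    f"{path}: sample column {c!r} lacks a '<condition>:<rep>' "
                    "name and no sample->condition mapping was given"
                )
            sample_conditions[c] = c.split(":", 1)[0]
    else:
        sample_conditions = dict(sample_conditions)
    index = pd.MultiIndex.from_frame(frame[id_cols]) if len(id_cols) == 2 else (
        pd.Index(frame["gene_id"], name="gene_id")
    )
    if index.has_duplicates:
        raise ValidationError(f"{path}: duplicate (gene, transcript) rows")
    rpkm = frame[sample_cols].copy()
    rpkm.index = index
    if (rpkm.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative RPKM values")
    counts = None
    if count_cols:
        counts = frame[count_cols].copy()
        counts.columns = [c.split(":", 1)[1] for c in count_cols]
        counts.index = index
    pvalues: Dict[str, pd.Series] = {}
    for c in pvalue_cols:
        s = frame[c].copy()
        s.index = index
        s.name = None
        pvalues[c[len(PVALUE_PREFIX):]] = s
    return ExpressionTable(
        rpkm=rpkm,
        sample_conditions=sample_conditions,
        counts=counts,
        pvalues=pvalues,
    )


def write_expression(table: ExpressionTable, path: PathLike) -> None:
    """Write an expression table in the TSV dialect :func:`read_expression`
    accepts (counts as ``count:<sample>``, p-values as ``pvalue:<contrast>``)."""
    frame = table.rpkm.reset_index()
    if table.counts is not None:
        for c in table.counts.columns:
            frame[f"count:{c}"] = table.counts[c].to_numpy()
    for name, s in table.pvalues.items():
        frame[f"{PVALUE_PREFIX}{name}"] = s.reindex(table.rpkm.index).to_numpy()
    frame.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated members."""
    sets = {}
    for lineno, fields in _records(path):
        if len(fields) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line has <3 fields")
        name = fields[0]
        members = [f for f in fields[2:] if f]
        if name in sets:
            raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
        if not members:
            raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
        sets[name] = members
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")


def write_signature(signature: Signature, path: PathLike) -> None:
    """Write a signature as TSV sorted by gene_id (header-only if empty)."""
    with open(path, "w") as fh:
        fh.write("\t".join(SIGNATURE_COLUMNS) + "\n")
        for gene_id in sorted(signature.members):
            ev = signature.members[gene_id]
            fh.write(
                "\t".join(
                    [
                        gene_id,
                        signature.tier,
                        repr(float(ev.fold_change)),
                        repr(float(ev.p_value)),
                        ev.best_peak_id,
                        repr(float(ev.best_amplitude)),
                        ev.direction,
                        ev.relation,
                    ]
                )
                + "\n"
            )


def read_signature(path: PathLike) -> Signature:
    """Read a signature TSV written by :func:`write_signature`."""
    frame = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip"
    )
    missing = set(SIGNATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    tiers = set(frame["tier"]) if len(frame) else {"full"}
    if len(tiers) != 1:
        raise ValidationError(f"{path}: mixed tiers {sorted(tiers)}")
    members = {
        row.gene_id: SignatureEvidence(
            fold_change=float(row.fold_change),
            p_value=float(row.p_value),
            direction=row.direction,
            best_peak_id=str(row.best_peak_id),
            best_amplitude=float(row.best_amplitude),
            relation=row.relation,
        )
        for row in frame.itertuples()
    }
    return Signature(tier=next(iter(tiers)), members=members)


def write_report(obj, path: PathLike) -> None:
    """Write a report: DataFrames go to TSV, everything JSON-serializable to
    JSON (by file extension)."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t")
    else:
        raise ValidationError(
            f"cannot write {type(obj).__name__} to {path.suffix or 'no-suffix'} file"
        )


def _jsonable(obj):
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj).__name__}")
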