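"""Readers and writers for every external format the pipeline touches.

Expression tables may be comma- or tab-delimited (the dialect is sniffed from
the header line); internal outputs are always TSV. Gene ids are opaque
strings throughout — numeric-looking protein ids are never parsed as numbers.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    ExpressionMatrix,
    KogAnnotation,
    PromoterSet,
    SampleMetadata,
    SpikeSet,
    ValidationError,
)

logger = logging.getLogger(__name__)


def _sniff_delimiter(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    # Tab wins if present: TSV headers may legitimately contain commas in
    # free-text columns, but a comma-delimited header never contains tabs.
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise ValidationError(f"could not detect delimiter (no tab or comma) in header of {path}")


def read_expression_table(path: str | Path, spike_ids: Iterable[str] = ()) -> ExpressionMatrix:
    """Read a genes x samples signal table (CSV or TSV, sniffed).

    First column holds gene/protein ids; the header row holds sample ids.
    Rows whose id is in ``spike_ids`` are flagged as spike-ins.
    """
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected a gene-id column plus >=1 sample column")
    # pandas mangles duplicate headers to name.1, name.2, ...; detect them.
    raw_header = open(path).readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    for name in raw_header:
        if name in seen:
            raise ValidationError(f"{path}: duplicate sample id in header: {name!r}")
        seen.add(name)
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str)
    if genes.duplicated().any():
        dups = genes[genes.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ids: {dups}")
    values = df.drop(columns=[gene_col])
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric expression value ({exc})") from exc
    values.index = pd.Index(genes, name="gene_id")
    spike_ids = set(spike_ids)
    missing = spike_ids - set(values.index)
    if missing:
        raise ValidationError(f"{path}: spike rows absent from table: {sorted(missing)}")
    flags = pd.Series(values.index.isin(spike_ids), index=values.index)
    return ExpressionMatrix(values=values, spike_flags=flags, scale="raw")


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_sample_sheet(path: str | Path) -> SampleMetadata:
    """Read a TSV sample sheet with columns sample, strain, pH, replicate."""
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype={"sample": str, "strain": str})
    missing = {"sample", "strain", "pH", "replicate"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df = df.set_index("sample")
    return SampleMetadata(table=df[["strain", "pH", "replicate"]])


def write_sample_sheet(meta: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    out = meta.table.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")
    return path


def read_spike_table(path: str | Path, anchor_id: str | None = None) -> SpikeSet:
    """Read a two-column table: spike_id, log10_concentration.

    An optional third boolean-ish column ``anchor`` marks the anchor spike;
    otherwise ``anchor_id`` must be given or match the package default.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype={0: str})
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns spike_id, log10_concentration")
    ids = df.iloc[:, 0].astype(str)
    conc = pd.Series(df.iloc[:, 1].astype(float).to_numpy(), index=ids)
    if anchor_id is None:
        if "anchor" in df.columns:
            marked = ids[df["anchor"].astype(bool).to_numpy()]
            if len(marked) != 1:
                raise ValidationError(f"{path}: exactly one anchor row required, found {len(marked)}")
            anchor_id = marked.iloc[0]
        else:
            from .containers import DEFAULT_ANCHOR_ID

            anchor_id = DEFAULT_ANCHOR_ID
    return SpikeSet(log10_concentration=conc, anchor_id=anchor_id)


def write_spike_table(spikes: SpikeSet, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "spike_id": spikes.spike_ids,
            "log10_concentration": spikes.log10_concentration.to_numpy(),
            "anchor": [sid == spikes.anchor_id for sid in spikes.spike_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_fasta_promoters(path: str | Path) -> PromoterSet:
    """Read promoter FASTA; record id = gene id (first token), uppercased."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gene = record.id
        if gene in sequences:
            raise ValidationError(f"{path}: duplicate FASTA record id {gene!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValidationError(f"{path}: empty sequence for record {gene!r}")
        sequences[gene] = seq
    if not sequences:
        raise ValidationError(f"{path}: no FASTA records found")
    return PromoterSet(sequences=sequences)


def write_fasta_promoters(promoters: PromoterSet, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for gene, seq in promoters.sequences.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


def read_kog_table(path: str | Path, vocabulary: Iterable[str] | None = None) -> KogAnnotation:
    """Read a two-column TSV: gene_id, KOG class(es).

    Multiple classes per gene may appear either as repeated rows or as a
    single cell of concatenated/comma-separated class letters.
    """
    df = pd.read_csv(path, sep=_sniff_delimiter(path), dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns gene_id, kog_class")
    classes: dict[str, set[str]] = {}
    for gene, cell in zip(df.iloc[:, 0], df.iloc[:, 1]):
        gene = str(gene)
        labels = classes.setdefault(gene, set())
        if isinstance(cell, str) and cell.strip():
            for token in cell.replace(",", ""):
                if not token.strip():
                    continue
                labels.add(token)
    kwargs = {}
    if vocabulary is not None:
        kwargs["vocabulary"] = frozenset(vocabulary)
    return KogAnnotation(classes={g: frozenset(s) for g, s in classes.items()}, **kwargs)


def write_kog_table(annotation: KogAnnotation, path: str | Path) -> Path:
    path = Path(path)
    rows = [{"gene_id": g, "kog_class": "".join(sorted(s))} for g, s in annotation.classes.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-id-per-line gene list; blank lines and #-comments ignored."""
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.append(line)
    if not ids:
        raise ValidationError(f"{path}: empty gene list")
    unique = set(ids)
    n_dup = len(ids) - len(unique)
    if n_dup:
        logger.warning("%s: %d duplicate id(s) collapsed (%d -> %d)", path, n_dup, len(ids), len(unique))
    return unique


def write_gene_set(genes: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for g in sorted(genes, key=str):
            fh.write(f"{g}\n")
    return path


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    parameters: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write result tables as TSV plus a JSON run manifest.

    Returns a mapping table-name -> written path; the manifest records input
    parameters, the seed and the package version for reproducibility.
    """
    from . import __version__

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        if not os.access(out_dir, os.W_OK):
            raise PermissionError(out_dir)
    except OSError as exc:
        raise ValidationError(f"unwritable output directory {out_dir}: {exc}") from exc
    paths: dict[str, Path] = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        table.to_csv(path, sep="\t", float_format="%.12g")
        paths[name] = path
    manifest = {
        "tables": {k: str(v) for k, v in paths.items()},
        "parameters": dict(parameters or {}),
        "seed": seed,
        "version": __version__,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    paths["manifest"] = manifest_path
    return paths


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def validate_inputs(
    expression: str | Path | None = None,
    sample_sheet: str | Path | None = None,
    spikes: str | Path | None = None,
    promoters: str | Path | None = None,
    kog: str | Path | None = None,
    spike_ids: Iterable[str] = (),
) -> dict[str, object]:
    """Parse and cross-validate whichever inputs are provided."""
    loaded: dict[str, object] = {}
    if spikes is not None:
        loaded["spikes"] = read_spike_table(spikes)
    if expression is not None:
        sp = loaded.get("spikes")
        ids = list(spike_ids) or (list(sp.spike_ids) if sp is not None else [])
        present = ids
        if ids:
            # Only flag spike rows that exist; full 10-row presence is
            # enforced when normalization is actually requested.
            with open(expression) as fh:
                first_col = {line.split(_sniff_delimiter(expression))[0] for line in fh}
            present = [i for i in ids if i in first_col]
        loaded["expression"] = read_expression_table(expression, spike_ids=present)
    if sample_sheet is not None:
        meta = read_sample_sheet(sample_sheet)
        loaded["samples"] = meta
        if "expression" in loaded:
            meta.check_matches(loaded["expression"], min_replicates=1)
    if promoters is not None:
        loaded["promoters"] = read_fasta_promoters(promoters)
    if kog is not None:
        loaded["kog"] = read_kog_table(kog)
    return loaded
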