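"""Readers and writers for the plain-text formats the pipeline exchanges.

Transients are two-column TSV (``time_s<TAB>fluorescence``), expression data
a counts/intensity TSV with gene-id row names plus a ``sample<TAB>group``
design TSV, promoters FASTA (wrapped at 60 columns, uppercased on read),
annotations two-column gene/term TSVs. All TSV uses UTF-8 and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .ojip import FluorescenceTransient
from .synth import ExpressionMatrix


def read_transient(path, label: str | None = None) -> FluorescenceTransient:
    """Read one two-column transient TSV; times must be strictly increasing."""
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse transient TSV: {exc}") from exc
    if not {"time_s", "fluorescence"} <= set(table.columns):
        raise FormatError(f"{path}: expected columns 'time_s' and 'fluorescence'")
    t = table["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0)) + 2
        raise FormatError(f"{path}: line {bad + 1}: times not strictly increasing")
    try:
        return FluorescenceTransient(
            time=t,
            fluorescence=table["fluorescence"].to_numpy(dtype=float),
            label=label if label is not None else path.stem,
        )
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_transient(transient: FluorescenceTransient, path) -> None:
    pd.DataFrame(
        {"time_s": transient.time, "fluorescence": transient.fluorescence}
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    """Trace manifest: columns ``file, condition`` (+ optional replicate etc.)."""
    table = pd.read_csv(path, sep="\t")
    if not {"file", "condition"} <= set(table.columns):
        raise FormatError(f"{path}: manifest needs 'file' and 'condition' columns")
    return table


def read_expression(counts_path, design_path, mode: str = "rnaseq") -> ExpressionMatrix:
    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = pd.read_csv(design_path, sep="\t")
    if not {"sample", "group"} <= set(design.columns):
        raise FormatError(f"{design_path}: design needs 'sample' and 'group' columns")
    return ExpressionMatrix(
        values=values, design=design.set_index("sample")["group"], mode=mode
    )


def write_expression(matrix: ExpressionMatrix, counts_path, design_path) -> None:
    matrix.values.to_csv(counts_path, sep="\t", index_label="gene")
    matrix.design.rename_axis("sample").rename("group").reset_index().to_csv(
        design_path, sep="\t", index=False
    )


def read_fasta(path) -> tuple[dict[str, str], bool]:
    """FASTA records as {id: uppercase sequence}; flags lowercase input."""
    seqs: dict[str, str] = {}
    had_lowercase = False
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if s != s.upper():
            had_lowercase = True
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seqs[rec.id] = s.upper()
    return seqs, had_lowercase


def write_fasta(seqs: Mapping[str, str] | list[SeqRecord], path) -> None:
    if isinstance(seqs, Mapping):
        records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    else:
        records = list(seqs)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # biopython wraps at 60 columns


def read_two_column_map(path, key: str, value: str) -> dict[str, set[str]]:
    """Generic two-column TSV (e.g. gene->GO term) into a multimap."""
    table = pd.read_csv(path, sep="\t")
    if not {key, value} <= set(table.columns):
        raise FormatError(f"{path}: expected columns {key!r} and {value!r}")
    out: dict[str, set[str]] = {}
    for k, v in zip(table[key], table[value]):
        out.setdefault(str(k), set()).add(str(v))
    return out


def read_motif2tf(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    if not {"motif", "tf_gene"} <= set(table.columns):
        raise FormatError(f"{path}: expected columns 'motif' and 'tf_gene'")
    return dict(zip(table["motif"].astype(str), table["tf_gene"].astype(str)))


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
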