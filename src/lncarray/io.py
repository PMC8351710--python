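"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: FASTA transcript references (with an optional biotype sidecar TSV),
Affymetrix-style probe-tab TSVs, feature x sample expression matrices as TSV,
clinical/survival tables as TSV, GMT gene-set collections, and TSV/JSON stage
outputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Union

import pandas as pd
from Bio import SeqIO
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .reannotation import ProbeRecord, ProbeSetAssignment, TranscriptRecord

PathLike = Union[str, Path]

_PROBE_TAB_ID_COLS = ("probeset_id", "probe set name", "probe_set_id")
_PROBE_TAB_IDX_COLS = ("probe_index", "probe_x", "probe x", "probe x position", "probe_x_position")
_PROBE_TAB_SEQ_COLS = ("probe_sequence", "probe sequence")


def read_transcripts(
    fasta_path: PathLike, biotype_table: Optional[PathLike] = None
) -> List[TranscriptRecord]:
    """Load a transcript reference from FASTA (wrapped or single-line).

    The FASTA id (first whitespace token) is the transcript id.  The optional
    sidecar TSV must carry columns transcript_id, gene_symbol, biotype;
    transcripts absent from the sidecar keep biotype "other".
    """
    meta: Dict[str, tuple] = {}
    if biotype_table is not None:
        side = pd.read_csv(biotype_table, sep="\t", dtype=str).fillna("")
        for _, row in side.iterrows():
            meta[row["transcript_id"]] = (
                row.get("gene_symbol") or None,
                row.get("biotype") or "other",
            )
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        symbol, biotype = meta.get(rec.id, (None, "other"))
        records.append(
            TranscriptRecord(rec.id, str(rec.seq), gene_symbol=symbol, biotype=biotype)
        )
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    return records


def write_transcripts(
    transcripts: Sequence[TranscriptRecord],
    fasta_path: PathLike,
    biotype_table: Optional[PathLike] = None,
    width: int = 70,
) -> None:
    with open(fasta_path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.transcript_id}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")
    if biotype_table is not None:
        pd.DataFrame(
            {
                "transcript_id": [t.transcript_id for t in transcripts],
                "gene_symbol": [t.gene_symbol or "" for t in transcripts],
                "biotype": [t.biotype for t in transcripts],
            }
        ).to_csv(biotype_table, sep="\t", index=False)


def _pick_column(columns: Sequence[str], wanted: Sequence[str], what: str) -> str:
    lower = {c.lower(): c for c in columns}
    for w in wanted:
        if w in lower:
            return lower[w]
    raise ValueError(f"probe-tab file lacks a {what} column (looked for {list(wanted)})")


def read_probe_tab(path: PathLike) -> List[ProbeRecord]:
    """Parse a tab-delimited probe-tab dialect with a header row.

    Requires at minimum a probeset id column, a probe index/x column and a
    probe sequence column; extra columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    id_col = _pick_column(df.columns, _PROBE_TAB_ID_COLS, "probeset id")
    idx_col = _pick_column(df.columns, _PROBE_TAB_IDX_COLS, "probe index")
    seq_col = _pick_column(df.columns, _PROBE_TAB_SEQ_COLS, "probe sequence")
    return [
        ProbeRecord(str(r[id_col]), int(r[idx_col]), str(r[seq_col]))
        for r in df.to_dict("records")
    ]


def write_probe_tab(probes: Sequence[ProbeRecord], path: PathLike) -> None:
    pd.DataFrame(
        {
            "probeset_id": [p.probeset_id for p in probes],
            "probe_index": [p.probe_index for p in probes],
            "probe_sequence": [p.sequence for p in probes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: PathLike) -> pd.DataFrame:
    """Feature x sample log2 matrix: first column feature ids, header row samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"expression matrix {path} contains missing values")
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ValueError(f"expression matrix {path} has duplicate feature or sample ids")
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id")


def read_clinical_table(path: PathLike) -> pd.DataFrame:
    """Clinical TSV keyed by sample_id; empty cells and "NA" are missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "NA"], keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ValueError(f"clinical table {path} lacks a sample_id column")
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError(f"clinical table {path} has duplicate sample ids")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def read_survival_table(path: PathLike) -> pd.DataFrame:
    """Survival TSV: sample_id, time_months, event plus group/covariate columns."""
    df = read_clinical_table(path)
    for col in ("time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table {path} lacks column {col!r}")
    df["time_months"] = df["time_months"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")
    return df


def read_gene_sets(path: PathLike) -> Dict[str, Set[str]]:
    """GMT collection: name, description, tab-separated member symbols."""
    sets = {name: set(genes) for name, genes in _gseapy_read_gmt(str(path)).items()}
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    for name, genes in sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
    return sets


def write_gene_sets(sets: Dict[str, Set[str]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for name in sets:
            fh.write("\t".join([name, "na", *sorted(sets[name])]) + "\n")


def write_assignments(assignments: Sequence[ProbeSetAssignment], path: PathLike) -> None:
    pd.DataFrame(
        {
            "probeset_id": [a.probeset_id for a in assignments],
            "transcript_id": [a.transcript_id or "" for a in assignments],
            "n_probes_total": [a.n_probes_total for a in assignments],
            "n_probes_matched": [a.n_probes_matched for a in assignments],
            "matched_probe_indices": [
                ",".join(map(str, a.matched_probe_indices)) for a in assignments
            ],
            "status": [a.status for a in assignments],
        }
    ).to_csv(path, sep="\t", index=False)


def read_assignments(path: PathLike) -> List[ProbeSetAssignment]:
    df = pd.read_csv(path, sep="\t", dtype={"probeset_id": str, "transcript_id": str})
    out = []
    for r in df.to_dict("records"):
        idxs = r["matched_probe_indices"]
        parsed = tuple(int(i) for i in str(idxs).split(",")) if pd.notna(idxs) and str(idxs) else ()
        tid = r["transcript_id"] if isinstance(r["transcript_id"], str) and r["transcript_id"] else None
        out.append(
            ProbeSetAssignment(
                str(r["probeset_id"]), tid, int(r["n_probes_total"]),
                int(r["n_probes_matched"]), parsed, r["status"],
            )
        )
    return out


def write_json(obj, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(obj)}")
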