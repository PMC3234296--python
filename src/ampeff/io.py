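"""File formats: FASTA amplicons, CSV primer pairs / features / predictions.

All CSVs are comma-separated UTF-8 with a mandatory header row and "."
decimals.  The feature CSV uses the fixed column schema of
:data:`ampeff.seqfeatures.FEATURE_COLUMNS`.
"""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO

from .errors import AmpeffError, SchemaError
from .seqfeatures import FEATURE_COLUMNS, PrimerPair, normalize_sequence

__all__ = [
    "ParseError",
    "read_fasta",
    "read_features_csv",
    "read_primer_pairs",
    "write_features_csv",
    "write_predictions_csv",
]


class ParseError(AmpeffError):
    """An input file is not in the expected format."""


def read_fasta(path) -> dict[str, str]:
    """Read amplicons from FASTA; record ids become amplicon ids."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected a '>' FASTA header, "
                    f"got {line.strip()[:30]!r}"
                )
            break
        else:
            raise ParseError(f"{path}: empty FASTA file")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seqs[rec.id] = normalize_sequence(str(rec.seq), name=f"record {rec.id!r}")
    return seqs


def read_primer_pairs(path) -> dict[str, PrimerPair]:
    """Read primer pairs from a CSV with columns id, forward, reverse."""
    df = pd.read_csv(path, dtype=str)
    missing = {"id", "forward", "reverse"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: primer CSV is missing columns {sorted(missing)}")
    pairs: dict[str, PrimerPair] = {}
    for _, row in df.iterrows():
        pid = str(row["id"])
        if pid in pairs:
            raise ParseError(f"{path}: duplicate primer pair id {pid!r}")
        pairs[pid] = PrimerPair(row["forward"], row["reverse"])
    return pairs


def write_features_csv(features: pd.DataFrame, path) -> None:
    """Write a feature table in the fixed schema (id index as first column)."""
    out = features.copy()
    for col in FEATURE_COLUMNS:
        if col not in out.columns:
            raise SchemaError(f"feature table is missing column {col!r}")
    out.to_csv(path, index=out.index.name is not None)


def read_features_csv(path, require_efficiency: bool = False) -> pd.DataFrame:
    """Read a feature table, checking the covariate schema."""
    df = pd.read_csv(path)
    if "id" in df.columns:
        df = df.set_index("id")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns and c != "efficiency"]
    if missing:
        raise SchemaError(f"{path}: feature CSV is missing columns {missing}")
    if require_efficiency and "efficiency" not in df.columns:
        raise SchemaError(f"{path}: feature CSV has no 'efficiency' column")
    return df


def write_predictions_csv(predictions: pd.DataFrame, path) -> None:
    out = predictions.reset_index(names="id")
    out.to_csv(path, index=False)
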