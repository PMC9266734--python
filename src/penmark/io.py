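"""Reading and writing of CT tables, annotations and result tables.

Dialect: UTF-8 CSV/TSV with a header row (separator inferred from the
file extension, ``.tsv`` = tab).  Undetermined CT values are written as
the literal ``NA``; identifiers are case-sensitive exact strings.
Result tables are TSV with 6-significant-digit floats and a stable column
order, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ANNOTATION_REQUIRED, CT_COLUMNS, CtTable, SampleAnnotation
from .errors import ReconciliationError, SchemaError

__all__ = [
    "load_dataset",
    "load_ct_table",
    "load_annotation",
    "save_ct_table",
    "save_annotation",
    "write_results",
    "write_manifest",
]

_NA = "NA"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path, sep=_sep_for(path), na_values=[_NA], keep_default_na=False
    )


def load_ct_table(path: str | Path) -> CtTable:
    path = Path(path)
    df = _read(path)
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name} is missing required column(s): {', '.join(missing)}",
            columns=missing,
        )
    df["replicate_index"] = df["replicate_index"].astype(int)
    df["ct"] = pd.to_numeric(df["ct"], errors="raise")
    return CtTable(df[CT_COLUMNS + [c for c in df.columns if c not in CT_COLUMNS]])


def load_annotation(path: str | Path) -> SampleAnnotation:
    path = Path(path)
    df = _read(path)
    missing = [c for c in ANNOTATION_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name} is missing required column(s): {', '.join(missing)}",
            columns=missing,
        )
    return SampleAnnotation(df)


def load_dataset(
    ct_path: str | Path, annotation_path: str | Path
) -> tuple[CtTable, SampleAnnotation]:
    """Load and cross-reference a CT table and its sample annotation.

    Every sample in the CT table must have exactly one annotation row and
    vice versa; mismatches raise a :class:`ReconciliationError` listing
    the offending sample ids.
    """
    ct = load_ct_table(ct_path)
    ann = load_annotation(annotation_path)
    ct_samples = set(ct.data["sample_id"])
    ann_samples = set(ann.data.index)
    only_ct = sorted(ct_samples - ann_samples)
    only_ann = sorted(ann_samples - ct_samples)
    if only_ct or only_ann:
        raise ReconciliationError(
            "sample mismatch between CT table and annotation: "
            f"CT-only={only_ct}, annotation-only={only_ann}",
            offenders=only_ct + only_ann,
        )
    return ct, ann


def save_ct_table(ct: CtTable, path: str | Path) -> None:
    path = Path(path)
    ct.data.to_csv(path, sep=_sep_for(path), index=False, na_rep=_NA)


def save_annotation(ann: SampleAnnotation, path: str | Path) -> None:
    path = Path(path)
    ann.data.reset_index().to_csv(path, sep=_sep_for(path), index=False, na_rep=_NA)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as deterministic TSV.

    Floats are formatted to 6 significant digits; column order is taken
    as given; an empty table yields a header-only file.  Identical input
    produces identical bytes.
    """
    if results is None:
        raise ValueError("results table is None")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = results.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(
                lambda v: _NA if pd.isna(v) else f"{v:.6g}"
            )
    df.to_csv(path, sep="\t", index=False, na_rep=_NA, lineterminator="\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    seed: int,
    inputs: list[str | Path],
    outputs: list[str | Path],
    timings: dict[str, float] | None = None,
) -> dict:
    """Write the JSON run manifest (config snapshot, seed, checksums)."""
    from . import __version__

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    manifest = {
        "package": "penmark",
        "version": __version__,
        "seed": int(seed),
        "config": _clean(config),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
        "stage_timings_s": {k: round(v, 3) for k, v in (timings or {}).items()},
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
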