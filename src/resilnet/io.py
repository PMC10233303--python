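"""Readers and writers for the pipeline's text formats.

Abundance matrices are TSV with a protein-id first column ("Symbol|Accession"
or bare symbol) and sample-id header; gene sets use the GMT dialect
(name, description, symbols, tab-delimited); metadata is CSV indexed by
sample id.  Parse errors carry 1-based line numbers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_meta",
    "write_meta",
    "file_sha256",
    "stage_seed",
]

_NA_TOKENS = {"", "NA", "NAN", "NaN", "nan", "na", "N/A", "null", "NULL"}


def read_matrix(path) -> pd.DataFrame:
    """Read a proteins x samples TSV abundance matrix.

    Raises ValueError (with the offending line number) on ragged rows,
    duplicate protein ids, or non-numeric cells; NA tokens and empty
    cells become missing values.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split("\t")
    n_fields = len(header)
    samples = header[1:]
    ids: list[str] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        if ln == "":
            continue
        fields = ln.split("\t")
        if len(fields) != n_fields:
            raise ValueError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        pid = fields[0]
        if pid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate protein id {pid!r}")
        seen.add(pid)
        row = []
        for j, cell in enumerate(fields[1:], start=2):
            if cell.strip() in _NA_TOKENS:
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {j}"
                ) from None
        ids.append(pid)
        data.append(row)
    return pd.DataFrame(data, index=pd.Index(ids, name="protein"), columns=samples)


def write_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", index_label="protein", na_rep="NA")


def read_gmt(path) -> dict[str, dict]:
    """Read a GMT file into {name: {"description": ..., "symbols": set}}.

    Symbols are uppercased and deduplicated; lines with fewer than three
    fields raise a ValueError with the line number.  CRLF endings are
    accepted.
    """
    path = Path(path)
    sets: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\r\n")
            if not ln:
                continue
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc = fields[0], fields[1]
            sets[name] = {
                "description": desc,
                "symbols": {s.upper() for s in fields[2:] if s},
            }
    return sets


def write_gmt(sets: dict, path) -> None:
    with open(path, "w") as fh:
        for name, body in sets.items():
            if isinstance(body, dict):
                desc, syms = body.get("description", ""), body["symbols"]
            else:
                desc, syms = "", body
            fh.write("\t".join([name, desc] + sorted({s.upper() for s in syms})) + "\n")


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index_label="sample_id")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# fixed stage table so reordering stages can never change derived seeds
_STAGE_IDS = {
    "simulate": 11, "preprocess": 22, "network": 33, "associate": 44,
    "enrich": 55, "diffexp": 66, "crossmap": 77, "report": 88,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    if stage not in _STAGE_IDS:
        raise KeyError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_default)
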