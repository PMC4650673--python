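"""Tab-separated table dialect shared by every pipeline stage.

All stage inputs and outputs are UTF-8 TSV: one header line, ``#`` comment
lines ignored, LF or CRLF endings accepted. Floats are serialized with six
significant digits so re-runs produce byte-identical files.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Sequence

import pandas as pd


class TsvParseError(ValueError):
    """Malformed TSV input; the message names the offending 1-based line."""


def read_tsv(path: str | Path | _io.TextIOBase) -> pd.DataFrame:
    """Read a single-header TSV into a DataFrame.

    Comment lines starting with ``#`` are skipped, CRLF is tolerated, and a
    ragged row raises :class:`TsvParseError` naming its line number. Column
    dtypes are inferred per column (int, then float, else str).
    """
    if isinstance(path, _io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()

    header: list[str] | None = None
    rows: list[list[str]] = []
    n_fields = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            n_fields = len(fields)
            continue
        if len(fields) != n_fields:
            raise TsvParseError(
                f"line {lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        rows.append(fields)
    if header is None:
        raise TsvParseError("line 1: missing header line")

    df = pd.DataFrame(rows, columns=header)
    for col in df.columns:
        for caster in (int, float):
            try:
                df[col] = df[col].map(caster)
                break
            except (TypeError, ValueError):
                continue
    return df


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(int(v))
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as the pipeline's TSV dialect (6 sig-digit floats)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-id-per-line file (``#`` comments and blanks skipped)."""
    out = []
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_id_list(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids), encoding="utf-8")
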