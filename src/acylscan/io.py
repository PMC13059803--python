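"""Reading and writing of LFQ tables, ortholog pairs, protein lists and results.

Two LFQ layouts are accepted:

* ``wide`` — one ``protein`` column, then one column per sample named
  ``<condition>_<replicate>`` (e.g. ``H8_2``, ``EV_1``).
* ``long`` — records with columns ``protein, sample, condition, replicate,
  intensity``.

Blank cells and zeros both mean "not detected". Delimiters are inferred from
the file extension (``.tsv`` tab, ``.csv`` comma) unless given explicitly.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping

import pandas as pd

from .matrix import DEFAULT_CONTROL_LABEL, LFQMatrix, SampleDescriptor, ValidationError

_WIDE_COL = re.compile(r"^(?P<condition>.+)_(?P<replicate>\d+)$")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_lfq_table(
    path: str | Path,
    layout: str = "wide",
    control_label: str = DEFAULT_CONTROL_LABEL,
    delimiter: str | None = None,
) -> LFQMatrix:
    """Read a delimited LFQ intensity table into a validated :class:`LFQMatrix`.

    Raises :class:`~acylscan.matrix.ValidationError` on negative intensities,
    duplicate protein ids, malformed sample names, or a missing control
    condition.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    if layout == "wide":
        df = pd.read_csv(path, sep=sep, dtype={0: str})
        protein_col = df.columns[0]
        df = df.set_index(protein_col)
        samples = []
        for col in df.columns:
            m = _WIDE_COL.match(str(col))
            if not m:
                raise ValidationError(
                    f"sample column {col!r} is not of the form <condition>_<replicate>"
                )
            samples.append(
                SampleDescriptor(str(col), m["condition"], int(m["replicate"]))
            )
        values = df.apply(pd.to_numeric, errors="raise").fillna(0.0).astype(float)
    elif layout == "long":
        df = pd.read_csv(path, sep=sep, dtype={"protein": str, "sample": str, "condition": str})
        required = {"protein", "sample", "condition", "replicate", "intensity"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"long layout missing columns: {sorted(missing)}")
        df["intensity"] = pd.to_numeric(df["intensity"], errors="raise").fillna(0.0)
        meta = df.drop_duplicates("sample")[["sample", "condition", "replicate"]]
        samples = [
            SampleDescriptor(str(r.sample), str(r.condition), int(r.replicate))
            for r in meta.itertuples()
        ]
        values = (
            df.pivot_table(
                index="protein", columns="sample", values="intensity", fill_value=0.0
            )
            .reindex(columns=[s.sample_id for s in samples])
        )
        # pivot_table sorts the index; keep first-appearance protein order
        order = df["protein"].drop_duplicates().tolist()
        values = values.reindex(order)
        values.index.name = "protein"
    else:
        raise ValueError(f"unknown layout {layout!r} (expected 'wide' or 'long')")
    return LFQMatrix(values=values, samples=tuple(samples), control_label=control_label)


def write_lfq_table(matrix: LFQMatrix, path: str | Path, layout: str = "wide") -> None:
    """Write an LFQ matrix as delimited text (inverse of :func:`read_lfq_table`)."""
    path = Path(path)
    sep = _delimiter_for(path, None)
    if layout == "wide":
        out = matrix.values.copy()
        out.index.name = "protein"
        out.to_csv(path, sep=sep, float_format="%.6g")
    elif layout == "long":
        records = []
        for s in matrix.samples:
            col = matrix.values[s.sample_id]
            for protein, intensity in col.items():
                records.append(
                    (protein, s.sample_id, s.condition, s.replicate, intensity)
                )
        pd.DataFrame(
            records, columns=["protein", "sample", "condition", "replicate", "intensity"]
        ).to_csv(path, sep=sep, index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_ortholog_pairs(path: str | Path, delimiter: str | None = None) -> set[tuple[str, str]]:
    """Read a two-column ortholog pair table; duplicates collapse to a set.

    Each data line maps an organism-A protein id to an organism-B protein id.
    A line with a missing field raises a :class:`ValidationError` naming it.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(sep)]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValidationError(
                    f"{path.name}:{lineno}: expected two non-empty fields, got {line!r}"
                )
            pairs.add((fields[0], fields[1]))
    return pairs


def read_protein_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line protein list (e.g. a reference substrate set)."""
    out: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            token = raw.strip()
            if token and not token.startswith("#"):
                out.add(token)
    return out


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    manifest: Mapping | None = None,
) -> dict[str, str]:
    """Write named result tables as TSV plus a JSON run manifest.

    Returns a manifest of files written (table name -> path). Column order is
    whatever each table carries, so identical runs produce byte-identical
    headers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for name, table in tables.items():
        dest = out_dir / f"{name}.tsv"
        table.to_csv(dest, sep="\t", index=False)
        written[name] = str(dest)
    if manifest is not None:
        dest = out_dir / "manifest.json"
        with open(dest, "w") as fh:
            json.dump(dict(manifest), fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        written["manifest"] = str(dest)
    return written
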