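"""Reading and writing the pipeline's text formats.

Instrument exports are plain-text files, one per breath sample, with columns
``retention time, absolute intensity[, relative intensity]``; any leading
lines whose first token is not a number are treated as header text and kept
in :attr:`Chromatogram.meta`. Peak-feature tables and study manifests are
plain CSV. All floats are written with 12 significant digits so that
write-then-read is the identity at that precision, locale-independently
(decimal points only).
"""
from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import IO, TYPE_CHECKING

import numpy as np
import pandas as pd

from .types import (
    Chromatogram,
    CONDITIONS,
    ParseError,
    SchemaError,
    StudySample,
    StudySet,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .peaks import PeakTable

#: Column schema of the peak-feature CSV, in writing order.
PEAK_TABLE_COLUMNS = (
    "sample_id",
    "apex_rt_min",
    "height",
    "prominence",
    "width_samples",
    "width_min",
    "area",
    "left_base_rt",
    "right_base_rt",
)

#: Retention times are minutes throughout; anything beyond this smells of seconds.
MAX_PLAUSIBLE_RT_MIN = 120.0

_FLOAT_FMT = "%.12g"


def _try_float(token: str) -> float | None:
    try:
        v = float(token)
    except ValueError:
        return None
    return v if math.isfinite(v) else v  # inf/nan parse fine; validation rejects later


def _tokenise(line: str) -> list[str]:
    # whitespace runs or single commas both act as delimiters
    return line.replace(",", " ").split()


def read_gcms_text(
    source: str | Path | IO[str],
    sample_id: str | None = None,
    rt_seconds: bool = False,
) -> Chromatogram:
    """Read one instrument text export into a validated :class:`Chromatogram`.

    Leading lines whose first whitespace token is not parseable as a number
    are header lines: ``key: value`` lines become ``meta`` entries, any other
    header line is kept verbatim under ``header_<k>`` (k counts header lines,
    1-based). Numeric rows are ``rt  absolute  [relative]`` with whitespace
    or comma delimiters.

    Parameters
    ----------
    source : path or open text stream
    sample_id : str, optional
        Defaults to the file stem, or ``"<stream>"`` for streams.
    rt_seconds : bool
        Interpret the retention-time column as seconds and convert to
        minutes. Without it, files with retention times beyond 120 are
        rejected as probably second-valued.
    """
    if hasattr(source, "read"):
        text = source.read()
        name = sample_id or getattr(source, "name", "<stream>")
    else:
        path = Path(source)
        text = path.read_text()
        name = sample_id or path.stem

    meta: dict[str, str] = {}
    rows: list[tuple[float, ...]] = []
    n_header = 0
    ncols: int | None = None
    in_data = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = _tokenise(line)
        if _try_float(tokens[0]) is None:
            if in_data:
                raise ParseError(f"non-numeric row after data began at line {lineno}: {raw!r}")
            n_header += 1
            if ":" in line:
                key, _, value = line.partition(":")
                meta[key.strip()] = value.strip()
            else:
                meta[f"header_{n_header}"] = line
            continue
        in_data = True
        values = [_try_float(t) for t in tokens]
        if any(v is None for v in values) or len(values) < 2:
            raise ParseError(
                f"data row with fewer than 2 numeric fields at line {lineno}: {raw!r}"
            )
        if ncols is None:
            ncols = min(len(values), 3)
        elif min(len(values), 3) != ncols:
            raise ParseError(f"inconsistent column count at line {lineno}: {raw!r}")
        rows.append(tuple(values[:3]))  # type: ignore[arg-type]

    if len(rows) < 2:
        raise ValidationError(f"empty signal: {name!r} has {len(rows)} numeric rows (need >= 2)")

    arr = np.asarray(rows, dtype=float)
    rt = arr[:, 0]
    if rt_seconds:
        rt = rt / 60.0
    elif rt.max() > MAX_PLAUSIBLE_RT_MIN:
        raise ValidationError(
            f"retention time {rt.max():g} exceeds {MAX_PLAUSIBLE_RT_MIN:g} min; "
            "the file is probably second-valued (pass rt_seconds=True / --rt-seconds)"
        )
    rel = arr[:, 2] if arr.shape[1] > 2 else None
    return Chromatogram(
        sample_id=name, rt=rt, intensity=arr[:, 1], relative_intensity=rel, meta=meta
    )


def write_gcms_text(chrom: Chromatogram, dest: str | Path | IO[str]) -> None:
    """Write a chromatogram back to the instrument text dialect.

    Header lines are emitted from ``meta`` (verbatim for ``header_<k>`` keys,
    ``key: value`` otherwise), then one ``rt<TAB>absolute[<TAB>relative]``
    row per point, 12 significant digits.
    """
    buf = _io.StringIO()
    for key, value in chrom.meta.items():
        if key.startswith("header_"):
            buf.write(f"{value}\n")
        else:
            buf.write(f"{key}: {value}\n")
    rel = chrom.relative_intensity
    for i in range(chrom.n):
        fields = [_FLOAT_FMT % chrom.rt[i], _FLOAT_FMT % chrom.intensity[i]]
        if rel is not None:
            fields.append(_FLOAT_FMT % rel[i])
        buf.write("\t".join(fields) + "\n")
    if hasattr(dest, "write"):
        dest.write(buf.getvalue())
    else:
        Path(dest).write_text(buf.getvalue())


def write_peak_table(table: "PeakTable", dest: str | Path | IO[str]) -> None:
    """Persist a peak table as CSV.

    Detection parameters are echoed as leading ``#`` comment lines, then a
    header row and one row per peak with the columns of
    :data:`PEAK_TABLE_COLUMNS`.
    """
    buf = _io.StringIO()
    for key in ("prominence_min", "width_min", "rel_height"):
        if key in table.params:
            buf.write(f"# {key} = {_FLOAT_FMT % table.params[key]}\n")
    df = table.df.reindex(columns=list(PEAK_TABLE_COLUMNS))
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    if hasattr(dest, "write"):
        dest.write(buf.getvalue())
    else:
        Path(dest).write_text(buf.getvalue())


def read_peak_table(source: str | Path | IO[str]) -> "PeakTable":
    """Read a peak-table CSV written by :func:`write_peak_table`.

    Raises
    ------
    SchemaError
        On unknown or missing columns.
    ParseError
        On a non-numeric cell, naming data row and column.
    """
    from .peaks import PeakTable  # deferred: peaks imports io for persistence

    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()

    params: dict[str, float] = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition("=")
            try:
                params[key.strip()] = float(value)
            except ValueError:
                pass  # unknown comment; ignore
        else:
            body.append(line)

    df = pd.read_csv(_io.StringIO("\n".join(body)), dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(PEAK_TABLE_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown peak-table column(s): {sorted(unknown)}")
    missing = set(PEAK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing peak-table column(s): {sorted(missing)}")
    out = pd.DataFrame({"sample_id": df["sample_id"].astype(str)})
    for col in PEAK_TABLE_COLUMNS[1:]:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].str.strip().str.lower().isin(["nan"])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ParseError(
                f"non-numeric cell at data row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        out[col] = converted.astype(float)
    sample_id = str(out["sample_id"].iloc[0]) if len(out) else ""
    return PeakTable(sample_id=sample_id, df=out, params=params)


def write_manifest(study: StudySet, dest: str | Path, chrom_paths: list[str]) -> None:
    """Write a study manifest CSV with columns path, subject_id, condition."""
    rows = [
        {"path": p, "subject_id": s.subject_id, "condition": s.condition}
        for s, p in zip(study.samples, chrom_paths)
    ]
    pd.DataFrame(rows, columns=["path", "subject_id", "condition"]).to_csv(dest, index=False)


def read_manifest(source: str | Path, rt_seconds: bool = False) -> StudySet:
    """Load a study manifest and every chromatogram it references.

    The manifest is a CSV with columns ``path, subject_id, condition``;
    relative paths resolve against the manifest's directory. All samples
    start with ``qc_pass=True``; QC flagging happens downstream.
    """
    path = Path(source)
    df = pd.read_csv(path, dtype=str)
    required = {"path", "subject_id", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"manifest missing column(s): {sorted(missing)}")
    samples: list[StudySample] = []
    for _, row in df.iterrows():
        cond = str(row["condition"]).strip()
        if cond not in CONDITIONS:
            raise ValidationError(
                f"condition must be one of {CONDITIONS}, got {cond!r} "
                f"for subject {row['subject_id']!r}"
            )
        fpath = Path(row["path"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        if not fpath.exists():
            raise FileNotFoundError(f"chromatogram file not found: {fpath}")
        chrom = read_gcms_text(fpath, rt_seconds=rt_seconds)
        samples.append(
            StudySample(chromatogram=chrom, subject_id=str(row["subject_id"]), condition=cond)
        )
    return StudySet(samples)
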