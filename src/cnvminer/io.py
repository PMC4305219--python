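"""Readers and writers for the plain-text formats of the tool.

The native mining input is the "chr_data" dialect: a whitespace/tab
delimited table, one row per probe in genomic order, first column the
probe ID, remaining columns 0/1 cells, with an optional header row of
sample IDs (detected when the second token of the first line is not a
number).  Intensity tables use the same layout with real-valued cells.
A probe-position table (probe_id, chromosome, bp) and a sample-group
label table (sample_id or index, group) are simple two/three-column TSVs.

Pattern output is one tab-separated line per pattern — chromosome,
direction, start/end probe index (0-based inclusive), size, support count,
support fraction, comma-separated supporting sample indices — sorted
deterministically and written with bare newlines so repeated runs are
byte-identical.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence, TextIO

import numpy as np

from .datatypes import (
    BinaryMatrix,
    Direction,
    IntensityMatrix,
    Interval,
    Pattern,
    ProbeTrack,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_chr_data",
    "write_chr_data",
    "read_intensity",
    "write_intensity",
    "read_probe_track",
    "read_group_labels",
    "write_patterns",
    "read_patterns",
    "PATTERN_HEADER",
]

PATTERN_HEADER = (
    "# cnvminer patterns v1: chromosome\tdirection\tstart_probe\tend_probe\t"
    "size\tsupport_count\tsupport_fraction\tsample_indices (0-based)"
)


class ParseError(ValidationError):
    """Malformed input file; the message names the offending line."""


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _read_table(
    handle: TextIO | str, binary: bool
) -> tuple[list[str], list[str] | None, np.ndarray]:
    """Shared parser: returns (probe_ids, sample_ids or None, values)."""
    if isinstance(handle, str):
        with open(handle, "r", encoding="utf-8") as fh:
            return _read_table(fh, binary)
    probe_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    sample_ids: list[str] | None = None
    width: int | None = None
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) < 2:
            raise ParseError(f"line {lineno}: need a probe ID and at least one cell")
        if not rows and sample_ids is None and not _is_number(toks[1]):
            sample_ids = toks[1:]  # header row
            width = len(sample_ids)
            continue
        if width is None:
            width = len(toks) - 1
        elif len(toks) - 1 != width:
            raise ParseError(
                f"line {lineno}: ragged row ({len(toks) - 1} cells, expected {width})"
            )
        pid = toks[0]
        if pid in seen:
            raise ParseError(f"line {lineno}: duplicate probe ID {pid!r}")
        seen.add(pid)
        vals = []
        for col, tok in enumerate(toks[1:], start=2):
            try:
                v = float(tok)
            except ValueError:
                raise ParseError(
                    f"line {lineno}, column {col}: {tok!r} is not a number"
                ) from None
            if binary and v not in (0.0, 1.0):
                raise ParseError(
                    f"line {lineno}, column {col}: {tok!r} is not a binary 0/1 entry"
                )
            vals.append(v)
        probe_ids.append(pid)
        rows.append(vals)
    if not rows:
        raise ParseError("empty table: no data rows")
    return probe_ids, sample_ids, np.asarray(rows)


def _build_track(
    probe_ids: list[str], track: ProbeTrack | None, chromosome: str
) -> ProbeTrack:
    if track is not None:
        order = {p: i for i, p in enumerate(track.probe_ids)}
        missing = [p for p in probe_ids if p not in order]
        if missing:
            raise ParseError(f"probes absent from position table: {missing[:5]}")
        return ProbeTrack(
            probe_ids,
            [track.chromosome[order[p]] for p in probe_ids],
            [track.position_bp[order[p]] for p in probe_ids],
        )
    return ProbeTrack(probe_ids, chromosome, [1000 * (i + 1) for i in range(len(probe_ids))])


def read_chr_data(
    path: TextIO | str,
    track: ProbeTrack | None = None,
    direction: Direction | str = Direction.GAIN,
    chromosome: str = "chr1",
) -> BinaryMatrix:
    """Read a binarized probe x sample matrix in the chr_data dialect."""
    probe_ids, sample_ids, values = _read_table(path, binary=True)
    return BinaryMatrix(
        values.astype(np.uint8),
        sample_ids=sample_ids,
        track=_build_track(probe_ids, track, chromosome),
        direction=direction,
    )


def write_chr_data(B: BinaryMatrix, stream: TextIO, header: bool = True) -> None:
    """Write a binary matrix back to the chr_data dialect (round-trip safe)."""
    if header:
        stream.write("probe_id\t" + "\t".join(B.sample_ids) + "\n")
    for i, pid in enumerate(B.track.probe_ids):
        stream.write(pid + "\t" + "\t".join(str(int(c)) for c in B.cells[i]) + "\n")


def read_intensity(
    path: TextIO | str,
    track: ProbeTrack | None = None,
    chromosome: str = "chr1",
) -> IntensityMatrix:
    """Read a continuous log-intensity-ratio table (same layout, real cells)."""
    probe_ids, sample_ids, values = _read_table(path, binary=False)
    return IntensityMatrix(
        values,
        sample_ids=sample_ids,
        track=_build_track(probe_ids, track, chromosome),
    )


def write_intensity(X: IntensityMatrix, stream: TextIO, header: bool = True) -> None:
    if header:
        stream.write("probe_id\t" + "\t".join(X.sample_ids) + "\n")
    for i, pid in enumerate(X.track.probe_ids):
        stream.write(
            pid + "\t" + "\t".join(format(v, ".6g") for v in X.values[i]) + "\n"
        )


def read_probe_track(path: TextIO | str) -> ProbeTrack:
    """Read a probe-position table: probe_id, chromosome, bp (TSV)."""
    if isinstance(path, str):
        with open(path, "r", encoding="utf-8") as fh:
            return read_probe_track(fh)
    ids, chroms, pos = [], [], []
    first_row = True
    for lineno, raw in enumerate(path, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 3:
            raise ParseError(f"line {lineno}: expected 'probe_id chrom bp'")
        if first_row and not toks[2].lstrip("-").isdigit():
            first_row = False
            continue  # header
        first_row = False
        try:
            bp = int(toks[2])
        except ValueError:
            raise ParseError(f"line {lineno}: bp {toks[2]!r} is not an integer") from None
        ids.append(toks[0])
        chroms.append(toks[1])
        pos.append(bp)
    if not ids:
        raise ParseError("empty probe-position table")
    return ProbeTrack(ids, chroms, pos)


def read_group_labels(
    path: TextIO | str, sample_ids: Sequence[str] | None = None
) -> list[str]:
    """Read sample group labels (two columns: sample id-or-index, group).

    Returns labels in sample column order.  First columns that are all
    integers are taken as 0-based sample indices; otherwise they are sample
    IDs and ``sample_ids`` must provide the column order.
    """
    if isinstance(path, str):
        with open(path, "r", encoding="utf-8") as fh:
            return read_group_labels(fh, sample_ids)
    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(path, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) != 2:
            raise ParseError(f"line {lineno}: expected 'sample group'")
        pairs.append((toks[0], toks[1]))
    if not pairs:
        raise ParseError("empty label table")
    if all(key.lstrip("-").isdigit() for key, _ in pairs):
        idx = {int(k): g for k, g in pairs}
        nmax = max(idx) + 1
        missing = [i for i in range(nmax) if i not in idx]
        if missing:
            raise ParseError(f"missing labels for sample indices {missing[:5]}")
        return [idx[i] for i in range(nmax)]
    if sample_ids is None:
        raise ParseError("ID-keyed label table requires the sample ID order")
    mapping = dict(pairs)
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ParseError(f"missing labels for samples {missing[:5]}")
    return [mapping[s] for s in sample_ids]


def write_patterns(patterns: Iterable[Pattern], stream: TextIO) -> None:
    """Write patterns, one per line, deterministically ordered.

    Columns: chromosome, direction, start probe, end probe (0-based,
    inclusive), size, support count, support fraction (6 decimals),
    comma-separated 0-based supporting sample indices (ascending).
    """
    stream.write(PATTERN_HEADER + "\n")
    ordered = sorted(
        patterns,
        key=lambda p: (p.interval.chromosome, p.interval.start, p.interval.end,
                       p.direction.value),
    )
    for p in ordered:
        stream.write(
            "\t".join(
                (
                    p.interval.chromosome,
                    p.direction.value,
                    str(p.interval.start),
                    str(p.interval.end),
                    str(p.size),
                    str(p.n_support),
                    format(p.support, ".6f"),
                    ",".join(str(i) for i in p.support_set),
                )
            )
            + "\n"
        )


def patterns_to_text(patterns: Iterable[Pattern]) -> str:
    buf = _io.StringIO()
    write_patterns(patterns, buf)
    return buf.getvalue()


def read_patterns(path: TextIO | str) -> list[Pattern]:
    """Read a pattern file written by :func:`write_patterns`."""
    if isinstance(path, str):
        with open(path, "r", encoding="utf-8") as fh:
            return read_patterns(fh)
    out: list[Pattern] = []
    for lineno, raw in enumerate(path, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split("\t")
        if len(toks) != 8:
            raise ParseError(f"line {lineno}: expected 8 tab-separated fields")
        chrom, direction, start, end, size, count, frac, samples = toks
        support_set = [int(t) for t in samples.split(",")]
        if len(support_set) != int(count):
            raise ParseError(f"line {lineno}: support count does not match indices")
        out.append(
            Pattern(
                Interval(int(start), int(end), chrom),
                support_set,
                support=float(frac),
                direction=direction,
            )
        )
    return out
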