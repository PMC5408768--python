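"""Reading event data and writing basecalls.

Two event sources are supported: a portable tab-separated event table
(columns start, length, mean, stdv, optionally preceded by a
"#read_id=..." comment) and ONT FAST5/HDF5 files carrying an
EventDetection-style events table.  FAST5 start/length values stored in
raw sample counts are converted to seconds using the channel sampling
rate.  Basecalls are written as FASTA (no quality values are produced),
one record per decoded strand, wrapped at 80 columns.

Floats in the portable TSV are written with Python's shortest round-trip
representation, so a write/read cycle preserves values bit-exactly.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .basecall import BasecallResult
from .pore_model import EventSequence

__all__ = [
    "ReadRecord",
    "read_event_table",
    "write_event_table",
    "read_fast5_events",
    "write_fasta",
    "format_fasta",
]

_EVENT_COLUMNS = ("start", "length", "mean", "stdv")


@dataclass
class ReadRecord:
    """One input read: its events and where they came from."""

    read_id: str
    events: EventSequence
    source: str


def read_event_table(path) -> ReadRecord:
    """Parse the portable event TSV.

    The read id defaults to the file stem; a leading "#read_id=NAME" line
    overrides it.  Errors carry 1-based line numbers.
    """
    read_id = os.path.splitext(os.path.basename(str(path)))[0]
    rows = []
    with open(path) as fh:
        lineno = 0
        header = None
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#read_id="):
                    read_id = line[len("#read_id=") :].strip()
                continue
            if header is None:
                header = line.split("\t")
                col = {}
                for c in _EVENT_COLUMNS:
                    if c not in header:
                        raise ValueError(f"{path}:{lineno}: missing column {c!r}")
                    col[c] = header.index(c)
                continue
            parts = line.split("\t")
            try:
                vals = [float(parts[col[c]]) for c in _EVENT_COLUMNS]
            except (ValueError, IndexError):
                raise ValueError(f"{path}:{lineno}: non-numeric or missing cell") from None
            if vals[1] <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive event length")
            rows.append(vals)
    if header is None:
        raise ValueError(f"{path}: empty event table")
    if not rows:
        raise ValueError(f"{path}: event table has no events")
    arr = np.array(rows)
    events = EventSequence(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], read_id)
    return ReadRecord(read_id=read_id, events=events, source=str(path))


def write_event_table(events: EventSequence, path, read_id: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#read_id={read_id or events.read_id}\n")
        fh.write("\t".join(_EVENT_COLUMNS) + "\n")
        for s, l, m, d in zip(events.start, events.length, events.mean, events.stdv):
            fh.write(f"{float(s)!r}\t{float(l)!r}\t{float(m)!r}\t{float(d)!r}\n")


# candidate HDF5 groups holding per-read EventDetection tables; group
# layouts vary across MinKNOW versions, the first match wins
_FAST5_EVENT_GROUPS = (
    "Analyses/EventDetection_000/Reads",
    "Analyses/EventDetection_001/Reads",
    "Raw/Reads",
)
_SAMPLING_RATE_PATHS = ("UniqueGlobalKey/channel_id",)


def read_fast5_events(path) -> ReadRecord:
    """Load an EventDetection events table from a FAST5 (HDF5) file.

    start/length columns with an integer dtype are taken to be raw sample
    counts and divided by the channel sampling rate.
    """
    import h5py

    with h5py.File(path, "r") as f:
        dset = None
        read_id = None
        for group in _FAST5_EVENT_GROUPS:
            if group not in f:
                continue
            g = f[group]
            for name in g:
                node = g[name]
                if isinstance(node, h5py.Group) and "Events" in node:
                    dset = node["Events"][...]
                    read_id = node.attrs.get("read_id", name)
                    break
            if dset is not None:
                break
        if dset is None:
            raise ValueError(f"{path}: no EventDetection events table found")
        for c in _EVENT_COLUMNS:
            if c not in dset.dtype.names:
                raise ValueError(f"{path}: events table lacks column {c!r}")
        start = np.asarray(dset["start"], dtype=float)
        length = np.asarray(dset["length"], dtype=float)
        if np.issubdtype(dset.dtype["start"], np.integer):
            rate = None
            for p in _SAMPLING_RATE_PATHS:
                if p in f and "sampling_rate" in f[p].attrs:
                    rate = float(f[p].attrs["sampling_rate"])
                    break
            if rate is None:
                raise ValueError(f"{path}: raw-sample starts but no sampling_rate attribute")
            start = start / rate
            length = length / rate
    if isinstance(read_id, bytes):
        read_id = read_id.decode()
    events = EventSequence(start, length, np.asarray(dset["mean"], float),
                           np.asarray(dset["stdv"], float), str(read_id))
    return ReadRecord(read_id=str(read_id), events=events, source=str(path))


def format_fasta(result: BasecallResult, width: int = 80) -> str:
    """FASTA text for one basecalled read, one record per decoded strand."""
    out = []
    for strand in ("template", "complement"):
        call = result.strands.get(strand)
        if call is None:
            continue
        out.append(f">{result.read_id}:{strand} model={call.model_name}")
        seq = call.sequence
        out.extend(seq[i : i + width] for i in range(0, len(seq), width))
    return "\n".join(out) + ("\n" if out else "")


def write_fasta(results, fh) -> None:
    for res in results:
        fh.write(format_fasta(res))
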