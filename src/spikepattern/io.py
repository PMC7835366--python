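"""Plain-text readers and writers binding the pipeline stages together.

Spike timestamp files hold one floating-point timestamp (seconds) per line,
sorted ascending, with an optional header line of the form::

    # neuron_id=Wt-003 duration=300.0

The cohort manifest is a tab-separated table with columns
``neuron_id, group, path, duration_s``; the ground-truth table and per-neuron
results are tab-separated as well.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import InvalidTrainError, SpikeTrain

__all__ = [
    "SpikeFileError",
    "read_spike_file",
    "write_spike_file",
    "read_manifest",
    "write_manifest",
    "write_acg_table",
    "write_ddh_table",
]

MANIFEST_COLUMNS = ("neuron_id", "group", "path", "duration_s")


class SpikeFileError(ValueError):
    """Raised for malformed spike timestamp files (with line number)."""


def read_spike_file(
    path: Union[str, Path],
    neuron_id: Optional[str] = None,
    group: Optional[str] = None,
    duration: Optional[float] = None,
) -> SpikeTrain:
    """Parse a timestamp file into a validated :class:`SpikeTrain`.

    The header (if present) supplies ``neuron_id`` and ``duration``; explicit
    arguments win over the header.  Without either, the duration is the last
    timestamp rounded up to the next whole second.

    Raises
    ------
    SpikeFileError
        For empty files, unparseable lines, or unsorted/negative timestamps,
        reporting the offending line number.
    """
    path = Path(path)
    header_id, header_dur = None, None
    times: List[float] = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("neuron_id="):
                        header_id = token.split("=", 1)[1]
                    elif token.startswith("duration="):
                        header_dur = float(token.split("=", 1)[1])
                continue
            try:
                t = float(line)
            except ValueError:
                raise SpikeFileError(
                    f"{path}:{ln}: not a timestamp: {line!r}"
                ) from None
            if t < 0:
                raise SpikeFileError(f"{path}:{ln}: negative timestamp {t}")
            if times and t <= times[-1]:
                raise SpikeFileError(
                    f"{path}:{ln}: timestamps not strictly increasing "
                    f"({t} after {times[-1]})"
                )
            times.append(t)
    if not times:
        raise SpikeFileError(f"{path}: no timestamps found")
    dur = duration if duration is not None else header_dur
    if dur is None:
        dur = float(math.ceil(times[-1])) or 1.0
    nid = neuron_id or header_id or path.stem
    try:
        return SpikeTrain(nid, np.asarray(times), dur, group)
    except InvalidTrainError as exc:
        raise SpikeFileError(f"{path}: {exc}") from exc


def write_spike_file(train: SpikeTrain, path: Union[str, Path]) -> None:
    """Write a train in the one-timestamp-per-line format with a header."""
    path = Path(path)
    # timestamps are serialized at 6 decimals, so round the duration UP at the
    # same precision or a final spike could land past the recorded duration
    dur = math.ceil(train.duration * 1e6) / 1e6
    with path.open("w") as fh:
        fh.write(f"# neuron_id={train.neuron_id} duration={dur:.6f}\n")
        for t in train.timestamps:
            fh.write(f"{t:.6f}\n")


def write_manifest(
    trains: Sequence[SpikeTrain], directory: Union[str, Path]
) -> Path:
    """Write each train to ``directory`` plus a TSV manifest; returns its path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for train in trains:
        fname = f"{train.neuron_id}.txt"
        write_spike_file(train, directory / fname)
        rows.append(
            {
                "neuron_id": train.neuron_id,
                "group": train.group or "",
                "path": fname,
                "duration_s": math.ceil(train.duration * 1e6) / 1e6,
            }
        )
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, sep="\t", index=False
    )
    return manifest


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    """Read a cohort manifest, validating the required columns."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"neuron_id": str, "group": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise SpikeFileError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def write_acg_table(acg, path: Union[str, Path]) -> None:
    """Export an autocorrelogram as (lag_ms, count) TSV for plotting."""
    df = pd.DataFrame(
        {"lag_ms": np.round(acg.lags * 1000.0, 6), "count": acg.counts}
    )
    df.to_csv(path, sep="\t", index=False)


def write_ddh_table(hist, path: Union[str, Path]) -> None:
    """Export a density histogram as (count_value, n_windows) TSV."""
    df = pd.DataFrame(
        {
            "count_value": np.arange(hist.occupancy.size),
            "n_windows": hist.occupancy,
        }
    )
    df.to_csv(path, sep="\t", index=False)
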