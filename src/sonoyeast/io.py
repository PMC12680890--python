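"""On-disk formats: HDF5 waveform containers and CSV feature tables.

One simulation run is stored as a single HDF5 file with one group per
measurement and one float dataset per signal; acquisition and sample
metadata travel as attributes.  A companion CSV index holds one row per
measurement.  Extracted features are written as a flat CSV with one row per
averaged signal, carrying the nine echo features plus the sample labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

from .datasets import FEATURE_COLUMNS, LABEL_COLUMNS
from .processing import AScan, EchoFeatureSet
from .simulate import SampleRecord, SimConfig, Strain

__all__ = [
    "write_simulation",
    "read_simulation",
    "write_feature_table",
    "read_feature_table",
    "features_to_frame",
]


def _group_name(i: int) -> str:
    return f"measurement_{i:04d}"


def write_simulation(
    path: str | Path,
    measurements: Iterable[tuple[SampleRecord, Sequence[AScan]]],
    config: SimConfig,
    index_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Stream measurements into an HDF5 container; return the index table."""
    rows = []
    with h5py.File(path, "w") as h5:
        h5.attrs["sampling_rate"] = config.sampling_rate
        h5.attrs["record_length_ns"] = config.record_length_ns
        h5.attrs["signals_per_measurement"] = config.signals_per_measurement
        h5.attrs["signal_interval_s"] = config.signal_interval_s
        for i, (record, scans) in enumerate(measurements):
            grp = h5.create_group(_group_name(i))
            grp.attrs["measurement_id"] = record.measurement_id
            grp.attrs["strain"] = record.strain.value
            grp.attrs["wort_wt_pct"] = record.wort_wt_pct
            grp.attrs["yeast_wt_pct"] = record.yeast_wt_pct
            grp.attrs["replicate"] = record.replicate
            grp.attrs["true_cell_count"] = record.true_cell_count
            grp.attrs["measured_cell_count"] = record.measured_cell_count
            for scan in scans:
                ds = grp.create_dataset(f"signal_{scan.signal_index:03d}", data=scan.raw)
                ds.attrs["timestamp_s"] = scan.timestamp_s
            rows.append(
                {
                    "group": _group_name(i),
                    "measurement_id": record.measurement_id,
                    "strain": record.strain.value,
                    "wort_wt_pct": record.wort_wt_pct,
                    "yeast_wt_pct": record.yeast_wt_pct,
                    "replicate": record.replicate,
                    "true_cell_count": record.true_cell_count,
                    "measured_cell_count": record.measured_cell_count,
                }
            )
    index = pd.DataFrame(rows)
    if index_csv is not None:
        index.to_csv(index_csv, index=False)
    return index


def read_simulation(path: str | Path) -> Iterator[tuple[SampleRecord, list[AScan]]]:
    """Yield (record, signals) per stored measurement, one at a time."""
    with h5py.File(path, "r") as h5:
        rate = float(h5.attrs["sampling_rate"])
        for gname in sorted(h5.keys()):
            grp = h5[gname]
            record = SampleRecord(
                strain=Strain(grp.attrs["strain"]),
                wort_wt_pct=float(grp.attrs["wort_wt_pct"]),
                yeast_wt_pct=float(grp.attrs["yeast_wt_pct"]),
                replicate=int(grp.attrs["replicate"]),
                true_cell_count=float(grp.attrs["true_cell_count"]),
                measured_cell_count=float(grp.attrs["measured_cell_count"]),
            )
            scans = []
            for k, dname in enumerate(sorted(grp.keys())):
                ds = grp[dname]
                scans.append(
                    AScan(
                        raw=ds[()],
                        sampling_rate=rate,
                        measurement_id=record.measurement_id,
                        signal_index=k,
                        timestamp_s=float(ds.attrs.get("timestamp_s", 0.0)),
                    )
                )
            yield record, scans


def features_to_frame(
    per_measurement: Iterable[tuple[SampleRecord, Sequence[EchoFeatureSet]]],
    collapse: bool = False,
) -> pd.DataFrame:
    """Flatten extracted features into one table, one row per averaged signal.

    With ``collapse=True`` the averaged-signal rows of each measurement are
    mean-pooled into a single row.
    """
    rows = []
    for record, feature_sets in per_measurement:
        for j, fs in enumerate(feature_sets):
            row = {
                "measurement_id": record.measurement_id,
                "signal_index": j,
                "strain": record.strain.value,
                "wort_wt_pct": record.wort_wt_pct,
                "yeast_wt_pct": record.yeast_wt_pct,
                "replicate": record.replicate,
                "measured_cell_count": record.measured_cell_count,
            }
            row.update(dict(zip(FEATURE_COLUMNS, fs.to_array())))
            rows.append(row)
    frame = pd.DataFrame(rows)
    if collapse and not frame.empty:
        keys = [c for c in LABEL_COLUMNS if c != "signal_index"]
        frame = (
            frame.groupby(keys, as_index=False, sort=False)[list(FEATURE_COLUMNS)]
            .mean()
            .assign(signal_index=0)
        )
    return frame.reset_index(drop=True)


def write_feature_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    return frame
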