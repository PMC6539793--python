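"""Readers and writers for the pipeline's text formats.

Everything is plain delimited text: peptide annotation lists (sequence,
modification spec, expected retention time, charges), centroided scan series
in long columnar form (scan_time, mz, intensity), and protein sequences in
FASTA.  mzML ingestion is available behind the same scan-series contract via
pyteomics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import fasta as _fasta

from .chrom import ScanSeries
from .masscalc import ModifiedPeptide, parse_mod_spec

__all__ = [
    "PeptideTarget",
    "read_peptide_list",
    "read_scan_series",
    "read_mzml",
    "read_fasta",
]


@dataclass
class PeptideTarget:
    """One annotated peptide: identity, expected elution, charge range."""

    peptide: ModifiedPeptide
    expected_tr: float  # minutes
    charges: tuple[int, ...]
    feature_id: str = ""


def _parse_charges(spec: str) -> tuple[int, ...]:
    spec = str(spec).strip()
    if ":" in spec:
        lo, hi = spec.split(":")
        return tuple(range(int(lo), int(hi) + 1))
    return tuple(int(z) for z in spec.replace(",", "/").split("/"))


def read_peptide_list(path) -> list[PeptideTarget]:
    """Read a peptide annotation table.

    Expected tab-separated columns: ``sequence``, ``modifications`` (e.g.
    ``K3:AMADORI;C5:CAM``, may be empty), ``tr_min``, ``charges`` (``2:4``,
    ``2/3`` or a single integer) and optional ``feature_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sequence", "modifications", "tr_min", "charges"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide list is missing columns: {sorted(missing)}")
    targets = []
    for _, row in df.iterrows():
        pep = parse_mod_spec(row["sequence"], row["modifications"])
        targets.append(
            PeptideTarget(
                pep,
                float(row["tr_min"]),
                _parse_charges(row["charges"]),
                row.get("feature_id", "") or str(pep),
            )
        )
    return targets


def read_scan_series(path) -> ScanSeries:
    """Read a centroided run from long columnar text.

    Expected tab-separated columns ``scan_time`` (minutes), ``mz``,
    ``intensity``; rows of one scan share the scan time.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"scan_time", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scan series is missing columns: {sorted(missing)}")
    times = np.sort(df["scan_time"].unique())
    grouped = df.groupby("scan_time")
    peaks = [
        grouped.get_group(t)[["mz", "intensity"]].to_numpy(dtype=float) for t in times
    ]
    return ScanSeries(times, peaks)


def write_scan_series(series: ScanSeries, path) -> None:
    rows = []
    for t, centroids in zip(series.times, series.peaks):
        for mz, inten in centroids:
            rows.append((t, mz, inten))
    pd.DataFrame(rows, columns=["scan_time", "mz", "intensity"]).to_csv(
        path, sep="\t", index=False
    )


def read_mzml(path) -> ScanSeries:
    """Read centroided MS1 scans from an mzML file into a ScanSeries."""
    from pyteomics import mzml as _mzml

    times: list[float] = []
    peaks: list[np.ndarray] = []
    with _mzml.MzML(str(path)) as reader:
        for spectrum in reader:
            if spectrum.get("ms level", 1) != 1:
                continue
            scan = spectrum["scanList"]["scan"][0]
            t = float(scan["scan start time"])
            # mzML scan times may be seconds or minutes; unit is carried
            unit = getattr(scan.get("scan start time"), "unit_info", "minute")
            if str(unit).startswith("second"):
                t /= 60.0
            times.append(t)
            peaks.append(
                np.column_stack(
                    [spectrum["m/z array"], spectrum["intensity array"]]
                ).astype(float)
            )
    order = np.argsort(times)
    return ScanSeries(np.asarray(times)[order], [peaks[i] for i in order])


def read_fasta(path) -> dict[str, str]:
    """Read protein sequences; returns {header: sequence}."""
    return {header: seq for header, seq in _fasta.read(str(path))}
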