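"""Reading and writing subject datasets and analysis tables.

A subject is stored as one directory: ``series.tsv`` with one column per
signal, a header row naming the series and a ``# fs=<Hz>`` comment
line, plus ``subject.json`` with node tags, gains, the behavioral score
and seed provenance.  Raw audio can be read from mono WAV files and
generic time series from delimited text with the same sampling-rate
header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .signal_prep import TimeSeries
from .synthetic import SubjectDataset

__all__ = ["write_subject", "read_subject", "write_cohort", "read_cohort", "read_timeseries", "read_wav"]


def write_subject(subject: SubjectDataset, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = {"audio_env": subject.audio_env.values, "lip_area": subject.lip_area.values}
    cols |= {name: ts.values for name, ts in subject.nodes.items()}
    df = pd.DataFrame(cols)
    tsv = path / "series.tsv"
    with open(tsv, "w") as fh:
        fh.write(f"# fs={subject.audio_env.fs}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")
    meta = {
        "subject_id": subject.subject_id,
        "comprehension": subject.comprehension,
        "congruent": subject.congruent,
        "node_kinds": subject.node_kinds,
        "node_gains": subject.node_gains,
        "seed": subject.seed_entropy,
        "fs": subject.audio_env.fs,
    }
    (path / "subject.json").write_text(json.dumps(meta, indent=2))
    return path


def read_subject(path: str | Path) -> SubjectDataset:
    path = Path(path)
    meta = json.loads((path / "subject.json").read_text())
    fs, df = _read_table(path / "series.tsv")
    nodes = {
        name: TimeSeries(df[name].to_numpy(), fs, label=name)
        for name in df.columns
        if name not in ("audio_env", "lip_area")
    }
    return SubjectDataset(
        audio_env=TimeSeries(df["audio_env"].to_numpy(), fs, "audio_env"),
        lip_area=TimeSeries(df["lip_area"].to_numpy(), fs, "lip_area"),
        nodes=nodes,
        node_kinds=meta["node_kinds"],
        node_gains=meta["node_gains"],
        comprehension=meta["comprehension"],
        congruent=meta["congruent"],
        subject_id=meta["subject_id"],
        seed_entropy=meta.get("seed"),
    )


def write_cohort(cohort: list[SubjectDataset], path: str | Path) -> Path:
    path = Path(path)
    for subject in cohort:
        write_subject(subject, path / f"subject_{subject.subject_id:03d}")
    return path


def read_cohort(path: str | Path) -> list[SubjectDataset]:
    dirs = sorted(Path(path).glob("subject_*"))
    if not dirs:
        raise FileNotFoundError(f"no subject_* directories under {path}")
    return [read_subject(d) for d in dirs]


def _read_table(path: Path) -> tuple[float, pd.DataFrame]:
    fs = None
    with open(path) as fh:
        first = fh.readline().strip()
        if first.startswith("#") and "fs=" in first:
            fs = float(first.split("fs=")[1])
        else:
            raise ValueError(f"{path} lacks the '# fs=<Hz>' header line")
        df = pd.read_csv(fh, sep="\t")
    return fs, df


def read_timeseries(path: str | Path, column: str | None = None) -> TimeSeries:
    """Read one column of a delimited text file with a '# fs=' header."""
    fs, df = _read_table(Path(path))
    name = column or df.columns[0]
    return TimeSeries(df[name].to_numpy(), fs, label=name)


def read_wav(path: str | Path) -> TimeSeries:
    """Read a mono WAV file as a float time series."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    return TimeSeries(np.asarray(data, dtype=float), float(fs), label=Path(path).stem)
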