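"""File formats: channel-per-column CSV records, EDF reading, result reports.

The canonical interchange format for records is a CSV with one column per
channel (header row = channel names, "." decimal) plus a JSON sidecar
carrying sampling rate, subject id and label.  EDF is supported read-only,
as an acquisition format from which a channel subset (typically
Fp1/Fpz/Fp2 out of a larger montage) is selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from eegfuse.train import EvalReport
from eegfuse.types import MultichannelRecord


@dataclass
class DatasetManifest:
    """Index of a dataset on disk: one row per record + ordered class names."""

    records: list[tuple[str, str, int, float]]  # (path, subject_id, label, fs)
    label_names: list[str]

    def __post_init__(self) -> None:
        labels = sorted({r[2] for r in self.records})
        if labels and labels != list(range(len(self.label_names))):
            raise ValueError(
                f"labels {labels} are not dense in 0..{len(self.label_names) - 1}"
            )


def read_record_csv(
    path, sampling_rate: float, label: int = 0, subject_id: str | None = None
) -> MultichannelRecord:
    """Load a channel-per-column CSV; header row gives channel names."""
    path = Path(path)
    try:
        # round_trip parser: text -> float64 is exact for %.17g output
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    if frame.shape[1] < 1 or frame.shape[0] < 1:
        raise ValueError(f"{path}: no data rows")
    for col in frame.columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} "
                f"at row {row + 2}, column {col!r}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")
        frame[col] = converted
    return MultichannelRecord(
        data=frame.to_numpy().T,
        sampling_rate=sampling_rate,
        channel_names=[str(c) for c in frame.columns],
        subject_id=subject_id if subject_id is not None else path.stem,
        label=label,
    )


def write_record_csv(record: MultichannelRecord, path, sidecar: bool = True) -> None:
    """Write the canonical CSV plus a JSON sidecar (<stem>.json)."""
    path = Path(path)
    # %.17g guarantees bit-exact float64 round-trips through the text form
    pd.DataFrame(record.data.T, columns=record.channel_names).to_csv(
        path, index=False, float_format="%.17g"
    )
    if sidecar:
        meta = {
            "sampling_rate": record.sampling_rate,
            "subject_id": record.subject_id,
            "label": record.label,
            "channel_names": record.channel_names,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_record_edf(
    path, channel_subset: list[str] | None = None, label: int = 0
) -> MultichannelRecord:
    """Read an EDF file, keeping ``channel_subset`` in the requested order.

    The sampling rate comes from the EDF header; values are returned in
    microvolts.  A missing channel raises with the list of available ones.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = raw.ch_names
    if channel_subset is not None:
        missing = [c for c in channel_subset if c not in available]
        if missing:
            raise KeyError(
                f"channels {missing} not present in {path} (available: {available})"
            )
        raw = raw.pick(channel_subset)
        order = [raw.ch_names.index(c) for c in channel_subset]
    else:
        order = list(range(len(available)))
    data = raw.get_data()[order] * 1e6  # volts -> microvolts
    names = [raw.ch_names[i] for i in order]
    return MultichannelRecord(
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_names=names,
        subject_id=Path(path).stem,
        label=label,
    )


def write_manifest(manifest: DatasetManifest, path) -> None:
    frame = pd.DataFrame(
        manifest.records, columns=["path", "subject_id", "label", "sampling_rate"]
    )
    frame.to_csv(path, index=False)
    Path(path).with_suffix(".labels.json").write_text(json.dumps(manifest.label_names))


def read_manifest(path) -> DatasetManifest:
    frame = pd.read_csv(path)
    labels_path = Path(path).with_suffix(".labels.json")
    if labels_path.exists():
        label_names = json.loads(labels_path.read_text())
    else:
        label_names = [str(i) for i in sorted(frame["label"].unique())]
    records = [
        (str(r.path), str(r.subject_id), int(r.label), float(r.sampling_rate))
        for r in frame.itertuples()
    ]
    missing = [p for p, *_ in records if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    return DatasetManifest(records=records, label_names=label_names)


def load_manifest_records(manifest: DatasetManifest) -> list[MultichannelRecord]:
    out = []
    for path, subject_id, label, fs in manifest.records:
        if str(path).lower().endswith(".edf"):
            rec = read_record_edf(path, label=label)
            rec.subject_id = subject_id
        else:
            rec = read_record_csv(path, fs, label=label, subject_id=subject_id)
        out.append(rec)
    return out


def write_eval_report(report: EvalReport, out_dir, label_names: list[str] | None = None,
                      plots: bool = True) -> dict[str, str]:
    """Serialize an evaluation: metrics JSON, confusion CSV, t-SNE CSV, PNG plots.

    Returns a mapping of artifact kind to written path.  Re-serialization of
    the same report is byte-identical (idempotent).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write-test"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    k = report.confusion.shape[0]
    names = label_names or [f"class{i}" for i in range(k)]
    written = {}

    metrics = {
        "accuracy": report.accuracy,
        "loss": report.loss,
        "n_test": int(report.confusion.sum()),
        "per_class_counts": report.per_class_counts.tolist(),
        "warnings": report.warnings,
    }
    (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    written["metrics"] = str(out_dir / "metrics.json")

    cm = pd.DataFrame(report.confusion, index=names, columns=names)
    cm.to_csv(out_dir / "confusion.csv")
    written["confusion"] = str(out_dir / "confusion.csv")

    if report.tsne_coords is not None:
        pd.DataFrame(report.tsne_coords, columns=["tsne1", "tsne2"]).to_csv(
            out_dir / "tsne.csv", index=False
        )
        written["tsne"] = str(out_dir / "tsne.csv")

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(report.confusion, cmap="Blues")
        for i in range(k):
            for j in range(k):
                ax.text(j, i, str(report.confusion[i, j]), ha="center", va="center")
        ax.set_xticks(range(k), names)
        ax.set_yticks(range(k), names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.tight_layout()
        fig.savefig(out_dir / "confusion.png", dpi=100)
        plt.close(fig)
        written["confusion_png"] = str(out_dir / "confusion.png")

    return written
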