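"""File interchange: HDF5 epoch/RDM containers, CSV RDMs and tables,
BrainVision raw recordings, and long-format result frames.

On-disk layout of the HDF5 epoch container: datasets ``data``
(trials x channels x samples), ``times`` (ms), ``labels``, scalar
``sample_rate`` attribute, plus ``channels`` names and optional masks.
RDMs travel as square CSV with condition ids as header row/column;
feature tables as delimited text with a condition-id column; results as
long-format delimited text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .erp import ContrastResult
from .preprocess import EpochSet
from .rdm import RDM, TimeResolvedRDM
from .rsa import RSATimecourse
from .stats import ClusterResult
from .synthetic import GroundTruth, TrialSequence
from .vp import VarianceDecomposition

__all__ = [
    "save_epochs_h5", "load_epochs_h5",
    "save_time_resolved_rdm_h5", "load_time_resolved_rdm_h5",
    "write_rdm_csv", "read_rdm_csv",
    "read_feature_table",
    "save_design", "load_design", "save_ground_truth_json",
    "read_brainvision", "write_brainvision",
    "timecourse_frame", "contrast_frame", "cluster_frame",
    "decomposition_frame",
]


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    if labels.dtype.kind in "US":
        return np.char.encode(labels.astype(str), "utf-8")
    return labels


def _decode_labels(ds) -> np.ndarray:
    arr = ds[()]
    if arr.dtype.kind == "S":
        return np.char.decode(arr, "utf-8")
    return arr


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def save_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("labels", data=_encode_labels(epochs.labels))
        f.create_dataset(
            "channels",
            data=np.char.encode(np.asarray(epochs.channel_names, dtype=str), "utf-8"),
        )
        f.create_dataset("bad_trials", data=epochs.bad_trials)
        f.create_dataset("bad_channels", data=epochs.bad_channels)
        if epochs.is_catch is not None:
            f.create_dataset("is_catch", data=epochs.is_catch)
        f.attrs["sample_rate"] = epochs.sample_rate


def load_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()],
            times=f["times"][()],
            sample_rate=float(f.attrs["sample_rate"]),
            labels=_decode_labels(f["labels"]),
            channel_names=list(np.char.decode(f["channels"][()], "utf-8")),
            bad_trials=f["bad_trials"][()] if "bad_trials" in f else None,
            bad_channels=f["bad_channels"][()] if "bad_channels" in f else None,
            is_catch=f["is_catch"][()] if "is_catch" in f else None,
        )


def save_time_resolved_rdm_h5(rdm: TimeResolvedRDM, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rdms", data=rdm.dissimilarities)
        f.create_dataset("window_centers_ms", data=rdm.window_centers_ms)
        f.create_dataset(
            "condition_ids",
            data=_encode_labels(np.asarray(rdm.condition_ids)),
        )


def load_time_resolved_rdm_h5(path: str | Path) -> TimeResolvedRDM:
    with h5py.File(path, "r") as f:
        return TimeResolvedRDM(
            dissimilarities=f["rdms"][()],
            window_centers_ms=f["window_centers_ms"][()],
            condition_ids=list(_decode_labels(f["condition_ids"])),
        )


# ---------------------------------------------------------------------------
# CSV RDMs and feature tables
# ---------------------------------------------------------------------------

def write_rdm_csv(rdm: RDM, path: str | Path) -> None:
    """Square CSV with condition ids as header row and index column."""
    pd.DataFrame(
        rdm.matrix, index=rdm.condition_ids, columns=rdm.condition_ids
    ).to_csv(path)


def read_rdm_csv(path: str | Path) -> RDM:
    df = pd.read_csv(path, index_col=0)
    return RDM(df.to_numpy(dtype=float), list(df.columns))


def read_feature_table(
    path: str | Path, id_column: str = "condition", sep: str | None = None
) -> pd.DataFrame:
    """Delimited text -> DataFrame indexed by condition id.

    ``sep=None`` sniffs comma vs tab from the file suffix (.tsv -> tab).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    return df.set_index(id_column)


# ---------------------------------------------------------------------------
# Design + ground truth
# ---------------------------------------------------------------------------

def save_design(design: TrialSequence, path: str | Path) -> None:
    design.to_frame().to_csv(path, index=False)


def load_design(path: str | Path) -> TrialSequence:
    df = pd.read_csv(path)
    return TrialSequence(
        df["block"].to_numpy(), df["condition"].to_numpy(),
        df["is_catch"].to_numpy(),
    )


def save_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    """JSON sidecar of the generator settings (RDMs live in CSV files)."""
    payload = {
        "seed": truth.seed,
        "noise_spatial_scale": truth.noise_spatial_scale,
        "noise_ar": truth.noise_ar,
        "noise_sd": truth.noise_sd,
        "ramp_ms": truth.ramp_ms,
        "features": [
            {"name": f.name, "onset_ms": f.onset_ms, "snr": f.snr}
            for f in truth.features
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def read_brainvision(vhdr_path: str | Path):
    """Read a BrainVision triplet via MNE.

    Returns ``(data_uv, sample_rate, channel_names, events)`` where
    ``events`` is a list of (sample_index, description) marker tuples and
    the data are channels x samples in microvolts.
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    events = [
        (int(round(a["onset"] * raw.info["sfreq"])), a["description"])
        for a in raw.annotations
    ]
    return data, float(raw.info["sfreq"]), list(raw.ch_names), events


def write_brainvision(
    data_uv: np.ndarray,
    sample_rate: float,
    path_stem: str | Path,
    channel_names: Sequence[str] | None = None,
    markers: Sequence[tuple[int, str]] = (),
) -> Path:
    """Write a minimal BrainVision triplet (.vhdr/.vmrk/.eeg).

    Multiplexed IEEE float32, unit microvolt.  ``markers`` are
    (sample_index, description) stimulus markers.  Returns the .vhdr
    path.
    """
    stem = Path(path_stem)
    n_chan, _ = np.asarray(data_uv).shape
    if channel_names is None:
        channel_names = [f"ch{i:02d}" for i in range(n_chan)]
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_chan}",
        f"SamplingInterval={1e6 / sample_rate:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    header += [
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(channel_names)
    ]
    vhdr.write_text("\n".join(header) + "\n", encoding="utf-8")

    marker_lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    marker_lines += [
        f"Mk{k + 2}=Stimulus,{desc},{int(sample) + 1},1,0"
        for k, (sample, desc) in enumerate(markers)
    ]
    vmrk.write_text("\n".join(marker_lines) + "\n", encoding="utf-8")

    np.asarray(data_uv, dtype="<f4").T.ravel().tofile(eeg)
    return vhdr


# ---------------------------------------------------------------------------
# Long-format result frames
# ---------------------------------------------------------------------------

def timecourse_frame(
    timecourses: Sequence[RSATimecourse], subjects: Sequence | None = None
) -> pd.DataFrame:
    """Long-format (subject, predictor, window_ms, statistic) frame."""
    rows = []
    subjects = subjects if subjects is not None else range(len(timecourses))
    for subj, tc in zip(subjects, timecourses):
        vals = np.atleast_2d(tc.values.T).T  # (win, k)
        preds = [tc.predictor] if isinstance(tc.predictor, str) else tc.predictor
        for j, pred in enumerate(preds):
            for w, t in enumerate(tc.window_centers_ms):
                rows.append(
                    {"subject": subj, "predictor": pred, "window_ms": t,
                     "statistic": vals[w, j], "kind": tc.kind}
                )
    return pd.DataFrame(rows)


def contrast_frame(result: ContrastResult) -> pd.DataFrame:
    """Long-format (channel, slice_start, slice_end, z, significant)."""
    rows = []
    edges = result.slice_edges_ms
    for i, ch in enumerate(result.channel_names):
        for k in range(len(edges) - 1):
            rows.append(
                {"channel": ch, "slice_start": edges[k], "slice_end": edges[k + 1],
                 "z": result.z[i, k], "significant": bool(result.mask[i, k])}
            )
    return pd.DataFrame(rows)


def cluster_frame(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        [{"start": c.start, "end": c.end, "cluster_sum": c.cluster_sum,
          "p_corrected": c.p_corrected, "significant": c.significant}
         for c in result.clusters]
    )


def decomposition_frame(decomp: VarianceDecomposition) -> pd.DataFrame:
    """Long-format (window_ms, component, value) frame of UV/SV/R² values."""
    rows = []
    for w, t in enumerate(decomp.window_centers_ms):
        for name, v in decomp.unique.items():
            rows.append({"window_ms": t, "component": f"UV({name})", "value": v[w]})
        for key, v in decomp.shared.items():
            rows.append({"window_ms": t, "component": f"SV({','.join(key)})",
                         "value": v[w]})
        rows.append({"window_ms": t, "component": "R2_full",
                     "value": decomp.full_r2()[w]})
    return pd.DataFrame(rows)
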