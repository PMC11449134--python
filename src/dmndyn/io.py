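"""Data model and readers/writers for signals, channel/event tables, and power tables.

Signals travel as an HDF5 matrix (channels x time, microvolts) with a JSON
sidecar giving the sampling rate and channel order.  Tabular artifacts are
tab-separated UTF-8 text with a header row; lines starting with ``#`` are
provenance comments and are ignored on read.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical 7-network intrinsic-connectivity labels plus the fallback
NETWORK_LABELS = (
    "default",
    "frontoparietal",
    "limbic",
    "ventral-attention",
    "dorsal-attention",
    "somatomotor",
    "visual",
    "unassigned",
)

DMN = "default"
FPN = "frontoparietal"

SUBSYSTEM_LABELS = ("dorsomedial-DMN", "lateral-DMN", "none")

CHANNEL_COLUMNS = ["channel_id", "probe_id", "contact_index", "x_mni", "y_mni", "z_mni"]
EVENT_COLUMNS = ["trial_id", "task", "block", "stim", "stage", "onset_s", "duration_s"]
POWER_COLUMNS = [
    "subject", "electrode", "network", "subsystem", "task", "stage",
    "bin_index", "bin_center_s", "band", "pct_change",
]


@dataclass
class Recording:
    """Multichannel LFP segment: ``samples`` is channels x time in microvolts."""

    samples: np.ndarray
    rate: float
    channel_ids: list[str]

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError("samples must be a 2-D channels x time array")
        if self.samples.shape[1] == 0:
            raise ValidationError("recording has zero samples")
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.channel_ids) != self.samples.shape[0]:
            raise ValidationError("channel_ids length does not match sample rows")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def pick(self, channel_ids: list[str]) -> "Recording":
        idx = [self.channel_ids.index(c) for c in channel_ids]
        return Recording(self.samples[idx], self.rate, list(channel_ids))


@dataclass
class Epoch:
    """One trial cutout spanning both task stages, with wavelet padding.

    Times are relative to the trial's stimulus onset; ``t0_offset_s`` is the
    (negative) time of the first sample.  The pre-trial baseline window
    always precedes the stimulus onset and is shared by both stages.
    ``stage_offsets``/``stage_spans`` give each stage's onset relative to the
    stimulus onset and its analyzed duration.
    """

    trial_id: int
    task: str
    block: int
    stim: int
    samples: np.ndarray
    rate: float
    channel_ids: list[str]
    t0_offset_s: float
    stage_offsets: dict = field(default_factory=dict)
    stage_spans: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset_s + np.arange(self.samples.shape[-1]) / self.rate


def write_signals(rec: Recording, path: str | Path) -> Path:
    """Write a recording as HDF5 (dataset ``samples``) plus a JSON sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"rate": rec.rate, "channel_ids": rec.channel_ids}))
    return path


def read_signals(path: str | Path, sidecar: str | Path | None = None,
                 allow_nan: bool = False) -> Recording:
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar for signal matrix: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("rate", "channel_ids"):
        if key not in meta:
            raise FormatError(f"sidecar {sidecar} lacks required key '{key}'")
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise FormatError(f"{path} has no 'samples' dataset")
        samples = f["samples"][...]
    if not allow_nan and not np.isfinite(samples).all():
        raise FormatError(f"{path} contains non-finite samples (pass allow_nan=True to accept)")
    return Recording(samples, float(meta["rate"]), list(meta["channel_ids"]))


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def validate_channels(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a channel table.

    Adds ``network``/``subsystem``/``status``/``status_reason`` columns when
    absent.  Duplicate channel ids and non-contiguous contact indices within a
    probe are rejected.
    """
    _require_columns(df, CHANNEL_COLUMNS, "channels")
    df = df.copy()
    if df["channel_id"].duplicated().any():
        dupes = df.loc[df["channel_id"].duplicated(), "channel_id"].tolist()
        raise SchemaError(f"duplicate channel_id(s): {dupes}")
    df["contact_index"] = df["contact_index"].astype(int)
    for probe, grp in df.groupby("probe_id"):
        idx = np.sort(grp["contact_index"].to_numpy())
        if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            raise SchemaError(f"contact_index not contiguous within probe {probe}")
    for col, default in [("network", "unassigned"), ("subsystem", "none"),
                         ("status", "ok"), ("status_reason", "")]:
        if col not in df.columns:
            df[col] = default
    df["status_reason"] = df["status_reason"].fillna("")
    return df


def validate_events(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial-events table; rows are sorted by onset with a warning."""
    _require_columns(df, EVENT_COLUMNS, "events")
    df = df.copy()
    if not df["onset_s"].is_monotonic_increasing:
        warnings.warn("event onsets out of order; sorting by onset_s", stacklevel=2)
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
    for c in ("trial_id", "block", "stim"):
        df[c] = df[c].astype(int)
    # stages within a trial must not overlap
    for tid, grp in df.groupby("trial_id"):
        ends = grp["onset_s"].to_numpy() + grp["duration_s"].to_numpy()
        if np.any(grp["onset_s"].to_numpy()[1:] < ends[:-1] - 1e-9):
            raise SchemaError(f"overlapping stages within trial {tid}")
    # every MW/AUT trial carries exactly one stimulus and one response stage
    for tid, grp in df[df["task"].isin(["MW", "AUT"])].groupby("trial_id"):
        stages = sorted(grp["stage"].tolist())
        if stages != ["response", "stimulus"]:
            raise SchemaError(
                f"trial {tid} must have exactly one stimulus and one response stage, got {stages}"
            )
    return df


def validate_power_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, POWER_COLUMNS, "power")
    df = df.copy()
    if not np.isfinite(df["pct_change"].to_numpy(dtype=float)).all():
        raise SchemaError("pct_change contains non-finite values")
    return df


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_channels(path: str | Path) -> pd.DataFrame:
    return validate_channels(_read_tsv(path))


def read_events(path: str | Path) -> pd.DataFrame:
    return validate_events(_read_tsv(path))


def read_power_table(path: str | Path) -> pd.DataFrame:
    return validate_power_table(_read_tsv(path))


def write_tsv(df: pd.DataFrame, path: str | Path, provenance: dict | None = None) -> Path:
    """Write a TSV with an optional ``#``-comment provenance header line."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as f:
        if provenance:
            f.write("# provenance: " + json.dumps(provenance, sort_keys=True) + "\n")
        df.to_csv(f, sep="\t", index=False)
    return path


def write_power_table(df: pd.DataFrame, path: str | Path,
                      provenance: dict | None = None) -> Path:
    return write_tsv(validate_power_table(df), path, provenance)


def expected_power_rows(n_electrodes: int, n_trial_conditions: int, n_stages: int = 2,
                        n_bins: int = 29, n_bands: int = 2) -> int:
    """Row count of a complete long power table (no missing cells)."""
    return n_electrodes * n_trial_conditions * n_stages * n_bins * n_bands
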