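"""Referencing, filtering, resampling, and epoching of depth-electrode signals.

The fixed pipeline order is: channel exclusion -> notch filtering (60 Hz and
harmonics) -> Laplacian local-average re-reference along each probe ->
downsampling to 500 Hz -> trial-stage epoching with wavelet padding.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ValidationError
from .io import Epoch, Recording

logger = logging.getLogger(__name__)

#: default epoch padding: half the support of a 7-cycle wavelet at 4 Hz,
#: rounded up, so edge artifacts stay clear of the baseline window and bin 1
DEFAULT_PAD_S = 2.0


def notch_filter(rec: Recording, base_hz: float = 60.0, n_harmonics: int = 3,
                 q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at ``base_hz`` and its harmonics.

    Each harmonic uses a second-order notch (quality factor ``q``) applied
    forward-backward (``filtfilt``), so there is no group delay.  Harmonics at
    or above the Nyquist frequency are clipped with a warning.
    """
    nyq = rec.rate / 2.0
    out = rec.samples.copy()
    for k in range(1, n_harmonics + 1):
        f = base_hz * k
        if f >= nyq:
            warnings.warn(f"notch harmonic {f:g} Hz >= Nyquist ({nyq:g} Hz); clipped",
                          stacklevel=2)
            break
        b, a = signal.iirnotch(f, q, fs=rec.rate)
        out = signal.filtfilt(b, a, out, axis=-1)
    return Recording(out, rec.rate, list(rec.channel_ids))


def _probe_neighbors(contacts: list[tuple[int, str, bool]], bridge_span: int = 2
                     ) -> dict[str, list[str]]:
    """Neighbor map along one probe.

    ``contacts`` is (contact_index, channel_id, usable) sorted by index.
    For each usable contact the nearest usable contact on each side within
    ``bridge_span`` index steps is taken (bridging across excluded contacts);
    probe-end contacts keep their single neighbor (bipolar).
    """
    neighbors: dict[str, list[str]] = {}
    idx = {c: (cid, ok) for c, cid, ok in contacts}
    for c, cid, ok in contacts:
        if not ok:
            continue
        found = []
        for direction in (-1, +1):
            for step in range(1, bridge_span + 1):
                other = idx.get(c + direction * step)
                if other is not None and other[1]:
                    found.append(other[0])
                    break
        neighbors[cid] = found
    return neighbors


def laplacian_reference(rec: Recording, channels: pd.DataFrame,
                        bridge_span: int = 2) -> tuple[Recording, pd.DataFrame]:
    """Local-average re-reference: out[i] = in[i] - mean(in[neighbors(i)]).

    Neighbors are the adjacent contacts of the same probe; excluded contacts
    are bridged up to ``bridge_span`` index steps.  Usable contacts with no
    usable neighbor are marked excluded (reason ``no-neighbor``).  Excluded
    channels are dropped from the output recording.  Returns the re-referenced
    recording and the updated channel table.
    """
    channels = channels.copy()
    data = {cid: rec.samples[i] for i, cid in enumerate(rec.channel_ids)}
    out_ids: list[str] = []
    out_rows: list[np.ndarray] = []
    for probe, grp in channels.groupby("probe_id", sort=False):
        grp = grp.sort_values("contact_index")
        contacts = [(int(r["contact_index"]), r["channel_id"],
                     r["status"] == "ok" and r["channel_id"] in data)
                    for _, r in grp.iterrows()]
        neighbors = _probe_neighbors(contacts, bridge_span)
        for cid, nbrs in neighbors.items():
            if not nbrs:
                channels.loc[channels["channel_id"] == cid,
                             ["status", "status_reason"]] = ["excluded", "no-neighbor"]
                logger.info("channel %s has no usable neighbor; excluded", cid)
                continue
            out_ids.append(cid)
            out_rows.append(data[cid] - np.mean([data[nb] for nb in nbrs], axis=0))
    if not out_rows:
        raise ValidationError("no referencable channels remain")
    order = [cid for cid in rec.channel_ids if cid in set(out_ids)]
    rows = dict(zip(out_ids, out_rows))
    return (Recording(np.vstack([rows[c] for c in order]), rec.rate, order), channels)


def downsample(rec: Recording, target_hz: float = 500.0) -> Recording:
    """Anti-aliased resampling to ``target_hz`` (polyphase FIR low-pass)."""
    if target_hz > rec.rate:
        raise ValidationError(f"target rate {target_hz} exceeds recording rate {rec.rate}")
    if target_hz == rec.rate:
        return Recording(rec.samples.copy(), rec.rate, list(rec.channel_ids))
    frac = Fraction(target_hz / rec.rate).limit_denominator(1000)
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=-1)
    return Recording(out, target_hz, list(rec.channel_ids))


def epoch(rec: Recording, events: pd.DataFrame, pad_s: float = DEFAULT_PAD_S,
          span_s: float = 15.0, baseline_lead_s: float = 0.5,
          tasks: tuple[str, ...] = ("MW", "AUT")) -> list[Epoch]:
    """Cut one epoch per trial, spanning both task stages.

    The epoch runs from ``baseline_lead + pad`` before the stimulus onset to
    ``min(span, duration) + pad`` after the last analyzed stage onset, so the
    single pre-trial baseline window and the first analysis bin of each stage
    are clear of wavelet edge effects.  Trials too close to the recording
    edges are dropped with a log entry.
    """
    epochs: list[Epoch] = []
    for tid, grp in events[events["task"].isin(tasks)].groupby("trial_id", sort=True):
        stim_rows = grp[grp["stage"] == "stimulus"]
        if len(stim_rows) != 1:
            logger.info("trial %s lacks a unique stimulus stage; dropped", tid)
            continue
        onset0 = float(stim_rows["onset_s"].iloc[0])
        offsets, spans = {}, {}
        for _, ev in grp.iterrows():
            offsets[ev["stage"]] = float(ev["onset_s"]) - onset0
            spans[ev["stage"]] = min(span_s, float(ev["duration_s"]))
        t0 = onset0 - baseline_lead_s - pad_s
        t1 = onset0 + max(off + spans[st] for st, off in offsets.items()) + pad_s
        i0, i1 = int(round(t0 * rec.rate)), int(round(t1 * rec.rate))
        if i0 < 0 or i1 > rec.n_samples:
            logger.info("trial %s outside recording; dropped", tid)
            continue
        first = grp.iloc[0]
        epochs.append(Epoch(
            trial_id=int(tid), task=str(first["task"]), block=int(first["block"]),
            stim=int(first["stim"]), samples=rec.samples[:, i0:i1].copy(),
            rate=rec.rate, channel_ids=list(rec.channel_ids),
            t0_offset_s=-(baseline_lead_s + pad_s),
            stage_offsets=offsets, stage_spans=spans))
    return epochs


def preprocess_recording(rec: Recording, channels: pd.DataFrame, events: pd.DataFrame,
                         notch_base_hz: float = 60.0, n_harmonics: int = 3,
                         target_hz: float = 500.0, pad_s: float = DEFAULT_PAD_S
                         ) -> tuple[list[Epoch], pd.DataFrame]:
    """Full preprocessing chain in the fixed order; returns epochs and the
    updated channel table."""
    usable = channels[channels["status"] == "ok"]
    rec = rec.pick([c for c in rec.channel_ids if c in set(usable["channel_id"])])
    rec = notch_filter(rec, notch_base_hz, n_harmonics)
    rec, channels = laplacian_reference(rec, channels)
    rec = downsample(rec, target_hz)
    return epoch(rec, events, pad_s=pad_s), channels
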