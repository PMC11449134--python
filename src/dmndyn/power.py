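"""Assembly of the long-format band-power table from preprocessed epochs.

One row per (subject, electrode, task, stage, time bin, band), holding the
trial-averaged baseline percent change after trial-level outlier rejection.
This table is the observation unit for all inferential models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import Epoch, validate_power_table
from .spectral import (
    DEFAULT_BANDS, DEFAULT_WINDOWS, BandDefinition, BaselineSpec, OutlierRule,
    WaveletFamily, WindowSpec, build_wavelet_family, epoch_band_bins,
    remove_outlier_trials,
)

logger = logging.getLogger(__name__)


def build_long_power_table(subject: str, epochs: list[Epoch], channels: pd.DataFrame,
                           family: WaveletFamily | None = None,
                           bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
                           baseline: BaselineSpec = BaselineSpec(),
                           windows: WindowSpec = DEFAULT_WINDOWS,
                           outlier_rule: OutlierRule = OutlierRule()) -> pd.DataFrame:
    """Compute the per-electrode trial-averaged percent-change table.

    Trials whose baseline is unusable are dropped with a log entry; outlier
    rejection runs per electrode x band x task x stage cell before averaging.
    Cells with no surviving trial are emitted as absent rows.
    """
    family = family or build_wavelet_family()
    meta = channels.set_index("channel_id")
    # per-(channel, band, task, stage): list of binned trial vectors
    cells: dict[tuple[str, str, str, str], list[np.ndarray]] = {}
    for ep in epochs:
        try:
            per_cell = epoch_band_bins(ep, family, bands, baseline, windows)
        except ValidationError as exc:
            logger.info("trial %s dropped: %s", ep.trial_id, exc)
            continue
        for (band_name, stage), vals in per_cell.items():
            for ci, cid in enumerate(ep.channel_ids):
                cells.setdefault((cid, band_name, ep.task, stage), []).append(vals[ci])

    rows = []
    centers = windows.centers
    for (cid, band_name, task, stage), trials in sorted(cells.items()):
        if cid not in meta.index or meta.loc[cid, "status"] != "ok":
            continue
        mat = np.vstack(trials)
        keep, log = remove_outlier_trials(mat, outlier_rule)
        for entry in log:
            logger.info("subject %s electrode %s %s %s/%s: trial excluded (%s)",
                        subject, cid, band_name, task, stage, entry["rule"])
        kept = mat[keep]
        if kept.shape[0] == 0:
            logger.warning("cell %s/%s/%s/%s lost all trials", cid, band_name, task, stage)
            continue
        means = kept.mean(axis=0)
        net = meta.loc[cid, "network"]
        sub = meta.loc[cid, "subsystem"]
        for b, (val, center) in enumerate(zip(means, centers), start=1):
            rows.append((subject, cid, net, sub, task, stage, b, center,
                         band_name, float(val)))
    df = pd.DataFrame(rows, columns=[
        "subject", "electrode", "network", "subsystem", "task", "stage",
        "bin_index", "bin_center_s", "band", "pct_change"])
    return validate_power_table(df)
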