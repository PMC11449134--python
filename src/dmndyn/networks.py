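"""Electrode-to-network assignment from coordinates and a parcellation point set.

Replaces surface-based atlas lookup with direct coordinate matching against a
labeled point cloud (synthetic or exported from any 7-network atlas): each
electrode takes the modal network label among parcel points within a 5 mm
radius.  Electrodes near DMN/FPN transition zones (both labels within the
radius) are excluded, and DMN electrodes are split into dorsomedial and
lateral-temporal subsystems by anatomical region.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import SchemaError, ValidationError
from .io import DMN, FPN

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_MM = 5.0

#: anatomical regions defining the dorsomedial DMN subsystem
DORSOMEDIAL_REGIONS = frozenset({
    "ventromedial prefrontal cortex",
    "anterior cingulate",
    "superior frontal gyrus",
    "posterior cingulate",
    "posterior parietal",
    "parahippocampal gyrus",
})

#: lateral-temporal regions defining the lateral DMN subsystem
LATERAL_REGIONS = frozenset({
    "middle temporal gyrus",
    "superior temporal sulcus",
    "middle temporal sulcus",
})


def read_parcellation(path) -> pd.DataFrame:
    parc = pd.read_csv(path, sep="\t", comment="#")
    return validate_parcellation(parc)


def validate_parcellation(parc: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("x", "y", "z", "label") if c not in parc.columns]
    if missing:
        raise SchemaError(f"parcellation is missing column(s): {', '.join(missing)}")
    if len(parc) == 0:
        raise ValidationError("empty parcellation")
    return parc


def _coords(df: pd.DataFrame, cols) -> np.ndarray:
    return df[list(cols)].to_numpy(dtype=float)


def assign_network(channels: pd.DataFrame, parcellation: pd.DataFrame,
                   radius_mm: float = DEFAULT_RADIUS_MM) -> pd.DataFrame:
    """Modal parcel label within ``radius_mm`` of each electrode (Euclidean,
    MNI mm); no parcel point in range -> ``unassigned``.

    Modal ties break by smaller mean distance to the tied label's points,
    then lexicographically; the result is invariant to parcel row order.
    """
    parcellation = validate_parcellation(parcellation)
    channels = channels.copy()
    tree = cKDTree(_coords(parcellation, ("x", "y", "z")))
    labels = parcellation["label"].to_numpy()
    pts = _coords(parcellation, ("x", "y", "z"))
    elec = _coords(channels, ("x_mni", "y_mni", "z_mni"))
    hits = tree.query_ball_point(elec, r=radius_mm)
    assigned = []
    for e, idx in enumerate(hits):
        if not idx:
            assigned.append("unassigned")
            continue
        cand = {}
        for i in idx:
            d = np.linalg.norm(pts[i] - elec[e])
            cand.setdefault(labels[i], []).append(d)
        best = sorted(cand.items(),
                      key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])), kv[0]))
        assigned.append(best[0][0])
    channels["network"] = assigned
    return channels


def exclude_transition_zone(channels: pd.DataFrame, parcellation: pd.DataFrame,
                            radius_mm: float = DEFAULT_RADIUS_MM) -> pd.DataFrame:
    """Exclude electrodes with both DMN and FPN parcel points within the
    radius (interlacing borders make these assignments unreliable).  The rule
    is specific to the DMN/FPN pair; proximity to other networks is ignored."""
    parcellation = validate_parcellation(parcellation)
    channels = channels.copy()
    pts = _coords(parcellation, ("x", "y", "z"))
    labels = parcellation["label"].to_numpy()
    tree = cKDTree(pts)
    elec = _coords(channels, ("x_mni", "y_mni", "z_mni"))
    hits = tree.query_ball_point(elec, r=radius_mm)
    for e, idx in enumerate(hits):
        near = {labels[i] for i in idx}
        if DMN in near and FPN in near:
            channels.iloc[e, channels.columns.get_loc("status")] = "excluded"
            channels.iloc[e, channels.columns.get_loc("status_reason")] = "transition-zone"
    return channels


def assign_subsystem(channels: pd.DataFrame, region_column: str = "region"
                     ) -> pd.DataFrame:
    """Split DMN electrodes into dorsomedial vs lateral-temporal subsystems
    from their anatomical region string; unknown regions map to ``none`` with
    a warning."""
    if region_column not in channels.columns:
        raise SchemaError(f"channels table lacks the '{region_column}' column")
    channels = channels.copy()
    subsystems = []
    for _, row in channels.iterrows():
        if row["network"] != DMN:
            subsystems.append("none")
            continue
        region = str(row[region_column]).strip().lower()
        if region in DORSOMEDIAL_REGIONS:
            subsystems.append("dorsomedial-DMN")
        elif region in LATERAL_REGIONS:
            subsystems.append("lateral-DMN")
        else:
            warnings.warn(f"DMN channel {row['channel_id']} has unknown region "
                          f"'{region}'; subsystem set to none", stacklevel=2)
            subsystems.append("none")
    channels["subsystem"] = subsystems
    return channels
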