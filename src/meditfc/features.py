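"""From recordings to labeled feature tables.

Each (subject, state, band, epoch) cell yields four scalar features:

* ``r``   — mean Pearson correlation over the 10 x 10 inter-hemispheric
  (left x right) electrode pairs,
* ``plv`` — mean phase-locking value over the same pairs,
* ``cc``  — mean weighted clustering coefficient of the connectivity graph,
* ``sp``  — characteristic (shortest) path length of that graph.

Feature tables condition on one factor and spread the other:

* state-wise layout: fix a state, columns ``<measure>_<band>`` (16 columns),
* band-wise layout: fix a band, columns ``<measure>_<state>`` (16 columns),
  with epochs paired across states by index and truncated to the
  shortest state, so every row is a complete sample.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import preprocessing as prep
from .connectivity import ConnectivityMatrix, connectivity_matrix
from .graphs import GraphMetrics, compute_graph_metrics, to_weighted_graph
from .synthetic import EEGRecording

MEASURES: tuple[str, ...] = ("r", "plv", "cc", "sp")

#: Which connectivity matrix the graph metrics are computed from.
DEFAULT_GRAPH_SOURCE = "plv"


def summarize_epoch(
    cm_r: ConnectivityMatrix, cm_plv: ConnectivityMatrix, gm: GraphMetrics
) -> dict[str, float]:
    """Collapse one epoch's connectivity into the four scalar features."""
    key = lambda cm: (cm.subject_id, cm.state, cm.band.name, cm.epoch_index)
    if key(cm_r) != key(cm_plv):
        raise ValueError(f"key mismatch between matrices: {key(cm_r)} vs {key(cm_plv)}")
    return {
        "r": float(cm_r.interhemispheric_block().mean()),
        "plv": float(cm_plv.interhemispheric_block().mean()),
        "cc": gm.mean_cc,
        "sp": gm.char_path_length,
    }


def extract_features(
    recording: EEGRecording,
    *,
    epoch_seconds: float = 10.0,
    bands: Sequence[prep.Band] = prep.DEFAULT_BANDS,
    states: Sequence[str] | None = None,
    graph_source: str = DEFAULT_GRAPH_SOURCE,
    threshold_q: float = 1.0,
) -> pd.DataFrame:
    """Tidy per-epoch feature rows for one recording.

    Columns: subject, group, state, band, epoch, r, plv, cc, sp.
    """
    split = (recording.hemisphere_indices("left"), recording.hemisphere_indices("right"))
    segments = prep.segment_states(recording)
    rows = []
    for state, seg in segments.items():
        if states is not None and state not in states:
            continue
        for band in bands:
            for ep in prep.epoch(
                seg,
                recording.sampling_rate,
                epoch_seconds,
                band,
                subject_id=recording.subject_id,
                group=recording.group,
                state=state,
                hemisphere_split=split,
            ):
                cm_r = connectivity_matrix(ep, "correlation")
                cm_plv = connectivity_matrix(ep, "plv")
                source = cm_plv if graph_source == "plv" else cm_r
                gm = compute_graph_metrics(to_weighted_graph(source, threshold_q=threshold_q))
                feats = summarize_epoch(cm_r, cm_plv, gm)
                rows.append(
                    {
                        "subject": recording.subject_id,
                        "group": recording.group,
                        "state": state,
                        "band": band.name,
                        "epoch": ep.epoch_index,
                        **feats,
                    }
                )
    return pd.DataFrame(rows)


def extract_cohort_features(cohort: Iterable[EEGRecording], **kwargs) -> pd.DataFrame:
    """Concatenated per-epoch features for a list of recordings."""
    frames = [extract_features(rec, **kwargs) for rec in cohort]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(
            columns=["subject", "group", "state", "band", "epoch", *MEASURES]
        )
    return pd.concat(frames, ignore_index=True)


def _unstack_wide(sub: pd.DataFrame, varying: str) -> pd.DataFrame:
    indexed = sub.set_index(["subject", "group", "epoch", varying])[list(MEASURES)]
    if indexed.index.duplicated().any():
        raise ValueError("duplicate (subject, epoch) feature cells")
    return indexed.unstack(varying)


def _check_complete(pivot: pd.DataFrame, expected_cols: list[str]) -> None:
    missing_cols = [c for c in expected_cols if c not in pivot.columns]
    if missing_cols:
        raise ValueError(f"feature cells missing entirely: {missing_cols}")
    if pivot[expected_cols].isna().any().any():
        bad = [
            (idx, col)
            for col in expected_cols
            for idx in pivot.index[pivot[col].isna()]
        ]
        raise ValueError(f"incomplete feature sets (subject, epoch) x column: {bad[:20]}")


def build_feature_table(
    features: pd.DataFrame, layout: str, fixed_factor: str
) -> pd.DataFrame:
    """Wide 16-column feature table conditioned on one state or band.

    Returns a frame indexed by (subject, epoch) with a ``group`` column
    plus the 16 feature columns. Incomplete cells raise (no imputation).
    """
    if layout == "statewise":
        sub = features[features["state"] == fixed_factor]
        if sub.empty:
            raise ValueError(f"no rows for state {fixed_factor!r}")
        values = [b.name for b in prep.DEFAULT_BANDS if b.name in set(features["band"])]
        pivot = _unstack_wide(sub, "band")
    elif layout == "bandwise":
        sub = features[features["band"] == fixed_factor]
        if sub.empty:
            raise ValueError(f"no rows for band {fixed_factor!r}")
        # pair epochs across states by index, truncated to the shortest state
        n_min = sub.groupby(["subject", "state"])["epoch"].nunique().groupby("subject").min()
        sub = sub[sub["epoch"] < sub["subject"].map(n_min)]
        values = [s for s in prep.STATE_ORDER if s in set(features["state"])]
        pivot = _unstack_wide(sub, "state")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    pivot.columns = [f"{measure}_{level}" for measure, level in pivot.columns]
    expected = [f"{m}_{v}" for m in MEASURES for v in values]
    _check_complete(pivot, expected)
    out = pivot[expected].reset_index().set_index(["subject", "epoch"])
    return out[["group", *expected]]
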