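"""Stage wiring: from a cohort of time series to maps, optimizations, nulls.

These helpers connect the primitive modules into the analysis order the
method prescribes: z-score -> bipartition -> filter -> agreement component
-> brain-behavior map -> optimize -> temporal null, and the RSS-decile
profile branch feeding the behavior clustering.
"""

from __future__ import annotations

import numpy as np

from framefilter.behavior import cost_mean_abs, edgewise_spearman, residualize
from framefilter.bipartition import BipartitionSeries, binarize, subject_agreement
from framefilter.core import (
    FrameSet,
    edge_time_series,
    pearson_fc,
    rss_amplitude,
    zscore_series,
)
from framefilter.template_filter import rss_decile_bins

__all__ = [
    "cohort_bipartitions", "cohort_full_fc", "cohort_full_agc",
    "true_event_components", "rss_profile_matrix",
]


def cohort_bipartitions(series_by_subject: dict) -> dict:
    """subject -> list of per-run BipartitionSeries (z-score then threshold)."""
    return {
        sid: [binarize(zscore_series(ts)) for ts in runs]
        for sid, runs in series_by_subject.items()
    }


def cohort_full_fc(series_by_subject: dict) -> dict:
    """subject -> run-averaged full Pearson-FC edge vector."""
    out = {}
    for sid, runs in series_by_subject.items():
        out[sid] = np.mean([pearson_fc(ts).vec() for ts in runs], axis=0)
    return out


def cohort_full_agc(bps_by_subject: dict) -> dict:
    """subject -> run-averaged all-frames corrected agreement edge vector."""
    out = {}
    for sid, runs in bps_by_subject.items():
        frames = [FrameSet.full(b.n_frames) for b in runs]
        out[sid] = subject_agreement(runs, frames)
    return out


def true_event_components(dataset) -> dict:
    """subject -> AGc edge vector built from the recorded true event frames.

    Runs without any recorded event fall back to the full frame set so the
    component stays defined.
    """
    bps = cohort_bipartitions(dataset.series)
    out = {}
    for sid, runs in bps.items():
        ev = dataset.truth["event_frames"][sid]
        frames = [
            FrameSet(indices=e, T=b.n_frames) if len(e) else FrameSet.full(b.n_frames)
            for e, b in zip(ev, runs)
        ]
        out[sid] = subject_agreement(runs, frames)
    return out


def rss_profile_matrix(
    series_by_subject: dict,
    behaviors: "pd.DataFrame",
    confounds=None,
) -> np.ndarray:
    """Behaviors x 10 matrix of mean |brain-behavior rho| per RSS decile.

    For each run, frames are sorted into RSS deciles; per-subject decile
    AGcs are averaged across runs, correlated edgewise with each behavior
    across subjects, and summarized by mean |rho| -- one amplitude profile
    per behavior (bin 1 = highest RSS).
    """
    bps_by_subject = cohort_bipartitions(series_by_subject)
    decile_vecs = {}  # subject -> list of 10 edge vectors
    for sid, runs in series_by_subject.items():
        per_run = []
        for ts, bps in zip(runs, bps_by_subject[sid]):
            ets = edge_time_series(zscore_series(ts))
            bins = rss_decile_bins(rss_amplitude(ets))
            per_run.append([subject_agreement([bps], [b]) for b in bins])
        decile_vecs[sid] = [
            np.mean([run[d] for run in per_run], axis=0) for d in range(10)
        ]

    ids = list(series_by_subject)
    C = confounds.loc[ids].to_numpy(dtype=float) if confounds is not None else None
    profiles = []
    for name in behaviors.columns:
        beh = behaviors.loc[ids, name].to_numpy(dtype=float)
        beh = residualize(beh, C)
        row = []
        for d in range(10):
            comp = np.vstack([decile_vecs[sid][d] for sid in ids])
            row.append(cost_mean_abs(edgewise_spearman(comp, beh)))
        profiles.append(row)
    return np.asarray(profiles)
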