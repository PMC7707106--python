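"""Event-specific-rate (ESR) analysis for the multi-lap loop task.

A cell recorded over ``t`` trials of ``n`` laps of an ``l``-bin loop is
summarized by its ESR vector: trial-average the activity, average across laps
to get the spatial profile, find the spatial peak bin ``s``, subtract the
spatial profile from each lap's profile (model-corrected activity), and read
off the MC activity at ``s``.  A cell whose activity factorizes into
(spatial profile) x (constant over laps) has an exactly zero ESR vector.

Cells are classified non-spatial when peak |ESR| / peak spatial activity
exceeds 1.25 (strict inequality).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

NONSPATIAL_RATIO = 1.25


@dataclasses.dataclass
class LapActivity:
    """Activity tensor (trials, laps, positions); defaults 15 x 4 x 8."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("LapActivity needs (trials, laps, positions)")
        if np.any(self.values < 0):
            raise ValueError("activity must be nonnegative")

    @property
    def n_laps(self):
        return self.values.shape[1]


@dataclasses.dataclass
class ESRVector:
    values: np.ndarray            # (n_laps,) MC activity at the peak bin
    peak_bin: int
    spatial_profile: np.ndarray   # (positions,) lap-average
    valid: bool = True


def esr_activity(act: LapActivity) -> ESRVector:
    """The five-step ESR procedure (trial average -> spatial profile ->
    peak bin -> model-corrected activity -> MC at peak)."""
    lap_profile = act.values.mean(axis=0)              # (laps, positions)
    spatial = lap_profile.mean(axis=0)                 # (positions,)
    if spatial.max() <= 0:
        return ESRVector(np.zeros(act.n_laps), -1, spatial, valid=False)
    s = int(np.argmax(spatial))
    mc = lap_profile - spatial[None, :]
    return ESRVector(mc[:, s].copy(), s, spatial)


def classify_nonspatial(esr: ESRVector,
                        ratio: float = NONSPATIAL_RATIO) -> bool:
    """True iff max |ESR| / max spatial activity > ratio (strict)."""
    if not esr.valid or esr.spatial_profile.max() <= 0:
        raise ValueError("undefined spatial peak (all-zero activity)")
    return bool(np.max(np.abs(esr.values)) /
                esr.spatial_profile.max() > ratio)


def _corr(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.std() < 1e-12 or b.std() < 1e-12:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def esr_remap_analysis(pop_a: Sequence[LapActivity],
                       pop_b: Sequence[LapActivity],
                       n_shuffles: int = 1000, seed: int = 0):
    """Across-environment preservation of lap specificity.

    For matched cells in two environments, correlates ESR vectors (lap
    specificity) and spatial profiles (spatial code) across environments;
    the shuffle null permutes cell identity in the second environment.
    Returns (per-cell DataFrame, summary dict with the shuffle null and
    active/ESR-cell overlap proportions)."""
    if len(pop_a) != len(pop_b):
        raise ValueError("populations must contain the same cells")
    esr_a = [esr_activity(a) for a in pop_a]
    esr_b = [esr_activity(b) for b in pop_b]
    rows = []
    for i, (ea, eb) in enumerate(zip(esr_a, esr_b)):
        nonsp_a = classify_nonspatial(ea) if ea.valid else False
        nonsp_b = classify_nonspatial(eb) if eb.valid else False
        rows.append({
            "cell_id": i,
            "esr_corr": _corr(ea.values, eb.values),
            "spatial_corr": _corr(ea.spatial_profile, eb.spatial_profile),
            "nonspatial_env1": nonsp_a, "nonspatial_env2": nonsp_b,
            "active_env1": ea.valid, "active_env2": eb.valid,
        })
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(seed)
    n = len(pop_a)
    null = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        for i in range(n):
            j = perm[i]
            if i == j:
                continue
            null.append(_corr(esr_a[i].values, esr_b[j].values))
    null = np.asarray([v for v in null if np.isfinite(v)])
    active_both = df["active_env1"] & df["active_env2"]
    esr1, esr2 = df["nonspatial_env1"], df["nonspatial_env2"]
    summary = {
        "esr_corr_mean": float(df["esr_corr"].mean(skipna=True)),
        "spatial_corr_mean": float(df["spatial_corr"].mean(skipna=True)),
        "shuffle_null": null,
        "shuffle_mean": float(null.mean()) if len(null) else np.nan,
        "prop_esr_env1": float(esr1.mean()),
        "prop_esr_env2": float(esr2.mean()),
        "prop_esr_both": float((esr1 & esr2).mean()),
        "prop_active_both": float(active_both.mean()),
    }
    return df, summary
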