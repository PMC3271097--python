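"""Fixation-report ingest, trial/fixation filters, AOI assignment, and
behavioral summaries.

The reference input dialect is a tab-delimited fixation report (the
kind exported by EyeLink Data Viewer), one row per fixation with named
columns::

    participant  trial  phase  orientation  start_position  face_id
    ordinal  x  y  onset_ms  duration_ms

Coordinates are degrees of visual angle in the screen frame (y down),
``ordinal`` is the 1-based fixation index within the trial, ``onset_ms``
is relative to stimulus onset.

Filters mirror the analysis conventions of start-position studies: only
the first five fixations per trial enter spatial analyses; the first
fixation and the center start position can be excluded; out-of-image
fixations are clamped to the nearest image-edge point rather than
dropped, so every trial keeps an equal number of fixations.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .geometry import AOI_LABELS, FaceGeometry, Rect

__all__ = [
    "REQUIRED_COLUMNS",
    "TRIAL_KEYS",
    "SchemaError",
    "read_fixation_report",
    "write_fixation_report",
    "select_first_k",
    "drop_first_and_center",
    "clamp_to_image",
    "assign_aoi",
    "relative_frequencies",
    "latency_to_first_saccade",
    "duration_profile",
    "dprime",
    "dprime_table",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "participant", "trial", "phase", "orientation", "start_position",
    "face_id", "ordinal", "x", "y", "onset_ms", "duration_ms",
)

#: Columns identifying one trial.
TRIAL_KEYS = ["participant", "trial"]

_NUMERIC = {"ordinal": int, "x": float, "y": float,
            "onset_ms": float, "duration_ms": float}


class SchemaError(ValueError):
    """Fixation report lacks required columns or has unusable rows."""


def read_fixation_report(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited fixation report into a typed DataFrame.

    Rows whose numeric fields fail to parse are dropped with a logged
    report of their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    bad = pd.Series(False, index=df.index)
    for col in _NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad |= converted.isna()
        df[col] = converted
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +1 header, +1 one-based
        logger.warning("%s: dropped %d unparseable rows at lines %s",
                       path, bad.sum(), lines)
        df = df[~bad]
    df = df.astype(_NUMERIC).reset_index(drop=True)
    # id-like columns keep their written representation but integer ids
    # come back as integers (round-trip fidelity for the common case)
    for col in ("participant", "trial", "face_id"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if len(df) and not converted.isna().any():
            as_int = converted.astype("int64", errors="ignore")
            df[col] = as_int if (converted == as_int).all() else converted
    _check_onsets(df, str(path))
    return df


def _check_onsets(df: pd.DataFrame, source: str) -> None:
    if df.empty:
        return
    ordered = df.sort_values(TRIAL_KEYS + ["ordinal"])
    non_mono = (
        ordered.groupby(TRIAL_KEYS, sort=False)["onset_ms"]
        .apply(lambda s: bool((s.diff().dropna() < 0).any()))
    )
    n = int(non_mono.sum())
    if n:
        logger.warning("%s: %d trials have non-monotone fixation onsets", source, n)


def write_fixation_report(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, list(REQUIRED_COLUMNS)].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters


def select_first_k(fixations: pd.DataFrame, k: int = 5,
                   strict: bool = False) -> pd.DataFrame:
    """Keep only the first ``k`` fixations (by ordinal) of each trial.

    Trials with fewer than ``k`` fixations are retained with whatever
    they have (their count is logged); ``strict=True`` drops them
    entirely instead.
    """
    out = fixations[fixations["ordinal"] <= k]
    counts = out.groupby(TRIAL_KEYS, sort=False)["ordinal"].max()
    short = counts[counts < k]
    if len(short):
        logger.info("select_first_k: %d trials have fewer than %d fixations",
                    len(short), k)
        if strict:
            keep = ~out.set_index(TRIAL_KEYS).index.isin(short.index)
            out = out[keep]
    removed = len(fixations) - len(out)
    if removed:
        logger.info("select_first_k: removed %d fixations beyond ordinal %d",
                    removed, k)
    return out.reset_index(drop=True)


def drop_first_and_center(
    fixations: pd.DataFrame, drop_first: bool = True, drop_center: bool = True
) -> pd.DataFrame:
    """Exclude ordinal-1 fixations and/or center-start trials.

    The first fixation is experimenter-constrained (it mostly reflects
    the landing of the initial saccade) and the center start position
    has qualitatively different timing, so spatial contrasts typically
    run on fixations 2+ of the four peripheral start positions.
    """
    out = fixations
    if drop_first:
        out = out[out["ordinal"] > 1]
    if drop_center:
        out = out[out["start_position"] != "center"]
    return out.reset_index(drop=True)


def clamp_to_image(fixations: pd.DataFrame, bounds: Rect) -> pd.DataFrame:
    """Project out-of-image fixations to the nearest image-edge point.

    The L2 projection onto an axis-aligned rectangle is the coordinate-
    wise clip. Keeps every fixation (analyses need equal counts per
    trial); the clamped fraction is logged.
    """
    out = fixations.copy()
    cx = out["x"].clip(bounds.x_min, bounds.x_max)
    cy = out["y"].clip(bounds.y_min, bounds.y_max)
    moved = (cx != out["x"]) | (cy != out["y"])
    if moved.any():
        logger.info("clamp_to_image: clamped %d/%d fixations (%.2f%%)",
                    moved.sum(), len(out), 100 * moved.mean())
    out["x"], out["y"] = cx, cy
    return out


# ---------------------------------------------------------------------------
# AOI assignment


def assign_aoi(
    fixations: pd.DataFrame, geometries: Mapping[str, FaceGeometry]
) -> pd.Series:
    """AOI label (or ``"outside"``) for each fixation, looked up in its
    own face's geometry.

    Rectangles are closed; a point in several AOIs gets the first label
    in :data:`fixmap.geometry.AOI_LABELS` priority order (eyes before
    nose before mouth).
    """
    labels = pd.Series("outside", index=fixations.index, dtype=object)
    for face_id, idx in fixations.groupby("face_id", sort=False).groups.items():
        geom = geometries[str(face_id)]
        x = fixations.loc[idx, "x"].to_numpy()
        y = fixations.loc[idx, "y"].to_numpy()
        assigned = np.full(len(idx), "outside", dtype=object)
        unset = np.ones(len(idx), dtype=bool)
        for lab in AOI_LABELS:  # priority order
            r = geom.aois[lab]
            hit = unset & (x >= r.x_min) & (x <= r.x_max) \
                        & (y >= r.y_min) & (y <= r.y_max)
            assigned[hit] = lab
            unset &= ~hit
        labels.loc[idx] = assigned
    return labels


def relative_frequencies(
    fixations: pd.DataFrame,
    geometries: Mapping[str, FaceGeometry],
    cell_keys: Sequence[str] = ("phase", "orientation", "start_position"),
    k: int = 5,
) -> pd.DataFrame:
    """Relative fixation frequency per AOI, participant, and condition cell.

    The denominator is the number of *possible* fixations — trials in
    the cell times ``k`` — so cells whose trials ran short of ``k``
    fixations implicitly count the shortfall as neither AOI nor outside;
    frequencies then sum to the observed/possible ratio. With complete
    trials rows sum to 1 across the 7 AOIs plus ``outside``.
    """
    fix = select_first_k(fixations, k=k)
    fix = fix.assign(aoi=assign_aoi(fix, geometries))
    group = ["participant", *cell_keys]
    n_trials = (
        fix.drop_duplicates(TRIAL_KEYS + list(cell_keys))
        .groupby(group, sort=False).size()
    )
    counts = (
        fix.groupby(group + ["aoi"], sort=False).size().unstack(fill_value=0)
    )
    for lab in (*AOI_LABELS, "outside"):
        if lab not in counts.columns:
            counts[lab] = 0
    counts = counts[[*AOI_LABELS, "outside"]]
    freqs = counts.div(n_trials * k, axis=0)
    return freqs.reset_index()


# ---------------------------------------------------------------------------
# timing


def latency_to_first_saccade(fixations: pd.DataFrame) -> pd.Series:
    """Per-trial latency (ms) from stimulus onset to the first saccade.

    Fixation reports come in two dialects and both are handled:

    * ordinal 1 is the residual pre-saccadic fixation spanning stimulus
      onset (onset_ms <= 0): the first saccade starts when it ends, so
      latency = onset + duration;
    * ordinal 1 is the first post-saccadic fixation on the stimulus
      (onset_ms > 0): saccade flight time is not recoverable from a
      fixation report, so latency = onset of that fixation.

    Trials with no ordinal-1 fixation get NaN.
    """
    first = fixations[fixations["ordinal"] == 1]
    pre_saccadic = first["onset_ms"] <= 0
    lat = (first["onset_ms"] + first["duration_ms"].where(pre_saccadic, 0.0))
    lat.index = pd.MultiIndex.from_frame(first[TRIAL_KEYS])
    all_trials = pd.MultiIndex.from_frame(
        fixations[TRIAL_KEYS].drop_duplicates()
    )
    return lat.reindex(all_trials)


def duration_profile(
    fixations: pd.DataFrame,
    cell_keys: Sequence[str] = ("phase", "orientation", "start_position"),
) -> dict[str, pd.DataFrame]:
    """Timing summaries per participant and condition cell.

    Returns ``{"durations": ..., "latency": ...}``: per-ordinal fixation
    duration mean/sd/n, and per-cell latency-to-first-saccade mean/sd/n.
    """
    group = ["participant", *cell_keys]
    durations = (
        fixations.groupby(group + ["ordinal"], sort=False)["duration_ms"]
        .agg(["mean", "std", "count"]).reset_index()
    )
    lat = latency_to_first_saccade(fixations).rename("latency_ms").reset_index()
    cells = fixations[TRIAL_KEYS + list(cell_keys)].drop_duplicates()
    lat = lat.merge(cells, on=TRIAL_KEYS, how="left")
    latency = (
        lat.groupby(group, sort=False)["latency_ms"]
        .agg(["mean", "std", "count"]).reset_index()
    )
    return {"durations": durations, "latency": latency}


# ---------------------------------------------------------------------------
# signal detection


def dprime(hits: int, misses: int, false_alarms: int,
           correct_rejections: int) -> float:
    """Equal-variance signal-detection sensitivity
    z(hit rate) - z(false-alarm rate).

    Extreme rates 0 and 1 are replaced by 1/(2N) and 1 - 1/(2N) of the
    relevant trial count, the standard loglinear-free correction.
    """
    for name, n in (("hits+misses", hits + misses),
                    ("false_alarms+correct_rejections",
                     false_alarms + correct_rejections)):
        if n <= 0:
            raise ValueError(f"no trials in class {name}")
    if min(hits, misses, false_alarms, correct_rejections) < 0:
        raise ValueError("counts must be non-negative")

    def rate(k: int, n: int) -> float:
        r = k / n
        if r == 0.0:
            r = 1.0 / (2 * n)
        elif r == 1.0:
            r = 1.0 - 1.0 / (2 * n)
        return r

    hr = rate(hits, hits + misses)
    fr = rate(false_alarms, false_alarms + correct_rejections)
    return float(norm.ppf(hr) - norm.ppf(fr))


def dprime_table(
    behavior: pd.DataFrame,
    cell_keys: Sequence[str] = ("orientation",),
) -> pd.DataFrame:
    """Per-participant d' (and median RT) from an old/new response table
    with columns participant, is_old (bool), response_old (bool), rt_ms."""
    rows = []
    for keys, grp in behavior.groupby(["participant", *cell_keys], sort=False):
        old = grp[grp["is_old"]]
        new = grp[~grp["is_old"]]
        h = int(old["response_old"].sum())
        fa = int(new["response_old"].sum())
        rows.append((*keys,
                     dprime(h, len(old) - h, fa, len(new) - fa),
                     float(grp["rt_ms"].median())))
    return pd.DataFrame(rows,
                        columns=["participant", *cell_keys, "dprime", "rt_ms"])
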