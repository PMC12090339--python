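"""FRET-kinetics fitness scoring.

Protease activity is read out by a FRET substrate: cleavage separates the
donor/acceptor pair, so donor emission (480 nm) rises relative to acceptor
emission (520 nm) under 430 nm excitation.  The reported *FRET ratio* is

    ratio(t) = (F480(t) - B480(t)) / (F520(t) - B520(t))

with B the mean over water-blank wells at each timepoint.  The ratio rises
from ~0.4 toward ~0.9 as substrate is cleaved.  A variant's *fitness* is the
initial rate of that rise: the trace is truncated before the first crossing
of a threshold ratio (default 0.55, where the curve is still near-linear),
an ordinary least-squares line is fit to each replicate, and slopes are
normalized by the wild-type mean slope, so the wild type scores exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Default truncation threshold: the FRET ratio above which cleavage curves
#: leave the initial-rate regime.
DEFAULT_TRUNCATION = 0.55


class ScoringError(ValueError):
    """Raised when a plate cannot be scored (no blanks, missing WT, ...)."""


@dataclass
class FluorescencePlate:
    """Two-channel plate-reader time series plus layout.

    ``wells`` maps well_id -> (2, T) array with row 0 the 480 nm emission
    series and row 1 the 520 nm series (arbitrary units).  ``layout`` maps
    well_id -> (variant_id, replicate_index) for sample wells; ``blanks``
    lists water-blank well ids.
    """

    timepoints: np.ndarray  # minutes, strictly increasing, shape (T,)
    wells: dict[str, np.ndarray]
    blanks: list[str]
    layout: dict[str, tuple[str, int]]

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        T = self.timepoints.size
        for w, arr in self.wells.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (2, T):
                raise ValueError(f"well {w!r}: expected shape (2, {T})")
            self.wells[w] = arr
        if not self.blanks:
            raise ValueError("plate needs at least one blank well")
        missing = set(self.blanks) - set(self.wells)
        missing |= set(self.layout) - set(self.wells)
        if missing:
            raise ValueError(f"wells referenced but absent: {sorted(missing)}")

    def blank_means(self) -> np.ndarray:
        """Per-timepoint mean blank signal, shape (2, T)."""
        return np.mean([self.wells[w] for w in self.blanks], axis=0)

    def variant_wells(self) -> dict[str, list[str]]:
        """variant_id -> well ids, ordered by replicate index."""
        out: dict[str, list[tuple[int, str]]] = {}
        for w, (vid, rep) in self.layout.items():
            out.setdefault(vid, []).append((rep, w))
        return {vid: [w for _, w in sorted(v)] for vid, v in out.items()}


@dataclass
class FretSeries:
    """A blank-subtracted FRET-ratio trace for one well."""

    timepoints: np.ndarray
    ratio: np.ndarray
    mask: np.ndarray = field(default=None)  # True where the point is valid

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.ratio)
        if not (self.timepoints.size == self.ratio.size == self.mask.size):
            raise ValueError("series fields must share a length")

    def valid(self) -> "FretSeries":
        return FretSeries(self.timepoints[self.mask], self.ratio[self.mask])


@dataclass
class FitnessScore:
    """Per-variant fitness summary on the WT-normalized scale."""

    variant_id: str
    replicate_slopes: list[float]       # raw OLS slopes, ratio units / min
    mean_slope: float
    sd_slope: float
    fitness: float                      # mean slope / WT mean slope, clipped >= 0
    sd_fitness: float
    n_replicates: int
    flags: list[str] = field(default_factory=list)


def fret_ratio(plate: FluorescencePlate, well: str) -> FretSeries:
    """Blank-subtracted 480/520 ratio trace for one well.

    Timepoints where the blank-subtracted 520 nm signal is <= 0 are masked
    with a warning (the ratio is undefined there); if every point is masked
    a :class:`ScoringError` is raised.
    """
    if well not in plate.wells:
        raise KeyError(f"unknown well {well!r}")
    b480, b520 = plate.blank_means()
    f480, f520 = plate.wells[well]
    denom = f520 - b520
    mask = denom > 0
    if not mask.any():
        raise ScoringError(f"well {well!r}: non-positive denominator everywhere")
    if not mask.all():
        warnings.warn(f"well {well!r}: {np.count_nonzero(~mask)} point(s) "
                      "masked (non-positive 520 nm signal after blanking)")
    ratio = np.full_like(denom, np.nan)
    ratio[mask] = (f480 - b480)[mask] / denom[mask]
    return FretSeries(plate.timepoints, ratio, mask)


def truncate_series(series: FretSeries,
                    threshold: float = DEFAULT_TRUNCATION) -> FretSeries:
    """Keep the prefix strictly before the first crossing of ``threshold``.

    The first-crossing rule (rather than dropping all points >= threshold)
    means a noisy dip back below threshold cannot re-admit late points,
    which would contaminate the initial-rate estimate.  If the trace never
    reaches the threshold the full series is returned.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    s = series.valid()
    crossed = np.nonzero(s.ratio >= threshold)[0]
    end = crossed[0] if crossed.size else s.ratio.size
    return FretSeries(s.timepoints[:end], s.ratio[:end])


def fit_initial_slope(series: FretSeries) -> float:
    """OLS slope (free intercept) of ratio vs time, in ratio units / minute."""
    s = series.valid()
    if s.timepoints.size < 2:
        raise ScoringError("need at least 2 points to fit a slope")
    if np.ptp(s.timepoints) == 0:
        raise ScoringError("zero time variance")
    return float(stats.linregress(s.timepoints, s.ratio).slope)


def normalize_fitness(replicate_slopes: dict[str, list[float]],
                      wt_variant_id: str,
                      flags: dict[str, list[str]] | None = None,
                      ) -> list[FitnessScore]:
    """Normalize per-replicate slopes by the WT mean slope.

    The wild type's own fitness is 1 by construction.  Negative normalized
    means are clipped to 0 (an enzyme cannot have negative activity; pure
    noise wells should score ~0) while the raw slopes are retained.
    """
    if wt_variant_id not in replicate_slopes:
        raise ScoringError(f"WT {wt_variant_id!r} has no scored replicates")
    wt_mean = float(np.mean(replicate_slopes[wt_variant_id]))
    if wt_mean <= 0:
        raise ScoringError(
            f"WT mean slope {wt_mean:.4g} <= 0: reference assay failed")
    flags = flags or {}
    out = []
    for vid, slopes in replicate_slopes.items():
        slopes = [float(s) for s in slopes]
        vflags = list(flags.get(vid, []))
        mean_slope = float(np.mean(slopes))
        norm = np.asarray(slopes) / wt_mean
        if len(slopes) >= 2:
            sd_slope = float(np.std(slopes, ddof=1))
            sd_fit = float(np.std(norm, ddof=1))
        else:
            sd_slope = sd_fit = float("nan")
            vflags.append("single_replicate")
        fitness = max(0.0, float(np.mean(norm)))
        if np.mean(norm) < 0:
            vflags.append("negative_slope_clipped")
        out.append(FitnessScore(vid, slopes, mean_slope, sd_slope,
                                fitness, sd_fit, len(slopes), vflags))
    return out


def score_plate(plate: FluorescencePlate,
                threshold: float = DEFAULT_TRUNCATION,
                wt_variant_id: str = "WT") -> pd.DataFrame:
    """Score every variant on a plate; returns one row per variant.

    Replicates whose truncated trace has fewer than 2 points are dropped
    with a flag.  Columns: variant_id, mean_slope, sd_slope, fitness,
    sd_fitness, n_replicates, flags.  Deterministic given the plate.
    """
    by_variant = plate.variant_wells()
    if wt_variant_id not in by_variant:
        raise ScoringError(f"WT {wt_variant_id!r} not on plate")
    slopes: dict[str, list[float]] = {}
    flags: dict[str, list[str]] = {}
    for vid, wells in by_variant.items():
        slopes[vid] = []
        for w in wells:
            try:
                trunc = truncate_series(fret_ratio(plate, w), threshold)
                slopes[vid].append(fit_initial_slope(trunc))
            except ScoringError as exc:
                flags.setdefault(vid, []).append(f"{w}:unscorable({exc})")
        if not slopes[vid]:
            flags.setdefault(vid, []).append("no_scorable_replicates")
    scorable = {vid: s for vid, s in slopes.items() if s}
    scores = normalize_fitness(scorable, wt_variant_id, flags)
    rows = [{
        "variant_id": sc.variant_id,
        "mean_slope": sc.mean_slope,
        "sd_slope": sc.sd_slope,
        "fitness": sc.fitness,
        "sd_fitness": sc.sd_fitness,
        "n_replicates": sc.n_replicates,
        "flags": ";".join(sc.flags),
    } for sc in scores]
    for vid in set(slopes) - set(scorable):
        rows.append({"variant_id": vid, "mean_slope": np.nan,
                     "sd_slope": np.nan, "fitness": np.nan,
                     "sd_fitness": np.nan, "n_replicates": 0,
                     "flags": ";".join(flags.get(vid, []))})
    return (pd.DataFrame(rows)
            .sort_values("variant_id").reset_index(drop=True))


# ---------------------------------------------------------------------------
# Plate-file dialects
# ---------------------------------------------------------------------------

def read_plate(plate_path, layout_path) -> FluorescencePlate:
    """Read the tidy plate dialect plus a layout table.

    Plate file: delimited text, one row per timepoint; first column
    ``time_min``, remaining columns named ``<well>_480`` / ``<well>_520``.
    Layout: columns well_id, variant_id, replicate, is_blank.
    """
    df = pd.read_csv(plate_path, sep=None, engine="python")
    if "time_min" not in df.columns:
        raise ValueError("plate file must have a 'time_min' column")
    t = df["time_min"].to_numpy(float)
    wells: dict[str, np.ndarray] = {}
    for col in df.columns:
        if col == "time_min":
            continue
        well, _, chan = col.rpartition("_")
        if chan not in ("480", "520") or not well:
            raise ValueError(f"unrecognized plate column {col!r}")
        arr = wells.setdefault(well, np.full((2, t.size), np.nan))
        arr[0 if chan == "480" else 1] = df[col].to_numpy(float)
    layout_df = pd.read_csv(layout_path, sep=None, engine="python")
    blanks, layout = _parse_layout(layout_df)
    return FluorescencePlate(t, wells, blanks, layout)


def read_polarstar_plate(plate_path, layout_path) -> FluorescencePlate:
    """Read a wide POLARstar-like CSV with one block per emission channel.

    Each block starts with a line ``channel,480`` (or ``520``), followed by a
    header row ``time_min,<well>,<well>,...`` and one row per timepoint.
    Blocks are separated by blank lines.
    """
    with open(plate_path) as fh:
        text = fh.read()
    blocks = [b.strip() for b in text.split("\n\n") if b.strip()]
    channel_frames: dict[str, pd.DataFrame] = {}
    for block in blocks:
        lines = block.splitlines()
        tag, _, chan = lines[0].partition(",")
        if tag.strip().lower() != "channel" or chan.strip() not in ("480", "520"):
            raise ValueError(f"bad block header {lines[0]!r}")
        from io import StringIO
        channel_frames[chan.strip()] = pd.read_csv(StringIO("\n".join(lines[1:])))
    if set(channel_frames) != {"480", "520"}:
        raise ValueError("need exactly one 480 and one 520 block")
    f480, f520 = channel_frames["480"], channel_frames["520"]
    t = f480["time_min"].to_numpy(float)
    if not np.array_equal(t, f520["time_min"].to_numpy(float)):
        raise ValueError("channel blocks disagree on timepoints")
    wells = {w: np.vstack([f480[w].to_numpy(float), f520[w].to_numpy(float)])
             for w in f480.columns if w != "time_min"}
    layout_df = pd.read_csv(layout_path, sep=None, engine="python")
    blanks, layout = _parse_layout(layout_df)
    return FluorescencePlate(t, wells, blanks, layout)


def _parse_layout(df: pd.DataFrame) -> tuple[list[str], dict[str, tuple[str, int]]]:
    required = {"well_id", "variant_id", "replicate", "is_blank"}
    if not required <= set(df.columns):
        raise ValueError(f"layout needs columns {sorted(required)}")
    blanks, layout = [], {}
    for r in df.itertuples(index=False):
        well = str(r.well_id)
        if bool(r.is_blank) and str(r.is_blank).lower() not in ("false", "0"):
            blanks.append(well)
        else:
            layout[well] = (str(r.variant_id), int(r.replicate))
    return blanks, layout


def write_plate(plate: FluorescencePlate, plate_path, layout_path) -> None:
    """Write a plate in the tidy dialect (inverse of :func:`read_plate`)."""
    data = {"time_min": plate.timepoints}
    for well in sorted(plate.wells):
        data[f"{well}_480"] = plate.wells[well][0]
        data[f"{well}_520"] = plate.wells[well][1]
    pd.DataFrame(data).to_csv(plate_path, index=False, float_format="%.6f")
    rows = [{"well_id": w, "variant_id": vid, "replicate": rep, "is_blank": False}
            for w, (vid, rep) in sorted(plate.layout.items())]
    rows += [{"well_id": w, "variant_id": "", "replicate": 0, "is_blank": True}
             for w in plate.blanks]
    pd.DataFrame(rows).to_csv(layout_path, index=False)
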