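"""Phenotype-microarray (Biolog PM) substrate-utilization scoring.

A PM plate is a 96-well array of substrates; respiration reduces a
tetrazolium dye, read as absorbance at 590 nm with a 750 nm reference.
The pipeline implemented here:

1. background correction: per well and timepoint, ``A590 - A750``;
2. time averaging: mean corrected absorbance over all timepoints;
3. per-plate, per-strain min-max rescaling to a PM score in [0, 100];
4. threshold estimation from the score distribution by Gaussian kernel
   density estimation (negative wells form a non-zero low-score mode;
   the cutoff is the density valley between the two main modes, with a
   fixed fallback of 7 when the distribution is not bimodal);
5. a binary utilization call per well (score strictly above threshold);
6. utilization fractions and two-proportion chi-square comparisons
   between strains (Yates continuity correction by default).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import gaussian_kde

__all__ = [
    "WellMeasurement",
    "PlateSeries",
    "WellScore",
    "ThresholdModel",
    "UtilizationCall",
    "PlateSummary",
    "ProportionTestResult",
    "DegeneratePlateWarning",
    "WELL_IDS",
    "parse_plate_series",
    "correct_and_summarize",
    "combine_replicates",
    "normalize_scores",
    "estimate_threshold",
    "call_utilization",
    "summarize_plate",
    "proportion_test",
    "score_plates",
    "calls_to_frame",
]

#: Row-major A1..H12 well coordinates of a 96-well plate.
WELL_IDS: tuple[str, ...] = tuple(f"{r}{c}" for r in "ABCDEFGH" for c in range(1, 13))
_WELL_SET = frozenset(WELL_IDS)
_PLATE_RE = re.compile(r"^PM\d{1,2}[A-C]?$")

#: Default negative-control well (water / no substrate on Biolog plates).
DEFAULT_CONTROL_WELLS = frozenset({"A1"})

_CSV_COLUMNS = ("strain_id", "plate_type", "well_id", "timepoint_h", "wavelength_nm", "absorbance")


class DegeneratePlateWarning(UserWarning):
    """Raised when all wells of a plate share the same corrected mean."""


@dataclass(frozen=True)
class WellMeasurement:
    """One dual-wavelength absorbance read of one well."""

    well_id: str
    timepoint: float
    a590: float
    a750: float


@dataclass
class PlateSeries:
    """All reads of one strain x plate (x replicate) combination."""

    strain_id: str
    plate_type: str
    measurements: list[WellMeasurement]
    substrate_map: dict[str, str]
    control_wells: frozenset[str] = DEFAULT_CONTROL_WELLS
    replicate: str = "1"

    def by_well(self) -> dict[str, list[WellMeasurement]]:
        out: dict[str, list[WellMeasurement]] = {}
        for m in self.measurements:
            out.setdefault(m.well_id, []).append(m)
        for ms in out.values():
            ms.sort(key=lambda m: m.timepoint)
        return out


@dataclass(frozen=True)
class WellScore:
    well_id: str
    corrected_mean: float
    score: float | None = None


@dataclass
class ThresholdModel:
    """Score cutoff plus the density estimate it was derived from."""

    scores_used: np.ndarray
    bandwidth: float | None
    grid: np.ndarray
    density: np.ndarray
    threshold: float
    mode: str  # "auto-valley" or "fixed"
    default_fixed: float = 7.0


@dataclass(frozen=True)
class UtilizationCall:
    well_id: str
    substrate: str
    score: float
    positive: bool
    is_control: bool = False


@dataclass(frozen=True)
class PlateSummary:
    n_positive: int
    n_total: int
    percent: float
    table: pd.DataFrame


@dataclass(frozen=True)
class ProportionTestResult:
    k1: int
    n1: int
    k2: int
    n2: int
    p1: float
    p2: float
    chi_squared: float
    p_value: float
    continuity_corrected: bool


def parse_plate_series(source, substrate_map: dict[str, str] | None = None,
                       control_wells=DEFAULT_CONTROL_WELLS) -> list[PlateSeries]:
    """Read a long-format plate CSV into one :class:`PlateSeries` per
    (strain, plate, replicate).

    The schema is ``strain_id, plate_type, well_id, timepoint_h,
    wavelength_nm, absorbance`` with optional ``replicate`` and
    ``substrate`` columns; each (well, timepoint) must carry both a 590
    and a 750 nm read.
    """
    df = pd.read_csv(source)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate CSV is missing required column(s): {', '.join(missing)}")
    if "replicate" not in df.columns:
        df = df.assign(replicate="1")
    df["replicate"] = df["replicate"].astype(str)

    bad_wl = set(df["wavelength_nm"].unique()) - {590, 750}
    if bad_wl:
        raise ValueError(f"unexpected wavelength_nm values: {sorted(bad_wl)}")
    bad_wells = set(df["well_id"]) - _WELL_SET
    if bad_wells:
        raise ValueError(f"well_id not on the 8x12 grid: {sorted(bad_wells)[:5]}")
    for pt in df["plate_type"].unique():
        if not _PLATE_RE.match(str(pt)):
            raise ValueError(f"unknown plate_type {pt!r} (expected e.g. PM1, PM2A)")

    key = ["strain_id", "plate_type", "replicate", "well_id", "timepoint_h", "wavelength_nm"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise ValueError(f"duplicate measurement row for {first}")

    out: list[PlateSeries] = []
    for (strain, plate, rep), grp in df.groupby(
            ["strain_id", "plate_type", "replicate"], sort=True):
        wide = grp.pivot_table(index=["well_id", "timepoint_h"], columns="wavelength_nm",
                               values="absorbance", aggfunc="first")
        if 590 not in wide.columns or 750 not in wide.columns or wide[[590, 750]].isna().any().any():
            raise ValueError(
                f"{strain}/{plate}: every (well, timepoint) needs both 590 and 750 nm reads")
        meas = [WellMeasurement(w, float(t), float(row[590]), float(row[750]))
                for (w, t), row in wide.iterrows()]
        meas.sort(key=lambda m: (m.well_id, m.timepoint))
        smap = dict(substrate_map) if substrate_map else {}
        if "substrate" in grp.columns:
            for w, s in zip(grp["well_id"], grp["substrate"]):
                if isinstance(s, str) and s:
                    smap.setdefault(w, s)
        for w in WELL_IDS:
            smap.setdefault(w, w)
        out.append(PlateSeries(strain_id=str(strain), plate_type=str(plate),
                               measurements=meas, substrate_map=smap,
                               control_wells=frozenset(control_wells), replicate=str(rep)))
    return out


def correct_and_summarize(series: PlateSeries) -> list[WellScore]:
    """Per well: mean over timepoints of the background-corrected signal
    ``A590 - A750``. Scores are left unset."""
    out = []
    for well, ms in sorted(series.by_well().items()):
        vals = np.array([m.a590 - m.a750 for m in ms], dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite absorbance in well {well}")
        out.append(WellScore(well_id=well, corrected_mean=float(vals.mean())))
    return out


def combine_replicates(per_replicate: list[list[WellScore]]) -> list[WellScore]:
    """Average corrected means across replicate plates, well by well."""
    if not per_replicate:
        raise ValueError("no replicates to combine")
    acc: dict[str, list[float]] = {}
    for rep in per_replicate:
        for ws in rep:
            acc.setdefault(ws.well_id, []).append(ws.corrected_mean)
    return [WellScore(w, float(np.mean(v))) for w, v in sorted(acc.items())]


def normalize_scores(well_scores: list[WellScore]) -> list[WellScore]:
    """Min-max rescale corrected means to a 0-100 PM score.

    Applied separately per plate and strain (the caller passes one
    plate's wells). A plate where all wells coincide gets all-zero
    scores and a :class:`DegeneratePlateWarning`.
    """
    if len(well_scores) < 2:
        raise ValueError("need at least 2 wells to normalize")
    vals = np.array([w.corrected_mean for w in well_scores])
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        warnings.warn("degenerate plate: all corrected means equal; scores set to 0",
                      DegeneratePlateWarning, stacklevel=2)
        return [replace(w, score=0.0) for w in well_scores]
    # divide before scaling so min/max land on exactly 0.0 and 100.0
    return [replace(w, score=float(100.0 * ((w.corrected_mean - lo) / (hi - lo))))
            for w in well_scores]


def _local_maxima(y: np.ndarray) -> list[int]:
    # interior maxima plus the grid endpoints, which matter because the
    # negative-well mode often peaks at score 0 after normalization
    idx = [i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] >= y[i + 1]]
    if len(y) >= 2 and y[0] > y[1]:
        idx.insert(0, 0)
    if len(y) >= 2 and y[-1] > y[-2]:
        idx.append(len(y) - 1)
    return idx


#: Default KDE kernel standard deviation in score units. Variance-based
#: rules (Scott/Silverman) badly oversmooth strongly bimodal score
#: distributions because the sample variance is dominated by the mode
#: separation, which misplaces the valley; a fixed kernel SD matched to
#: the width of the negative-well mode resolves both modes reliably.
DEFAULT_KDE_BANDWIDTH = 3.0


def estimate_threshold(scores, mode: str = "auto", fixed: float = 7.0,
                       bandwidth: float | str | None = None, grid_size: int = 512,
                       min_mode_fraction: float = 0.05,
                       min_valley_depth: float = 0.5) -> ThresholdModel:
    """Estimate the positive/negative score cutoff from a plate's scores.

    A Gaussian KDE (kernel SD ``bandwidth`` in score units, default
    :data:`DEFAULT_KDE_BANDWIDTH`; the strings ``"silverman"`` and
    ``"scott"`` select the classical data-driven rules) is evaluated on
    a ``grid_size``-point grid over [0, 100], with boundary reflection
    at 0 and 100 so the density integrates to ~1 on the grid. In
    ``auto`` mode the threshold is the density minimum strictly between
    the two highest modes; the valley must be deep (below
    ``min_valley_depth`` times the lower of the two mode peaks) and each
    mode adequately supported (at least ``min_mode_fraction`` of the
    wells, minimum 2), otherwise the model falls back to the ``fixed``
    cutoff and reports ``mode="fixed"``.
    """
    s = np.asarray(list(scores), dtype=float)
    if s.size == 0:
        raise ValueError("empty score list")
    grid = np.linspace(0.0, 100.0, grid_size)

    def _fixed(dens=None, bw=None):
        if dens is None:
            dens = np.full_like(grid, np.nan)
        return ThresholdModel(s, bw, grid, dens, float(fixed), "fixed", float(fixed))

    if mode == "fixed":
        return _fixed()
    if mode != "auto":
        raise ValueError(f"unknown threshold mode {mode!r}")

    std = s.std(ddof=1) if s.size > 1 else 0.0
    if s.size < 8 or std == 0.0:
        return _fixed()
    if bandwidth is None:
        bandwidth = DEFAULT_KDE_BANDWIDTH
    bw_method = bandwidth if isinstance(bandwidth, str) else bandwidth / std
    kde = gaussian_kde(s, bw_method=bw_method)
    bw = float(kde.factor * std)
    density = kde(grid) + kde(-grid) + kde(200.0 - grid)  # reflect at both bounds

    maxima = _local_maxima(density)
    if len(maxima) < 2:
        return _fixed(density, bw)
    top2 = sorted(sorted(maxima, key=lambda i: density[i], reverse=True)[:2])
    i1, i2 = top2
    if i2 - i1 < 2:
        return _fixed(density, bw)
    valley = i1 + 1 + int(np.argmin(density[i1 + 1:i2]))
    thr = float(grid[valley])
    if density[valley] >= min_valley_depth * min(density[i1], density[i2]):
        return _fixed(density, bw)
    need = max(2, math.ceil(min_mode_fraction * s.size))
    if (s <= thr).sum() < need or (s > thr).sum() < need:
        return _fixed(density, bw)
    return ThresholdModel(s, bw, grid, density, thr, "auto-valley", float(fixed))


def call_utilization(well_scores: list[WellScore], threshold: ThresholdModel,
                     substrate_map: dict[str, str] | None = None,
                     control_wells=DEFAULT_CONTROL_WELLS) -> list[UtilizationCall]:
    """Binary call per well: positive iff score strictly above the cutoff.

    Control wells are flagged but still called.
    """
    if not 0.0 <= threshold.threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    smap = substrate_map or {}
    out = []
    for ws in well_scores:
        if ws.score is None:
            raise ValueError(f"well {ws.well_id} has no normalized score")
        out.append(UtilizationCall(
            well_id=ws.well_id,
            substrate=smap.get(ws.well_id, ws.well_id),
            score=ws.score,
            positive=ws.score > threshold.threshold,
            is_control=ws.well_id in control_wells,
        ))
    return out


def summarize_plate(calls: list[UtilizationCall], include_controls: bool = True) -> PlateSummary:
    """Utilization fraction (percent of wells called positive) plus the
    per-substrate call table. The denominator is all wells passed in
    (all 96, including the A1 control, by default)."""
    if not calls:
        raise ValueError("no calls to summarize")
    used = calls if include_controls else [c for c in calls if not c.is_control]
    k = sum(c.positive for c in used)
    table = calls_to_frame(calls)
    return PlateSummary(n_positive=k, n_total=len(used),
                        percent=100.0 * k / len(used), table=table)


def calls_to_frame(calls: list[UtilizationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {"well_id": [c.well_id for c in calls],
         "substrate": [c.substrate for c in calls],
         "score": [c.score for c in calls],
         "positive": [c.positive for c in calls],
         "is_control": [c.is_control for c in calls]})


def proportion_test(k1: int, n1: int, k2: int, n2: int,
                    corrected: bool = True) -> ProportionTestResult:
    """Chi-square test of equal proportions for two binomial samples.

    Pooled-variance statistic with optional Yates continuity correction
    (on by default): with pooled p = (k1+k2)/(n1+n2), difference
    d = |k1/n1 - k2/n2| and correction c = (1/n1 + 1/n2)/2,

        X^2 = max(d - c, 0)^2 / (p (1-p) (1/n1 + 1/n2))

    referred to a chi-square distribution with 1 degree of freedom.
    Matches R's ``prop.test`` for 2x2 inputs.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pbar = (k1 + k2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        chi, p = 0.0, 1.0
    else:
        d = abs(p1 - p2)
        c = 0.5 * (1.0 / n1 + 1.0 / n2) if corrected else 0.0
        chi = max(d - c, 0.0) ** 2 / (pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n2))
        p = float(_chi2_dist.sf(chi, 1))
    return ProportionTestResult(k1, n1, k2, n2, p1, p2, float(chi), p, corrected)


def score_plates(plates: list[PlateSeries], threshold_mode: str = "auto",
                 fixed_threshold: float = 7.0, bandwidth: float | None = None,
                 average_replicates: bool = True, include_controls: bool = True):
    """Run the full scoring pipeline for a batch of parsed plates.

    Returns ``{(strain_id, plate_type): (calls, summary, threshold_model)}``.
    Replicate plates of the same strain x plate are averaged on the
    corrected-mean scale before normalization unless
    ``average_replicates`` is false, in which case keys gain the
    replicate id.
    """
    groups: dict[tuple, list[PlateSeries]] = {}
    for p in plates:
        key = (p.strain_id, p.plate_type) if average_replicates \
            else (p.strain_id, p.plate_type, p.replicate)
        groups.setdefault(key, []).append(p)

    results = {}
    for key, members in sorted(groups.items()):
        corrected = combine_replicates([correct_and_summarize(m) for m in members])
        scored = normalize_scores(corrected)
        model = estimate_threshold([w.score for w in scored], mode=threshold_mode,
                                   fixed=fixed_threshold, bandwidth=bandwidth)
        calls = call_utilization(scored, model, members[0].substrate_map,
                                 members[0].control_wells)
        summary = summarize_plate(calls, include_controls=include_controls)
        results[key] = (calls, summary, model)
    return results
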