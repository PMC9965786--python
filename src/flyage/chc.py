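"""GC-MS cuticular-hydrocarbon pipeline: retention indexing against a
C7–C40 n-alkane ladder, percent-of-total-area composition, minor-compound
filtering and feature-table assembly.

Retention indexing uses the linear (van den Dool–Kratz) form appropriate
for temperature-programmed runs: a peak at retention time rt bracketed by
the Cn and Cn+1 alkanes gets ``RI = 100·n + 100·(rt − rt_n)/(rt_{n+1} −
rt_n)``. The isothermal logarithmic Kovats form is available behind a
flag. Compound assignment is by nearest catalog retention index within a
configurable window (±5 RI units by default); spectral library matching is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CHCProfile, FeatureTable

DEFAULT_AREA_THRESHOLD = 0.5   # percent of total peak area
DEFAULT_RI_WINDOW = 5.0        # retention-index units


@dataclass
class AlkaneLadder:
    """The C7–C40 n-alkane external standard: carbon number → retention time."""

    carbons: np.ndarray
    retention_times: np.ndarray

    def __post_init__(self) -> None:
        self.carbons = np.asarray(self.carbons, dtype=int)
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        if self.carbons.size != self.retention_times.size:
            raise ValueError("carbons and retention_times differ in length")
        if self.carbons.size < 2:
            raise ValueError("ladder needs at least 2 alkanes")
        order = np.argsort(self.carbons)
        self.carbons = self.carbons[order]
        self.retention_times = self.retention_times[order]
        if np.any(np.diff(self.carbons) <= 0):
            raise ValueError("duplicate carbon numbers in ladder")
        if np.any(np.diff(self.retention_times) <= 0):
            raise ValueError("retention times must strictly increase with carbon number")

    @classmethod
    def from_csv(cls, path) -> "AlkaneLadder":
        df = pd.read_csv(path)
        return cls(df["carbon_number"].to_numpy(),
                   df["retention_time_min"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"carbon_number": self.carbons,
                      "retention_time_min": self.retention_times}
                     ).to_csv(path, index=False)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.retention_times[0]), float(self.retention_times[-1])


def default_alkane_ladder() -> AlkaneLadder:
    """A plausible C7–C40 ladder for a ramped 50→300 °C oven program:
    retention time grows monotonically, slightly super-linear in carbon
    number (minutes)."""
    n = np.arange(7, 41)
    rt = 2.0 + 0.55 * (n - 7) + 0.004 * (n - 7) ** 2
    return AlkaneLadder(n, rt)


def retention_index(rt, ladder: AlkaneLadder, kovats_log: bool = False):
    """Linear retention index of peak(s) at retention time ``rt``.

    Piecewise linear through the knots (rt_n, 100·n); with ``kovats_log``
    the interpolation is in log(rt) (isothermal Kovats convention). A
    ladder alkane's own retention time maps exactly to 100 × its carbon
    number. Raises for retention times outside the ladder span.
    """
    rt_arr = np.asarray(rt, dtype=float)
    lo, hi = ladder.span
    if np.any(rt_arr < lo) or np.any(rt_arr > hi):
        raise ValueError(
            f"unbracketed retention time: outside ladder span [{lo}, {hi}] min")
    if kovats_log:
        ri = np.interp(np.log(rt_arr), np.log(ladder.retention_times),
                       100.0 * ladder.carbons)
    else:
        ri = np.interp(rt_arr, ladder.retention_times, 100.0 * ladder.carbons)
    return float(ri) if np.isscalar(rt) else ri


def rt_from_retention_index(ri, ladder: AlkaneLadder):
    """Inverse of :func:`retention_index` (linear form)."""
    ri_arr = np.asarray(ri, dtype=float)
    knots = 100.0 * ladder.carbons
    if np.any(ri_arr < knots[0]) or np.any(ri_arr > knots[-1]):
        raise ValueError("retention index outside ladder span")
    rt = np.interp(ri_arr, knots, ladder.retention_times)
    return float(rt) if np.isscalar(ri) else rt


def relative_areas(areas) -> np.ndarray:
    """Percent of total peak area: 100 · area_i / Σ areas."""
    a = np.asarray(areas, dtype=float)
    if a.size == 0 or np.all(a == 0):
        raise ValueError("no peak with positive area")
    if np.any(a < 0):
        raise ValueError("negative peak area")
    return 100.0 * a / a.sum()


def assign_peaks(peaks: pd.DataFrame, catalog: pd.DataFrame,
                 ladder: AlkaneLadder, ri_window: float = DEFAULT_RI_WINDOW,
                 kovats_log: bool = False) -> pd.DataFrame:
    """Assign peaks to catalog compounds by nearest nominal retention index.

    ``peaks`` needs columns retention_time_min and area. Returns a copy
    with retention_index and assignment columns (assignment is the
    compound name, or NA when no catalog entry lies within ±ri_window).
    """
    out = peaks.copy()
    ri = retention_index(out["retention_time_min"].to_numpy(), ladder,
                         kovats_log=kovats_log)
    out["retention_index"] = ri
    nominal = catalog["nominal_ri"].to_numpy(dtype=float)
    names = catalog["name"].to_numpy()
    idx = np.abs(nominal[None, :] - np.atleast_1d(ri)[:, None]).argmin(axis=1)
    dist = np.abs(nominal[idx] - np.atleast_1d(ri))
    assigned = np.where(dist <= ri_window, names[idx], None)
    out["assignment"] = assigned
    return out


def peaks_to_profile(peaks: pd.DataFrame, catalog: pd.DataFrame,
                     ladder: AlkaneLadder, meta: dict | None = None,
                     ri_window: float = DEFAULT_RI_WINDOW,
                     kovats_log: bool = False) -> CHCProfile:
    """Peak table → compound percent profile.

    Percentages are relative to the total area of *all* peaks (assigned or
    not); areas of peaks mapping to the same compound are summed.
    """
    if (peaks["area"] < 0).any():
        raise ValueError("negative peak area")
    total = peaks["area"].sum()
    if total <= 0:
        raise ValueError("no peak with positive area")
    assigned = assign_peaks(peaks, catalog, ladder, ri_window, kovats_log)
    known = assigned.dropna(subset=["assignment"])
    sums = known.groupby("assignment")["area"].sum()
    percents = (100.0 * sums / total).rename_axis(None).rename(None)
    return CHCProfile(percents=percents, meta=dict(meta or {}))


def filter_minor(profile: CHCProfile,
                 threshold: float = DEFAULT_AREA_THRESHOLD) -> CHCProfile:
    """Drop compounds at or below ``threshold`` percent of total peak area.

    Remaining percentages are *not* renormalized: they stay interpretable
    as percent-of-total-area, so the operation is idempotent.
    """
    kept = profile.percents[profile.percents > threshold]
    if kept.empty:
        raise ValueError(f"no compounds above {threshold}% threshold")
    return profile.replace(percents=kept)


def build_feature_table(profiles: Sequence[CHCProfile],
                        catalog: pd.DataFrame) -> FeatureTable:
    """Assemble profiles into a rectangular samples × compounds table.

    Columns are the union of compounds retained in ≥1 profile, ordered by
    nominal retention index; compounds absent from a sample are zero.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to assemble")
    order = {name: ri for name, ri in
             zip(catalog["name"], catalog["nominal_ri"])}
    union: set[str] = set()
    for p in profiles:
        union.update(p.compounds)
    unknown = union - set(order)
    if unknown:
        raise ValueError(f"compounds missing from catalog: {sorted(unknown)}")
    columns = sorted(union, key=lambda c: order[c])
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_ids: {dupes}")
    data = pd.DataFrame(0.0, index=pd.Index(ids, name="sample_id"),
                        columns=columns)
    meta_rows = []
    for p in profiles:
        data.loc[p.sample_id, p.percents.index] = p.percents.to_numpy()
        meta_rows.append({k: p.meta.get(k)
                          for k in ("temperature_C", "age_days", "replicate")})
    meta = pd.DataFrame(meta_rows, index=data.index)
    return FeatureTable(data, meta)


# ---------------------------------------------------------------------------
# instrument-level emulation and IO
# ---------------------------------------------------------------------------

def peaks_from_profile(profile: CHCProfile, catalog: pd.DataFrame,
                       ladder: AlkaneLadder, total_area: float = 1.0e6,
                       rt_jitter_sd: float = 0.0,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emulate the integrated GC-MS peak table implied by a percent profile:
    each compound becomes one peak at the retention time of its nominal
    retention index, with area percent/100 × total_area. Optional Gaussian
    retention-time jitter (minutes) exercises the assignment window."""
    cat = catalog.set_index("name")
    rows = []
    for compound, percent in profile.percents.items():
        ri = float(cat.loc[compound, "nominal_ri"])
        rt = rt_from_retention_index(ri, ladder)
        if rt_jitter_sd > 0:
            if rng is None:
                raise ValueError("rt_jitter_sd > 0 requires an rng")
            rt += rng.normal(0.0, rt_jitter_sd)
        rows.append({"retention_time_min": rt,
                     "area": percent / 100.0 * total_area})
    return pd.DataFrame(rows).sort_values("retention_time_min").reset_index(drop=True)


def read_peak_tables(path) -> dict[str, pd.DataFrame]:
    """Read a combined peak CSV (sample_id, retention_time_min, area) into
    one table per sample."""
    df = pd.read_csv(path)
    return {str(sid): sub[["retention_time_min", "area"]].reset_index(drop=True)
            for sid, sub in df.groupby("sample_id", sort=False)}


def read_profiles(path) -> list[CHCProfile]:
    """Read the long profile CSV written by the generator
    (sample_id, compound, percent)."""
    df = pd.read_csv(path)
    profiles = []
    meta_cols = [c for c in ("temperature_C", "age_days", "replicate")
                 if c in df.columns]
    for sid, sub in df.groupby("sample_id", sort=False):
        meta = {"sample_id": str(sid)}
        for c in meta_cols:
            meta[c] = int(sub[c].iloc[0])
        profiles.append(CHCProfile(
            percents=pd.Series(sub["percent"].to_numpy(dtype=float),
                               index=sub["compound"].astype(str).to_numpy()),
            meta=meta))
    return profiles
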