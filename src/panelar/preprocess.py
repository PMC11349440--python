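"""Trap-count preprocessing: standardized densities and yearly growth rates.

Small-rodent monitoring programmes record, per location and year, the number
of animals captured and the trapping effort in trap-nights.  The standard
survey protocol is 50 snap traps set for three nights on a 0.5 ha grid, i.e.
150 trap-nights; captures are rescaled to that protocol to give a
*standardized density* ``Z``.  The yearly *population growth rate*

    Y_t = (Z_t - Z_{t-1}) / (1 + Z_{t-1})

is the fractional change of ``1 + Z`` (the unit shift keeps the rate finite
when a year records zero captures); ``ln(1+Z_t) - ln(1+Z_{t-1})`` is its
first-order Taylor approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: trap-nights of the standard protocol: 50 traps x 3 nights on 0.5 ha
PROTOCOL_EFFORT = 150.0


class PreprocessingError(ValueError):
    """Raised for structurally invalid capture tables."""


@dataclass
class PanelData:
    """Tidy panel of per-location annual series.

    Parameters
    ----------
    table : pandas.DataFrame
        Columns ``location, year, density`` and, once :func:`growth_rate`
        has been applied, ``growth_rate`` (NaN for the first year of each
        contiguous run).  Optionally ``species``, ``captures``,
        ``trap_nights``.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"location", "year", "density"}
        missing = required - set(self.table.columns)
        if missing:
            raise PreprocessingError(f"panel table missing columns: {sorted(missing)}")
        if (self.table["density"] < 0).any():
            raise PreprocessingError("negative density")
        dup = self.table.duplicated(subset=["location", "year"])
        if dup.any():
            raise PreprocessingError(
                f"duplicate (location, year) rows: {self.table.loc[dup, ['location', 'year']].values.tolist()}"
            )
        self.table = self.table.sort_values(["location", "year"]).reset_index(drop=True)

    @property
    def locations(self) -> list:
        return list(self.table["location"].unique())

    def density_series(self, location) -> pd.Series:
        sub = self.table[self.table["location"] == location]
        return pd.Series(sub["density"].to_numpy(), index=sub["year"].to_numpy())

    def growth_series(self, location) -> pd.Series:
        """Growth-rate series for one location, indexed by year, NaN rows dropped."""
        sub = self.table[self.table["location"] == location]
        s = pd.Series(sub["growth_rate"].to_numpy(), index=sub["year"].to_numpy())
        return s.dropna()

    def growth_arrays(self) -> dict:
        """Mapping location -> (years, Y) over the longest contiguous run."""
        out = {}
        for loc in self.locations:
            s = self.growth_series(loc)
            if len(s):
                out[loc] = (s.index.to_numpy(), s.to_numpy(float))
        return out

    def to_csv(self, path) -> None:
        cols = [c for c in ("location", "year", "density", "growth_rate") if c in self.table.columns]
        self.table[cols].to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "PanelData":
        return cls(pd.read_csv(path))


def read_captures(path_or_df, species: str | None = None) -> pd.DataFrame:
    """Read a capture CSV (location,year,species,captures,trap_nights).

    ``species`` filters a multi-species table.  Header is required; extra
    columns are preserved.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    required = {"location", "year", "captures", "trap_nights"}
    missing = required - set(df.columns)
    if missing:
        raise PreprocessingError(f"capture table missing columns: {sorted(missing)}")
    if species is not None:
        if "species" not in df.columns:
            raise PreprocessingError("species filter requested but no species column")
        df = df[df["species"] == species]
    return df.copy()


def standardize_density(records, protocol_effort: float = PROTOCOL_EFFORT) -> PanelData:
    """Rescale captures to the standard protocol effort.

    ``Z = captures * protocol_effort / trap_nights``, degree 1 in captures
    and degree -1 in effort.  Records with non-positive trap-nights are
    rejected (collected on ``PanelData.dropped`` with a warning); duplicate
    (location, year) pairs are a hard error.
    """
    if protocol_effort <= 0:
        raise PreprocessingError("protocol_effort must be positive")
    df = read_captures(records)
    if (df["captures"] < 0).any():
        raise PreprocessingError("negative capture counts")
    bad = df["trap_nights"] <= 0
    dropped = df[bad].copy()
    if bad.any():
        warnings.warn(
            f"rejected {int(bad.sum())} record(s) with non-positive trap_nights",
            stacklevel=2,
        )
    df = df[~bad].copy()
    dup = df.duplicated(subset=["location", "year"])
    if dup.any():
        raise PreprocessingError(
            f"duplicate (location, year) records: {df.loc[dup, ['location', 'year']].values.tolist()}"
        )
    df["density"] = df["captures"] * protocol_effort / df["trap_nights"]
    return PanelData(df.reset_index(drop=True), dropped=dropped)


def growth_rate_series(density: np.ndarray) -> np.ndarray:
    """Growth rates of one contiguous density series (one element shorter)."""
    z = np.asarray(density, dtype=float)
    if z.ndim != 1 or len(z) < 2:
        raise PreprocessingError("density series must be 1-D with length >= 2")
    if (z < 0).any():
        raise PreprocessingError("negative density")
    return (z[1:] - z[:-1]) / (1.0 + z[:-1])


def reconstruct_density(z0: float, rates: np.ndarray) -> np.ndarray:
    """Invert :func:`growth_rate_series` from an initial density (round trip)."""
    z = [float(z0)]
    for y in np.asarray(rates, dtype=float):
        z.append(z[-1] + y * (1.0 + z[-1]))
    return np.array(z)


def growth_rate(panel: PanelData) -> PanelData:
    """Fill the ``growth_rate`` column, respecting gaps in the year coverage.

    A growth rate exists only when the immediately preceding calendar year was
    surveyed at the same location; missing years split a series into
    contiguous runs and the first year of each run gets NaN.
    """
    df = panel.table.copy()
    out = np.full(len(df), np.nan)
    for _, idx in df.groupby("location").groups.items():
        sub = df.loc[idx]
        years = sub["year"].to_numpy()
        z = sub["density"].to_numpy(float)
        prev = np.concatenate([[False], np.diff(years) == 1])
        y_all = np.full(len(z), np.nan)
        contiguous = np.flatnonzero(prev)
        y_all[contiguous] = (z[contiguous] - z[contiguous - 1]) / (1.0 + z[contiguous - 1])
        out[np.asarray(idx)] = y_all
    df["growth_rate"] = out
    return PanelData(df, dropped=panel.dropped)


def dominance_stats(vole_panel: PanelData, mouse_panel: PanelData) -> pd.DataFrame:
    """Per-location capture totals, mean densities and vole percentage.

    The dominance of the focal species in the rodent community is the
    percentage of its captures in the combined captures across all shared
    years of the two panels.
    """
    for p, name in ((vole_panel, "vole"), (mouse_panel, "mouse")):
        if "captures" not in p.table.columns:
            raise PreprocessingError(f"{name} panel lacks raw capture counts")
    v = vole_panel.table[["location", "year", "captures", "density"]]
    m = mouse_panel.table[["location", "year", "captures", "density"]]
    merged = v.merge(m, on=["location", "year"], suffixes=("_vole", "_mouse"))
    if merged.empty:
        raise PreprocessingError("no overlapping (location, year) records between panels")
    g = merged.groupby("location")
    out = pd.DataFrame(
        {
            "total_voles": g["captures_vole"].sum(),
            "total_mice": g["captures_mouse"].sum(),
            "mean_density_vole": g["density_vole"].mean(),
            "mean_density_mouse": g["density_mouse"].mean(),
        }
    )
    total = out["total_voles"] + out["total_mice"]
    out["pct_voles"] = np.where(total > 0, 100.0 * out["total_voles"] / total, np.nan)
    return out.reset_index()
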