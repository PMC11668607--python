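"""Binary allometric aboveground-biomass models for spruce and fir.

Single-tree AGB follows the power-law form of the Chinese forestry-industry
standards (LY/T series) for *Picea* and *Abies*::

    M = a * D^b * H^c      [kg per tree]

where D is diameter at breast height (cm) and H is tree height (m).
Per-tree masses are in kilograms and are converted to tonnes when
aggregated to a per-hectare plot density (t/hm2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "SPECIES_COEFFICIENTS",
    "TreeRecord",
    "PlotRecord",
    "tree_agb",
    "plot_agb",
    "read_plot_csv",
    "write_plot_agb_csv",
]

#: (a, b, c) of M = a * D^b * H^c, mass in kg, D in cm, H in m.
SPECIES_COEFFICIENTS: dict[str, tuple[float, float, float]] = {
    "spruce": (0.09152, 2.21060, 0.25663),
    "fir": (0.06127, 2.05753, 0.50839),
}

KG_PER_TONNE = 1000.0


class UnsupportedSpeciesError(ValueError):
    """Raised for a species with no registered allometric model."""


@dataclass(frozen=True)
class TreeRecord:
    """One measured stem: species, DBH in cm and height in m."""

    species: str
    dbh_cm: float
    height_m: float

    def __post_init__(self) -> None:
        if not self.dbh_cm > 0:
            raise ValueError(f"dbh_cm must be positive, got {self.dbh_cm}")
        if not self.height_m > 0:
            raise ValueError(f"height_m must be positive, got {self.height_m}")


@dataclass
class PlotRecord:
    """A field plot with its tree list.

    ``area_hm2`` is the plot area in hectares; ``agb_t_per_hm2`` is the
    derived AGB density (total tree mass in tonnes divided by area).
    """

    plot_id: str
    x: float
    y: float
    area_hm2: float
    trees: list[TreeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.area_hm2 > 0:
            raise ValueError(f"area_hm2 must be positive, got {self.area_hm2}")

    @property
    def agb_t_per_hm2(self) -> float:
        return plot_agb(self)


def tree_agb(tree: TreeRecord) -> float:
    """Aboveground biomass of a single tree in kilograms.

    Evaluates the species' binary power-law model a * D^b * H^c.
    Raises :class:`UnsupportedSpeciesError` for species without a model
    (mixed-stand plots may carry other species; callers exclude them).
    """
    try:
        a, b, c = SPECIES_COEFFICIENTS[tree.species]
    except KeyError:
        raise UnsupportedSpeciesError(
            f"no allometric model for species {tree.species!r}; "
            f"supported: {sorted(SPECIES_COEFFICIENTS)}"
        ) from None
    return a * tree.dbh_cm**b * tree.height_m**c


def plot_agb(plot: PlotRecord) -> float:
    """Plot AGB density in tonnes per hectare (t/hm2).

    Sums per-tree masses (kg), converts to tonnes and divides by plot
    area. An empty tree list gives 0.
    """
    if not plot.area_hm2 > 0:
        raise ValueError("plot area must be positive")
    total_kg = sum(tree_agb(t) for t in plot.trees)
    return total_kg / KG_PER_TONNE / plot.area_hm2


def read_plot_csv(path) -> list[PlotRecord]:
    """Read plots from a long-format CSV.

    Expected columns: plot_id, x, y, area_hm2, species, dbh_cm, height_m —
    one row per tree; plots with no tree rows are not representable in
    this format (write an explicit zero-density row downstream instead).
    """
    df = pd.read_csv(path)
    plots: list[PlotRecord] = []
    for pid, grp in df.groupby("plot_id", sort=False):
        head = grp.iloc[0]
        trees = [
            TreeRecord(r.species, float(r.dbh_cm), float(r.height_m))
            for r in grp.itertuples()
        ]
        plots.append(
            PlotRecord(
                plot_id=str(pid),
                x=float(head.x),
                y=float(head.y),
                area_hm2=float(head.area_hm2),
                trees=trees,
            )
        )
    return plots


def write_plot_agb_csv(plots: list[PlotRecord], path) -> pd.DataFrame:
    """Write a per-plot AGB density table (plot_id, x, y, area_hm2, n_trees, agb_t_per_hm2)."""
    df = pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "x": [p.x for p in plots],
            "y": [p.y for p in plots],
            "area_hm2": [p.area_hm2 for p in plots],
            "n_trees": [len(p.trees) for p in plots],
            "agb_t_per_hm2": [p.agb_t_per_hm2 for p in plots],
        }
    )
    df.to_csv(path, index=False)
    return df
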