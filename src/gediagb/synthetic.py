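"""Synthetic GEDI-like scenes: metric fields, orbital footprint tracks, plots, waveforms.

Everything downstream (filtering, thinning, interpolation, biomass
modeling) is testable without any granule download by emulating the
acquisition geometry of a spaceborne full-waveform lidar:

* ~25 m footprints every 60 m along track, eight parallel beams 600 m
  apart (4.2 km swath), several crossing overpasses producing the
  characteristic overlap lattice;
* spatially autocorrelated canopy-metric fields (Gaussian random fields
  with an exponential covariance, synthesized spectrally);
* quality-flag contamination at configurable rates;
* field plots whose tree lists (species, DBH, height) are generated so
  the resulting allometric plot AGB tracks a linear combination of the
  local metric fields plus noise.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from .allometry import PlotRecord, TreeRecord, tree_agb
from .raster import RasterGrid

__all__ = [
    "METRIC_SCHEMA",
    "DEFAULT_METRIC_STATS",
    "FieldSpec",
    "OrbitSpec",
    "PlotSimSpec",
    "SimulatedWaveform",
    "generate_field",
    "simulate_tracks",
    "sample_footprints",
    "simulate_plots",
    "simulate_waveform",
    "default_scene",
    "SyntheticScene",
]

#: The 14 footprint-level L2B modeling metrics.
METRIC_SCHEMA: tuple[str, ...] = (
    "cover",
    "dem",
    "fhd_normal",
    "landsat_treecover",
    "leaf_off_doy",
    "leaf_on_doy",
    "modis_treecover",
    "modis_nonvegetated",
    "pai",
    "pgap_thea",
    "rg",
    "rh100",
    "rv",
    "sensitivity",
)

#: Realistic (mean, sill) defaults per metric for a high-elevation
#: spruce-fir landscape: canopy cover fractions, DEM around 3500 m,
#: plant-area index ~3, ground/vegetation return integrals, 25 m canopies.
DEFAULT_METRIC_STATS: dict[str, tuple[float, float]] = {
    "cover": (0.55, 0.020),
    "dem": (3500.0, 4.0e4),
    "fhd_normal": (2.7, 0.09),
    "landsat_treecover": (65.0, 150.0),
    "leaf_off_doy": (300.0, 400.0),
    "leaf_on_doy": (120.0, 400.0),
    "modis_treecover": (60.0, 120.0),
    "modis_nonvegetated": (10.0, 16.0),
    "pai": (3.0, 0.5),
    "pgap_thea": (0.40, 0.015),
    "rg": (40.0, 90.0),
    "rh100": (25.0, 25.0),
    "rv": (30.0, 60.0),
    "sensitivity": (0.95, 4.0e-4),
}

Extent = tuple[float, float, float, float]  # (xmin, ymin, xmax, ymax)


class OutOfExtentError(ValueError):
    """A footprint or plot falls outside the metric-field extent."""


def _derive_seed(seed: int, label: str) -> int:
    """Stable per-label sub-seed (crc32 mix, keeps values < 2**31)."""
    return (int(seed) ^ zlib.crc32(label.encode())) % (2**31 - 1)


def _check_extent(extent: Extent) -> Extent:
    xmin, ymin, xmax, ymax = (float(v) for v in extent)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate extent {extent}")
    return (xmin, ymin, xmax, ymax)


# ---------------------------------------------------------------------------
# Random metric fields


@dataclass(frozen=True)
class FieldSpec:
    """Gaussian-random-field specification for one or more metrics.

    ``means``/``sills`` map metric name -> field mean and variance;
    ``range_m`` is the exponential-covariance correlation length and
    ``nugget`` the fraction of the sill assigned to uncorrelated
    micro-scale variance.
    """

    extent: Extent
    means: dict[str, float]
    sills: dict[str, float]
    range_m: float = 12000.0
    nugget: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        _check_extent(self.extent)
        if not self.range_m > 0:
            raise ValueError("range_m must be positive")
        if not 0.0 <= self.nugget <= 1.0:
            raise ValueError("nugget must be in [0, 1]")
        for name, sill in self.sills.items():
            if sill < 0:
                raise ValueError(f"sill for {name!r} must be >= 0")
        if set(self.means) != set(self.sills):
            raise ValueError("means and sills must cover the same metrics")

    @classmethod
    def from_dict(cls, cfg: dict) -> "FieldSpec":
        return cls(
            extent=tuple(cfg["extent"]),
            means=dict(cfg["means"]),
            sills=dict(cfg["sills"]),
            range_m=float(cfg.get("range_m", 12000.0)),
            nugget=float(cfg.get("nugget", 0.02)),
            seed=int(cfg["seed"]),
        )


def _grf_exponential(
    shape: tuple[int, int], cell: float, range_m: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance stationary field with exponential covariance exp(-r/a).

    Spectral synthesis: white Gaussian noise is filtered in Fourier space
    with the square root of the 2-D spectral density of the exponential
    covariance, S(k) ~ a^2 / (1 + (a k)^2)^(3/2); the realization is then
    rescaled to unit sample variance so the target sill is met exactly.
    """
    ny, nx = shape
    # pad to reduce periodic wrap-around correlation
    py = int(2 ** np.ceil(np.log2(max(2 * ny, 8))))
    px = int(2 ** np.ceil(np.log2(max(2 * nx, 8))))
    ky = np.fft.fftfreq(py, d=cell) * 2.0 * np.pi
    kx = np.fft.fftfreq(px, d=cell) * 2.0 * np.pi
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    spec = (1.0 + (range_m**2) * k2) ** (-1.5)
    noise = rng.standard_normal((py, px))
    f = np.fft.ifft2(np.fft.fft2(noise) * np.sqrt(spec)).real[:ny, :nx]
    sd = f.std()
    if sd == 0:  # degenerate 1x1 grid
        return np.zeros(shape)
    return (f - f.mean()) / sd


def generate_field(spec: FieldSpec, resolution_m: float) -> dict[str, RasterGrid]:
    """Generate one autocorrelated raster per metric in the spec.

    A zero sill yields a constant field equal to the mean. Identical
    spec + seed give bit-identical grids (per-metric sub-seeds are
    derived from the metric name, so adding a metric does not perturb
    the others).
    """
    if not resolution_m > 0:
        raise ValueError("resolution_m must be positive")
    xmin, ymin, xmax, ymax = _check_extent(spec.extent)
    n_cols = max(1, int(round((xmax - xmin) / resolution_m)))
    n_rows = max(1, int(round((ymax - ymin) / resolution_m)))
    grids: dict[str, RasterGrid] = {}
    for name in spec.means:
        mean, sill = spec.means[name], spec.sills[name]
        if sill == 0:
            values = np.full((n_rows, n_cols), mean)
        else:
            rng = np.random.default_rng(_derive_seed(spec.seed, f"field:{name}"))
            corr = _grf_exponential((n_rows, n_cols), resolution_m, spec.range_m, rng)
            values = mean + np.sqrt(sill * (1.0 - spec.nugget)) * corr
            if spec.nugget > 0:
                values = values + rng.normal(
                    0.0, np.sqrt(sill * spec.nugget), size=values.shape
                )
        grids[name] = RasterGrid(
            origin_x=xmin,
            origin_y=ymin + n_rows * resolution_m,
            cell_size_m=resolution_m,
            values=values,
            variable=name,
        )
    return grids


# ---------------------------------------------------------------------------
# Orbital track geometry


@dataclass(frozen=True)
class OrbitSpec:
    """Acquisition geometry: beam layout and overpass directions.

    Defaults mirror the instrument: 60 m shot spacing along track, eight
    beams 600 m apart across a 4.2 km swath, ~25 m footprints. Each
    entry of ``overpass_azimuths`` (degrees clockwise from north) adds
    one full beam family crossing the scene.
    """

    along_track_spacing_m: float = 60.0
    cross_track_spacing_m: float = 600.0
    swath_width_m: float = 4200.0
    n_beams: int = 8
    footprint_diameter_m: float = 25.0
    overpass_azimuths: tuple[float, ...] = (0.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        for nm in ("along_track_spacing_m", "cross_track_spacing_m", "swath_width_m"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be positive")
        if self.n_beams < 1:
            raise ValueError("n_beams must be >= 1")
        if (self.n_beams - 1) * self.cross_track_spacing_m > self.swath_width_m:
            raise ValueError("beams do not fit in the swath")
        object.__setattr__(
            self, "overpass_azimuths", tuple(float(a) for a in self.overpass_azimuths)
        )

    @classmethod
    def from_dict(cls, cfg: dict) -> "OrbitSpec":
        kwargs = {k: cfg[k] for k in cfg if k in cls.__dataclass_fields__}
        return cls(**kwargs)


def simulate_tracks(orbit: OrbitSpec, extent: Extent) -> pd.DataFrame:
    """Place footprint centers along every beam of every overpass.

    Shots sit every ``along_track_spacing_m`` along each beam line,
    starting where the line enters the extent; beams are offset
    symmetrically about the overpass center line. Shot numbering is
    sequential within each beam. Returns a table with columns
    (shot_id, beam, track, x, y); empty (with a warning) when no track
    crosses the extent.
    """
    xmin, ymin, xmax, ymax = _check_extent(extent)
    bbox = box(xmin, ymin, xmax, ymax)
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    reach = float(np.hypot(xmax - xmin, ymax - ymin))

    rows: list[tuple[int, str, str, float, float]] = []
    for t_idx, az in enumerate(orbit.overpass_azimuths):
        theta = np.deg2rad(az)
        dx, dy = np.sin(theta), np.cos(theta)  # along-track direction
        nx, ny = np.cos(theta), -np.sin(theta)  # cross-track normal
        for b_idx in range(orbit.n_beams):
            off = (b_idx - (orbit.n_beams - 1) / 2.0) * orbit.cross_track_spacing_m
            px, py = cx + off * nx, cy + off * ny
            line = LineString(
                [(px - reach * dx, py - reach * dy), (px + reach * dx, py + reach * dy)]
            )
            seg = line.intersection(bbox)
            if seg.is_empty or seg.length == 0:
                continue
            s = orbit.along_track_spacing_m
            n_shots = int(np.floor(seg.length / s + 1e-9)) + 1
            for rank in range(n_shots):
                pt = seg.interpolate(rank * s)
                shot_id = (t_idx * 100 + b_idx) * 10_000_000 + rank
                rows.append((shot_id, f"BEAM{b_idx:02d}", f"T{t_idx}", pt.x, pt.y))

    table = pd.DataFrame(rows, columns=["shot_id", "beam", "track", "x", "y"])
    if table.empty:
        warnings.warn("no track intersects the extent; returning empty table")
        table = pd.DataFrame(
            {
                "shot_id": pd.Series(dtype="int64"),
                "beam": pd.Series(dtype="object"),
                "track": pd.Series(dtype="object"),
                "x": pd.Series(dtype="float64"),
                "y": pd.Series(dtype="float64"),
            }
        )
    return table


# ---------------------------------------------------------------------------
# Footprint metric sampling and quality contamination


def sample_footprints(
    table: pd.DataFrame,
    fields: dict[str, RasterGrid],
    noise_std: float | dict[str, float] = 0.0,
    contamination: Optional[dict[str, float]] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach metric values and quality fields to footprint geometries.

    Each metric is read from its field at the cell containing the
    footprint (exact lookup at zero noise) plus independent Gaussian
    noise. ``contamination`` fractions ({"quality", "degrade",
    "sensitivity"}) control how many records violate each quality
    criterion: quality_flag 0 instead of 1, degrade_flag 1 instead of 0,
    sensitivity below 0.9 instead of in [0.9, 1).
    """
    contamination = dict(contamination or {})
    unknown = set(contamination) - {"quality", "degrade", "sensitivity"}
    if unknown:
        raise ValueError(f"unknown contamination keys: {sorted(unknown)}")
    out = table.copy()
    if len(out) == 0:
        for name in fields:
            out[name] = pd.Series(dtype=float)
        for name in ("sensitivity", "quality_flag", "degrade_flag"):
            if name not in out:
                out[name] = pd.Series(dtype=float)
        return out

    x = out["x"].to_numpy(float)
    y = out["y"].to_numpy(float)
    rng = np.random.default_rng(_derive_seed(seed, "sample_footprints"))
    for name, grid in fields.items():
        if not np.all(grid.contains(x, y)):
            raise OutOfExtentError(f"footprints outside the {name!r} field extent")
        vals = grid.value_at(x, y)
        sd = noise_std.get(name, 0.0) if isinstance(noise_std, dict) else noise_std
        if sd:
            vals = vals + rng.normal(0.0, sd, size=vals.shape)
        out[name] = vals

    n = len(out)
    # sensitivity doubles as metric and quality field; when no field
    # supplies it, draw plausible forest values in [0.9, 1)
    if "sensitivity" not in out:
        out["sensitivity"] = rng.uniform(0.90, 0.995, size=n)
    bad_sens = rng.random(n) < contamination.get("sensitivity", 0.0)
    out.loc[bad_sens, "sensitivity"] = rng.uniform(0.5, 0.899, size=int(bad_sens.sum()))

    quality = np.ones(n, dtype=int)
    quality[rng.random(n) < contamination.get("quality", 0.0)] = 0
    degrade = np.zeros(n, dtype=int)
    degrade[rng.random(n) < contamination.get("degrade", 0.0)] = 1
    out["quality_flag"] = quality
    out["degrade_flag"] = degrade
    return out


# ---------------------------------------------------------------------------
# Field plots with tree lists


@dataclass(frozen=True)
class PlotSimSpec:
    """Specification for simulated inventory plots.

    Tree DBH is lognormal (``dbh_log_mu``/``dbh_log_sigma`` on the log
    scale, cm); height follows a Chapman-Richards curve
    H = 1.3 + h_a * (1 - exp(-h_b * D))**h_c with multiplicative
    lognormal noise of coefficient of variation ``height_noise_cv``.
    ``agb_field_coupling`` ties plot AGB to local metric-field values:
    {"intercept": t/hm2, "coefficients": {metric: t/hm2 per metric
    unit}, "noise_sd": t/hm2}; when present, the tree list is grown
    until the allometric plot AGB best matches the coupled target, so
    plot AGB is always the allometry of the actual tree list.
    """

    n_plots: int = 138
    plot_area_hm2: float = 0.0667
    stems_per_plot: tuple[int, int] = (0, 3000)
    dbh_log_mu: float = np.log(22.0)
    dbh_log_sigma: float = 0.35
    height_a: float = 38.0
    height_b: float = 0.045
    height_c: float = 1.2
    height_noise_cv: float = 0.08
    species_mix: float = 0.6
    agb_field_coupling: Optional[dict] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.plot_area_hm2 > 0:
            raise ValueError("plot_area_hm2 must be positive")
        if not 0.0 <= self.species_mix <= 1.0:
            raise ValueError("species_mix must be in [0, 1]")
        lo, hi = self.stems_per_plot
        if lo < 0 or hi < lo:
            raise ValueError("stems_per_plot must be a (min, max) range with 0 <= min <= max")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PlotSimSpec":
        kwargs = {k: cfg[k] for k in cfg if k in cls.__dataclass_fields__}
        if "stems_per_plot" in kwargs:
            kwargs["stems_per_plot"] = tuple(kwargs["stems_per_plot"])
        return cls(**kwargs)


def _draw_tree(spec: PlotSimSpec, rng: np.random.Generator) -> TreeRecord:
    species = "spruce" if rng.random() < spec.species_mix else "fir"
    d = float(rng.lognormal(spec.dbh_log_mu, spec.dbh_log_sigma))
    h_det = 1.3 + spec.height_a * (1.0 - np.exp(-spec.height_b * d)) ** spec.height_c
    sigma = np.sqrt(np.log(1.0 + spec.height_noise_cv**2))
    h = float(h_det * rng.lognormal(-0.5 * sigma**2, sigma))
    return TreeRecord(species, d, max(h, 1.5))


def simulate_plots(
    spec: PlotSimSpec, fields: dict[str, RasterGrid]
) -> list[PlotRecord]:
    """Simulate inventory plots inside the field extent.

    Without coupling, each plot receives a uniform random stem count in
    ``stems_per_plot``. With coupling, trees are added one at a time
    until the plot's allometric AGB density is as close as possible to
    the coupled target (intercept + sum coef * field value + noise),
    clipped below at 1 t/hm2 — the discrete tree granularity is the only
    residual at zero coupling noise.
    """
    if not fields:
        raise ValueError("at least one metric field is required to place plots")
    any_grid = next(iter(fields.values()))
    xmin, ymin, xmax, ymax = any_grid.extent
    rng = np.random.default_rng(_derive_seed(spec.seed, "plots"))
    coupling = spec.agb_field_coupling
    if coupling is not None:
        missing = set(coupling.get("coefficients", {})) - set(fields)
        if missing:
            raise ValueError(f"coupling references absent fields: {sorted(missing)}")

    plots: list[PlotRecord] = []
    lo, hi = spec.stems_per_plot
    for i in range(spec.n_plots):
        px = float(rng.uniform(xmin, xmax))
        py = float(rng.uniform(ymin, ymax))
        plot = PlotRecord(
            plot_id=f"P{i:04d}", x=px, y=py, area_hm2=spec.plot_area_hm2
        )
        if coupling is None:
            n_stems = int(rng.integers(lo, hi + 1))
            plot.trees = [_draw_tree(spec, rng) for _ in range(n_stems)]
        else:
            target = float(coupling.get("intercept", 0.0))
            for name, coef in coupling.get("coefficients", {}).items():
                target += coef * float(fields[name].value_at(px, py)[0])
            noise_sd = float(coupling.get("noise_sd", 0.0))
            if noise_sd:
                target += float(rng.normal(0.0, noise_sd))
            target = max(target, 1.0)
            trees: list[TreeRecord] = []
            agb = 0.0
            while len(trees) < hi:
                cand = _draw_tree(spec, rng)
                new_agb = agb + _tree_density(cand, spec.plot_area_hm2)
                if abs(new_agb - target) >= abs(agb - target) and len(trees) >= lo:
                    break
                trees.append(cand)
                agb = new_agb
            plot.trees = trees
        plots.append(plot)
    return plots


def _tree_density(tree: TreeRecord, area_hm2: float) -> float:
    return tree_agb(tree) / 1000.0 / area_hm2


def plots_to_tree_table(plots: Sequence[PlotRecord]) -> pd.DataFrame:
    """Long-format tree table (plot_id, x, y, area_hm2, species, dbh_cm, height_m)."""
    rows = [
        (p.plot_id, p.x, p.y, p.area_hm2, t.species, t.dbh_cm, t.height_m)
        for p in plots
        for t in p.trees
    ]
    return pd.DataFrame(
        rows, columns=["plot_id", "x", "y", "area_hm2", "species", "dbh_cm", "height_m"]
    )


# ---------------------------------------------------------------------------
# Waveforms


@dataclass(frozen=True)
class SimulatedWaveform:
    """A synthetic waveform plus its ground-truth signal extent (merged segments)."""

    waveform: "object"
    true_segments: tuple[tuple[int, int], ...]

    @property
    def true_extent(self) -> Optional[tuple[int, int]]:
        if not self.true_segments:
            return None
        return (self.true_segments[0][0], self.true_segments[-1][1])


def simulate_waveform(
    n_bins: int,
    noise_mean: float,
    noise_std: float,
    signal_segments: Sequence[tuple[int, int, float]] = (),
    seed: int = 0,
    bin_width_ns: float = 2.0,
    constant_c: float = 4.0,
) -> SimulatedWaveform:
    """Gaussian noise floor plus rectangular signal bumps.

    ``signal_segments`` are (start_bin, end_bin, amplitude) with
    inclusive ends; overlapping or touching segments are merged (with a
    warning) in the recorded ground truth. The returned waveform carries
    the configured noise statistics for thresholding.
    """
    from .waveform import Waveform

    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    if noise_std < 0:
        raise ValueError("noise_std must be non-negative")
    rng = np.random.default_rng(_derive_seed(seed, "waveform"))
    intensities = rng.normal(noise_mean, noise_std, size=n_bins)

    segs = sorted((int(s), int(e), float(a)) for s, e, a in signal_segments)
    merged: list[list[int]] = []
    for s, e, a in segs:
        if s > e or s < 0 or e >= n_bins:
            raise ValueError(f"segment ({s}, {e}) outside [0, {n_bins - 1}]")
        intensities[s : e + 1] += a
        if merged and s <= merged[-1][1] + 1:
            warnings.warn("overlapping signal segments merged in ground truth")
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    wf = Waveform(
        intensities=intensities,
        bin_width_ns=bin_width_ns,
        noise_mean=noise_mean,
        noise_std=noise_std,
        constant_c=constant_c,
    )
    return SimulatedWaveform(wf, tuple((s, e) for s, e in merged))


# ---------------------------------------------------------------------------
# The default end-to-end scene


@dataclass
class SyntheticScene:
    """A complete simulated study area ready for the full workflow."""

    extent: Extent
    fields: dict[str, RasterGrid]
    footprints: pd.DataFrame  # with metrics + quality fields
    plots: list[PlotRecord]
    field_spec: FieldSpec
    orbit_spec: OrbitSpec
    plot_spec: PlotSimSpec


#: Metrics coupled to plot AGB in the default scene (the structure/terrain
#: variables a biomass model is expected to latch onto), with coefficients
#: expressed per standard deviation of each field.
DEFAULT_COUPLING_SD_UNITS: dict[str, float] = {
    "rg": 37.0,
    "pai": 30.0,
    "pgap_thea": -25.0,
    "cover": 25.0,
    "fhd_normal": 20.0,
}


def default_coupling(
    means: dict[str, float],
    sills: dict[str, float],
    mean_agb: float = 100.0,
    noise_sd: float = 0.0,
    sd_units: Optional[dict[str, float]] = None,
) -> dict:
    """Translate per-SD coupling strengths into natural metric units.

    The intercept is set so a plot sitting at every field's mean gets
    ``mean_agb`` t/hm2.
    """
    sd_units = dict(DEFAULT_COUPLING_SD_UNITS if sd_units is None else sd_units)
    coeffs = {m: c / np.sqrt(sills[m]) for m, c in sd_units.items()}
    intercept = mean_agb - sum(c * means[m] for m, c in coeffs.items())
    return {"intercept": intercept, "coefficients": coeffs, "noise_sd": noise_sd}


def default_scene(
    seed: int = 0,
    extent_km: float = 42.0,
    n_overpasses: int = 21,
    field_resolution_m: float = 60.0,
    n_plots: int = 138,
    coupling_noise_fraction: float = 0.30,
    contamination: Optional[dict[str, float]] = None,
    metric_noise_fraction: float = 0.05,
) -> SyntheticScene:
    """Build the default synthetic study area.

    A ~42 km square with 26 crossing overpasses of 8 beams reproduces
    the scale of a real mountainous study area: ~1.3e5 raw footprints,
    so interval-100 thinning of the quality-filtered set retains ~1.3e3
    — the density regime the sampling experiment targets. 138 plots are
    coupled to five structure metrics with coupling noise SD equal to
    ``coupling_noise_fraction`` of the deterministic AGB SD.
    """
    half = extent_km * 500.0
    extent: Extent = (-half, -half, half, half)
    means = {m: DEFAULT_METRIC_STATS[m][0] for m in METRIC_SCHEMA}
    sills = {m: DEFAULT_METRIC_STATS[m][1] for m in METRIC_SCHEMA}
    fspec = FieldSpec(
        extent=extent, means=means, sills=sills, seed=_derive_seed(seed, "scene-fields")
    )
    fields = generate_field(fspec, field_resolution_m)

    azimuths = tuple(np.linspace(0.0, 180.0, n_overpasses, endpoint=False))
    ospec = OrbitSpec(overpass_azimuths=azimuths, seed=_derive_seed(seed, "scene-orbit"))
    tracks = simulate_tracks(ospec, extent)
    if contamination is None:
        contamination = {"quality": 0.05, "degrade": 0.02, "sensitivity": 0.05}
    noise = {
        m: metric_noise_fraction * np.sqrt(sills[m])
        for m in METRIC_SCHEMA
        if m != "sensitivity"
    }
    foot_fields = {m: fields[m] for m in METRIC_SCHEMA if m != "sensitivity"}
    footprints = sample_footprints(
        tracks,
        foot_fields,
        noise_std=noise,
        contamination=contamination,
        seed=_derive_seed(seed, "scene-sample"),
    )

    # deterministic coupled targets at probe sites fix the noise scale
    coupling0 = default_coupling(means, sills)
    probe_rng = np.random.default_rng(_derive_seed(seed, "scene-noise-scale"))
    px = probe_rng.uniform(extent[0], extent[2], size=400)
    py = probe_rng.uniform(extent[1], extent[3], size=400)
    det = np.full(400, coupling0["intercept"])
    for m, c in coupling0["coefficients"].items():
        det = det + c * fields[m].value_at(px, py)
    coupling = default_coupling(
        means, sills, noise_sd=coupling_noise_fraction * float(det.std())
    )
    pspec = PlotSimSpec(
        n_plots=n_plots,
        agb_field_coupling=coupling,
        seed=_derive_seed(seed, "scene-plots"),
    )
    plots = simulate_plots(pspec, fields)
    return SyntheticScene(extent, fields, footprints, plots, fspec, ospec, pspec)
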