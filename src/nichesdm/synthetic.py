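"""Virtual climates and virtual species with analytically known niche shifts.

Every downstream stage of the pipeline (niche comparison, ensemble SDM,
projection) can be validated against simulated data generated here:

* spatially autocorrelated climate layers with bioclim-like value ranges,
* a virtual species whose suitability is a product of independent Gaussian
  responses, one per climate layer,
* paired native/invasive occurrence sets whose niche overlap (Schoener's D)
  and COUE expansion/stability/unfilling are computed by brute-force
  numerical integration of the two response surfaces over the realized
  climate — an oracle that is entirely independent of the kernel-density
  estimator in :mod:`nichesdm.niche`.

Both the estimator and the oracle treat the response as zero beyond
``SUPPORT_SD`` standard deviations (breadths) from the optimum, so "niche
membership" has one deterministic definition across the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .occurrences import make_occurrence_frame
from .raster import ClimateStack, GridTransform, SuitabilityMap

__all__ = [
    "SUPPORT_SD",
    "SyntheticClimateSpec",
    "VirtualNicheSpec",
    "ShiftScenario",
    "NicheTruth",
    "generate_climate_stack",
    "true_suitability",
    "sample_occurrences",
    "make_shift_scenario",
    "niche_truth",
    "default_climate_spec",
]

#: Gaussian responses (and the estimator's kernels) are truncated to zero
#: beyond this many standard deviations; defines niche support exactly.
SUPPORT_SD = 4.0


class InvalidSpecError(ValueError):
    """Synthetic specification violates its invariants."""


class InsufficientHabitatError(RuntimeError):
    """Fewer positive-suitability cells than occurrences requested."""


@dataclass(frozen=True)
class SyntheticClimateSpec:
    """Recipe for a stack of smooth random climate layers.

    ``extent`` is (west, south, east, north) in degrees; ``resolution`` is
    the cell size in arcminutes; ``autocorrelation_length`` is the Gaussian
    smoothing scale in cells (0 = white noise); ``value_ranges`` maps each
    layer name to the (min, max) it is rescaled to.
    """

    extent: tuple[float, float, float, float] = (-20.0, 30.0, 20.0, 60.0)
    resolution: float = 10.0  # arcminutes
    layer_names: tuple[str, ...] = ("bio4", "bio5", "bio6", "bio12", "bio15")
    autocorrelation_length: float = 5.0
    value_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "bio4": (100.0, 1200.0),  # temperature seasonality (sd*100, deg C)
            "bio5": (5.0, 42.0),  # max temperature of warmest month (deg C)
            "bio6": (-30.0, 20.0),  # min temperature of coldest month (deg C)
            "bio12": (0.0, 3000.0),  # annual precipitation (mm)
            "bio15": (5.0, 120.0),  # precipitation seasonality (CV)
        }
    )
    #: distribution of layer values over cells: "normal" keeps the smoothed
    #: field's bell-shaped histogram; "uniform" rank-transforms it so every
    #: value in the range is equally available (handy for calibration studies)
    marginal: str = "normal"
    seed: int = 0

    def validate(self) -> None:
        west, south, east, north = self.extent
        if east <= west or north <= south:
            raise InvalidSpecError(f"empty extent {self.extent}")
        if self.resolution <= 0:
            raise InvalidSpecError("resolution must be > 0")
        if self.autocorrelation_length < 0:
            raise InvalidSpecError("autocorrelation_length must be >= 0")
        if self.marginal not in ("normal", "uniform"):
            raise InvalidSpecError(f"unknown marginal {self.marginal!r}")
        for name in self.layer_names:
            if name not in self.value_ranges:
                raise InvalidSpecError(f"no value range for layer {name!r}")
            lo, hi = self.value_ranges[name]
            if not lo < hi:
                raise InvalidSpecError(f"layer {name!r}: need min < max, got {lo, hi}")


def default_climate_spec(**overrides) -> SyntheticClimateSpec:
    """The package's standard virtual study area (a 40 x 30 degree region at
    10-arcminute resolution with the five retained bioclim layers)."""
    return SyntheticClimateSpec(**overrides)


@dataclass(frozen=True)
class VirtualNicheSpec:
    """Gaussian response per layer: optimum and breadth in layer units."""

    layers: tuple[str, ...]
    optimum: tuple[float, ...]
    breadth: tuple[float, ...]
    max_suitability: float = 1.0

    def validate(self) -> None:
        if not (len(self.layers) == len(self.optimum) == len(self.breadth)):
            raise InvalidSpecError("optimum/breadth must have one entry per layer")
        if any(b <= 0 for b in self.breadth):
            raise InvalidSpecError("breadth must be strictly positive")
        if not 0 <= self.max_suitability <= 1:
            raise InvalidSpecError("max_suitability must be in [0, 1]")

    def response(self, env: np.ndarray, truncate: float | None = SUPPORT_SD) -> np.ndarray:
        """Suitability for environment rows (n, k); Gaussian product.

        With ``truncate`` the response is zeroed beyond that Mahalanobis
        (breadth-scaled) radius from the optimum, giving the niche a
        sharp elliptical support — the oracle's definition of presence.
        """
        self.validate()
        env = np.asarray(env, dtype=float)
        z = (env - np.asarray(self.optimum)) / np.asarray(self.breadth)
        r2 = np.sum(z**2, axis=-1)
        s = self.max_suitability * np.exp(-0.5 * r2)
        if truncate is not None:
            s = np.where(r2 > truncate**2, 0.0, s)
        return s


@dataclass(frozen=True)
class ShiftScenario:
    """Paired native/invasive virtual niches over one climate."""

    native_niche: VirtualNicheSpec
    invasive_niche: VirtualNicheSpec
    n_native: int = 500
    n_invasive: int = 500
    seed: int = 0

    def validate(self) -> None:
        self.native_niche.validate()
        self.invasive_niche.validate()
        if self.n_native < 20 or self.n_invasive < 20:
            raise InvalidSpecError("need at least 20 occurrences per range")
        if self.native_niche.layers != self.invasive_niche.layers:
            raise InvalidSpecError("both niches must be defined over the same layers")


@dataclass(frozen=True)
class NicheTruth:
    """Oracle niche-dynamics values from dense numerical integration."""

    d: float
    expansion: float
    stability: float
    unfilling: float


def generate_climate_stack(spec: SyntheticClimateSpec) -> ClimateStack:
    """Smooth seeded white noise into spatially autocorrelated layers.

    Each layer is an independent white-noise field smoothed with a Gaussian
    kernel of width ``autocorrelation_length`` (in cells) and affinely
    rescaled so its min/max hit the configured value range exactly.
    """
    spec.validate()
    west, south, east, north = spec.extent
    cell = spec.resolution / 60.0
    ncol = max(int(round((east - west) / cell)), 1)
    nrow = max(int(round((north - south) / cell)), 1)
    rng = np.random.default_rng(spec.seed)
    layers = {}
    for name in spec.layer_names:
        field_ = rng.standard_normal((nrow, ncol))
        if spec.autocorrelation_length > 0:
            field_ = gaussian_filter(
                field_, sigma=spec.autocorrelation_length, mode="reflect"
            )
        lo, hi = spec.value_ranges[name]
        if spec.marginal == "uniform":
            # rank transform: preserves the spatial pattern, flattens the
            # value histogram so availability is even across the range
            order = np.argsort(field_, axis=None)
            ranks = np.empty(field_.size)
            ranks[order] = np.arange(field_.size)
            field_ = (ranks / max(field_.size - 1, 1)).reshape(field_.shape)
            field_ = lo + field_ * (hi - lo)
        else:
            fmin, fmax = field_.min(), field_.max()
            if fmax > fmin:
                field_ = lo + (field_ - fmin) * (hi - lo) / (fmax - fmin)
            else:  # pragma: no cover - degenerate single-cell grid
                field_ = np.full_like(field_, 0.5 * (lo + hi))
        layers[name] = field_
    transform = GridTransform(west=west, north=north, cell_size=cell)
    return ClimateStack(layers=layers, transform=transform)


def true_suitability(climate: ClimateStack, niche: VirtualNicheSpec) -> SuitabilityMap:
    """Evaluate the Gaussian-product response on every climate cell.

    The response is *not* truncated here: this is the smooth ground-truth
    surface used for sampling and for SDM-recovery checks.  Nodata cells
    propagate as NaN.
    """
    niche.validate()
    climate.require_layers(niche.layers)
    env = np.stack([climate.layers[n] for n in niche.layers], axis=-1)
    s = niche.response(env.reshape(-1, len(niche.layers)), truncate=None)
    s = s.reshape(climate.shape)
    s = np.where(climate.nodata_mask, np.nan, s)
    return SuitabilityMap(values=s, transform=climate.transform, scenario="truth")


def sample_occurrences(
    truth: SuitabilityMap,
    n: int,
    seed: int,
    species: str = "virtual",
    status: str = "unknown",
) -> pd.DataFrame:
    """Draw n distinct cells with probability proportional to suitability.

    Records are placed at cell centres (one record per cell, matching the
    thinned resolution of real analyses).
    """
    values = truth.values
    ok = np.isfinite(values) & (values > 0)
    rows, cols = np.nonzero(ok)
    if len(rows) < n:
        raise InsufficientHabitatError(
            f"requested {n} occurrences but only {len(rows)} cells have "
            "positive suitability"
        )
    w = values[rows, cols]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(rows), size=n, replace=False, p=w / w.sum())
    lon, lat = truth.transform.cell_center(rows[idx], cols[idx])
    return make_occurrence_frame(lon, lat, species=species, status=status)


def _occupied_env_bins(env: np.ndarray, bins_per_axis: int | None = None):
    """Bin centres tiling the support of the realized environment.

    The bin width is chosen so that an average occupied bin holds several
    climate cells — the occupied-bin set then approximates the *region* the
    environment covers (uniform measure over support), rather than echoing
    the cell density.  Interior holes left by sparse sampling are closed
    morphologically.
    """
    from scipy.ndimage import binary_closing

    n, k = env.shape
    if bins_per_axis is None:
        bins_per_axis = max(12, int((n / 8) ** (1.0 / k)))
    lo = env.min(axis=0)
    hi = env.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    width = span / bins_per_axis
    idx = np.floor((env - lo) / width).astype(int)
    idx = np.minimum(idx, bins_per_axis - 1)
    occupied = np.zeros((bins_per_axis,) * k, dtype=bool)
    occupied[tuple(idx.T)] = True
    occupied = binary_closing(occupied, structure=np.ones((3,) * k, dtype=bool))
    uniq = np.argwhere(occupied)
    centers = lo + (uniq + 0.5) * width
    return centers


def niche_truth(
    climate: ClimateStack,
    native: VirtualNicheSpec,
    invasive: VirtualNicheSpec,
    bins_per_axis: int | None = None,
) -> NicheTruth:
    """Brute-force niche-dynamics oracle in raw layer units.

    The realized environment (all valid climate cells) is binned on a dense
    lattice; on each occupied bin the two truncated Gaussian responses are
    evaluated and normalized to unit mass under the uniform measure over
    occupied bins — the distributional analogue of the occupancy-corrected
    surfaces the estimator builds in PCA space.  Schoener's D and the COUE
    indices follow directly:

    * D = 1 - 0.5 * sum |z_nat - z_inv|
    * expansion = invasive mass on bins where the native response is zero
    * unfilling = native mass on bins where the invasive response is zero
    * stability = 1 - expansion
    """
    native.validate()
    invasive.validate()
    if native.layers != invasive.layers:
        raise InvalidSpecError("niches must share layers")
    climate.require_layers(native.layers)
    rows, cols = climate.valid_cells()
    env = climate.env_matrix(list(native.layers), rows, cols)
    centers = _occupied_env_bins(env, bins_per_axis)

    s_nat = native.response(centers)
    s_inv = invasive.response(centers)
    if s_nat.sum() == 0 or s_inv.sum() == 0:
        raise InsufficientHabitatError("a niche has no support on the realized climate")
    z_nat = s_nat / s_nat.sum()
    z_inv = s_inv / s_inv.sum()

    d = float(1.0 - 0.5 * np.abs(z_nat - z_inv).sum())
    expansion = float(z_inv[s_nat == 0].sum())
    unfilling = float(z_nat[s_inv == 0].sum())
    return NicheTruth(
        d=d, expansion=expansion, stability=1.0 - expansion, unfilling=unfilling
    )


def two_regime_climate(seed: int = 0) -> ClimateStack:
    """A study area whose climate falls into two disjoint environmental
    regimes (e.g. a temperate and a tropical zone with no intermediate
    conditions).

    The western half draws ``bio5`` from 8-20 degC, the eastern half from
    36-48 degC, with a shared precipitation range; the value histograms are
    rank-flattened so every available condition is (approximately) equally
    frequent.  Niche expansion into the second regime — conditions simply
    absent from the first — is the cleanest real-world mechanism of niche
    shift, and the gap between the regimes keeps kernel smoothing on one
    side from bleeding into the other.
    """
    rng = np.random.default_rng(seed)
    s1, s2 = (int(x) for x in rng.integers(0, 2**31 - 1, size=2))
    west = generate_climate_stack(
        SyntheticClimateSpec(
            extent=(-20.0, 30.0, 0.0, 60.0),
            layer_names=("bio5", "bio12"),
            value_ranges={"bio5": (8.0, 20.0), "bio12": (600.0, 1400.0)},
            marginal="uniform",
            seed=s1,
        )
    )
    east = generate_climate_stack(
        SyntheticClimateSpec(
            extent=(0.0, 30.0, 20.0, 60.0),
            layer_names=("bio5", "bio12"),
            value_ranges={"bio5": (36.0, 48.0), "bio12": (600.0, 1400.0)},
            marginal="uniform",
            seed=s2,
        )
    )
    layers = {
        n: np.concatenate([west.layers[n], east.layers[n]], axis=1)
        for n in west.layers
    }
    return ClimateStack(layers=layers, transform=west.transform)


def coue_oracle_suite(
    n_per_range: int = 2000, seed: int = 0
) -> tuple[ClimateStack, dict[str, ShiftScenario]]:
    """Reference scenarios whose oracle expansion spans 0 to 1.

    Built on :func:`two_regime_climate`; the native niche lives in the
    western (cool) regime, and the invasive niche either contracts inside
    it (expansion 0), broadens across both regimes (expansion about 0.25 /
    0.5 / 0.75, depending on how far its optimum sits toward the warm
    regime), or relocates entirely into the warm regime (expansion 1).
    """
    layers = ("bio5", "bio12")
    climate = two_regime_climate(seed=seed)
    native = VirtualNicheSpec(layers, optimum=(14.0, 1000.0), breadth=(2.5, 200.0))
    invaders = {
        "expansion_0.00": VirtualNicheSpec(layers, (14.0, 1000.0), (1.75, 140.0)),
        "expansion_0.25": VirtualNicheSpec(layers, (23.0, 1000.0), (10.0, 200.0)),
        "expansion_0.50": VirtualNicheSpec(layers, (28.0, 1000.0), (10.0, 200.0)),
        "expansion_0.75": VirtualNicheSpec(layers, (33.0, 1000.0), (10.0, 200.0)),
        "expansion_1.00": VirtualNicheSpec(layers, (42.0, 1000.0), (2.5, 200.0)),
    }
    rng = np.random.default_rng(seed + 1)
    scenarios = {
        name: ShiftScenario(
            native_niche=native,
            invasive_niche=inv,
            n_native=n_per_range,
            n_invasive=n_per_range,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for name, inv in invaders.items()
    }
    return climate, scenarios


def make_shift_scenario(
    scenario: ShiftScenario, climate: ClimateStack
) -> tuple[pd.DataFrame, pd.DataFrame, NicheTruth]:
    """Sample native and invasive occurrence sets plus their oracle truth."""
    scenario.validate()
    truth_nat = true_suitability(climate, scenario.native_niche)
    truth_inv = true_suitability(climate, scenario.invasive_niche)
    rng = np.random.default_rng(scenario.seed)
    seed_nat, seed_inv = rng.integers(0, 2**31 - 1, size=2)
    occ_nat = sample_occurrences(
        truth_nat, scenario.n_native, int(seed_nat), status="native"
    )
    occ_inv = sample_occurrences(
        truth_inv, scenario.n_invasive, int(seed_inv), status="invasive"
    )
    truth = niche_truth(climate, scenario.native_niche, scenario.invasive_niche)
    return occ_nat, occ_inv, truth
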