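"""Synthetic stream-survey generator with planted two-tier group structure.

The generator emulates the statistical structure the classification
pipeline assumes about wadeable-stream monitoring data:

* a bimodal annual-rainfall gradient defining two regions (dry *West*,
  wet *East*), with the other climate/geology features mildly
  region-correlated;
* nested habitat archetypes (*Plains*: sandy, run-dominated, wide and
  shallow; *Valley*: silty, pool-dominated, deep; *Rocky*: coarse
  substrate with riffles, East only by default) expressed through
  Dirichlet-distributed six-part substrate and three-part channel-unit
  compositions plus Normal continuous habitat features;
* repeated surveys per site across monitoring cycles with survey noise,
  including an inflated-noise site subset whose cycle-level draws
  straddle group boundaries (producing "non-modal" sites);
* region-correlated conductivity/alkalinity and water chemistry, with a
  configurable fraction of surveys missing chemistry entirely;
* anthropogenic stressor features independent of archetype conditional
  on region (with an optional deliberately biased mode that links crop
  cover to one archetype, for testing the span screen);
* pseudo-ecoregion labels built from a noisy geography proxy so that
  each pseudo-ecoregion mixes archetypes.

Ground truth (per-site region and archetype) is returned alongside
every table, so recovery can be scored with the adjusted Rand index.
All randomness flows through one ``numpy.random.default_rng(seed)``
(PCG64): a fixed seed gives bit-identical tables.

The numeric defaults are generator settings chosen to reproduce the
qualitative contrasts between archetypes at realistic survey noise;
they are not estimates of any particular monitoring program's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from streamarch.datamodel import (
    CHANNEL_UNIT_FEATURES,
    SUBSTRATE_FEATURES,
    SampleTable,
    feature_set,
)

ARCHETYPES = ("Plains", "Valley", "Rocky")
REGIONS = ("West", "East")

#: Dirichlet concentrations over (Silt, Sand, Gravel, Cobble, Boulder, Bedrock).
DEFAULT_SUBSTRATE_ALPHAS = {
    "Plains": (2.0, 12.0, 2.0, 1.0, 0.5, 0.5),
    "Valley": (12.0, 3.0, 2.0, 1.0, 0.5, 0.5),
    "Rocky": (1.0, 2.0, 8.0, 5.0, 2.0, 2.0),
}
#: Dirichlet concentrations over (Pools, Runs, Riffles).
DEFAULT_CHANNEL_ALPHAS = {
    "Plains": (2.0, 10.0, 1.0),
    "Valley": (10.0, 3.0, 1.0),
    "Rocky": (4.0, 4.0, 4.0),
}

# Continuous Tier-II habitat features: (per-archetype mean, within-group SD).
# Units: Sin unitless, W.D unitless, covers %, depths m, Depth.Var m^2,
# Alkalinity mg/L CaCO3, Conductivity uS/cm.
_HABITAT_MEANS = {
    #               Plains  Valley  Rocky    SD
    "Sin":           (1.10,  1.45,  1.25,   0.12),
    "Rocky.Cover":   (6.0,  12.0,  55.0,    9.0),
    "Woody.Cover":  (12.0,  42.0,  16.0,    9.0),
    "Veg.Cover":    (22.0,  14.0,   9.0,    6.0),
    "W.D":          (26.0,   8.0,  15.0,    3.0),
    "Depth.Var":    (0.02,  0.16,  0.08,   0.03),
    "Max.Pool.Depth": (0.5,  1.7,   1.0,    0.2),
}
_NONNEGATIVE = ("Rocky.Cover", "Woody.Cover", "Veg.Cover", "W.D", "Depth.Var",
                "Max.Pool.Depth")
_PERCENT = ("Rocky.Cover", "Woody.Cover", "Veg.Cover")

# Tier-I climate/geology: (West mean, East mean, SD). AnRainC comes from
# rainfall_params instead.  Region shifts are kept below ~1.5 SD so the
# rainfall gradient (~3.8 SD between region means) stays the primary
# discriminator between regions.
_TIER1_MEANS = {
    "Elevation": (550.0, 350.0, 140.0),
    "Slope":     (1.5,   3.0,   1.0),
    "PermCat":   (5.8,   4.2,   1.2),
    "RockDep":   (145.0, 95.0,  35.0),
    "WTDep":     (175.0, 125.0, 35.0),
    "CaOWs":     (5.5,   2.5,   2.0),
    "SWs":       (0.7,   0.3,   0.3),
}

# Water chemistry medians: per-(region, archetype-sensitivity) settings.
# (West mean, East mean, SD, per-archetype shift in SD units P/V/R)
_CHEM_MEANS = {
    "TN":                (1.2,   0.8,  0.30, (0.5, 0.2, -0.6)),
    "Available.N":       (0.30,  0.20, 0.08, (0.4, 0.1, -0.5)),
    "TP":                (0.15,  0.08, 0.04, (0.4, 0.2, -0.6)),
    "OP":                (0.05,  0.03, 0.015, (0.3, 0.1, -0.4)),
    "Chloride":          (90.0,  15.0, 12.0, (0.0, 0.0, 0.0)),
    "Sulfate":           (120.0, 25.0, 18.0, (0.0, 0.0, 0.0)),
    "DO":                (7.5,   8.2,  0.8,  (-0.2, -0.3, 0.5)),
    "DO.perc":           (88.0,  95.0, 8.0,  (-0.2, -0.3, 0.5)),
    "pH":                (8.1,   7.6,  0.25, (0.0, 0.0, 0.1)),
    "TSS":               (45.0,  18.0, 10.0, (0.5, 0.3, -0.6)),
    "Turbidity":         (30.0,  12.0, 7.0,  (0.5, 0.3, -0.6)),
    "Temperature.Water": (24.0,  21.0, 1.5,  (0.3, 0.0, -0.3)),
}

# Alkalinity/Conductivity: East means; the West offset is chem_region_shift.
_ALK_EAST, _ALK_SD = 110.0, 28.0
_COND_EAST, _COND_SD = 320.0, 90.0

# Stressor features: (West mean, East mean, SD); ICI/CCHEM are Beta-drawn.
# Region shifts are mild: the dominant stressor gradients (development,
# catchment integrity) are shared statewide, with cultivation somewhat
# more common in the dry West and hay/pasture in the wet East.
_STRESSOR_MEANS = {
    "OpenUrb":   (4.5, 4.5, 2.0),
    "LowUrb":    (2.5, 2.5, 1.2),
    "MedUrb":    (1.2, 1.2, 0.8),
    "HiUrb":     (0.6, 0.6, 0.5),
    "Hay":       (18.0, 24.0, 8.0),
    "Crop":      (20.0, 15.0, 8.0),
    "CBNF":      (5.8, 5.2, 2.5),
    "Fert":      (20.0, 17.0, 7.0),
    "Manure":    (7.5, 9.0, 3.0),
    "RoadDens":  (1.2, 1.2, 0.5),
    "Road_Xing": (0.4, 0.4, 0.2),
    "Houses":    (10.0, 10.0, 5.0),
    "Population": (25.0, 25.0, 12.0),
}


class ConfigError(ValueError):
    """A synthetic-data configuration value is out of range."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for the synthetic survey generator.

    ``survey_noise_sd`` multiplies each habitat feature's within-group
    SD per cycle; ``composition_concentration`` multiplies the Dirichlet
    concentrations (large values approach per-archetype point masses).
    ``nonmodal_fraction`` is the design target for the fraction of sites
    whose repeated surveys straddle group boundaries.  It is realised by
    marking four times that fraction of sites as *boundary sites*: each
    cycle of a boundary site draws its habitat means blended toward a
    partner archetype of the same region with a fresh random weight in
    ``nonmodal_blend_range`` (the site's true archetype always keeps the
    larger weight, so ground truth stays single-valued and recoverable).
    Whether a boundary site actually ends up without a unique modal
    label depends on the clustering; at the default noise level roughly
    half the target fraction is realised.
    """

    n_sites_per_group: int = 40
    groups: tuple[tuple[str, str], ...] = (
        ("West", "Plains"),
        ("West", "Valley"),
        ("East", "Plains"),
        ("East", "Valley"),
        ("East", "Rocky"),
    )
    cycles_per_site: int = 2
    rainfall_params: dict = field(
        default_factory=lambda: {"West": (700.0, 120.0), "East": (1150.0, 120.0)}
    )
    survey_noise_sd: float = 1.0
    composition_concentration: float = 1.0
    nonmodal_fraction: float = 0.10
    nonmodal_blend_range: tuple[float, float] = (0.1, 0.5)
    chem_region_shift: dict = field(
        default_factory=lambda: {"Alkalinity": 160.0, "Conductivity": 650.0}
    )
    tier1_sd_scale: float = 1.0
    chem_missing_fraction: float = 0.15
    chem_measurements_per_cycle: int = 5
    k_ecoregion: int = 13
    ecoregion_noise_sd: float = 150.0
    biased_stressor: bool = False
    biased_archetype: str = "Plains"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites_per_group < 1:
            raise ConfigError("n_sites_per_group must be positive")
        if not 1 <= self.cycles_per_site <= 4:
            raise ConfigError("cycles_per_site must be in 1..4")
        if not 0.0 <= self.nonmodal_fraction < 1.0:
            raise ConfigError("nonmodal_fraction must be in [0, 1)")
        if self.composition_concentration <= 0:
            raise ConfigError("composition_concentration must be positive")
        for region, (_, sd) in self.rainfall_params.items():
            if sd < 0:
                raise ConfigError(f"rainfall SD for {region} must be >= 0")
        for region, arch in self.groups:
            if region not in REGIONS or arch not in ARCHETYPES:
                raise ConfigError(f"unknown (region, archetype) pair {(region, arch)}")

    def zero_noise(self) -> "SyntheticConfig":
        """Degenerate well-separated limit: no survey noise, near
        point-mass compositions, fully separated region rainfall, no
        non-modal sites, no missing chemistry."""
        return replace(
            self,
            survey_noise_sd=0.0,
            composition_concentration=500.0,
            rainfall_params={r: (mu, min(sd, 40.0)) for r, (mu, sd) in self.rainfall_params.items()},
            tier1_sd_scale=0.25,
            nonmodal_fraction=0.0,
            chem_missing_fraction=0.0,
        )


@dataclass
class GroundTruth:
    """Per-site true region/archetype plus the planted rainfall boundary."""

    sites: pd.DataFrame  # site_id, region, archetype, boundary_site
    rainfall_threshold: float

    def labels(self, kind: str) -> pd.Series:
        return self.sites.set_index("site_id")[kind]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng([config.seed, stream])


def generate_sites(config: SyntheticConfig) -> tuple[SampleTable, GroundTruth]:
    """Draw site-level Tier-I climate/geology features with planted regions.

    Rainfall is Normal per region; the remaining Tier-I features get mild
    region-correlated shifts, so the regions are separable primarily by
    rainfall.  The planted boundary is the midpoint of the region means.
    """
    rng = _rng(config, 1)
    rows = []
    truth_rows = []
    idx = 0
    for region, arch in config.groups:
        mu_rain, sd_rain = config.rainfall_params[region]
        for _ in range(config.n_sites_per_group):
            site = f"S{idx:04d}"
            idx += 1
            row = {"site_id": site, "cycle_id": "SITE"}
            row["AnRainC"] = mu_rain + sd_rain * rng.standard_normal()
            for name, (w_mu, e_mu, sd) in _TIER1_MEANS.items():
                mu = e_mu if region == "East" else w_mu
                row[name] = mu + sd * config.tier1_sd_scale * rng.standard_normal()
            rows.append(row)
            truth_rows.append({"site_id": site, "region": region, "archetype": arch})
    sites = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    # boundary-site subset, the source of non-modal sites
    n_sites = len(truth)
    n_boundary = int(round(min(1.0, 4.0 * config.nonmodal_fraction) * n_sites))
    boundary = np.zeros(n_sites, dtype=bool)
    if config.nonmodal_fraction > 0 and n_boundary > 0:
        boundary[rng.choice(n_sites, size=n_boundary, replace=False)] = True
    truth["boundary_site"] = boundary
    means = [config.rainfall_params[r][0] for r in ("West", "East")]
    gt = GroundTruth(truth, rainfall_threshold=float(np.mean(means)))
    order = list(sites.columns)
    return SampleTable(sites[order]), gt


def _composition(rng, alphas, conc, n) -> np.ndarray:
    a = np.asarray(alphas, dtype=float) * conc
    return rng.dirichlet(a, size=n) * 100.0


def generate_surveys(
    sites: SampleTable, truth: GroundTruth, config: SyntheticConfig
) -> SampleTable:
    """Draw per-(site, cycle) Tier-II habitat rows.

    Substrate and channel-unit compositions come from the archetype's
    Dirichlet (scaled to sum to 100); continuous habitat features are
    Normal around archetype means with ``survey_noise_sd`` per-cycle
    noise.  With ``survey_noise_sd == 0`` a single draw is reused for
    every cycle of a site, so cycles are identical.  Alkalinity and
    conductivity are drawn here (region-shifted for the West) and also
    emitted by the chemistry generator as median analytes.
    """
    rng = _rng(config, 2)
    tinfo = truth.sites.set_index("site_id")
    region_archs = {r: sorted({a for rr, a in config.groups if rr == r}) for r in REGIONS}
    arch_mu = {
        a: {name: vals[i] for name, (*vals, _) in _HABITAT_MEANS.items()}
        for i, a in enumerate(ARCHETYPES)
    }
    rows = []
    for site in sites.data["site_id"]:
        rec = tinfo.loc[site]
        arch = rec["archetype"]
        if arch not in ARCHETYPES:
            raise ConfigError(f"unknown archetype {arch!r} for site {site}")
        region = rec["region"]
        others = [a for a in region_archs.get(region, []) if a != arch]
        partner = str(rng.choice(others)) if (rec["boundary_site"] and others) else None
        noise = config.survey_noise_sd
        conc = config.composition_concentration
        ncyc = config.cycles_per_site
        frozen = noise == 0.0 and partner is None
        ndraw = 1 if frozen else ncyc
        blend = (
            rng.uniform(*config.nonmodal_blend_range, size=ndraw)
            if partner is not None
            else np.zeros(ndraw)
        )
        sub = np.empty((ndraw, len(SUBSTRATE_FEATURES)))
        chan = np.empty((ndraw, len(CHANNEL_UNIT_FEATURES)))
        for i in range(ndraw):
            a_sub = np.asarray(DEFAULT_SUBSTRATE_ALPHAS[arch])
            a_chan = np.asarray(DEFAULT_CHANNEL_ALPHAS[arch])
            if partner is not None:
                a_sub = (1 - blend[i]) * a_sub + blend[i] * np.asarray(
                    DEFAULT_SUBSTRATE_ALPHAS[partner]
                )
                a_chan = (1 - blend[i]) * a_chan + blend[i] * np.asarray(
                    DEFAULT_CHANNEL_ALPHAS[partner]
                )
            sub[i] = _composition(rng, a_sub, conc, 1)[0]
            chan[i] = _composition(rng, a_chan, conc, 1)[0]
        cont = {}
        for name, (*_means, sd) in _HABITAT_MEANS.items():
            mu = arch_mu[arch][name] * (1 - blend) + (
                arch_mu[partner][name] * blend if partner is not None else 0.0
            )
            cont[name] = mu + sd * noise * rng.standard_normal(ndraw)
        ws_area = 10.0 ** (2.0 + 0.5 * rng.standard_normal())  # km^2, site-level
        alk_mu = _ALK_EAST + (config.chem_region_shift["Alkalinity"] if region == "West" else 0.0)
        cond_mu = _COND_EAST + (config.chem_region_shift["Conductivity"] if region == "West" else 0.0)
        cont["Alkalinity"] = alk_mu + _ALK_SD * noise * rng.standard_normal(ndraw)
        cont["Conductivity"] = cond_mu + _COND_SD * noise * rng.standard_normal(ndraw)
        for c in range(ncyc):
            i = 0 if frozen else c
            row = {"site_id": site, "cycle_id": f"C{c + 1}"}
            row.update(zip(SUBSTRATE_FEATURES, sub[i]))
            row.update(zip(CHANNEL_UNIT_FEATURES, chan[i]))
            row["WS_Area"] = ws_area
            for name in cont:
                val = cont[name][i]
                if name in _NONNEGATIVE or name in ("Alkalinity", "Conductivity"):
                    val = max(val, 0.0)
                if name in _PERCENT:
                    val = min(val, 100.0)
                row[name] = val
            rows.append(row)
    fset = feature_set("TIER2")
    df = pd.DataFrame(rows)
    # chemistry-derived columns are produced by the chemistry generator;
    # keep Alkalinity/Conductivity here as the survey-table copies.
    df = df[["site_id", "cycle_id"] + fset.names]
    return SampleTable(df)


def generate_chemistry(
    surveys: SampleTable, truth: GroundTruth, config: SyntheticConfig
) -> pd.DataFrame:
    """Long-format water-chemistry measurements for each surveyed cycle.

    Emits ``chem_measurements_per_cycle`` raw measurements per analyte
    around a per-cell latent median (region- and mildly archetype-
    shifted), for the 12 post-hoc analytes plus Alkalinity and
    Conductivity.  A ``chem_missing_fraction`` of (site, cycle) cells is
    omitted entirely, emulating surveys without chemistry.
    """
    rng = _rng(config, 3)
    tinfo = truth.sites.set_index("site_id")
    arch_idx = {a: i for i, a in enumerate(ARCHETYPES)}
    rows = []
    cells = surveys.data[["site_id", "cycle_id"]].drop_duplicates()
    alk = surveys.data.set_index(["site_id", "cycle_id"])[["Alkalinity", "Conductivity"]]
    nrep = max(1, config.chem_measurements_per_cycle)
    for site, cycle in cells.itertuples(index=False, name=None):
        if rng.random() < config.chem_missing_fraction:
            continue
        rec = tinfo.loc[site]
        region, arch = rec["region"], rec["archetype"]
        for analyte, (w_mu, e_mu, sd, shifts) in _CHEM_MEANS.items():
            mu = (e_mu if region == "East" else w_mu) + shifts[arch_idx[arch]] * sd
            vals = mu + sd * 0.5 * rng.standard_normal(nrep)
            vals = np.maximum(vals, 0.0)
            for v in vals:
                rows.append((site, cycle, analyte, float(v)))
        for analyte in ("Alkalinity", "Conductivity"):
            centre = float(alk.loc[(site, cycle), analyte])
            vals = np.maximum(centre * (1.0 + 0.05 * rng.standard_normal(nrep)), 0.0)
            for v in vals:
                rows.append((site, cycle, analyte, float(v)))
    return pd.DataFrame(rows, columns=["site_id", "cycle_id", "analyte", "value"])


def generate_stressors(
    sites: SampleTable, truth: GroundTruth, config: SyntheticConfig
) -> SampleTable:
    """Per-site anthropogenic stressor features, independent of archetype.

    Land-use mix is region-correlated (more cultivation in the dry
    region, more hay/pasture in the wet one) but conditionally
    independent of habitat archetype, as a valid reference grouping
    requires.  ``ICI``/``CCHEM`` are Beta(4, 2.5) catchment-integrity
    scores in [0, 1].  With ``biased_stressor=True``, ``Crop`` and
    ``ICI`` are deliberately linked to ``biased_archetype`` so the span
    screen has a planted failure mode to detect.
    """
    rng = _rng(config, 4)
    tinfo = truth.sites.set_index("site_id")
    rows = []
    for site in sites.data["site_id"]:
        rec = tinfo.loc[site]
        region, arch = rec["region"], rec["archetype"]
        row = {"site_id": site, "cycle_id": "SITE"}
        for name, (w_mu, e_mu, sd) in _STRESSOR_MEANS.items():
            mu = e_mu if region == "East" else w_mu
            row[name] = max(mu + sd * rng.standard_normal(), 0.0)
        row["ICI"] = float(rng.beta(4.0, 2.5))
        row["CCHEM"] = float(np.clip(row["ICI"] + 0.1 * rng.standard_normal(), 0.0, 1.0))
        if config.biased_stressor and arch == config.biased_archetype:
            row["Crop"] = row["Crop"] + 40.0
            row["ICI"] = float(row["ICI"] * 0.3)
            row["CCHEM"] = float(row["CCHEM"] * 0.3)
        rows.append(row)
    fset = feature_set("STRESSOR")
    df = pd.DataFrame(rows)[["site_id", "cycle_id"] + fset.names]
    return SampleTable(df)


def generate_ecoregions(
    sites: SampleTable, config: SyntheticConfig
) -> pd.Series:
    """Assign ``k_ecoregion`` pseudo-ecoregion labels by a noisy geography proxy.

    The proxy is site rainfall plus Normal noise, cut into k quantile
    bins.  Because archetype is independent of rainfall within a region,
    each pseudo-ecoregion mixes archetypes — the comparison scenario in
    which the planted groups should out-explain the ecoregions.
    """
    rng = _rng(config, 5)
    rain = sites.data.set_index("site_id")["AnRainC"]
    proxy = rain + config.ecoregion_noise_sd * rng.standard_normal(len(rain))
    k = config.k_ecoregion
    ranks = proxy.rank(method="first")
    bins = np.ceil(ranks * k / len(proxy)).astype(int)
    labels = bins.map(lambda b: f"E{b:02d}")
    labels.name = "ecoregion"
    return labels


def simulate_bundle(config: SyntheticConfig) -> dict:
    """Generate every table the pipeline consumes, plus ground truth.

    Returns a dict with keys ``sites``, ``surveys``, ``chemistry``,
    ``stressors`` (tables), ``ecoregions`` (per-site Series) and
    ``truth`` (:class:`GroundTruth`).
    """
    sites, truth = generate_sites(config)
    surveys = generate_surveys(sites, truth, config)
    chemistry = generate_chemistry(surveys, truth, config)
    stressors = generate_stressors(sites, truth, config)
    ecoregions = generate_ecoregions(sites, config)
    return {
        "sites": sites,
        "surveys": surveys,
        "chemistry": chemistry,
        "stressors": stressors,
        "ecoregions": ecoregions,
        "truth": truth,
    }
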