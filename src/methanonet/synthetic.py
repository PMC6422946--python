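"""Synthetic factorial temperature-shift experiment.

Emulates a three-soil incubation study: each soil is pre-incubated at
25, 35 and 45 degC, then each pre-incubation is continued at each of the
three temperatures in a full factorial ("I45e25" = Italian-style soil,
pre-incubated at 45 degC, shifted to 25 degC), with three replicate
vessels per treatment.

Community model
---------------
Every OTU carries a Gaussian thermal niche,
``response(T) = exp(-(T - optimum)^2 / (2 width^2))``.  Pre-incubation
samples sit at thermal equilibrium (expected abundance ``baseline *
response(T_pre)``).  Shift samples are legacy-dominated: the long
pre-incubation sets the structure and the short shift phase modulates it
with a damped exponent, ``baseline * max(response(T_pre), floor) *
response(T_inc)^gamma`` — which is why samples group primarily by
pre-incubation temperature, with up-shifts to 45 degC (thermophile
blooms seeded from the floor) as the main exception.  Hysteresis-flagged
OTUs are killed permanently by a 45 degC pre-incubation: their
expectation is zero in every sample with ``pre_temp == 45`` regardless
of the later shift.  Reads are drawn by multinomial sampling at a fixed
depth per domain (archaeal and bacterial libraries are sequenced
separately), on top of per-sample lognormal replicate noise.

Function model
--------------
Guilds (acetoclastic methanogens, hydrogenotrophic methanogens,
syntrophic acetate oxidizers, fermenters, non-methanogenic archaea)
determine process measurements.  The apparent isotope fractionation
factor between CO2 and CH4 interpolates linearly between the mixed
endmember (~1.04, acetoclastic + hydrogenotrophic methanogenesis) and
the purely hydrogenotrophic endmember (~1.08) as acetoclastic activity
vanishes.  Acetate accumulates only when both acetate-consuming guilds
(acetoclastic methanogens and syntrophic acetate oxidizers) are absent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .containers import OtuTable, validate_metadata

GUILDS = ("acetoclastic", "hydrogenotrophic", "sao", "fermenter", "non_methanogenic")

_GUILD_LINEAGE = {
    ("Archaea", "acetoclastic"): "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosarcinaceae",
    ("Archaea", "hydrogenotrophic_meso"): "Archaea;Euryarchaeota;Methanomicrobia;Methanocellales;Methanocellaceae",
    ("Archaea", "hydrogenotrophic_thermo"): "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae",
    ("Archaea", "non_methanogenic"): "Archaea;Bathyarchaeota;uncultured;uncultured;uncultured",
    ("Bacteria", "sao"): "Bacteria;Firmicutes;Clostridia;Thermoanaerobacterales;Thermoanaerobacteraceae",
    ("Bacteria", "fermenter_meso25"): "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae",
    ("Bacteria", "fermenter_meso35"): "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
    ("Bacteria", "fermenter_thermo"): "Bacteria;Firmicutes;Clostridia;Clostridiales;Heliobacteriaceae",
    ("Bacteria", "fermenter_thermo2"): "Bacteria;Firmicutes;Clostridia;Clostridiales;Peptococcaceae",
    ("Bacteria", "shared_meso25"): "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfuromonadales;Geobacteraceae",
    ("Bacteria", "shared_meso35"): "Bacteria;Acidobacteria;Acidobacteriia;Acidobacteriales;Acidobacteriaceae",
}


@dataclass
class NicheSpec:
    """Thermal niche, guild and taxonomy of one OTU."""

    optimum: float
    width: float
    hysteresis: bool
    guild: str
    lineage: str
    shared_baseline: float | None = None  # fixed cross-soil baseline weight


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic experiment.

    Defaults are the test-scale study conditions: 3 soils x (3
    pre-incubation temperatures + 9 factorial shifts) x 3 replicates,
    60 bacterial + 30 archaeal OTUs organised in three temperature
    assemblages (optima 25/35/45 degC), reduced sequencing depths of
    10 000 bacterial and 2 000 archaeal reads per sample.  The
    field-scale depths (281 947 / 10 162) are available by overriding
    ``depth_bacteria`` / ``depth_archaea``.
    """

    soils: tuple[str, ...] = ("I", "P", "U")
    temps: tuple[int, ...] = (25, 35, 45)
    n_replicates: int = 3
    n_otus_bacteria: int = 60
    n_otus_archaea: int = 30
    depth_bacteria: int = 10_000
    depth_archaea: int = 2_000
    lognormal_sigma: float = 1.5      # dispersion of per-soil baseline weights
    replicate_sigma: float = 0.8      # per-sample lognormal noise (log scale)
    meso_width: float = 7.0           # overlapping 25/35 degC niches
    thermo_width: float = 3.0
    aceto_width: float = 5.0          # acetoclasts are strictly mesophilic
    shift_response_exponent: float = 0.5  # damped response to the new temperature
    legacy_floor: float = 0.05        # rare-biosphere seed for blooms after up-shift
    hysteresis_temp: float = 45.0
    activity_threshold: float = 0.01  # within-domain fraction for guild activity
    alpha_hydro: float = 1.08
    alpha_mixed: float = 1.04
    d13_co2_baseline: float = -10.0   # permil vs VPDB
    d13_co2_noise_sd: float = 0.5
    isotope_noise_sd: float = 1.0     # permil on d13-CH4
    alpha_relax_tau_days: float = 5.0
    n_timepoints: int = 10
    t_end_days: float = 30.0
    ch4_rate_umol_day: float = 2.0
    co2_rate_umol_day: float = 4.0
    gas_noise_sd: float = 0.5
    qpcr_arch_log10_mean: float = 9.0
    qpcr_bact_arch_ratio: float = 10.0
    qpcr_log10_sd: float = 0.15
    acetate_baseline_mM: float = 0.5
    acetate_accumulated_mM: float = 70.0
    seed: int = 0
    assemblage_spec: dict[str, NicheSpec] | None = None
    ecotype_map: dict[tuple[str, str], dict[str, Any]] | None = None

    # ------------------------------------------------------------------
    def validate(self) -> list[str]:
        """Return all invariant violations (empty list = valid)."""
        bad: list[str] = []
        if len(self.temps) == 0:
            bad.append("temps must be non-empty")
        if self.n_replicates < 1:
            bad.append("n_replicates must be >= 1")
        for name in ("depth_bacteria", "depth_archaea"):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be > 0")
        for name in ("n_otus_bacteria", "n_otus_archaea"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        for name in ("meso_width", "thermo_width", "aceto_width"):
            if getattr(self, name) <= 0:
                bad.append(f"{name} must be > 0")
        for name in ("alpha_hydro", "alpha_mixed"):
            if getattr(self, name) <= 1.0:
                bad.append(f"{name} must be > 1")
        for name in ("lognormal_sigma", "replicate_sigma", "isotope_noise_sd",
                     "d13_co2_noise_sd", "gas_noise_sd", "qpcr_log10_sd"):
            if getattr(self, name) < 0:
                bad.append(f"{name} must be >= 0")
        if not (0 < self.activity_threshold <= 1):
            bad.append("activity_threshold must be in (0, 1]")
        if self.assemblage_spec is not None:
            for otu, spec in self.assemblage_spec.items():
                if spec.width <= 0:
                    bad.append(f"niche width of {otu} must be > 0")
                if spec.guild not in GUILDS:
                    bad.append(f"unknown guild {spec.guild!r} for {otu}")
        return bad

    def require_valid(self) -> None:
        bad = self.validate()
        if bad:
            raise ValueError("invalid generator configuration: " + "; ".join(bad))

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        data = asdict(self)
        data.pop("assemblage_spec")
        data.pop("ecotype_map")
        data["soils"] = list(self.soils)
        data["temps"] = list(self.temps)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "soils" in data:
            data["soils"] = tuple(data["soils"])
        if "temps" in data:
            data["temps"] = tuple(data["temps"])
        return cls(**data)


# ----------------------------------------------------------------------
# default community blueprint
# ----------------------------------------------------------------------

def default_assemblages(config: GeneratorConfig) -> dict[str, NicheSpec]:
    """Three temperature assemblages with guild structure.

    Bacteria split evenly over the 25/35/45 degC assemblages; the
    thermophilic assemblage hosts the syntrophic acetate oxidizers.
    Archaea: acetoclasts are strictly mesophilic (25 degC assemblage,
    narrow niche), hydrogenotrophs occur in all assemblages.  Mesophilic
    OTUs are hysteresis-flagged: once lost at 45 degC they do not return.
    A few abundant bacterial OTUs get a fixed cross-soil baseline so that
    some taxa are shared between all soil networks.
    """
    spec: dict[str, NicheSpec] = {}
    nb = config.n_otus_bacteria
    per = nb // 3
    mw, tw = config.meso_width, config.thermo_width
    for i in range(nb):
        otu = f"OTU_B{i + 1:03d}"
        # hysteresis is pervasive: a 45 degC episode is irreversible for
        # nearly all mesophiles; two bacteria per mesophilic assemblage
        # recover after a down-shift (suppressed per soil via ecotypes)
        if i < per:  # 25 degC assemblage
            kind = "shared_meso25" if i == 1 else "fermenter_meso25"
            spec[otu] = NicheSpec(25.0, mw, i not in (4, 12), "fermenter",
                                  _GUILD_LINEAGE[("Bacteria", kind)])
        elif i < 2 * per:  # 35 degC assemblage
            j = i - per
            kind = "shared_meso35" if j == 1 else "fermenter_meso35"
            spec[otu] = NicheSpec(35.0, mw, j not in (4, 12), "fermenter",
                                  _GUILD_LINEAGE[("Bacteria", kind)])
        else:  # 45 degC assemblage
            j = i - 2 * per
            if j < 4:
                spec[otu] = NicheSpec(45.0, tw, False, "sao", _GUILD_LINEAGE[("Bacteria", "sao")])
            else:
                kind = "fermenter_thermo" if j % 2 else "fermenter_thermo2"
                spec[otu] = NicheSpec(45.0, tw, False, "fermenter", _GUILD_LINEAGE[("Bacteria", kind)])
    # planted cross-soil OTUs: fixed high baseline in every soil
    for otu in ("OTU_B002", f"OTU_B{per + 2:03d}", f"OTU_B{2 * per + 5:03d}", f"OTU_B{2 * per + 6:03d}"):
        if otu in spec:
            spec[otu].shared_baseline = 4.0

    na = config.n_otus_archaea
    per_a = na // 3
    for i in range(na):
        otu = f"OTU_A{i + 1:03d}"
        if i < per_a:  # 25 degC assemblage: acetoclasts + mesophilic hydrogenotrophs
            if i < 4:
                spec[otu] = NicheSpec(25.0, config.aceto_width, True, "acetoclastic",
                                      _GUILD_LINEAGE[("Archaea", "acetoclastic")])
            elif i < per_a - 2:
                spec[otu] = NicheSpec(25.0, mw, True, "hydrogenotrophic",
                                      _GUILD_LINEAGE[("Archaea", "hydrogenotrophic_meso")])
            else:
                spec[otu] = NicheSpec(25.0, mw, True, "non_methanogenic",
                                      _GUILD_LINEAGE[("Archaea", "non_methanogenic")])
        elif i < 2 * per_a:  # 35 degC assemblage
            if i < per_a + (per_a - 2):
                spec[otu] = NicheSpec(35.0, mw, True, "hydrogenotrophic",
                                      _GUILD_LINEAGE[("Archaea", "hydrogenotrophic_meso")])
            else:
                spec[otu] = NicheSpec(35.0, mw, True, "non_methanogenic",
                                      _GUILD_LINEAGE[("Archaea", "non_methanogenic")])
        else:  # 45 degC assemblage: thermophilic hydrogenotrophs
            j = i - 2 * per_a
            if j < per_a - 2:
                spec[otu] = NicheSpec(45.0, tw, False, "hydrogenotrophic",
                                      _GUILD_LINEAGE[("Archaea", "hydrogenotrophic_thermo")])
            else:
                spec[otu] = NicheSpec(45.0, tw, False, "non_methanogenic",
                                      _GUILD_LINEAGE[("Archaea", "non_methanogenic")])
    return spec


def default_ecotypes(config: GeneratorConfig) -> dict[tuple[str, str], dict[str, Any]]:
    """Per-soil niche overrides giving each soil its functional character.

    * Soil 1 ("Italian-like"): one acetoclastic OTU loses the hysteresis
      flag, so the acetoclastic function recovers after a down-shift.
    * Soil 2 ("Philippines-like"): acetoclasts get broad, non-hysteretic
      niches and are active at every temperature (mixed pathway always).
    * Soil 3 ("Utah-like"): syntrophic acetate oxidizers are effectively
      absent, so a 45 degC pre-incubation leaves no acetate consumer and
      acetate accumulates.  One mesophilic fermenter is a thermophilic
      ecotype here (same OTU label, different thermal response).
    """
    eco: dict[tuple[str, str], dict[str, Any]] = {}
    soils = config.soils
    spec = config.assemblage_spec or default_assemblages(config)
    aceto = [o for o, s in spec.items() if s.guild == "acetoclastic"]
    sao = [o for o, s in spec.items() if s.guild == "sao"]
    if len(soils) >= 1 and aceto:
        eco[(soils[0], aceto[0])] = {"hysteresis": False}
    if len(soils) >= 2:
        for otu in aceto:
            eco[(soils[1], otu)] = {"optimum": 35.0, "width": 15.0, "hysteresis": False}
    if len(soils) >= 3:
        for otu in sao:
            eco[(soils[2], otu)] = {"baseline_scale": 1e-6}
        # nothing recovers in the third soil: the bacterial recoverers are
        # hysteretic ecotypes there, consistent with its stalled function
        for otu, s in spec.items():
            if s.guild == "fermenter" and not s.hysteresis and s.optimum < 40:
                eco[(soils[2], otu)] = {"hysteresis": True}
        if "OTU_B001" in spec:
            eco[(soils[2], "OTU_B001")] = {"optimum": 45.0, "width": config.thermo_width,
                                           "hysteresis": False}
    return eco


# ----------------------------------------------------------------------
# ground truth container
# ----------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Planted structure of one simulated experiment.

    ``otus``: one row per (soil, OTU) with guild, resolved niche and the
    assemblage (module) temperature label.  ``samples``: per-sample guild
    activities, hydrogenotrophic-exclusivity fraction f, true alpha and
    the acetate-accumulation indicator.  ``expected``: noise-free
    within-domain expected relative abundances (OTU x sample).  The true
    alpha mixes the endmembers linearly, ``f * alpha_hydro + (1 - f) *
    alpha_mixed`` — a modeling choice, since the activity-to-alpha map is
    not identified by endmember values alone.
    """

    otus: pd.DataFrame
    samples: pd.DataFrame
    expected: pd.DataFrame

    def assemblage_of(self, soil: str) -> pd.Series:
        sub = self.otus[self.otus["soil"] == soil]
        return pd.Series(sub["assemblage"].to_numpy(), index=sub["otu_id"].to_numpy())


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream so changing one output leaves the others intact."""
    h = np.frombuffer(stream.encode(), dtype=np.uint8).sum() * 7919 + len(stream)
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), int(h) % (2**31)]))


# ----------------------------------------------------------------------
# operations
# ----------------------------------------------------------------------

def build_design(config: GeneratorConfig) -> pd.DataFrame:
    """Factorial sample sheet: per soil, |temps| x reps pre-incubation
    samples plus |temps|^2 x reps temperature-shift samples."""
    if len(config.temps) == 0:
        raise ValueError("invalid configuration: temps must be non-empty")
    if config.n_replicates < 1:
        raise ValueError("invalid configuration: n_replicates must be >= 1")
    rows = []
    for soil in config.soils:
        for pre in config.temps:
            for rep in range(1, config.n_replicates + 1):
                code = f"{soil}{pre}"
                rows.append((f"{code}_r{rep}", soil, pre, np.nan, rep, "pre", code))
        for pre in config.temps:
            for inc in config.temps:
                for rep in range(1, config.n_replicates + 1):
                    code = f"{soil}{pre}e{inc}"
                    rows.append((f"{code}_r{rep}", soil, pre, float(inc), rep, "shift", code))
    design = pd.DataFrame(
        rows, columns=["sample_id", "soil", "pre_temp", "inc_temp", "replicate",
                       "phase", "treatment_code"])
    return validate_metadata(design)


def _resolve_niches(config: GeneratorConfig) -> tuple[dict[str, NicheSpec],
                                                      dict[tuple[str, str], dict[str, Any]]]:
    spec = config.assemblage_spec if config.assemblage_spec is not None else default_assemblages(config)
    if config.ecotype_map is not None:
        eco = config.ecotype_map
    elif config.assemblage_spec is None:
        eco = default_ecotypes(config)
    else:  # custom assemblage without an explicit ecotype map: no overrides
        eco = {}
    return spec, eco


def _soil_niche_frame(config: GeneratorConfig, spec: dict[str, NicheSpec],
                      eco: dict[tuple[str, str], dict[str, Any]]) -> pd.DataFrame:
    """Resolve per-(soil, OTU) niches with ecotype overrides and baselines."""
    rng = _rng(config.seed, "baselines")
    temps = np.asarray(config.temps, float)
    rows = []
    for soil in config.soils:
        for otu, base in spec.items():
            over = eco.get((soil, otu), {})
            opt = float(over.get("optimum", base.optimum))
            width = float(over.get("width", base.width))
            hyst = bool(over.get("hysteresis", base.hysteresis))
            scale = float(over.get("baseline_scale", 1.0))
            if base.shared_baseline is not None:
                baseline = base.shared_baseline * scale
            else:
                baseline = float(rng.lognormal(0.0, config.lognormal_sigma)) * scale
            assemblage = int(temps[np.argmin(np.abs(temps - opt))]) if len(temps) else 0
            domain = base.lineage.split(";")[0]
            rows.append((soil, otu, domain, base.guild, base.lineage, opt, width, hyst,
                         baseline, assemblage))
    return pd.DataFrame(rows, columns=[
        "soil", "otu_id", "domain", "guild", "lineage", "optimum", "width",
        "hysteresis", "baseline", "assemblage"])


def _thermal_response(t_eff: float, opt: np.ndarray, width: np.ndarray) -> np.ndarray:
    return np.exp(-((t_eff - opt) ** 2) / (2.0 * width**2))


def _sample_weights(config: GeneratorConfig, row: pd.Series, soil_n: pd.DataFrame
                    ) -> np.ndarray:
    """Expected (unnormalised) abundance of every OTU in one sample.

    Pre-incubation samples sit at their thermal equilibrium,
    ``baseline * response(T_pre)``.  Shift samples are legacy-dominated:
    the community carries the pre-incubation structure (floored at
    ``legacy_floor`` so rare survivors can bloom after an up-shift) and
    responds to the new temperature only with a damped exponent, because
    the shift phase is short relative to the pre-incubation.  A 45 degC
    pre-incubation permanently removes hysteresis-flagged OTUs.
    """
    opt = soil_n["optimum"].to_numpy()
    width = soil_n["width"].to_numpy()
    baseline = soil_n["baseline"].to_numpy()
    pre = float(row["pre_temp"])
    if row["phase"] == "pre" or pd.isna(row["inc_temp"]):
        w = baseline * _thermal_response(pre, opt, width)
    else:
        legacy = np.maximum(_thermal_response(pre, opt, width), config.legacy_floor)
        now = _thermal_response(float(row["inc_temp"]), opt, width)
        w = baseline * legacy * now**config.shift_response_exponent
    if pre >= config.hysteresis_temp:
        w = np.where(soil_n["hysteresis"].to_numpy(), 0.0, w)
    return w


def simulate_counts(config: GeneratorConfig, design: pd.DataFrame
                    ) -> tuple[OtuTable, GroundTruth]:
    """Draw the OTU count table and record the planted ground truth.

    Column sums equal the configured depth exactly within each domain.
    """
    config.require_valid()
    spec, eco = _resolve_niches(config)
    niches = _soil_niche_frame(config, spec, eco)
    otu_ids = list(spec.keys())
    lineages = pd.Series({o: s.lineage for o, s in spec.items()})

    rng = _rng(config.seed, "counts")
    n_otu = len(otu_ids)
    counts = np.zeros((n_otu, len(design)), dtype=np.int64)
    expected = np.zeros((n_otu, len(design)))
    domains = lineages.loc[otu_ids].str.split(";").str[0].to_numpy()
    sample_rows = []

    for s_idx, row in design.reset_index(drop=True).iterrows():
        soil_n = niches[niches["soil"] == row["soil"]].set_index("otu_id").loc[otu_ids]
        w = _sample_weights(config, row, soil_n)
        noisy = w * rng.lognormal(0.0, config.replicate_sigma, size=n_otu) \
            if config.replicate_sigma > 0 else w.copy()
        for dom, depth in (("Bacteria", config.depth_bacteria),
                           ("Archaea", config.depth_archaea)):
            mask = domains == dom
            if not mask.any():
                continue
            tot_e = w[mask].sum()
            expected[mask, s_idx] = w[mask] / tot_e if tot_e > 0 else 0.0
            tot = noisy[mask].sum()
            if tot <= 0:
                raise ValueError(f"sample {row['sample_id']}: no {dom} OTU has positive "
                                 "expected abundance; cannot draw reads")
            counts[mask, s_idx] = rng.multinomial(depth, noisy[mask] / tot)
        sample_rows.append(_sample_truth(config, row, soil_n, domains, w))

    table = OtuTable(
        pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"),
                     columns=design["sample_id"].tolist()),
        lineages.loc[otu_ids])
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    expected_df = pd.DataFrame(expected, index=pd.Index(otu_ids, name="otu_id"),
                               columns=design["sample_id"].tolist())
    truth = GroundTruth(otus=niches, samples=samples, expected=expected_df)
    return table, truth


def _guild_activities(config: GeneratorConfig, soil_n: pd.DataFrame,
                      domains: np.ndarray, w: np.ndarray) -> dict[str, float]:
    """Within-domain expected relative abundance of each functional guild."""
    out = {}
    guilds = soil_n["guild"].to_numpy()
    for guild, dom in (("acetoclastic", "Archaea"), ("hydrogenotrophic", "Archaea"),
                       ("sao", "Bacteria")):
        dmask = domains == dom
        tot = w[dmask].sum()
        gmask = dmask & (guilds == guild)
        out[guild] = float(w[gmask].sum() / tot) if tot > 0 else 0.0
    return out


def _exclusivity(config: GeneratorConfig, aceto_activity: float) -> float:
    """Hydrogenotrophic exclusivity f: 1 when acetoclasts are absent, 0
    when they are active at or above the activity threshold."""
    return float(np.clip(1.0 - aceto_activity / config.activity_threshold, 0.0, 1.0))


def _sample_truth(config: GeneratorConfig, row: pd.Series, soil_n: pd.DataFrame,
                  domains: np.ndarray, w: np.ndarray) -> dict[str, Any]:
    act = _guild_activities(config, soil_n, domains, w)
    f = _exclusivity(config, act["acetoclastic"])
    alpha_true = f * config.alpha_hydro + (1.0 - f) * config.alpha_mixed

    # the community state inherited from pre-incubation sets the initial alpha
    w_pre = soil_n["baseline"].to_numpy() * _thermal_response(
        float(row["pre_temp"]), soil_n["optimum"].to_numpy(), soil_n["width"].to_numpy())
    if float(row["pre_temp"]) >= config.hysteresis_temp:
        w_pre = np.where(soil_n["hysteresis"].to_numpy(), 0.0, w_pre)
    act_pre = _guild_activities(config, soil_n, domains, w_pre)
    f_pre = _exclusivity(config, act_pre["acetoclastic"])
    alpha_pre = f_pre * config.alpha_hydro + (1.0 - f_pre) * config.alpha_mixed

    thr = config.activity_threshold
    regime_cut = 0.5 * (config.alpha_hydro + config.alpha_mixed)
    return {
        "sample_id": row["sample_id"],
        "soil": row["soil"],
        "aceto_activity": act["acetoclastic"],
        "hydro_activity": act["hydrogenotrophic"],
        "sao_activity": act["sao"],
        "f_hydro": f,
        "alpha_true": alpha_true,
        "alpha_pre": alpha_pre,
        "regime": "hydrogenotrophic" if alpha_true >= regime_cut else "mixed",
        "acetate_accumulating": bool(act["acetoclastic"] < thr and act["sao"] < thr),
    }


def simulate_isotopes(config: GeneratorConfig, design: pd.DataFrame,
                      truth: GroundTruth) -> pd.DataFrame:
    """Gas and isotope time series for every shift-phase vessel.

    The true fractionation relaxes exponentially from the pre-incubation
    state toward the sample's equilibrium alpha (time constant
    ``alpha_relax_tau_days``); d13C-CH4 follows from the defining
    identity alpha = (d13CO2 + 1000)/(d13CH4 + 1000) plus measurement
    noise.  CH4/CO2 amounts accumulate linearly, scaled by methanogen
    activity.
    """
    config.require_valid()
    rng = _rng(config.seed, "isotopes")
    times = np.linspace(config.t_end_days / config.n_timepoints, config.t_end_days,
                        config.n_timepoints)
    rows = []
    shift = design[design["phase"] == "shift"]
    for _, row in shift.iterrows():
        s = truth.samples.loc[row["sample_id"]]
        f = float(s["f_hydro"])
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"hydrogenotrophic fraction f={f} outside [0, 1]")
        alpha_eq, alpha0 = float(s["alpha_true"]), float(s["alpha_pre"])
        meth_act = float(s["hydro_activity"]) + float(s["aceto_activity"])
        stalled = bool(s["acetate_accumulating"])
        act_scale = 0.05 if stalled else min(1.0, 10.0 * meth_act)
        for t in times:
            alpha_t = alpha_eq + (alpha0 - alpha_eq) * np.exp(-t / config.alpha_relax_tau_days)
            d_co2 = config.d13_co2_baseline + rng.normal(0.0, config.d13_co2_noise_sd)
            d_ch4 = (d_co2 + 1e3) / alpha_t - 1e3 + rng.normal(0.0, config.isotope_noise_sd)
            ch4 = max(0.0, config.ch4_rate_umol_day * act_scale * t
                      + rng.normal(0.0, config.gas_noise_sd))
            co2 = max(0.0, config.co2_rate_umol_day * t + rng.normal(0.0, config.gas_noise_sd))
            rows.append((row["sample_id"], row["soil"], row["treatment_code"], float(t),
                         float(d_co2), float(d_ch4), float(alpha_t), float(ch4), float(co2)))
    return pd.DataFrame(rows, columns=[
        "sample_id", "soil", "treatment_code", "time_days", "d13_co2", "d13_ch4",
        "alpha_true", "ch4_umol", "co2_umol"])


def simulate_ancillary(config: GeneratorConfig, design: pd.DataFrame,
                       truth: GroundTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR 16S copy numbers and end-of-incubation VFA concentrations.

    Bacterial copy numbers exceed archaeal by the configured ratio
    (default one order of magnitude).  Acetate sits at baseline wherever
    at least one acetate-consuming guild is active and at the accumulated
    level (>= 10x baseline) where both are absent.
    """
    config.require_valid()
    rng = _rng(config.seed, "ancillary")
    qpcr_rows, vfa_rows = [], []
    arch_mean = config.qpcr_arch_log10_mean
    bact_mean = arch_mean + np.log10(config.qpcr_bact_arch_ratio)
    for _, row in design.iterrows():
        s = truth.samples.loc[row["sample_id"]]
        for dom, mean in (("Archaea", arch_mean), ("Bacteria", bact_mean)):
            log10 = rng.normal(mean, config.qpcr_log10_sd)
            qpcr_rows.append((row["sample_id"], row["soil"], row["treatment_code"],
                              dom, float(10.0 ** log10)))
        if bool(s["acetate_accumulating"]):
            acetate = config.acetate_accumulated_mM * rng.lognormal(0.0, 0.2)
        else:
            acetate = config.acetate_baseline_mM * rng.lognormal(0.0, 0.3)
        propionate = 0.2 * rng.lognormal(0.0, 0.3)
        vfa_rows.append((row["sample_id"], row["soil"], row["treatment_code"],
                         float(acetate), float(propionate)))
    qpcr = pd.DataFrame(qpcr_rows, columns=["sample_id", "soil", "treatment_code",
                                            "domain", "copies_per_g"])
    vfa = pd.DataFrame(vfa_rows, columns=["sample_id", "soil", "treatment_code",
                                          "acetate_mM", "propionate_mM"])
    return qpcr, vfa


def simulate_experiment(config: GeneratorConfig):
    """Run the full generator: design, counts, isotopes, qPCR and VFA."""
    design = build_design(config)
    table, truth = simulate_counts(config, design)
    isotopes = simulate_isotopes(config, design, truth)
    qpcr, vfa = simulate_ancillary(config, design, truth)
    return design, table, truth, isotopes, qpcr, vfa
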