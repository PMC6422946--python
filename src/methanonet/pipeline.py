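"""End-to-end orchestration of the analysis for one soil (or all soils).

Stage order per soil: generate-or-read inputs -> per-domain rarefaction
-> alpha diversity with Kruskal-Wallis letters -> Bray-Curtis / NMDS /
ANOSIM ordination -> discriminant-OTU heatmap -> co-occurrence network
-> process measures (alpha_app pathways, gas rates, qPCR letters, VFA).
All randomness flows from a single global seed through named substreams;
rerunning with the same configuration produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import community, diversity, network, otu_io, process
from .containers import OtuTable
from .synthetic import GeneratorConfig, simulate_experiment

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the study's printed settings.

    Rarefaction depths are ceilings: each domain is rarefied to the
    smaller of the configured depth and its smallest library, matching
    the convention of standardising to the lowest number of sequences.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    input_otu_table: str | None = None    # read instead of simulate when set
    input_metadata: str | None = None
    soil: str | None = None               # None = loop all soils + shared-OTU report
    rarefy_depth_bacteria: int = 281_947
    rarefy_depth_archaea: int = 10_162
    filter_bacteria: float = 0.001        # max within-domain rel. abundance cutoffs
    filter_archaea: float = 0.01
    rho_lo: float = 0.8
    rho_hi: float = 0.9
    q_max: float = 0.01
    k_archaea: int = 25                   # discriminant OTUs per PCA axis
    k_bacteria: int = 50
    n_permutations: int = 999
    alpha: float = 0.05
    nmds_restarts: int = 20
    louvain_restarts: int = 10
    heatmap_floor_pct: float = 0.1
    pathway_window: int = 5
    seed: int = 0
    outdir: str = "results"

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["generator"]["soils"] = list(self.generator.soils)
        data["generator"]["temps"] = list(self.generator.temps)
        for key in ("assemblage_spec", "ecotype_map"):
            data["generator"].pop(key, None)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        gen = data.pop("generator", {})
        if "soils" in gen:
            gen["soils"] = tuple(gen["soils"])
        if "temps" in gen:
            gen["temps"] = tuple(gen["temps"])
        return cls(generator=GeneratorConfig(**gen), **data)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        for key in ("assemblage_spec", "ecotype_map"):
            data["generator"].pop(key, None)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_config(config: PipelineConfig) -> list[str]:
    """All invariant violations at once (empty list = valid)."""
    bad = list(config.generator.validate())
    if config.rarefy_depth_bacteria <= 0:
        bad.append("rarefy_depth_bacteria must be > 0")
    if config.rarefy_depth_archaea <= 0:
        bad.append("rarefy_depth_archaea must be > 0")
    if config.rho_lo > config.rho_hi:
        bad.append(f"rho_lo={config.rho_lo} > rho_hi={config.rho_hi}")
    if not 0 < config.q_max <= 1:
        bad.append("q_max must be in (0, 1]")
    for name in ("filter_bacteria", "filter_archaea"):
        if not 0 <= getattr(config, name) <= 1:
            bad.append(f"{name} must be in [0, 1]")
    for name in ("k_archaea", "k_bacteria", "n_permutations", "nmds_restarts",
                 "louvain_restarts", "pathway_window"):
        if getattr(config, name) < 1:
            bad.append(f"{name} must be >= 1")
    if not 0 < config.alpha < 1:
        bad.append("alpha must be in (0, 1)")
    if config.heatmap_floor_pct <= 0:
        bad.append("heatmap_floor_pct must be > 0")
    if (config.input_otu_table is None) != (config.input_metadata is None):
        bad.append("input_otu_table and input_metadata must be given together")
    return bad


# ----------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, float_format=_FLOAT_FMT, index=index)


def _stage(manifest: dict, name: str, t0: float, **counts) -> None:
    elapsed = time.perf_counter() - t0
    log.info("stage=%s wall=%.2fs seed=%s %s", name, elapsed, manifest.get("seed"),
             " ".join(f"{k}={v}" for k, v in counts.items()))
    manifest["stages"].append({"name": name, **counts})


def rarefy_per_domain(table: OtuTable, depth_bacteria: int, depth_archaea: int,
                      seed: int) -> OtuTable:
    """Rarefy each domain to min(configured depth, smallest library)."""
    parts = []
    for dom, depth in (("Bacteria", depth_bacteria), ("Archaea", depth_archaea)):
        sub = table.domain_table(dom)
        if sub.shape[0] == 0:
            continue
        totals = sub.counts.sum(axis=0)
        eff = int(min(depth, totals.min())) if len(totals) else depth
        parts.append(diversity.rarefy(sub, eff, seed=seed))
    counts = pd.concat([p.counts for p in parts])
    taxonomy = pd.concat([p.taxonomy for p in parts])
    return OtuTable(counts.loc[:, parts[0].counts.columns], taxonomy)


def run(config: PipelineConfig) -> dict:
    """Execute the pipeline; returns the run manifest (also written to
    ``outdir/manifest.json``)."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(), "seed": config.seed,
                      "version": __version__, "stages": [], "outputs": [],
                      "status": "running"}

    def save(name: str) -> Path:
        path = outdir / name
        manifest["outputs"].append(name)
        return path

    try:
        # ------------------------------------------------ inputs
        t0 = time.perf_counter()
        isotopes = qpcr = vfa = truth = None
        if config.input_otu_table is not None:
            table = otu_io.read_otu_table(config.input_otu_table)
            metadata = otu_io.read_metadata(config.input_metadata)
        else:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            metadata, table, truth, isotopes, qpcr, vfa = simulate_experiment(gen)
            otu_io.write_otu_table(table, save("otu_table.tsv"))
            otu_io.write_metadata(metadata, save("metadata.tsv"))
            otu_io.write_series_table(isotopes, save("isotopes.tsv"))
            otu_io.write_series_table(qpcr, save("qpcr.tsv"))
            otu_io.write_series_table(vfa, save("vfa.tsv"))
            otu_io.write_series_table(truth.otus, save("ground_truth_otus.tsv"))
            truth.samples.reset_index().pipe(
                otu_io.write_series_table, save("ground_truth_samples.tsv"))
        _stage(manifest, "inputs", t0, n_otus=table.shape[0], n_samples=table.shape[1])

        soils = [config.soil] if config.soil else sorted(metadata["soil"].unique())
        networks: dict[str, object] = {}
        for soil in soils:
            _run_soil(config, soil, table, metadata, isotopes, qpcr, vfa,
                      outdir, manifest, save, networks)
        if len(networks) >= 2:
            t0 = time.perf_counter()
            shared = network.shared_otus(networks)
            _write_csv(shared, save("shared_otus.csv"), index=False)
            _stage(manifest, "shared_otus", t0, n_shared=shared["otu_id"].nunique())
        if vfa is not None:
            # flag against the cross-treatment median over ALL soils: a
            # per-soil median is inflated when half a soil's treatments
            # accumulate acetate
            t0 = time.perf_counter()
            vt = process.vfa_summary(vfa, metadata)
            _write_csv(vt, save("vfa_summary.csv"), index=False)
            _stage(manifest, "vfa", t0, n_flagged=int(vt["acetate_accumulating"].sum()))
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_soil(config: PipelineConfig, soil: str, table: OtuTable,
              metadata: pd.DataFrame, isotopes, qpcr, vfa,
              outdir: Path, manifest: dict, save, networks: dict) -> None:
    md = metadata[metadata["soil"] == soil]
    sub = table.subset_samples(md["sample_id"].tolist())

    # ------------------------------------------------ rarefaction
    t0 = time.perf_counter()
    rarefied = rarefy_per_domain(sub, config.rarefy_depth_bacteria,
                                 config.rarefy_depth_archaea, seed=config.seed)
    _stage(manifest, f"rarefy[{soil}]", t0, n_in=sub.shape[1], n_out=rarefied.shape[1])

    # ------------------------------------------------ alpha diversity
    t0 = time.perf_counter()
    div_frames = []
    for dom in ("Archaea", "Bacteria"):
        dt = rarefied.domain_table(dom)
        if dt.shape[0] == 0:
            continue
        frame = diversity.alpha_diversity(dt)
        frame.insert(0, "domain", dom)
        div_frames.append(frame)
    div = pd.concat(div_frames)
    div.insert(1, "treatment_code",
               md.set_index("sample_id")["treatment_code"].reindex(div.index))
    _write_csv(div, save(f"diversity_{soil}.csv"))
    letters = []
    for dom, sub_div in div.groupby("domain"):
        lt = diversity.kruskal_letter_groups(
            sub_div["shannon"].to_numpy(), sub_div["treatment_code"].to_numpy(),
            alpha=config.alpha)
        lt.insert(0, "domain", dom)
        letters.append(lt)
    _write_csv(pd.concat(letters), save(f"diversity_letters_{soil}.csv"), index=False)
    _stage(manifest, f"diversity[{soil}]", t0, n_samples=div.shape[0] // 2)

    # ------------------------------------------------ ordination
    t0 = time.perf_counter()
    ord_rows = []
    md_idx = md.set_index("sample_id")
    for dom in ("Archaea", "Bacteria"):
        dt = rarefied.domain_table(dom).drop_singletons()
        if dt.shape[0] < 3:
            continue
        bc = community.bray_curtis(dt)
        ord_res = community.nmds(bc, n_restarts=config.nmds_restarts, seed=config.seed)
        pre = md_idx.loc[bc.index, "pre_temp"].astype(int).to_numpy()
        r, p = community.anosim(bc, pre, n_perm=config.n_permutations, seed=config.seed)
        coords = ord_res.coordinates.copy()
        coords.insert(0, "domain", dom)
        ord_rows.append((dom, coords, ord_res.stress, r, p))
    _write_csv(pd.concat([c for _, c, *_ in ord_rows]), save(f"nmds_{soil}.csv"))
    _write_csv(pd.DataFrame(
        [(d, s, r, p) for d, _, s, r, p in ord_rows],
        columns=["domain", "stress", "anosim_R", "anosim_p"]),
        save(f"anosim_{soil}.csv"), index=False)
    _stage(manifest, f"ordination[{soil}]", t0, n_domains=len(ord_rows))

    # ------------------------------------------------ heatmap selection
    t0 = time.perf_counter()
    selections = {}
    for dom, k in (("Archaea", config.k_archaea), ("Bacteria", config.k_bacteria)):
        dt = rarefied.domain_table(dom).drop_singletons()
        if dt.shape[0] == 0:
            continue
        k_eff = min(k, dt.shape[0])
        selected = community.select_discriminant_otus(dt, k_eff)
        spec = community.heatmap_matrix(dt, selected, floor_pct=config.heatmap_floor_pct)
        selections[dom] = selected
        _write_csv(spec.matrix, save(f"heatmap_{dom.lower()}_{soil}.csv"))
    _write_csv(pd.DataFrame(
        [(d, o) for d, sel in selections.items() for o in sel],
        columns=["domain", "otu_id"]), save(f"discriminant_otus_{soil}.csv"), index=False)
    _stage(manifest, f"heatmap[{soil}]", t0,
           n_selected=sum(len(v) for v in selections.values()))

    # ------------------------------------------------ network
    t0 = time.perf_counter()
    net = network.build_conetwork(
        rarefied, md, seed=config.seed, rho_lo=config.rho_lo, rho_hi=config.rho_hi,
        q_max=config.q_max,
        thresholds={"Bacteria": config.filter_bacteria, "Archaea": config.filter_archaea},
        temps=config.generator.temps, n_restarts=config.louvain_restarts)
    networks[soil] = net
    otu_io.export_network(net, save(f"network_{soil}.graphml"), format="graphml")
    mod_rows = [(n, d["module"], d["temperature"], d["domain"])
                for n, d in net.graph.nodes(data=True)]
    _write_csv(pd.DataFrame(sorted(mod_rows),
                            columns=["otu_id", "module", "temperature", "domain"]),
               save(f"modules_{soil}.csv"), index=False)
    _stage(manifest, f"network[{soil}]", t0, n_nodes=net.n_nodes, n_edges=net.n_edges,
           n_major_modules=len(net.major_modules()))

    # ------------------------------------------------ process measures
    t0 = time.perf_counter()
    n_proc = 0
    if isotopes is not None:
        iso = isotopes[isotopes["soil"] == soil]
        at = process.alpha_table(iso, window=config.pathway_window)
        _write_csv(at, save(f"alpha_app_{soil}.csv"), index=False)
        rates = [(s, process.accumulation_rate(g["time_days"], g["ch4_umol"]).slope,
                  process.accumulation_rate(g["time_days"], g["co2_umol"]).slope)
                 for s, g in iso.groupby("sample_id", sort=True)]
        _write_csv(pd.DataFrame(rates, columns=["sample_id", "ch4_rate_umol_day",
                                                "co2_rate_umol_day"]),
                   save(f"gas_rates_{soil}.csv"), index=False)
        n_proc += len(at)
    if qpcr is not None:
        qt = process.qpcr_letters(qpcr[qpcr["soil"] == soil], alpha=config.alpha)
        _write_csv(pd.concat([f.assign(domain=d) for d, f in qt.items()]),
                   save(f"qpcr_letters_{soil}.csv"), index=False)
    _stage(manifest, f"process[{soil}]", t0, n_vessels=n_proc)
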