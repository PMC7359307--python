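"""End-to-end orchestration: simulate -> QC -> statistics -> scans -> candidates.

One flat YAML config drives the whole run; every stage writes TSV outputs
(floats at 10 significant digits, so reruns with the same seed are
byte-identical) plus a JSON manifest recording the config hash and
per-stage counts.  Stages can also be run independently on each other's
files through the CLI.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .panel import HaplotypePanel, read_pop_map, write_pop_map
from .simulate import SimulationConfig, simulate_neutral_panel, simulate_split_populations, simulate_sweep, write_vcf
from . import qc as qc_mod
from . import popstats
from . import regions as regions_mod
from .ehh import ies as _ies_scan, ihs as _ihs_scan, rsb as _rsb_scan

log = logging.getLogger("selsweep")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All pipeline settings, with standard resequencing-QC defaults.

    ``scan_threshold`` may be a number (-log10 p) or the string
    "bonferroni" to derive it from the number of scanned SNPs at
    ``alpha``.  Window/step sizes default to 250 kb / 10 kb for pi and
    250 kb / 25 kb for F_ST; LD decay uses 100 kb bins.
    """

    # inputs (either files or a simulation block)
    vcf: str | None = None
    pop_map: str | None = None
    gff: str | None = None
    simulation: dict | None = None

    # QC thresholds
    min_qual: float = 30.0
    min_site_call_rate: float = 0.90
    mito_contigs: tuple = ("MT",)
    hwe_min_p: float = 1e-9
    min_maf: float = 0.05
    min_sample_call_rate: float = 0.80
    max_pi_hat: float = 0.5

    # statistics
    pi_window: int = 250_000
    pi_step: int = 10_000
    fst_window: int = 250_000
    fst_step: int = 25_000
    ld_bin_width: int = 100_000
    ld_max_dist: int = 1_000_000

    # scans and candidates
    ehh_cutoff: float = 0.05
    scan_threshold: float | str = 7.4
    alpha: float = 0.05
    fst_top_fraction: float = 0.005
    region_span: int = 250_000

    seed: int = 0
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
        if "mito_contigs" in raw:
            raw["mito_contigs"] = tuple(raw["mito_contigs"])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["mito_contigs"] = list(d["mito_contigs"])
        return yaml.safe_dump(d, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def qc_thresholds(self) -> dict:
        return dict(
            min_qual=self.min_qual,
            min_site_call_rate=self.min_site_call_rate,
            mito_contigs=self.mito_contigs,
            hwe_min_p=self.hwe_min_p,
            min_maf=self.min_maf,
            min_sample_call_rate=self.min_sample_call_rate,
            max_pi_hat=self.max_pi_hat,
        )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    sim = dict(config.simulation or {})
    mode = sim.pop("mode", "split")
    sim.setdefault("seed", config.seed)
    sim_cfg = SimulationConfig(**sim)
    truth = None
    if mode == "neutral":
        panel = simulate_neutral_panel(sim_cfg)
    elif mode == "sweep":
        panel, truth = simulate_sweep(sim_cfg)
    elif mode == "split":
        panel = simulate_split_populations(sim_cfg)
    else:
        raise PipelineError("simulate", f"unknown simulation mode {mode!r}")
    write_vcf(panel, outdir / "simulated.vcf")
    write_pop_map(panel.population_of, outdir / "populations.tsv")
    info = dict(
        mode=mode,
        n_sites=panel.n_sites,
        n_samples=panel.n_samples,
        populations=panel.populations,
    )
    if truth is not None:
        info["sweep_truth"] = dataclasses.asdict(truth)
        (outdir / "sweep_truth.json").write_text(json.dumps(info["sweep_truth"]))
    log.info("simulate: %d samples x %d segregating sites", panel.n_samples, panel.n_sites)
    return info


def stage_qc(
    config: PipelineConfig, vcf: Path, pop_map: Path, outdir: Path, report_only: bool = False
) -> tuple[qc_mod.VariantDataset | None, dict]:
    dataset = qc_mod.read_vcf(vcf, pop_map)
    filtered, var_report, sample_report = qc_mod.apply_qc(dataset, config.qc_thresholds())
    _write_tsv(var_report.to_frame(), outdir / "qc_variants.tsv")
    _write_tsv(sample_report.to_frame(), outdir / "qc_samples.tsv")
    info = dict(
        n_variants_in=var_report.n_input,
        n_variants_out=var_report.n_output,
        n_samples_in=sample_report.n_input,
        n_samples_out=sample_report.n_output,
        variant_steps={name: n for name, n, _ in var_report.steps},
        sample_steps={name: n for name, n, _ in sample_report.steps},
    )
    for name, n, thr in var_report.steps + sample_report.steps:
        log.info("qc: %-18s removed %6d (%s)", name, n, thr)
    if filtered.n_sites == 0:
        raise PipelineError("qc", "all variants removed by QC; nothing to analyse")
    if filtered.n_samples == 0:
        raise PipelineError("qc", "all samples removed by QC; nothing to analyse")
    if report_only:
        return None, info
    if filtered.haplotypes is not None:
        write_vcf(filtered.to_panel(), outdir / "filtered.vcf")
        write_pop_map(filtered.population_of, outdir / "filtered_populations.tsv")
    return filtered, info


def stage_stats(config: PipelineConfig, dataset: qc_mod.VariantDataset, outdir: Path) -> dict:
    pop_idx = dataset.pop_indices()
    pops = list(pop_idx)
    positions = dataset.variants["pos"].to_numpy()
    chrom_ids = dataset.variants["chrom"].to_numpy(dtype=object)
    clens = dataset.chrom_lengths

    het_rows = []
    pi_frames = []
    ld_frames = []
    for pop, idx in pop_idx.items():
        g = dataset.genotypes[idx]
        ho, he = popstats.heterozygosity(g)
        pi_df = popstats.nucleotide_diversity_windows(
            g, positions, chrom_ids, clens, config.pi_window, config.pi_step
        )
        pi_df.insert(0, "population", pop)
        pi_frames.append(pi_df)
        mean_pi = float(np.average(pi_df["value"], weights=pi_df["end"] - pi_df["start"] + 1)) if len(pi_df) else float("nan")
        het_rows.append(dict(population=pop, n=idx.size, ho=ho, he=he, pi=mean_pi))
        if dataset.haplotypes is not None:
            rows = np.empty(2 * idx.size, dtype=np.int64)
            rows[0::2] = 2 * idx
            rows[1::2] = 2 * idx + 1
            ld = popstats.ld_r2_decay(
                dataset.haplotypes[rows], positions, config.ld_max_dist, config.ld_bin_width
            )
            ld.insert(0, "population", pop)
            ld_frames.append(ld)
    _write_tsv(pd.DataFrame(het_rows), outdir / "diversity.tsv")
    _write_tsv(pd.concat(pi_frames, ignore_index=True), outdir / "pi_windows.tsv")
    if ld_frames:
        _write_tsv(pd.concat(ld_frames, ignore_index=True), outdir / "ld_decay.tsv")

    fst_rows = []
    fst_window_frames = []
    for pa, pb in itertools.combinations(pops, 2):
        comp = popstats.wc_fst_per_snp(
            dataset.genotypes[pop_idx[pa]], dataset.genotypes[pop_idx[pb]]
        )
        pair = f"{pa}-{pb}"
        fst_rows.append(dict(pair=pair, mean_weighted_fst=popstats.mean_weighted_fst(comp)))
        win = popstats.wc_fst_windows(
            comp, positions, chrom_ids, clens, config.fst_window, config.fst_step
        )
        win.insert(0, "pair", pair)
        fst_window_frames.append(win)
    if fst_rows:
        _write_tsv(pd.DataFrame(fst_rows), outdir / "fst_pairs.tsv")
        _write_tsv(pd.concat(fst_window_frames, ignore_index=True), outdir / "fst_windows.tsv")

    eig, coords, pct = popstats.pca(dataset.genotypes)
    pca_df = pd.DataFrame(
        coords[:, : min(10, coords.shape[1])],
        columns=[f"PC{i+1}" for i in range(min(10, coords.shape[1]))],
    )
    pca_df.insert(0, "sample", dataset.sample_ids)
    pca_df.insert(1, "population", [dataset.population_of[s] for s in dataset.sample_ids])
    _write_tsv(pca_df, outdir / "pca.tsv")
    _write_tsv(
        pd.DataFrame(dict(component=np.arange(1, pct.size + 1), eigenvalue=eig, pct_variance=pct)),
        outdir / "pca_eigenvalues.tsv",
    )
    if config.make_plots and ld_frames:
        from . import plotting

        plotting.plot_ld_decay(
            {f.iloc[0]["population"]: f for f in ld_frames}, outdir / "ld_decay.png"
        )
        if fst_window_frames:
            for win in fst_window_frames:
                pair = win.iloc[0]["pair"]
                plotting.plot_fst_windows(
                    win, title=f"FST {pair}", path=outdir / f"fst_windows_{pair}.png"
                )
    return dict(
        diversity=het_rows,
        fst_pairs=fst_rows,
        pca_pct_first_two=float(pct[:2].sum()) if pct.size >= 2 else None,
    )


def stage_scan(config: PipelineConfig, dataset: qc_mod.VariantDataset, outdir: Path) -> dict:
    if dataset.haplotypes is None:
        raise PipelineError(
            "scan", "haplotype scans need phased, fully called genotypes"
        )
    panel = dataset.to_panel()
    pops = panel.populations
    ihs_frames = []
    ies_tables = {}
    for pop in pops:
        sub = panel.for_population(pop)
        scores, _bins = _ihs_scan(sub, cutoff=config.ehh_cutoff)
        ihs_frames.append(scores)
        ies_tables[pop] = _ies_scan(sub, cutoff=config.ehh_cutoff)
    ihs_all = pd.concat(ihs_frames, ignore_index=True)
    _write_tsv(ihs_all, outdir / "ihs.tsv")

    rsb_frames = []
    for pa, pb in itertools.combinations(pops, 2):
        r = _rsb_scan(ies_tables[pa], ies_tables[pb], populations=(pa, pb))
        r.insert(0, "pair", f"{pa}-{pb}")
        rsb_frames.append(r)
    if rsb_frames:
        rsb_all = pd.concat(rsb_frames, ignore_index=True)
        _write_tsv(rsb_all, outdir / "rsb.tsv")
    else:
        rsb_all = pd.DataFrame()

    if config.make_plots:
        from . import plotting

        thr = resolve_threshold(config, int(ihs_all["score"].notna().sum()))
        plotting.plot_manhattan(ihs_all, thr, "iHS", outdir / "ihs_manhattan.png")
        if len(rsb_all):
            plotting.plot_manhattan(rsb_all, thr, "Rsb", outdir / "rsb_manhattan.png")
    return dict(
        n_ihs_scored=int(ihs_all["score"].notna().sum()),
        n_rsb_scored=int(rsb_all["score"].notna().sum()) if len(rsb_all) else 0,
    )


def resolve_threshold(config: PipelineConfig, n_tests: int) -> float:
    if config.scan_threshold == "bonferroni":
        return regions_mod.bonferroni_threshold(max(1, n_tests), config.alpha)
    return float(config.scan_threshold)


def stage_candidates(
    config: PipelineConfig,
    ihs_scores: pd.DataFrame,
    rsb_scores: pd.DataFrame,
    fst_windows: pd.DataFrame,
    outdir: Path,
    annotation: regions_mod.GeneAnnotation | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> dict:
    all_regions: list[regions_mod.CandidateRegion] = []

    n_tests = int(ihs_scores["score"].notna().sum()) if len(ihs_scores) else 1
    threshold = resolve_threshold(config, n_tests)
    for pop, grp in ihs_scores.groupby("population", sort=True):
        if not pop:
            continue
        sig = regions_mod.significant_snps(grp.dropna(subset=["score"]), threshold)
        all_regions += regions_mod.make_regions(
            sig, "iHS", str(pop), config.region_span, chrom_lengths
        )
    if len(rsb_scores):
        for (pair, pop), grp in rsb_scores.groupby(["pair", "population"], sort=True):
            if not pop:
                continue
            sig = regions_mod.significant_snps(grp.dropna(subset=["score"]), threshold)
            all_regions += regions_mod.make_regions(
                sig, "Rsb", str(pop), config.region_span, chrom_lengths
            )
    if len(fst_windows):
        for pair, grp in fst_windows.groupby("pair", sort=True):
            top = regions_mod.top_fst_windows(grp, config.fst_top_fraction)
            all_regions += regions_mod.regions_from_windows(top, "FST", str(pair))

    info: dict = dict(threshold=threshold, n_regions=len(all_regions))
    if annotation is not None:
        regions_mod.intersect_genes(all_regions, annotation)
        gene_sets: dict[str, set[str]] = {"iHS": set(), "Rsb": set(), "FST": set()}
        for r in all_regions:
            gene_sets[r.method].update(r.genes)
        overlap = regions_mod.method_overlap(gene_sets)
        _write_tsv(
            pd.DataFrame(
                [dict(cell=k, n_genes=v) for k, v in overlap.items()]
            ),
            outdir / "method_overlap.tsv",
        )
        info["method_overlap"] = overlap
        # per-method, per-population overlaps are recoverable from the
        # regions table; effect classes for candidate peaks:
        effects = [
            regions_mod.classify_effect(r.chrom, r.peak_pos, annotation)
            for r in all_regions
        ]
        eff_counts = pd.Series(effects).value_counts().to_dict() if effects else {}
        info["peak_effect_classes"] = eff_counts
    _write_tsv(regions_mod.regions_to_frame(all_regions), outdir / "candidate_regions.tsv")
    regions_mod.regions_to_bed(all_regions, outdir / "candidate_regions.bed")
    return info


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages; returns (and writes) the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = dict(
        selsweep_version=__version__,
        numpy_version=np.__version__,
        config_hash=config.hash(),
        seed=config.seed,
        stages={},
    )
    (outdir / "config.yaml").write_text(config.to_yaml())

    if config.simulation is not None:
        manifest["stages"]["simulate"] = stage_simulate(config, outdir)
        vcf, pop_map = outdir / "simulated.vcf", outdir / "populations.tsv"
    elif config.vcf and config.pop_map:
        vcf, pop_map = Path(config.vcf), Path(config.pop_map)
    else:
        raise PipelineError("config", "need either input files or a simulation block")

    dataset, qc_info = stage_qc(config, vcf, pop_map, outdir)
    manifest["stages"]["qc"] = qc_info
    manifest["stages"]["stats"] = stage_stats(config, dataset, outdir)
    manifest["stages"]["scan"] = stage_scan(config, dataset, outdir)

    ihs_scores = pd.read_csv(outdir / "ihs.tsv", sep="\t")
    rsb_path = outdir / "rsb.tsv"
    rsb_scores = pd.read_csv(rsb_path, sep="\t") if rsb_path.exists() else pd.DataFrame()
    fst_path = outdir / "fst_windows.tsv"
    fst_windows = pd.read_csv(fst_path, sep="\t") if fst_path.exists() else pd.DataFrame()
    annotation = regions_mod.read_gff3(config.gff) if config.gff else None
    manifest["stages"]["candidates"] = stage_candidates(
        config, ihs_scores, rsb_scores, fst_windows, outdir, annotation,
        dataset.chrom_lengths,
    )

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
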