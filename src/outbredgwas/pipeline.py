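"""End-to-end orchestration: simulate/load -> QC -> structure -> scans ->
thresholds -> multilocus -> precision, with a manifest for exact reruns."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .genotypes import GenotypeMatrix
from .multilocus import rmip
from .precision import distance_summary, precision_simulation, runs_to_frame
from .qc import collapse_identical, filter_snps, impute_missing
from .scan import run_scan
from .significance import permutation_threshold
from .structure import entropy_windows, ibs_kinship, ld_decay, ld_pairs
from .synth import PRESETS, TruthRecord, simulate_population, simulate_trait

logger = logging.getLogger(__name__)

VALID_TESTS = ("trend", "anova", "mixed")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``preset`` (with optional overrides) or both ``genotypes`` and
    ``phenotypes`` paths must be given.
    """

    out_dir: str = "pipeline_out"
    seed: int = 0
    preset: str | None = None
    preset_overrides: dict = field(default_factory=dict)
    genotypes: str | None = None  # .tsv or ped path (with .map sibling)
    phenotypes: str | None = None
    traits: list[str] | None = None
    maf_min: float = 0.02
    hwe_max: float = 20.0
    miss_max: float = 0.40
    collapse_window: int = 2_000_000
    tests: list[str] = field(default_factory=lambda: ["trend", "anova", "mixed"])
    threshold_methods: list[str] = field(default_factory=lambda: ["structured", "free"])
    threshold_reps: int = 100
    alphas: list[float] = field(default_factory=lambda: [0.05])
    ld_window: int = 50_000_000
    entropy_window: int = 4_000_000
    rmip_reps: int = 0          # 0 disables the stage
    rmip_window: int = 1_000_000
    rmip_max_terms: int = 20
    precision_sims: int = 0     # 0 disables the stage
    precision_var_explained: float = 0.2
    precision_test: str = "mixed"

    def validate(self) -> None:
        if not self.tests:
            raise ValueError("no tests selected")
        for t in self.tests:
            if t not in VALID_TESTS:
                raise ValueError(f"unknown test {t!r}")
        for m in self.threshold_methods:
            if m not in ("structured", "free"):
                raise ValueError(f"unknown threshold method {m!r}")
        if self.preset is None and (self.genotypes is None or self.phenotypes is None):
            raise ValueError("either a simulation preset or genotype+phenotype paths are required")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choices: {sorted(PRESETS)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def _load_inputs(cfg: PipelineConfig) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    meta: dict = {}
    if cfg.preset is not None:
        sim_cfg = PRESETS[cfg.preset](seed=cfg.seed, **cfg.preset_overrides)
        G = simulate_population(sim_cfg)
        pheno = None
        meta["simulation"] = {"preset": cfg.preset, "config": sim_cfg.__dict__}
        return G, pheno, meta
    gpath = Path(cfg.genotypes)
    if gpath.suffix == ".ped":
        G = gio.read_ped_map(gpath, gpath.with_suffix(".map"))
    elif gpath.suffix in (".vcf", ".gz"):
        G = gio.read_vcf(gpath)
    else:
        G = gio.read_genotype_tsv(gpath)
    pheno = gio.read_phenotype_tsv(cfg.phenotypes)
    meta["inputs"] = {"genotypes": str(cfg.genotypes), "phenotypes": str(cfg.phenotypes)}
    return G.sort_by_position(), pheno, meta


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Run the configured stages, writing all artifacts plus a manifest.

    Returns the manifest dictionary.  Any stage failure halts the pipeline
    with a stage-attributed error; artifacts written so far are preserved.
    """
    cfg = PipelineConfig.from_dict(config) if isinstance(config, dict) else config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "config": {k: v for k, v in cfg.__dict__.items()},
    }
    rng_seeds = np.random.SeedSequence(cfg.seed).spawn(8)

    def _stage(name):
        def deco(fn):
            try:
                info = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_manifest(out, manifest)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"status": "complete", **(info or {})}
            _write_manifest(out, manifest)
        return deco

    state: dict = {}

    @_stage("load")
    def _load():
        G, pheno, meta = _load_inputs(cfg)
        state["G_raw"], state["pheno"] = G, pheno
        return {"n_samples": G.n_samples, "n_snps": G.n_snps, **meta}

    @_stage("qc")
    def _qc():
        G, report = filter_snps(
            state["G_raw"], maf_min=cfg.maf_min, hwe_max=cfg.hwe_max, miss_max=cfg.miss_max
        )
        G = impute_missing(G, seed=int(rng_seeds[0].generate_state(1)[0]))
        G, mapping = collapse_identical(G, window=cfg.collapse_window)
        report.n_after_collapse = G.n_snps
        report.to_json(out / "qc_report.json")
        with open(out / "collapse_map.json", "w") as fh:
            json.dump(mapping, fh)
        gio.write_genotype_tsv(G, out / "genotypes_qc.tsv")
        state["G"] = G
        return {
            "n_pass_filters": report.n_pass_filters,
            "n_after_collapse": report.n_after_collapse,
        }

    @_stage("phenotypes")
    def _pheno():
        G = state["G"]
        if state["pheno"] is None:
            kin = ibs_kinship(G)
            truth = TruthRecord([], [], 1.0, 1.0)
            y, truth = simulate_trait(
                G, kin.matrix, truth, seed=int(rng_seeds[1].generate_state(1)[0])
            )
            pheno = pd.DataFrame({"trait": y}, index=pd.Index(G.sample_ids, name="sample_id"))
            truth.to_json(out / "truth.json")
        else:
            pheno = state["pheno"].loc[[s for s in G.sample_ids if s in state["pheno"].index]]
            missing = set(G.sample_ids) - set(pheno.index)
            if missing:
                raise ValueError(f"phenotypes missing for samples: {sorted(missing)[:5]} ...")
        traits = cfg.traits or [c for c in pheno.columns]
        state["pheno_df"] = pheno[traits]
        gio.write_phenotype_tsv(list(pheno.index), {t: pheno[t].to_numpy() for t in traits}, out / "phenotypes.tsv")
        return {"traits": traits}

    @_stage("structure")
    def _structure():
        G = state["G"]
        kin = ibs_kinship(G)
        state["K"] = kin
        gio.write_kinship_tsv(kin, out / "kinship.tsv")
        pairs = ld_pairs(G, window=cfg.ld_window)
        info = {}
        if len(pairs) >= 100:
            curve = ld_decay(pairs, window=cfg.ld_window)
            pd.DataFrame(
                {"bin_center": curve.bin_center, "median_r2": curve.median_r2,
                 "smoothed_r2": curve.smoothed_r2}
            ).to_csv(out / "ld_curve.tsv", sep="\t", index=False)
            info["ld_decay_radius_bp"] = curve.decay_radius
        entropy_windows(G, window=cfg.entropy_window).to_csv(
            out / "entropy_windows.tsv", sep="\t", index=False
        )
        return info

    @_stage("scan")
    def _scan():
        G, K = state["G"], state["K"]
        peaks = {}
        for trait in state["pheno_df"].columns:
            y = state["pheno_df"][trait].to_numpy(dtype=float)
            for test in cfg.tests:
                res = run_scan(y, G, K.matrix, test=test)
                res.to_tsv(out / f"scan_{trait}_{test}.tsv")
                peaks[f"{trait}:{test}"] = {
                    "snp": str(res.peak()["snp_id"]),
                    "neg_log10_p": float(res.peak()["neg_log10_p"]),
                }
        state["peaks"] = peaks
        return {"peaks": peaks}

    @_stage("thresholds")
    def _thresholds():
        G, K = state["G"], state["K"]
        rows = []
        for trait in state["pheno_df"].columns:
            y = state["pheno_df"][trait].to_numpy(dtype=float)
            for test in cfg.tests:
                for method in cfg.threshold_methods:
                    thr = permutation_threshold(
                        y, G, K.matrix, test=test, R=cfg.threshold_reps,
                        alphas=tuple(cfg.alphas),
                        seed=int(rng_seeds[2].generate_state(1)[0]),
                        method=method, trait=trait,
                    )
                    thr.to_json(out / f"threshold_{trait}_{test}_{method}.json")
                    for a, v in thr.thresholds.items():
                        rows.append(
                            {"trait": trait, "test": test, "method": method,
                             "alpha": a, "threshold": v}
                        )
        grid = pd.DataFrame(rows)
        grid.to_csv(out / "threshold_grid.tsv", sep="\t", index=False)
        state["thresholds"] = grid
        return {"n_thresholds": len(rows)}

    if cfg.rmip_reps > 0:
        @_stage("rmip")
        def _rmip():
            G = state["G"]
            for trait in state["pheno_df"].columns:
                y = state["pheno_df"][trait].to_numpy(dtype=float)
                res = rmip(
                    y, G, R=cfg.rmip_reps, window=cfg.rmip_window,
                    max_terms=min(cfg.rmip_max_terms, G.n_samples - 2),
                    seed=int(rng_seeds[3].generate_state(1)[0]),
                )
                res.to_tsv(out / f"rmip_{trait}.tsv")
                res.selections_to_json(out / f"rmip_{trait}_selections.json")
            return {}

    if cfg.precision_sims > 0:
        @_stage("precision")
        def _precision():
            G, K = state["G"], state["K"]
            runs = precision_simulation(
                G, K.matrix, cfg.precision_var_explained,
                sigma_g2=1.0, sigma_e2=1.0, n_sim=cfg.precision_sims,
                test=cfg.precision_test, seed=int(rng_seeds[4].generate_state(1)[0]),
            )
            runs_to_frame(runs).to_csv(out / "precision_runs.tsv", sep="\t", index=False)
            summ = distance_summary(runs)
            with open(out / "precision_summary.json", "w") as fh:
                json.dump(
                    {"quantiles_bp": {str(k): v for k, v in summ.quantiles.items()},
                     "same_chromosome_rate": summ.same_chromosome_rate,
                     "n_runs": summ.n_runs},
                    fh, indent=2,
                )
            return {"same_chromosome_rate": summ.same_chromosome_rate}

    manifest["significant"] = _significant_peaks(state, cfg)
    _write_manifest(out, manifest)
    return manifest


def _significant_peaks(state: dict, cfg: PipelineConfig) -> list[dict]:
    if "thresholds" not in state or "peaks" not in state:
        return []
    grid = state["thresholds"]
    out = []
    for key, peak in state["peaks"].items():
        trait, test = key.split(":")
        sel = grid[(grid["trait"] == trait) & (grid["test"] == test)]
        if sel.empty:
            continue
        thr = float(sel["threshold"].min())
        if peak["neg_log10_p"] > thr:
            out.append({"trait": trait, "test": test, **peak, "threshold": thr})
    return out


def _write_manifest(out: Path, manifest: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_default)
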