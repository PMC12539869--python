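"""Pipeline orchestration: simulate -> process -> metrics -> stats.

One :class:`RunConfig` plus a master seed produce a deterministic run
directory: per-trial bin tables, bin-width scans, per-animal metrics,
group summaries and a stats report. The master seed deterministically
spawns per-stage seeds (logged), so re-runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .io import (
    read_manifest,
    read_trace,
    sha256_file,
    write_cohort,
    write_report,
)
from .metrics import (
    DEFAULT_BIN_WIDTH_S,
    DEFAULT_PO2_FLOOR_KPA,
    DEFAULT_SCAN_WIDTHS_S,
    alpha_from_hypoxia,
    fit_mass_scaling,
    mass_correct,
    mmr_from_trial,
    pcmax,
)
from .simulate import Cohort, CohortConfig, GroupSpec, simulate_cohort
from .stats import (
    levene,
    lilliefors,
    perm_anova_oneway,
    perm_linreg,
    summarize_groups,
    tukey_posthoc,
)
from .traces import bin_slopes, microbial_rate, subtract_background
from .units import WaterConditions

__all__ = ["RunConfig", "Pipeline", "run_pipeline"]

log = logging.getLogger("respirox")


@dataclass
class RunConfig:
    seed: int
    outdir: Path = Path("run")
    cohort: CohortConfig = field(default_factory=CohortConfig)
    bin_width_s: float = DEFAULT_BIN_WIDTH_S
    scan_widths: tuple = DEFAULT_SCAN_WIDTHS_S
    common_mass: float = 594.1
    n_perm: int = 10000
    mmr_mode: str = "period_regression"
    po2_floor: float = DEFAULT_PO2_FLOOR_KPA
    measure_duration_s: float = 900.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a master seed is mandatory")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            craw = dict(raw["cohort"])
            if "groups" in craw:
                craw["groups"] = tuple(GroupSpec(**g) for g in craw["groups"])
            for key in ("mass_range", "mmr_start_po2", "chamber_volumes",
                        "chamber_mass_cutoffs"):
                if key in craw:
                    craw[key] = tuple(craw[key])
            raw["cohort"] = CohortConfig(**craw)
        if "scan_widths" in raw:
            raw["scan_widths"] = tuple(raw["scan_widths"])
        return cls(**raw)

    def hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir", None)  # runs in different directories stay comparable
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class TrialResult:
    trial_id: str
    animal_id: str
    trial_type: str
    start_po2_kpa: float
    mmr: float | None = None
    microbial_share_pct: float | None = None


class Pipeline:
    """Stage-wise driver over one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        seqs = np.random.SeedSequence(config.seed).spawn(2)
        self.sim_seed, self.stats_seed = seqs
        self.stage_seeds = {
            "simulate": seqs[0].entropy,
            "stats": int(seqs[1].generate_state(1)[0]),
        }
        self.cohort: Cohort | None = None
        self.metrics: pd.DataFrame | None = None
        self.shares: pd.DataFrame | None = None
        self._setup_log()

    def _setup_log(self) -> None:
        self.outdir.mkdir(parents=True, exist_ok=True)
        log.setLevel(logging.INFO)
        if not any(
            isinstance(h, logging.FileHandler)
            and getattr(h, "_respirox_dir", None) == str(self.outdir)
            for h in log.handlers
        ):
            handler = logging.FileHandler(self.outdir / "run.log")
            handler._respirox_dir = str(self.outdir)
            handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
            log.addHandler(handler)
        log.info("respirox %s, config hash %s", __version__, self.config.hash())
        log.info("stage seeds: %s", self.stage_seeds)
        log.info(
            "defaults in force: bin_width=%ss, scan=%s, common_mass=%sg, "
            "po2_floor=%skPa, mmr_mode=%s",
            self.config.bin_width_s, list(self.config.scan_widths),
            self.config.common_mass, self.config.po2_floor, self.config.mmr_mode,
        )

    # -- stage 1 ----------------------------------------------------------
    def simulate(self) -> Cohort:
        self.cohort = simulate_cohort(self.config.cohort, self.sim_seed)
        write_cohort(self.cohort, self.outdir)
        log.info("simulated %d trials for %d animals",
                 len(self.cohort.manifest), self.cohort.truth.shape[0])
        return self.cohort

    # -- helpers ----------------------------------------------------------
    def _load(self):
        manifest = read_manifest(self.outdir / "manifest.csv")
        traces = {}
        for row in manifest.itertuples():
            cond = WaterConditions(
                temperature_c=float(row.temp_C),
                salinity_psu=float(row.salinity_psu),
            )
            traces[row.trial_id] = read_trace(
                self.outdir / str(row.trace_file), cond
            )
        return manifest, traces

    def _backgrounds(self, manifest, traces) -> dict[str, float]:
        """Whole-chamber microbial rate (umol/h) per animal id."""
        out = {}
        blanks = manifest[manifest["trial_type"] == "blank"]
        for row in blanks.itertuples():
            mr = microbial_rate(traces[row.trial_id], float(row.chamber_volume_L))
            wc = max(mr.whole_chamber, 0.0)
            if mr.whole_chamber < 0:
                log.warning("blank %s gave a negative rate; clamped to 0",
                            row.trial_id)
            out[str(row.animal_id)] = wc
        for aid in manifest["animal_id"].unique():
            if str(aid) not in out:
                warnings.warn(
                    f"no blank trial for animal {aid}; proceeding with zero "
                    "background", stacklevel=2,
                )
                log.warning("MISSING BLANK for %s: zero background assumed", aid)
                out[str(aid)] = 0.0
        return out

    # -- stage 2 ----------------------------------------------------------
    def process(self) -> None:
        """Write per-trial bin tables and hypoxia bin-width scans."""
        cfg = self.config
        manifest, traces = self._load()
        backgrounds = self._backgrounds(manifest, traces)
        share_rows = []
        for row in manifest.itertuples():
            if row.trial_type == "blank":
                continue
            trace = traces[row.trial_id]
            mass = float(row.animal_mass_g)
            volume = float(row.chamber_volume_L)
            bg = backgrounds[str(row.animal_id)]
            frames = []
            for label, _ in trace.sealed_segments():
                bins = bin_slopes(trace, cfg.bin_width_s, label, volume, mass)
                bins.insert(0, "segment", label)
                frames.append(bins)
            raw = pd.concat(frames, ignore_index=True)
            total_rate = float(raw["mo2_umol_g_h"].mean()) * mass  # incl. microbial
            share = 100.0 * bg / total_rate if total_rate > 0 else np.nan
            share_rows.append(dict(
                trial_id=row.trial_id, animal_id=row.animal_id,
                trial_type=row.trial_type,
                microbial_whole_chamber_umol_h=bg,
                total_whole_chamber_umol_h=total_rate,
                microbial_share_pct=share,
            ))
            corrected = subtract_background(raw, bg, mass)
            corrected.insert(0, "trial_id", row.trial_id)
            corrected.to_csv(
                self.outdir / f"bins_{row.trial_id}.csv", index=False
            )
            if row.trial_type == "hypoxia":
                est = alpha_from_hypoxia(
                    trace, volume, mass, background_umol_h=bg,
                    widths=cfg.scan_widths, po2_floor=cfg.po2_floor,
                )
                est.scan.to_csv(
                    self.outdir / f"scan_{row.trial_id}.csv", index=False
                )
        self.shares = pd.DataFrame(share_rows)
        self.shares.to_csv(self.outdir / "microbial_shares.csv", index=False)
        over = self.shares[self.shares["microbial_share_pct"] > 5.0]
        if len(over):
            log.warning("microbial share exceeds 5%% in trials: %s",
                        list(over["trial_id"]))

    # -- stage 3 ----------------------------------------------------------
    def compute_metrics(self) -> pd.DataFrame:
        cfg = self.config
        manifest, traces = self._load()
        backgrounds = self._backgrounds(manifest, traces)
        per_animal: dict[str, dict] = {}
        for row in manifest.itertuples():
            if row.trial_type == "blank":
                continue
            aid = str(row.animal_id)
            rec = per_animal.setdefault(aid, dict(
                animal_id=aid, group_psu=float(row.group_psu),
                mass_g=float(row.animal_mass_g), mmr_trials={},
            ))
            trace = traces[row.trial_id]
            mass = float(row.animal_mass_g)
            volume = float(row.chamber_volume_L)
            bg = backgrounds[aid]
            mmr, _ = mmr_from_trial(
                trace, volume, mass, background_umol_h=bg,
                width_s=cfg.bin_width_s,
                measure_duration_s=cfg.measure_duration_s,
                mode=cfg.mmr_mode,
            )
            rec["mmr_trials"][float(row.start_po2_kpa)] = mmr
            if row.trial_type == "hypoxia":
                est = alpha_from_hypoxia(
                    trace, volume, mass, background_umol_h=bg,
                    widths=cfg.scan_widths, po2_floor=cfg.po2_floor,
                )
                rec["alpha_raw"] = est.alpha
                rec["sd_top3"] = est.sd_top3
                rec["selected_bin_width_s"] = est.selected_width_s
                rec["scan_stable"] = est.stable

        animals = list(per_animal.values())
        masses = [a["mass_g"] for a in animals]
        mmr_max_raw = [max(a["mmr_trials"].values()) for a in animals]
        fit = fit_mass_scaling(masses, mmr_max_raw, common_mass=cfg.common_mass)
        log.info("mass scaling fit: c=%.4f b=%.4f (n=%d)", fit.c, fit.b, fit.n)

        rows = []
        for a, mmr_raw in zip(animals, mmr_max_raw):
            corr = lambda v: mass_correct(v, a["mass_g"], fit)  # noqa: E731
            rec = dict(
                animal_id=a["animal_id"], group_psu=a["group_psu"],
                mass_g=a["mass_g"],
            )
            for start, v in sorted(a["mmr_trials"].items()):
                rec[f"mmr_{start:g}"] = corr(v)
            alpha = corr(a["alpha_raw"])
            rec.update(
                mmr_max_corrected=corr(mmr_raw),
                alpha=alpha,
                alpha_raw=a["alpha_raw"],
                sd_top3=a["sd_top3"],
                selected_bin_width_s=a["selected_bin_width_s"],
                pcmax=pcmax(corr(mmr_raw), alpha),
            )
            rows.append(rec)
        self.metrics = pd.DataFrame(rows).sort_values("animal_id").reset_index(drop=True)
        self.scaling_fit = fit
        self.metrics.to_csv(self.outdir / "metrics.csv", index=False)
        return self.metrics

    # -- stage 4 ----------------------------------------------------------
    def compute_stats(self) -> dict:
        cfg = self.config
        if self.metrics is None:
            mpath = self.outdir / "metrics.csv"
            if not mpath.exists():
                self.compute_metrics()
            else:
                self.metrics = pd.read_csv(mpath)
        m = self.metrics
        rng_seed = self.stage_seeds["stats"]
        report: dict = {
            "version": __version__,
            "config_hash": self.config.hash(),
            "seed": cfg.seed,
            "stage_seeds": {k: str(v) for k, v in self.stage_seeds.items()},
            "n_perm": cfg.n_perm,
            "tests": {},
        }

        def pack(res):
            return dict(
                statistic=res.statistic_name, observed=res.observed,
                p_perm=res.p_perm, p_classical=res.p_classical,
                n_perm=res.n_perm,
            )

        # normality / homogeneity per endpoint across salinity groups
        for ep in ("alpha", "pcmax", "mmr_max_corrected"):
            vals = m[ep].to_numpy()
            report["tests"][f"lilliefors_{ep}"] = pack(
                lilliefors(vals, n_mc=cfg.n_perm, seed=rng_seed)
            )
            report["tests"][f"levene_{ep}"] = pack(
                levene(vals, m["group_psu"], n_perm=cfg.n_perm, seed=rng_seed)
            )

        # per-salinity one-way ANOVA of MMR across PO2 treatments + Tukey
        mmr_cols = [c for c in m.columns if c.startswith("mmr_")
                    and c not in ("mmr_max_corrected",)]
        long = m.melt(
            id_vars=["animal_id", "group_psu"], value_vars=mmr_cols,
            var_name="po2_label", value_name="mmr",
        )
        anovas = {}
        for g, sub in long.groupby("group_psu"):
            res = perm_anova_oneway(
                sub["mmr"], sub["po2_label"], n_perm=cfg.n_perm, seed=rng_seed
            )
            entry = pack(res)
            if res.p_perm < 0.05:
                tk = tukey_posthoc(sub["mmr"], sub["po2_label"],
                                   n_perm=cfg.n_perm, seed=rng_seed)
                entry["tukey"] = tk.to_dict(orient="records")
            anovas[f"{g:g}"] = entry
        report["tests"]["mmr_anova_by_salinity"] = anovas

        # linear regressions of each endpoint on salinity
        regs = {}
        for ep in ("mmr_max_corrected", "alpha", "pcmax"):
            r = perm_linreg(m["group_psu"], m[ep], n_perm=cfg.n_perm,
                            seed=rng_seed)
            regs[ep] = dict(
                b1=r.slope, t=r.t_stat, p_t=r.p_t, r2=r.r2, r2_adj=r.r2_adj,
                F=r.f_stat, p_classical=r.p_classical, p_perm=r.p_perm,
            )
        report["tests"]["salinity_regressions"] = regs

        table, effects = summarize_groups(m, ["alpha", "pcmax"] + mmr_cols
                                          + ["mmr_max_corrected"])
        table.to_csv(self.outdir / "group_stats.csv", index=False)
        report["effects"] = effects
        write_report(report, self.outdir / "stats_report.json")
        self._write_file_manifest()
        self.report = report
        return report

    def _write_file_manifest(self) -> None:
        files = {}
        for p in sorted(self.outdir.rglob("*")):
            if p.is_file() and p.name not in ("run.log", "files.json"):
                files[str(p.relative_to(self.outdir))] = sha256_file(p)
        write_report({"files": files}, self.outdir / "files.json")

    def run_all(self) -> dict:
        self.simulate()
        self.process()
        self.compute_metrics()
        return self.compute_stats()


def run_pipeline(config: RunConfig) -> dict:
    """Convenience wrapper: run every stage and return the stats report."""
    return Pipeline(config).run_all()
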