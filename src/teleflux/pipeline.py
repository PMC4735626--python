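"""End-to-end orchestration: simulate or load inputs, classify phases,
build anomalies, fit composites and the NBP EOF, and write a result
bundle (CSV/NetCDF/JSON) with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anomaly import annual_integral, annual_regional_series, deseasonalize
from .composites import PhaseCompositeModel, ensemble_envelope, seasonal_flux_curves
from .eof import nbp_pca, regional_variance_share
from .grid import STUDY_REGIONS, build_region_mask
from .synthetic import SyntheticConfig, SyntheticWorld, simulate_world, save_truth
from .teleconnections import (classify_phases, composite_membership,
                              longest_antiphase_run, winter_index)

log = logging.getLogger("teleflux")

STAGES = ("indices", "phases", "anomalies", "composites", "eof", "curves")


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    out_dir: Path
    seed: int = 0
    n_years: int = 31
    regions: tuple[str, ...] = ("europe", "iberia", "central_europe",
                               "western_russia", "scandinavia")
    base_period: tuple[int, int] | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if not self.regions:
            raise ValueError("validation error: no regions configured")
        unknown = [r for r in self.regions if r not in STUDY_REGIONS]
        if unknown:
            raise ValueError(f"validation error: unknown regions {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        if "base_period" in raw and raw["base_period"] is not None:
            raw["base_period"] = tuple(raw["base_period"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in sorted(self.__dict__.items())
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultBundle:
    """Everything a report needs, plus the manifest of the run."""

    config: PipelineConfig
    world: SyntheticWorld
    assignment: object
    membership: dict
    annual_series: list  # AnnualAnomalySeries, all datasets x regions
    composite_results: object  # PhaseCompositeResults
    eof_results: dict  # group -> EOFResult
    curves: object  # SeasonalCurveSet
    envelope: pd.DataFrame
    variance_shares: pd.DataFrame
    manifest: dict


def _annual_series_for(world, assignment, regions) -> list:
    out = []
    groups = {}
    sets = [("dgvm", world.members), ("inversion", world.inversions)]
    for gname, members in sets:
        for i, stacks in enumerate(members):
            name = f"{gname}{i:02d}"
            groups[name] = "dgvms" if gname == "dgvm" else "inversions"
            anoms = deseasonalize(stacks["NBP"])
            for region in regions:
                mask = build_region_mask(STUDY_REGIONS[region], world.config.make_flux_grid())
                s = annual_regional_series(anoms, mask, dataset=name)
                out.append(s)
    return out, groups


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Execute the full simulate-then-analyse pipeline and write outputs."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    done = []
    syn_kwargs = dict(config.synthetic)
    syn_kwargs.setdefault("seed", config.seed)
    syn_kwargs.setdefault("n_years", config.n_years)
    scfg = SyntheticConfig(**syn_kwargs)

    log.info("stage indices: simulating synthetic world (seed=%d)", scfg.seed)
    world = simulate_world(scfg)
    save_truth(world.truth, out / "truth.json")
    done.append("indices")

    log.info("stage phases: winter means + tercile classification")
    try:
        assignment = classify_phases(winter_index(world.nao), winter_index(world.ea),
                                     base_period=config.base_period)
    except ValueError as e:
        raise RuntimeError(f"stage phases failed on simulated indices: {e}") from e
    membership = composite_membership(assignment)
    assignment.to_csv(out / "phase_assignment.csv")
    done.append("phases")

    log.info("stage anomalies: deseasonalized annual regional series")
    try:
        annual_series, groups = _annual_series_for(world, assignment, config.regions)
    except ValueError as e:
        raise RuntimeError(f"stage anomalies failed: {e}") from e
    pd.concat([s.to_frame() for s in annual_series], ignore_index=True)\
        .to_csv(out / "annual_anomalies.csv", index=False)
    done.append("anomalies")

    log.info("stage composites: pooled composite ANOVA")
    model = PhaseCompositeModel.from_series(annual_series, groups, assignment)
    results = model.fit()
    results.stats.to_csv(out / "composite_stats.csv", index=False)
    results.pairwise.to_csv(out / "composite_pairwise.csv", index=False)
    results.per_dataset.to_csv(out / "composite_per_dataset.csv", index=False)
    done.append("composites")

    log.info("stage eof: field PCA of annual NBP anomalies per group")
    eof_results = {}
    for gname, members in (("dgvms", world.members), ("inversions", world.inversions)):
        fields = []
        years = None
        for stacks in members:
            anoms = deseasonalize(stacks["NBP"])
            yrs = [int(y) for y in np.unique(anoms.times.year)]
            fields.append(np.stack([annual_integral(anoms, y) for y in yrs]))
            years = yrs
        mean_fields = np.mean(np.stack(fields), axis=0)
        eof_results[gname] = nbp_pca(years, mean_fields, world.config.make_flux_grid())
    done.append("eof")

    log.info("stage curves: seasonal composite curves + ensemble envelope")
    grid = world.config.make_flux_grid()
    europe = build_region_mask(STUDY_REGIONS["europe"], grid)
    gpp_anoms = [deseasonalize(m["GPP"]) for m in world.members]
    reco_anoms = [deseasonalize(m["RECO"]) for m in world.members]
    curves = seasonal_flux_curves(gpp_anoms, reco_anoms, None, membership,
                                  europe, region="europe")
    continental = [s for s in annual_series if s.region == "europe"]
    envelope = ensemble_envelope(continental)
    envelope.to_csv(out / "nbp_envelope.csv")
    shares = []
    by_ds = {(s.dataset, s.region): s for s in annual_series}
    for (ds, region), s in by_ds.items():
        if region == "europe":
            continue
        cont = by_ds.get((ds, "europe"))
        if cont is not None:
            shares.append({
                "dataset": ds, "region": region,
                "share_pct": regional_variance_share(s.values, cont.values),
            })
    variance_shares = pd.DataFrame(shares)
    variance_shares.to_csv(out / "variance_shares.csv", index=False)
    done.append("curves")

    run_start, run_len = longest_antiphase_run(assignment)
    manifest = {
        "package_version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "stages_complete": done,
        "n_winters": int(len(assignment.years)),
        "longest_antiphase_run": {"start": int(run_start), "length": int(run_len)},
        "outputs": sorted(p.name for p in out.glob("*") if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return ResultBundle(
        config=config, world=world, assignment=assignment, membership=membership,
        annual_series=annual_series, composite_results=results,
        eof_results=eof_results, curves=curves, envelope=envelope,
        variance_shares=variance_shares, manifest=manifest,
    )


def make_report(bundle: ResultBundle, out_dir=None) -> list[Path]:
    """Render summary figures and tables from a completed bundle.

    Produces the composite bar chart with per-dataset lines, composite
    anomaly maps (leading EOF), seasonal curves with the ensemble
    envelope, and the tidy composite-statistics table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    missing = [s for s in STAGES if s not in bundle.manifest.get("stages_complete", [])]
    if missing:
        raise ValueError(f"incomplete bundle: missing stages {missing}")
    out = Path(out_dir) if out_dir is not None else bundle.config.out_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    written = []

    # composite bar chart (continental scale, pooled) with per-dataset points
    stats = bundle.composite_results.stats
    sel = stats[(stats["region"] == "europe")]
    fig, ax = plt.subplots(figsize=(7, 4))
    comps = [c for c in sel["composite"].unique()]
    for gi, (group, gsub) in enumerate(sel.groupby("group")):
        gsub = gsub.set_index("composite").reindex(comps)
        x = np.arange(len(comps)) + 0.35 * gi
        label_extra = ""
        ax.bar(x, gsub["mean"], width=0.3, label=f"{group}{label_extra}")
        for xi, comp in zip(x, comps):
            n = gsub.loc[comp, "n"]
            if n == 0 or not np.isfinite(gsub.loc[comp, "mean"]):
                ax.annotate("n = 0", (xi, 0), ha="center", fontsize=8)
    per = bundle.composite_results.per_dataset
    per_e = per[per["region"] == "europe"]
    for ds, dsub in per_e.groupby("dataset"):
        dsub = dsub.set_index("composite").reindex(comps)
        ax.plot(np.arange(len(comps)) + 0.17, dsub["mean"], "o-", lw=0.5, ms=2,
                alpha=0.4, color="k")
    ax.set_xticks(np.arange(len(comps)) + 0.17)
    ax.set_xticklabels(comps, rotation=20)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("NBP anomaly (PgC yr$^{-1}$)")
    ax.legend()
    fig.tight_layout()
    p = out / "composite_bars.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # EOF maps
    fig, axes = plt.subplots(1, len(bundle.eof_results), figsize=(10, 4))
    axes = np.atleast_1d(axes)
    grid = bundle.world.config.make_flux_grid()
    for ax, (group, res) in zip(axes, bundle.eof_results.items()):
        im = ax.imshow(res.eof1, origin="lower",
                       extent=[grid.lon[0], grid.lon[-1], grid.lat[0], grid.lat[-1]],
                       cmap="RdBu_r")
        ax.set_title(f"{group}: EOF1 ({100 * res.explained_variance:.0f}%)")
        fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    p = out / "eof_maps.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # seasonal curves
    curves = bundle.curves.curves
    fig, axes = plt.subplots(1, len(curves), figsize=(3 * len(curves), 3),
                             sharey=True)
    for ax, (comp, df) in zip(np.atleast_1d(axes), curves.items()):
        if df[["gpp", "reco"]].isna().all().all():
            ax.annotate("n = 0", (0.5, 0.5), xycoords="axes fraction", ha="center")
        else:
            ax.fill_between(df.index, df["gpp_min"], df["gpp_max"], alpha=0.2,
                            color="green")
            ax.plot(df.index, df["gpp"], color="green", label="GPP")
            ax.fill_between(df.index, df["reco_min"], df["reco_max"], alpha=0.2,
                            color="red")
            ax.plot(df.index, df["reco"], color="red", label="RECO")
        ax.set_title(comp, fontsize=9)
        ax.axhline(0, color="k", lw=0.4)
    fig.tight_layout()
    p = out / "seasonal_curves.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    # tables
    p = out / "composite_stats.csv"
    bundle.composite_results.stats.to_csv(p, index=False)
    written.append(p)
    p = out / "summary.txt"
    p.write_text(bundle.composite_results.summary() + "\n")
    written.append(p)
    return written
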