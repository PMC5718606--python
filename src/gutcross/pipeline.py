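"""Pipeline orchestration: generate -> chemistry -> alpha -> beta -> differential
-> core -> variation partitioning, as one reproducible run.

A run is fully determined by its config plus a single seed; the global seed
fans out to per-stage child seeds by stable hashing of stage names, so
toggling one stage never shifts another stage's random stream. Each stage
reads its inputs from the run directory and fails fast, naming the missing
upstream artifact, when a required stage was toggled off. A manifest records
the seed, config, per-stage wall time and output digests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import alpha as alpha_mod
from . import beta as beta_mod
from . import chem as chem_mod
from . import coremicro
from . import differential as diff_mod
from . import synthetic
from . import varpart as varpart_mod
from ._util import stage_seed, write_tsv

STAGES = ("simulate", "chem", "alpha", "beta", "diff", "core", "varpart")

_SCHEMA = {
    "seed": int,
    "scale": (int, float),
    "outdir": str,
    "stages": dict,
    "generator": dict,
    "beta": dict,
    "diff": dict,
    "core": dict,
    "varpart": dict,
}
_BLOCK_KEYS = {
    "stages": set(STAGES),
    "beta": {"metrics", "n_perm", "mantel_perm", "unifrac"},
    "diff": {"n_perm", "alpha", "effect_threshold", "sparse_threshold"},
    "core": {"grid_points"},
    "varpart": {"n_perm", "alpha", "r_max", "probe", "partition_perm"},
}


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    scale: float = 1.0
    outdir: str = "run"
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    generator: dict = field(default_factory=dict)
    beta: dict = field(
        default_factory=lambda: {
            "metrics": ["braycurtis", "jaccard", "thetayc", "morisitahorn"],
            "n_perm": 10_000,
            "mantel_perm": 9_999,
            "unifrac": True,
        }
    )
    diff: dict = field(
        default_factory=lambda: {
            "n_perm": 1000,
            "alpha": 0.05,
            "effect_threshold": diff_mod.DEFAULT_EFFECT_THRESHOLD,
            "sparse_threshold": diff_mod.DEFAULT_SPARSE_THRESHOLD,
        }
    )
    core: dict = field(default_factory=lambda: {"grid_points": 30})
    varpart: dict = field(
        default_factory=lambda: {
            "n_perm": 5000,
            "alpha": 0.05,
            "r_max": 0.8,
            "probe": False,
            "partition_perm": 999,
        }
    )

    def generator_config(self) -> synthetic.GeneratorConfig:
        try:
            return synthetic.GeneratorConfig(
                seed=stage_seed(self.seed, "simulate"), scale=self.scale, **self.generator
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid generator config: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Parse and schema-validate a YAML run config; unknown keys are rejected."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
    if overrides:
        raw = {**raw, **overrides}
    for key, value in raw.items():
        if key not in _SCHEMA:
            raise ValueError(f"unknown config key {key!r}")
        if not isinstance(value, _SCHEMA[key]):
            raise ValueError(f"config field {key!r} must be {_SCHEMA[key]}")
    for block, allowed in _BLOCK_KEYS.items():
        for sub in raw.get(block, {}):
            if sub not in allowed:
                raise ValueError(f"unknown config key {block}.{sub!r}")
    gen_fields = {f for f in synthetic.GeneratorConfig.__dataclass_fields__} - {"seed", "scale"}
    for sub in raw.get("generator", {}):
        if sub not in gen_fields:
            raise ValueError(f"unknown config key generator.{sub!r}")
    defaults = RunConfig()
    merged = {}
    for key in ("seed", "scale", "outdir", "generator"):
        merged[key] = raw.get(key, getattr(defaults, key))
    for block in ("stages", "beta", "diff", "core", "varpart"):
        base = dict(getattr(defaults, block))
        base.update(raw.get(block, {}))
        merged[block] = base
    config = RunConfig(**merged)
    config.generator_config()  # validates generator values, naming the field
    return config


def _require(outdir: Path, name: str, stage: str, needed_by: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} requires {name} produced by stage {stage!r}; "
            f"enable it or supply the file"
        )
    return path


def _read_counts(outdir: Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(outdir / "counts.tsv", sep="\t", index_col=0, comment="#")
    lineage = df.pop("lineage")
    return df, lineage


def _write_commented(df: pd.DataFrame, path: Path, comments: list[str], index_label=None) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index_label=index_label)


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    gc = config.generator_config()
    design = synthetic.generate_design(gc)
    counts, ledger = synthetic.generate_counts(design, gc)
    tree = synthetic.generate_tree(list(counts.index), seed=gc.seed)
    spectra, tsoc, spec_truth = synthetic.generate_spectra(design, gc)
    peaks = synthetic.generate_peak_tables(design, gc)
    matrices, coupling = synthetic.generate_metadata_matrices(
        design, gc, gradient=ledger["gradient"]
    )
    iec_samples, iec_standards, _ = synthetic.generate_conductivity(design, gc)
    full_ledger = {
        "effect_taxa": ledger["effect_taxa"],
        "effect_samples": ledger["effect_samples"],
        "bacteroides_fold": ledger["bacteroides_fold"],
        "metadata_coupling": coupling,
    }
    synthetic.write_outputs(
        outdir, design, counts, tree, spectra, tsoc, peaks, matrices, full_ledger
    )
    iec_samples.to_csv(outdir / "iec_samples.tsv", sep="\t", index=False)
    iec_standards.to_csv(outdir / "iec_standards.tsv", sep="\t", index=False)


def _stage_chem(config: RunConfig, outdir: Path) -> None:
    spectra = pd.read_csv(
        _require(outdir, "spectra.tsv", "simulate", "chem"), sep="\t"
    )
    tsoc = pd.read_csv(
        _require(outdir, "tsoc.tsv", "simulate", "chem"), sep="\t", index_col=0
    )
    dom = chem_mod.dom_indices_table(spectra, tsoc)
    _write_commented(
        dom,
        outdir / "dom_indices.tsv",
        ["Napierian a = 2.303*A/l, l = 2/3 cm, dilution-corrected (undiluted basis, per cm)",
         "suva/svia per TSOC (g C per g dry matter)"],
        index_label="sample",
    )
    samples = pd.read_csv(_require(outdir, "iec_samples.tsv", "simulate", "chem"), sep="\t")
    standards = pd.read_csv(_require(outdir, "iec_standards.tsv", "simulate", "chem"), sep="\t")
    cal = chem_mod.calibrate_conductivity(samples, standards)
    iec = cal.calibrated.to_frame()
    _write_commented(
        iec,
        outdir / "iec.tsv",
        [f"linear standards calibration R^2 = {cal.r_squared:.5f}; "
         f"flagged batches (>5% drift): {cal.flagged_batches}"],
        index_label="sample_id",
    )
    cal.drift.to_csv(outdir / "iec_drift.tsv", sep="\t", index=False)
    for cls in ("sterol", "polyphenol"):
        peaks = pd.read_csv(
            _require(outdir, f"peaks_{cls}.tsv", "simulate", "chem"), sep="\t", index_col=0
        )
        totals, profiles = chem_mod.fingerprint_table(peaks)
        out = profiles.copy()
        out.insert(0, "total_content", totals)
        write_tsv(out, outdir / f"chem_profiles_{cls}.tsv", index_label="sample_id")


def _stage_alpha(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "counts.tsv", "simulate", "alpha")
    counts, _ = _read_counts(outdir)
    depth = int(counts.sum(axis=0).min())
    rare = beta_mod.rarefy_counts(counts, depth, seed=stage_seed(config.seed, "alpha"))
    table = alpha_mod.alpha_table(rare, mode="counts")
    _write_commented(
        table,
        outdir / "alpha.tsv",
        [f"computed after subsampling every sample to {depth} reads",
         "Shannon_H uses the natural logarithm; Chao1 is the bias-corrected form"],
        index_label="sample",
    )
    for cls in ("sterol", "polyphenol"):
        prof_path = outdir / f"chem_profiles_{cls}.tsv"
        if prof_path.exists():
            prof = pd.read_csv(prof_path, sep="\t", index_col=0).drop(columns="total_content")
            chem_alpha = alpha_mod.alpha_table(prof.T, mode="profile")
            write_tsv(chem_alpha, outdir / f"chem_alpha_{cls}.tsv", index_label="sample")


def _stage_beta(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "counts.tsv", "simulate", "beta")
    counts, _ = _read_counts(outdir)
    design = pd.read_csv(_require(outdir, "design.tsv", "simulate", "beta"), sep="\t", index_col=0)
    seed = stage_seed(config.seed, "beta")
    depth = int(counts.sum(axis=0).min())
    rare = beta_mod.rarefy_counts(counts, depth, seed=seed)
    dms = {}
    for metric in config.beta["metrics"]:
        dms[metric] = beta_mod.pairwise_distance(rare, metric)
        write_tsv(
            pd.DataFrame(dms[metric].data, index=dms[metric].ids, columns=dms[metric].ids),
            outdir / f"dm_{metric}.tsv",
            index_label="sample",
        )
    if config.beta.get("unifrac", True):
        tree = _require(outdir, "tree.nwk", "simulate", "beta").read_text()
        for weighted, tag in ((False, "unweighted_unifrac"), (True, "weighted_unifrac")):
            dm = beta_mod.unifrac(rare, tree, weighted=weighted)
            dms[tag] = dm
            write_tsv(
                pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids),
                outdir / f"dm_{tag}.tsv",
                index_label="sample",
            )
    # endpoint contrast: arms at the final-week samples
    meta = design.loc[list(rare.columns)]
    endpoint = meta[meta["week"] == 4].index
    rows = []
    n_perm = int(config.beta["n_perm"])
    for metric, dm in dms.items():
        sub = dm.filter(endpoint)
        groups = meta.loc[list(sub.ids), "arm"]
        for method, func in (
            ("permanova", beta_mod.permanova),
            ("amova", beta_mod.amova),
            ("homova", beta_mod.homova),
        ):
            res = func(sub, groups, n_perm=n_perm, seed=seed)
            rows.append((method, metric, "arm@week4", res.statistic, res.p_value, res.n_permutations))
    if "braycurtis" in dms and "morisitahorn" in dms:
        res = beta_mod.mantel(
            dms["braycurtis"], dms["morisitahorn"],
            n_perm=int(config.beta["mantel_perm"]), seed=seed,
        )
        rows.append(
            ("mantel", "braycurtis~morisitahorn", "all", res.statistic, res.p_value,
             res.n_permutations)
        )
    tests = pd.DataFrame(
        rows, columns=["method", "metric", "grouping", "statistic", "p", "n_perm"]
    )
    tests["adjusted_p"] = beta_mod.bh_fdr(tests["p"])
    tests.to_csv(outdir / "tests.tsv", sep="\t", index=False)


def _stage_diff(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "counts.tsv", "simulate", "diff")
    counts, lineage = _read_counts(outdir)
    design = pd.read_csv(_require(outdir, "design.tsv", "simulate", "diff"), sep="\t", index_col=0)
    gc = config.generator_config()
    seed = stage_seed(config.seed, "diff")
    meta = design.loc[list(counts.columns)]
    effect_days = list(gc.effect_days)
    reports = []
    for other in [a for a in synthetic.ARMS if a != gc.effect_arm]:
        cohort_a = meta[(meta["arm"] == gc.effect_arm) & meta["day"].isin(effect_days)].index
        cohort_b = meta[(meta["arm"] == other) & meta["day"].isin(effect_days)].index
        rep = diff_mod.run_battery(
            counts, design.reset_index(), list(cohort_a), list(cohort_b),
            n_perm=int(config.diff["n_perm"]), seed=seed,
            sparse_threshold=int(config.diff["sparse_threshold"]),
            alpha=float(config.diff["alpha"]),
            effect_threshold=float(config.diff["effect_threshold"]),
        )
        rep.insert(0, "contrast", f"{gc.effect_arm}_vs_{other}")
        reports.append(rep)
    pd.concat(reports).to_csv(outdir / "differential.tsv", sep="\t", index_label="taxon")
    taxonomy = synthetic.taxonomy_table()
    ratio, rates = diff_mod.fb_ratio_series(counts, taxonomy, design.reset_index())
    write_tsv(ratio.to_frame(), outdir / "fb_ratio.tsv", index_label="sample_id")
    rates.to_csv(outdir / "fb_rates.tsv", sep="\t", index=False)


def _stage_core(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "counts.tsv", "simulate", "core")
    counts, _ = _read_counts(outdir)
    design = pd.read_csv(_require(outdir, "design.tsv", "simulate", "core"), sep="\t", index_col=0)
    profiles = diff_mod.relative_abundance(counts)
    meta = design.loc[list(counts.columns)]
    grid = coremicro.default_grid(profiles, n=int(config.core["grid_points"]))
    cohorts = {"baseline": meta[meta["week"] == 0].index}
    for arm in synthetic.ARMS:
        cohorts[f"{arm}_week4"] = meta[(meta["arm"] == arm) & (meta["week"] == 4)].index
    plot_rows = []
    for name, cohort in cohorts.items():
        if len(cohort) == 0:
            continue
        datum = coremicro.classify_cores(profiles, list(cohort))
        datum.insert(0, "cohort", name)
        plot_rows.append(datum)
    pd.concat(plot_rows).to_csv(outdir / "core_plot.tsv", sep="\t", index_label="taxon")
    surface = coremicro.core_fraction_surface(profiles, list(cohorts["baseline"]), grid)
    surface.to_csv(outdir / "core_surface.tsv", sep="\t", index_label="abundance_threshold")
    gc = config.generator_config()
    seed = stage_seed(config.seed, "core")
    a = list(cohorts[f"{gc.effect_arm}_week4"])
    others = [arm for arm in synthetic.ARMS if arm != gc.effect_arm]
    rows = []
    for other in others:
        b = list(cohorts[f"{other}_week4"])
        for taxon in profiles.index:
            res = coremicro.awks_test(profiles, a, b, taxon, grid=grid, seed=seed)
            rows.append((taxon, f"{gc.effect_arm}_vs_{other}", res.statistic, res.p_value))
    awks = pd.DataFrame(rows, columns=["taxon", "contrast", "awks", "p"])
    awks["adjusted_p"] = beta_mod.bh_fdr(awks["p"])
    awks.to_csv(outdir / "awks.tsv", sep="\t", index=False)


def _stage_varpart(config: RunConfig, outdir: Path) -> None:
    _require(outdir, "counts.tsv", "simulate", "varpart")
    counts, _ = _read_counts(outdir)
    seed = stage_seed(config.seed, "varpart")
    Y = varpart_mod.hellinger(counts)
    mats = {}
    for name in ("chem", "design", "diet"):
        path = _require(outdir, f"meta_{name}.tsv", "simulate", "varpart")
        mats[name] = pd.read_csv(path, sep="\t", index_col=0).loc[Y.index]
    retained = {}
    for i, (name, X) in enumerate(mats.items()):
        retained[name] = varpart_mod.stepdown_screen(
            Y, X,
            n_perm=int(config.varpart["n_perm"]),
            alpha=float(config.varpart["alpha"]),
            r_max=float(config.varpart["r_max"]),
            probe=bool(config.varpart["probe"]),
            seed=seed + i,
        )
    result = varpart_mod.partition_variation(
        Y,
        mats["chem"][retained["chem"]],
        mats["design"][retained["design"]],
        mats["diet"][retained["diet"]],
        n_perm=int(config.varpart["partition_perm"]),
        seed=seed,
        names=("chem", "design", "diet"),
    )
    summary = result.summary().to_frame("fraction")
    summary["p"] = pd.Series(result.p_values).reindex(summary.index.str.removeprefix("pure_")).to_numpy()
    summary.to_csv(outdir / "partition.tsv", sep="\t", index_label="component")
    rows = [(name, v) for name, vs in retained.items() for v in vs]
    pd.DataFrame(rows, columns=["matrix", "variable"]).to_csv(
        outdir / "retained_vars.tsv", sep="\t", index=False
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "chem": _stage_chem,
    "alpha": _stage_alpha,
    "beta": _stage_beta,
    "diff": _stage_diff,
    "core": _stage_core,
    "varpart": _stage_varpart,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order and write a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        t0 = time.perf_counter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _STAGE_FUNCS[stage](config, outdir)
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "wall_s": round(time.perf_counter() - t0, 3),
        }
    digests = {}
    for path in sorted(outdir.iterdir()):
        if path.name == "manifest.json" or path.is_dir():
            continue
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    manifest["digests"] = digests
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
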