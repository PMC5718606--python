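"""Synthetic-data generator for a randomized crossover bed-rest microbiome study.

Emulates the study layout this pipeline targets: 9 participants crossing over
three intervention arms (normoxic bed rest NBR, hypoxic bed rest HBR, hypoxic
ambulation HAmb), stool sampling at days -5/-1 (run-in) and 3/10/18/21, 16S
genus count tables at ~105,300 +/- 39,200 reads per sample, a *Bacteroides*
enrichment confined to the HBR arm in the final week, intestinal electrical
conductivity rising in week 1 (HBR +67%, NBR +32%), DOM absorbance spectra in
three dilutions, HPLC peak fingerprints, and three explanatory metadata
matrices of 109/12/110 variables.

Every output is drawn from a single seed and is bit-reproducible; planted
effects are recorded in ledgers naming exactly the taxa/samples/variables
perturbed, so downstream tests can score recovery against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import stage_rng, write_tsv

ARMS = ("NBR", "HBR", "HAmb")
DAYS = (-5, -1, 3, 10, 18, 21)
WEEK_OF_DAY = {-5: 0, -1: 0, 3: 1, 10: 2, 18: 3, 21: 4}

# Baseline community: 60 gut genera across 5 phyla, geometric-series ranks with
# the familiar dominant genera first so Firmicutes + Bacteroidetes carry >= 80%
# of the mass. (phylum, class, order, family, genus)
_TAXA: list[tuple[str, str]] = [
    ("Bacteroidetes", "Bacteroides"),
    ("Firmicutes", "Faecalibacterium"),
    ("Bacteroidetes", "Prevotella"),
    ("Firmicutes", "Blautia"),
    ("Firmicutes", "Ruminococcus"),
    ("Bacteroidetes", "Alistipes"),
    ("Firmicutes", "Roseburia"),
    ("Firmicutes", "Eubacterium"),
    ("Firmicutes", "Clostridium"),
    ("Bacteroidetes", "Parabacteroides"),
    ("Firmicutes", "Coprococcus"),
    ("Firmicutes", "Dorea"),
    ("Actinobacteria", "Bifidobacterium"),
    ("Firmicutes", "Oscillibacter"),
    ("Firmicutes", "Lachnospira"),
    ("Firmicutes", "Subdoligranulum"),
    ("Bacteroidetes", "Odoribacter"),
    ("Firmicutes", "Dialister"),
    ("Verrucomicrobia", "Akkermansia"),
    ("Firmicutes", "Anaerostipes"),
    ("Firmicutes", "Phascolarctobacterium"),
    ("Bacteroidetes", "Barnesiella"),
    ("Actinobacteria", "Collinsella"),
    ("Firmicutes", "Butyrivibrio"),
    ("Firmicutes", "Veillonella"),
    ("Proteobacteria", "Escherichia"),
    ("Firmicutes", "Streptococcus"),
    ("Bacteroidetes", "Butyricimonas"),
    ("Firmicutes", "Flavonifractor"),
    ("Firmicutes", "Intestinimonas"),
    ("Proteobacteria", "Sutterella"),
    ("Firmicutes", "Lactobacillus"),
    ("Bacteroidetes", "Paraprevotella"),
    ("Firmicutes", "Megasphaera"),
    ("Firmicutes", "Holdemanella"),
    ("Actinobacteria", "Eggerthella"),
    ("Firmicutes", "Anaerotruncus"),
    ("Bacteroidetes", "Alloprevotella"),
    ("Firmicutes", "Romboutsia"),
    ("Firmicutes", "Turicibacter"),
    ("Proteobacteria", "Parasutterella"),
    ("Firmicutes", "Christensenella"),
    ("Firmicutes", "Catenibacterium"),
    ("Bacteroidetes", "Coprobacter"),
    ("Firmicutes", "Acidaminococcus"),
    ("Actinobacteria", "Adlercreutzia"),
    ("Firmicutes", "Mitsuokella"),
    ("Proteobacteria", "Bilophila"),
    ("Firmicutes", "Enterococcus"),
    ("Bacteroidetes", "Porphyromonas"),
    ("Firmicutes", "Sarcina"),
    ("Proteobacteria", "Desulfovibrio"),
    ("Firmicutes", "Marvinbryantia"),
    ("Bacteroidetes", "Dysgonomonas"),
    ("Actinobacteria", "Slackia"),
    ("Firmicutes", "Anaerofustis"),
    ("Bacteroidetes", "Tannerella"),
    ("Verrucomicrobia", "Victivallis"),
    ("Actinobacteria", "Rothia"),
    ("Proteobacteria", "Haemophilus"),
]

_CLASS_OF = {
    "Firmicutes": "Clostridia",
    "Bacteroidetes": "Bacteroidia",
    "Actinobacteria": "Actinomycetia",
    "Proteobacteria": "Gammaproteobacteria",
    "Verrucomicrobia": "Verrucomicrobiae",
}


def taxonomy_table() -> pd.DataFrame:
    """Genus-indexed taxonomy with full lineage strings 'Phylum;Class;Order;Family;Genus'."""
    rows = []
    for phylum, genus in _TAXA:
        lineage = ";".join(
            [phylum, _CLASS_OF[phylum], f"{phylum}ales", f"{genus}aceae", genus]
        )
        rows.append((genus, phylum, lineage))
    return pd.DataFrame(rows, columns=["genus", "phylum", "lineage"]).set_index("genus")


def baseline_composition(decay: float = 0.9) -> pd.Series:
    """Geometric-series baseline relative abundances over the 60-genus panel."""
    w = decay ** np.arange(len(_TAXA))
    w = w / w.sum()
    return pd.Series(w, index=[g for _, g in _TAXA], name="relabund")


@dataclass
class GeneratorConfig:
    """Study conditions for the generator; defaults reproduce the target design at scale 1."""

    n_participants: int = 9
    depth_mean: float = 105_300.0
    depth_sd: float = 39_200.0
    bacteroides_fold: float = 2.0
    effect_days: tuple[int, ...] = (18, 21)
    effect_arm: str = "HBR"
    iec_week1_increase: dict = field(
        default_factory=lambda: {"HBR": 0.67, "NBR": 0.32, "HAmb": 0.0}
    )
    n_meta_vars: tuple[int, int, int] = (109, 12, 110)
    seed: int = 0
    scale: float = 1.0
    dropout_rate: float = 0.0
    # Dirichlet-multinomial noise model
    concentration: float = 50.0
    participant_sigma: float = 0.3
    # spectra model (None = drawn per sample)
    spec_a0: float | None = None
    spec_slope: float | None = None
    spec_bands: bool = True
    spec_noise_sd: float = 0.003
    # metadata coupling
    meta_coupled: tuple[int, int, int] = (8, 3, 8)
    meta_coupling: float = 1.0
    # peak tables
    peak_effect_class: str | None = None
    peak_effect_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.bacteroides_fold <= 0:
            raise ValueError("bacteroides_fold must be positive")
        if self.depth_mean <= 0 or self.depth_sd < 0:
            raise ValueError("inconsistent depth parameters")
        if self.effect_arm not in ARMS:
            raise ValueError(f"effect_arm must be one of {ARMS}")
        if any(w < 1 for w in self.n_meta_vars):
            raise ValueError("metadata matrix widths must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


def generate_design(config: GeneratorConfig) -> pd.DataFrame:
    """Crossover sampling design: participants x 3 arms x 6 days.

    Arm (campaign) order per participant follows a seeded Latin-square
    assignment: participants cycle through the three cyclic shifts of the arm
    list, with participant order and the base rotation drawn from the seed.
    """
    rng = stage_rng(config.seed, "design")
    shifts = rng.permutation(3)
    rows = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        shift = shifts[i % 3]
        order = [ARMS[(shift + k) % 3] for k in range(3)]
        for campaign, arm in enumerate(order, start=1):
            for day in DAYS:
                rows.append(
                    {
                        "sample_id": f"{pid}_{arm}_d{day}",
                        "participant_id": pid,
                        "arm": arm,
                        "campaign": campaign,
                        "day": day,
                        "week": WEEK_OF_DAY[day],
                    }
                )
    design = pd.DataFrame(rows)
    if config.dropout_rate > 0:
        keep = rng.random(len(design)) >= config.dropout_rate
        design = design.loc[keep].reset_index(drop=True)
    return design


def _draw_depths(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    """Truncated-normal sequencing depths, floor 1000*scale (>=1 read)."""
    mean = config.depth_mean * config.scale
    sd = config.depth_sd * config.scale
    lo = max(1.0, 1000.0 * config.scale)
    depths = rng.normal(mean, sd, size=n)
    for _ in range(100):
        bad = depths < lo
        if not bad.any():
            break
        depths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(depths, lo).round().astype(np.int64)


def _latent_compositions(
    design: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-sample expected compositions with participant tilt and planted effect.

    Returns (n_samples x n_taxa expectation matrix, effect taxa, effect sample ids).
    """
    base = baseline_composition().to_numpy()
    taxa = list(baseline_composition().index)
    participants = sorted(design["participant_id"].unique())
    tilt = {
        p: np.exp(config.participant_sigma * rng.standard_normal(len(taxa)))
        for p in participants
    }
    effect_idx = taxa.index("Bacteroides")
    effect_samples: list[str] = []
    pis = np.empty((len(design), len(taxa)))
    for r, row in enumerate(design.itertuples(index=False)):
        pi = base * tilt[row.participant_id]
        pi = pi / pi.sum()
        if (
            config.bacteroides_fold != 1.0
            and row.arm == config.effect_arm
            and row.day in config.effect_days
        ):
            # multiply the *expected relative abundance* by the fold exactly:
            # compensate for renormalization so E[relabund] = fold * baseline
            p0 = pi[effect_idx]
            q = config.bacteroides_fold * p0
            if q >= 1.0:
                raise ValueError("bacteroides_fold pushes relative abundance past 1")
            mult = q * (1.0 - p0) / (p0 * (1.0 - q))
            pi = pi.copy()
            pi[effect_idx] *= mult
            pi = pi / pi.sum()
            effect_samples.append(row.sample_id)
        pis[r] = pi
    effect_taxa = ["Bacteroides"] if config.bacteroides_fold != 1.0 else []
    return pis, effect_taxa, effect_samples


def generate_counts(
    design: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, dict]:
    """Dirichlet-multinomial genus counts (taxa x samples) plus a true-effect ledger.

    Expected relative abundance of the genus *Bacteroides* is multiplied by
    ``bacteroides_fold`` in (effect_arm, effect_days) samples; fold 1 is the
    null mode. The ledger names exactly the perturbed taxa and samples and
    carries the per-sample latent ln-Bacteroides gradient used to couple the
    metadata matrices.
    """
    if len(design) == 0:
        raise ValueError("design is empty")
    rng = stage_rng(config.seed, "counts")
    pis, effect_taxa, effect_samples = _latent_compositions(design, config, rng)
    taxa = list(baseline_composition().index)
    depths = _draw_depths(rng, len(design), config)
    counts = np.empty((len(design), len(taxa)), dtype=np.int64)
    for r in range(len(design)):
        p = rng.dirichlet(config.concentration * pis[r])
        counts[r] = rng.multinomial(depths[r], p)
    table = pd.DataFrame(counts.T, index=taxa, columns=design["sample_id"].to_numpy())
    # latent community gradient: leading axes of the sqrt latent compositions
    # (participant tilts + planted effect), used to couple metadata matrices
    H = np.sqrt(pis)
    Hc = H - H.mean(axis=0)
    U, S, _ = np.linalg.svd(Hc, full_matrices=False)
    k = min(8, U.shape[1])
    axes = pd.DataFrame(
        U[:, :k] * S[:k],
        index=design["sample_id"].to_numpy(),
        columns=[f"axis{i + 1}" for i in range(k)],
    )
    ledger = {
        "effect_taxa": effect_taxa,
        "effect_samples": effect_samples,
        "bacteroides_fold": config.bacteroides_fold,
        "gradient": axes,
    }
    return table, ledger


def generate_paired_counts(
    design: pd.DataFrame, config: GeneratorConfig, extra_concentration: float = 100.0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two count tables re-drawn from shared latent compositions.

    Stands in for paired amplicon regions sequenced from the same DNA (e.g.
    V1-V2 vs V6-V7): each table multinomially resamples its own Dirichlet
    perturbation of the common latent composition, so their community
    structure is correlated but not identical.
    """
    rng = stage_rng(config.seed, "paired_counts")
    pis, effect_taxa, effect_samples = _latent_compositions(design, config, rng)
    taxa = list(baseline_composition().index)
    tables = []
    for _ in range(2):
        depths = _draw_depths(rng, len(design), config)
        counts = np.empty((len(design), len(taxa)), dtype=np.int64)
        for r in range(len(design)):
            p = rng.dirichlet(extra_concentration * pis[r])
            counts[r] = rng.multinomial(depths[r], p)
        tables.append(
            pd.DataFrame(counts.T, index=taxa, columns=design["sample_id"].to_numpy())
        )
    ledger = {"effect_taxa": effect_taxa, "effect_samples": effect_samples}
    return tables[0], tables[1], ledger


def generate_tree(taxa: list[str], seed: int = 0) -> str:
    """Random bifurcating newick tree over the taxa, strictly positive branch lengths."""
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")
    rng = stage_rng(seed, "tree")
    nodes = [f"{t}" for t in taxa]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (i, j) if i < j else (j, i)
        bi, bj = rng.exponential(0.1, size=2) + 0.01
        merged = f"({nodes[i]}:{bi:.6f},{nodes[j]}:{bj:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return nodes[0] + ";"


WAVELENGTHS = np.arange(200, 801, 5)
DILUTIONS = (10, 50, 100)
PATH_LENGTH_CM = 2.0 / 3.0


def generate_spectra(
    design: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Microtiter absorbance spectra (200-800 nm, 5 nm step) in three dilutions.

    The undiluted Napierian absorption model is an exponentially decaying CDOM
    term a0*exp(-S*(lambda-275)) plus Gaussian chromophore bands (aromatics
    near 280 nm, an indole-like band near 217 nm). Recorded absorbance is
    A = a*l/2.303 divided by the dilution factor, plus additive noise.

    Returns (long spectra table, per-sample TSOC table, ground-truth ledger
    holding the noiseless absorption coefficients at the index wavelengths).
    """
    rng = stage_rng(config.seed, "spectra")
    lam = WAVELENGTHS.astype(float)
    key_wl = np.array([217.0, 254.0, 275.0, 287.0, 295.0, 350.0, 365.0, 420.0])
    rows = []
    tsoc_rows = []
    truth: dict[str, dict] = {}
    for row in design.itertuples(index=False):
        a0 = config.spec_a0 if config.spec_a0 is not None else rng.lognormal(np.log(40.0), 0.3)
        slope = config.spec_slope if config.spec_slope is not None else rng.normal(0.016, 0.002)
        tsoc = rng.lognormal(np.log(25.0), 0.25)

        def a_true(w: np.ndarray) -> np.ndarray:
            a = a0 * np.exp(-slope * (w - 275.0))
            if config.spec_bands:
                a = a + band280 * np.exp(-0.5 * ((w - 280.0) / 15.0) ** 2)
                a = a + band217 * np.exp(-0.5 * ((w - 217.0) / 10.0) ** 2)
            return a

        band280 = rng.lognormal(np.log(8.0), 0.4) if config.spec_bands else 0.0
        band217 = rng.lognormal(np.log(15.0), 0.4) if config.spec_bands else 0.0
        a_grid = a_true(lam)
        A_undiluted = a_grid * PATH_LENGTH_CM / 2.303
        for dil in DILUTIONS:
            A = A_undiluted / dil
            if config.spec_noise_sd > 0:
                A = A + rng.normal(0.0, config.spec_noise_sd, size=A.size)
            for w, av in zip(lam, A):
                rows.append((row.sample_id, dil, w, av))
        tsoc_rows.append((row.sample_id, tsoc))
        truth[row.sample_id] = {
            "a0": a0,
            "slope": slope,
            "tsoc": tsoc,
            "a_true": dict(zip(key_wl.tolist(), a_true(key_wl).tolist())),
        }
    spectra = pd.DataFrame(rows, columns=["sample", "dilution", "wavelength_nm", "absorbance"])
    tsoc = pd.DataFrame(tsoc_rows, columns=["sample", "tsoc"]).set_index("sample")
    return spectra, tsoc, truth


def generate_peak_tables(
    design: pd.DataFrame, config: GeneratorConfig
) -> dict[str, pd.DataFrame]:
    """HPLC peak tables (samples x peaks) per compound class with a shared
    retention-time registry, lognormal areas, and no group effect by default."""
    rng = stage_rng(config.seed, "peaks")
    out = {}
    for cls in ("sterol", "polyphenol"):
        n_peaks = int(rng.integers(10, 31))
        rts = np.sort(rng.uniform(2.0, 35.0, size=n_peaks))
        mu = rng.normal(np.log(100.0), 0.8, size=n_peaks)
        cols = [f"{cls}_rt{rt:.2f}" for rt in rts]
        areas = rng.lognormal(mu, 0.4, size=(len(design), n_peaks))
        if config.peak_effect_class == cls and config.peak_effect_factor != 1.0:
            mask = (
                (design["arm"] == config.effect_arm)
                & design["day"].isin(config.effect_days)
            ).to_numpy()
            areas[mask, 0] *= config.peak_effect_factor
        out[cls] = pd.DataFrame(areas, index=design["sample_id"].to_numpy(), columns=cols)
    return out


def generate_metadata_matrices(
    design: pd.DataFrame,
    config: GeneratorConfig,
    gradient: pd.Series | pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Three samples x variables explanatory matrices (chem/design/diet widths
    109/12/110 by default); a configured subset of variables per matrix is
    linearly coupled to the planted community gradient (one or more latent
    community axes, assigned round-robin), the rest pure noise."""
    rng = stage_rng(config.seed, "metadata")
    names = ("chem", "design", "diet")
    if gradient is None:
        G = np.zeros((len(design), 1))
        coupled_counts = (0, 0, 0)
    else:
        if isinstance(gradient, pd.Series):
            gradient = gradient.to_frame()
        G = gradient.reindex(design["sample_id"]).to_numpy()
        sd = G.std(axis=0)
        G = (G - G.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        coupled_counts = config.meta_coupled
    matrices: dict[str, pd.DataFrame] = {}
    coupling: dict[str, list[str]] = {}
    for name, width, n_coupled in zip(names, config.n_meta_vars, coupled_counts):
        X = rng.standard_normal((len(design), width))
        cols = [f"{name}_v{j + 1}" for j in range(width)]
        n_coupled = min(n_coupled, width)
        for j in range(n_coupled):
            g = G[:, j % G.shape[1]]
            X[:, j] = config.meta_coupling * g + rng.standard_normal(len(design))
        matrices[name] = pd.DataFrame(X, index=design["sample_id"].to_numpy(), columns=cols)
        coupling[name] = cols[:n_coupled]
    return matrices, {"coupled": coupling, "strength": config.meta_coupling}


# Nominal conductivity (mS/cm, 28 C) of 1 M KCl and its 10-fold dilutions.
KCL_NOMINAL = {1.0: 111.9, 0.1: 12.89, 0.01: 1.413, 0.001: 0.1469}


def generate_conductivity(
    design: pd.DataFrame,
    config: GeneratorConfig,
    gain_drift: float = 0.001,
    noise_sd: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Conductivity run: sample readings with KCl standards interleaved every 5 samples.

    True IEC starts near 2.5 mS/cm per participant; intervention samples
    (day >= 3) are raised by the configured per-arm week-1 fraction. A slow
    multiplicative electrode gain drift distorts readings; standards (1 M KCl
    and its 10-fold dilutions, triplicate per batch) let the calibration
    module undo it.
    """
    rng = stage_rng(config.seed, "iec")
    base = {
        p: rng.lognormal(np.log(2.5), 0.15) for p in sorted(design["participant_id"].unique())
    }
    true_iec = []
    for row in design.itertuples(index=False):
        v = base[row.participant_id]
        if row.day >= 3:
            v *= 1.0 + config.iec_week1_increase.get(row.arm, 0.0)
        true_iec.append(v * (1.0 + rng.normal(0.0, 0.03)))
    true_iec = np.asarray(true_iec)

    n = len(design)
    n_batches = int(np.ceil(n / 5)) + 1
    gains = 1.0 + gain_drift * np.arange(n_batches) + rng.normal(0, 1e-4, n_batches)
    batch_of_sample = np.arange(n) // 5
    readings = gains[batch_of_sample] * true_iec + rng.normal(0, noise_sd, n)
    samples = pd.DataFrame(
        {
            "sample_id": design["sample_id"].to_numpy(),
            "batch": batch_of_sample,
            "reading": readings,
        }
    )
    std_rows = []
    for b in range(n_batches):
        for molarity, nominal in KCL_NOMINAL.items():
            for rep in range(3):
                std_rows.append(
                    (b, molarity, nominal, rep, gains[b] * nominal + rng.normal(0, noise_sd))
                )
    standards = pd.DataFrame(
        std_rows, columns=["batch", "molarity", "nominal", "replicate", "reading"]
    )
    truth = {"true_iec": pd.Series(true_iec, index=design["sample_id"].to_numpy()), "gains": gains}
    return samples, standards, truth


def write_outputs(
    outdir: str | Path,
    design: pd.DataFrame,
    counts: pd.DataFrame,
    tree_newick: str,
    spectra: pd.DataFrame,
    tsoc: pd.DataFrame,
    peaks: dict[str, pd.DataFrame],
    matrices: dict[str, pd.DataFrame],
    ledger: dict,
) -> None:
    """Write the generator products in the pipeline's tab-separated exchange formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(design.set_index("sample_id"), outdir / "design.tsv", index_label="sample_id")
    tax = taxonomy_table()
    counts_out = counts.copy()
    counts_out.insert(0, "lineage", tax.loc[counts.index, "lineage"].to_numpy())
    write_tsv(counts_out, outdir / "counts.tsv", index_label="taxon")
    (outdir / "tree.nwk").write_text(tree_newick + "\n")
    spectra.to_csv(outdir / "spectra.tsv", sep="\t", index=False)
    write_tsv(tsoc, outdir / "tsoc.tsv", index_label="sample")
    for cls, table in peaks.items():
        write_tsv(table, outdir / f"peaks_{cls}.tsv", index_label="sample_id")
    for name, m in matrices.items():
        write_tsv(m, outdir / f"meta_{name}.tsv", index_label="sample_id")
    serializable = {
        k: (v.to_dict() if isinstance(v, pd.Series) else v) for k, v in ledger.items()
    }
    (outdir / "ledger.json").write_text(json.dumps(serializable, indent=1))


def config_to_dict(config: GeneratorConfig) -> dict:
    return asdict(config)
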