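"""End-to-end harness: synth -> imaging -> spectra -> inference.

:func:`run_synthetic_study` generates habitat images per class and fish
images per individual (each with a prescribed spectral slope drawn from a
hierarchical ground-truth model), measures every slope through the full
patch/spectrum pipeline, assembles the study table, runs the classical
tests and both mixed models, and writes a reproducible output bundle.
:func:`run_empirical` is the same analysis starting from images on disk
plus a study table, the path a user with real photographs takes.

Determinism: one global seed is split into fixed per-stage substreams;
patch offsets are seeded per source image from a stable hash of its
identifier, so the in-memory and on-disk paths of the same study give
byte-identical results.  Images are quantized to the 16-bit grid at
generation time for the same reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, DataError
from .imaging import LuminanceImage, read_image, sample_patches, write_image_16bit
from .inference import (
    ModelSpec,
    Posterior,
    fit_mcmc_lmm,
    one_way_anova,
    read_newick,
    sex_deviation_model,
    two_sample_t,
)
from .spectra import BinnedSpectrum, BinningSpec, class_reference, deviation, estimate_slope, patch_spectrum
from .synth import SpectralNoiseConfig, StudySimConfig, generate_spectral_noise_image, generate_study_dataset

__all__ = [
    "DEFAULT_HABITAT_SLOPES",
    "DEFAULT_SPECIES_HABITAT",
    "DEFAULT_TREE_NEWICK",
    "RunConfig",
    "run_synthetic_study",
    "run_empirical",
    "report",
]

# Five substrate classes with true spectral slopes averaging -2.35, the
# steep aquatic regime; spacing gives clear between-class separation.
DEFAULT_HABITAT_SLOPES: dict[str, float] = {
    "sand": -2.0,
    "gravel": -2.2,
    "boulder": -2.4,
    "detritus": -2.5,
    "bedrock": -2.65,
}

# Ten darter species grouped by substrate preference.
DEFAULT_SPECIES_HABITAT: dict[str, str] = {
    "E_chlorosomum": "sand",
    "E_olmstedi": "sand",
    "E_pyrrhogaster": "sand",
    "E_blennioides": "boulder",
    "E_camurum": "boulder",
    "E_caeruleum": "gravel",
    "E_zonale": "gravel",
    "E_gracile": "detritus",
    "E_swaini": "detritus",
    "E_barrenense": "bedrock",
}

# Synthetic ultrametric tree (depth 1) for the ten species, clustered by
# habitat so phylogeny and habitat covary as in real darter communities.
# This is a synthetic stand-in, not an inferred phylogeny.
DEFAULT_TREE_NEWICK = (
    "(((E_chlorosomum:0.3,E_pyrrhogaster:0.3):0.3,E_olmstedi:0.6):0.4,"
    "((E_gracile:0.4,E_swaini:0.4):0.2,"
    "(((E_caeruleum:0.15,E_zonale:0.15):0.05,"
    "(E_blennioides:0.15,E_camurum:0.15):0.05):0.2,"
    "E_barrenense:0.4):0.2):0.4);"
)

# Fixed substream labels so every stage reseeds identically across runs
# and across the in-memory / on-disk paths.
_STAGE_KEYS = {"study": 1, "chain_male": 2, "chain_female": 3, "chain_dev": 4}


def _stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGE_KEYS[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _patch_seed(global_seed: int, source_id: str) -> int:
    return int((global_seed * 1000003 + zlib.crc32(source_id.encode())) % (2**31))


def _image_seed(global_seed: int, source_id: str) -> int:
    return int((global_seed * 998244353 + zlib.crc32(source_id.encode())) % (2**31))


@dataclass
class RunConfig:
    """Configuration for one full study run.

    Chain defaults (20,000 / 2,000 / 10) are the desk-scale settings used
    throughout the test harness; production-scale analyses should raise
    them (the mixed-model layer documents 1,000,000 / 10,000 / 50).
    """

    seed: int = 0
    out_dir: str | None = None
    mode: str = "synthetic"
    # spectral analysis
    box_px: int = 200
    reps: int = 2
    alpha: float = 2.0
    f_min: float = 10.0
    f_max: float = 110.0
    n_bins: int = 20
    # synthetic study design
    habitat_slopes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_SLOPES)
    )
    species_habitat: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_HABITAT)
    )
    tree_newick: str = DEFAULT_TREE_NEWICK
    tree_file: str | None = None
    sites_per_species: int = 2
    fish_per_site: int = 6
    images_per_class: int = 20
    habitat_image_px: int = 600
    fish_image_px: int = 256
    intercept_b0: float = -2.5
    effect_b: float = 0.262
    sigma_phylo: float = 0.15
    sigma_site: float = 0.05
    sigma_resid: float = 0.25
    sex_effect: float = -0.166
    mean_level: float = 0.5
    contrast: float = 0.2
    write_images: bool = False
    # chains
    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 10
    # empirical inputs
    fish_image_dir: str | None = None
    habitat_image_dir: str | None = None
    study_csv: str | None = None

    def binning(self) -> BinningSpec:
        return BinningSpec(self.f_min, self.f_max, self.n_bins)

    def model_spec(self, response: str, fixed: tuple[str, ...], stage: str) -> ModelSpec:
        return ModelSpec(
            response=response,
            fixed=fixed,
            random=("phylo", "site"),
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            seed=_stage_seed(self.seed, stage),
        )


def _quantize16(pixels: np.ndarray) -> np.ndarray:
    """Snap [0,1] floats to the 16-bit grid so disk round-trips are exact."""
    return np.round(np.clip(pixels, 0.0, 1.0) * 65535.0) / 65535.0


def _analyze_image(
    image: LuminanceImage, config: RunConfig
) -> list[tuple[dict, BinnedSpectrum]]:
    """Patch an image and return (metadata, binned spectrum) per patch."""
    seed = _patch_seed(config.seed, image.source_id)
    patches = sample_patches(image, box_px=config.box_px, n=config.reps, seed=seed)
    out = []
    for p in patches:
        binned = patch_spectrum(p, alpha=config.alpha, binning=config.binning())
        fit = estimate_slope(binned)
        meta = {
            "source_id": p.source_id,
            "replicate": p.replicate,
            "row": p.offset_rc[0],
            "col": p.offset_rc[1],
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
        }
        out.append((meta, binned))
    return out


def _mean_binned(spectra: list[BinnedSpectrum]) -> BinnedSpectrum:
    return BinnedSpectrum(
        bin_log10_center=np.mean([s.bin_log10_center for s in spectra], axis=0),
        bin_log10_power=np.mean([s.bin_log10_power for s in spectra], axis=0),
        spec=spectra[0].spec,
    )


def _habitat_stage_synthetic(config: RunConfig, out_images: str | None):
    """Generate + analyze habitat images; return patch table, refs, class means."""
    patch_rows = []
    class_bins: dict[str, list[BinnedSpectrum]] = {}
    for hab in sorted(config.habitat_slopes):
        beta = config.habitat_slopes[hab]
        class_bins[hab] = []
        for i in range(config.images_per_class):
            src = f"{hab}_{i:03d}"
            img_cfg = SpectralNoiseConfig(
                side_px=config.habitat_image_px,
                beta=beta,
                mean_level=config.mean_level,
                contrast=config.contrast,
                seed=_image_seed(config.seed, src),
            )
            image = generate_spectral_noise_image(img_cfg)
            image = LuminanceImage(_quantize16(image.pixels), source_id=src)
            if out_images is not None:
                d = os.path.join(out_images, "habitat", hab)
                os.makedirs(d, exist_ok=True)
                write_image_16bit(os.path.join(d, f"{src}.tif"), image.pixels)
            for meta, binned in _analyze_image(image, config):
                meta["habitat_class"] = hab
                patch_rows.append(meta)
                class_bins[hab].append(binned)
    patch_table = pd.DataFrame(patch_rows)
    refs = {hab: class_reference(bins) for hab, bins in class_bins.items()}
    class_slope = patch_table.groupby("habitat_class")["slope"].mean().to_dict()
    return patch_table, refs, class_slope


def _fish_stage(
    config: RunConfig,
    study: pd.DataFrame,
    refs: dict[str, np.ndarray],
    class_slope: dict[str, float],
    image_for_fish,
) -> pd.DataFrame:
    """Measure per-fish slope and deviation given an image source callback."""
    rows = []
    for rec in study.itertuples(index=False):
        image = image_for_fish(rec)
        analyzed = _analyze_image(image, config)
        slopes = [meta["slope"] for meta, _ in analyzed]
        fish_bins = _mean_binned([b for _, b in analyzed])
        dev = deviation(
            fish_bins,
            refs[rec.habitat_class],
            fish_id=rec.fish_id,
            habitat_class=rec.habitat_class,
        )
        rows.append(
            {
                "fish_id": rec.fish_id,
                "species": rec.species,
                "sex": rec.sex,
                "site": rec.site,
                "habitat_class": rec.habitat_class,
                "slope": float(np.mean(slopes)),
                "habitat_slope": class_slope[rec.habitat_class],
                "deviation": dev.mse,
            }
        )
    return pd.DataFrame(rows)


def _fit_models(config: RunConfig, table: pd.DataFrame, tree) -> dict:
    males = table[table["sex"] == "male"].reset_index(drop=True)
    females = table[table["sex"] == "female"].reset_index(drop=True)
    stats = {
        "anova_habitat": None,  # filled by caller (needs patch table)
        "anova_males": one_way_anova(
            {sp: g["slope"].to_numpy() for sp, g in males.groupby("species")}
        ),
        "anova_females": one_way_anova(
            {sp: g["slope"].to_numpy() for sp, g in females.groupby("species")}
        ),
        "ttest_sex": two_sample_t(males["slope"], females["slope"]),
    }
    post_male = fit_mcmc_lmm(
        males, config.model_spec("slope", ("habitat_slope",), "chain_male"), tree
    )
    post_female = fit_mcmc_lmm(
        females, config.model_spec("slope", ("habitat_slope",), "chain_female"), tree
    )
    post_dev = sex_deviation_model(
        table,
        tree,
        config.model_spec("deviation", ("is_female",), "chain_dev"),
    )
    return {
        "stats": stats,
        "post_male": post_male,
        "post_female": post_female,
        "post_dev": post_dev,
    }


def _posterior_rows(name: str, post: Posterior) -> pd.DataFrame:
    df = post.summaries.copy()
    df.insert(0, "model", name)
    dic_row = pd.DataFrame(
        [{"model": name, "parameter": "DIC", "mean": post.dic,
          "hpd_lo": np.nan, "hpd_hi": np.nan, "pmcmc": np.nan}]
    )
    return pd.concat([df, dic_row], ignore_index=True)


def _stats_table(stats: dict) -> pd.DataFrame:
    rows = []
    for name in ("anova_habitat", "anova_males", "anova_females"):
        a = stats[name]
        rows.append(
            {"test": name, "statistic": a.f_stat, "df1": a.df_between,
             "df2": a.df_within, "p_value": a.p_value}
        )
    t = stats["ttest_sex"]
    rows.append(
        {"test": "ttest_sex", "statistic": t.t_stat, "df1": t.df,
         "df2": np.nan, "p_value": t.p_value}
    )
    return pd.DataFrame(rows)


def _write_bundle(config: RunConfig, bundle: dict) -> dict:
    """Write CSVs, report and manifest; return manifest dict."""
    out = config.out_dir
    manifest: dict = {
        "version": __version__,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "checksums": {},
    }
    if out is None:
        return manifest
    os.makedirs(out, exist_ok=True)
    files = {
        "habitat_patches.csv": bundle["habitat_patches"],
        "study_table.csv": bundle["study_table"],
        "stats_summary.csv": _stats_table(bundle["stats"]),
        "model_summaries.csv": pd.concat(
            [
                _posterior_rows("male_habitat", bundle["post_male"]),
                _posterior_rows("female_habitat", bundle["post_female"]),
                _posterior_rows("sex_deviation", bundle["post_dev"]),
            ],
            ignore_index=True,
        ),
    }
    if "true_study" in bundle:
        files["true_study.csv"] = bundle["true_study"]
    for name, df in files.items():
        path = os.path.join(out, name)
        df.to_csv(path, index=False, float_format="%.12g")
        with open(path, "rb") as fh:
            manifest["checksums"][name] = hashlib.sha256(fh.read()).hexdigest()
    text = report(bundle)
    rpath = os.path.join(out, "report.md")
    with open(rpath, "w") as fh:
        fh.write(text)
    with open(rpath, "rb") as fh:
        manifest["checksums"]["report.md"] = hashlib.sha256(fh.read()).hexdigest()
    import time

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_synthetic_study(config: RunConfig) -> tuple[dict, dict]:
    """Full synthetic pipeline; returns (bundle, manifest).

    The bundle holds the habitat patch table, the measured study table,
    the classical test results, and the three posteriors; the manifest
    holds the config snapshot and SHA-256 checksums of everything written.
    """
    tree = read_newick(
        open(config.tree_file).read() if config.tree_file else config.tree_newick
    )
    sim = StudySimConfig(
        habitat_slopes=dict(config.habitat_slopes),
        species_habitat=dict(config.species_habitat),
        sites_per_species=config.sites_per_species,
        fish_per_site=config.fish_per_site,
        intercept_b0=config.intercept_b0,
        effect_b=config.effect_b,
        sigma_phylo=config.sigma_phylo,
        sigma_site=config.sigma_site,
        sigma_resid=config.sigma_resid,
        sex_effect=config.sex_effect,
        seed=_stage_seed(config.seed, "study"),
    )
    true_study = generate_study_dataset(sim, tree)

    out_images = (
        os.path.join(config.out_dir, "images")
        if (config.out_dir and config.write_images)
        else None
    )
    patch_table, refs, class_slope = _habitat_stage_synthetic(config, out_images)

    def image_for_fish(rec) -> LuminanceImage:
        cfg = SpectralNoiseConfig(
            side_px=config.fish_image_px,
            beta=rec.slope,  # true per-fish slope drives its image
            mean_level=config.mean_level,
            contrast=config.contrast,
            seed=_image_seed(config.seed, rec.fish_id),
        )
        img = generate_spectral_noise_image(cfg)
        img = LuminanceImage(_quantize16(img.pixels), source_id=rec.fish_id)
        if out_images is not None:
            d = os.path.join(out_images, "fish")
            os.makedirs(d, exist_ok=True)
            write_image_16bit(os.path.join(d, f"{rec.fish_id}.tif"), img.pixels)
        return img

    study = _fish_stage(config, true_study, refs, class_slope, image_for_fish)
    models = _fit_models(config, study, tree)
    models["stats"]["anova_habitat"] = one_way_anova(
        {h: g["slope"].to_numpy() for h, g in patch_table.groupby("habitat_class")}
    )

    bundle = {
        "habitat_patches": patch_table,
        "study_table": study,
        "true_study": true_study,
        **models,
    }
    if out_images is not None:
        # companion inputs for the empirical path
        true_study.drop(columns=["habitat_slope", "slope"]).to_csv(
            os.path.join(config.out_dir, "study_input.csv"), index=False
        )
        with open(os.path.join(config.out_dir, "tree.nwk"), "w") as fh:
            fh.write(tree.newick if isinstance(tree.newick, str) else tree.write_newick())
    manifest = _write_bundle(config, bundle)
    return bundle, manifest


def _find_image(directory: str, stem: str) -> str | None:
    for ext in (".tif", ".tiff", ".png"):
        path = os.path.join(directory, stem + ext)
        if os.path.exists(path):
            return path
    return None


def run_empirical(config: RunConfig) -> tuple[dict, dict]:
    """Analyze images on disk plus a study table; same bundle shape.

    Expects ``study_csv`` with columns fish_id, species, sex, site,
    habitat_class; ``fish_image_dir`` with one image per fish_id; and
    ``habitat_image_dir`` with one subdirectory of images per habitat
    class.  Grayscale images are treated as luminance directly.
    """
    for attr in ("study_csv", "fish_image_dir", "habitat_image_dir"):
        if getattr(config, attr) is None:
            raise ConfigurationError(f"empirical run requires {attr}")
    study = pd.read_csv(config.study_csv)
    required = {"fish_id", "species", "sex", "site", "habitat_class"}
    missing_cols = required - set(study.columns)
    if missing_cols:
        raise DataError(f"study table missing columns: {sorted(missing_cols)}")
    tree = read_newick(
        open(config.tree_file).read() if config.tree_file else config.tree_newick
    )

    # habitat stage from disk
    patch_rows = []
    class_bins: dict[str, list[BinnedSpectrum]] = {}
    for hab in sorted(study["habitat_class"].astype(str).unique()):
        d = os.path.join(config.habitat_image_dir, hab)
        names = sorted(
            f for f in (os.listdir(d) if os.path.isdir(d) else [])
            if f.lower().endswith((".tif", ".tiff", ".png"))
        )
        if not names:
            raise DataError(f"no images found for habitat class {hab!r}")
        class_bins[hab] = []
        for fname in names:
            src = os.path.splitext(fname)[0]
            arr = read_image(os.path.join(d, fname))
            if arr.ndim != 2:
                raise DataError(f"habitat image {fname} is not grayscale luminance")
            image = LuminanceImage(arr, source_id=src)
            for meta, binned in _analyze_image(image, config):
                meta["habitat_class"] = hab
                patch_rows.append(meta)
                class_bins[hab].append(binned)
    patch_table = pd.DataFrame(patch_rows)
    refs = {hab: class_reference(b) for hab, b in class_bins.items()}
    class_slope = patch_table.groupby("habitat_class")["slope"].mean().to_dict()

    def image_for_fish(rec) -> LuminanceImage:
        path = _find_image(config.fish_image_dir, rec.fish_id)
        if path is None:
            raise DataError(f"no image found for fish_id {rec.fish_id!r}")
        arr = read_image(path)
        if arr.ndim != 2:
            raise DataError(f"fish image for {rec.fish_id!r} is not grayscale luminance")
        return LuminanceImage(arr, source_id=rec.fish_id)

    table = _fish_stage(config, study, refs, class_slope, image_for_fish)
    models = _fit_models(config, table, tree)
    models["stats"]["anova_habitat"] = one_way_anova(
        {h: g["slope"].to_numpy() for h, g in patch_table.groupby("habitat_class")}
    )
    bundle = {"habitat_patches": patch_table, "study_table": table, **models}
    manifest = _write_bundle(config, bundle)
    return bundle, manifest


def _fmt_anova(label: str, a) -> str:
    return (
        f"- {label}: F = {a.f_stat:.4g}, df = ({a.df_between}, {a.df_within}), "
        f"p = {a.p_value:.4g}"
    )


def _fmt_posterior(label: str, post: Posterior) -> list[str]:
    lines = [f"### {label}"]
    for _, row in post.summaries.iterrows():
        if str(row["parameter"]).startswith("sigma2"):
            lines.append(
                f"- {row['parameter']}: mean = {row['mean']:.4g}, "
                f"95% HPD [{row['hpd_lo']:.4g}, {row['hpd_hi']:.4g}]"
            )
        else:
            lines.append(
                f"- {row['parameter']}: mean = {row['mean']:.4g}, "
                f"95% HPD [{row['hpd_lo']:.4g}, {row['hpd_hi']:.4g}], "
                f"pMCMC = {row['pmcmc']:.4g}"
            )
    lines.append(f"- DIC = {post.dic:.6g}")
    return lines


def report(bundle: dict) -> str:
    """Render the four-block summary of one run as markdown.

    Blocks: habitat-class ANOVA; species ANOVAs by sex; male-female t
    test; mixed-model summaries (habitat-slope models per sex and, when
    deviations are present, the sex-deviation model).  Pure function of
    the bundle: re-rendering is byte-identical.
    """
    missing = [
        k for k in ("stats", "post_male", "post_female", "study_table")
        if k not in bundle
    ]
    if missing:
        raise DataError(f"incomplete bundle; missing: {missing}")
    stats = bundle["stats"]
    lines = ["# Study summary", ""]
    lines.append("## Habitat spectral slopes by class")
    lines.append(_fmt_anova("one-way ANOVA (habitat class)", stats["anova_habitat"]))
    n_hab = len(bundle["habitat_patches"]) if "habitat_patches" in bundle else 0
    lines.append(f"- habitat patches analyzed: {n_hab}")
    lines.append("")
    lines.append("## Fish spectral slopes by species")
    lines.append(_fmt_anova("males", stats["anova_males"]))
    lines.append(_fmt_anova("females", stats["anova_females"]))
    lines.append("")
    lines.append("## Male vs female slopes")
    t = stats["ttest_sex"]
    table = bundle["study_table"]
    m = table[table["sex"] == "male"]["slope"]
    f = table[table["sex"] == "female"]["slope"]
    lines.append(
        f"- two-tailed t test: t = {t.t_stat:.4g}, df = {t.df}, p = {t.p_value:.4g}"
    )
    lines.append(
        f"- male mean = {m.mean():.4g} (sd {m.std():.3g}), "
        f"female mean = {f.mean():.4g} (sd {f.std():.3g})"
    )
    lines.append("")
    lines.append("## Mixed models")
    lines.extend(_fmt_posterior("Habitat-slope effect, males", bundle["post_male"]))
    lines.extend(_fmt_posterior("Habitat-slope effect, females", bundle["post_female"]))
    if "post_dev" in bundle and bundle["post_dev"] is not None:
        lines.extend(_fmt_posterior("Sex effect on habitat deviation", bundle["post_dev"]))
    else:
        lines.append("### Sex effect on habitat deviation")
        lines.append("- omitted: no deviation values in this bundle")
    lines.append("")
    return "\n".join(lines)
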