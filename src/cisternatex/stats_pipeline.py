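"""Group statistics and end-to-end pipeline orchestration.

The texture comparison follows the chain: omnibus MANOVA over the four
GLCM properties (Pillai's trace and Roy's largest root reported), then a
one-way ANOVA per property with a Bonferroni correction across the four
properties, then Tukey HSD pairwise comparisons.  Width/curvature/transport
metrics use Kruskal-Wallis with a Dunn post-hoc test.  Significance stars
follow the convention *: 0.05-0.01, **: 0.01-0.001, ***: <= 0.001.

``run_pipeline`` drives phantoms -> segmentation -> texture metrics ->
statistics from a single config and writes tidy CSVs plus a provenance
manifest; it is deterministic under a fixed seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.multivariate.manova import MANOVA

from . import __version__ as _pkg_version
from . import cisterna_metrics as cm
from . import er_segment as seg
from . import phantoms as ph

TEXTURE_METRICS = ("contrast", "correlation", "energy", "homogeneity")


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


def significance_stars(p: float) -> str:
    """Map an adjusted p-value to the figure-legend star convention."""
    if not (0 <= p <= 1):
        raise ValueError("p-value outside [0, 1]")
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class StatsReport:
    omnibus: list                 # dicts: test, statistic_name, statistic, p
    posthoc: pd.DataFrame         # pairwise table with stars
    adjustment: str
    anova: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Group table
# ---------------------------------------------------------------------------

KEY_COLUMNS = ["condition", "biological_replicate", "technical_replicate",
               "metric_name"]


def make_group_table(rows) -> pd.DataFrame:
    """Validate a tidy per-replicate metric table.

    Columns: condition, biological_replicate, technical_replicate,
    metric_name, value.  Duplicate keys or non-finite values are errors.
    """
    df = pd.DataFrame(rows)
    missing = set(KEY_COLUMNS + ["value"]) - set(df.columns)
    if missing:
        raise ConfigError(f"group table missing columns {sorted(missing)}")
    if df.duplicated(KEY_COLUMNS).any():
        raise ValueError("duplicated (condition, replicate, metric) keys")
    if not np.all(np.isfinite(df["value"].to_numpy(dtype=float))):
        raise ValueError("non-finite metric values")
    return df


def _wide_metrics(table: pd.DataFrame, metrics) -> pd.DataFrame:
    wide = (table[table["metric_name"].isin(metrics)]
            .pivot_table(index=["condition", "biological_replicate",
                                "technical_replicate"],
                         columns="metric_name", values="value")
            .reset_index())
    absent = set(metrics) - set(wide.columns)
    if absent:
        raise ConfigError(f"metrics missing from table: {sorted(absent)}")
    if wide[list(metrics)].isna().any().any():
        raise ValueError("incomplete metric rows (NaN after pivot)")
    return wide


# ---------------------------------------------------------------------------
# Parametric chain: MANOVA -> ANOVA (Bonferroni) -> Tukey HSD
# ---------------------------------------------------------------------------

def _check_within_covariance(wide: pd.DataFrame, metrics) -> None:
    resid = wide[list(metrics)] - wide.groupby("condition")[list(metrics)] \
        .transform("mean")
    corr = resid.corr()
    for a, b in itertools.combinations(metrics, 2):
        if abs(corr.loc[a, b]) > 1 - 1e-10:
            raise ValueError(
                f"singular within-group covariance: metrics {a!r} and "
                f"{b!r} are collinear")


def compare_texture(table: pd.DataFrame,
                    metrics=TEXTURE_METRICS) -> StatsReport:
    """MANOVA omnibus, per-metric ANOVA with Bonferroni across metrics,
    and Tukey HSD pairwise tables with significance stars."""
    wide = _wide_metrics(make_group_table(table), metrics)
    conditions = wide["condition"].unique()
    if len(conditions) < 2:
        raise ConfigError("need at least 2 conditions")
    sizes = wide.groupby("condition").size()
    if (sizes < 3).any():
        raise ConfigError("need >= 3 observations per condition")
    _check_within_covariance(wide, metrics)

    omnibus = []
    if len(metrics) == 1:
        # 1-D MANOVA degenerates to the one-way ANOVA: Pillai's trace is
        # SSB/SST, Roy's largest root SSB/SSW, and both share the ANOVA p
        m = metrics[0]
        v = wide[m].to_numpy(dtype=float)
        grand = v.mean()
        ssb = float(sum(len(g) * (g[m].mean() - grand) ** 2
                        for _, g in wide.groupby("condition")))
        ssw = float(sum(((g[m] - g[m].mean()) ** 2).sum()
                        for _, g in wide.groupby("condition")))
        groups = [g[m].to_numpy() for _, g in wide.groupby("condition")]
        if ssw == 0 and ssb == 0:
            p1 = 1.0
        else:
            _, p1 = sps.f_oneway(*groups)
            p1 = float(p1) if np.isfinite(p1) else 1.0
        sst = ssb + ssw
        omnibus.append({"test": "MANOVA", "statistic_name": "Pillai's trace",
                        "statistic": ssb / sst if sst else 0.0, "p": p1})
        omnibus.append({"test": "MANOVA",
                        "statistic_name": "Roy's greatest root",
                        "statistic": ssb / ssw if ssw else 0.0, "p": p1})
    else:
        grand = wide[list(metrics)].mean()
        ssb = sum(len(g) * ((g[list(metrics)].mean() - grand) ** 2).sum()
                  for _, g in wide.groupby("condition"))
        ssw = sum(((g[list(metrics)] - g[list(metrics)].mean()) ** 2)
                  .to_numpy().sum() for _, g in wide.groupby("condition"))
        if ssb <= 1e-12 * (ssb + ssw):
            # between-group scatter is exactly zero: degenerate omnibus
            for name in ("Pillai's trace", "Roy's greatest root"):
                omnibus.append({"test": "MANOVA", "statistic_name": name,
                                "statistic": 0.0, "p": 1.0})
        else:
            formula = " + ".join(metrics) + " ~ C(condition)"
            mv = MANOVA.from_formula(formula, data=wide).mv_test()
            stat = mv.results["C(condition)"]["stat"]
            for name in ("Pillai's trace", "Roy's greatest root"):
                omnibus.append({"test": "MANOVA", "statistic_name": name,
                                "statistic": float(stat.loc[name, "Value"]),
                                "p": float(stat.loc[name, "Pr > F"])})

    anova_rows, posthoc_rows = [], []
    for m in metrics:
        groups = [g[m].to_numpy() for _, g in wide.groupby("condition")]
        if np.ptp(np.concatenate(groups)) == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = sps.f_oneway(*groups)
            if not np.isfinite(p):
                f_stat, p = 0.0, 1.0
        p_adj = min(1.0, float(p) * len(metrics))
        anova_rows.append({"metric": m, "F": float(f_stat), "p": float(p),
                           "p_bonferroni": p_adj,
                           "stars": significance_stars(p_adj)})
        cond_names = sorted(wide["condition"].unique())
        by_cond = {c: wide.loc[wide["condition"] == c, m].to_numpy()
                   for c in cond_names}
        tk = sps.tukey_hsd(*(by_cond[c] for c in cond_names))
        for a, b in itertools.combinations(range(len(cond_names)), 2):
            padj = float(tk.pvalue[a, b])
            if not np.isfinite(padj):
                padj = 1.0
            posthoc_rows.append({
                "metric": m,
                "group1": cond_names[a], "group2": cond_names[b],
                "meandiff": float(by_cond[cond_names[b]].mean()
                                  - by_cond[cond_names[a]].mean()),
                "p_adj": padj, "stars": significance_stars(padj)})
    return StatsReport(omnibus=omnibus,
                       posthoc=pd.DataFrame(posthoc_rows),
                       adjustment="bonferroni (across metrics) + tukey-hsd",
                       anova=pd.DataFrame(anova_rows))


# ---------------------------------------------------------------------------
# Nonparametric chain: Kruskal-Wallis -> Dunn
# ---------------------------------------------------------------------------

def dunn_test(groups: dict, p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc test on rank sums with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal
    p-values, Bonferroni-adjusted over all pairs by default.
    """
    names = list(groups)
    values = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(values)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, i0 = {}, {}, 0
    for k, v in zip(names, values):
        mean_ranks[k] = ranks[i0:i0 + len(v)].mean()
        sizes[k] = len(v)
        i0 += len(v)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts ** 3 - tie_counts).sum()) / (12.0 * (N - 1)) \
        if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    pairs = list(itertools.combinations(names, 2))
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": float(z),
                     "p": float(p)})
    df = pd.DataFrame(rows)
    if p_adjust == "bonferroni":
        df["p_adj"] = np.minimum(1.0, df["p"] * len(pairs))
    elif p_adjust is None or p_adjust == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    df["stars"] = df["p_adj"].map(significance_stars)
    return df


def compare_nonparam(table: pd.DataFrame, metric: str) -> StatsReport:
    """Kruskal-Wallis omnibus plus Dunn pairwise comparisons for one
    metric; fully tied data yield H = 0, p = 1 rather than an error."""
    df = make_group_table(table)
    df = df[df["metric_name"] == metric]
    if df.empty:
        raise ConfigError(f"metric {metric!r} not in table")
    groups = {c: g["value"].to_numpy(dtype=float)
              for c, g in df.groupby("condition")}
    if len(groups) < 2:
        raise ConfigError("need at least 2 conditions")
    if any(len(v) < 2 for v in groups.values()):
        raise ConfigError("need >= 2 observations per condition")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        omnibus = [{"test": "kruskal-wallis", "statistic_name": "H",
                    "statistic": 0.0, "p": 1.0}]
    else:
        H, p = sps.kruskal(*groups.values())
        omnibus = [{"test": "kruskal-wallis", "statistic_name": "H",
                    "statistic": float(H), "p": float(p)}]
    return StatsReport(omnibus=omnibus, posthoc=dunn_test(groups),
                       adjustment="bonferroni")


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": None,
    "image_shape": [192, 192],
    "pixel_size_nm": ph.DEFAULT_PIXEL_SIZE_NM,
    "psf_fwhm_nm": ph.DEFAULT_PSF_FWHM_NM,
    "photon_scale": 200.0,
    "read_noise_sd": 2.0,
    "background_level": 10.0,
    "channels": ["lumen"],
    "n_junctions": 4,
    "n_cisternae": 6,
    "cisterna_radius_nm": 650.0,
    "profile_bins": 10,
    "segmentation": {},
    "glcm": {"radius": "auto", "n_levels": 8, "symmetric": True},
    "conditions": [
        {"name": "sac_like", "substructure": "sac", "n_images": 6},
        {"name": "nanohole_like", "substructure": "sac_nanoholes",
         "n_images": 6},
    ],
}

_VALID_CHANNELS = {"lumen", "membrane", "morphogen"}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        if str(config).endswith((".yml", ".yaml")):
            import yaml
            config = yaml.safe_load(text)
        else:
            config = json.loads(text)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping or a path to one")
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["glcm"] = {**DEFAULT_CONFIG["glcm"], **cfg.get("glcm", {})}
    if not cfg.get("channels"):
        raise ConfigError("config must name at least one channel")
    bad = set(cfg["channels"]) - _VALID_CHANNELS
    if bad:
        raise ConfigError(f"unknown channels {sorted(bad)}")
    if not cfg.get("conditions"):
        raise ConfigError("config must define conditions")
    for cond in cfg["conditions"]:
        for key in ("name", "substructure", "n_images"):
            if key not in cond:
                raise ConfigError(f"condition missing key {key!r}")
    return cfg


@dataclass
class PipelineResult:
    per_image: pd.DataFrame
    per_cisterna: pd.DataFrame
    texture_report: StatsReport
    manifest: dict
    skipped: list = field(default_factory=list)


def analyze_er_image(image: np.ndarray, pixel_size_nm: float,
                     psf_fwhm_nm: float,
                     seg_params: seg.SegmentationParams,
                     glcm_cfg: dict):
    """Segment one lumenal-channel image and compute its texture summary.

    Returns (segmentation, tubule-width estimate, GLCMSummary); raises
    InsufficientCisternaeError when the >= 5-cisternae rule fails.
    """
    pre = seg.preprocess(image, seg_params)
    eff_px = pixel_size_nm / seg_params.upsample_factor
    mask = seg.segment_er(pre, seg_params)
    segmentation = seg.identify_cisternae(mask, pre, seg_params)
    if glcm_cfg.get("radius", "auto") == "auto":
        est = seg.estimate_tubule_radius(pre, segmentation,
                                         psf_fwhm_nm=psf_fwhm_nm,
                                         pixel_size_nm=eff_px)
        radius = max(1.0, est.radius_px)
    else:
        est = None
        radius = float(glcm_cfg["radius"])
    gspec = cm.GLCMSpec(neighbourhood_radius_px=radius,
                        n_levels=int(glcm_cfg.get("n_levels", 8)),
                        symmetric=bool(glcm_cfg.get("symmetric", True)))
    summary = cm.summarize_image(pre, segmentation, gspec)
    return segmentation, est, summary


def run_pipeline(config) -> PipelineResult:
    """Phantoms -> segmentation -> texture metrics -> statistics.

    Writes per-image/per-cisterna CSVs, the post-hoc tables, a provenance
    manifest and a short human-readable summary to ``out_dir`` (if set).
    Deterministic under a fixed seed.
    """
    cfg = _load_config(config)
    seg_params = seg.SegmentationParams(**cfg["segmentation"])
    base_seed = int(cfg["seed"])

    per_image_rows, per_cist_rows, skipped = [], [], []
    try:
        for ci, cond in enumerate(cfg["conditions"]):
            sub_params = dict(cond.get("substructure_params", {}))
            for i in range(int(cond["n_images"])):
                spec = ph.PhantomSpec(
                    image_shape=tuple(cfg["image_shape"]),
                    pixel_size_nm=cfg["pixel_size_nm"],
                    psf_fwhm_nm=cfg["psf_fwhm_nm"],
                    photon_scale=cfg["photon_scale"],
                    read_noise_sd=cfg["read_noise_sd"],
                    background_level=cfg["background_level"],
                    seed=(base_seed * 10007 + ci * 1009 + i) % (2**31 - 1))
                layout = ph.make_er_scene(
                    spec, n_junctions=cfg["n_junctions"],
                    n_cisternae=cfg["n_cisternae"],
                    substructure=cond["substructure"],
                    cisterna_radius_nm=cfg["cisterna_radius_nm"],
                    substructure_params=sub_params)
                img, _gt = ph.render_er_image(layout, spec,
                                              channels=cfg["channels"])
                image_id = f"{cond['name']}_{i:03d}"
                try:
                    _s, est, summary = analyze_er_image(
                        img.channel("lumen"), spec.pixel_size_nm,
                        spec.psf_fwhm_nm, seg_params, cfg["glcm"])
                except cm.InsufficientCisternaeError as err:
                    skipped.append({"image": image_id, "reason": str(err)})
                    continue
                row = {"condition": cond["name"],
                       "biological_replicate": 1,
                       "technical_replicate": image_id,
                       **summary.pooled}
                if est is not None:
                    row["tubule_radius_nm"] = est.radius_nm
                per_image_rows.append(row)
                per = summary.per_cisterna.copy()
                per.insert(0, "image", image_id)
                per.insert(0, "condition", cond["name"])
                per_cist_rows.append(per)

        per_image = pd.DataFrame(per_image_rows)
        per_cisterna = (pd.concat(per_cist_rows, ignore_index=True)
                        if per_cist_rows else pd.DataFrame())
        tidy = per_image.melt(
            id_vars=["condition", "biological_replicate",
                     "technical_replicate"],
            value_vars=list(TEXTURE_METRICS),
            var_name="metric_name", value_name="value")
        report = compare_texture(tidy)
    except Exception as err:
        _write_failure_manifest(cfg, err)
        raise

    manifest = {
        "package": "cisternatex", "version": _pkg_version,
        "seed": base_seed, "config": _jsonable_cfg(cfg),
        "n_images_analysed": len(per_image_rows),
        "skipped": skipped,
        "glcm_provenance": {
            "quantisation": "per-cisterna min-max",
            "neighbourhood": "pooled disc offsets, symmetric counting",
        },
    }
    _write_outputs(cfg, per_image, per_cisterna, report, manifest)
    return PipelineResult(per_image=per_image, per_cisterna=per_cisterna,
                          texture_report=report, manifest=manifest,
                          skipped=skipped)


def _jsonable_cfg(cfg: dict) -> dict:
    return json.loads(json.dumps(cfg, default=str))


def _write_failure_manifest(cfg, err) -> None:
    out = cfg.get("out_dir")
    if out:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        (out / "failure_manifest.json").write_text(json.dumps(
            {"failed": True, "error": f"{type(err).__name__}: {err}",
             "config": _jsonable_cfg(cfg)}, indent=1))


def _write_outputs(cfg, per_image, per_cisterna, report, manifest) -> None:
    out = cfg.get("out_dir")
    if not out:
        return
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    per_image.to_csv(out / "per_image.csv", index=False)
    per_cisterna.to_csv(out / "per_cisterna.csv", index=False)
    report.posthoc.to_csv(out / "posthoc_tukey.csv", index=False)
    report.anova.to_csv(out / "anova.csv", index=False)
    pd.DataFrame(report.omnibus).to_csv(out / "omnibus_manova.csv",
                                        index=False)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    lines = ["# Texture comparison summary", ""]
    for o in report.omnibus:
        lines.append(f"- {o['test']} {o['statistic_name']}: "
                     f"stat={o['statistic']:.4g}, p={o['p']:.3g}")
    lines.append("")
    for _, r in report.posthoc.iterrows():
        lines.append(f"- {r['metric']}: {r['group1']} vs {r['group2']}: "
                     f"diff={r['meandiff']:+.4g}, p_adj={r['p_adj']:.3g} "
                     f"{r['stars']}")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
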