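"""End-to-end orchestration: simulate -> screen -> select -> search -> score
-> evaluate, with deterministic CSV artifacts and a checksummed manifest.

Each stage is a plain function over in-memory objects plus persisted CSV/TSV
artifacts, so any stage can be re-run in isolation from its inputs on disk.
Re-running the whole pipeline with an identical config and seed reproduces
bit-identical artifacts (wall-clock timings live only in the manifest, which
is not part of the checksummed surface).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gim import GimConfig, GIMSearch, PolynomialScore, published_risk_score, score_hazard_ratio
from .horizon import (
    boxplot_summary,
    label_at_horizon,
    mannwhitney_u,
    roc_curve,
    youden_optimal,
)
from .io import (
    float_repr,
    load_yaml_config,
    read_cohort_csv,
    read_spectra_tsv,
    write_cohort_csv,
    write_spectra_tsv,
)
from .nmr import (
    AnnotationLibrary,
    SpectralMatrix,
    annotate_bins,
    default_annotation_library,
    normalize_to_reference,
    normalize_total_area,
    pareto_scale,
    screen_bins,
)
from .survival import km_estimate, logrank_test, multivariate_fit, tertile_stratify, univariate_screen
from .synth import DEFAULT_UPLC_REL_NOISE, GeneratorConfig, emulate_uplc, generate_cohort, generate_spectra

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

logger = logging.getLogger(__name__)

CLINICAL_VARIABLES = [
    "age_years",
    "male",
    "hbv",
    "hcv",
    "ast",
    "alt",
    "ast_alt_ratio",
    "platelet",
    "fib4",
]
BINARY_VARIABLES = {"male", "hbv", "hcv"}


@dataclass
class PipelineConfig:
    """Full pipeline configuration; every default overridable from YAML."""

    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    screen_alpha: float = 0.01
    univariate_alpha: float = 0.05
    gim_candidates: tuple[str, ...] | None = None  # None -> carried-forward continuous
    gim_max_degree: int = 2
    gim_max_terms: int = 8
    gim_penalty: str = "BIC"
    horizons: tuple[float, ...] = (1.0, 2.0, 3.0)
    output_dir: str = "metabosurv_run"
    fixture_score: bool = False  # evaluate the packaged published score instead of searching
    normalization: str = "total_area"  # none | total_area | reference
    reference_bin: float = 5.235
    proxy_stat: str = "mean"  # mean | max over a metabolite's annotated bins
    uplc_rel_noise: float = DEFAULT_UPLC_REL_NOISE

    def __post_init__(self):
        if not 0 < self.screen_alpha < 1 or not 0 < self.univariate_alpha < 1:
            raise ValueError("alphas must lie in (0, 1)")
        horizons = tuple(float(h) for h in self.horizons)
        if any(h <= 0 for h in horizons) or any(np.diff(horizons) <= 0):
            raise ValueError("horizons must be positive and strictly increasing")
        self.horizons = horizons
        if self.normalization not in ("none", "total_area", "reference"):
            raise ValueError("normalization must be none|total_area|reference")
        if self.proxy_stat not in ("mean", "max"):
            raise ValueError("proxy_stat must be mean|max")
        if self.gim_candidates is not None:
            self.gim_candidates = tuple(self.gim_candidates)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = load_yaml_config(path)
        gen = GeneratorConfig(**raw.pop("generator", {}))
        cfg = cls(generator=gen, **raw)
        return cfg

    def snapshot(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = dataclasses.asdict(self)
        d["generator"]["true_score"] = {
            "terms": [list(t) for t in self.generator.true_score.terms],
            "intercept": self.generator.true_score.intercept,
        }
        return plain(d)


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, software version,
    per-artifact checksums and wall-clock per stage."""

    config: dict
    version: str
    checksums: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "checksums": self.checksums,
                    "stage_seconds": self.stage_seconds,
                },
                sort_keys=True,
            ),
            encoding="utf-8",
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _proxy_columns(
    matrix: SpectralMatrix, screen: pd.DataFrame, library: AnnotationLibrary, stat: str
) -> pd.DataFrame:
    """Per-patient metabolite proxies: mean (or max) normalized intensity
    over the annotated significant bins of each metabolite, standardized to
    z-scores so downstream hazard ratios are per sd of normalized intensity
    rather than per (tiny) absolute intensity unit."""
    reducer = np.mean if stat == "mean" else np.max
    cols: dict[str, np.ndarray] = {}
    annotated = screen[screen["significant"] & (screen["annotation"] != "")]
    names = sorted({n for a in annotated["annotation"] for n in a.split(";")})
    for name in names:
        centers = annotated.loc[
            annotated["annotation"].str.split(";").apply(lambda xs: name in xs), "bin_center"
        ].to_numpy()
        idx = np.isin(np.round(matrix.bin_centers, 3), np.round(centers, 3))
        key = "nmr_" + name.lower().replace("-", "_")
        raw = reducer(matrix.intensities[:, idx], axis=1)
        sd = raw.std(ddof=1)
        cols[key] = (raw - raw.mean()) / sd if sd > 0 else raw - raw.mean()
    return pd.DataFrame(cols, index=range(matrix.n_patients))


def stage_simulate(config: PipelineConfig, outdir: Path):
    cohort, record = generate_cohort(config.generator.replace(seed=config.seed))
    spectra = generate_spectra(cohort, seed=config.seed + 1)
    uplc = pd.DataFrame(
        {
            "id": cohort["id"],
            "phe_uplc_um": emulate_uplc(
                cohort["phe_um"].to_numpy(), config.uplc_rel_noise, seed=config.seed + 2
            ),
            "gln_uplc_um": emulate_uplc(
                cohort["gln_um"].to_numpy(), config.uplc_rel_noise, seed=config.seed + 3
            ),
        }
    )
    write_cohort_csv(cohort, outdir / "cohort.csv")
    write_spectra_tsv(spectra, outdir / "spectra.tsv")
    uplc.to_csv(outdir / "uplc.csv", index=False, float_format=float_repr)
    return cohort, spectra, record


def stage_screen(config: PipelineConfig, cohort: pd.DataFrame, spectra: SpectralMatrix, outdir: Path):
    if config.normalization == "reference":
        norm = normalize_to_reference(spectra, config.reference_bin)
    elif config.normalization == "total_area":
        norm = normalize_total_area(spectra)
    else:
        norm = spectra
    scaled = pareto_scale(norm)
    library = default_annotation_library()
    screen = screen_bins(scaled, cohort["event"].to_numpy(), alpha=config.screen_alpha)
    screen = annotate_bins(screen, library)
    screen.to_csv(outdir / "screen.csv", index=False, float_format=float_repr)
    proxies = _proxy_columns(norm, screen, library, config.proxy_stat)
    return screen, proxies


def stage_cox(config: PipelineConfig, cohort: pd.DataFrame, proxies: pd.DataFrame, outdir: Path):
    frame = pd.concat([cohort.reset_index(drop=True), proxies.reset_index(drop=True)], axis=1)
    variables = CLINICAL_VARIABLES + list(proxies.columns)
    uni = univariate_screen(frame, variables, alpha=config.univariate_alpha)
    uni.to_csv(outdir / "univariate.csv", index=False, float_format=float_repr)
    carried = uni.loc[uni["flagged"], "variable"].tolist()
    multi = None
    if len(carried) >= 1:
        try:
            multi = multivariate_fit(frame, carried)
            multi.to_frame().assign(variable=multi.params.index).to_csv(
                outdir / "multivariate.csv", index=False, float_format=float_repr
            )
        except ValueError as exc:
            logger.warning("multivariate fit skipped: %s", exc)
    return frame, uni, carried, multi


def stage_gim(config: PipelineConfig, frame: pd.DataFrame, carried: list[str], outdir: Path):
    if config.fixture_score:
        score = published_risk_score()
        trace = pd.DataFrame(
            columns=["step", "action", "term", "log_partial_likelihood", "penalized_criterion"]
        )
    else:
        if config.gim_candidates is not None:
            candidates = list(config.gim_candidates)
        else:
            candidates = [v for v in carried if v not in BINARY_VARIABLES]
        candidates = [c for c in candidates if c in frame.columns]
        if not candidates:
            logger.warning("no continuous candidates carried forward; GIM returns empty model")
            score, trace = PolynomialScore(()), pd.DataFrame(
                columns=["step", "action", "term", "log_partial_likelihood", "penalized_criterion"]
            )
        else:
            gim_cfg = GimConfig(
                candidate_variables=tuple(candidates),
                max_degree=config.gim_max_degree,
                max_terms=config.gim_max_terms,
                selection_penalty=config.gim_penalty,
            )
            try:
                res = GIMSearch.from_dataframe(frame, "time_years", "event", gim_cfg).fit()
                score, trace = res.score, res.trace
            except ValueError as exc:
                logger.warning("GIM found no improving model (%s); empty score", exc)
                score, trace = PolynomialScore(()), pd.DataFrame(
                    columns=["step", "action", "term", "log_partial_likelihood", "penalized_criterion"]
                )
    score.to_csv(outdir / "score.csv")
    trace.to_csv(outdir / "gim_trace.csv", index=False, float_format=float_repr)
    return score, trace


def stage_score_eval(config: PipelineConfig, frame: pd.DataFrame, score: PolynomialScore, outdir: Path):
    if not score.terms:
        logger.warning("empty score: hazard-ratio and tertile stages skipped")
        return None
    fit = score_hazard_ratio(frame, score)
    fit.to_frame().to_csv(outdir / "score_hr.csv", float_format=float_repr)
    values = np.asarray(score(frame), dtype=float)
    tert = tertile_stratify(values)
    km_rows = []
    for label in ("T1", "T2", "T3"):
        mask = tert == label
        curve = km_estimate(frame.loc[mask, "time_years"], frame.loc[mask, "event"])
        for t, s, r, d in zip(curve.event_times, curve.survival, curve.at_risk, curve.n_events):
            km_rows.append({"tertile": label, "time_years": t, "survival": s, "at_risk": r, "events": d})
    pd.DataFrame(km_rows).to_csv(outdir / "km_tertiles.csv", index=False, float_format=float_repr)
    lr_rows = []
    for a, b in (("T1", "T2"), ("T1", "T3"), ("T2", "T3")):
        ga = (frame.loc[tert == a, "time_years"], frame.loc[tert == a, "event"])
        gb = (frame.loc[tert == b, "time_years"], frame.loc[tert == b, "event"])
        try:
            lr = logrank_test([ga, gb])
            lr_rows.append({"groups": f"{a} vs {b}", "chi2": lr.chi2, "df": lr.df, "p": lr.p_value})
        except ValueError as exc:
            lr_rows.append({"groups": f"{a} vs {b}", "chi2": np.nan, "df": 1, "p": np.nan})
            logger.warning("log-rank %s vs %s failed: %s", a, b, exc)
    pd.DataFrame(lr_rows).to_csv(outdir / "logrank_pairwise.csv", index=False, float_format=float_repr)
    return fit


def stage_horizon(config: PipelineConfig, frame: pd.DataFrame, score: PolynomialScore, outdir: Path):
    markers: dict[str, np.ndarray] = {}
    if score.terms:
        markers["risk_score"] = np.asarray(score(frame), dtype=float)
    for col in ("phe_um", "gln_um"):
        if col in frame.columns:
            markers[col] = frame[col].to_numpy(dtype=float)
    rows = []
    for h in config.horizons:
        labels = label_at_horizon(frame["time_years"], frame["event"], h)
        for name, values in markers.items():
            row = {
                "horizon": h,
                "marker": name,
                "n_case": labels.n_case,
                "n_control": labels.n_control,
                "n_excluded": labels.n_excluded,
            }
            try:
                # convention: higher marker value predicts case; a marker
                # that runs the other way simply shows AUC < 0.5
                roc = roc_curve(values, labels)
                best = youden_optimal(roc)
                row.update(
                    auc=roc.auc,
                    auc_p=roc.auc_p,
                    cutoff=best.cutoff,
                    youden=best.youden_j,
                    sensitivity=best.sensitivity,
                    specificity=best.specificity,
                    ppv=best.ppv,
                    npv=best.npv,
                )
            except ValueError as exc:
                logger.warning("horizon %s marker %s skipped: %s", h, name, exc)
                row.update(auc=np.nan, auc_p=np.nan, cutoff=np.nan, youden=np.nan,
                           sensitivity=np.nan, specificity=np.nan, ppv=np.nan, npv=np.nan)
            rows.append(row)
    report = pd.DataFrame(
        rows,
        columns=["horizon", "marker", "auc", "auc_p", "cutoff", "youden", "sensitivity",
                 "specificity", "ppv", "npv", "n_case", "n_control", "n_excluded"],
    )
    report.to_csv(outdir / "horizon_report.csv", index=False, float_format=float_repr)

    # biomarker distributions at the last horizon: rank test between the
    # case/control groups plus box-plot numbers per group
    last = config.horizons[-1]
    labels = label_at_horizon(frame["time_years"], frame["event"], last)
    dist_rows = []
    for col in ("phe_um", "gln_um"):
        if col not in frame.columns:
            continue
        v = frame[col].to_numpy(dtype=float)
        cases = v[labels.labels == "case"]
        controls = v[labels.labels == "control"]
        if len(cases) == 0 or len(controls) == 0 or min(len(cases), len(controls)) < 5:
            continue
        _, p = mannwhitney_u(cases, controls)
        for group, values in (("case", cases), ("control", controls)):
            box = boxplot_summary(values)
            dist_rows.append(
                {
                    "horizon": last, "marker": col, "group": group, "n": len(values),
                    "mannwhitney_p": p, "median": box.median, "q1": box.q1, "q3": box.q3,
                    "whisker_low": box.whisker_low, "whisker_high": box.whisker_high,
                    "n_outliers": len(box.outliers),
                }
            )
    pd.DataFrame(dist_rows).to_csv(
        outdir / "biomarker_distributions.csv", index=False, float_format=float_repr
    )
    return report


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage, write artifacts under ``config.output_dir`` and
    return the checksummed manifest.  A stage failure writes a FAILED marker
    naming the stage and re-raises; earlier artifacts are retained."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.snapshot(), version=__version__)
    state: dict = {}

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(config, *args)
        except Exception as exc:
            (outdir / "FAILED").write_text(f"stage {name}: {exc}\n", encoding="utf-8")
            logger.error("stage %s failed: %s", name, exc)
            raise
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 4)
        logger.info("stage %s done in %.2fs", name, manifest.stage_seconds[name])
        return result

    def simulate(cfg):
        return stage_simulate(cfg, outdir)

    cohort, spectra, record = run_stage("simulate", simulate)
    state["cohort"] = cohort
    screen, proxies = run_stage("screen", lambda cfg: stage_screen(cfg, cohort, spectra, outdir))
    frame, uni, carried, multi = run_stage("cox", lambda cfg: stage_cox(cfg, cohort, proxies, outdir))
    score, trace = run_stage("gim", lambda cfg: stage_gim(cfg, frame, carried, outdir))
    run_stage("score_eval", lambda cfg: stage_score_eval(cfg, frame, score, outdir))
    run_stage("horizon", lambda cfg: stage_horizon(cfg, frame, score, outdir))

    summary = _human_summary(config, cohort, screen, carried, score)
    (outdir / "summary.txt").write_text(summary, encoding="utf-8")
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    for artifact in sorted(outdir.iterdir()):
        if artifact.name not in ("manifest.yaml", "run.log") and artifact.is_file():
            manifest.checksums[artifact.name] = _sha256(artifact)
    manifest.write(outdir / "manifest.yaml")
    return manifest


def _human_summary(config, cohort, screen, carried, score) -> str:
    lines = [
        f"metabosurv pipeline v{__version__}",
        f"seed {config.seed}; n = {len(cohort)} patients, {int(cohort['event'].sum())} events",
        f"screen: {int(screen['significant'].sum())} / {len(screen)} bins flagged at alpha {config.screen_alpha}",
        f"carried forward (p < {config.univariate_alpha}): {', '.join(carried) if carried else 'none'}",
    ]
    if score.terms:
        lines.append("risk score terms:")
        for var, power, coef in score.terms:
            lines.append(f"  {var}^{power}: {coef:.8g}")
    else:
        lines.append("risk score: empty (no term improved the criterion)")
    return "\n".join(lines) + "\n"
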