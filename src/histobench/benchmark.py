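"""End-to-end benchmark runs: register, re-apply, measure, tabulate.

One run evaluates a list of aligners at one or more resolutions against a
dataset (a synthetic phantom or stacks on disk), always including the
unregistered stack as a baseline row. For every aligner x resolution the
estimated (or imported) per-section transforms are re-applied to the
tissue, mask and landmark stacks; the full metric panel is computed; and
three artifacts are written: ``summary.csv`` (one row per method x
resolution with µ/max/σ TRE and ATRE, mean Jaccard, RMSE, f2 and ΔA-%),
``metrics_long.csv`` (every per-pair/per-section value) and
``trajectories.csv`` (per-section landmark positions and cumulative mean
displacement, for drift plotting).
"""

from __future__ import annotations

import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import HistobenchError
from .metrics import (
    GlcmAccumulator,
    MetricSeries,
    atre_cumulative,
    atre_linefit,
    delta_area,
    glcm_accumulate,
    glcm_features,
    jaccard,
    pairwise_tre,
    pixel_similarity,
    summarize,
)
from .registration import (
    alignment_from_csv,
    apply_alignment,
    feature_aligner,
    ls_aligner,
    opt_aligner,
    register_stack,
)
from .stack_io import (
    LandmarkSet,
    SectionStack,
    decode_landmarks,
    decode_pairwise_landmarks,
    downsample_stack,
    read_stack,
    to_gray,
)
from .synthetic import PhantomDataset, PhantomSpec, generate_phantom
from .transform import PlanarTransform, StackAlignment

log = logging.getLogger("histobench")

__all__ = ["AlignerConfig", "BenchmarkConfig", "run_benchmark", "evaluate_alignment"]


@dataclass
class AlignerConfig:
    """One aligner to benchmark.

    ``method`` is one of ``none`` (unregistered baseline), ``ls``, ``opt``,
    ``feat`` or ``import`` (read transforms serialized by an external tool).
    """

    name: str
    method: str
    params: dict = field(default_factory=dict)
    observer: int = 1            # landmark observer used by the LS fit
    transforms_file: str | None = None

    def __post_init__(self) -> None:
        if self.method not in ("none", "ls", "opt", "feat", "import"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "import" and not self.transforms_file:
            raise ValueError("import aligner needs transforms_file")


@dataclass
class BenchmarkConfig:
    aligners: list[AlignerConfig]
    resolutions: list[int] = field(default_factory=lambda: [1])
    reference_index: int = 0
    output_dir: str = "benchmark_out"
    seed: int = 0
    eval_observer: int = 1
    # either a synthetic spec ...
    synthetic: PhantomSpec | None = None
    # ... or paths to stacks on disk
    tissue_dir: str | None = None
    mask_dir: str | None = None
    landmark_csv: str | None = None
    pixel_size: float = 1.0
    section_spacing: float = 5.0

    def __post_init__(self) -> None:
        if not self.aligners or not self.resolutions:
            raise ValueError("need at least one aligner and one resolution")

    @classmethod
    def from_toml(cls, path) -> "BenchmarkConfig":
        raw = tomllib.loads(Path(path).read_text())
        aligners = [AlignerConfig(**a) for a in raw.pop("aligners")]
        synth = raw.pop("synthetic", None)
        if synth is not None:
            for key in ("image_size", "tissue_radii"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            synth = PhantomSpec(**synth)
        return cls(aligners=aligners, synthetic=synth, **raw)


def _identity_alignment(n: int, reference_index: int = 0) -> StackAlignment:
    return StackAlignment(
        [PlanarTransform.identity() for _ in range(n)], reference_index
    )


def evaluate_alignment(
    alignment: StackAlignment,
    tissue: SectionStack,
    masks: SectionStack,
    landmark_stacks: list[SectionStack],
    colormap,
    pairwise_design: bool,
    observer: int = 1,
) -> tuple[dict, pd.DataFrame, LandmarkSet]:
    """Re-apply an alignment to all stacks and compute the metric panel.

    Returns (report dict of MetricSeries/scalars, long-format table,
    decoded landmarks in the common frame).
    """
    px = tissue.pixel_size
    n = tissue.n_sections
    reg_tissue = apply_alignment(tissue, alignment, interpolation="linear")
    reg_masks = apply_alignment(masks, alignment, interpolation="linear",
                                is_mask=True)
    warped_lm = [
        apply_alignment(s, alignment, interpolation="linear")
        for s in landmark_stacks
    ]
    if pairwise_design:
        decoded = decode_pairwise_landmarks(
            warped_lm[0], warped_lm[1], colormap, observer=observer
        )
    else:
        decoded = decode_landmarks(warped_lm[0], colormap, observer=observer)

    tre_df, tre = pairwise_tre(decoded, pixel_size=px, n_sections=n)
    if pairwise_design:
        atre = atre_cumulative(decoded, pixel_size=px, n_sections=n)
        atre_long = pd.DataFrame(
            dict(index=np.arange(len(atre.values)), value=atre.values)
        ).assign(metric="ATRE")
    else:
        atre_df, atre = atre_linefit(decoded, pixel_size=px)
        atre_long = atre_df.rename(
            columns={"section": "index", "atre_um": "value"}
        )[["index", "value"]].assign(metric="ATRE")

    jac, da, rmse, ncc, mi, nmi = [], [], [], [], [], []
    glcm = GlcmAccumulator()
    grays = [to_gray(im) for im in reg_tissue.images]
    for i in range(n - 1):
        a, b = reg_masks[i], reg_masks[i + 1]
        jac.append(jaccard(a, b))
        overlap = a & b
        sim = pixel_similarity(grays[i], grays[i + 1], overlap)
        rmse.append(sim["RMSE"])
        ncc.append(sim["NCC"])
        mi.append(sim["MI"])
        nmi.append(sim["NMI"])
        glcm_accumulate(grays[i], grays[i + 1], overlap, glcm)
    for i in range(n):
        da.append(
            delta_area(masks[i], reg_masks[i], masks.pixel_size, reg_masks.pixel_size)
        )
    haralick = glcm_features(glcm)

    report = {
        "TRE": tre,
        "ATRE": atre,
        "Jaccard": MetricSeries("Jaccard", jac),
        "dA_percent": MetricSeries("dA_percent", da, "%"),
        "RMSE": MetricSeries("RMSE", rmse),
        "NCC": MetricSeries("NCC", ncc),
        "MI": MetricSeries("MI", mi, "bits"),
        "NMI": MetricSeries("NMI", nmi),
        "f2": haralick["f2"],
        "f3": haralick["f3"],
        "failure": alignment.failure_flag,
    }
    long_parts = [
        tre_df.rename(columns={"pair": "index", "tre_um": "value"})[
            ["index", "value"]
        ].assign(metric="TRE"),
        atre_long,
    ]
    for mname, vals in [("Jaccard", jac), ("dA_percent", da), ("RMSE", rmse),
                        ("NCC", ncc), ("MI", mi), ("NMI", nmi)]:
        long_parts.append(pd.DataFrame(
            dict(index=np.arange(len(vals)), value=vals)
        ).assign(metric=mname))
    long_df = pd.concat(long_parts, ignore_index=True)
    return report, long_df, decoded


def _trajectories(decoded: LandmarkSet) -> pd.DataFrame:
    """Per-section landmark positions plus cumulative mean displacement."""
    df = decoded.df.sort_values(["section", "point_id"]).copy()
    n = int(df["section"].max()) + 1 if len(df) else 0
    cum = np.zeros(2)
    drift_rows = [dict(section=0, drift_x=0.0, drift_y=0.0)]
    for i in range(n - 1):
        if decoded.is_pairwise:
            a = decoded.points(i, pair=i)
            b = decoded.points(i + 1, pair=i)
        else:
            a = decoded.points(i)
            b = decoded.points(i + 1)
        common = sorted(set(a) & set(b))
        if common:
            disp = np.mean([a[j] - b[j] for j in common], axis=0)
            cum = cum + disp
        drift_rows.append(dict(section=i + 1, drift_x=cum[0], drift_y=cum[1]))
    drift = pd.DataFrame(drift_rows)
    out = df[["section", "point_id", "x", "y"]].merge(drift, on="section", how="left")
    return out


def _make_pair_method(cfg: AlignerConfig, landmarks: LandmarkSet | None, seed: int):
    if cfg.method == "ls":
        if landmarks is None:
            raise HistobenchError("LS aligner needs landmarks")
        return ls_aligner(landmarks.for_observer(cfg.observer), **cfg.params)
    if cfg.method == "opt":
        return opt_aligner(**cfg.params)
    if cfg.method == "feat":
        return feature_aligner(seed=seed, **cfg.params)
    raise ValueError(cfg.method)


def _load_dataset(config: BenchmarkConfig) -> PhantomDataset | dict:
    if config.synthetic is not None:
        return generate_phantom(config.synthetic)
    if config.tissue_dir is None or config.mask_dir is None:
        raise HistobenchError("config needs either [synthetic] or stack paths")
    meta = dict(pixel_size=config.pixel_size,
                section_spacing=config.section_spacing)
    tissue = read_stack(config.tissue_dir, **meta)
    masks = read_stack(config.mask_dir, **meta)
    masks = SectionStack([m.astype(bool) if m.dtype != bool else m
                          for m in masks.images], **meta)
    landmarks = (LandmarkSet.read_csv(config.landmark_csv)
                 if config.landmark_csv else None)
    return dict(tissue=tissue, masks=masks, landmarks=landmarks)


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Run every aligner x resolution, write CSVs, return the summary table."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: BenchmarkConfig, out: Path) -> pd.DataFrame:
    data = _load_dataset(config)
    if isinstance(data, PhantomDataset):
        tissue, masks = data.tissue, data.masks
        landmarks = data.landmarks
        colormap = data.colormap
        pairwise_design = data.spec.landmark_design == "pairwise"
        lm_stacks_full = data.landmark_stacks(config.eval_observer)
    else:
        tissue, masks, landmarks = data["tissue"], data["masks"], data["landmarks"]
        if landmarks is None:
            raise HistobenchError("benchmarking requires landmarks")
        from .stack_io import LandmarkColorMap, encode_landmarks, encode_pairwise_landmarks

        colormap = LandmarkColorMap()
        lm_eval = landmarks.for_observer(config.eval_observer)
        pairwise_design = lm_eval.is_pairwise
        shape = tissue.shapes[0]
        if pairwise_design:
            lm_stacks_full = list(encode_pairwise_landmarks(
                lm_eval, shape, colormap, n_sections=tissue.n_sections))
        else:
            lm_stacks_full = [encode_landmarks(
                lm_eval, shape, colormap, n_sections=tissue.n_sections)]

    reports, longs, trajs = [], [], []
    for factor in config.resolutions:
        t_res = downsample_stack(tissue, factor)
        m_res = downsample_stack(masks, factor)
        # block averaging maps original pixel x to (x - (f-1)/2) / f
        off = -(factor - 1) / (2 * factor)
        scale = PlanarTransform(
            np.array([[1 / factor, 0, off], [0, 1 / factor, off]])
        )
        lm_scaled = (landmarks.transformed(
            [scale] * tissue.n_sections) if landmarks is not None else None)
        lm_stacks_res = [downsample_stack(s, factor) for s in lm_stacks_full]
        for cfg in config.aligners:
            t0 = time.perf_counter()
            label = f"{cfg.name}@x{factor}"
            try:
                if cfg.method == "none":
                    alignment = _identity_alignment(
                        t_res.n_sections, config.reference_index)
                elif cfg.method == "import":
                    alignment = alignment_from_csv(cfg.transforms_file)
                else:
                    method = _make_pair_method(cfg, lm_scaled, config.seed)
                    alignment = register_stack(
                        t_res, method, reference_index=config.reference_index)
                report, long_df, decoded = evaluate_alignment(
                    alignment, t_res, m_res, lm_stacks_res, colormap,
                    pairwise_design, observer=config.eval_observer,
                )
            except Exception as err:
                log.error("%s failed: %s", label, err)
                reports.append(dict(method=cfg.name, resolution=factor,
                                    failure=True))
                continue
            report = {"method": cfg.name, "resolution": factor, **report}
            reports.append(report)
            long_df["method"] = cfg.name
            long_df["resolution"] = factor
            longs.append(long_df)
            traj = _trajectories(decoded)
            traj["method"] = cfg.name
            traj["resolution"] = factor
            trajs.append(traj)
            log.info("%s done in %.1f s (mean TRE %.3g um)", label,
                     time.perf_counter() - t0, report["TRE"].mean)

    summary = summarize(reports)
    summary.to_csv(out / "summary.csv", index=False)
    if longs:
        pd.concat(longs, ignore_index=True).to_csv(
            out / "metrics_long.csv", index=False)
    if trajs:
        pd.concat(trajs, ignore_index=True).to_csv(
            out / "trajectories.csv", index=False)
    return summary
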