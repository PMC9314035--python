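"""Retrospective undersampling-parameter optimization.

Grid search over ``(R, pp, calib)``: for every setting and mask
replicate, generate a Poisson-disk mask, retrospectively undersample
the fully sampled k-space, estimate coil sensitivities from that mask's
calibration block, reconstruct with FISTA, and score the result against
the fully sampled reference with the vessel-masked SSIM and the
peak-count metric. The reference is the fully sampled data combined
through the sensitivity-weighted adjoint (the same coil-combination
path the reconstructions use), not the ground-truth phantom, so
coil-combination bias cancels out of the score.

Every cell's mask seed derives deterministically from the sweep
configuration via ``numpy.random.SeedSequence`` keyed on
``(seed_base, R, pp, calib, replicate, volume id)``, so any single cell
can be re-run in isolation bit-identically.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from csmra.metrics import (
    MIPImage,
    VesselMask2D,
    make_vessel_mask,
    masked_ssim,
    mip,
    normalize_p99,
    peak_count_metric,
    relative_peak_change,
)
from csmra.phantom import KSpaceData
from csmra.recon import (
    ReconConfig,
    SenseOperator,
    estimate_sensitivities,
    fista_recon,
    retrospective_undersample,
)
from csmra.sampling import InfeasibleMaskError, MaskParams, generate_mask

logger = logging.getLogger(__name__)

DEFAULT_R_LIST = (5.0, 7.0, 9.0, 11.0, 13.0, 15.0)
DEFAULT_PP_LIST = (0.0, 0.4, 0.8, 1.2, 1.6, 2.0, 2.4, 2.8)
DEFAULT_CALIB_LIST = (10, 12, 16, 20, 24, 28, 32)


@dataclass(frozen=True)
class SweepConfig:
    """Grid definition for the undersampling-parameter sweep.

    Defaults cover acceleration factors 5–15, polynomial orders 0–2.8
    in steps of 0.4, and calibration sizes from the smallest the
    sensitivity estimator accepts (10) up to 32 lines, with two mask
    replicates per setting.
    """

    R_list: tuple[float, ...] = DEFAULT_R_LIST
    pp_list: tuple[float, ...] = DEFAULT_PP_LIST
    calib_list: tuple[int, ...] = DEFAULT_CALIB_LIST
    masks_per_setting: int = 2
    seed_base: int = 0
    recon: ReconConfig = field(default_factory=ReconConfig)
    calib_ref: int = 32
    peak_coverage: float = 0.5
    peak_lines: int | None = None  # None: min(100, rows in coverage band)
    min_prominence: float = 0.15

    def __post_init__(self) -> None:
        if self.masks_per_setting < 1:
            raise ValueError("masks_per_setting must be >= 1")
        if not (self.R_list and self.pp_list and self.calib_list):
            raise ValueError("parameter lists must be nonempty")


def cell_seed(
    seed_base: int, R: float, pp: float, calib: int, replicate: int, volume_id: str
) -> int:
    """Deterministic per-cell mask seed (< 2**31), derivable from config alone."""
    key = [
        seed_base,
        int(round(R * 1000)),
        int(round(pp * 1000)),
        int(calib),
        int(replicate),
        zlib.crc32(volume_id.encode()),
    ]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % 2**31)


@dataclass
class ReferenceImages:
    """Fully sampled reference: adjoint-combined MIP plus vessel mask."""

    mip: MIPImage
    vessel_mask: VesselMask2D
    n_peaks: int


def _n_lines(cfg_lines: int | None, coverage: float, n_rows: int) -> int:
    span = int(round(coverage * n_rows))
    return min(100, span) if cfg_lines is None else cfg_lines


def make_reference(
    kspace: KSpaceData,
    calib_ref: int = 32,
    peak_coverage: float = 0.5,
    peak_lines: int | None = None,
    min_prominence: float = 0.15,
) -> ReferenceImages:
    """Reference MIP, vessel mask, and peak count from fully sampled data."""
    sens = estimate_sensitivities(kspace, calib_ref)
    ones = np.ones(kspace.data.shape[2:], dtype=bool)
    img = SenseOperator(ones, sens).adjoint(kspace.data)
    ref_mip = normalize_p99(mip(np.abs(img)))
    vmask = make_vessel_mask(ref_mip)
    n_lines = _n_lines(peak_lines, peak_coverage, ref_mip.image.shape[0])
    peaks = peak_count_metric(ref_mip, n_lines, peak_coverage, min_prominence)
    return ReferenceImages(mip=ref_mip, vessel_mask=vmask, n_peaks=peaks.n_peaks)


def evaluate_cell(
    kspace: KSpaceData,
    reference: ReferenceImages,
    params: MaskParams,
    recon_cfg: ReconConfig,
    peak_coverage: float = 0.5,
    peak_lines: int | None = None,
    min_prominence: float = 0.15,
) -> dict:
    """Mask → undersample → calibrate → reconstruct → score, for one cell."""
    t0 = time.perf_counter()
    shape_yz = kspace.data.shape[2:]
    mask = generate_mask(shape_yz, params)
    und = retrospective_undersample(kspace, mask)
    sens = estimate_sensitivities(und, max(params.calib, 4))
    rec = fista_recon(und, mask, sens, recon_cfg)
    rec_mip = normalize_p99(mip(rec.magnitude))
    ssim = masked_ssim(reference.mip, rec_mip, reference.vessel_mask)
    n_lines = _n_lines(peak_lines, peak_coverage, rec_mip.image.shape[0])
    peaks = peak_count_metric(rec_mip, n_lines, peak_coverage, min_prominence)
    ref_result = type(peaks)(n_peaks=reference.n_peaks)
    logger.debug(
        "cell R=%.3g pp=%.3g calib=%d seed=%d: ssim=%.4f peaks=%d (%.1fs)",
        params.R, params.pp, params.calib, params.seed,
        ssim, peaks.n_peaks, time.perf_counter() - t0,
    )
    return {
        "ssim": ssim,
        "n_peaks": peaks.n_peaks,
        "rel_peak_change": relative_peak_change(peaks, ref_result),
        "achieved_R": mask.achieved_R,
        "runtime_s": time.perf_counter() - t0,
        "error": None,
    }


def run_parameter_sweep(
    cfg: SweepConfig, datasets: dict[str, KSpaceData]
) -> pd.DataFrame:
    """Run the full (R, pp, calib) grid over all volumes and mask replicates.

    Returns one row per (setting x replicate x volume). Infeasible
    cells (calibration block exceeding the sample budget at the
    requested R) are recorded with their failure reason rather than
    dropped, so the table is always complete.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    n_cells = (
        len(cfg.R_list) * len(cfg.pp_list) * len(cfg.calib_list)
        * cfg.masks_per_setting * len(datasets)
    )
    logger.info(
        "sweep: %d cells (%d R x %d pp x %d calib x %d masks x %d volumes), "
        "lam=%g n_iter=%d seed_base=%d",
        n_cells, len(cfg.R_list), len(cfg.pp_list), len(cfg.calib_list),
        cfg.masks_per_setting, len(datasets),
        cfg.recon.lam, cfg.recon.n_iter, cfg.seed_base,
    )
    references = {
        vid: make_reference(
            ks, cfg.calib_ref, cfg.peak_coverage, cfg.peak_lines, cfg.min_prominence
        )
        for vid, ks in datasets.items()
    }
    rows = []
    for vid, ks in datasets.items():
        for R in cfg.R_list:
            for pp in cfg.pp_list:
                for calib in cfg.calib_list:
                    for rep in range(cfg.masks_per_setting):
                        seed = cell_seed(cfg.seed_base, R, pp, calib, rep, vid)
                        row = {
                            "R": R,
                            "pp": pp,
                            "calib": calib,
                            "mask_seed": seed,
                            "volume_id": vid,
                        }
                        try:
                            params = MaskParams(R=R, pp=pp, calib=calib, seed=seed)
                            row.update(
                                evaluate_cell(
                                    ks,
                                    references[vid],
                                    params,
                                    cfg.recon,
                                    cfg.peak_coverage,
                                    cfg.peak_lines,
                                    cfg.min_prominence,
                                )
                            )
                        except (InfeasibleMaskError, ValueError) as exc:
                            row.update(
                                ssim=np.nan,
                                n_peaks=np.nan,
                                rel_peak_change=np.nan,
                                achieved_R=np.nan,
                                runtime_s=np.nan,
                                error=str(exc),
                            )
                        rows.append(row)
    return pd.DataFrame(rows)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(R, pp, calib) mean/SD of SSIM and peak metrics across cells."""
    if records.empty:
        raise ValueError("no records to aggregate")
    ok = records[records["error"].isna()]
    agg = (
        ok.groupby(["R", "pp", "calib"])
        .agg(
            ssim_mean=("ssim", "mean"),
            ssim_sd=("ssim", "std"),
            peaks_mean=("n_peaks", "mean"),
            rel_peak_change_mean=("rel_peak_change", "mean"),
            n=("ssim", "size"),
        )
        .reset_index()
    )
    agg["ssim_sd"] = agg["ssim_sd"].fillna(0.0)
    return agg


def select_optimum(agg: pd.DataFrame, R: float) -> tuple[float, int]:
    """Best (pp, calib) at acceleration R by mean vessel-masked SSIM.

    Ties break toward smaller calib, then smaller pp.
    """
    sel = agg[np.isclose(agg["R"], R)]
    if sel.empty:
        raise ValueError(f"R={R} not present in the aggregated table")
    best = sel["ssim_mean"].max()
    cand = sel[np.isclose(sel["ssim_mean"], best, rtol=0, atol=0)]
    cand = cand.sort_values(["calib", "pp"])
    row = cand.iloc[0]
    return float(row["pp"]), int(row["calib"])


def plot_ssim_heatmaps(agg: pd.DataFrame, out_path: str) -> None:
    """SSIM heatmaps (pp x calib), one panel per R.

    Each panel's color range runs from that R's maximum mean SSIM down
    to 90% of the maximum, which makes the location of the optimum
    visible regardless of the overall SSIM level at that acceleration.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r_values = sorted(agg["R"].unique())
    fig, axes = plt.subplots(
        1, len(r_values), figsize=(3.2 * len(r_values), 3.2), squeeze=False
    )
    for ax, R in zip(axes[0], r_values):
        sub = agg[np.isclose(agg["R"], R)]
        pivot = sub.pivot(index="pp", columns="calib", values="ssim_mean")
        top = np.nanmax(pivot.values)
        im = ax.imshow(
            pivot.values,
            origin="lower",
            aspect="auto",
            vmin=0.9 * top,
            vmax=top,
            extent=(
                pivot.columns.min(),
                pivot.columns.max(),
                pivot.index.min(),
                pivot.index.max(),
            ),
        )
        ax.set_title(f"R = {R:g}")
        ax.set_xlabel("calib")
        ax.set_ylabel("pp")
        fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def run_recon_param_grid(
    lam_list: tuple[float, ...],
    iter_list: tuple[int, ...],
    datasets: dict[str, KSpaceData],
    R_list: tuple[float, ...] = (9.0, 13.0),
    mask_pp: float = 2.0,
    mask_calib: int = 12,
    seed_base: int = 0,
    calib_ref: int = 32,
    peak_coverage: float = 0.5,
    peak_lines: int | None = None,
) -> pd.DataFrame:
    """Preliminary reconstruction-parameter grid over (λ, n_iter).

    For each dataset and acceleration, one fixed undersampling mask is
    reused across the (λ, n_iter) grid so the comparison isolates the
    reconstruction parameters.
    """
    if not (lam_list and iter_list and R_list):
        raise ValueError("parameter lists must be nonempty")
    rows = []
    for vid, ks in datasets.items():
        ref = make_reference(ks, calib_ref, peak_coverage, peak_lines)
        for R in R_list:
            seed = cell_seed(seed_base, R, mask_pp, mask_calib, 0, vid)
            params = MaskParams(R=R, pp=mask_pp, calib=mask_calib, seed=seed)
            for lam in lam_list:
                for n_iter in iter_list:
                    cfg = ReconConfig(lam=lam, n_iter=n_iter)
                    res = evaluate_cell(
                        ks, ref, params, cfg, peak_coverage, peak_lines
                    )
                    rows.append(
                        {
                            "lam": lam,
                            "n_iter": n_iter,
                            "R": R,
                            "volume_id": vid,
                            "ssim": res["ssim"],
                            "n_peaks": res["n_peaks"],
                            "runtime_s": res["runtime_s"],
                        }
                    )
    return pd.DataFrame(rows)
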