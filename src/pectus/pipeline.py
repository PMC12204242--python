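"""End-to-end patient pipeline: segment -> select slice -> measure -> report.

``run_pipeline`` reads an axial stack, obtains interior masks (from a trained
model or, in oracle mode, from supplied ground-truth masks), selects the
deepest-depression slice, measures the indices on the neighborhood, and
writes: per-slice masks (PNG), the per-slice depth table (CSV), the indices
table (CSV), a JSON report, and an annotated overlay of the target slice.
Every output carries the configuration hash so identical configurations
reproduce byte-identical CSV/JSON.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as pio
from .errors import DataError, ParameterError, PectusError, StageError
from .geometry import extract_inner_contour, find_landmarks
from .indices import PatientReport, measure_patient
from .phantom import AxialSlice
from .seg import predict_mask, resample, resample_mask
from .slices import select_target

logger = logging.getLogger("pectus")

__all__ = ["PipelineConfig", "run_pipeline", "config_hash"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; flags mirror these field names."""

    input_path: str = ""
    input_format: str | None = None        # dicom_dir | nifti | png_stack
    spacing_mm: float | None = None        # override when the input lacks it
    model_path: str | None = None          # checkpoint stem (.npz/.json)
    use_truth_masks: bool = False          # oracle mode: masks provided
    truth_mask_dir: str | None = None
    selection_mode: str = "inclusive"      # inclusive 7-slice | literal_six
    probability_threshold: float = 0.5
    error_fraction: float = 0.10
    spine_window: float = 0.15
    neighborhood_k: int = 3
    output_dir: str = "pectus_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("probability_threshold", "error_fraction", "spine_window"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.selection_mode not in ("inclusive", "literal_six"):
            raise ParameterError(f"unknown selection_mode {self.selection_mode!r}")
        if not self.use_truth_masks and not self.model_path:
            raise ParameterError(
                "no model checkpoint given and oracle-mask mode not enabled"
            )
        if self.use_truth_masks and not self.truth_mask_dir:
            raise ParameterError("oracle-mask mode needs truth_mask_dir")


def config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _segment(cfg: PipelineConfig, slices: list[AxialSlice]) -> list:
    if cfg.use_truth_masks:
        mask_dir = Path(cfg.truth_mask_dir)
        masks = []
        for i in range(len(slices)):
            f = mask_dir / f"mask_{i:04d}.png"
            if not f.exists():
                raise DataError(f"oracle mask {f} missing")
            masks.append(pio.read_mask_png(f))
        return masks
    from .nn import UNet

    model = UNet.load(cfg.model_path)
    size = model.cfg.input_size
    masks = []
    for sl in slices:
        rs = resample(sl, size) if sl.image.shape[0] != size else sl
        m = predict_mask(model, rs, threshold=cfg.probability_threshold)
        if m is not None and rs.image.shape != sl.image.shape:
            m = resample_mask(m, sl.image.shape[0])
        masks.append(m)
    return masks


def _overlay(slice_: AxialSlice, mask, headline, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(slice_.image, cmap="gray", interpolation="nearest")
    try:
        contour = extract_inner_contour(mask, slice_.spacing_mm)
        ax.plot(contour.vertices[:, 1], contour.vertices[:, 0], "c-", lw=1)
        lm = find_landmarks(contour)
        for name in "abcd":
            r, c = getattr(lm, name)
            ax.plot(c, r, "r+", ms=8)
            ax.annotate(name, (c, r), color="yellow", fontsize=9)
    except PectusError:
        pass
    if headline is not None:
        text = (f"HI {headline.haller:.2f} ({headline.severity})\n"
                f"CI {headline.correction_pct:.1f}%\n"
                f"AI {headline.asymmetry:.2f}")
        ax.text(0.02, 0.98, text, transform=ax.transAxes, va="top",
                color="yellow", fontsize=10)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, metadata={"Software": None})
    plt.close(fig)


def _write_depths(selection, path: Path, chash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={chash}; slice indices are 0-based\n")
        w = csv.writer(fh)
        w.writerow(["slice_index", "depth_cm", "is_target", "in_neighborhood"])
        for i, depth in enumerate(selection.per_slice_depth_cm):
            w.writerow([i, f"{depth:.4f}", int(i == selection.target_index),
                        int(i in selection.neighborhood)])


def _write_indices(report: PatientReport, path: Path, chash: str) -> None:
    cols = ["slice_index", "is_target", "haller", "correction_pct", "asymmetry",
            "severity", "transverse_cm", "ap_depth_cm", "ab_cm", "cd_cm",
            "L_cm", "R_cm", "flags"]
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash={chash}; slice indices are 0-based; distances in cm\n")
        w = csv.writer(fh)
        w.writerow(cols)
        for iset in report.per_slice:
            w.writerow([
                iset.slice_index,
                int(iset.slice_index == report.selection.target_index),
                f"{iset.haller:.4f}", f"{iset.correction_pct:.2f}",
                f"{iset.asymmetry:.4f}", iset.severity,
                f"{iset.transverse_cm:.3f}", f"{iset.ap_depth_cm:.3f}",
                f"{iset.ab_cm:.3f}", f"{iset.cd_cm:.3f}",
                f"{iset.L_cm:.3f}", f"{iset.R_cm:.3f}",
                "|".join(sorted(iset.flags)),
            ])


def run_pipeline(cfg: PipelineConfig) -> PatientReport:
    """Execute the full measurement pipeline and write all report files."""
    cfg.validate()
    chash = config_hash(cfg)
    logging.basicConfig(level=cfg.log_level)
    logger.info("pipeline start: seed=%d config=%s", cfg.seed, chash)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    slices = pio.read_stack(cfg.input_path, cfg.input_format, cfg.spacing_mm)
    logger.info("read %d slices", len(slices))

    try:
        masks = _segment(cfg, slices)
    except PectusError:
        raise
    except Exception as exc:
        raise StageError("segment", str(exc)) from exc
    mask_dir = outdir / "masks"
    mask_dir.mkdir(exist_ok=True)
    for i, m in enumerate(masks):
        if m is not None:
            pio.write_mask_png(m, mask_dir / f"mask_{i:04d}.png")

    try:
        selection = select_target(slices, k=cfg.neighborhood_k,
                                  literal_six=cfg.selection_mode == "literal_six")
    except PectusError as exc:
        raise StageError("select-slice", str(exc)) from exc
    _write_depths(selection, outdir / "depths.csv", chash)
    logger.info("target slice %d, neighborhood %s",
                selection.target_index, selection.neighborhood)

    report = measure_patient(slices, masks, selection)
    _write_indices(report, outdir / "indices.csv", chash)

    payload = {
        "config_hash": chash,
        "seed": cfg.seed,
        "slice_indexing": "0-based",
        "status": report.status,
        "error": report.error,
        "target_slice": selection.target_index,
        "neighborhood": selection.neighborhood,
        "per_slice_depth_cm": [round(d, 4) for d in selection.per_slice_depth_cm],
        "headline": report.headline.as_dict() if report.headline else None,
        "per_slice_indices": [s.as_dict() for s in report.per_slice],
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    target = selection.target_index
    if masks[target] is not None:
        _overlay(slices[target], masks[target], report.headline,
                 outdir / "overlay_target.png")
    logger.info("pipeline done: status=%s", report.status)
    return report
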