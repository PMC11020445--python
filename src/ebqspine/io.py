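"""File formats: images, annotation JSON, cohort CSV, result writers.

Images travel as PNG (8/16-bit integer, lossy for float phantoms), TIFF
(float, lossless) or single-slice NIfTI (float, spacing in the header).
PNG/TIFF carry no spacing, so it must come from the caller or from the
side-car annotation JSON.  All writers are deterministic: sorted JSON keys
and a fixed float format, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .ebq import CsfRegion, EndplateAnnotation
from .image import Image2D
from .phantom import PhantomGroundTruth
from .stats import GroupSummary, LevelSummary, LogisticFit, RocResult

__all__ = [
    "read_image",
    "write_image",
    "annotations_to_json",
    "annotations_from_json",
    "read_cohort",
    "write_cohort",
    "write_results",
]

_FLOAT_FMT = "%.10g"


def _jsonify(obj):
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def _dump_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(_jsonify(payload), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------


def read_image(path: Union[str, Path], spacing_mm: Optional[float] = None) -> Image2D:
    """Load a 2-D grayscale image as an :class:`Image2D`.

    For PNG/TIFF the pixel spacing must be supplied (it usually lives in
    the side-car annotation JSON).  For NIfTI the spacing comes from the
    header and must be isotropic in-plane.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix in (".nii", ".nii.gz"):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path.name}: expected a single 2-D slice, got shape {data.shape}")
        zooms = img.header.get_zooms()[:2]
        if abs(zooms[0] - zooms[1]) > 1e-9:
            raise ValueError(
                f"{path.name}: anisotropic in-plane spacing {zooms} is unsupported")
        # NIfTI stores (x, y); our raster is (row, col) = (y, x)
        return Image2D(data.T, float(zooms[0]))
    if suffix.lower() in (".png", ".tif", ".tiff"):
        if spacing_mm is None:
            raise ValueError(
                f"{path.name}: pixel spacing is required for {suffix} images "
                "(supply spacing_mm or read it from the annotation JSON)")
        data = np.asarray(iio.imread(path), dtype=float)
        if data.ndim == 3:  # collapse trivial channel axes
            if data.shape[2] not in (1,):
                raise ValueError(f"{path.name}: expected grayscale, got shape {data.shape}")
            data = data[:, :, 0]
        return Image2D(data, float(spacing_mm))
    raise ValueError(f"unknown image format {suffix!r} for {path.name}")


def write_image(path: Union[str, Path], image: Image2D) -> Path:
    """Write an image as 16-bit PNG (rounded), float TIFF, or NIfTI.

    PNG quantizes to integers in [0, 65535]; TIFF and NIfTI round-trip the
    float pixel grid bit-identically.
    """
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix in (".nii", ".nii.gz"):
        affine = np.diag([image.spacing_mm, image.spacing_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(image.pixels.T.astype(np.float64), affine), str(path))
    elif suffix.lower() in (".tif", ".tiff"):
        iio.imwrite(path, image.pixels.astype(np.float64))
    elif suffix.lower() == ".png":
        px = np.round(image.pixels)
        if px.max() > 65535:
            raise ValueError("pixel values exceed the 16-bit PNG range")
        iio.imwrite(path, px.astype(np.uint16))
    else:
        raise ValueError(f"unknown image format {suffix!r} for {path.name}")
    return path


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def annotations_to_json(
    path: Union[str, Path],
    spacing_mm: float,
    levels: dict,
    csf_polygon_mm: np.ndarray,
) -> Path:
    """Write the annotation schema shared by the phantom and the measurer.

    ``levels`` maps level label -> (upper EndplateAnnotation, lower
    EndplateAnnotation) or -> dict with an optional ``exclusions_mm`` list.
    """
    entries = []
    for label, value in levels.items():
        if isinstance(value, dict):
            upper, lower = value["upper"], value["lower"]
            exclusions = value.get("exclusions_mm", [])
        else:
            upper, lower = value
            exclusions = []
        entries.append({
            "level": label,
            "upper_endplate": {
                "polyline_mm": upper.polyline_mm,
                "body_side_hint_mm": upper.body_side_hint_mm,
            },
            "lower_endplate": {
                "polyline_mm": lower.polyline_mm,
                "body_side_hint_mm": lower.body_side_hint_mm,
            },
            "exclusions_mm": exclusions,
        })
    payload = {"spacing_mm": spacing_mm, "levels": entries,
               "csf_polygon_mm": np.asarray(csf_polygon_mm)}
    path = Path(path)
    _dump_json(path, payload)
    return path


def ground_truth_to_json(path: Union[str, Path], gt: PhantomGroundTruth) -> Path:
    """Serialize a phantom ground truth as annotation JSON (plus truths)."""
    levels = {
        label: {"upper": gt.annotations[label][0], "lower": gt.annotations[label][1],
                "exclusions_mm": gt.exclusions_for(label)}
        for label in gt.levels
    }
    path = annotations_to_json(path, gt.spacing_mm, levels, gt.csf.polygon_mm)
    truth_path = Path(str(path).replace(".json", ".truth.json"))
    _dump_json(truth_path, {
        "true_ebq": gt.true_ebq,
        "tissue_means": gt.tissue_means,
        "band_depth_mm": gt.band_depth_mm,
    })
    return path


def annotations_from_json(path: Union[str, Path]) -> dict:
    """Read annotation JSON; returns ``{"spacing_mm", "levels", "csf"}``.

    ``levels`` maps label -> dict with ``upper``/``lower`` annotations and
    an ``exclusions_mm`` polygon list.
    """
    payload = json.loads(Path(path).read_text())
    levels = {}
    for entry in payload["levels"]:
        label = entry["level"]
        anns = {}
        for role in ("upper_endplate", "lower_endplate"):
            spec = entry[role]
            anns[role.split("_")[0]] = EndplateAnnotation(
                level=label, role=role,
                polyline_mm=np.asarray(spec["polyline_mm"], dtype=float),
                body_side_hint_mm=np.asarray(spec["body_side_hint_mm"], dtype=float),
            )
        anns["exclusions_mm"] = [np.asarray(p, dtype=float)
                                 for p in entry.get("exclusions_mm", [])]
        levels[label] = anns
    return {
        "spacing_mm": float(payload["spacing_mm"]),
        "levels": levels,
        "csf": CsfRegion(np.asarray(payload["csf_polygon_mm"], dtype=float)),
    }


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {missing}")
    outcome = pd.unique(df["subsided"])
    if not set(outcome).issubset({0, 1}):
        raise ValueError(f"'subsided' must be binary 0/1, found values {sorted(outcome)}")
    for col in ("age", "bmi", "tscore", "ebq", "preop_height_mm", "final_height_mm"):
        if df[col].isna().any():
            raise ValueError(f"column {col!r} has missing values")
    return df


def write_cohort(path: Union[str, Path], cohort: pd.DataFrame) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# analysis artifacts
# ---------------------------------------------------------------------------


def _table1_frame(table1: list[GroupSummary]) -> pd.DataFrame:
    rows = []
    for gs in table1:
        row: dict = {"variable": gs.variable, "test": gs.test_used, "p_value": gs.p_value}
        for g, s in gs.groups.items():
            tag = f"g{g}"
            row[f"{tag}_n"] = s["n"]
            row[f"{tag}_mean"] = s["mean"]
            row[f"{tag}_sd"] = s["sd"]
            if s.get("ci95"):
                row[f"{tag}_ci_lo"], row[f"{tag}_ci_hi"] = s["ci95"]
        rows.append(row)
    return pd.DataFrame(rows)


def _table2_frame(fit: LogisticFit) -> pd.DataFrame:
    rows = []
    for name, est in fit.params.items():
        rows.append({"covariate": name, "B": est.B, "se": est.se, "p": est.p,
                     "OR": est.or_, "or_ci_lo": est.or_ci95[0], "or_ci_hi": est.or_ci95[1]})
    return pd.DataFrame(rows)


def _table3_frame(table3: list[LevelSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {"level": s.level, "n": s.n, "mean_ebq": s.mean, "sd": s.sd,
         "ci_lo": s.ci95[0], "ci_hi": s.ci95[1]} for s in table3
    ])


def write_results(out_dir: Union[str, Path], results: dict) -> dict:
    """Write the analysis artifacts of :func:`ebqspine.stats.analyze_cohort`.

    Emits table1.csv, table2.csv, table3.csv, roc.csv, roc.json,
    correlation.json and a human-readable report.md (2-dp display rounding
    lives only in the report; the CSV/JSON keep full precision).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    t1 = _table1_frame(results["table1"])
    t1.to_csv(out / "table1.csv", index=False, float_format=_FLOAT_FMT)
    paths["table1"] = out / "table1.csv"

    t2 = _table2_frame(results["table2"])
    t2.to_csv(out / "table2.csv", index=False, float_format=_FLOAT_FMT)
    paths["table2"] = out / "table2.csv"

    t3 = _table3_frame(results["table3"])
    t3.to_csv(out / "table3.csv", index=False, float_format=_FLOAT_FMT)
    paths["table3"] = out / "table3.csv"

    roc_res: RocResult = results["roc"]
    pd.DataFrame({
        "threshold": roc_res.thresholds,
        "sensitivity": roc_res.sensitivity,
        "specificity": roc_res.specificity,
    }).to_csv(out / "roc.csv", index=False, float_format=_FLOAT_FMT)
    paths["roc_curve"] = out / "roc.csv"
    _dump_json(out / "roc.json", {
        "auc": roc_res.auc,
        "auc_ci95": list(roc_res.auc_ci95),
        "cutoff": roc_res.cutoff,
        "sensitivity": roc_res.cutoff_sensitivity,
        "specificity": roc_res.cutoff_specificity,
        "youden_j": roc_res.youden_j,
    })
    paths["roc"] = out / "roc.json"

    corr = results["correlation"]
    _dump_json(out / "correlation.json", dataclasses.asdict(corr))
    paths["correlation"] = out / "correlation.json"

    report = _pretty_report(results)
    (out / "report.md").write_text(report)
    paths["report"] = out / "report.md"
    return paths


def _fmt_ci(ci) -> str:
    return f"{ci[0]:.2f} to {ci[1]:.2f}" if ci else ""


def _pretty_report(results: dict) -> str:
    lines = ["# Cohort analysis report", ""]
    lines.append(f"n = {results['n']}, subsidence prevalence = "
                 f"{100 * results['prevalence']:.2f}%")
    lines.append("")
    lines.append("## Group comparison")
    lines.append("")
    lines.append("| variable | group 0 (mean±SD, 95% CI) | group 1 (mean±SD, 95% CI) | p | test |")
    lines.append("|---|---|---|---|---|")
    for gs in results["table1"]:
        cells = []
        for g in sorted(gs.groups):
            s = gs.groups[g]
            if s["mean"] is None:
                cells.append(f"n={s['n']}")
            elif s["sd"] is None:
                cells.append(f"{s['mean']:.2f} (n={s['n']})")
            else:
                cells.append(f"{s['mean']:.2f}±{s['sd']:.2f} ({_fmt_ci(s['ci95'])})")
        lines.append(f"| {gs.variable} | {cells[0]} | {cells[1]} | "
                     f"{gs.p_value:.3f} | {gs.test_used} |")
    lines.append("")
    lines.append("## Logistic regression (subsidence)")
    lines.append("")
    lines.append("| covariate | B | p | OR | 95% CI |")
    lines.append("|---|---|---|---|---|")
    for name, est in results["table2"].params.items():
        lines.append(f"| {name} | {est.B:.3f} | {est.p:.3f} | {est.or_:.3f} | "
                     f"{est.or_ci95[0]:.3f}-{est.or_ci95[1]:.3f} |")
    lines.append("")
    lines.append("## EBQ by disc level (non-subsided)")
    lines.append("")
    for s in results["table3"]:
        lines.append(f"- {s.level} (n={s.n}): {s.mean:.2f} ± {s.sd:.2f} "
                     f"(95% CI {_fmt_ci(s.ci95)})")
    lines.append("")
    roc_res = results["roc"]
    lines.append("## ROC (EBQ predicting subsidence)")
    lines.append("")
    lines.append(f"AUC = {roc_res.auc:.3f} (95% CI {roc_res.auc_ci95[0]:.3f}-"
                 f"{roc_res.auc_ci95[1]:.3f}); optimal cutoff = {roc_res.cutoff:.2f} "
                 f"(sensitivity {100 * roc_res.cutoff_sensitivity:.1f}%, "
                 f"specificity {100 * roc_res.cutoff_specificity:.1f}%)")
    lines.append("")
    corr = results["correlation"]
    lines.append(f"Pearson correlation EBQ vs height loss: r = {corr.r:.3f} "
                 f"(p = {corr.p_value:.3g}, n = {corr.n})")
    lines.append("")
    return "\n".join(lines)
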