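"""End-to-end workflow: micrographs in, feature/gating tables and a
population report out.

``run_pipeline`` chains the preprocessing transformer, the feature
extractor and the gate classifier, and serializes three artefacts with
stable contracts:

* features CSV — object_id, area_px, N_boundary, mu_d, sigma_d, CV,
  rect_ratio, rect_signed, R (one row per retained nucleus);
* gating CSV — object_id, R, CV, region, weight, binary_call, pc1;
* population JSON — per surface: n_cells, counts R1-R5, p', DS, class,
  undeformed fraction.

Outputs are written atomically (temp file + rename); identical inputs,
config and seeds give byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .features import ShapeFeatureExtractor
from .preprocess import NucleusPreprocessor
from .scoring import (
    DeformationGater,
    pc1_projection,
    population_profile,
    surface_summary,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "read_image", "write_report", "load_masks"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a TIFF or PNG micrograph as an array (first page of a multi-page TIFF)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim == 3 and data.shape[0] not in (1, 3, 4) and data.shape[-1] not in (3, 4):
            data = data[0]  # multi-page stack: first page
        if data.ndim == 3 and data.shape[0] in (3, 4) and data.shape[-1] not in (3, 4):
            data = np.moveaxis(data, 0, -1)  # planar RGB to interleaved
        return data
    import imageio.v3 as iio

    return iio.imread(str(path))


def load_masks(paths: list[str | Path]) -> list[np.ndarray]:
    """Read pre-segmented binary/label masks (PNG) as boolean arrays."""
    import imageio.v3 as iio

    return [np.asarray(iio.imread(str(p))) > 0 for p in paths]


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _float_fmt(x) -> str:
    return f"{x:.6g}"


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV contract: comma-separated, UTF-8, header, floats at 6 significant digits."""
    _atomic_write(Path(path), df.to_csv(index=False, float_format="%.6g"))


def write_report(report: dict, path: str | Path) -> None:
    """Versioned population JSON report."""
    payload = {"schema_version": 1, **report}
    _atomic_write(Path(path), json.dumps(payload, indent=2, sort_keys=True) + "\n")


def score_features(features: pd.DataFrame, group_by: str | None = None) -> dict:
    """Gate a feature table and aggregate per-population reports.

    ``features`` needs columns R and CV; ``group_by`` names an optional
    population column (e.g. surface_id).  Returns {"populations": {...}}
    plus a per-cell gating frame under the key "_gating".
    """
    gater = DeformationGater().fit()
    regions = gater.predict(features)
    calls = gater.predict_binary(features)
    gating = pd.DataFrame(
        {
            "object_id": features.get("object_id", pd.RangeIndex(len(features))),
            "R": features["R"],
            "CV": features["CV"],
            "region": [f"R{r}" for r in regions],
            "weight": regions,
            "binary_call": calls,
            "pc1": pc1_projection(features["R"].to_numpy(), features["CV"].to_numpy()),
        }
    )
    populations = {}
    if group_by and group_by in features.columns:
        groups = features.groupby(group_by, sort=True).indices.items()
    else:
        groups = [("all", np.arange(len(features)))]
    for name, idx in groups:
        sub = features.iloc[np.asarray(idx)]
        profile = population_profile(regions[np.asarray(idx)])
        summary = surface_summary(sub, surface_id=str(name))
        entry = profile.to_dict()
        entry["surface_id"] = str(name)
        entry["undeformed_fraction"] = summary.undeformed_fraction
        entry["deformed_fraction"] = summary.deformed_fraction
        populations[str(name)] = entry
    return {"populations": populations, "_gating": gating}


def run_pipeline(
    images: list,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    source_ids: list[str] | None = None,
) -> dict:
    """Execute preprocess -> features -> gating -> scoring on micrographs.

    ``images`` may be file paths or arrays.  Returns a dict with keys
    ``features`` (DataFrame), ``gating`` (DataFrame), ``qc`` (DataFrame)
    and ``report`` (population dict); if ``out_dir`` is given the three
    file artefacts are also written there atomically.

    Raises on an empty image list or unreadable input.  An empty retained
    set is reported (with partial outputs) rather than raised.
    """
    cfg = (config or RunConfig()).validate()
    if not images:
        raise ValueError("no input images")
    arrays = []
    for i, img in enumerate(images):
        if isinstance(img, (str, Path)):
            arrays.append(read_image(img))
        else:
            arrays.append(np.asarray(img))
    pre = NucleusPreprocessor(
        resize_factor=cfg.resize_factor,
        std_limit=cfg.std_limit,
        min_area_px=cfg.min_area_px,
        max_area_frac=cfg.max_area_frac,
        target_dim=cfg.target_dim,
        mitosis_second_basin_frac=cfg.mitosis_second_basin_frac,
        mitosis_peak_merge_px=cfg.mitosis_peak_merge_px,
        channel=cfg.channel,
    )
    nuclei = pre.transform(arrays)
    qc = pre.qc_table_
    if source_ids is not None:
        mapping = dict(enumerate(source_ids))
        qc["source_id"] = qc["source_id"].map(lambda s: mapping.get(int(s), s) if str(s).isdigit() else s)
    log.info("retained %d nuclei of %d objects", len(nuclei), len(qc))

    extractor = ShapeFeatureExtractor(sigma_divisor=cfg.sigma_divisor)
    features = extractor.transform([n.mask for n in nuclei])

    if len(features) == 0:
        report = {"populations": {}, "note": "no nuclei passed QC"}
        gating = pd.DataFrame(columns=["object_id", "R", "CV", "region", "weight", "binary_call", "pc1"])
    else:
        scored = score_features(features)
        gating = scored.pop("_gating")
        report = scored
    report["config"] = cfg.to_dict()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_csv(features, out / "features.csv")
        write_csv(gating, out / "gating.csv")
        write_csv(qc, out / "qc.csv")
        write_report(report, out / "population.json")
    return {"features": features, "gating": gating, "qc": qc, "report": report}
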