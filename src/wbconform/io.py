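"""CSV / JSON / YAML / raster input-output and the run log.

Cohort tables are UTF-8 comma-separated with a mandatory header
``id,strain,sex,age_wk,live_weight_g,wb_score,M0..M11``.  The binary
woody-breast status is always derived from the ordinal score on read
(score >= 2.0 is positive) and never trusted from a file.  Masks travel as
single-channel PNG/TIFF with a JSON sidecar carrying the spatial scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import SilhouetteMask
from .logit import BinaryLogitResults
from .metrics import EvalReport
from .synthdata import (
    CohortConfig,
    DeformationModel,
    NoiseModel,
    SeverityModel,
    SizeModel,
    STRAINS,
    SEXES,
)

__all__ = [
    "COHORT_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_fit",
    "write_fit",
    "read_report",
    "write_report",
    "load_mask",
    "save_mask",
    "cohort_config_from_yaml",
    "RunLog",
]

COHORT_COLUMNS = ["id", "strain", "sex", "age_wk", "live_weight_g", "wb_score"] + [
    f"M{i}" for i in range(12)
]
_REQUIRED = COHORT_COLUMNS[:6] + ["M0", "M1", "M2", "M3"]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; derive ``wb_binary`` and fill ratios.

    Rejects unknown strain/sex codes and scores off the 0.0–3.0 half-step
    grid, naming the first offending data row (1-based, header excluded).
    Missing ratio columns (M8–M11) are recomputed from the measurements.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks column(s) {missing}")

    def first_bad(bad: pd.Series) -> int:
        return int(np.nonzero(bad.to_numpy())[0][0]) + 1

    bad = ~df["strain"].isin(STRAINS)
    if bad.any():
        raise ValueError(
            f"unknown strain code {df.loc[bad, 'strain'].iloc[0]!r} "
            f"at data row {first_bad(bad)}"
        )
    bad = ~df["sex"].isin(SEXES)
    if bad.any():
        raise ValueError(
            f"unknown sex code {df.loc[bad, 'sex'].iloc[0]!r} "
            f"at data row {first_bad(bad)}"
        )
    score = df["wb_score"].astype(float)
    on_grid = (
        (score >= 0.0)
        & (score <= 3.0)
        & (np.isclose(score * 2.0, np.round(score * 2.0), atol=1e-9))
    )
    if not on_grid.all():
        bad = ~on_grid
        raise ValueError(
            f"wb_score {score[bad].iloc[0]} off the half-step grid "
            f"at data row {first_bad(bad)}"
        )
    df["wb_score"] = score
    # binary status is always derived, never trusted from file
    df["wb_binary"] = (score >= 2.0).astype(int)
    # fill derivable quantities that the file may omit
    derivations = {
        "M4": lambda d: 2.0 * np.degrees(np.arctan(d["M3"] / (2.0 * d["M2"]))),
        "M5": lambda d: 0.5 * d["M3"] * d["M2"],
        "M6": lambda d: d["M5"] + d["M7"] if "M7" in d.columns else np.nan,
        "M7": lambda d: d["M6"] - d["M5"],
        "M8": lambda d: d["M3"] / d["M1"],
        "M9": lambda d: d["M3"] / d["M2"],
        "M10": lambda d: d["M7"] / d["M5"],
        "M11": lambda d: d["M1"] / d["M0"],
    }
    for col, rule in derivations.items():
        if col not in df.columns:
            df[col] = rule(df)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write the canonical cohort columns (derived/truth columns dropped)."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# fits and evaluation reports (JSON, full double precision)


def write_fit(results: BinaryLogitResults, path) -> None:
    Path(path).write_text(json.dumps(results.to_dict(), indent=1))


def read_fit(path) -> BinaryLogitResults:
    return BinaryLogitResults.from_dict(json.loads(Path(path).read_text()))


def write_report(report: EvalReport, path) -> None:
    # a missing AUC (single-class split) serialises as null, not 0
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def read_report(path) -> EvalReport:
    return EvalReport.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# masks


def load_mask(image_path, scale_cm_per_px: float | None = None) -> SilhouetteMask:
    """Load a single-channel PNG/TIFF mask (foreground = nonzero).

    The scale comes from ``scale_cm_per_px`` or else from a JSON sidecar
    ``<stem>.json`` with key ``scale_cm_per_px`` next to the image.
    """
    image_path = Path(image_path)
    if scale_cm_per_px is None:
        sidecar = image_path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(
                f"no scale given and no sidecar {sidecar.name} next to the mask"
            )
        scale_cm_per_px = float(
            json.loads(sidecar.read_text())["scale_cm_per_px"]
        )
    arr = np.asarray(Image.open(image_path).convert("L"))
    return SilhouetteMask(arr != 0, scale_cm_per_px=scale_cm_per_px)


def save_mask(mask: SilhouetteMask, image_path) -> None:
    """Write the mask as 0/255 PNG plus its scale sidecar."""
    image_path = Path(image_path)
    Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(image_path)
    image_path.with_suffix(".json").write_text(
        json.dumps({"scale_cm_per_px": mask.scale_cm_per_px})
    )


# ---------------------------------------------------------------------------
# YAML configuration


def _build(cls, d: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} key(s) {sorted(unknown)}")
    d = dict(d)
    if "cutpoints" in d:
        d["cutpoints"] = tuple(d["cutpoints"])
    if "ages" in d:
        d["ages"] = tuple(d["ages"])
    return cls(**d)


def cohort_config_from_yaml(path) -> CohortConfig:
    """Cohort configuration from YAML, overlaid on the defaults.

    Top-level keys mirror :class:`~wbconform.synthdata.CohortConfig`; the
    nested models (``size``, ``severity``, ``deformation``, ``noise``) are
    mappings of their dataclass fields.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    nested = {
        "size": SizeModel,
        "severity": SeverityModel,
        "deformation": DeformationModel,
        "noise": NoiseModel,
    }
    kwargs = {}
    for key, val in raw.items():
        if key in nested:
            kwargs[key] = _build(nested[key], val)
        else:
            kwargs[key] = val
    cfg = _build(CohortConfig, kwargs)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# run log


class RunLog:
    """Timestamped stage events with a stable configuration hash."""

    def __init__(self, seed: int, config=None):
        self.seed = seed
        self.config_hash = self.hash_config(config) if config is not None else None
        self.events: list[tuple[float, str, str]] = []
        self._open: set[str] = set()
        self._event("run", f"seed={seed} config_hash={self.config_hash}")

    @staticmethod
    def hash_config(config) -> str:
        if dataclasses.is_dataclass(config) and not isinstance(config, type):
            config = dataclasses.asdict(config)
        blob = json.dumps(config, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def _event(self, kind: str, message: str) -> None:
        self.events.append((time.time(), kind, message))

    def begin(self, stage: str) -> None:
        self._open.add(stage)
        self._event("begin", stage)

    def end(self, stage: str) -> None:
        self._open.discard(stage)
        self._event("end", stage)

    def warn(self, message: str) -> None:
        self._event("warning", message)

    def to_text(self) -> str:
        lines = []
        for ts, kind, msg in self.events:
            stamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.localtime(ts))
            lines.append(f"{stamp} {kind:<8} {msg}")
        return "\n".join(lines) + "\n"

    def save(self, path) -> None:
        if self._open:
            raise RuntimeError(f"stage(s) never ended: {sorted(self._open)}")
        Path(path).write_text(self.to_text())
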