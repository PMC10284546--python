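"""File formats, serialization, and run manifests.

Formats used across the pipeline:

* feature matrices — delimited CSV (first column the sample id) or a
  binary array container (``.npz`` with ``ids`` and ``values``);
* label tables — CSV with columns ``image_id, category, animacy, size``
  and an optional ``split``;
* codebook archives — a ``.npy`` tensor plus a JSON sidecar carrying the
  grid shape, config echo (seed included), and training traces; the pair
  is byte-reproducible for a fixed seed;
* map grids — row-major CSV with ``# key=value`` metadata header lines;
* run manifests — JSON with config echoes, input digests, seeds, and the
  ordered stage log, sufficient to re-run a pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .som import Codebook, TrainConfig, TrainingTrace

__all__ = [
    "FeatureMatrix",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_label_table",
    "write_label_table",
    "join_check",
    "save_codebook",
    "load_codebook",
    "write_map_csv",
    "read_map_csv",
    "save_heatmap",
    "RunManifest",
]

logger = logging.getLogger("somtopo")

CODEBOOK_FORMAT_VERSION = 1
ANIMACY_LEVELS = ("animate", "inanimate")
SIZE_LEVELS = ("big", "small")


@dataclass
class FeatureMatrix:
    """Sample ids plus an (n_samples, n_features) real matrix."""

    ids: np.ndarray
    values: np.ndarray
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (n_samples x n_features)")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("one id per row required")
        if len(set(map(str, self.ids))) != len(self.ids):
            raise ValueError("sample ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("missing values not allowed")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.values.shape[1]


# --------------------------------------------------------------------------
# feature matrices
# --------------------------------------------------------------------------


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    return "binary-array" if path.suffix == ".npz" else "delimited"


def read_feature_matrix(path: str | Path, format: str | None = None) -> FeatureMatrix:
    """Read a feature matrix from CSV (first column id) or ``.npz``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature matrix file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "binary-array":
        with np.load(path, allow_pickle=False) as npz:
            return FeatureMatrix(ids=npz["ids"].astype(object), values=npz["values"])
    if fmt != "delimited":
        raise ValueError(f"unknown format '{fmt}'")
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus at least one feature column")
    ids = df.iloc[:, 0].to_numpy()
    dup = pd.Series(ids).duplicated()
    if dup.any():
        rows = [str(i + 2) for i in np.flatnonzero(dup.to_numpy())]  # 1-based + header
        raise ValueError(f"{path}: duplicate ids at row(s) {', '.join(rows)}")
    raw = df.iloc[:, 1:]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.any().any() or raw.isna().any().any():
        rows = sorted(
            set(np.flatnonzero(bad.any(axis=1).to_numpy()))
            | set(np.flatnonzero(raw.isna().any(axis=1).to_numpy()))
        )
        rows_s = ", ".join(str(r + 2) for r in rows)
        raise ValueError(f"{path}: non-numeric or missing cells at row(s) {rows_s}")
    return FeatureMatrix(ids=ids, values=numeric.to_numpy(dtype=np.float64))


def write_feature_matrix(
    fm: FeatureMatrix, path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "binary-array":
        np.savez(path, ids=np.asarray([str(i) for i in fm.ids]), values=fm.values)
        return
    df = pd.DataFrame(fm.values, columns=[f"f{i}" for i in range(fm.feature_dim)])
    df.insert(0, "id", [str(i) for i in fm.ids])
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# label tables
# --------------------------------------------------------------------------

REQUIRED_LABEL_COLUMNS = ("image_id", "category", "animacy", "size")


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a label table CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label table file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    return validate_label_table(df, source=str(path))


def validate_label_table(df: pd.DataFrame, source: str = "label table") -> pd.DataFrame:
    for col in REQUIRED_LABEL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{source}: missing required column '{col}'")
    if df["image_id"].duplicated().any():
        raise ValueError(f"{source}: duplicate image_id values")
    bad_anim = set(df["animacy"].unique()) - set(ANIMACY_LEVELS)
    if bad_anim:
        raise ValueError(f"{source}: unknown animacy value(s) {sorted(bad_anim)}")
    bad_size = set(df["size"].unique()) - set(SIZE_LEVELS)
    if bad_size:
        raise ValueError(f"{source}: unknown size value(s) {sorted(bad_size)}")
    if "split" not in df.columns:
        df = df.assign(split="probe")
    return df


def write_label_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def join_check(features: FeatureMatrix, labels: pd.DataFrame) -> pd.DataFrame:
    """Align a label table to a feature matrix row order.

    Every labelled id must exist in the feature matrix and vice versa;
    missing ids are listed in the error.
    """
    fids = [str(i) for i in features.ids]
    fid_set = set(fids)
    lids = set(labels["image_id"])
    missing = [i for i in lids if i not in fid_set]
    if missing:
        raise ValueError(f"label ids missing from features: {', '.join(sorted(missing)[:20])}")
    unlabelled = [i for i in fids if i not in lids]
    if unlabelled:
        raise ValueError(f"feature ids missing from labels: {', '.join(sorted(unlabelled)[:20])}")
    return labels.set_index("image_id").loc[fids].reset_index()


# --------------------------------------------------------------------------
# codebook archives
# --------------------------------------------------------------------------


def save_codebook(
    codebook: Codebook,
    path: str | Path,
    config: TrainConfig | None = None,
    trace: TrainingTrace | None = None,
) -> None:
    """Write ``<path>.npy`` (the W x H x F tensor) plus a JSON sidecar.

    Raw ``.npy`` is used (rather than a zip container) so the archive
    bytes depend only on the tensor — identical seeds give identical
    files.
    """
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    np.save(path, codebook.tuning)
    sidecar = {
        "format_version": CODEBOOK_FORMAT_VERSION,
        "grid_width_W": codebook.grid_width_W,
        "grid_height_H": codebook.grid_height_H,
        "feature_dim_F": codebook.feature_dim_F,
        "config": config.to_dict() if config is not None else None,
        "qe_initial": trace.qe_initial if trace is not None else None,
        "qe_per_epoch": trace.qe_per_epoch if trace is not None else None,
        "learning_rate_per_epoch": trace.learning_rate_per_epoch if trace is not None else None,
        "radius_per_epoch": trace.radius_per_epoch if trace is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_codebook(path: str | Path) -> tuple[Codebook, dict]:
    path = Path(path)
    if path.suffix != ".npy":
        path = path.with_suffix(".npy")
    if not path.exists():
        raise FileNotFoundError(f"codebook archive not found: {path}")
    tuning = np.load(path)
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    cb = Codebook(tuning)
    if sidecar:
        expect = (sidecar["grid_width_W"], sidecar["grid_height_H"], sidecar["feature_dim_F"])
        if expect != (cb.grid_width_W, cb.grid_height_H, cb.feature_dim_F):
            raise ValueError(f"sidecar shape {expect} disagrees with tensor {cb.tuning.shape}")
    return cb, sidecar


# --------------------------------------------------------------------------
# map grids
# --------------------------------------------------------------------------


def write_map_csv(grid: np.ndarray, path: str | Path, metadata: dict | None = None) -> None:
    """Row-major W x H grid as CSV with ``# key=value`` header lines."""
    grid = np.asarray(grid)
    path = Path(path)
    meta = {"grid_width_W": grid.shape[0], "grid_height_H": grid.shape[1]}
    meta.update(metadata or {})
    lines = [f"# {k}={v}" for k, v in meta.items()]
    for row in grid:
        lines.append(",".join(str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_map_csv(path: str | Path, dtype=float) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"map file not found: {path}")
    meta: dict = {}
    rows = []
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            k, _, v = line.lstrip("# ").partition("=")
            meta[k] = v
            continue
        cells = line.split(",")
        rows.append([dtype(c) for c in cells] if dtype is not str else cells)
    grid = np.array(rows, dtype=object if dtype is str else np.float64)
    return grid, meta


def save_heatmap(
    grid: np.ndarray,
    path: str | Path,
    vmin: float | None = None,
    vmax: float | None = None,
    symmetric: bool = False,
    cmap: str = "RdBu_r",
    title: str | None = None,
) -> None:
    """Render a map grid as a PNG heatmap with saturation-clipping limits.

    ``symmetric=True`` centers the color limits at 0 with equal reach on
    both sides; values beyond the limits saturate.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = np.asarray(grid, dtype=np.float64)
    if symmetric:
        lim = max(abs(np.nanmin(grid)), abs(np.nanmax(grid))) if vmax is None else vmax
        vmin, vmax = -lim, lim
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(grid, vmin=vmin, vmax=vmax, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("h (col)")
    ax.set_ylabel("w (row)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline stage bit-identically."""

    stage: str
    configs: dict
    inputs: dict
    seeds: dict
    software_version: str
    timestamp: str
    stage_log: list[str]

    @classmethod
    def create(
        cls,
        stage: str,
        configs: dict | None = None,
        input_paths: dict | None = None,
        seeds: dict | None = None,
        stage_log: list[str] | None = None,
    ) -> "RunManifest":
        from . import __version__

        inputs = {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (input_paths or {}).items()
        }
        return cls(
            stage=stage,
            configs=configs or {},
            inputs=inputs,
            seeds=seeds or {},
            software_version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            stage_log=stage_log or [],
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
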