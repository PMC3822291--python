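"""File formats, run configuration, and report serialisation.

CSV dialect throughout: UTF-8, comma-separated, header row required;
Hiragana symbols are stored as the characters themselves.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .colorimetry import Palette, load_default_palette
from .consistency import WelchResult, validate_responses
from .graphemes import GraphemeInventory, load_default_inventory
from .second_order import BinnedTable, RegressionResult
from .synthetic import SyntheticDataset

__all__ = [
    "RunConfig",
    "read_responses",
    "write_responses",
    "write_dataset",
    "report_to_jsonable",
    "write_report",
    "write_manifest",
]


@dataclass
class RunConfig:
    """Configuration for an analysis run, loadable from YAML."""

    palette_path: str | None = None
    responses_path: str | None = None
    inventory_paths: dict = field(default_factory=dict)
    norms_paths: dict = field(default_factory=dict)
    features_path: str | None = None
    scripts: tuple[str, ...] = ("hiragana", "latin")
    bin_sizes: dict = field(default_factory=lambda: {"hiragana": 15, "latin": 5})
    hue_mode: str = "circular"
    shape_measure: str = "rated"
    session: int = 1
    exclude_no_color: bool = False
    seed: int = 0
    output_dir: str = "synmap_out"

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.bin_sizes.values()):
            raise ValueError("bin sizes must be positive")
        for p in filter(None, [self.palette_path, self.responses_path,
                               self.features_path]):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "scripts" in data:
            data["scripts"] = tuple(data["scripts"])
        return cls(**data)

    def load_palette(self) -> Palette:
        if self.palette_path:
            return Palette.from_csv(self.palette_path)
        return load_default_palette()

    def load_inventories(self) -> dict[str, GraphemeInventory]:
        from .graphemes import load_inventory

        out = {}
        for script in self.scripts:
            if script in self.inventory_paths:
                out[script] = load_inventory(script, self.inventory_paths[script])
            else:
                out[script] = load_default_inventory(script)
        return out

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_responses(path: str | Path, palette: Palette) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "session" in df.columns:
        df["session"] = df["session"].astype(int)
    validate_responses(df, palette)
    return df


def write_responses(responses: pd.DataFrame, path: str | Path) -> None:
    responses.to_csv(path, index=False)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> list[Path]:
    """Write a synthetic dataset as the CSV fixtures the analysis consumes.

    Emits the response table, per-script similarity norms, shape-feature
    tables and familiarity-carrying inventories, plus a JSON ground-truth
    sidecar with the generating configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    p = outdir / "responses.csv"
    write_responses(dataset.responses, p)
    written.append(p)

    truth_json: dict = {"config": dataclasses.asdict(dataset.config)}
    for script, truth in dataset.ground_truth.items():
        p = outdir / f"norms_{script}.csv"
        truth.norms.to_csv(p)
        written.append(p)
        p = outdir / f"features_{script}.csv"
        truth.features.to_csv(p)
        written.append(p)
        inv = dataset.inventories[script]
        p = outdir / f"inventory_{script}.csv"
        pd.DataFrame(
            {
                "symbol": [g.symbol for g in inv],
                "script": script,
                "position": [g.position for g in inv],
                "name_phonemes": ["|".join(g.name_phonemes) for g in inv],
                "familiarity": [g.familiarity for g in inv],
            }
        ).to_csv(p, index=False)
        written.append(p)
        truth_json[script] = {"familiarity": truth.familiarity}
    p = outdir / "ground_truth.json"
    p.write_text(json.dumps(truth_json, indent=1, default=str))
    written.append(p)
    return written


def _jsonable(obj):
    if isinstance(obj, RegressionResult):
        return _jsonable(obj.to_dict())
    if isinstance(obj, WelchResult):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, BinnedTable):
        return {"n_bins": obj.n_bins, "bin_size": obj.bin_size}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def report_to_jsonable(report: dict) -> dict:
    """Convert a consistency or mapping report into plain JSON types."""
    return _jsonable(report)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_to_jsonable(report), indent=1))


def write_manifest(outdir: str | Path, config: RunConfig) -> Path:
    """Record everything needed to reproduce a run byte-for-byte."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        from importlib.metadata import version

        pkg_version = version("synmap")
    except Exception:  # pragma: no cover - not installed
        pkg_version = "unknown"
    manifest = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "versions": {
            "synmap": pkg_version,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
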