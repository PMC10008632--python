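"""File dialects and run manifests.

One fixed dialect everywhere: 8-bit 0/255 multi-page TIFF for masks,
16-bit for textures; CSV with header rows and unit-suffixed column
names (``_um``, ``_s``, ``_day``) because the source quantities mix
micrometres, seconds, hours and days and unit-suffixed columns prevent
silent mistakes.  Every CLI invocation writes exactly one manifest JSON
echoing the config, seed, versions, paths and warnings.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

__all__ = ["write_stack", "read_stack", "write_csv", "read_csv", "RunManifest"]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a multi-page TIFF (masks as uint8 0/255, textures uint16)."""
    arr = np.asarray(stack)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    tifffile.imwrite(str(path), arr)


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunManifest:
    """Provenance record of one command invocation."""

    command: str
    seed: int | None = None
    config: dict[str, Any] = dc_field(default_factory=dict)
    inputs: list[str] = dc_field(default_factory=list)
    outputs: list[str] = dc_field(default_factory=list)
    warnings: list[str] = dc_field(default_factory=list)
    timings_s: dict[str, float] = dc_field(default_factory=dict)
    results: dict[str, Any] = dc_field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        from smcluster import __version__

        doc = {
            "tool": "smcluster",
            "version": __version__,
            "python": platform.python_version(),
            "created_unix": time.time(),
            "command": self.command,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "warnings": self.warnings,
            "timings_s": self.timings_s,
            "results": self.results,
        }
        Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)
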