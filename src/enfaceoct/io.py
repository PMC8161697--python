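"""File formats and run provenance.

Standard formats only: multi-page TIFF for depth stacks (page k = slab k,
optional trailing coverage-mask page), CSV for tables and thickness
profiles, JSON for configs, grids, truth sidecars and results. Manifests
record config/input hashes, package versions and seeds so deterministic
stages are reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .enface import EnfaceStack
from .geometry import SectorGrid


def write_stack(stack: EnfaceStack, path) -> None:
    """Write an enface stack as multi-page TIFF (float32, one page per slab).

    The coverage mask, if any, is appended as a final uint8 page; stack
    metadata travels in the TIFF description as JSON.
    """
    path = Path(path)
    meta = {
        "normalized": stack.normalized,
        "transverse_scale_um_per_px": stack.transverse_scale_um_per_px,
        "origin_px": list(stack.origin_px),
        "n_slabs": stack.n_slabs,
        "has_coverage": stack.coverage is not None,
        **{k: v for k, v in stack.meta.items() if _json_safe(v)},
    }
    pages = stack.slabs.astype(np.float32)
    with tifffile.TiffWriter(path) as tif:
        tif.write(pages, description=json.dumps(meta))
        if stack.coverage is not None:
            tif.write(stack.coverage.astype(np.uint8))


def read_stack(path) -> EnfaceStack:
    """Read a multi-page TIFF written by :func:`write_stack`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        desc = tif.pages[0].description
        meta = json.loads(desc) if desc else {}
        series = tif.series[0].asarray()
        coverage = None
        if meta.get("has_coverage") and len(tif.series) > 1:
            coverage = tif.series[1].asarray().astype(bool)
    slabs = np.asarray(series, dtype=float)
    if slabs.ndim == 2:
        slabs = slabs[None]
    known = {"normalized", "transverse_scale_um_per_px", "origin_px", "n_slabs", "has_coverage"}
    return EnfaceStack(
        slabs=slabs,
        normalized=bool(meta.get("normalized", False)),
        transverse_scale_um_per_px=float(meta.get("transverse_scale_um_per_px", 10.0)),
        origin_px=tuple(meta.get("origin_px", (0, 0))),
        coverage=coverage,
        meta={k: v for k, v in meta.items() if k not in known},
    )


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_coerce) + "\n")


def _coerce(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    raise TypeError(f"not JSON serializable: {type(v)}")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_grid(grid: SectorGrid, path) -> None:
    write_json(grid.to_dict(), path)


def read_grid(path) -> SectorGrid:
    return SectorGrid.from_dict(read_json(path))


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort(path, require=("eye_id", "group", "sector")) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in require if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table lacks required column(s): {', '.join(missing)}")
    return table


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: dict[str, str], seed=None) -> None:
    """Record run provenance: config hash, input-file hashes, versions, seed."""
    import scipy
    import statsmodels

    from . import __version__

    config_json = json.dumps(config, sort_keys=True, default=_coerce)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs": {name: sha256_of(p) for name, p in inputs.items()},
        "seed": seed,
        "versions": {
            "enfaceoct": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    write_json(manifest, path)
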