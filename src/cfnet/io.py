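"""Artifact I/O: weight snapshots, spike rasters, run manifests."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .simulator import EventStream, Network


def save_weights(net: Network, path: str | Path) -> None:
    """Snapshot learnable state to an .npz with a JSON metadata sidecar.

    Metadata records shapes, the max deviation of row norms from one, and
    the config hash, so a snapshot can be audited without loading it.
    """
    path = Path(path)
    arrays = {"W": net.W}
    if net.d is not None:
        arrays["d"] = net.d
    if net.homeostasis is not None:
        arrays["theta"] = net.homeostasis.values
    np.savez(path, **arrays)
    norms = np.linalg.norm(net.W, axis=1)
    meta = {
        "shape": list(net.W.shape),
        "max_norm_error": float(np.abs(norms - 1.0).max()),
        "config_hash": net.cfg.content_hash(),
        "arrays": sorted(arrays),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_weights(net: Network, path: str | Path) -> None:
    """Restore a snapshot into a network of matching shape."""
    data = np.load(Path(path))
    if data["W"].shape != net.W.shape:
        raise ValueError(
            f"snapshot shape {data['W'].shape} != network {net.W.shape}"
        )
    net.W[:] = data["W"]
    if net.d is not None and "d" in data:
        net.d = data["d"].copy()
    if net.homeostasis is not None and "theta" in data:
        net.homeostasis.values[:] = data["theta"]


def weights_to_csv(net: Network, path: str | Path) -> None:
    np.savetxt(Path(path), net.W, delimiter=",")


def raster_to_csv(stream: EventStream, path: str | Path) -> None:
    """Export captured events as CSV rows (time, unit_id, kind)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time", "unit_id", "kind"])
        writer.writerows(stream.to_rows())


def write_manifest(config: RunConfig, seed: int, out_dir: str | Path) -> Path:
    """Write the run manifest (full config, seed, version) for reproduction."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": seed,
        "cfnet_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
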