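"""Per-subject, per-condition collections of ROI ("scout") time-series epochs.

An :class:`EpochSet` holds, for every subject and each of the two conditions
(``"pre"`` = pre-interictal, ``"rest"`` = resting state), a list of epochs,
each an ``(n_rois, n_samples)`` float matrix sampled at a common rate.

On-disk layout (plain text, UTF-8):

.. code-block:: text

    <root>/
      manifest.json                # fs, roi_labels, subjects, conditions, meta
      sub-001/
        pre.json                   # sidecar: subject, condition, fs, epoch files
        pre_epoch000.csv           # rows = samples, columns = ROIs, header row
        rest.json
        rest_epoch000.csv
      ...

CSV files use '.' decimals and comma separators; floats are written with 17
significant digits and parsed with round-trip precision, so a write/read
cycle is lossless for float64.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("pre", "rest")


@dataclass
class EpochSet:
    """ROI time-series epochs for a two-condition, multi-subject recording."""

    fs: float
    roi_labels: list[str]
    #: subject id -> condition -> list of (n_rois, n_samples) arrays
    data: dict[str, dict[str, list[np.ndarray]]]
    meta: dict = field(default_factory=dict)

    @property
    def subjects(self) -> list[str]:
        return list(self.data.keys())

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def validate(self) -> None:
        for sub, conds in self.data.items():
            for cond, epochs in conds.items():
                if cond not in CONDITIONS:
                    raise ValueError(f"{sub}: unknown condition {cond!r}")
                for k, ep in enumerate(epochs):
                    if ep.ndim != 2 or ep.shape[0] != self.n_rois:
                        raise ValueError(
                            f"{sub}/{cond} epoch {k}: expected {self.n_rois} ROIs, "
                            f"got array of shape {ep.shape}"
                        )


def write_epoch_set(es: EpochSet, path: str | Path) -> Path:
    """Serialize an epoch set to a directory tree of CSV + JSON sidecars."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    es.validate()
    for sub, conds in es.data.items():
        subdir = root / sub
        subdir.mkdir(exist_ok=True)
        for cond, epochs in conds.items():
            files = []
            for k, ep in enumerate(epochs):
                fname = f"{cond}_epoch{k:03d}.csv"
                pd.DataFrame(ep.T, columns=es.roi_labels).to_csv(
                    subdir / fname, index=False, float_format="%.17g")
                files.append(fname)
            sidecar = {
                "subject": sub,
                "condition": cond,
                "fs": es.fs,
                "n_epochs": len(files),
                "epoch_files": files,
            }
            (subdir / f"{cond}.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    manifest = {
        "fs": es.fs,
        "roi_labels": es.roi_labels,
        "subjects": es.subjects,
        "conditions": list(CONDITIONS),
        "meta": es.meta,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return root


def read_epoch_set(path: str | Path) -> EpochSet:
    """Load an epoch set written by :func:`write_epoch_set`.

    Raises a hard error naming the offending file when an epoch's ROI count
    disagrees with the manifest, and ``ValueError("no epochs found ...")`` on
    an empty or unrelated directory.
    """
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise ValueError(f"no epochs found under {root} (missing manifest.json)")
    manifest = json.loads(mpath.read_text())
    roi_labels = list(manifest["roi_labels"])
    data: dict[str, dict[str, list[np.ndarray]]] = {}
    n_total = 0
    for sub in manifest["subjects"]:
        subdir = root / sub
        data[sub] = {}
        for cond in manifest["conditions"]:
            sidecar_path = subdir / f"{cond}.json"
            if not sidecar_path.exists():
                raise ValueError(f"missing sidecar {sidecar_path}")
            sidecar = json.loads(sidecar_path.read_text())
            epochs = []
            for fname in sidecar["epoch_files"]:
                df = pd.read_csv(subdir / fname, float_precision="round_trip")
                if df.shape[1] != len(roi_labels):
                    raise ValueError(
                        f"{subdir / fname}: subject {sub!r} condition {cond!r}: "
                        f"expected {len(roi_labels)} ROI columns, found {df.shape[1]}"
                    )
                epochs.append(df.to_numpy(dtype=float).T)
                n_total += 1
            data[sub][cond] = epochs
    if n_total == 0:
        raise ValueError(f"no epochs found under {root}")
    return EpochSet(fs=float(manifest["fs"]), roi_labels=roi_labels, data=data,
                    meta=manifest.get("meta", {}))
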