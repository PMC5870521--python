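"""File formats: long-format landmark CSV, metadata CSV, symmetry-map JSON.

Landmark CSV is long format with columns ``specimen_id, landmark, x, y, z``
(landmark indices 1-based); a missing landmark is an absent row or a row
with empty coordinate cells.  The symmetry map JSON has 1-based ``paired``
(list of 2-element lists) and ``midline`` (list of ints).  Trees are read
through :meth:`phylomorph.phylo.Phylogeny.from_file` (Newick or NEXUS).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .geometry import LandmarkConfiguration, SymmetryMap

__all__ = [
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_metadata_csv",
    "read_symmetry_json",
    "write_symmetry_json",
]

METADATA_HABITATS = ("marine", "brackish", "fresh")


def write_landmarks_csv(configs: list[LandmarkConfiguration], path) -> None:
    rows = []
    for c in configs:
        for lm in range(c.n_landmarks):
            if c.present_mask[lm]:
                x, y, z = c.coords[lm]
                rows.append((c.specimen_id, lm + 1, repr(float(x)), repr(float(y)),
                             repr(float(z))))
            else:
                rows.append((c.specimen_id, lm + 1, "", "", ""))
    pd.DataFrame(rows, columns=["specimen_id", "landmark", "x", "y", "z"]).to_csv(
        path, index=False
    )


def read_landmarks_csv(path, n_landmarks: int | None = None) -> list[LandmarkConfiguration]:
    """Read long-format landmark data; K is inferred as the maximum landmark
    index unless given.  Absent rows and empty cells both mean missing."""
    df = pd.read_csv(path, dtype={"specimen_id": str})
    required = {"specimen_id", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    df["landmark"] = df["landmark"].astype(int)
    k = int(df["landmark"].max()) if n_landmarks is None else n_landmarks
    if (df["landmark"] < 1).any() or (df["landmark"] > k).any():
        raise ValueError(f"landmark indices must lie in 1..{k}")
    configs = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        if grp["landmark"].duplicated().any():
            dup = grp.loc[grp["landmark"].duplicated(), "landmark"].tolist()
            raise ValueError(f"specimen {sid!r}: duplicate landmark rows {dup}")
        coords = np.zeros((k, 3))
        mask = np.zeros(k, dtype=bool)
        idx = grp["landmark"].to_numpy() - 1
        vals = grp[["x", "y", "z"]].to_numpy(dtype=float)
        present = ~np.isnan(vals).any(axis=1)
        coords[idx[present]] = vals[present]
        mask[idx[present]] = True
        configs.append(LandmarkConfiguration(specimen_id=str(sid), coords=coords,
                                             present_mask=mask))
    return configs


def read_metadata_csv(path, require_habitat: bool = True) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=str).fillna("")
    if "specimen_id" not in meta.columns or "species" not in meta.columns:
        raise ValueError("metadata CSV needs specimen_id and species columns")
    if meta["specimen_id"].duplicated().any():
        dup = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen_id values: {dup}")
    if require_habitat and "habitat" in meta.columns:
        bad = sorted(set(meta["habitat"]) - set(METADATA_HABITATS) - {""})
        if bad:
            raise ValueError(
                f"habitat values {bad} outside controlled vocabulary {METADATA_HABITATS}"
            )
    return meta


def read_symmetry_json(path) -> SymmetryMap:
    with open(path) as fh:
        data = json.load(fh)
    paired = [(int(a) - 1, int(b) - 1) for a, b in data.get("paired", [])]
    midline = [int(m) - 1 for m in data.get("midline", [])]
    return SymmetryMap(paired=tuple(paired), midline=tuple(midline))


def write_symmetry_json(smap: SymmetryMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "paired": [[a + 1, b + 1] for a, b in smap.paired],
                "midline": [m + 1 for m in smap.midline],
            },
            fh,
            indent=2,
        )
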