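"""On-disk segment store.

One directory per dataset containing:

* ``index.jsonl`` — one JSON object per segment (id, beat counts, bsqi,
  sampling parameters);
* ``segments.npz`` — named arrays per segment id: ``{id}/x``,
  ``{id}/centers``, ``{id}/widths``, ``{id}/labels``, ``{id}/beat_idx``;
* ``manifest.json`` — the generation/preprocessing manifest (seed, specs),
  sufficient to regenerate the store exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .boxes import Box1D
from .records import EcgSegment, GtObject

__all__ = ["write_store", "read_store"]


def write_store(path: str | Path, segments: list[EcgSegment],
                manifest: dict | None = None, force: bool = False) -> None:
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not force:
        raise FileExistsError(f"output directory {path} is not empty (use force)")
    path.mkdir(parents=True, exist_ok=True)
    arrays: dict[str, np.ndarray] = {}
    with open(path / "index.jsonl", "w") as fh:
        for k, seg in enumerate(segments):
            sid = f"seg{k:06d}"
            boxes, classes = seg.gt_arrays()
            arrays[f"{sid}/x"] = seg.x
            arrays[f"{sid}/centers"] = boxes[:, 0]
            arrays[f"{sid}/widths"] = boxes[:, 1]
            arrays[f"{sid}/labels"] = classes
            arrays[f"{sid}/beat_idx"] = np.array([b[0] for b in seg.beats], dtype=np.intp)
            row = {
                "id": sid, "source_id": seg.source_id, "fs": seg.fs,
                "duration_s": seg.duration_s, "n_beats": len(seg.objects),
                "n_af": int((classes == 1).sum()), "bsqi": seg.bsqi,
                "polarity_flipped": seg.polarity_flipped,
            }
            fh.write(json.dumps(row) + "\n")
    np.savez_compressed(path / "segments.npz", **arrays)
    if manifest is not None:
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_store(path: str | Path) -> list[EcgSegment]:
    path = Path(path)
    rows = [json.loads(line) for line in (path / "index.jsonl").read_text().splitlines()]
    segments: list[EcgSegment] = []
    with np.load(path / "segments.npz") as arrays:
        for row in rows:
            sid = row["id"]
            x = arrays[f"{sid}/x"]
            centers = arrays[f"{sid}/centers"]
            widths = arrays[f"{sid}/widths"]
            labels = arrays[f"{sid}/labels"].astype(int)
            beat_idx = arrays[f"{sid}/beat_idx"]
            seg = EcgSegment(
                x=x, fs=row["fs"], duration_s=row["duration_s"],
                beats=[(int(i), "N") for i in beat_idx],
                beat_classes=[int(l) for l in labels],
                bsqi=row.get("bsqi"), source_id=row.get("source_id", ""),
                polarity_flipped=row.get("polarity_flipped", False),
                normalized=True,
            )
            seg.objects = [
                GtObject(c=int(c), b=Box1D(float(cx), float(w)))
                for c, cx, w in zip(labels, centers, widths)
            ]
            segments.append(seg)
    return segments
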